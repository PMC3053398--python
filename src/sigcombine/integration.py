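"""Integration of per-set prognostic indices into one risk predictor.

Two complementary views of the R x n PI matrix:

* hierarchical clustering of patients on 1 - Spearman correlation of their
  PI profiles (average linkage, tree cut into two risk groups), and
* principal components analysis of the PI rows (covariance basis by
  default -- higher-variance PIs are assumed to carry more information --
  or correlation basis when a high-variance, weakly-correlated row would
  otherwise dominate PC1), with the PC1 score dichotomized at its median
  (strictly above = high risk).

Null-model rows (identically zero PIs from gene sets without an interior
CV optimum) are excluded before either analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .containers import SurvivalData
from .signature import PIMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Two-cluster patient partition from PI-profile clustering."""

    sample_ids: list[str]
    linkage: np.ndarray
    assignment: np.ndarray  # cluster index 1/2 per patient
    risk_labels: np.ndarray  # "high"/"low" per patient
    event_counts: dict  # cluster index -> (events, size); empty w/o survival


@dataclass
class CombinedPI:
    """PCA combination of the PI matrix and the derived risk grouping."""

    basis: str
    set_names: list[str]
    sample_ids: list[str]
    loadings: np.ndarray  # R x R, orthonormal columns
    variance_fraction: np.ndarray  # non-increasing, sums to 1
    scores: np.ndarray  # components x n
    pc1_median: float
    risk_labels: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variance_fraction) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pc1": self.scores[0],
                "pc2": self.scores[1] if self.scores.shape[0] > 1 else np.nan,
                "risk": self.risk_labels,
            },
            index=self.sample_ids,
        )


def _patient_dissimilarity(pi: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between patient PI profiles.

    A constant profile has undefined rank correlation; its dissimilarity to
    every other patient is set to 1 (logged).
    """
    R, n = pi.shape
    ranks = np.vstack([rankdata(col) for col in pi.T])  # n x R
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("cluster_patients: %d constant PI profiles, "
                    "dissimilarity set to 1", int(constant.sum()))
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.where(sd > 0, sd, 1.0) * np.sqrt(R)
    z = centered / denom[:, None]
    corr = z @ z.T
    corr = np.clip(corr, -1.0, 1.0)
    dis = 1.0 - corr
    dis[constant, :] = 1.0
    dis[:, constant] = 1.0
    np.fill_diagonal(dis, 0.0)
    return dis


def cluster_patients(
    pim: PIMatrix, surv: SurvivalData | None = None
) -> ClusterResult:
    """Average-linkage clustering of patients into two risk groups.

    The cluster with the higher observed event fraction is labeled high
    risk when survival data are supplied; otherwise the cluster with the
    larger mean PI is.
    """
    pim = pim.nonnull()
    if len(pim.set_names) < 2:
        raise ValueError("clustering needs >= 2 non-null PI rows")
    if len(pim.sample_ids) < 3:
        raise ValueError("clustering needs >= 3 patients")
    dis = _patient_dissimilarity(pim.pi)
    # squareform requires exact symmetry; the rank products are symmetric
    # up to round-off
    dis = (dis + dis.T) / 2.0
    linkage = average(squareform(dis, checks=False))
    assignment = fcluster(linkage, t=2, criterion="maxclust")
    if len(np.unique(assignment)) < 2:
        raise RuntimeError("tree cut produced a single cluster")

    stat = {}
    event_counts = {}
    for c in (1, 2):
        members = assignment == c
        if surv is not None:
            sub = surv.subset([s for s, m in zip(pim.sample_ids, members) if m])
            event_counts[c] = (sub.n_events, sub.n)
            stat[c] = sub.n_events / sub.n
        else:
            stat[c] = float(pim.pi[:, members].mean())
    high_cluster = max(stat, key=lambda c: stat[c])
    risk_labels = np.where(assignment == high_cluster, "high", "low")
    return ClusterResult(
        sample_ids=list(pim.sample_ids),
        linkage=linkage,
        assignment=assignment,
        risk_labels=risk_labels,
        event_counts=event_counts,
    )


def trim_for_display(pi: np.ndarray, quantile: float = 0.01) -> np.ndarray:
    """Clamp PI values outside the [q, 1-q] quantiles for heatmap export."""
    lo, hi = np.quantile(pi, [quantile, 1.0 - quantile])
    return np.clip(pi, lo, hi)


def export_heatmap_data(pim: PIMatrix, quantile: float = 0.01) -> pd.DataFrame:
    pim = pim.nonnull()
    return pd.DataFrame(
        trim_for_display(pim.pi, quantile),
        index=pim.set_names,
        columns=pim.sample_ids,
    )


def combine_pca(pim: PIMatrix, basis: str = "covariance") -> CombinedPI:
    """PCA of the PI rows over patients; PC1 oriented toward high risk.

    Eigendecomposition of the R x R covariance (or correlation) matrix of
    the non-null PI rows.  Scores are the loadings applied to the
    row-centered (and, for the correlation basis, row-scaled) PI matrix.
    PC1's sign is fixed so its scores correlate non-negatively with the
    across-set mean PI (eigenvectors are sign-ambiguous; high PC1 must mean
    high predicted risk); lower components get a deterministic
    largest-entry-positive sign.
    """
    if basis not in ("covariance", "correlation"):
        raise ValueError(f"unknown PCA basis {basis!r}")
    pim = pim.nonnull()
    R, n = pim.pi.shape
    if R < 2:
        raise ValueError("PCA combination needs >= 2 non-null PI rows")
    centered = pim.pi - pim.pi.mean(axis=1, keepdims=True)
    if basis == "correlation":
        sd = pim.pi.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant non-null PI row; correlation basis undefined")
        centered = centered / sd[:, None]
    mat = (centered @ centered.T) / (n - 1)
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order]
    variance_fraction = eigval / eigval.sum()
    scores = loadings.T @ centered

    mean_pi = pim.pi.mean(axis=0)
    orient = np.corrcoef(scores[0], mean_pi)[0, 1]
    if np.isfinite(orient) and orient < 0:
        loadings[:, 0] *= -1.0
        scores[0] *= -1.0
    for comp in range(1, R):
        j = int(np.argmax(np.abs(loadings[:, comp])))
        if loadings[j, comp] < 0:
            loadings[:, comp] *= -1.0
            scores[comp] *= -1.0

    pc1_median = float(np.median(scores[0]))
    risk_labels = np.where(scores[0] > pc1_median, "high", "low")
    logger.info("combine_pca(%s): PC1 captures %.1f%% of variance",
                basis, 100 * variance_fraction[0])
    return CombinedPI(
        basis=basis,
        set_names=list(pim.set_names),
        sample_ids=list(pim.sample_ids),
        loadings=loadings,
        variance_fraction=variance_fraction,
        scores=scores,
        pc1_median=pc1_median,
        risk_labels=risk_labels,
    )


def median_cut(
    scores: np.ndarray, median: float | None = None
) -> tuple[np.ndarray, float]:
    """Dichotomize PC1 scores at the (frozen) median: strictly above = high.

    Returns the labels and the median used, so the cut can be reapplied
    deterministically to new patients.
    """
    scores = np.asarray(scores, dtype=float)
    if median is None:
        median = float(np.median(scores))
    return np.where(scores > median, "high", "low"), median
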