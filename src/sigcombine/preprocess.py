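"""Missing-value imputation and per-gene standardization.

Imputation follows the gene-neighbor KNN scheme of Troyanskaya et al.: the
neighbors of a gene are other genes, distances are Euclidean over the
columns observed in both rows, and a missing cell is filled with the
inverse-distance-weighted mean of the k nearest genes observed in that
column (plain unweighted means behind a flag).

Standardization centers and scales each gene row to mean 0 / sd 1 and is
applied independently within each cohort -- training and test each use
their own means and sds, never pooled.  This is what makes predicted
prognostic indices on a test cohort come out roughly centered around zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class StandardizationParams:
    """Per-gene centering/scaling constants (sd with n-1 denominator)."""

    gene_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    source_cohort: str = ""

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("standardization sd must be > 0 for retained genes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd}, index=self.gene_ids
        )


def _pairwise_complete_sqdist(values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance over columns observed in both rows.

    Pairs sharing no observed column get +inf.  Computed with three matrix
    products: sum_c m_i m_j (x_i - x_j)^2 expands into masked square/cross
    terms.
    """
    X = np.where(observed, values, 0.0)
    M = observed.astype(float)
    X2 = X * X
    sq = X2 @ M.T + M @ X2.T - 2.0 * (X @ X.T)
    shared = M @ M.T
    sq = np.maximum(sq, 0.0)  # guard tiny negative round-off
    sq[shared == 0] = np.inf
    return sq


def knn_impute(
    expr: ExpressionMatrix,
    k: int = 10,
    weighted: bool = True,
) -> ExpressionMatrix:
    """Fill missing cells from the k nearest genes observed in that column.

    Observed cells are never changed.  When no candidate neighbor is
    observed in the target column, the gene's own observed mean is used and
    the fallback is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= expr.n_genes:
        raise ValueError(f"k={k} must be smaller than the number of genes "
                         f"({expr.n_genes})")
    observed = ~expr.missing_mask
    zero_obs = np.flatnonzero(observed.sum(axis=1) == 0)
    if zero_obs.size:
        names = [expr.gene_ids[i] for i in zero_obs]
        raise ValueError(f"genes with zero observed values: {names}")
    if not expr.missing_mask.any():
        return ExpressionMatrix(
            gene_ids=list(expr.gene_ids),
            sample_ids=list(expr.sample_ids),
            values=expr.values.copy(),
            missing_mask=np.zeros_like(expr.missing_mask),
        )

    sqdist = _pairwise_complete_sqdist(expr.values, observed)
    np.fill_diagonal(sqdist, np.inf)
    dist = np.sqrt(sqdist)

    out = expr.values.copy()
    row_means = np.array(
        [expr.values[i, observed[i]].mean() for i in range(expr.n_genes)]
    )
    n_fallback = 0
    genes_with_missing = np.flatnonzero(expr.missing_mask.any(axis=1))
    for i in genes_with_missing:
        order = np.argsort(dist[i], kind="stable")
        for j in np.flatnonzero(expr.missing_mask[i]):
            candidates = order[observed[order, j] & np.isfinite(dist[i, order])]
            if candidates.size == 0:
                out[i, j] = row_means[i]
                n_fallback += 1
                continue
            nearest = candidates[:k]
            vals = expr.values[nearest, j]
            if weighted:
                d = dist[i, nearest]
                if np.any(d == 0):  # exact-profile neighbors dominate
                    out[i, j] = vals[d == 0].mean()
                else:
                    w = 1.0 / d
                    out[i, j] = float(np.dot(w, vals) / w.sum())
            else:
                out[i, j] = float(vals.mean())
    if n_fallback:
        logger.info("knn_impute: %d cells fell back to the gene's own mean",
                    n_fallback)
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        values=out,
        missing_mask=np.zeros_like(expr.missing_mask),
    )


def standardize(
    expr: ExpressionMatrix, source_cohort: str = ""
) -> tuple[ExpressionMatrix, StandardizationParams]:
    """Center and scale each gene row to mean 0, sd 1 (n-1 denominator).

    Genes with zero variance are dropped and logged.  Requires a complete
    (imputed) matrix with at least two samples.
    """
    if expr.missing_mask.any():
        raise ValueError("standardize requires a complete matrix; impute first")
    if expr.n_samples < 2:
        raise ValueError("standardize requires >= 2 samples")
    mean = expr.values.mean(axis=1)
    sd = expr.values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if dropped:
        logger.info("standardize: dropped %d constant genes: %s",
                    len(dropped), dropped)
    gene_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    values = (expr.values[keep] - mean[keep, None]) / sd[keep, None]
    params = StandardizationParams(
        gene_ids=gene_ids, mean=mean[keep], sd=sd[keep],
        source_cohort=source_cohort,
    )
    out = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=list(expr.sample_ids),
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
    )
    return out, params
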