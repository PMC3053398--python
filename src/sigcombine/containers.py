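"""Core in-memory containers shared by every pipeline stage.

The pipeline moves three kinds of data around: a genes x samples
log-expression matrix with an explicit missing-value mask, per-sample
right-censored survival outcomes with clinical covariates, and named gene
sets whose identifiers may live in different namespaces (platform clone ids,
UniGene cluster ids, gene symbols, aliases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: identifier namespaces a gene-set entry may use
NAMESPACES = ("clone_id", "unigene", "symbol", "alias", "probe_id")


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Log-ratio expression values, genes in rows, samples in columns.

    ``values`` is float with shape ``(n_genes, n_samples)``; positions where
    ``missing_mask`` is True carry no information (the stored float there is
    NaN by convention).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.values.shape != shape:
            raise ValidationError(
                f"values shape {self.values.shape} != (genes, samples) {shape}"
            )
        if self.missing_mask.shape != shape:
            raise ValidationError("missing_mask shape differs from values shape")
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise ValidationError("non-finite value in an observed (unmasked) cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        values = frame.to_numpy(dtype=float)
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=values,
            missing_mask=np.isnan(values),
        )

    def to_frame(self) -> pd.DataFrame:
        values = self.values.copy()
        values[self.missing_mask] = np.nan
        return pd.DataFrame(values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=self.sample_ids,
            values=self.values[rows],
            missing_mask=self.missing_mask[rows],
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            sample_ids=list(samples),
            values=self.values[:, cols],
            missing_mask=self.missing_mask[:, cols],
        )


@dataclass
class SurvivalData:
    """Right-censored follow-up per sample plus clinical covariates.

    ``time`` is in months and strictly positive; ``event`` is 1 when the
    endpoint (e.g. systemic recurrence or disease-specific death) was
    observed and 0 when the sample was censored at ``time``.
    ``covariates`` holds any extra clinical columns (may contain missing
    levels) indexed by sample id.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        _check_unique(self.sample_ids, "sample ids")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length differs from sample count")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValidationError("follow-up times must be finite and > 0")
        ev = np.unique(self.event)
        if not np.all(np.isin(ev, [0, 1])):
            raise ValidationError(f"event indicator outside {{0,1}}: {ev}")
        self.event = self.event.astype(int)
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=pd.Index(self.sample_ids))
        else:
            self.covariates = self.covariates.reindex(self.sample_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, samples: list[str]) -> "SurvivalData":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples absent from survival data: {missing}")
        rows = [index[s] for s in samples]
        return SurvivalData(
            sample_ids=list(samples),
            time=self.time[rows],
            event=self.event[rows],
            covariates=self.covariates.iloc[rows],
        )


@dataclass
class GeneSet:
    """A named list of genes, each an (identifier, namespace) pair."""

    name: str
    genes: list[tuple[str, str]]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        for ident, ns in self.genes:
            if ns not in NAMESPACES:
                raise ValidationError(
                    f"gene set {self.name!r}: unknown namespace {ns!r} for {ident!r}"
                )

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene-set names")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class RunConfig:
    """Tuning knobs for a pipeline run.

    The penalty grid is strictly positive and increasing; the
    cross-validation scheme is either leave-one-out (``cv_scheme='loo'``) or
    k-fold (``cv_scheme='kfold'`` with ``cv_k >= 2``); the PCA combination
    may use the covariance or the correlation matrix of the PI rows.
    """

    lambda_min: float = 1.0
    lambda_max: float = 1e5
    lambda_points: int = 40
    lambda_log: bool = True
    cv_scheme: str = "loo"
    cv_k: int = 10
    pca_basis: str = "covariance"
    seed: int = 0
    endpoint: str = "event"
    trim_quantile: float = 0.01
    knn_k: int = 10
    record_timestamps: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.lambda_min < self.lambda_max):
            raise ValidationError("lambda grid must satisfy 0 < min < max")
        if self.lambda_points < 2:
            raise ValidationError("lambda grid needs >= 2 points")
        if self.cv_scheme not in ("loo", "kfold"):
            raise ValidationError(f"unknown CV scheme {self.cv_scheme!r}")
        if self.cv_scheme == "kfold" and self.cv_k < 2:
            raise ValidationError("kfold CV requires k >= 2")
        if self.pca_basis not in ("covariance", "correlation"):
            raise ValidationError(f"unknown PCA basis {self.pca_basis!r}")
        if not (0 <= self.trim_quantile < 0.5):
            raise ValidationError("trim quantile must be in [0, 0.5)")

    @property
    def lambda_grid(self) -> np.ndarray:
        if self.lambda_log:
            return np.geomspace(self.lambda_min, self.lambda_max, self.lambda_points)
        return np.linspace(self.lambda_min, self.lambda_max, self.lambda_points)


def align_samples(
    expr: ExpressionMatrix, surv: SurvivalData
) -> tuple[ExpressionMatrix, SurvivalData]:
    """Intersect an expression matrix and survival table on sample ids.

    Order follows the expression matrix.  Dropped ids on either side are
    reported at INFO level.
    """
    common = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
    dropped_expr = sorted(set(expr.sample_ids) - set(common))
    dropped_surv = sorted(set(surv.sample_ids) - set(common))
    if dropped_expr:
        logger.info("align_samples: dropped %d expression-only samples: %s",
                    len(dropped_expr), dropped_expr)
    if dropped_surv:
        logger.info("align_samples: dropped %d survival-only samples: %s",
                    len(dropped_surv), dropped_surv)
    if not common:
        raise ValidationError("no samples in common between expression and survival data")
    return expr.subset_samples(common), surv.subset(common)
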