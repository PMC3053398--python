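"""From fitted gene-set models to test-cohort prognostic indices.

A fitted model's prognostic index for test patient i is the weighted sum
PI_i = sum_k beta_k x_ik over the model's genes present in the
(independently standardized) test matrix -- a log relative hazard up to an
additive constant.  Predictive value on the test cohort is summarized by
the change in deviance against the no-gene null model, and clinical calls
are made by dichotomizing the PI at zero (strictly positive = high risk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalData
from .coxridge import CoxRidgeModel, partial_loglik

logger = logging.getLogger(__name__)


@dataclass
class PIMatrix:
    """Gene sets x test patients grid of predicted prognostic indices."""

    set_names: list[str]
    sample_ids: list[str]
    pi: np.ndarray
    status: list[str]  # per set: "converged" | "null_model"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("PI grid shape inconsistent with labels")
        for row, st in zip(self.pi, self.status):
            if st == "null_model" and np.any(row != 0):
                raise ValueError("null-model PI row must be identically 0")

    @property
    def sd(self) -> np.ndarray:
        """Per-set sample sd of the PI row (0 exactly for null models)."""
        out = self.pi.std(axis=1, ddof=1)
        out[np.array(self.status) == "null_model"] = 0.0
        return out

    def nonnull(self) -> "PIMatrix":
        keep = [i for i, st in enumerate(self.status) if st != "null_model"]
        return PIMatrix(
            set_names=[self.set_names[i] for i in keep],
            sample_ids=list(self.sample_ids),
            pi=self.pi[keep],
            status=[self.status[i] for i in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pi, index=self.set_names, columns=self.sample_ids)


def predict_pi(model: CoxRidgeModel, test_expr: ExpressionMatrix) -> np.ndarray:
    """PI_i = sum_k beta_k x_ik over model genes retained in the test matrix.

    Model genes absent from the test matrix are dropped with a warning and
    their weights excluded; if fewer than 50% of the model's genes are
    present the prediction is meaningless and an error is raised.  A null
    model predicts all zeros.
    """
    if model.is_null:
        return np.zeros(test_expr.n_samples)
    present = [g for g in model.gene_ids if g in set(test_expr.gene_ids)]
    missing = [g for g in model.gene_ids if g not in set(test_expr.gene_ids)]
    if len(present) < 0.5 * len(model.gene_ids):
        raise ValueError(
            f"only {len(present)}/{len(model.gene_ids)} model genes present "
            "in the test matrix (< 50%); prediction refused"
        )
    if missing:
        logger.warning("predict_pi: %d model genes absent from test matrix, "
                       "weights excluded: %s", len(missing), missing)
    keep = [i for i, g in enumerate(model.gene_ids) if g in set(present)]
    sub = test_expr.subset_genes([model.gene_ids[i] for i in keep])
    if sub.missing_mask.any():
        raise ValueError("test matrix must be imputed before prediction")
    return model.beta[keep] @ sub.values


def build_pi_matrix(
    models: dict[str, CoxRidgeModel], test_expr: ExpressionMatrix
) -> PIMatrix:
    names = list(models)
    pi = np.vstack([predict_pi(models[n], test_expr) for n in names])
    return PIMatrix(
        set_names=names,
        sample_ids=list(test_expr.sample_ids),
        pi=pi,
        status=[models[n].status for n in names],
    )


def delta_deviance(
    model: CoxRidgeModel,
    test_expr: ExpressionMatrix,
    test_surv: SurvivalData,
) -> float:
    """Change in deviance on the test cohort: -2 [l(beta_hat) - l(0)].

    The training-derived weights are plugged into the test-cohort partial
    likelihood with no refitting, so this is a pure prediction metric:
    negative values indicate predictive gain, positive values a model that
    transfers poorly.  Null models score exactly 0.
    """
    if test_surv.n_events == 0:
        raise ValueError("test cohort has no events")
    if model.is_null:
        return 0.0
    present = [g for g in model.gene_ids if g in set(test_expr.gene_ids)]
    keep = [i for i, g in enumerate(model.gene_ids) if g in set(present)]
    sub = test_expr.subset_genes([model.gene_ids[i] for i in keep])
    expr_aligned, surv_aligned = _align(sub, test_surv)
    X = expr_aligned.values.T
    beta = model.beta[keep]
    l1 = partial_loglik(beta, X, surv_aligned)
    l0 = partial_loglik(np.zeros_like(beta), X, surv_aligned)
    return -2.0 * (l1 - l0)


def _align(expr: ExpressionMatrix, surv: SurvivalData):
    from .containers import align_samples

    return align_samples(expr, surv)


def dichotomize_pi(pi: np.ndarray) -> np.ndarray:
    """Risk labels from PI sign: strictly positive = 'high', else 'low'."""
    pi = np.asarray(pi, dtype=float)
    return np.where(pi > 0, "high", "low")


@dataclass
class SignatureReport:
    """Per-set test-cohort prediction characteristics."""

    set_names: list[str]
    delta_deviance: np.ndarray
    pi_sd: np.ndarray
    logrank_p: np.ndarray  # NaN when the dichotomized groups degenerate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_deviance": self.delta_deviance,
                "pi_sd": self.pi_sd,
                "logrank_p": self.logrank_p,
            },
            index=self.set_names,
        )


def summarize_signatures(
    models: dict[str, CoxRidgeModel],
    pim: PIMatrix,
    test_expr: ExpressionMatrix,
    test_surv: SurvivalData,
) -> SignatureReport:
    """Table of delta deviance, PI sd and dichotomous logrank p per set."""
    from .evaluation import logrank_test

    dd = []
    lrp = []
    surv = test_surv.subset(pim.sample_ids)
    for name, row, status in zip(pim.set_names, pim.pi, pim.status):
        dd.append(delta_deviance(models[name], test_expr, test_surv))
        labels = dichotomize_pi(row)
        if status == "null_model" or len(np.unique(labels)) < 2:
            lrp.append(np.nan)
        else:
            _, _, p = logrank_test(surv, labels)
            lrp.append(p)
    return SignatureReport(
        set_names=list(pim.set_names),
        delta_deviance=np.asarray(dd),
        pi_sd=pim.sd,
        logrank_p=np.asarray(lrp),
    )
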