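"""L2-penalized Cox regression with cross-validated penalty selection.

The model is Cox proportional hazards: h(t | x) = h0(t) exp(x'beta), so the
relative hazard between two patients is constant over time and the baseline
hazard cancels from the partial likelihood.  With gene-expression
covariates p is comparable to or larger than n, so beta is estimated by
maximizing the penalized partial log-likelihood

    l_pen(beta) = l(beta) - (lambda / 2) * ||beta||_2^2

by Newton-Raphson with step halving.  Ties are handled with the Breslow
approximation (tied event times share one risk set).  The penalty weight
lambda is chosen by maximizing the Verweij-van Houwelingen cross-validated
partial log-likelihood

    CV(lambda) = sum_folds [ l(beta_{-f}) - l_{-f}(beta_{-f}) ]

where l is the full-data partial log-likelihood and l_{-f} omits fold f.
When CV has no interior maximum on the grid the data support no covariate
effect at any admissible penalty and the gene set is assigned the null
model (beta = 0, lambda = +inf sentinel).

Note the absolute scale of lambda under this (lambda/2)*sum(beta^2)
convention depends on the data and on the penalty convention; only the
shape of the CV profile and the selected model are transferable across
conventions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .containers import SurvivalData

logger = logging.getLogger(__name__)

_GRAD_TOL = 1e-6
_MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """Newton iteration hit the cap; carries the last gradient max-norm."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm


@dataclass
class CoxRidgeModel:
    """A fitted gene-set model (weights in per-standardized-expression units)."""

    gene_ids: list[str]
    beta: np.ndarray
    lam: float  # +inf sentinel for the null model
    status: str  # "converged" | "null_model"
    train_loglik: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.gene_ids):
            raise ValueError("beta length differs from gene count")
        if self.status == "null_model" and np.any(self.beta != 0):
            raise ValueError("null model must have all-zero beta")

    @property
    def is_null(self) -> bool:
        return self.status == "null_model"


@dataclass
class CVProfile:
    """Cross-validated likelihood over a lambda grid."""

    lambda_grid: np.ndarray
    cvpl: np.ndarray
    lambda_opt: float | None
    n_skipped_folds: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lambda": self.lambda_grid, "cvpl": self.cvpl})


def _loglik_parts(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    need_grad: bool = False,
    need_hess: bool = False,
):
    """Breslow partial log-likelihood, gradient and Hessian of l(beta).

    Risk sets are suffixes of the ascending time order; tied event times
    share the risk set anchored at the first index of their tie group.
    Fully vectorized over tie groups; the n x p x p cumulant needed for the
    Hessian falls back to a per-group loop when p is large.
    """
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order].astype(bool)
    Xs = X[order]
    eta = Xs @ beta
    c = float(eta.max()) if len(eta) else 0.0
    w = np.exp(eta - c)

    n, p = Xs.shape
    # tie-group structure: start index of each group and events per group
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    np.not_equal(t[1:], t[:-1], out=new_group[1:])
    group_id = np.cumsum(new_group) - 1
    starts = np.flatnonzero(new_group)
    d = np.bincount(group_id, weights=e).astype(float)  # events per group
    ev_groups = np.flatnonzero(d > 0)
    if ev_groups.size == 0:
        zero_g = np.zeros(p) if need_grad else None
        zero_h = np.zeros((p, p)) if need_hess else None
        return 0.0, zero_g, zero_h

    S0_rev = np.cumsum(w[::-1])[::-1]
    S0 = S0_rev[starts[ev_groups]]
    d_ev = d[ev_groups]
    loglik = float(eta[e].sum()) - float(d_ev @ (np.log(S0) + c))
    grad = None
    hess = None
    if need_grad or need_hess:
        S1_rev = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        xbar = S1_rev[starts[ev_groups]] / S0[:, None]
    if need_grad:
        grad = Xs[e].sum(axis=0) - d_ev @ xbar
    if need_hess:
        if p * p * n <= 2_000_000:
            Z = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
            S2_rev = np.cumsum(Z[::-1], axis=0)[::-1]
            S2 = S2_rev[starts[ev_groups]] / S0[:, None, None]
            hess = -(
                np.einsum("t,tij->ij", d_ev, S2)
                - np.einsum("t,ti,tj->ij", d_ev, xbar, xbar)
            )
        else:
            hess = np.zeros((p, p))
            # accumulate the weighted Gram matrix from the largest times down
            S2 = np.zeros((p, p))
            boundary = len(starts)  # rows >= this index already absorbed
            for gi in ev_groups[::-1]:
                lo = starts[gi]
                hi = starts[boundary] if boundary < len(starts) else n
                rows = Xs[lo:hi]
                S2 += (rows * w[lo:hi, None]).T @ rows
                boundary = gi
                s0 = S0_rev[lo]
                xb = S1_rev[lo] / s0
                hess -= d[gi] * (S2 / s0 - np.outer(xb, xb))
    return loglik, grad, hess


def partial_loglik(
    beta: np.ndarray, X: np.ndarray, surv: SurvivalData
) -> float:
    """Breslow partial log-likelihood l(beta) on one cohort."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariate matrix contains non-finite values")
    if X.shape != (surv.n, len(beta)):
        raise ValueError(f"X shape {X.shape} does not match "
                         f"(n={surv.n}, p={len(beta)})")
    if surv.n_events == 0:
        raise ValueError("partial likelihood undefined with no events")
    loglik, _, _ = _loglik_parts(beta, X, surv.time, surv.event)
    return loglik


def fit_cox_ridge(
    X: np.ndarray,
    surv: SurvivalData,
    lam: float,
    gene_ids: list[str] | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _GRAD_TOL,
) -> CoxRidgeModel:
    """Maximize l(beta) - (lam/2)||beta||^2 by step-halving Newton.

    Deterministic from its inputs; converged when the penalized gradient
    max-norm is <= ``tol``.  ``lam`` may be 0 for ordinary Cox regression
    (used by the evaluation suite); the Hessian must then be nonsingular.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if gene_ids is None:
        gene_ids = [f"x{i}" for i in range(p)]
    if surv.n_events == 0:
        raise ValueError("cannot fit a Cox model with no events")
    beta, ll = _fit_ridge_raw(X, surv.time, surv.event, lam, beta0=beta0,
                              max_iter=max_iter, tol=tol)
    return CoxRidgeModel(
        gene_ids=list(gene_ids), beta=beta, lam=lam,
        status="converged", train_loglik=ll,
    )


def _fit_ridge_raw(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _GRAD_TOL,
) -> tuple[np.ndarray, float]:
    """Array-level ridge Newton; returns (beta_hat, unpenalized loglik)."""
    n, p = X.shape
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eye = np.eye(p)

    def objective(b):
        ll, _, _ = _loglik_parts(b, X, time, event)
        return ll - 0.5 * lam * float(b @ b)

    obj = objective(beta)
    grad_norm = np.inf
    for _ in range(max_iter):
        ll, grad, hess = _loglik_parts(
            beta, X, time, event, need_grad=True, need_hess=True
        )
        pen_grad = grad - lam * beta
        grad_norm = float(np.max(np.abs(pen_grad)))
        if grad_norm <= tol:
            return beta, ll
        # Newton direction: solve (-H + lam I) step = penalized gradient
        A = -hess + lam * eye
        try:
            step = np.linalg.solve(A, pen_grad)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular Hessian in Cox-ridge Newton step"
            ) from None
        if not np.all(np.isfinite(step)):
            raise np.linalg.LinAlgError("non-finite Newton step (singular system)")
        # step halving on the penalized objective
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        obj = objective(beta)
    raise ConvergenceError(
        f"Cox-ridge did not converge in {max_iter} iterations "
        f"(last penalized gradient max-norm {grad_norm:.3e})",
        grad_norm,
    )


def make_folds(
    n: int, scheme: str, k: int = 10, seed: int | None = 0
) -> list[np.ndarray]:
    """Fold index arrays: singletons for LOO, seeded permutation for k-fold."""
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        if k < 2:
            raise ValueError("kfold requires k >= 2")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return [np.sort(part) for part in np.array_split(perm, k)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cvpl(
    X: np.ndarray,
    surv: SurvivalData,
    lam: float,
    scheme: str = "loo",
    k: int = 10,
    seed: int | None = 0,
    folds: list[np.ndarray] | None = None,
    warm_betas: list[np.ndarray] | None = None,
) -> float:
    """Verweij-van Houwelingen cross-validated partial log-likelihood.

    CV(lambda) = sum_f [ l(beta_{-f}) - l_{-f}(beta_{-f}) ], with l the
    full-data partial log-likelihood.  Fold assignment is the only source
    of randomness (none for LOO).  A fold whose removal leaves zero events
    is skipped with a warning.  ``warm_betas`` (mutated in place) lets a
    grid search warm-start each fold's Newton iteration at the previous
    lambda's solution.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if folds is None:
        folds = make_folds(n, scheme, k=k, seed=seed)
    time, event = surv.time, surv.event
    total = 0.0
    skipped = 0
    for f_idx, fold in enumerate(folds):
        keep = np.setdiff1d(np.arange(n), fold)
        if event[keep].sum() == 0:
            skipped += 1
            continue
        beta0 = warm_betas[f_idx] if warm_betas is not None else None
        beta, l_without = _fit_ridge_raw(
            X[keep], time[keep], event[keep], lam, beta0=beta0
        )
        if warm_betas is not None:
            warm_betas[f_idx] = beta
        l_full, _, _ = _loglik_parts(beta, X, time, event)
        total += l_full - l_without
    if skipped:
        logger.warning("cvpl: skipped %d/%d folds with no remaining events",
                       skipped, len(folds))
    return total


def select_lambda(
    X: np.ndarray,
    surv: SurvivalData,
    grid: np.ndarray,
    scheme: str = "loo",
    k: int = 10,
    seed: int | None = 0,
) -> CVProfile:
    """Maximize CV(lambda) over a grid; null model on boundary behavior.

    The optimum must be interior with respect to the upper grid end: if the
    argmax sits on the largest lambda, or the profile is monotone
    non-decreasing, the cross-validation function has no maximum in the
    search range and ``lambda_opt`` is None (downstream builds a null
    model).
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 5:
        raise ValueError("lambda grid needs >= 5 points")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be strictly positive and increasing")
    n = np.asarray(X).shape[0]
    folds = make_folds(n, scheme, k=k, seed=seed)
    warm: list[np.ndarray | None] = [None] * len(folds)
    values = np.empty(len(grid))
    # descend the grid (strong penalty first) so warm starts stay stable
    for idx in range(len(grid) - 1, -1, -1):
        values[idx] = cvpl(
            X, surv, grid[idx], folds=folds, warm_betas=warm
        )
    argmax = int(np.argmax(values))
    monotone = bool(np.all(np.diff(values) >= -1e-12))
    if argmax == len(grid) - 1 or monotone:
        lambda_opt = None
    else:
        lambda_opt = float(grid[argmax])
    logger.info("select_lambda: argmax index %d/%d, lambda_opt=%s",
                argmax, len(grid) - 1, lambda_opt)
    return CVProfile(lambda_grid=grid, cvpl=values, lambda_opt=lambda_opt)


def fit_gene_set(
    X: np.ndarray,
    surv: SurvivalData,
    gene_ids: list[str],
    grid: np.ndarray,
    scheme: str = "loo",
    k: int = 10,
    seed: int | None = 0,
) -> tuple[CoxRidgeModel, CVProfile]:
    """Penalty selection plus final fit; null model when no interior optimum."""
    profile = select_lambda(X, surv, grid, scheme=scheme, k=k, seed=seed)
    if profile.lambda_opt is None:
        l0 = partial_loglik(np.zeros(len(gene_ids)), X, surv)
        model = CoxRidgeModel(
            gene_ids=list(gene_ids),
            beta=np.zeros(len(gene_ids)),
            lam=math.inf,
            status="null_model",
            train_loglik=l0,
        )
    else:
        model = fit_cox_ridge(X, surv, profile.lambda_opt, gene_ids=gene_ids)
    return model, profile
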