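"""Survival-statistics suite for comparing risk predictors.

Implements the comparison battery applied to every predictor (clinical or
gene-expression derived): Kaplan-Meier curves, the two-sample logrank
test, ordinary (unpenalized, optionally stratified) Cox regression with
likelihood-ratio and Wald inference, deviance and a likelihood-ratio R^2
as the proportion of variation explained (PVE), Harrell's concordance
index, Fisher's exact odds ratio, AIC-guided hybrid stepwise model
selection, and the Grambsch-Therneau proportional-hazards diagnostic on
scaled Schoenfeld residuals.

The unpenalized Cox fits reuse the penalized core at lambda = 0; a
monotone likelihood (perfect separation) surfaces as a flagged,
non-converged result rather than a silent estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .containers import SurvivalData
from .coxridge import ConvergenceError, _loglik_parts, fit_cox_ridge

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier and logrank


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(
    surv: SurvivalData, groups: np.ndarray | None = None
) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group (single group when labels omitted)."""
    if groups is None:
        groups = np.array(["all"] * surv.n)
    groups = np.asarray(groups)
    out: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[sel], surv.event[sel])
        table = kmf.event_table
        sf = kmf.survival_function_.iloc[:, 0]
        out[str(g)] = KMCurve(
            group=str(g),
            times=table.index.to_numpy(dtype=float),
            survival=sf.to_numpy(dtype=float),
            at_risk=table["at_risk"].to_numpy(dtype=float),
            events=table["observed"].to_numpy(dtype=float),
        )
    return out


def logrank_test(
    surv: SurvivalData, groups: np.ndarray
) -> tuple[float, int, float]:
    """Two-sample logrank test: (chi2, df=1, p).

    At each distinct event time the observed group-1 event count is
    compared with its hypergeometric expectation given the risk sets.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"logrank test needs exactly 2 groups, got {len(levels)}")
    if surv.n_events == 0:
        raise ValueError("logrank test needs >= 1 event")
    in1 = groups == levels[0]
    time, event = surv.time, surv.event
    event_times = np.unique(time[event == 1])
    O_minus_E = 0.0
    V = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & in1).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1, 1.0
    chi2 = O_minus_E**2 / V
    return float(chi2), 1, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# ordinary Cox fits (lambda = 0 through the penalized core)


@dataclass
class CoxFit:
    """An unpenalized (optionally stratified) Cox fit with its curvature."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray  # inverse observed information at beta_hat
    loglik: float
    loglik0: float
    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    strata: np.ndarray | None = None
    converged: bool = True

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.X @ self.beta

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)


def _strat_loglik_parts(beta, X, time, event, strata, need_grad=False,
                        need_hess=False):
    if strata is None:
        return _loglik_parts(beta, X, time, event, need_grad, need_hess)
    loglik = 0.0
    grad = np.zeros_like(beta) if need_grad else None
    hess = np.zeros((len(beta), len(beta))) if need_hess else None
    for s in pd.unique(strata):
        sel = strata == s
        ll, g, h = _loglik_parts(beta, X[sel], time[sel], event[sel],
                                 need_grad, need_hess)
        loglik += ll
        if need_grad:
            grad += g
        if need_hess:
            hess += h
    return loglik, grad, hess


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    names: list[str] | None = None,
    strata: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> CoxFit:
    """Unpenalized Cox fit sharing one beta across strata.

    Each stratum keeps its own baseline hazard (its own risk sets); strata
    without events are dropped with a warning.  Non-convergence or a
    singular information matrix yields ``converged=False`` with NaN
    estimates rather than a silent answer.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if strata is not None:
        strata = np.asarray(strata)
        keep = np.ones(n, dtype=bool)
        for s in pd.unique(strata):
            sel = strata == s
            if event[sel].sum() == 0:
                logger.warning("fit_cox: stratum %r has no events; dropped", s)
                keep &= ~sel
        X, time, event, strata = X[keep], time[keep], event[keep], strata[keep]
        n = len(time)
    if event.sum() == 0:
        raise ValueError("no events; Cox fit undefined")

    beta = np.zeros(p)
    loglik0, _, _ = _strat_loglik_parts(beta, X, time, event, strata)
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _strat_loglik_parts(
            beta, X, time, event, strata, need_grad=True, need_hess=True
        )
        if float(np.max(np.abs(grad))) <= tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)) or np.max(np.abs(beta + step)) > 50:
            # monotone likelihood / perfect separation escape
            break
        new_beta = beta + step
        new_ll, _, _ = _strat_loglik_parts(new_beta, X, time, event, strata)
        scale = 1.0
        while not (np.isfinite(new_ll) and new_ll >= ll - 1e-12) and scale > 1e-8:
            scale *= 0.5
            new_beta = beta + scale * step
            new_ll, _, _ = _strat_loglik_parts(new_beta, X, time, event, strata)
        beta = new_beta
    ll, _, hess = _strat_loglik_parts(
        beta, X, time, event, strata, need_grad=True, need_hess=True
    )
    if converged and len(beta) and np.std(X @ beta) > 10:
        # a fitted log-relative-hazard spread this extreme signals a
        # monotone likelihood (perfect separation): beta is drifting to
        # infinity even though the gradient has flattened out
        converged = False
    if converged:
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            converged = False
            cov = np.full((p, p), np.nan)
    else:
        cov = np.full((p, p), np.nan)
        beta = np.full(p, np.nan)
        ll = np.nan
        logger.warning("fit_cox: non-convergence (monotone likelihood or "
                       "singular information); flagged result")
    return CoxFit(
        names=list(names), beta=beta, cov=cov, loglik=float(ll),
        loglik0=float(loglik0), X=X, time=time, event=event, strata=strata,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# scalar performance measures


def pve(l0: float, l1: float, n: int) -> float:
    """Likelihood-ratio R^2: 1 - exp(-2 (l1 - l0) / n), in [0, 1).

    ``n`` is the number of subjects.  0 iff the fit adds nothing; strictly
    increasing in the log-likelihood gain.
    """
    if l1 < l0 - 1e-10:
        raise ValueError(f"l1={l1} < l0={l0}: fitted model worse than null")
    return float(1.0 - math.exp(-2.0 * max(l1 - l0, 0.0) / n))


def concordance_index(pi: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's C over usable pairs.

    A pair is usable when its members can be ordered under censoring: the
    earlier time is an observed event and the times differ.  Concordant
    (higher predicted risk fails first) scores 1, a tied prediction 0.5.
    """
    pi = np.asarray(pi, dtype=float)
    time, event = surv.time, surv.event
    t_i = time[:, None]
    usable = (t_i < time[None, :]) & (event[:, None] == 1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    diff = pi[:, None] - pi[None, :]
    concordant = (usable & (diff > 0)).sum()
    tied = (usable & (diff == 0)).sum()
    return float((concordant + 0.5 * tied) / n_usable)


def fisher_exact_or(table) -> tuple[float, tuple[float, float], float]:
    """Conditional-MLE odds ratio, exact 95% CI and exact two-sided p.

    The odds ratio maximizes the noncentral hypergeometric likelihood; the
    CI inverts the one-sided exact tests; the two-sided p sums hypergeometric
    outcomes no more probable than the observed table.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = _scipy_odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), (float(ci.low), float(ci.high)), float(p)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic


def ph_test(fit: CoxFit) -> tuple[dict[str, float], float]:
    """Grambsch-Therneau test on scaled Schoenfeld residuals.

    Correlates each covariate's scaled Schoenfeld residuals with
    Kaplan-Meier-transformed event time; returns per-covariate p-values
    and a global chi-square p across covariates.
    """
    if not fit.converged:
        raise ValueError("ph_test requires a converged fit")
    d_total = fit.n_events
    if d_total < 3:
        raise ValueError("too few events (<3) for the PH diagnostic")
    # KM transform of time, from the whole fitted sample
    kmf = KaplanMeierFitter()
    kmf.fit(fit.time, fit.event)
    km_at = kmf.survival_function_.iloc[:, 0]

    resid_rows = []
    g_values = []
    strata = fit.strata if fit.strata is not None else np.zeros(len(fit.time))
    for s in pd.unique(strata):
        sel = strata == s
        X, time, event = fit.X[sel], fit.time[sel], fit.event[sel]
        eta = X @ fit.beta
        w = np.exp(eta - eta.max())
        order = np.argsort(time, kind="mergesort")
        Xs, ts, es, ws = X[order], time[order], event[order], w[order]
        S0_rev = np.cumsum(ws[::-1])[::-1]
        S1_rev = np.cumsum((ws[:, None] * Xs)[::-1], axis=0)[::-1]
        # anchor of each tie group
        starts = np.zeros(len(ts), dtype=int)
        for i in range(1, len(ts)):
            starts[i] = starts[i - 1] if ts[i] == ts[starts[i - 1]] else i
        for i in np.flatnonzero(es == 1):
            s0 = S0_rev[starts[i]]
            xbar = S1_rev[starts[i]] / s0
            resid_rows.append(Xs[i] - xbar)
            g_values.append(1.0 - float(km_at.asof(ts[i])))
    r = np.vstack(resid_rows)  # d x p
    g = np.asarray(g_values)
    w_t = g - g.mean()
    ssw = float(w_t @ w_t)
    if ssw == 0:
        raise ValueError("degenerate time transform (all events tied)")
    u = w_t @ r  # p-vector
    V = fit.cov
    vu = V @ u
    per_cov = {}
    for k, name in enumerate(fit.names):
        chi2_k = d_total * vu[k] ** 2 / (V[k, k] * ssw)
        per_cov[name] = float(stats.chi2.sf(chi2_k, df=1))
    chi2_g = d_total * float(u @ vu) / ssw
    global_p = float(stats.chi2.sf(chi2_g, df=len(fit.names)))
    return per_cov, global_p


# ---------------------------------------------------------------------------
# design-matrix construction and predictor summaries


def _encode(predictor, name: str = "predictor",
            reference: str | None = None) -> pd.DataFrame:
    """Numeric column as-is; categorical dummy-coded against a reference.

    Levels sort alphabetically, except that 'low' is preferred as the
    reference so two-level risk predictors report high-vs-low hazard
    ratios.
    """
    s = pd.Series(predictor)
    if pd.api.types.is_numeric_dtype(s):
        return pd.DataFrame({name: s.astype(float).to_numpy()})
    levels = sorted(s.dropna().unique())
    if reference is None:
        reference = "low" if "low" in levels else levels[0]
    cols = {}
    for lev in levels:
        if lev != reference:
            cols[f"{name}:{lev} (vs {reference})"] = (s == lev).astype(float).to_numpy()
    out = pd.DataFrame(cols)
    out[s.isna().to_numpy()] = np.nan
    return out


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    parts = [_encode(covariates[c], name=str(c)) for c in covariates.columns]
    return pd.concat(parts, axis=1)


@dataclass
class EvaluationSummary:
    """One predictor's row of the comparison table."""

    name: str
    n: int
    n_events: int
    converged: bool
    lrt_p: float = np.nan
    deviance: float = np.nan
    pve: float = np.nan
    c_index: float = np.nan
    hr: dict = field(default_factory=dict)  # term -> (hr, lo, hi, wald_p)
    ph_p: dict = field(default_factory=dict)
    ph_global_p: float = np.nan
    aic: float = np.nan
    partial_pve: dict = field(default_factory=dict)
    fit: CoxFit | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "covariate": self.name,
                "term": "(overall effect)",
                "p": self.lrt_p,
                "PVE": self.pve,
                "Deviance": self.deviance,
                "C": self.c_index,
                "HR": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        ]
        for term, (hr, lo, hi, wp) in self.hr.items():
            rows.append(
                {
                    "covariate": self.name,
                    "term": term,
                    "p": wp,
                    "PVE": np.nan,
                    "Deviance": np.nan,
                    "C": np.nan,
                    "HR": hr,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def _wald_terms(fit: CoxFit) -> dict:
    out = {}
    se = np.sqrt(np.diag(fit.cov))
    with np.errstate(over="ignore"):
        for name, b, s in zip(fit.names, fit.beta, se):
            z = b / s
            out[name] = (
                float(np.exp(b)),
                float(np.exp(b - 1.959963984540054 * s)),
                float(np.exp(b + 1.959963984540054 * s)),
                float(2.0 * stats.norm.sf(abs(z))),
            )
    return out


def univariate_cox(
    surv: SurvivalData,
    predictor,
    name: str = "predictor",
    reference: str | None = None,
) -> EvaluationSummary:
    """Unpenalized Cox fit of one predictor with the full measure battery.

    Reports the likelihood-ratio p for the overall effect, deviance
    2[l(beta) - l(0)], PVE, Harrell's C on the fitted linear predictor,
    per-level hazard ratios with Wald 95% CIs, and the PH diagnostic.
    """
    design = _encode(predictor, name=name, reference=reference)
    keep = ~design.isna().any(axis=1).to_numpy()
    if not keep.all():
        logger.info("univariate_cox[%s]: dropped %d samples with missing "
                    "predictor", name, int((~keep).sum()))
    X = design.to_numpy()[keep]
    if X.shape[1] == 0 or np.all(X == X[0], axis=0).all():
        raise ValueError(f"predictor {name!r} is constant")
    time, event = surv.time[keep], surv.event[keep]
    fit = fit_cox(X, time, event, names=list(design.columns))
    n = int(keep.sum())
    summary = EvaluationSummary(
        name=name, n=n, n_events=int(event.sum()), converged=fit.converged,
        fit=fit,
    )
    if not fit.converged:
        return summary
    dev = 2.0 * (fit.loglik - fit.loglik0)
    summary.deviance = float(dev)
    summary.lrt_p = float(stats.chi2.sf(dev, df=X.shape[1]))
    summary.pve = pve(fit.loglik0, fit.loglik, n)
    sub = SurvivalData(
        sample_ids=[surv.sample_ids[i] for i in np.flatnonzero(keep)],
        time=time, event=event,
    )
    summary.c_index = concordance_index(fit.linear_predictor, sub)
    summary.hr = _wald_terms(fit)
    summary.aic = fit.aic
    try:
        summary.ph_p, summary.ph_global_p = ph_test(fit)
    except ValueError:
        pass
    return summary


def multivariate_cox(
    surv: SurvivalData,
    covariates: pd.DataFrame,
    strata: np.ndarray | None = None,
    name: str = "multivariate",
) -> EvaluationSummary:
    """Stratified multivariate Cox fit with per-covariate partial PVE.

    The partial likelihood is the sum of per-stratum partial likelihoods
    sharing one coefficient vector.  Partial PVE of a covariate is
    PVE(full) minus PVE of the model refit without that covariate's
    columns.  A covariate constant within every stratum is non-identifiable
    and raises.
    """
    design = _design(covariates)
    keep = ~design.isna().any(axis=1).to_numpy()
    if strata is not None:
        strata = np.asarray(strata)
        keep &= ~pd.isna(strata)
    X = design.to_numpy()[keep]
    time, event = surv.time[keep], surv.event[keep]
    strat = strata[keep] if strata is not None else None
    # identifiability: each design column must vary within some stratum
    groups = strat if strat is not None else np.zeros(len(time))
    for j, col in enumerate(design.columns):
        varies = any(
            len(np.unique(X[groups == s, j])) > 1 for s in pd.unique(groups)
        )
        if not varies:
            raise ValueError(
                f"covariate column {col!r} is constant within every stratum; "
                "its coefficient is not identifiable"
            )
    fit = fit_cox(X, time, event, names=list(design.columns), strata=strat)
    n = int(len(fit.time))
    summary = EvaluationSummary(
        name=name, n=n, n_events=fit.n_events, converged=fit.converged, fit=fit,
    )
    if not fit.converged:
        return summary
    dev = 2.0 * (fit.loglik - fit.loglik0)
    summary.deviance = float(dev)
    summary.lrt_p = float(stats.chi2.sf(dev, df=X.shape[1]))
    summary.pve = pve(fit.loglik0, fit.loglik, n)
    summary.hr = _wald_terms(fit)
    summary.aic = fit.aic
    sub = SurvivalData(
        sample_ids=[f"s{i}" for i in range(n)], time=fit.time, event=fit.event,
    )
    summary.c_index = concordance_index(fit.linear_predictor, sub)
    try:
        summary.ph_p, summary.ph_global_p = ph_test(fit)
    except ValueError:
        pass
    # partial PVE per original covariate (refit without its columns)
    full_pve = summary.pve
    for cov_name in covariates.columns:
        others = [c for c in covariates.columns if c != cov_name]
        if not others:
            summary.partial_pve[str(cov_name)] = full_pve
            continue
        reduced = multivariate_cox(
            surv, covariates[others], strata=strata, name="reduced",
        )
        summary.partial_pve[str(cov_name)] = full_pve - reduced.pve
    return summary


def analysis_of_deviance(small: CoxFit, big: CoxFit) -> float:
    """LRT p between nested Cox fits (chi2, df = parameter difference)."""
    df = len(big.beta) - len(small.beta)
    if df <= 0:
        raise ValueError("models are not nested small < big")
    dev = 2.0 * (big.loglik - small.loglik)
    return float(stats.chi2.sf(max(dev, 0.0), df=df))


def stepwise_aic(
    surv: SurvivalData,
    candidates: pd.DataFrame,
    strata: np.ndarray | None = None,
) -> tuple[list[str], EvaluationSummary | None, list[tuple[str, str, float]]]:
    """Hybrid greedy AIC search over candidate covariates.

    At each step every single addition and single deletion is scored by
    AIC = -2 l(beta) + 2 (number of coefficients); the best strictly
    improving move is taken (ties broken by covariate name order, since
    candidates are scanned sorted).  Returns the selected covariate names,
    the final fitted summary (None for the empty model) and the full trace
    of (action, covariate, AIC).
    """
    if candidates.shape[1] < 1:
        raise ValueError("need >= 1 candidate covariate")

    def model_aic(names: list[str]) -> float:
        if not names:
            # empty model: AIC = -2 l(0), zero estimated coefficients
            design = _design(candidates[[candidates.columns[0]]])
            keep = ~design.isna().any(axis=1).to_numpy()
            if strata is not None:
                keep &= ~pd.isna(np.asarray(strata))
            strat = np.asarray(strata)[keep] if strata is not None else None
            l0, _, _ = _strat_loglik_parts(
                np.zeros(0), np.empty((int(keep.sum()), 0)),
                surv.time[keep], surv.event[keep], strat,
            )
            return -2.0 * l0
        fitted = multivariate_cox(surv, candidates[names], strata=strata)
        if not fitted.converged:
            return np.inf
        return fitted.aic

    selected: list[str] = []
    current_aic = model_aic(selected)
    trace: list[tuple[str, str, float]] = [("start", "", current_aic)]
    all_names = sorted(str(c) for c in candidates.columns)
    while True:
        best_move = None
        best_aic = current_aic - 1e-9
        for cand in all_names:
            if cand in selected:
                trial = [c for c in selected if c != cand]
                action = "drop"
            else:
                trial = sorted(selected + [cand])
                action = "add"
            try:
                a = model_aic(trial)
            except ValueError:
                continue
            if a < best_aic:
                best_aic = a
                best_move = (action, cand, trial)
        if best_move is None:
            break
        action, cand, selected = best_move
        current_aic = best_aic
        trace.append((action, cand, current_aic))
        logger.info("stepwise_aic: %s %r -> AIC %.3f", action, cand, current_aic)
    final = (
        multivariate_cox(surv, candidates[selected], strata=strata)
        if selected
        else None
    )
    return selected, final, trace
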