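"""Ridge-penalized Cox regression and cross-validated prognostic indexes.

The prognostic procedure: coefficients ``beta`` of a Cox proportional
hazards model with an L2 (ridge) penalty are estimated on gene
expression; a patient's *prognostic index* (PI) is the expression-
weighted sum ``sum_g beta_g * x_g``, computed out-of-fold under k-fold
cross-validation repeated several times with fresh random partitions so
the score does not depend on one particular split.  Patients above the
median PI form the high-risk group, and a two-group log-rank test reads
out whether the signature carries outcome information.

The penalized log partial likelihood (Breslow handling of tied event
times) is maximized by Newton iterations with step-halving:

    l_pen(beta) = l(beta) - (lambda/2) * ||beta||^2 .

Covariates are standardized internally (training-fold parameters are
applied to test rows during cross-validation, so no information leaks
from test to training).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iodata import SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "LogRankResult",
    "PrognosticIndex",
    "RidgeCoxFit",
    "RiskGroups",
    "assign_risk_groups",
    "breslow_loglik",
    "cv_prognostic_index",
    "km_estimate",
    "logrank_test",
    "ridge_cox_fit",
    "select_lambda",
]

_GRID_DEFAULT = tuple(float(v) for v in np.logspace(-2, 2, 9))


# ---------------------------------------------------------------------------
# Breslow partial likelihood
# ---------------------------------------------------------------------------

def _risk_order(time: np.ndarray) -> np.ndarray:
    """Indices sorting times descending (risk sets become prefixes)."""
    return np.argsort(-time, kind="mergesort")


def breslow_loglik(beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox log partial likelihood with the Breslow convention for ties."""
    order = _risk_order(time)
    xs, ts, es = x[order], time[order], event[order]
    eta = xs @ beta
    # shift by the max so the cumulative sum of exponentials cannot overflow
    shift = eta.max()
    cum = np.cumsum(np.exp(eta - shift))
    ll = 0.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        d = es[i : j + 1].sum()
        if d > 0:
            ll += eta[i : j + 1][es[i : j + 1] == 1].sum() - d * (np.log(cum[j]) + shift)
        i = j + 1
    return float(ll)


def _loglik_grad_hess(
    beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow log partial likelihood with gradient and Hessian."""
    order = _risk_order(time)
    xs, ts, es = x[order], time[order], event[order]
    n, p = xs.shape
    eta = xs @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        block = slice(i, j + 1)
        d = int(es[block].sum())
        if d > 0:
            ev = es[block] == 1
            ll += eta[block][ev].sum() - d * np.log(s0[j])
            xbar = s1[j] / s0[j]
            grad += xs[block][ev].sum(axis=0) - d * xbar
            hess -= d * (s2[j] / s0[j] - np.outer(xbar, xbar))
        i = j + 1
    return float(ll), grad, hess


@dataclass
class RidgeCoxFit:
    """Penalized Cox fit on internally standardized covariates."""

    beta: np.ndarray
    lam: float
    converged: bool
    n_iter: int
    log_partial_likelihood: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))

    def linear_predictor(self, x_new: np.ndarray) -> np.ndarray:
        """Risk score for new rows, using the fit's standardization."""
        z = (np.asarray(x_new, dtype=float) - self.center) / self.scale
        return z @ self.beta


def _standardize_cols(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns contribute 0
    return (x - center) / scale, center, scale


def ridge_cox_fit(
    x: np.ndarray,
    surv: SurvivalTable,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RidgeCoxFit:
    """Maximize the ridge-penalized Breslow partial likelihood by Newton
    iterations with step-halving.

    ``x`` is patients x genes, rows aligned to ``surv``; columns are
    standardized internally and ``beta`` lives on that standardized
    scale.  Convergence: max-norm of the penalized gradient < ``tol``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate matrix contains non-finite values")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if x.shape[0] != len(surv):
        raise ValueError("covariate rows must align with survival records")
    if surv.event.sum() == 0:
        raise ValueError("no events in the survival table")
    z, center, scale = _standardize_cols(x)
    time, event = surv.time, surv.event
    p = z.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, z, time, event)
    obj = ll - 0.5 * lam * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad_pen = grad - lam * beta
        if np.max(np.abs(grad_pen)) < tol:
            converged = True
            it -= 1
            break
        hess_pen = hess - lam * np.eye(p)
        try:
            step = np.linalg.solve(-hess_pen, grad_pen)
        except np.linalg.LinAlgError:
            step = grad_pen  # fall back to gradient ascent
        # step-halving keeps the objective monotone
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_c, grad_c, hess_c = _loglik_grad_hess(cand, z, time, event)
            obj_c = ll_c - 0.5 * lam * cand @ cand
            if np.isfinite(obj_c) and obj_c >= obj - 1e-12:
                beta, ll, grad, hess, obj = cand, ll_c, grad_c, hess_c, obj_c
                break
            t *= 0.5
        else:
            break  # no ascent step found; report unconverged
    else:
        grad_pen = grad - lam * beta
        converged = bool(np.max(np.abs(grad_pen)) < tol)
    grad_pen = grad - lam * beta
    converged = converged or bool(np.max(np.abs(grad_pen)) < tol)
    return RidgeCoxFit(
        beta=beta,
        lam=float(lam),
        converged=converged,
        n_iter=it,
        log_partial_likelihood=ll,
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# lambda selection and cross-validated prognostic index
# ---------------------------------------------------------------------------

def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def select_lambda(
    x: np.ndarray,
    surv: SurvivalTable,
    grid=_GRID_DEFAULT,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Pick the ridge penalty by k-fold cross-validated partial likelihood.

    Uses the full-minus-fold criterion: a fold's contribution is
    ``l_all(beta_train) - l_train(beta_train)`` evaluated without any
    penalty, summed over folds; the grid value maximizing the sum wins.
    Folds whose training half has no events are skipped with a warning.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("lambda grid is empty")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if len(grid) == 1:
        return grid[0]
    x = np.asarray(x, dtype=float)
    n = len(surv)
    rng = np.random.default_rng(seed)
    folds = _partition(n, k, rng)
    cv = np.zeros(len(grid))
    n_used = 0
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        surv_train = surv.subset([surv.patient_ids[i] for i in train])
        if surv_train.event.sum() == 0:
            logger.warning("select_lambda: training fold without events skipped")
            continue
        n_used += 1
        for gi, lam in enumerate(grid):
            fit = ridge_cox_fit(x[train], surv_train, lam)
            z_all = (x - fit.center) / fit.scale
            z_train = z_all[train]
            ll_all = breslow_loglik(fit.beta, z_all, surv.time, surv.event)
            ll_train = breslow_loglik(fit.beta, z_train, surv_train.time, surv_train.event)
            cv[gi] += ll_all - ll_train
    if n_used == 0:
        raise ValueError("every fold lacked training events; cannot select lambda")
    return grid[int(np.argmax(cv))]


@dataclass
class PrognosticIndex:
    """Out-of-fold risk scores averaged over repeated CV partitions."""

    pi: pd.Series
    n_repeats: int
    fold_count: int
    seed: int


def cv_prognostic_index(
    x: np.ndarray,
    surv: SurvivalTable,
    k: int = 10,
    repeats: int = 10,
    lambda_spec: float | str = "cv",
    seed: int = 0,
) -> PrognosticIndex:
    """Repeated k-fold cross-validated prognostic index.

    Per repeat, patients are partitioned into ``k`` random folds; each
    fold's PI is predicted by a ridge Cox model trained on the other
    folds (training-fold standardization applied to the held-out rows).
    The final PI is the mean over repeats.  ``lambda_spec`` is either a
    fixed penalty or ``"cv"`` for inner 5-fold selection on each
    training set.  A partition leaving some training set without events
    is redrawn (up to 20 attempts).
    """
    x = np.asarray(x, dtype=float)
    n = len(surv)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} patients for {k}-fold CV")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for _ in range(repeats):
        for attempt in range(20):
            folds = _partition(n, k, rng)
            trainings = [np.setdiff1d(np.arange(n), f) for f in folds]
            if all(surv.event[t].sum() > 0 for t in trainings):
                break
        else:
            raise ValueError("could not draw a partition with events in every training set")
        pi_rep = np.empty(n)
        for fold, train in zip(folds, trainings):
            surv_train = surv.subset([surv.patient_ids[i] for i in train])
            if lambda_spec == "cv":
                lam = select_lambda(
                    x[train], surv_train, k=5, seed=int(rng.integers(2**31 - 1))
                )
            else:
                lam = float(lambda_spec)
            fit = ridge_cox_fit(x[train], surv_train, lam)
            pi_rep[fold] = fit.linear_predictor(x[fold])
        total += pi_rep
    pi = pd.Series(total / repeats, index=surv.patient_ids, name="prognostic_index")
    return PrognosticIndex(pi=pi, n_repeats=repeats, fold_count=k, seed=seed)


# ---------------------------------------------------------------------------
# risk grouping, Kaplan-Meier, log-rank
# ---------------------------------------------------------------------------

@dataclass
class RiskGroups:
    """High/low risk dichotomy at a PI percentile threshold."""

    assignments: dict[str, str]
    threshold: float

    def members(self, label: str) -> list[str]:
        return [p for p, g in self.assignments.items() if g == label]


def assign_risk_groups(pindex: PrognosticIndex | pd.Series, percentile: float = 50.0) -> RiskGroups:
    """Split patients at a PI percentile (linear interpolation).

    A patient is high risk iff its PI is strictly above the threshold;
    ties at the threshold fall to low risk.
    """
    pi = pindex.pi if isinstance(pindex, PrognosticIndex) else pindex
    if len(pi) < 2:
        raise ValueError("need at least 2 patients to form risk groups")
    values = pi.to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        raise ValueError("all prognostic indexes identical; grouping degenerate")
    threshold = float(np.percentile(values, percentile))
    assignments = {p: ("high" if v > threshold else "low") for p, v in pi.items()}
    labels = set(assignments.values())
    if labels != {"high", "low"}:
        raise ValueError("degenerate grouping: one risk group is empty")
    return RiskGroups(assignments=assignments, threshold=threshold)


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def km_estimate(surv: SurvivalTable) -> KMCurve:
    """Kaplan-Meier estimator ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)``.

    Patients censored exactly at an event time are counted at risk at
    that time.  With no events the curve is empty (S identically 1).
    """
    time, event = surv.time, surv.event
    event_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in event_times], dtype=int)
    n_events = np.array([((time == t) & (event == 1)).sum() for t in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(event_times=event_times, survival=survival, at_risk=at_risk, n_events=n_events)


@dataclass
class LogRankResult:
    """Two-group log-rank test summary (chi-square, 1 df)."""

    chi_square: float
    p: float
    df: int = 1


def logrank_test(surv: SurvivalTable, groups: RiskGroups) -> LogRankResult:
    """Two-group log-rank test.

    ``chi^2 = (sum_i (O_1i - E_1i))^2 / sum_i V_i`` over distinct event
    times, with the hypergeometric variance ``V_i``; p from the
    chi-square distribution with 1 df.
    """
    idx = {p: i for i, p in enumerate(surv.patient_ids)}
    g1 = [idx[p] for p in groups.members("high")]
    g2 = [idx[p] for p in groups.members("low")]
    if not g1 or not g2:
        raise ValueError("both risk groups must be non-empty")
    if surv.event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    time, event = surv.time, surv.event
    in1 = np.zeros(len(surv), dtype=bool)
    in1[g1] = True
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        died = (time == t) & (event == 1)
        d = int(died.sum())
        d1 = int((died & in1).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(chi_square=0.0, p=1.0)
    chi = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi, df=1))
    return LogRankResult(chi_square=float(chi), p=max(p, np.finfo(float).tiny))
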