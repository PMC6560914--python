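"""Survival statistics engine.

Cox proportional-hazards fitting with the Efron tie correction is implemented
directly (Newton–Raphson on the partial likelihood) because downstream stages
need genome-scale univariable screens with a deterministic degenerate-fit
convention: monotone-likelihood fits are capped at ``|beta| = BETA_CAP`` and
flagged rather than erroring, so that every gene still receives a rank.
Kaplan–Meier estimation, the k-sample log-rank test and the Grambsch–Therneau
proportional-hazards diagnostic delegate to :mod:`lifelines`; the Mann–Whitney
U test delegates to :mod:`scipy.stats`.

Hazard ratios are reported on two scales: per unit of the covariate and per
0.1 increment (``exp(0.1 * beta)``), the natural scale for covariates that are
[0, 1] relative-expression averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

BETA_CAP = 15.0
_NEWTON_TOL = 1e-9
_NEWTON_MAXITER = 100


class DegenerateCovariateError(ValueError):
    """A covariate has zero variance (or is not finite)."""


class InsufficientEventsError(ValueError):
    """Fewer than two events: the partial likelihood is uninformative."""


@dataclass
class CoxResult:
    """Result of a Cox proportional-hazards fit.

    All per-covariate quantities are numpy arrays aligned with ``names``;
    single-covariate fits are the common case and index ``[0]``.
    """

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    degenerate: bool
    ph_p: np.ndarray | None = None
    r2_nagelkerke: float | None = None

    @property
    def hr_per_unit(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def hr_per_01(self) -> np.ndarray:
        """Hazard ratio per 0.1 covariate increment: exp(0.1 * beta)."""
        return np.exp(0.1 * self.beta)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "covariate": self.names,
                "beta": self.beta,
                "se": self.se,
                "hr_per_unit": self.hr_per_unit,
                "hr_per_0.1": self.hr_per_01,
                "wald_p": self.wald_p,
            }
        )
        df["n"] = self.n
        df["n_events"] = self.n_events
        df["converged"] = self.converged
        df["degenerate"] = self.degenerate
        if self.ph_p is not None:
            df["ph_p"] = self.ph_p
        return df


def _prepare(times, events, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if times.shape[0] != events.shape[0] or times.shape[0] != X.shape[0]:
        raise ValueError("times, events and covariates must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    return times, events, X


def _efron_ll_grad_hess(beta, x_sorted, events_sorted, group_starts):
    """Log partial likelihood, gradient and Hessian under Efron ties.

    Rows are sorted by descending time so that risk-set sums are prefix
    sums; ``group_starts`` delimits blocks of equal time.  Fully vectorized
    (segment reductions + per-death expansion of the Efron correction), so
    an evaluation is O(n p^2) numpy work with no Python loop over times.
    """
    n, p = x_sorted.shape
    eta = np.clip(x_sorted @ beta, -500, 500)
    w = np.exp(eta)
    xw = x_sorted * w[:, None]
    xxw = np.einsum("ij,ik->ijk", x_sorted, xw)
    cw = np.cumsum(w)
    cxw = np.cumsum(xw, axis=0)
    cxxw = np.cumsum(xxw, axis=0)

    starts = group_starts[:-1]
    ends = group_starts[1:]
    ev = events_sorted.astype(bool)
    evf = ev.astype(float)
    # per-block death counts and tied-death sums (reduceat over blocks)
    d = np.add.reduceat(evf, starts).astype(int)
    has = d > 0
    if not np.any(has):
        return 0.0, np.zeros(p), np.zeros((p, p))
    Sd = np.add.reduceat(w * evf, starts)[has]
    Zd = np.add.reduceat(xw * evf[:, None], starts, axis=0)[has]
    Qd = np.add.reduceat(xxw * evf[:, None, None], starts, axis=0)[has]
    S = cw[ends - 1][has]
    Z = cxw[ends - 1][has]
    Q = cxxw[ends - 1][has]
    d = d[has]

    ll = float(eta[ev].sum())
    grad = x_sorted[ev].sum(axis=0)

    # expand each death time into its d Efron terms with frac = l/d
    reps = d
    idx = np.repeat(np.arange(len(d)), reps)
    ell = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    frac = ell / d[idx]
    denom = S[idx] - frac * Sd[idx]
    zl = Z[idx] - frac[:, None] * Zd[idx]
    ql = Q[idx] - frac[:, None, None] * Qd[idx]
    mu = zl / denom[:, None]
    ll -= float(np.log(denom).sum())
    grad -= mu.sum(axis=0)
    hess = -(ql / denom[:, None, None]).sum(axis=0) \
        + np.einsum("ij,ik->jk", mu, mu)
    return ll, grad, hess


def _sort_for_fit(times, events):
    # descending time; within ties events are grouped by the equal-time blocks
    order = np.argsort(-times, kind="stable")
    t_sorted = times[order]
    boundaries = np.flatnonzero(np.diff(t_sorted) != 0) + 1
    group_starts = np.concatenate(([0], boundaries, [len(times)]))
    return order, group_starts


def fit_cox(
    times: Sequence[float],
    events: Sequence[int],
    X,
    names: Sequence[str] | None = None,
    compute_r2: bool = False,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton–Raphson (Efron ties).

    Convergence: change in log partial likelihood below 1e-9, at most 100
    iterations, with step halving. Monotone likelihood (any ``|beta|``
    exceeding 15 during iteration) sets the ``degenerate`` flag and caps the
    coefficient at +/-15 so rankings stay total.

    Raises
    ------
    InsufficientEventsError
        fewer than 2 events.
    DegenerateCovariateError
        a covariate with zero variance or non-finite values.
    """
    times, events, X = _prepare(times, events, X)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    else:
        names = tuple(names)
    n_events = int(events.sum())
    if n_events < 2:
        raise InsufficientEventsError(f"need >=2 events, got {n_events}")
    if not np.all(np.isfinite(X)):
        raise DegenerateCovariateError("non-finite covariate values")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateCovariateError(f"zero-variance covariate(s): {bad}")

    order, group_starts = _sort_for_fit(times, events)
    xs = X[order]
    es = events[order]

    beta = np.zeros(p)
    ll, grad, hess = _efron_ll_grad_hess(beta, xs, es, group_starts)
    ll0 = ll
    converged = False
    degenerate = False
    for _ in range(_NEWTON_MAXITER):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = -grad / (np.diag(hess) - 1e-12)
        # step halving
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            ll_new, g_new, h_new = _efron_ll_grad_hess(cand, xs, es, group_starts)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        if np.any(np.abs(cand) > BETA_CAP):
            degenerate = True
            cand = np.clip(cand, -BETA_CAP, BETA_CAP)
            ll_new, g_new, h_new = _efron_ll_grad_hess(cand, xs, es, group_starts)
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
            break
        delta = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if abs(delta) < _NEWTON_TOL:
            converged = True
            break

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            var = np.diag(cov).copy()
        except np.linalg.LinAlgError:
            var = np.full(p, np.nan)
    var[var <= 0] = np.nan
    se = np.sqrt(var)
    z = beta / se
    wald_p = 2.0 * sps.norm.sf(np.abs(z))

    r2 = None
    if compute_r2:
        r2 = nagelkerke_r2(ll, ll0, n)

    return CoxResult(
        names=names,
        beta=beta,
        se=se,
        wald_p=wald_p,
        loglik=float(ll),
        loglik_null=float(ll0),
        n=n,
        n_events=n_events,
        converged=converged and not degenerate,
        degenerate=degenerate,
        r2_nagelkerke=r2,
    )


def nagelkerke_r2(loglik: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's R^2 for a Cox model (Cox–Snell rescaled to [0, 1))."""
    r2_cs = 1.0 - np.exp(-2.0 * (loglik - loglik_null) / n)
    r2_max = 1.0 - np.exp(2.0 * loglik_null / n)
    if r2_max <= 0:
        return 0.0
    return float(r2_cs / r2_max)


def cox_screen(
    times,
    events,
    X: pd.DataFrame,
) -> pd.DataFrame:
    """Univariable Cox fit for every column of ``X`` (genome-wide screen).

    Returns one row per covariate with beta, se, both HR scales, Wald p and
    the degenerate flag. Zero-variance covariates are reported with NaN
    statistics and ``degenerate=True`` rather than aborting the screen.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    rows = []
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        try:
            res = fit_cox(times, events, x, names=(name,))
            rows.append(
                (name, res.beta[0], res.se[0], res.hr_per_unit[0],
                 res.hr_per_01[0], res.wald_p[0], res.degenerate)
            )
        except DegenerateCovariateError:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, np.nan, True))
    out = pd.DataFrame(
        rows,
        columns=["gene", "beta", "se", "hr_per_unit", "hr_per_0.1", "wald_p",
                 "degenerate"],
    ).set_index("gene")
    out.attrs["n"] = len(times)
    out.attrs["n_events"] = int(events.sum())
    return out


def ph_test(times, events, X, names: Sequence[str] | None = None) -> np.ndarray:
    """Grambsch–Therneau proportional-hazards test per covariate.

    Score test on scaled Schoenfeld residuals with the Kaplan–Meier time
    transform (the field-default configuration). Returns one two-sided
    p-value per covariate; fewer than 3 events yields NaN (not testable).
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    times, events, X = _prepare(times, events, X)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if int(events.sum()) < 3:
        return np.full(X.shape[1], np.nan)
    df = pd.DataFrame(X, columns=list(names))
    df["_t"] = times
    df["_e"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_t", event_col="_e")
    res = proportional_hazard_test(cph, df, time_transform="km")
    pvals = res.summary["p"]
    return np.array([float(pvals.loc[nm]) for nm in names])


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float = field(default=np.nan)  # NaN when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate.

    Subjects censored at an event time are counted at risk at that time.
    Median survival is the smallest t with S(t) <= 0.5 (NaN if never).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    at_risk = tab["at_risk"].to_numpy()
    keep = grid > 0 if grid[0] == 0 and tab["observed"].iloc[0] == 0 and tab["censored"].iloc[0] == 0 else np.ones(len(grid), bool)
    med = kmf.median_survival_time_
    med = float(med) if np.isfinite(med) else np.nan
    return KMCurve(times=grid[keep], survival=surv[keep], at_risk=at_risk[keep], median=med)


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank(times, events, groups) -> LogRankResult:
    """k-sample log-rank test (chi-square with k-1 df)."""
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs >=2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    chi2 = float(res.test_statistic)
    df = len(labels) - 1
    return LogRankResult(chi2=chi2, df=df, p=float(res.p_value))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann–Whitney U with two-sided p.

    Exact enumeration when both samples have n <= 8 and there are no ties;
    otherwise the normal approximation with midranks and tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 8 and len(b) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
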