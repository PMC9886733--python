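"""Prognostic evaluation machinery.

Kaplan-Meier quartile curves with log-rank tests (lifelines-backed), a Cox
proportional-hazards fit by Newton iteration on the partial likelihood
(Efron or Breslow ties, optional per-event-time weights, model-based or
robust sandwich variance), Grambsch-Therneau tests on scaled Schoenfeld
residuals, time-dependent cumulative/dynamic AUC(t) with inverse-probability-
of-censoring weights, and Prentice-weighted average hazard ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "KMEstimate",
    "CoxFit",
    "AUCtEstimate",
    "km_logrank",
    "fi_quartile_groups",
    "cox_fit",
    "schoenfeld_test",
    "auc_t",
    "ahr_fit",
    "prentice_weights",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    curves: dict  # group -> DataFrame(time, survival, at_risk)
    logrank_stat: float | None
    logrank_p: float | None
    logrank_df: int | None


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit estimate as a step function over distinct event times."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    table = kmf.event_table
    surv = kmf.survival_function_
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


def km_logrank(time, event, groups) -> KMEstimate:
    """Per-group KM curves plus the k-group log-rank chi-square test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if event.sum() < 1:
        raise ValueError("need at least one observed event")
    curves = {}
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        curves[g] = km_curve(time[mask], event[mask])
    if len(curves) >= 2:
        from lifelines.statistics import multivariate_logrank_test

        res = multivariate_logrank_test(time, groups, event)
        stat, p, df = float(res.test_statistic), float(res.p_value), int(res.degrees_of_freedom)
    else:
        stat = p = df = None
    return KMEstimate(curves=curves, logrank_stat=stat, logrank_p=p, logrank_df=df)


def fi_quartile_groups(fi) -> np.ndarray:
    """Quartile labels 1-4 from linear-interpolation sample quartiles.

    Values equal to a cut point fall in the lower quartile.
    """
    fi = np.asarray(fi, dtype=float)
    cuts = np.quantile(fi, [0.25, 0.5, 0.75])
    return (1 + (fi[:, None] > cuts[None, :]).sum(axis=1)).astype(int)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Newton), weighted variant, robust variance
# ---------------------------------------------------------------------------


def _prepare(X, time, event):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order], order


def _event_groups(time, event):
    """Indices of tied event groups, ascending in time."""
    groups = []
    ev_times = np.unique(time[event == 1])
    for t in ev_times:
        idx = np.where((time == t) & (event == 1))[0]
        groups.append((t, idx))
    return groups


def _cox_derivs(beta, X, time, event, ties, event_weight, groups=None):
    """Log partial likelihood, score, information (negative Hessian)."""
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    # reverse cumulative sums give risk-set aggregates at each sorted position
    S0_rev = np.cumsum(w[::-1])[::-1]
    S1_rev = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2_rev = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    if groups is None:
        groups = _event_groups(time, event)
    firsts = np.searchsorted(time, [t for t, _ in groups], side="left")
    wts = np.array([event_weight(t) for t, _ in groups])
    ds = np.array([len(idx) for _, idx in groups])

    # vectorised Breslow terms over all event groups
    S0 = S0_rev[firsts]
    S1 = S1_rev[firsts]
    S2 = S2_rev[firsts]
    xbar = S1 / S0[:, None]
    all_idx = np.concatenate([idx for _, idx in groups]) if groups else np.empty(0, dtype=int)
    rep_w = np.repeat(wts, ds)
    if np.all(ds == 1):
        xs = X[all_idx]
    else:
        xs = np.vstack([X[idx].sum(axis=0) for _, idx in groups]) if groups else np.empty((0, p))

    untied = ties == "breslow" or bool(np.all(ds == 1))
    if untied:
        ll = float((rep_w * eta[all_idx]).sum() - (wts * ds * np.log(S0)).sum())
        score = (wts[:, None] * (xs - ds[:, None] * xbar)).sum(axis=0)
        info = ((wts * ds)[:, None, None] * (S2 / S0[:, None, None] - xbar[:, None, :] * xbar[:, :, None])).sum(axis=0)
        return ll, score, info.reshape(p, p)

    ll = float((rep_w * eta[all_idx]).sum())
    score = np.zeros(p)
    info = np.zeros((p, p))
    for g, (t, idx) in enumerate(groups):
        S0g, S1g, S2g = S0[g], S1[g], S2[g]
        d = ds[g]
        wt = wts[g]
        if d == 1:
            xb = S1g / S0g
            ll -= wt * np.log(S0g)
            score += wt * (xs[g] - xb)
            info += wt * (S2g / S0g - np.outer(xb, xb))
            continue
        s0d = w[idx].sum()
        s1d = (w[idx, None] * X[idx]).sum(axis=0)
        s2d = (w[idx, None, None] * (X[idx, :, None] * X[idx, None, :])).sum(axis=0)
        for l in range(d):
            f = l / d
            phi0 = S0g - f * s0d
            phi1 = S1g - f * s1d
            phi2 = S2g - f * s2d
            ll -= wt * np.log(phi0)
            score += wt * (xs[g] / d - phi1 / phi0)
            info += wt * (phi2 / phi0 - np.outer(phi1, phi1) / phi0**2)
    return ll, score, info


def _newton(X, time, event, ties, event_weight, tol=1e-9, max_iter=100):
    p = X.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    groups = _event_groups(time, event)
    for it in range(max_iter):
        ll, score, info = _cox_derivs(beta, X, time, event, ties, event_weight, groups)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "singular information matrix: monotone likelihood or collinear covariates"
            ) from exc
        # step-halving to guarantee ascent
        for _ in range(30):
            beta_new = beta + step
            ll_new, _, _ = _cox_derivs(beta_new, X, time, event, ties, event_weight, groups)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        if np.any(np.abs(beta_new) > 50):
            raise RuntimeError("monotone likelihood suspected (diverging coefficients)")
        converged = abs(ll_new - ll_old) < tol and np.max(np.abs(beta_new - beta)) < np.sqrt(tol)
        beta = beta_new
        ll_old = ll_new
        if converged:
            break
    else:
        raise RuntimeError(f"Newton did not converge in {max_iter} iterations")
    ll, score, info = _cox_derivs(beta, X, time, event, ties, event_weight, groups)
    return beta, ll, info, it + 1


def _score_residuals(beta, X, time, event, event_weight):
    """Per-subject score residuals (Breslow-style cumulative sums)."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    S0_rev = np.cumsum(w[::-1])[::-1]
    S1_rev = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    groups = _event_groups(time, event)
    U = np.zeros((n, p))
    # event-term contribution
    xbar_at = {}
    for t, idx in groups:
        first = np.searchsorted(time, t, side="left")
        xbar_at[t] = S1_rev[first] / S0_rev[first]
        U[idx] += event_weight(t) * (X[idx] - xbar_at[t])
    # cumulative risk-set contribution
    A = 0.0
    B = np.zeros(p)
    cum = []
    for t, idx in groups:
        first = np.searchsorted(time, t, side="left")
        d = len(idx)
        wt = event_weight(t)
        A += wt * d / S0_rev[first]
        B += wt * d * xbar_at[t] / S0_rev[first]
        cum.append((t, A, B.copy()))
    if cum:
        ev_times = np.array([c[0] for c in cum])
        A_arr = np.array([c[1] for c in cum])
        B_arr = np.vstack([c[2] for c in cum])
        pos = np.searchsorted(ev_times, time, side="right") - 1
        safe = np.clip(pos, 0, None)
        Ai = np.where(pos >= 0, A_arr[safe], 0.0)
        Bi = np.where((pos >= 0)[:, None], B_arr[safe], 0.0)
        U -= w[:, None] * (X * Ai[:, None] - Bi)
    return U


@dataclass
class CoxFit:
    params: pd.Series
    se: pd.Series
    robust_se: pd.Series | None
    cov: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    schoenfeld: pd.DataFrame = field(repr=False, default=None)  # event-time indexed residuals
    event_times: np.ndarray = field(repr=False, default=None)
    info: np.ndarray = field(repr=False, default=None)
    weighted: bool = False

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    def confint(self, alpha: float = 0.05, robust: bool | None = None) -> pd.DataFrame:
        se = self.robust_se if (robust or (robust is None and self.robust_se is not None)) else self.se
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * se)
        hi = np.exp(self.params + z * se)
        return pd.DataFrame({"hr": np.exp(self.params), "lower": lo, "upper": hi})

    def summary(self) -> pd.DataFrame:
        se = self.robust_se if self.robust_se is not None else self.se
        z = self.params / se
        ci = self.confint()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "hr": ci["hr"],
                "hr_lower95": ci["lower"],
                "hr_upper95": ci["upper"],
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    ties: str = "efron",
    robust: bool = False,
    event_weight: Callable[[float], float] | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson on the partial likelihood.

    ``event_weight`` maps an event time to a weight applied to that event
    time's estimating-equation contribution (used by :func:`ahr_fit`); the
    default of 1 everywhere gives the ordinary Cox model.
    """
    covariates = list(covariates)
    sub = data[[duration_col, event_col, *covariates]].dropna()
    X = sub[covariates].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant covariate(s): {bad}")
    time = sub[duration_col].to_numpy(dtype=float)
    event = sub[event_col].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one observed event")
    Xs, ts, es, _ = _prepare(X, time, event)
    weighted = event_weight is not None
    ew = event_weight if weighted else (lambda t: 1.0)
    beta, ll, info, n_iter = _newton(Xs, ts, es, ties, ew, tol=tol, max_iter=max_iter)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    robust_se = None
    if robust or weighted:
        U = _score_residuals(beta, Xs, ts, es, ew)
        sandwich = cov @ (U.T @ U) @ cov
        robust_se = pd.Series(np.sqrt(np.diag(sandwich)), index=covariates)

    # Breslow-style Schoenfeld residuals at each individual event
    eta = Xs @ beta
    w = np.exp(eta)
    S0_rev = np.cumsum(w[::-1])[::-1]
    S1_rev = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    res_rows, res_times = [], []
    for t, idx in _event_groups(ts, es):
        first = np.searchsorted(ts, t, side="left")
        xbar = S1_rev[first] / S0_rev[first]
        for i in idx:
            res_rows.append(Xs[i] - xbar)
            res_times.append(t)
    schoenfeld = pd.DataFrame(res_rows, columns=covariates)
    schoenfeld.insert(0, "time", res_times)

    return CoxFit(
        params=pd.Series(beta, index=covariates, name="coef"),
        se=pd.Series(se, index=covariates),
        robust_se=robust_se,
        cov=pd.DataFrame(cov, index=covariates, columns=covariates),
        loglik=float(ll),
        n=len(sub),
        n_events=int(event.sum()),
        ties=ties,
        n_iter=n_iter,
        schoenfeld=schoenfeld,
        event_times=np.array(res_times),
        info=info,
    )


def schoenfeld_test(fit: CoxFit, transform: str = "km", time=None, event=None) -> pd.DataFrame:
    """Grambsch-Therneau proportional-hazards test on scaled residuals.

    Correlates the Schoenfeld residuals with a transform g of event time
    (default ``"km"``: one minus the overall KM survival estimate; also
    ``"identity"`` and ``"rank"``).  Returns per-covariate chi-square tests
    plus a GLOBAL row.
    """
    if fit.n_events < 2:
        raise ValueError("too few events for a proportional-hazards test")
    resid = fit.schoenfeld.drop(columns="time").to_numpy()
    t_ev = fit.schoenfeld["time"].to_numpy()
    d, p = resid.shape
    if transform == "identity":
        g = t_ev.astype(float)
    elif transform == "rank":
        g = stats.rankdata(t_ev, method="average")
    elif transform == "km":
        if time is None or event is None:
            raise ValueError("km transform needs the full time/event vectors")
        curve = km_curve(time, event)
        s = np.interp(t_ev, curve["time"], curve["survival"])
        g = 1.0 - s
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    V_bar = fit.info / d
    u = gc @ resid  # length p
    denom = (gc**2).sum()
    rows = []
    for j, name in enumerate(fit.params.index):
        var_j = denom * V_bar[j, j]
        if var_j <= 0:
            raise ValueError(f"no residual variance for covariate {name!r}")
        chi2 = u[j] ** 2 / var_j
        rows.append({"covariate": name, "chi2": chi2, "df": 1, "p": stats.chi2.sf(chi2, 1)})
    D = denom * V_bar
    chi2_g = float(u @ np.linalg.solve(D, u))
    rows.append({"covariate": "GLOBAL", "chi2": chi2_g, "df": p, "p": stats.chi2.sf(chi2_g, p)})
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# Time-dependent AUC with IPCW
# ---------------------------------------------------------------------------


@dataclass
class AUCtEstimate:
    times: np.ndarray
    auc: np.ndarray
    ci_lower: np.ndarray | None
    ci_upper: np.ndarray | None
    n_boot: int


def _km_left(time, event):
    """Left-continuous KM evaluator S(t-) for the given event indicator."""
    curve = km_curve(time, event)
    ts = curve["time"].to_numpy()
    ss = curve["survival"].to_numpy()

    def S_minus(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(ts, t, side="left") - 1
        out = np.where(idx >= 0, ss[np.clip(idx, 0, len(ss) - 1)], 1.0)
        return out

    return S_minus


def _ipcw_auc_at(marker, time, event, t, G_minus):
    case = (time <= t) & (event == 1)
    control = time > t
    if case.sum() == 0 or control.sum() == 0:
        return np.nan
    Gc = G_minus(time[case])
    if np.any(Gc <= 0):
        raise ValueError("censoring-survival estimate reaches 0 at a required time")
    Gt = float(G_minus(np.array([np.nextafter(t, np.inf)]))[0])
    if Gt <= 0:
        raise ValueError("censoring-survival estimate reaches 0 at a required time")
    w_case = 1.0 / Gc
    w_ctrl = np.full(int(control.sum()), 1.0 / Gt)
    mc = marker[case]
    mk = marker[control]
    gt = (mc[:, None] > mk[None, :]).astype(float)
    tie = (mc[:, None] == mk[None, :]).astype(float)
    num = (w_case[:, None] * w_ctrl[None, :] * (gt + 0.5 * tie)).sum()
    den = w_case.sum() * w_ctrl.sum()
    return float(num / den)


def auc_t(
    marker,
    time,
    event,
    time_grid,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> AUCtEstimate:
    """Cumulative-case / dynamic-control AUC(t) with IPCW.

    Cases at t are subjects with an observed event by t, weighted by
    1/G(T_i-); controls are subjects still at risk beyond t, weighted by
    1/G(t); G is the KM estimate of the censoring distribution.  Confidence
    intervals are percentile bootstrap over subjects (``n_boot`` replicates).
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    grid = np.asarray(time_grid, dtype=float)
    G_minus = _km_left(time, 1 - event)
    point = np.array([_ipcw_auc_at(marker, time, event, t, G_minus) for t in grid])
    lo = hi = None
    if n_boot > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        n = len(marker)
        boots = np.empty((n_boot, len(grid)))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Gb = _km_left(time[idx], 1 - event[idx])
            for j, t in enumerate(grid):
                try:
                    boots[b, j] = _ipcw_auc_at(marker[idx], time[idx], event[idx], t, Gb)
                except ValueError:
                    boots[b, j] = np.nan
        lo = np.nanquantile(boots, alpha / 2, axis=0)
        hi = np.nanquantile(boots, 1 - alpha / 2, axis=0)
    return AUCtEstimate(times=grid, auc=point, ci_lower=lo, ci_upper=hi, n_boot=n_boot)


# ---------------------------------------------------------------------------
# Average hazard ratio (Prentice weights with censoring correction)
# ---------------------------------------------------------------------------


def prentice_weights(time, event) -> Callable[[float], float]:
    """Event-time weight w(t) = S(t-) / G(t-) from left-continuous KM estimates.

    S is the KM estimate of the event-time survival function and G of the
    censoring distribution; dividing by G corrects the survival-function
    weight for censoring.
    """
    S_minus = _km_left(time, event)
    G_minus = _km_left(time, 1 - np.asarray(event, dtype=int))

    def weight(t: float) -> float:
        s = float(S_minus(np.array([t]))[0])
        g = float(G_minus(np.array([t]))[0])
        if g <= 0:
            logger.warning("censoring survival reached 0 at t=%s; weight truncated", t)
            return 0.0
        return s / g

    return weight


def ahr_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    weight_fn: Callable | None = None,
) -> CoxFit:
    """Average hazard ratios from weighted Cox estimating equations.

    Uses Prentice-type event-time weights with censoring correction by
    default and reports sandwich (robust) standard errors.  Exponentiated
    coefficients are interpreted as average hazard ratios.
    """
    sub = data[[duration_col, event_col, *covariates]].dropna()
    if weight_fn is None:
        weight_fn = prentice_weights(
            sub[duration_col].to_numpy(dtype=float), sub[event_col].to_numpy(dtype=int)
        )
    fit = cox_fit(
        sub,
        duration_col,
        event_col,
        covariates,
        ties="breslow",
        robust=True,
        event_weight=weight_fn,
    )
    fit.weighted = True
    return fit
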