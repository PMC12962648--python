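"""Group comparisons and the survival toolkit.

One-way ANOVA with Tukey HSD post-hoc tests (scipy-backed) for comparing
ALPS values across ROI categories, and a native survival stack:
Kaplan-Meier product-limit curves with Greenwood variance, the two-group
log-rank test, and Cox proportional-hazards regression by Newton-Raphson
maximization of the partial likelihood with Efron (default) or Breslow
handling of tied event times.  Continuous Cox covariates are z-scored by
default so hazard ratios read per standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SurvivalData",
    "KmCurve",
    "CoxResult",
    "LogrankResult",
    "anova_tukey",
    "dichotomize_median",
    "km_estimate",
    "logrank",
    "cox_fit",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.44


class ConvergenceError(RuntimeError):
    """Cox fit failed to converge (or the likelihood is monotone)."""


@dataclass
class SurvivalData:
    """Right-censored survival outcomes with optional group/covariates."""

    time: np.ndarray  # days, > 0
    event: np.ndarray  # 1 = death observed, 0 = censored
    group: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time/event length mismatch")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event flags must be 0/1")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != self.time.shape:
                raise ValueError("group length mismatch")

    def __len__(self) -> int:
        return self.time.shape[0]


@dataclass
class KmCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    median_days: float  # nan if the curve never reaches 0.5
    n: int

    @property
    def median_months(self) -> float:
        return self.median_days / DAYS_PER_MONTH

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    chi2: float
    p: float
    hr: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    n_per_group: dict = field(default_factory=dict)


@dataclass
class CoxResult:
    """Per-covariate Wald statistics from a Cox PH fit."""

    summary: pd.DataFrame  # index: covariate; beta, se, z, p, hr, ci_lo, ci_hi
    n: int
    n_events: int
    ties_method: str
    standardized: bool
    loglik: float
    n_iter: int

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.summary.loc[covariate]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def anova_tukey(values, groups) -> dict:
    """One-way ANOVA F test plus Tukey HSD adjusted pairwise p-values.

    Returns {"F", "p", "pairwise": {(level_a, level_b): p_adj}}.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in pd.unique(groups)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    for g, s in zip(levels, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    if np.all(values == values[0]):
        raise ValueError("all values identical; ANOVA undefined")
    F, p = sps.f_oneway(*samples)
    if not np.isfinite(F):  # zero within-group variance, unequal means
        raise ValueError("zero within-group variance")
    tk = sps.tukey_hsd(*samples)
    pairwise = {
        (levels[i], levels[j]): float(tk.pvalue[i, j])
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
    }
    return {"F": float(F), "p": float(p), "pairwise": pairwise}


def dichotomize_median(values) -> np.ndarray:
    """Split at the median: value > median -> "high", else "low"."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("all values identical; cannot dichotomize")
    med = np.median(values)
    return np.where(values > med, "high", "low")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_estimate(sd: SurvivalData) -> KmCurve:
    """Product-limit estimator with Greenwood variance.

    The median is the first time the curve reaches 0.5; if it sits at
    exactly 0.5 on a plateau, the midpoint between that event time and
    the next is reported (linear convention).
    """
    n = len(sd)
    if n < 1:
        raise ValueError("empty survival data")
    order = np.argsort(sd.time, kind="stable")
    t, e = sd.time[order], sd.event[order]
    ev_times = np.unique(t[e == 1])
    at_risk = n - np.searchsorted(t, ev_times, side="left")
    d = np.array([int(((t == tt) & (e == 1)).sum()) for tt in ev_times])
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
        greenwood = surv**2 * np.cumsum(gw_terms)
    greenwood = np.where(surv > 0, greenwood, 0.0)  # S=0: variance degenerate

    median = np.nan
    hit = np.flatnonzero(surv <= 0.5 + 1e-12)
    if hit.size:
        i = hit[0]
        if abs(surv[i] - 0.5) <= 1e-12 and i + 1 < ev_times.size:
            median = 0.5 * (ev_times[i] + ev_times[i + 1])
        else:
            median = float(ev_times[i])
    return KmCurve(
        times=ev_times,
        survival=surv,
        at_risk=at_risk,
        n_events=d,
        greenwood_var=greenwood,
        median_days=median,
        n=n,
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def logrank_chi2(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float]:
    """(chi2, p) of the two-group log-rank test (O-E with hypergeometric
    variance, 1 df).  Fast path shared by the cutpoint scan."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], g1[order]
    n = t.size

    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        raise ValueError("no events")
    left = np.searchsorted(t, ev_times, side="left")
    n_at = n - left
    cum_g = np.concatenate([[0], np.cumsum(g)])
    n1_at = cum_g[-1] - cum_g[left]

    # events at each distinct time, overall and in group 1
    idx_all = np.searchsorted(ev_times, t[e == 1])
    d = np.bincount(idx_all, minlength=ev_times.size)
    d1 = np.bincount(idx_all, weights=g[e == 1].astype(float), minlength=ev_times.size)

    frac1 = n1_at / n_at
    o_minus_e = float(np.sum(d1 - d * frac1))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac1 * (1 - frac1) * (n_at - d) / np.maximum(n_at - 1, 1)
    v = np.where(n_at > 1, v, 0.0)
    var = float(v.sum())
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def logrank(sd: SurvivalData, compute_hr: bool = True) -> LogrankResult:
    """Two-group log-rank test; HR and 95% CI come from a univariate Cox
    fit on the group indicator (second group label vs first)."""
    if sd.group is None:
        raise ValueError("survival data carries no group labels")
    levels = list(pd.unique(sd.group))
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    g1 = sd.group == levels[1]
    if g1.all() or (~g1).all():
        raise ValueError("one group is empty")
    chi2, p = logrank_chi2(sd.time, sd.event, g1)
    hr, ci = np.nan, (np.nan, np.nan)
    if compute_hr:
        try:
            res = cox_fit(
                sd.time,
                sd.event,
                pd.DataFrame({"group": g1.astype(float)}),
                standardize=False,
            )
            row = res["group"]
            hr, ci = float(row["hr"]), (float(row["ci_lo"]), float(row["ci_hi"]))
        except (ConvergenceError, ValueError):
            pass
    return LogrankResult(
        chi2=chi2,
        p=p,
        hr=hr,
        ci95=ci,
        n_per_group={lv: int((sd.group == lv).sum()) for lv in levels},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def _partial_lik(
    beta: np.ndarray,
    X: np.ndarray,
    w_order: tuple,
    want_derivs: bool = True,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Log partial likelihood (+ gradient, Hessian) at beta.

    ``w_order`` packs the time-sorted (descending) structures prepared
    once per fit; ties are handled by the Efron/Breslow correction
    factors c_l (l/d for Efron, 0 for Breslow).
    """
    (Xs, risk_idx, grp_starts, grp_sizes, ev_x_sum, ev_members, breslow) = w_order
    p = Xs.shape[1]
    eta = np.clip(Xs @ beta, -500, 500)
    w = np.exp(eta)
    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w[:, None] * Xs, axis=0)
    if want_derivs:
        wxx = w[:, None, None] * Xs[:, :, None] * Xs[:, None, :]
        cum2 = np.cumsum(wxx, axis=0)

    if max(grp_sizes) == 1:  # no tied event times: fully vectorized
        ridx = np.asarray(risk_idx)
        members = np.concatenate(ev_members)
        S0R = cum0[ridx]  # (g,)
        loglik = float(eta[members].sum() - np.log(S0R).sum())
        if not want_derivs:
            return loglik, None, None
        psi = cum1[ridx] / S0R[:, None]  # (g, p)
        grad = Xs[members].sum(axis=0) - psi.sum(axis=0)
        hess = -(cum2[ridx] / S0R[:, None, None]).sum(axis=0)
        hess += np.einsum("lp,lq->pq", psi, psi)
        return loglik, grad, hess

    loglik = 0.0
    grad = np.zeros(p) if want_derivs else None
    hess = np.zeros((p, p)) if want_derivs else None

    for gi in range(len(grp_starts)):
        members = ev_members[gi]
        d = grp_sizes[gi]
        r = risk_idx[gi]
        S0R = cum0[r]
        S1R = cum1[r]
        wD = w[members]
        c = np.zeros(d) if (breslow or d == 1) else np.arange(d) / d
        S0D = wD.sum()
        phi = S0R - c * S0D  # (d,)
        loglik += float(eta[members].sum() - np.log(phi).sum())
        if want_derivs:
            S1D = (wD[:, None] * Xs[members]).sum(axis=0)
            psi = (S1R[None, :] - c[:, None] * S1D[None, :]) / phi[:, None]  # (d, p)
            grad += ev_x_sum[gi] - psi.sum(axis=0)
            S2R = cum2[r]
            S2D = (wD[:, None, None] * Xs[members][:, :, None] * Xs[members][:, None, :]).sum(
                axis=0
            )
            num2 = S2R[None] - c[:, None, None] * S2D[None]
            hess -= (num2 / phi[:, None, None]).sum(axis=0)
            hess += np.einsum("lp,lq->pq", psi, psi)
    return loglik, grad, hess


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "efron",
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson with step-halving.

    ``ties``: "efron" (default, more accurate) or "breslow"; they agree
    exactly when no event times are tied.  With ``standardize``,
    continuous covariates (more than two distinct values) are z-scored,
    so their hazard ratios are per SD.  Raises :class:`ConvergenceError`
    on non-convergence or monotone likelihood (perfect separation).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates))
    names = [str(c) for c in covariates.columns]
    X = covariates.to_numpy(float)
    n, p = X.shape
    n_events = int(event.sum())
    if n_events < p + 1:
        raise ValueError(f"{n_events} events cannot support {p} covariates")
    for j, name in enumerate(names):
        if np.unique(X[:, j]).size < 2:
            raise ValueError(f"constant covariate column {name!r}")

    scaled = np.zeros(p, dtype=bool)
    if standardize:
        for j in range(p):
            if np.unique(X[:, j]).size > 2:
                X = X.copy()
                X[:, j] = (X[:, j] - X[:, j].mean()) / X[:, j].std(ddof=0)
                scaled[j] = True

    # descending time order; risk set of t = prefix of entries with time >= t
    order = np.argsort(-time, kind="stable")
    ts, es, Xs = time[order], event[order], X[order]

    ev_times = np.unique(ts[es == 1])[::-1]  # descending
    risk_idx = []
    grp_starts = []
    grp_sizes = []
    ev_x_sum = []
    ev_members = []
    for t in ev_times:
        k = np.searchsorted(-ts, -t, side="right")
        risk_idx.append(k - 1)
        members = np.flatnonzero((ts == t) & (es == 1))
        grp_starts.append(members[0])
        grp_sizes.append(members.size)
        ev_members.append(members)
        ev_x_sum.append(Xs[members].sum(axis=0))
    packed = (
        Xs,
        np.asarray(risk_idx),
        grp_starts,
        grp_sizes,
        ev_x_sum,
        ev_members,
        ties == "breslow",
    )

    beta = np.zeros(p)
    loglik, grad, hess = _partial_lik(beta, X, packed)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, *_ = _partial_lik(new_beta, X, packed, want_derivs=False)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 40:
            step *= 0.5
            new_beta = beta + step
            new_ll, *_ = _partial_lik(new_beta, X, packed, want_derivs=False)
            halvings += 1
        delta_ll = new_ll - loglik
        beta = new_beta
        loglik, grad, hess = _partial_lik(beta, X, packed)
        # monotone likelihood: the per-SD effect runs away while the
        # likelihood plateaus (exp(15) per SD is beyond any real hazard)
        col_sd = X.std(axis=0, ddof=0)
        if np.max(np.abs(beta) * col_sd) > 15.0:
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation?): "
                f"per-SD |beta| exceeded 15 at iteration {n_iter}"
            )
        if abs(delta_ll) < tol and np.max(np.abs(grad)) < 1e-5:
            break
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(|grad|_max = {np.max(np.abs(grad)):.3g}, loglik = {loglik:.6g})"
        )

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": pvals,
            "hr": np.exp(beta),
            "ci_lo": np.exp(np.clip(beta - 1.96 * se, -700, 700)),
            "ci_hi": np.exp(np.clip(beta + 1.96 * se, -700, 700)),
            "per_sd": scaled,
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxResult(
        summary=summary,
        n=n,
        n_events=n_events,
        ties_method=ties,
        standardized=standardize,
        loglik=float(loglik),
        n_iter=n_iter,
    )
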