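"""ComBat location/scale harmonization of scalar biomarkers across sites.

Model per feature v, subject j of site i:

    y_ijv = alpha_v + X_j beta_v + gamma_iv + delta_iv eps_ijv

where gamma (additive) and delta (multiplicative) are site effects and X
holds biological covariates (age, sex) whose structure must be
preserved.  Fitting standardizes each feature by the covariate-adjusted
grand mean and pooled variance, estimates per-site location/scale on the
standardized scale, and — with two or more features — shrinks the
per-site estimates with parametric empirical Bayes (normal prior on
gamma, inverse-gamma on delta, moment-matched, solved by the standard
fixed-point iteration).  Applying the model removes (gamma*, delta*)
and restores the pooled scale and covariate structure.

Variances use the maximum-likelihood (1/n) convention throughout, which
makes harmonization exactly idempotent in the covariate-free,
no-shrinkage case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "combat_fit", "combat_apply"]


@dataclass
class CombatModel:
    """Fitted ComBat parameters for a set of features across sites."""

    features: list[str]
    sites: list[str]
    covariates: list[str]
    alpha: np.ndarray  # (F,) grand intercepts
    beta: np.ndarray  # (C, F) covariate coefficients
    var_pooled: np.ndarray  # (F,)
    gamma_star: np.ndarray  # (S, F)
    delta_star: np.ndarray  # (S, F) variances, > 0
    gamma_hat: np.ndarray  # (S, F) pre-shrinkage
    delta_hat: np.ndarray  # (S, F) pre-shrinkage
    eb_used: bool
    n_per_site: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "sites": self.sites,
            "covariates": self.covariates,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "eb_used": self.eb_used,
            "n_per_site": self.n_per_site,
        }


def _design(
    table: pd.DataFrame, sites: list[str], batch: str, covariates: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    D = np.column_stack([(table[batch] == s).to_numpy(float) for s in sites])
    X = (
        table[covariates].to_numpy(float)
        if covariates
        else np.empty((len(table), 0))
    )
    return D, X


def _eb_shrink(
    gamma_hat_i: np.ndarray,
    delta_hat_i: np.ndarray,
    n_i: int,
    max_iter: int = 500,
    conv: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric EB fixed point for one site across features."""
    gbar = gamma_hat_i.mean()
    t2 = gamma_hat_i.var(ddof=1)
    dmean = delta_hat_i.mean()
    dvar = delta_hat_i.var(ddof=1)
    if dvar <= 0 or t2 <= 0:
        return gamma_hat_i.copy(), delta_hat_i.copy()
    a = (2.0 * dvar + dmean**2) / dvar
    b = (dmean * dvar + dmean**3) / dvar

    g = gamma_hat_i.copy()
    d = delta_hat_i.copy()
    for _ in range(max_iter):
        g_new = (n_i * t2 * gamma_hat_i + d * gbar) / (n_i * t2 + d)
        ssq = n_i * (delta_hat_i + (gamma_hat_i - g_new) ** 2)
        d_new = (b + 0.5 * ssq) / (n_i / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g).max(initial=0.0), np.abs(d_new - d).max(initial=0.0)
        )
        g, d = g_new, d_new
        if change < conv:
            break
    return g, d


def combat_fit(
    table: pd.DataFrame,
    features: list[str],
    batch: str = "site",
    covariates: list[str] | tuple[str, ...] = ("age", "sex"),
    parametric: bool = True,
) -> CombatModel:
    """Fit the ComBat model on a cohort table.

    Requires >= 2 sites with >= 3 subjects each and no missing feature
    values.  EB shrinkage engages when ``parametric`` and there are
    >= 2 features; otherwise raw per-site estimates are used
    (``eb_used=False``).
    """
    features = list(features)
    covariates = list(covariates) if covariates else []
    sites = sorted(table[batch].astype(str).unique())
    if len(sites) < 2:
        warnings.warn(
            "single site: harmonization degenerates to a no-op", stacklevel=2
        )
    counts = table[batch].astype(str).value_counts()
    if counts.min() < 3:
        raise ValueError("every site needs at least 3 subjects")
    Y = table[features].to_numpy(float)
    if np.isnan(Y).any():
        raise ValueError("missing feature values")

    tbl = table.copy()
    tbl[batch] = tbl[batch].astype(str)
    D, X = _design(tbl, sites, batch, covariates)
    n = len(tbl)
    n_i = D.sum(axis=0)  # (S,)

    for s in sites:
        sub = Y[tbl[batch].to_numpy() == s]
        if np.any(np.ptp(sub, axis=0) == 0):
            raise ValueError(f"constant feature value within site {s!r}")

    full = np.hstack([D, X])
    coef, *_ = np.linalg.lstsq(full, Y, rcond=None)
    mu = coef[: len(sites)]  # (S, F) per-site intercepts
    beta = coef[len(sites):]  # (C, F)
    alpha = (n_i / n) @ mu  # (F,)

    resid = Y - full @ coef
    var_pooled = (resid**2).mean(axis=0)  # MLE variance
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled variance")

    stand_mean = alpha[None, :] + X @ beta
    Z = (Y - stand_mean) / np.sqrt(var_pooled)

    S, F = len(sites), len(features)
    gamma_hat = np.empty((S, F))
    delta_hat = np.empty((S, F))
    site_arr = tbl[batch].to_numpy()
    for i, s in enumerate(sites):
        zi = Z[site_arr == s]
        gamma_hat[i] = zi.mean(axis=0)
        delta_hat[i] = ((zi - gamma_hat[i]) ** 2).mean(axis=0)

    eb_used = bool(parametric and F >= 2)
    if eb_used:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(S):
            gamma_star[i], delta_star[i] = _eb_shrink(
                gamma_hat[i], delta_hat[i], int(n_i[i])
            )
    else:
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
    if np.any(delta_star <= 0):
        raise ValueError("nonpositive shrunken scale estimate")

    return CombatModel(
        features=features,
        sites=sites,
        covariates=covariates,
        alpha=np.asarray(alpha),
        beta=np.asarray(beta),
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        eb_used=eb_used,
        n_per_site={s: int(c) for s, c in zip(sites, n_i)},
    )


def combat_apply(
    model: CombatModel, table: pd.DataFrame, batch: str = "site"
) -> pd.DataFrame:
    """Remove fitted site effects; returns a copy with features replaced."""
    site_arr = table[batch].astype(str).to_numpy()
    unseen = set(site_arr) - set(model.sites)
    if unseen:
        raise ValueError(f"unseen site ids: {sorted(unseen)}")
    Y = table[model.features].to_numpy(float)
    X = (
        table[model.covariates].to_numpy(float)
        if model.covariates
        else np.empty((len(table), 0))
    )
    stand_mean = model.alpha[None, :] + X @ model.beta
    Z = (Y - stand_mean) / np.sqrt(model.var_pooled)
    idx = np.array([model.sites.index(s) for s in site_arr])
    Z_adj = (Z - model.gamma_star[idx]) / np.sqrt(model.delta_star[idx])
    out = table.copy()
    out[model.features] = Z_adj * np.sqrt(model.var_pooled) + stand_mean
    return out
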