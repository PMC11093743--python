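"""Wave-stress/morphometry coupling and AICc model ranking.

Per site, yearly pooled mean S and HQF are regressed on the mean winter
(Jan-Mar) orbital current preceding each sampling; the determination
coefficients R2_S and R2_HQF measure how tightly that site's barnacle
shape tracks wave forcing.  Across sites, those R2 values are modelled on
topographic exposure predictors (alpha, nearshore slope, site-mean u) with
Gaussian linear models, and candidate models over all admissible term
subsets are ranked by small-sample AICc with Akaike weights ("dredge"
style, marginality enforced).  Skewed positive responses (S, HQF) use
Gamma GLMs with a log link; coefficients come from IRLS and the Gamma
shape is then estimated by maximum likelihood, so each model's parameter
count includes the shape.

Random effects are not implemented: site and intertidal level enter as
fixed factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "CouplingResult",
    "GlmFit",
    "winter_mean_u",
    "site_coupling",
    "gamma_glm_fit",
    "gaussian_lm_fit",
    "fit_glm",
    "aicc",
    "dredge",
    "mcfadden_r2",
    "r2_topography_models",
    "adjust_unit_interval",
]


@dataclass
class CouplingResult:
    """Per-site regression of pooled S and HQF on winter mean u."""

    site_id: str
    n: int
    slope_S: float
    r2_S: float
    slope_HQF: float
    r2_HQF: float
    u_bar_site: float  # long-term mean winter u at the site (m/s)


@dataclass
class GlmFit:
    """A fitted fixed-effects GLM/LM with its exact log-likelihood."""

    family: str  # "gamma_log" | "gaussian_identity"
    params: pd.Series
    loglik: float
    n_params: int  # coefficients + 1 dispersion/shape parameter
    nobs: int
    deviance: float
    shape: float | None = None  # Gamma shape (None for gaussian)
    scale: float | None = None  # Gaussian ML sigma^2
    mu: np.ndarray = field(default=None, repr=False)
    formula: str | None = None


def winter_mean_u(days: pd.DataFrame, year: int, months=(1, 2, 3)) -> float:
    """Mean daily-max orbital current over the given months of one year.

    Returns NaN when the window holds no records (missing-value marker
    propagated downstream).
    """
    dates = pd.to_datetime(pd.Series(days["date"].to_numpy()))
    mask = (dates.dt.year == year).to_numpy() & dates.dt.month.isin(set(months)).to_numpy()
    if mask.sum() == 0:
        return float("nan")
    return float(days["u_i_max"].to_numpy(float)[mask].mean())


def _ols_r2(x: np.ndarray, y: np.ndarray):
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        return 0.0, 0.0
    reg = stats.linregress(x, y)
    return float(reg.slope), float(reg.rvalue**2)


def site_coupling(site_id: str, paired: pd.DataFrame) -> CouplingResult:
    """OLS of pooled mean S and HQF on winter mean u for one site.

    ``paired`` needs columns ``winter_u``, ``mean_S``, ``HQF`` (one row per
    sampling year); rows with missing winter u are dropped. At least three
    complete pairs are required.
    """
    df = paired.dropna(subset=["winter_u", "mean_S", "HQF"])
    if len(df) < 3:
        raise InsufficientDataError(
            f"site {site_id}: need >= 3 paired year observations, got {len(df)}"
        )
    u = df["winter_u"].to_numpy(float)
    slope_S, r2_S = _ols_r2(u, df["mean_S"].to_numpy(float))
    slope_H, r2_H = _ols_r2(u, df["HQF"].to_numpy(float))
    return CouplingResult(
        site_id=site_id,
        n=len(df),
        slope_S=slope_S,
        r2_S=r2_S,
        slope_HQF=slope_H,
        r2_HQF=r2_H,
        u_bar_site=float(u.mean()),
    )


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """ML Gamma shape given fitted means; solves log(a) - digamma(a) = -c."""
    c = 1.0 + float(np.mean(np.log(y / mu) - y / mu))
    if c > -1e-12:  # essentially perfect fit
        return 1e8

    def f(log_a):
        a = np.exp(log_a)
        return np.log(a) - special.digamma(a) + c

    return float(np.exp(optimize.brentq(f, -30.0, 30.0, xtol=1e-12)))


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    return float(np.sum(stats.gamma.logpdf(y, a=shape, scale=mu / shape)))


def gamma_glm_fit(y, X, formula: str | None = None) -> GlmFit:
    """Gamma GLM with log link: IRLS coefficients, then ML shape and logLik.

    For the Gamma family the ML coefficients do not depend on the shape, so
    IRLS (via statsmodels) gives the ML betas; the shape is then profiled
    out by maximum likelihood and the log-likelihood evaluated there.

    ``X`` is the full design matrix (include the intercept column).
    """
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise DomainError("Gamma response must be strictly positive")
    Xm = np.asarray(X, float) if not isinstance(X, pd.DataFrame) else X
    Xa = np.asarray(Xm, float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise DomainError("design matrix is rank deficient")
    model = sm.GLM(y, Xm, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    mu = np.asarray(res.fittedvalues, float)
    shape = _gamma_shape_mle(y, mu)
    ll = _gamma_loglik(y, mu, shape)
    params = res.params if isinstance(res.params, pd.Series) else pd.Series(res.params)
    return GlmFit(
        family="gamma_log",
        params=params,
        loglik=ll,
        n_params=len(params) + 1,
        nobs=len(y),
        deviance=float(res.deviance),
        shape=shape,
        mu=mu,
        formula=formula,
    )


def gaussian_lm_fit(y, X, formula: str | None = None) -> GlmFit:
    """Gaussian identity-link linear model with exact ML log-likelihood."""
    y = np.asarray(y, float)
    Xa = np.asarray(X, float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise DomainError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    n = len(y)
    rss = float(np.sum(res.resid**2))
    # variance floor keeps degenerate exact fits comparable across models
    sigma2 = max(rss / n, 1e-12)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    params = res.params if isinstance(res.params, pd.Series) else pd.Series(res.params)
    return GlmFit(
        family="gaussian_identity",
        params=params,
        loglik=ll,
        n_params=len(params) + 1,
        nobs=n,
        deviance=rss,
        scale=sigma2,
        mu=np.asarray(res.fittedvalues, float),
        formula=formula,
    )


def _check_rank(exog, formula: str) -> None:
    X = np.asarray(exog, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DomainError(f"rank-deficient design for {formula!r}")


def fit_glm(formula: str, data: pd.DataFrame, family: str = "gamma_log") -> GlmFit:
    """Formula-interface fit (categorical factors expanded automatically)."""
    if family == "gamma_log":
        model = smf.glm(
            formula, data, family=sm.families.Gamma(link=sm.families.links.Log())
        )
        _check_rank(model.exog, formula)
        y = np.asarray(model.endog, float)
        if np.any(y <= 0):
            raise DomainError("Gamma response must be strictly positive")
        res = model.fit()
        mu = np.asarray(res.fittedvalues, float)
        shape = _gamma_shape_mle(y, mu)
        return GlmFit(
            family="gamma_log",
            params=res.params,
            loglik=_gamma_loglik(y, mu, shape),
            n_params=len(res.params) + 1,
            nobs=len(y),
            deviance=float(res.deviance),
            shape=shape,
            mu=mu,
            formula=formula,
        )
    if family == "gaussian_identity":
        model = smf.ols(formula, data)
        _check_rank(model.exog, formula)
        res = model.fit()
        n = int(res.nobs)
        rss = float(np.sum(res.resid**2))
        sigma2 = max(rss / n, 1e-12)
        return GlmFit(
            family="gaussian_identity",
            params=res.params,
            loglik=-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0),
            n_params=len(res.params) + 1,
            nobs=n,
            deviance=rss,
            scale=sigma2,
            mu=np.asarray(res.fittedvalues, float),
            formula=formula,
        )
    raise DomainError(f"unknown family {family!r}")


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC: -2 logLik + 2p + 2p(p+1)/(n-p-1)."""
    if n_obs <= n_params + 1:
        raise DomainError(f"AICc undefined for n={n_obs} <= p+1={n_params + 1}")
    p = n_params
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n_obs - p - 1)


def _admissible_subsets(terms):
    """All subsets of ``terms`` respecting marginality (interactions need
    every lower-order relative that is itself a candidate term)."""
    comp = {t: frozenset(t.split(":")) for t in terms}
    by_comp = {comp[t]: t for t in terms}
    out = []
    for r in range(len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            sset = set(sub)
            ok = True
            for t in sub:
                parts = sorted(comp[t])
                for k in range(1, len(parts)):
                    for lower in itertools.combinations(parts, k):
                        lt = by_comp.get(frozenset(lower))
                        if lt is not None and lt not in sset:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                out.append(tuple(sub))
    return out


def dredge(
    data: pd.DataFrame,
    response: str,
    terms,
    family: str = "gaussian_identity",
) -> pd.DataFrame:
    """Fit every admissible term subset and rank by AICc.

    Returns a DataFrame sorted by (AICc, df) with columns ``terms``
    (``+``-joined, ``"1"`` for the null model), ``df``, ``logLik``,
    ``AICc``, ``delta`` and Akaike ``weight`` (weights sum to 1 over the
    models that fit successfully), plus the fitted objects in ``fit``.
    """
    rows = []
    for sub in _admissible_subsets(list(terms)):
        rhs = " + ".join(sub) if sub else "1"
        formula = f"{response} ~ {rhs}"
        try:
            f = fit_glm(formula, data, family)
            rows.append(
                {
                    "terms": rhs,
                    "df": f.n_params,
                    "logLik": f.loglik,
                    "AICc": aicc(f.loglik, f.n_params, f.nobs),
                    "fit": f,
                    "failed": False,
                }
            )
        except Exception as exc:  # noqa: BLE001 - failed members are flagged
            rows.append(
                {
                    "terms": rhs,
                    "df": np.nan,
                    "logLik": np.nan,
                    "AICc": np.nan,
                    "fit": None,
                    "failed": True,
                    "error": str(exc),
                }
            )
    tab = pd.DataFrame(rows)
    ok = ~tab["failed"]
    best = tab.loc[ok, "AICc"].min()
    tab.loc[ok, "delta"] = tab.loc[ok, "AICc"] - best
    w = np.exp(-0.5 * tab.loc[ok, "delta"])
    tab.loc[ok, "weight"] = w / w.sum()
    tab = tab.sort_values(["AICc", "df"], na_position="last").reset_index(drop=True)
    return tab


def mcfadden_r2(fit: GlmFit, null_fit: GlmFit) -> float:
    """McFadden pseudo-R2: 1 - logLik(fit)/logLik(null)."""
    if null_fit.loglik == 0.0:
        raise DomainError("null log-likelihood is zero; pseudo-R2 undefined")
    return float(1.0 - fit.loglik / null_fit.loglik)


def r2_topography_models(
    site_table: pd.DataFrame,
    response: str = "r2_S",
) -> pd.DataFrame:
    """Rank Gaussian models of per-site R2 on topographic predictors.

    ``site_table`` needs one row per site with columns ``alpha``, ``slope``,
    ``u_bar`` and the response (``r2_S`` or ``r2_HQF``). All main effects
    and interactions of the three predictors are candidates.
    """
    if len(site_table) < 8:
        raise InsufficientDataError(
            f"need >= 8 sites for topographic models, got {len(site_table)}"
        )
    terms = [
        "alpha",
        "slope",
        "u_bar",
        "alpha:slope",
        "alpha:u_bar",
        "slope:u_bar",
        "alpha:slope:u_bar",
    ]
    return dredge(site_table, response, terms, family="gaussian_identity")


def adjust_unit_interval(p, n):
    """Compress proportions away from {0, 1}: (p*(n-1) + 0.5)/n.

    Applied to HQF before Gamma fitting, which needs a strictly positive
    response.
    """
    p = np.asarray(p, float)
    n = np.asarray(n, float)
    out = (p * (n - 1) + 0.5) / n
    return out if out.ndim else float(out)
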