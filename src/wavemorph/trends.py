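"""Seasonal/long-term decomposition of daily orbital-current series.

The daily maximum orbital current u(t) is modelled as an additive sum

    u(t) = f_trend(t) + f_season(day of year) + eps

with a clamped cubic B-spline basis for the slow trend (default 15 basis
functions) and a cyclic cubic B-spline basis for the annual cycle (default
12), fitted jointly by penalized least squares with second-difference
(P-spline) penalties.  Smoothing strength is chosen by generalized
cross-validation on a fixed log-spaced lambda grid, ties broken toward the
smoother fit.  The long-term rate of change is the OLS slope of the fitted
trend component against time in years; seasonal-subset (e.g. Jan-Mar)
trends are OLS fits to yearly subset means.

This is a deterministic stand-in for mixed-model additive smoothers: no
random effects, no autocorrelation structure, and slope p-values come from
plain OLS t-tests (a noted limitation for serially correlated series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .errors import InsufficientDataError

__all__ = ["TrendFit", "SubsetTrend", "decompose", "subset_trend"]

#: period of the seasonal cycle in days
YEAR_DAYS = 365.25

#: GCV search grid for the smoothing parameters
LAMBDA_GRID = np.logspace(-4, 4, 10)


@dataclass
class TrendFit:
    """Result of the additive trend/seasonal decomposition."""

    dates: np.ndarray
    trend_values: np.ndarray
    seasonal_values: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    linear_slope: float
    slope_se: float
    slope_p: float
    knots_trend: int
    knots_seasonal: int
    lambda_trend: float
    lambda_seasonal: float

    @property
    def seasonal_peak_doy(self) -> float:
        """Day of year at which the fitted seasonal component peaks."""
        grid = np.arange(0.0, YEAR_DAYS, 0.25)
        vals = self._seasonal_on(grid)
        return float(grid[np.argmax(vals)]) + 1.0

    # populated by decompose() so the seasonal shape can be re-evaluated
    _seasonal_on: callable = field(default=None, repr=False, compare=False)


@dataclass
class SubsetTrend:
    """Linear trend of yearly means restricted to a set of months."""

    months: frozenset
    annual_means: pd.Series  # index: year
    linear_slope: float
    slope_se: float
    slope_p: float


def _folded_doy(ts: pd.Series) -> np.ndarray:
    """0-based day of year with Feb 29 folded onto Feb 28 (doy 58)."""
    doy = ts.dt.dayofyear.to_numpy(float)
    leap = ts.dt.is_leap_year.to_numpy()
    doy = np.where(leap & (doy >= 60), doy - 1.0, doy)
    return doy - 1.0


def _trend_design(x: np.ndarray, n_basis: int, degree: int = 3):
    """Clamped cubic B-spline design matrix with ``n_basis`` columns."""
    x0, x1 = float(x.min()), float(x.max())
    inner = np.linspace(x0, x1 + 1e-9, n_basis - degree + 1)
    t = np.r_[[x0] * degree, inner, [x1 + 1e-9] * degree]
    B = BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()
    return B


def _cyclic_design(doy: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Periodic cubic B-spline design on [0, YEAR_DAYS) with ``n_basis`` columns.

    Each column is a shifted copy of the cardinal cubic B-spline, with the
    argument wrapped modulo the period; columns form a partition of unity.
    """
    h = YEAR_DAYS / n_basis
    card = BSpline.basis_element(np.arange(degree + 2) * h, extrapolate=False)
    B = np.empty((len(doy), n_basis))
    for j in range(n_basis):
        arg = np.mod(doy - j * h, YEAR_DAYS)
        vals = card(arg)
        B[:, j] = np.nan_to_num(vals, nan=0.0)
    return B


def _diff2(n: int) -> np.ndarray:
    return np.diff(np.eye(n), n=2, axis=0)


def _cyclic_diff2(n: int) -> np.ndarray:
    D = np.zeros((n, n))
    for i in range(n):
        D[i, i] += 1.0
        D[i, (i + 1) % n] -= 2.0
        D[i, (i + 2) % n] += 1.0
    return D


def decompose(
    series: pd.DataFrame,
    knots_trend: int = 15,
    knots_seasonal: int = 12,
) -> TrendFit:
    """Fit the additive trend + seasonal model to a daily ``u_i_max`` series.

    Parameters
    ----------
    series : DataFrame
        Columns ``date`` (datetime-like) and ``u_i_max`` (m/s). Gaps are
        allowed; the basis is evaluated at the observed days only.
    knots_trend, knots_seasonal : int
        Number of basis functions for the long-term and seasonal smooths.

    Raises
    ------
    InsufficientDataError
        If the series spans fewer than two full years.
    """
    dates = pd.to_datetime(pd.Series(series["date"].to_numpy()))
    y = series["u_i_max"].to_numpy(float)
    order = np.argsort(dates.to_numpy())
    dates = dates.iloc[order].reset_index(drop=True)
    y = y[order]

    span_days = (dates.iloc[-1] - dates.iloc[0]).days
    if span_days < 2 * 365:
        raise InsufficientDataError(
            f"need at least 2 full years of data, got {span_days} days"
        )

    t_years = (dates - dates.iloc[0]).dt.days.to_numpy(float) / YEAR_DAYS
    doy = _folded_doy(dates)

    Bt = _trend_design(t_years, knots_trend)
    Bs = _cyclic_design(doy, knots_seasonal)
    s_means = Bs.mean(axis=0)
    Bs_c = Bs - s_means  # remove confounding with the trend intercept

    X = np.hstack([Bt, Bs_c])
    nt, ns = Bt.shape[1], Bs.shape[1]
    Dt = _diff2(nt)
    Ds = _cyclic_diff2(ns)
    Pt = Dt.T @ Dt
    Ps = Ds.T @ Ds
    XtX = X.T @ X
    Xty = X.T @ y
    n = len(y)
    # tiny ridge pins the seasonal sum-to-zero null direction
    ridge = 1e-8 * np.eye(nt + ns)
    ridge[:nt, :nt] = 0.0

    best = None
    for lam_t in LAMBDA_GRID:
        for lam_s in LAMBDA_GRID:
            P = np.zeros_like(XtX)
            P[:nt, :nt] = lam_t * Pt
            P[nt:, nt:] = lam_s * Ps
            A = XtX + P + ridge
            beta = np.linalg.solve(A, Xty)
            edf = np.trace(np.linalg.solve(A, XtX))
            rss = float(np.sum((y - X @ beta) ** 2))
            gcv = n * rss / (n - edf) ** 2
            # <= prefers larger lambda (grid scanned small -> large)
            if best is None or gcv <= best[0]:
                best = (gcv, lam_t, lam_s, beta)
    _, lam_t, lam_s, beta = best

    beta_t, beta_s = beta[:nt], beta[nt:]
    trend_vals = Bt @ beta_t
    seas_vals = Bs_c @ beta_s

    # re-centre so the seasonal component averages to zero over one year
    grid = np.arange(0.0, YEAR_DAYS, 0.25)
    seas_grid = (_cyclic_design(grid, knots_seasonal) - s_means) @ beta_s
    offset = float(seas_grid.mean())
    trend_vals = trend_vals + offset
    seas_vals = seas_vals - offset

    fitted = trend_vals + seas_vals
    resid = y - fitted

    reg = stats.linregress(t_years, trend_vals)

    def seasonal_on(doy_grid: np.ndarray) -> np.ndarray:
        return (_cyclic_design(np.asarray(doy_grid, float), knots_seasonal) - s_means) @ beta_s - offset

    fit = TrendFit(
        dates=dates.to_numpy(),
        trend_values=trend_vals,
        seasonal_values=seas_vals,
        fitted=fitted,
        residuals=resid,
        linear_slope=float(reg.slope),
        slope_se=float(reg.stderr),
        slope_p=float(reg.pvalue),
        knots_trend=knots_trend,
        knots_seasonal=knots_seasonal,
        lambda_trend=float(lam_t),
        lambda_seasonal=float(lam_s),
    )
    fit._seasonal_on = seasonal_on
    return fit


def subset_trend(series: pd.DataFrame, months) -> SubsetTrend:
    """Linear trend of yearly mean u over a fixed month subset (e.g. {1,2,3}).

    Years with no records in the subset are absent from the yearly means.
    Requires at least three represented years.
    """
    months = frozenset(int(m) for m in months)
    if not months:
        raise InsufficientDataError("month subset must be non-empty")
    dates = pd.to_datetime(pd.Series(series["date"].to_numpy()))
    u = series["u_i_max"].to_numpy(float)
    mask = dates.dt.month.isin(months).to_numpy()
    if mask.sum() == 0:
        raise InsufficientDataError("no records fall in the requested months")
    yearly = (
        pd.DataFrame({"year": dates.dt.year.to_numpy()[mask], "u": u[mask]})
        .groupby("year")["u"]
        .mean()
    )
    if len(yearly) < 3:
        raise InsufficientDataError(
            f"need >= 3 yearly means for a subset trend, got {len(yearly)}"
        )
    x = yearly.index.to_numpy(float)
    yv = yearly.to_numpy(float)
    if np.ptp(yv) == 0.0:
        slope, se, p = 0.0, 0.0, 1.0
    else:
        reg = stats.linregress(x, yv)
        slope, se, p = float(reg.slope), float(reg.stderr), float(reg.pvalue)
    return SubsetTrend(
        months=months,
        annual_means=yearly,
        linear_slope=slope,
        slope_se=se,
        slope_p=p,
    )
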