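"""Quality-morphometry geometry: the Gompertz HQF(S) law and the TL-DBC
quality domain.

Across sites and years the high quality fraction falls with the population
mean morphometric index S along a descending sigmoid

    HQF(S) = A / (1 + exp((S - x0)/b)),   b > 0

(A ~ 1: near-100% quality at low S).  In the TL-DBC plane a population
with mean index S lies on the ray TL = S*DBC; where that ray crosses the
sigmoidal quality-limit curve marks the largest capitulum diameter at
which an average individual is still good quality.  Rays for low S may
never cross the limit within the observed size range - every size class
is then good quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DomainError, FitFailureError, InsufficientDataError
from .morphometry import PARADA_DEFAULT, ParadaParams, is_good_quality, parada_limit

__all__ = [
    "GompertzFit",
    "GOMPERTZ_REPORTED",
    "gompertz_predict",
    "fit_gompertz",
    "ray_limit_intersection",
    "quality_domain_report",
    "plot_quality_domain",
]


@dataclass(frozen=True)
class GompertzFit:
    """Parameters of the descending sigmoid HQF(S) = A/(1+exp((S-x0)/b))."""

    A: float
    x0: float
    b: float
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.b > 0):
            raise DomainError("require A > 0 and b > 0")


#: published parameterisation of the HQF(S) sigmoid (field-data fit)
GOMPERTZ_REPORTED = GompertzFit(A=1.0116, x0=3.1816, b=0.2782, r2=0.798)


def gompertz_predict(S, params: GompertzFit = GOMPERTZ_REPORTED):
    """Predicted HQF at morphometric index S (fraction, decreasing in S)."""
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0):
        raise DomainError("S must be positive")
    out = params.A / (1.0 + np.exp((S - params.x0) / params.b))
    return out if out.ndim else float(out)


def fit_gompertz(S, HQF) -> GompertzFit:
    """Nonlinear least-squares fit of the descending sigmoid to (S, HQF).

    Multi-start: x0 over quantiles of S, b over {0.1, 0.3, 1.0}, A started
    at max(HQF); the best sum of squares wins.  Needs >= 5 points spanning
    the transition; a flat response cannot pin the midpoint and raises
    :class:`FitFailureError`.
    """
    S = np.asarray(S, float)
    H = np.asarray(HQF, float)
    if S.size < 5:
        raise InsufficientDataError("need >= 5 points to fit the sigmoid")
    if np.ptp(H) < 1e-12:
        raise FitFailureError("response is constant; sigmoid midpoint unidentifiable")

    def model(s, A, x0, b):
        return A / (1.0 + np.exp((s - x0) / b))

    best = None
    for q in (0.25, 0.5, 0.75):
        for b0 in (0.1, 0.3, 1.0):
            p0 = (max(float(H.max()), 1e-6), float(np.quantile(S, q)), b0)
            try:
                popt, _ = optimize.curve_fit(
                    model,
                    S,
                    H,
                    p0=p0,
                    bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((H - model(S, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise FitFailureError("sigmoid fit did not converge from any start")
    sse, (A, x0, b) = best
    sst = float(np.sum((H - H.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return GompertzFit(A=float(A), x0=float(x0), b=float(b), r2=r2)


def ray_limit_intersection(
    S: float,
    params: ParadaParams = PARADA_DEFAULT,
    domain=(2.0, 50.0),
    tol: float = 1e-8,
) -> np.ndarray:
    """All DBC (mm) in ``domain`` where the ray TL = S*DBC meets the limit.

    Roots of f(DBC) = S*DBC - TL_limit(DBC), located by sign-change
    bracketing on a fine grid followed by bisection (brentq) to ``tol`` mm.
    An empty array is a valid outcome: the ray stays on one side of the
    limit over the whole domain.
    """
    if S <= 0:
        raise DomainError("S must be positive")
    lo, hi = float(domain[0]), float(domain[1])
    if not (0 < lo < hi):
        raise DomainError(f"invalid DBC domain {domain}")

    def f(d):
        return S * d - parada_limit(d, params)

    grid = np.linspace(lo, hi, 2001)
    vals = f(grid)
    roots = []
    exact = np.flatnonzero(vals == 0.0)
    roots.extend(grid[exact])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    for i in sign_change:
        roots.append(optimize.brentq(f, grid[i], grid[i + 1], xtol=tol))
    return np.array(sorted(set(np.round(roots, 12))))


def quality_domain_report(
    S_values,
    params: ParadaParams = PARADA_DEFAULT,
    legal_min_dbc: float = 15.0,
    optimum_dbc: float = 18.01,
    domain=(2.0, 50.0),
) -> pd.DataFrame:
    """Good-quality size envelope for each population mean S.

    For each S: the largest good-quality DBC within ``domain`` (NaN with
    flag ``unbounded_in_domain`` when the ray never crosses the limit, i.e.
    every size class is good), and the good/bad classification of an
    average-shaped individual at the legal minimum size and at the optimum
    capture size.
    """
    rows = []
    for S in np.atleast_1d(np.asarray(S_values, float)):
        roots = ray_limit_intersection(S, params, domain)
        max_good = float(roots[0]) if roots.size else float("nan")
        rows.append(
            {
                "S": float(S),
                "max_good_dbc_mm": max_good,
                "unbounded_in_domain": roots.size == 0,
                "good_at_legal_min": bool(
                    is_good_quality(S * legal_min_dbc, legal_min_dbc, params)
                ),
                "good_at_optimum": bool(
                    is_good_quality(S * optimum_dbc, optimum_dbc, params)
                ),
            }
        )
    return pd.DataFrame(rows)


def plot_quality_domain(
    S_values=(2.37, 3.27, 1.51),
    params: ParadaParams = PARADA_DEFAULT,
    legal_min_dbc: float = 15.0,
    optimum_dbc: float = 18.01,
    domain=(2.0, 50.0),
    ax=None,
):
    """Diagnostic TL-DBC plot: quality limit, constant-S rays, size marks."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    d = np.linspace(domain[0], domain[1], 400)
    limit = parada_limit(d, params)
    ax.plot(d, limit, label="quality limit")
    ax.fill_between(d, 0, limit, alpha=0.15)
    for S in S_values:
        ax.plot(d, S * d, lw=1, label=f"S = {S:g}")
        roots = ray_limit_intersection(S, params, domain)
        for r in roots:
            ax.axvline(r, color="k", lw=0.6, alpha=0.6)
            ax.plot([r], [S * r], "ko", ms=4)
    ax.axvline(legal_min_dbc, color="red", lw=2, alpha=0.6, label="legal min DBC")
    ax.axvline(optimum_dbc, color="green", lw=2, alpha=0.6, label="optimum DBC")
    ax.set_xlabel("DBC (mm)")
    ax.set_ylabel("TL (mm)")
    ax.set_ylim(0, params.tl_max * 1.4)
    ax.legend(fontsize=8)
    return ax
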