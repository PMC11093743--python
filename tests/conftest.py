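"""Shared fixtures and independent numerical oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("repro")

G = 9.81


# ---------------------------------------------------------------- oracles
def exact_wavelength(T: float, d: float, g: float = G) -> float:
    """Wavelength from the exact dispersion relation sigma^2 = g k tanh(kd),
    solved iteratively; independent of the Eckart closed form under test."""
    sigma = 2.0 * np.pi / T
    f = lambda k: g * k * np.tanh(k * d) - sigma**2  # noqa: E731
    k = brentq(f, 1e-10, 1e4, xtol=1e-14, rtol=1e-14)
    return 2.0 * np.pi / k


def group_velocity_shoaling(H_o, T, d_o, d_i, g: float = G) -> float:
    """Shoaling via K_s = sqrt(c_g,o / c_g,i) with exact dispersion."""
    sigma = 2.0 * np.pi / T

    def cg(d):
        L = exact_wavelength(T, d, g)
        k = 2.0 * np.pi / L
        c = sigma / k
        return 0.5 * c * (1.0 + 2.0 * k * d / np.sinh(2.0 * k * d))

    return H_o * np.sqrt(cg(d_o) / cg(d_i))


def grid_gamma_mle_loglik(y, X, rounds: int = 5, pts: int = 21) -> float:
    """Maximum Gamma-GLM (log link) log-likelihood by iterated grid search
    over (betas, log shape); independent of any IRLS machinery."""
    from scipy.stats import gamma as gamma_dist

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]
    centers = np.zeros(p + 1)
    centers[0] = np.log(y.mean())
    widths = np.full(p + 1, 4.0)

    best_ll, best_par = -np.inf, centers.copy()
    for _ in range(rounds):
        axes = [np.linspace(c - w, c + w, pts) for c, w in zip(centers, widths)]
        mesh = np.meshgrid(*axes, indexing="ij")
        params = np.stack([m.ravel() for m in mesh], axis=1)  # (m, p+1)
        eta = X @ params[:, :p].T  # (n, m)
        mu = np.exp(eta)
        shape = np.exp(params[:, p])  # (m,)
        ll = gamma_dist.logpdf(y[:, None], a=shape[None, :], scale=mu / shape[None, :]).sum(
            axis=0
        )
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best_par = float(ll[i]), params[i].copy()
        centers = best_par
        widths = widths * 2.5 / (pts - 1)  # shrink around the incumbent
    return best_ll


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def parada():
    from wavemorph.morphometry import PARADA_DEFAULT

    return PARADA_DEFAULT


@pytest.fixture(scope="session")
def small_world():
    """One seeded synthetic study system shared across tests."""
    from wavemorph.simulate import WorldConfig, gen_world

    return gen_world(WorldConfig(seed=7))


@pytest.fixture()
def barnacle_frame():
    """Hand-built tiny barnacle table: 2 sites x 2 dates, known S values."""
    rows = []
    for site, dates in [("A", ["2015-07-01", "2016-07-01"]), ("B", ["2015-07-01"])]:
        for d in dates:
            for level, s_vals in [("lower", (1.0, 2.0)), ("middle", (3.0,))]:
                for s in s_vals:
                    rows.append(
                        {
                            "site_id": site,
                            "date": d,
                            "level": level,
                            "TL_mm": 10.0 * s,
                            "DBC_mm": 10.0,
                        }
                    )
    return pd.DataFrame(rows)
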