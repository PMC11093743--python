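"""Seeded synthetic generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes:

* an hourly offshore sea-state series with a seasonal cycle peaking in
  January-March, a long-term linear increase, persistent (AR(1)) noise and
  Poisson winter storm bursts, with periods correlated with heights and
  directions von Mises-concentrated around a prevailing bearing;
* barnacle morphometric records (30-50 individuals per site x intertidal
  level x year) in which the morphometric index S - not TL - is the
  generative variable, with site-specific sensitivity of mean S to the
  preceding-winter orbital current ("coupled" sites) or none
  ("decoupled" sites), and TL = S * DBC derived;
* an idealized straight coastline with planar seaward-sloping bathymetry
  and therefore known ground-truth shore normal, incidence angle and slope.

Every generator is deterministic per seed (numpy PCG64) and returns a
ground-truth sidecar dict alongside the data so parameter-recovery tests
can close the loop.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import DomainError
from .topography import BathymetryGrid, Coastline, LocalProjection
from .waves import PhysicalConstants, WavePoint, daily_max_inshore

__all__ = [
    "WaveGenConfig",
    "PopGenConfig",
    "CoastGenConfig",
    "WorldConfig",
    "gen_wave_series",
    "gen_barnacle_population",
    "gen_coast_bathy",
    "gen_world",
]

#: intertidal-level shifts of mean S (upper shore animals are slightly
#: stubbier / higher quality)
LEVEL_SHIFTS = {"lower": 0.05, "middle": 0.0, "upper": -0.05}


@dataclass(frozen=True)
class WaveGenConfig:
    """Offshore sea-state generator settings.

    Defaults reproduce the hindcast study conditions: a 15-year hourly
    series (2006 onward) whose winter (Jan-Mar) daily-max orbital currents
    sit in the 5-8 m/s range and summer in the 4-5 m/s range, with a
    long-term height increase equivalent to roughly +0.07 m/s/yr in u.
    """

    years: int = 15
    start_year: int = 2006
    base_H: float = 1.4  # mean offshore significant height, m
    seasonal_amplitude: float = 0.9  # m, cosine peaking in late January
    seasonal_peak_doy: float = 30.0
    trend_H: float = 0.055  # m of offshore H per year
    storm_rate: float = 10.0  # Poisson events per winter (Nov-Mar)
    storm_scale: float = 1.2  # mean exponential height surcharge, m
    storm_decay_h: float = 12.0  # e-folding of a storm burst, hours
    noise_sd: float = 0.45  # marginal sd of the AR(1) hourly noise, m
    ar_phi: float = 0.9
    prevailing_dir: float = 280.0  # waves come from WNW
    dir_kappa: float = 4.0
    tp_base: float = 4.5  # s
    tp_per_sqrtH: float = 3.2  # s per sqrt(m)
    d_o: float = 100.0  # offshore depth at the model point, m
    point_id: str = "SYN0"
    lon: float = -9.1
    lat: float = 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 2:
            raise DomainError("need at least 2 years of waves")
        for name in ("seasonal_amplitude", "storm_rate", "storm_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PopGenConfig:
    """Barnacle population generator settings.

    Mean S per site-year responds to the preceding-winter mean orbital
    current with sensitivity ``coupling_beta`` (S per m/s; negative means
    rougher winters widen the animals) at coupled sites and 0 at decoupled
    sites.
    """

    n_sites: int = 26
    years: int = 8
    start_year: int = 2013
    n_min: int = 30
    n_max: int = 50
    S_mean: float = 2.37  # grand mean of the morphometric index
    S_site_sd: float = 0.25  # between-site spread of mean S
    S_sigma: float = 0.22  # within-group lognormal sigma of S
    coupling_beta: float = -0.15  # change in mean S per m/s of winter u
    coupled_fraction: float = 0.5
    dbc_median: float = 10.0  # mm
    dbc_sigma: float = 0.4  # lognormal sigma of DBC
    dbc_range: tuple = (2.05, 35.0)  # mm, post-filter support
    sampling_month: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30 <= self.n_min <= self.n_max <= 50):
            raise DomainError("group sizes must lie within [30, 50]")


@dataclass(frozen=True)
class CoastGenConfig:
    """Idealized coast + planar bathymetry around one site."""

    center_lon: float = -8.885
    center_lat: float = 42.0
    orientation: float = 0.0  # coastline bearing, deg (0 = N-S)
    seaward_bearing: float = 270.0  # which side the ocean is on
    true_slope: float = 0.02  # depth increase per metre seaward
    curvature: float = 0.0  # lateral offset per m^2 (gentle bends)
    coast_half_length: float = 2500.0  # m
    grid_half_extent: float = 2500.0  # m
    cell_size_deg: float = 4.0e-4  # ~40 m
    seed: int = 0


@dataclass(frozen=True)
class WorldConfig:
    """A complete synthetic study system.

    Half the sites (by default) are "coupled" with gentle nearshore slopes,
    half "decoupled" with steep slopes, mirroring the exposure contrast the
    coupling analysis is meant to resolve.
    """

    n_sites: int = 8
    years_waves: int = 10
    years_pop: int = 8
    start_year: int = 2011
    pop_start_year: int = 2013
    gentle_slope: float = 0.02
    steep_slope: float = 0.09
    coupled_fraction: float = 0.5
    coupling_beta: float = -0.3
    S_sigma: float = 0.22
    year_noise_sd: float = 0.03  # extra site-year noise on mean S
    seed: int = 0


def _hourly_index(start_year: int, years: int) -> pd.DatetimeIndex:
    return pd.date_range(
        start=f"{start_year}-01-01",
        end=f"{start_year + years - 1}-12-31 23:00",
        freq="h",
        tz="UTC",
    )


def gen_wave_series(cfg: WaveGenConfig):
    """Generate the hourly offshore sea-state table for one model point.

    Returns ``(df, point, truth)``: a DataFrame with columns
    ``timestamp, point_id, Hs_m, Tp_s, dir_deg``, the :class:`WavePoint`,
    and a ground-truth dict (injected trend, seasonal amplitude, ...).
    """
    rng = np.random.default_rng(cfg.seed)
    idx = _hourly_index(cfg.start_year, cfg.years)
    n = len(idx)
    t_years = (idx - idx[0]).days.to_numpy(float) / 365.25
    doy = idx.dayofyear.to_numpy(float)

    seasonal = cfg.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - cfg.seasonal_peak_doy) / 365.25
    )
    trend = cfg.trend_H * t_years

    innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.ar_phi**2)
    noise = lfilter([1.0], [1.0, -cfg.ar_phi], rng.normal(0.0, innov_sd, n))

    storms = np.zeros(n)
    winter = np.isin(idx.month.to_numpy(), (11, 12, 1, 2, 3))
    # winter season label: Nov/Dec belong to the following year's winter
    season = idx.year.to_numpy() + (idx.month.to_numpy() >= 11)
    for s in np.unique(season[winter]):
        hours = np.flatnonzero(winter & (season == s))
        k = rng.poisson(cfg.storm_rate)
        if k == 0 or hours.size == 0:
            continue
        centers = rng.choice(hours, size=k, replace=True)
        amps = rng.exponential(cfg.storm_scale, size=k)
        for c, a in zip(centers, amps):
            lo = max(0, c - 72)
            hi = min(n, c + 73)
            rel = np.arange(lo, hi) - c
            storms[lo:hi] += a * np.exp(-np.abs(rel) / cfg.storm_decay_h)

    H = np.maximum(0.1, cfg.base_H + seasonal + trend + noise + storms)
    Tp = np.clip(
        cfg.tp_base + cfg.tp_per_sqrtH * np.sqrt(H) + rng.normal(0.0, 0.5, n),
        3.0,
        22.0,
    )
    dirs = (np.degrees(rng.vonmises(0.0, cfg.dir_kappa, n)) + cfg.prevailing_dir) % 360.0

    df = pd.DataFrame(
        {
            "timestamp": idx,
            "point_id": cfg.point_id,
            "Hs_m": H,
            "Tp_s": Tp,
            "dir_deg": dirs,
        }
    )
    point = WavePoint(point_id=cfg.point_id, lon=cfg.lon, lat=cfg.lat, d_o=cfg.d_o)
    truth = {"config": asdict(cfg)}
    return df, point, truth


def gen_barnacle_population(cfg: PopGenConfig, winter_u: pd.DataFrame):
    """Generate individual TL/DBC records driven by winter orbital currents.

    ``winter_u`` needs columns ``site_id, year, winter_u`` covering every
    site x sampling year (raises :class:`DomainError` on gaps).  Returns
    ``(records, truth)`` where ``records`` has columns
    ``site_id, date, level, TL_mm, DBC_mm``.
    """
    rng = np.random.default_rng(cfg.seed)
    site_ids = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]
    n_coupled = int(round(cfg.coupled_fraction * cfg.n_sites))
    coupled = {s: i < n_coupled for i, s in enumerate(site_ids)}
    site_base = {
        s: float(rng.normal(cfg.S_mean, cfg.S_site_sd)) for s in site_ids
    }
    years = list(range(cfg.start_year, cfg.start_year + cfg.years))

    wu = winter_u.set_index(["site_id", "year"])["winter_u"]
    for s in site_ids:
        for y in years:
            if (s, y) not in wu.index or not np.isfinite(wu.loc[(s, y)]):
                raise DomainError(f"missing winter u for site {s}, year {y}")
    u_site_mean = {
        s: float(np.mean([wu.loc[(s, y)] for y in years])) for s in site_ids
    }

    rows = []
    for s in site_ids:
        beta = cfg.coupling_beta if coupled[s] else 0.0
        for y in years:
            shift = beta * (float(wu.loc[(s, y)]) - u_site_mean[s])
            for level, lshift in LEVEL_SHIFTS.items():
                n_ind = int(rng.integers(cfg.n_min, cfg.n_max + 1))
                mean_S = max(0.5, site_base[s] + shift + lshift)
                mu_ln = np.log(mean_S) - cfg.S_sigma**2 / 2.0
                S = rng.lognormal(mu_ln, cfg.S_sigma, n_ind)
                dbc = np.clip(
                    rng.lognormal(np.log(cfg.dbc_median), cfg.dbc_sigma, n_ind),
                    cfg.dbc_range[0],
                    cfg.dbc_range[1],
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "site_id": s,
                            "date": f"{y}-{cfg.sampling_month:02d}-01",
                            "level": level,
                            "TL_mm": S * dbc,
                            "DBC_mm": dbc,
                        }
                    )
                )
    records = pd.concat(rows, ignore_index=True)
    truth = {
        "config": asdict(cfg),
        "coupled": coupled,
        "site_base_S": site_base,
        "u_site_mean": u_site_mean,
    }
    return records, truth


def gen_coast_bathy(cfg: CoastGenConfig):
    """Idealized coastline and planar bathymetry around one site.

    The coastline runs through the site along ``orientation``; depth grows
    linearly with signed seaward distance at ``true_slope`` (negative
    values inland represent land elevation, keeping the surface planar so
    bilinear sampling is exact).  Returns ``(coast, bathy, truth)``.
    """
    proj = LocalProjection(cfg.center_lon, cfg.center_lat)
    b = np.radians(cfg.orientation)
    along = np.array([np.sin(b), np.cos(b)])
    sw = np.radians(cfg.seaward_bearing)
    seaward = np.array([np.sin(sw), np.cos(sw)])

    s = np.linspace(-cfg.coast_half_length, cfg.coast_half_length, 101)
    pts = np.outer(s, along) + np.outer(cfg.curvature * s**2, seaward)
    lon, lat = proj.to_lonlat(pts[:, 0], pts[:, 1])
    coast = Coastline(np.column_stack([lon, lat]))

    half_deg = cfg.grid_half_extent / 111_000.0
    nrows = ncols = int(np.ceil(2 * half_deg / cfg.cell_size_deg)) + 1
    xll = cfg.center_lon - (ncols / 2) * cfg.cell_size_deg
    yll = cfg.center_lat - (nrows / 2) * cfg.cell_size_deg
    lon_c = xll + cfg.cell_size_deg * (np.arange(ncols) + 0.5)
    lat_c = yll + cfg.cell_size_deg * (nrows - 1 - np.arange(nrows) + 0.5)
    LON, LAT = np.meshgrid(lon_c, lat_c)
    X, Y = proj.to_xy(LON, LAT)
    d_seaward = X * seaward[0] + Y * seaward[1]
    depth = cfg.true_slope * d_seaward
    bathy = BathymetryGrid(
        data=depth, xll=xll, yll=yll, cellsize=cfg.cell_size_deg
    )
    truth = {
        "config": asdict(cfg),
        "shore_normal": cfg.seaward_bearing % 360.0,
        "slope": -cfg.true_slope,
    }
    return coast, bathy, truth


def gen_world(cfg: WorldConfig):
    """Generate a coherent synthetic study system.

    One offshore model point drives all sites.  Sites alternate between
    "coupled + gentle slope" and "decoupled + steep slope" profiles; site
    mean S responds to the preceding-winter mean orbital current only at
    coupled sites.  Returns a dict with keys ``waves`` (hourly df),
    ``point``, ``inshore`` (daily df), ``winter_u`` (site x year df),
    ``records`` (barnacle df), ``sites`` (per-site profile df with ground
    truth), and ``truth``.
    """
    from .coupling import winter_mean_u  # deferred: avoids a cycle

    rng = np.random.default_rng(cfg.seed)
    wave_cfg = WaveGenConfig(
        years=cfg.years_waves,
        start_year=cfg.start_year,
        seed=int(rng.integers(2**31 - 1)),
    )
    waves_df, point, wave_truth = gen_wave_series(wave_cfg)
    inshore = daily_max_inshore(waves_df, point, PhysicalConstants())

    years = list(range(cfg.pop_start_year, cfg.pop_start_year + cfg.years_pop))
    u_by_year = {y: winter_mean_u(inshore, y) for y in years}

    n_coupled = int(round(cfg.coupled_fraction * cfg.n_sites))
    site_rows = []
    for i in range(cfg.n_sites):
        coupled = i < n_coupled
        orientation = float((13.0 * i) % 75.0)  # varies exposure angle alpha
        site_rows.append(
            {
                "site_id": f"S{i + 1:02d}",
                "coupled": coupled,
                "true_slope": cfg.gentle_slope if coupled else cfg.steep_slope,
                "lat": 41.90 + 0.02 * i,
                "lon": -8.885,
                "orientation": orientation,
                "seaward_bearing": (orientation + 270.0) % 360.0,
                # local fetch/sheltering multiplier on the shared offshore u
                "exposure_factor": float(rng.uniform(0.85, 1.15)),
            }
        )
    sites = pd.DataFrame(site_rows)

    winter_u = pd.DataFrame(
        [
            {"site_id": s, "year": y, "winter_u": f * u_by_year[y]}
            for s, f in zip(sites["site_id"], sites["exposure_factor"])
            for y in years
        ]
    )

    pop_cfg = PopGenConfig(
        n_sites=cfg.n_sites,
        years=cfg.years_pop,
        start_year=cfg.pop_start_year,
        coupling_beta=cfg.coupling_beta,
        coupled_fraction=cfg.coupled_fraction,
        S_sigma=cfg.S_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )
    records, pop_truth = gen_barnacle_population(pop_cfg, winter_u)

    # extra site-year noise on S (environmental variability beyond waves)
    if cfg.year_noise_sd > 0:
        key = records["site_id"] + "|" + records["date"].astype(str)
        shifts = {
            k: rng.normal(0.0, cfg.year_noise_sd) for k in key.unique()
        }
        factor = 1.0 + key.map(shifts).to_numpy() / records.eval("TL_mm / DBC_mm").mean()
        records["TL_mm"] = records["TL_mm"] * np.maximum(factor, 0.1)

    truth = {
        "wave": wave_truth,
        "pop": pop_truth,
        "winter_u_by_year": {int(y): float(u) for y, u in u_by_year.items()},
        "config": asdict(cfg),
    }
    return {
        "waves": waves_df,
        "point": point,
        "inshore": inshore,
        "winter_u": winter_u,
        "records": records,
        "sites": sites,
        "truth": truth,
    }
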