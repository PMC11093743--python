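"""Barnacle morphometric index S and quality classification.

S = TL/DBC, the ratio of total length (capitulum + peduncle) to the
diameter of the base of the capitulum: elongated, breakage-prone animals
have high S, stubby high-value animals have low S.  The market quality
boundary is a sigmoidal TL(DBC) curve ("Parada limit"): an individual
lying on or below the curve is good quality, above it bad.  HQF (high
quality fraction) is the proportion of good-quality individuals in a
sample.

All lengths are millimetres; the limit-curve constants are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

__all__ = [
    "LEVELS",
    "ParadaParams",
    "PARADA_DEFAULT",
    "morphological_index",
    "parada_limit",
    "is_good_quality",
    "classify_individual",
    "hqf",
    "apply_study_filters",
    "summarize",
]

#: the three intertidal sampling strata
LEVELS = ("lower", "middle", "upper")


@dataclass(frozen=True)
class ParadaParams:
    """Constants of the sigmoidal quality-limit curve (all mm except hill).

    TL_limit(DBC) = tl_max + (tl_min - tl_max) / (1 + (DBC/dbc_half)^hill)

    rises from ``tl_min`` at small DBC to the ``tl_max`` plateau, with
    half-saturation at ``dbc_half`` and Hill steepness ``hill``.
    """

    tl_max: float = 67.8055
    tl_min: float = 10.9002
    dbc_half: float = 12.216
    hill: float = 2.8008

    def __post_init__(self) -> None:
        if not (self.tl_max > self.tl_min > 0):
            raise DomainError("require tl_max > tl_min > 0")
        if not (self.dbc_half > 0 and self.hill > 0):
            raise DomainError("dbc_half and hill must be positive")


PARADA_DEFAULT = ParadaParams()


def morphological_index(TL, DBC):
    """Morphometric index S = TL/DBC (dimensionless)."""
    TL = np.asarray(TL, dtype=float)
    DBC = np.asarray(DBC, dtype=float)
    if np.any(TL <= 0) or np.any(DBC <= 0):
        raise DomainError("TL and DBC must be positive")
    out = TL / DBC
    return out if out.ndim else float(out)


def parada_limit(DBC, params: ParadaParams = PARADA_DEFAULT):
    """Quality-limit TL (mm) at a given DBC (mm).

    Strictly increasing in DBC, bounded in (tl_min, tl_max).
    """
    DBC = np.asarray(DBC, dtype=float)
    if np.any(DBC <= 0):
        raise DomainError("DBC must be positive")
    out = params.tl_max + (params.tl_min - params.tl_max) / (
        1.0 + (DBC / params.dbc_half) ** params.hill
    )
    return out if out.ndim else float(out)


def is_good_quality(TL, DBC, params: ParadaParams = PARADA_DEFAULT):
    """True where the individual falls on or below the quality limit.

    The boundary convention is inclusive: a point exactly on the curve is
    good (keeps HQF upper-semicontinuous in TL).
    """
    TL = np.asarray(TL, dtype=float)
    out = TL <= parada_limit(DBC, params)
    return out if out.ndim else bool(out)


def classify_individual(TL: float, DBC: float, params: ParadaParams = PARADA_DEFAULT) -> str:
    """Classify one individual as ``"good"`` or ``"bad"``."""
    return "good" if is_good_quality(TL, DBC, params) else "bad"


def hqf(TL, DBC, params: ParadaParams = PARADA_DEFAULT) -> float:
    """High quality fraction of a sample: (# good) / (# total), in [0, 1]."""
    good = np.asarray(is_good_quality(TL, DBC, params))
    if good.size == 0:
        raise InsufficientDataError("HQF of an empty group is undefined")
    return float(np.mean(good))


def apply_study_filters(
    records: pd.DataFrame,
    min_years: int = 6,
    min_dbc: float = 2.0,
    *,
    consecutive: bool = False,
) -> pd.DataFrame:
    """Apply the measurement and series-length filters.

    Drops individuals with DBC <= ``min_dbc`` (the 2 mm measurement cutoff
    is strict), then drops entire sites with fewer than ``min_years``
    distinct sampling years.  With ``consecutive=True`` the years must in
    addition contain a run of ``min_years`` consecutive calendar years.
    """
    df = records.copy()
    df = df[df["DBC_mm"].to_numpy(float) > min_dbc]
    years = pd.to_datetime(df["date"]).dt.year
    keep_sites = []
    for site, ys in years.groupby(df["site_id"]):
        uniq = np.sort(ys.unique())
        if len(uniq) < min_years:
            continue
        if consecutive:
            runs = np.split(uniq, np.where(np.diff(uniq) != 1)[0] + 1)
            if max(len(r) for r in runs) < min_years:
                continue
        keep_sites.append(site)
    return df[df["site_id"].isin(keep_sites)].reset_index(drop=True)


def summarize(
    records: pd.DataFrame,
    params: ParadaParams = PARADA_DEFAULT,
    *,
    pool_levels: bool = False,
) -> pd.DataFrame:
    """Per-group sample size, mean S and HQF.

    Grouping is site x date x level, or site x date with the three
    intertidal levels pooled (``pool_levels=True``; the pooled ``level``
    column reads ``"pooled"``).

    Returns columns ``site_id, date, level, n, mean_S, HQF``.
    """
    df = records.copy()
    df["S"] = morphological_index(df["TL_mm"].to_numpy(float), df["DBC_mm"].to_numpy(float))
    df["good"] = is_good_quality(
        df["TL_mm"].to_numpy(float), df["DBC_mm"].to_numpy(float), params
    )
    keys = ["site_id", "date"] if pool_levels else ["site_id", "date", "level"]
    out = (
        df.groupby(keys, sort=True)
        .agg(n=("S", "size"), mean_S=("S", "mean"), HQF=("good", "mean"))
        .reset_index()
    )
    if pool_levels:
        out.insert(2, "level", "pooled")
    return out[["site_id", "date", "level", "n", "mean_S", "HQF"]]
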