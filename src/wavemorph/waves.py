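"""Linear-wave-theory transformation of offshore sea states to inshore conditions.

Offshore hourly significant wave heights at hindcast model points are shoaled
to the shallow intertidal (default depth 1 m), the daily maximum inshore
height is extracted, and the associated wave orbital current u = sqrt(g*H)
is computed.  The orbital current is the mechanical stressor felt by
attached intertidal organisms such as stalked barnacles.

Wavelengths use the Eckart explicit approximation to the dispersion
relation; the shoaling coefficient is the classical energy-flux form
written in terms of sinh/tanh of k*d at the two depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "WavePoint",
    "PhysicalConstants",
    "wavelength",
    "wavenumber",
    "shoal_height",
    "orbital_current",
    "daily_max_inshore",
]


@dataclass(frozen=True)
class WavePoint:
    """A fixed hindcast model point with its local (offshore) depth.

    Parameters
    ----------
    point_id : str
        Model-point label (e.g. ``"3014000"``).
    lon, lat : float
        Position in decimal degrees.
    d_o : float
        Water depth at the point, metres, positive downward. Must be > 0.
    """

    point_id: str
    lon: float
    lat: float
    d_o: float

    def __post_init__(self) -> None:
        if not self.d_o > 0:
            raise DomainError(f"offshore depth must be positive, got {self.d_o}")


@dataclass(frozen=True)
class PhysicalConstants:
    """Gravity and the inshore reference depth.

    ``d_i`` defaults to 1 m, the depth of the shallowest intertidal zone
    where the barnacles live.
    """

    g: float = 9.81
    d_i: float = 1.0

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise DomainError("g must be positive")
        if not self.d_i > 0:
            raise DomainError("d_i must be positive")


def wavelength(T_p, d, g: float = 9.81):
    """Wavelength (m) from period and depth via the Eckart approximation.

    l_w = (g*T^2 / 2*pi) * sqrt(tanh(4*pi^2*d / (T^2*g)))

    Accurate to a few percent against the exact dispersion relation across
    shallow to deep water. Accepts scalars or arrays.
    """
    T_p = np.asarray(T_p, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(T_p <= 0):
        raise DomainError("wave period must be positive")
    if np.any(d <= 0):
        raise DomainError("depth must be positive")
    deep = g * T_p**2 / (2.0 * np.pi)
    arg = 4.0 * np.pi**2 * d / (T_p**2 * g)
    out = deep * np.sqrt(np.tanh(arg))
    return out if out.ndim else float(out)


def wavenumber(l_w):
    """Wave number k = 2*pi / l_w (1/m)."""
    l_w = np.asarray(l_w, dtype=float)
    if np.any(l_w <= 0):
        raise DomainError("wavelength must be positive")
    out = 2.0 * np.pi / l_w
    return out if out.ndim else float(out)


def shoal_height(H_o, T_p, d_o, d_i, g: float = 9.81, *, literal_printed_form: bool = False):
    """Shoal an offshore wave height to an inshore depth.

    H_i = H_o * sqrt( [(1 + 2 k_o d_o / sinh 2 k_o d_o) /
                       (1 + 2 k_i d_i / sinh 2 k_i d_i)] *
                      tanh(k_o d_o) / tanh(k_i d_i) )

    which is the energy-flux shoaling coefficient; wave numbers come from
    :func:`wavelength` at each depth. Equal depths give H_i = H_o exactly.

    Parameters
    ----------
    literal_printed_form : bool
        If True, reproduce a published variant in which the inshore
        denominator term reads ``2 k_i d_o`` instead of ``2 k_i d_i``.
        The symmetric default is the physically standard form; the flag
        exists only for comparison against that source.
    """
    H_o = np.asarray(H_o, dtype=float)
    T_p = np.asarray(T_p, dtype=float)
    d_o_a = np.asarray(d_o, dtype=float)
    d_i_a = np.asarray(d_i, dtype=float)
    if np.any(H_o < 0):
        raise DomainError("wave height must be non-negative")
    if np.any(T_p <= 0) or np.any(d_o_a <= 0) or np.any(d_i_a <= 0):
        raise DomainError("period and depths must be positive")

    k_o = wavenumber(wavelength(T_p, d_o_a, g))
    k_i = wavenumber(wavelength(T_p, d_i_a, g))
    ko_do = k_o * d_o_a
    ki_di = k_i * d_i_a

    with np.errstate(over="ignore"):
        num = 1.0 + 2.0 * ko_do / np.sinh(2.0 * ko_do)
        if literal_printed_form:
            den = 1.0 + 2.0 * k_i * d_o_a / np.sinh(2.0 * ki_di)
        else:
            den = 1.0 + 2.0 * ki_di / np.sinh(2.0 * ki_di)
    ratio = (num / den) * np.tanh(ko_do) / np.tanh(ki_di)
    out = H_o * np.sqrt(ratio)
    return out if out.ndim else float(out)


def orbital_current(H_i, g: float = 9.81):
    """Wave orbital current scale u = sqrt(g * H_i) (m/s)."""
    H_i = np.asarray(H_i, dtype=float)
    if np.any(H_i < 0):
        raise DomainError("wave height must be non-negative")
    out = np.sqrt(g * H_i)
    return out if out.ndim else float(out)


def daily_max_inshore(
    series: pd.DataFrame,
    point: WavePoint,
    consts: PhysicalConstants = PhysicalConstants(),
    *,
    literal_printed_form: bool = False,
) -> pd.DataFrame:
    """Daily maximum inshore wave height and orbital current.

    Every hourly offshore height is shoaled with that hour's period
    (transform-then-max, since shoaling depends on T_p), then the maximum
    inshore height per UTC calendar day is retained and converted to an
    orbital current.

    Parameters
    ----------
    series : DataFrame
        Columns ``timestamp`` (datetime-like, UTC), ``Hs_m``, ``Tp_s``.
        A ``point_id`` column is carried through if present.
    point : WavePoint
        Supplies the offshore depth ``d_o``.

    Returns
    -------
    DataFrame with columns ``date``, ``point_id``, ``H_i_max``, ``u_i_max``,
    one row per calendar day with data; gap days are absent.
    """
    cols = ["date", "point_id", "H_i_max", "u_i_max"]
    if len(series) == 0:
        return pd.DataFrame(columns=cols)
    ts = pd.to_datetime(series["timestamp"], utc=True, errors="raise")
    H_i = shoal_height(
        series["Hs_m"].to_numpy(float),
        series["Tp_s"].to_numpy(float),
        point.d_o,
        consts.d_i,
        consts.g,
        literal_printed_form=literal_printed_form,
    )
    daily = (
        pd.DataFrame({"date": ts.dt.date, "H_i": H_i})
        .groupby("date", sort=True)["H_i"]
        .max()
        .rename("H_i_max")
        .reset_index()
    )
    daily["u_i_max"] = orbital_current(daily["H_i_max"].to_numpy(), consts.g)
    daily["point_id"] = point.point_id
    return daily[cols]
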