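"""Derived quantities: molecular weight, release curves, characteristic times.

The number-average molecular weight is mapped from the fields by the
end-scission proxy Mn(t)/Mn(0) = <Ce>/Ce0 (volume-averaged over the polymer):
each scission removes one monomer from a chain end while the chain count stays
constant, consistent with the rate laws where every scission yields exactly
one monomer.  Alternative mappings can be passed where a callable is accepted.

Release through a surface group is reported as an instantaneous molar flux
(mol/day) and its cumulative integral (mol); cumulative series from the
solvers are exact discrete balances, while :func:`release_summary` integrates
reported flux samples by the trapezoidal rule when it needs to re-derive them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticParameters
from .units import days_to_seconds, seconds_to_days

__all__ = [
    "ReleaseRecord",
    "MnTrajectory",
    "CharacteristicTimes",
    "mn_from_state",
    "characteristic_times",
    "release_summary",
    "time_to_fraction",
]


@dataclass
class ReleaseRecord:
    """Flux and cumulative release through one surface group."""

    group: str
    times: np.ndarray          # days
    flux: np.ndarray           # mol/day, sampled at `times`
    cumulative: np.ndarray     # mol, exact discrete running integral

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if not (len(self.times) == len(self.flux) == len(self.cumulative)):
            raise ValueError("times, flux and cumulative must share a length")
        if np.any(np.diff(self.cumulative) < -1e-12 * max(1.0, self.cumulative[-1])):
            raise ValueError("cumulative release must be non-decreasing")

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])


@dataclass
class MnTrajectory:
    """Relative and absolute number-average molecular weight vs time."""

    times: np.ndarray
    mn_rel: np.ndarray
    mn0: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mn_rel = np.asarray(self.mn_rel, dtype=float)
        if not np.isclose(self.mn_rel[np.argmin(self.times)], 1.0, atol=1e-9):
            raise ValueError("mn_rel must equal 1 at t = 0")
        if np.any(self.mn_rel < -1e-12) or np.any(self.mn_rel > 1 + 1e-12):
            raise ValueError("mn_rel must lie in [0, 1]")

    @property
    def mn(self) -> np.ndarray:
        return self.mn_rel * self.mn0


@dataclass(frozen=True)
class CharacteristicTimes:
    """Characteristic times (seconds) of the three release-limiting processes.

    * diffusion through the matrix: thickness^2 / D_eff
    * non-catalytic scission: 1/k1
    * autocatalytic scission: 1/(k2 * Ce0^beta)

    The largest of the three identifies the rate-limiting step; for the
    canonical scaffold the matrix diffusion time dominates by orders of
    magnitude, so release is transport limited.
    """

    t_diffusion_s: float
    t_noncatalytic_s: float
    t_autocatalytic_s: float
    thickness_m: float
    d_eff_m2_per_s: float

    def as_days(self) -> dict[str, float]:
        return {
            "t_diffusion_days": seconds_to_days(self.t_diffusion_s),
            "t_noncatalytic_days": seconds_to_days(self.t_noncatalytic_s),
            "t_autocatalytic_days": seconds_to_days(self.t_autocatalytic_s),
        }


def mn_from_state(ce, ce0: float, mn0: float = 1.0, weights=None) -> tuple[float, float]:
    """Map an ester field to (Mn/Mn0, Mn) by the end-scission proxy.

    ``ce`` is the ester concentration over the polymer domain; ``weights``
    are cell/control volumes (uniform if omitted).
    """
    ce = np.asarray(ce, dtype=float).ravel()
    if ce.size == 0:
        raise ValueError("empty polymer domain")
    if ce0 <= 0:
        raise ValueError("ce0 must be positive")
    if weights is None:
        mean = float(np.mean(ce))
    else:
        w = np.asarray(weights, dtype=float).ravel()
        mean = float(np.sum(ce * w) / np.sum(w))
    mn_rel = mean / ce0
    return mn_rel, mn_rel * mn0


def characteristic_times(
    params: KineticParameters, thickness: float, d_eff_m2_per_s: float
) -> CharacteristicTimes:
    """Characteristic times of diffusion and the two scission channels.

    ``d_eff_m2_per_s`` is the effective matrix diffusivity in m^2/s (the
    package otherwise works per-day; this observable is conventionally quoted
    in seconds).
    """
    if thickness <= 0 or d_eff_m2_per_s <= 0:
        raise ValueError("thickness and d_eff must be positive")
    t_diff = thickness**2 / d_eff_m2_per_s
    t_noncat = days_to_seconds(1.0 / params.k1)
    t_autocat = days_to_seconds(1.0 / (params.k2 * params.ce0**params.beta))
    return CharacteristicTimes(
        t_diffusion_s=float(t_diff),
        t_noncatalytic_s=float(t_noncat),
        t_autocatalytic_s=float(t_autocat),
        thickness_m=float(thickness),
        d_eff_m2_per_s=float(d_eff_m2_per_s),
    )


def release_summary(records: list[ReleaseRecord]) -> pd.DataFrame:
    """Per-group summary: peak flux, time of peak, cumulative total, fraction.

    Fractions are of the total exported over all groups (all zero fluxes give
    zero fractions).  All records must share the same time axis.
    """
    if not records:
        raise ValueError("no release records given")
    t0 = records[0].times
    for rec in records[1:]:
        if len(rec.times) != len(t0) or not np.allclose(rec.times, t0):
            raise ValueError("release records have mismatched time axes")
    totals = np.array([rec.total for rec in records])
    grand = totals.sum()
    rows = []
    for rec, tot in zip(records, totals):
        ipk = int(np.argmax(rec.flux))
        rows.append(
            {
                "group": rec.group,
                "peak_flux_mol_per_day": float(rec.flux[ipk]),
                "t_peak_days": float(rec.times[ipk]),
                "cumulative_mol": float(tot),
                "fraction": float(tot / grand) if grand > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def time_to_fraction(record: ReleaseRecord, fraction: float, total: float) -> float:
    """First time at which cumulative release reaches ``fraction * total``.

    Linear interpolation between output samples; ``inf`` if never reached.
    """
    target = fraction * total
    cum = record.cumulative
    if cum[-1] < target:
        return float("inf")
    idx = int(np.searchsorted(cum, target))
    if idx == 0:
        return float(record.times[0])
    c0, c1 = cum[idx - 1], cum[idx]
    t0, t1 = record.times[idx - 1], record.times[idx]
    if c1 == c0:
        return float(t1)
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))
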