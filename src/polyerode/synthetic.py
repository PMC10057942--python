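"""Synthetic degradation datasets and reference release curves.

The measurement campaign this emulates: GPC molecular weights of replicate
polymer rods (n = 3, 1.6 mm diameter x 6 mm height) degraded at 50 C in
buffer, sampled at t = 0 and t = 56 days.  Datasets are produced by the
forward rod model plus multiplicative lognormal measurement noise with a
stated coefficient of variation (GPC errors scale with magnitude); cv = 0
reproduces the forward model exactly and identical seeds give identical
datasets.

These generators are the test bed for the calibration module: noiseless
generation composed with fitting must recover the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import DegradationDataset
from .geometry import build_rod
from .kinetics import KineticParameters
from .solver import SolverSettings, solve_rod_1d
from .observables import ReleaseRecord

__all__ = [
    "NoiseModel",
    "generate_degradation_dataset",
    "study_timepoints",
    "generate_release_reference",
]

#: The study's sampling design: GPC at the start and after ~2 months.
study_timepoints = (0.0, 56.0)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise with unit mean.

    ``cv`` is the coefficient of variation; ``cv = 0`` disables noise.  The
    seed is mandatory so generated datasets are reproducible bit-for-bit.
    """

    cv: float = 0.05
    seed: int = 0
    kind: str = "lognormal"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.kind != "lognormal":
            raise ValueError("only multiplicative lognormal noise is supported")

    def factors(self, shape: tuple[int, ...]) -> np.ndarray:
        """Unit-mean noise factors with sd/mean = cv, seeded."""
        if self.cv == 0:
            return np.ones(shape)
        rng = np.random.default_rng(self.seed)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def generate_degradation_dataset(
    params: KineticParameters,
    timepoints: Sequence[float] = study_timepoints,
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(cv=0.05, seed=0),
    radius: float = 0.8e-3,
    height: float = 6e-3,
    mn0: float = 1.0e5,
    n_radial: int = 40,
    dt: float = 2.0,
) -> DegradationDataset:
    """Replicate Mn(t) dataset from the forward rod model plus noise.

    Defaults mirror the study conditions (t = {0, 56} days, n = 3, rod
    0.8 mm radius x 6 mm height); ``params.temperature`` states the bath
    temperature.  ``mn0`` is the nominal initial molecular weight (g/mol);
    only relative Mn carries information for calibration.
    """
    times = np.unique(np.asarray(timepoints, dtype=float))
    if times[0] != 0.0:
        raise ValueError("timepoints must include 0")
    grid = build_rod(radius, height, n_radial)
    settings = SolverSettings(dt=dt, t_end=float(times.max()), output_times=times)
    res = solve_rod_1d(grid, params, settings)
    mn_rel = res.mn_trajectory(params.ce0).mn_rel
    clean = mn0 * mn_rel
    mn = clean[:, None] * noise.factors((len(times), n_replicates))
    return DegradationDataset(
        times=times, mn=mn, temperature=params.temperature,
        radius=radius, height=height, mn0=mn0,
    )


def generate_release_reference(
    params: KineticParameters,
    scenario: str = "bulk",
    thickness: float = 0.010,
    voxel_size: float = 1.0e-3,
    t_end: float = 60.0,
    dt: float = 2.0,
    cm0_fraction: float = 0.01,
    open_channel_mode: str = "ALL",
) -> ReleaseRecord:
    """Deterministic delivered-release curve at pinned coarse settings.

    Serves as a regression fixture: re-generation with identical arguments
    is bit-identical.  Returns the combined record over the delivered
    (contact-side) surface groups.
    """
    from .scenarios import run_scenario, delivered_record  # local: avoid cycle

    result = run_scenario(
        scenario=scenario,
        params=params,
        thickness=thickness,
        voxel_size=voxel_size,
        open_channel_mode=open_channel_mode,
        settings=SolverSettings(
            dt=dt, t_end=t_end,
            output_times=np.arange(0.0, t_end + 1e-9, 10.0),
            cm0_polymer=cm0_fraction * params.ce0,
        ),
    )
    return delivered_record(result, scenario)
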