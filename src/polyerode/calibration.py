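"""Calibration of (k1, k2, D0) from molecular-weight degradation data.

The workflow mirrors accelerated-ageing practice: replicate GPC measurements
of Mn(t) on small rod samples at elevated temperature are fitted by forward
simulation of the 1-D axisymmetric rod model, and the fitted constants are
then transferred to other temperatures with the Arrhenius relation.

The fitting core follows the statsmodels convention: build a
:class:`RodDegradationModel` from a :class:`DegradationDataset`, call
:meth:`~RodDegradationModel.fit`, and read estimates, per-timepoint errors
and diagnostics off the returned :class:`RodDegradationResults` (including a
``summary()`` table).

The objective is the mean squared *relative* Mn error over timepoints
(replicate-averaged), which is scale-free: converting Mn units leaves the fit
unchanged.  Two optimisers are offered: a bounded derivative-free local
search in log-parameter space (default, `scipy.optimize.least_squares`), and
a coordinate-wise "one parameter at a time" refinement matching how such
fits are often done by hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .geometry import build_rod
from .kinetics import KineticParameters, arrhenius_transfer
from .solver import SolverSettings, solve_rod_1d

__all__ = [
    "DegradationDataset",
    "RodDegradationModel",
    "RodDegradationResults",
    "percentage_error",
    "fit_parameters",
    "extrapolate_parameters",
]

_FREE_DEFAULT = ("k1", "k2", "d0")


def percentage_error(mn_sim, mn_obs) -> float | np.ndarray:
    """Percentage error 100*|sim - obs|/obs; ``obs`` must be positive."""
    mn_obs = np.asarray(mn_obs, dtype=float)
    if np.any(mn_obs <= 0):
        raise ValueError("observed Mn must be positive")
    err = 100.0 * np.abs(np.asarray(mn_sim, dtype=float) - mn_obs) / mn_obs
    return err if err.ndim else float(err)


@dataclass
class DegradationDataset:
    """Replicate Mn measurements vs time at a stated temperature.

    ``mn`` has shape (n_times, n_replicates), g/mol.  ``times`` must include
    0; ``mn0`` defaults to the replicate mean at t = 0.
    """

    times: np.ndarray
    mn: np.ndarray
    temperature: float
    radius: float = 0.8e-3
    height: float = 6e-3
    mn0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mn = np.atleast_2d(np.asarray(self.mn, dtype=float))
        if self.mn.shape[0] != len(self.times):
            raise ValueError("mn must have one row per timepoint")
        if not np.any(self.times == 0.0):
            raise ValueError("times must include 0")
        if np.any(self.mn <= 0):
            raise ValueError("Mn values must be positive")
        if self.mn.shape[1] < 1:
            raise ValueError("need at least one replicate")
        if self.mn0 is None:
            self.mn0 = float(self.mn[np.argmin(self.times)].mean())

    @property
    def n_replicates(self) -> int:
        return self.mn.shape[1]

    def replicate_mean(self) -> np.ndarray:
        return self.mn.mean(axis=1)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        temperature: float,
        radius: float = 0.8e-3,
        height: float = 6e-3,
        mn0: float | None = None,
    ) -> "DegradationDataset":
        """Build from long-format columns time_days, replicate, mn_g_per_mol."""
        wide = df.pivot(index="time_days", columns="replicate", values="mn_g_per_mol")
        wide = wide.sort_index()
        return cls(
            times=wide.index.to_numpy(dtype=float),
            mn=wide.to_numpy(dtype=float),
            temperature=temperature,
            radius=radius,
            height=height,
            mn0=mn0,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"time_days": t, "replicate": r, "mn_g_per_mol": self.mn[i, r]}
            for i, t in enumerate(self.times)
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows)


class RodDegradationModel:
    """Forward rod-degradation model bound to a dataset, ready to fit.

    Parameters
    ----------
    dataset : DegradationDataset
        Replicate Mn(t) observations and the sample geometry.
    init_params : KineticParameters
        Starting parameter set (also supplies Ce0, beta, alpha, which are
        held fixed during fitting).
    free : sequence of {'k1', 'k2', 'd0'}
        Parameters to vary; the rest stay at their initial values.
    bounds : mapping, optional
        Per-parameter (lo, hi); defaults to (init/100, init*100).
    n_radial, dt : int, float
        Forward-solver resolution.  The same discretisation must be used to
        generate and to fit synthetic data for exact self-consistency.
    """

    def __init__(
        self,
        dataset: DegradationDataset,
        init_params: KineticParameters,
        free: Sequence[str] = _FREE_DEFAULT,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        n_radial: int = 40,
        dt: float = 2.0,
    ) -> None:
        unknown = set(free) - set(_FREE_DEFAULT)
        if unknown:
            raise ValueError(f"unknown free parameters: {unknown}")
        self.dataset = dataset
        self.init_params = init_params.replace(temperature=dataset.temperature)
        self.free = tuple(free)
        self.bounds = {
            name: (
                bounds[name]
                if bounds and name in bounds
                else (getattr(init_params, name) / 100.0, getattr(init_params, name) * 100.0)
            )
            for name in self.free
        }
        self.grid = build_rod(dataset.radius, dataset.height, n_radial)
        t_end = float(dataset.times.max())
        if t_end <= 0:
            raise ValueError("dataset needs at least one positive timepoint")
        self.settings = SolverSettings(dt=dt, t_end=t_end, output_times=dataset.times)
        self._obs_rel = dataset.replicate_mean() / dataset.mn0

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        init_params: KineticParameters,
        temperature: float,
        radius: float = 0.8e-3,
        height: float = 6e-3,
        **kwargs,
    ) -> "RodDegradationModel":
        ds = DegradationDataset.from_dataframe(df, temperature, radius, height)
        return cls(ds, init_params, **kwargs)

    # -- forward machinery -------------------------------------------------

    def params_from_vector(self, x: np.ndarray) -> KineticParameters:
        """Map a log-parameter vector of the free subset to a parameter set."""
        return self.init_params.replace(
            **{name: float(np.exp(v)) for name, v in zip(self.free, x)}
        )

    def vector_from_params(self, params: KineticParameters) -> np.ndarray:
        return np.log([getattr(params, name) for name in self.free])

    def simulate_mn_rel(self, params: KineticParameters) -> np.ndarray:
        """Forward Mn(t)/Mn0 at the dataset timepoints."""
        res = solve_rod_1d(self.grid, params, self.settings)
        return res.mn_trajectory(params.ce0).mn_rel

    def residuals(self, params: KineticParameters) -> np.ndarray:
        """Relative Mn residuals (sim - obs)/obs at the dataset timepoints."""
        sim = self.simulate_mn_rel(params)
        return (sim - self._obs_rel) / self._obs_rel

    def objective(self, params: KineticParameters) -> float:
        """Mean squared relative Mn error."""
        r = self.residuals(params)
        return float(np.mean(r**2))

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        method: str = "least_squares",
        max_nfev: int = 400,
        n_sweeps: int = 8,
    ) -> "RodDegradationResults":
        """Estimate the free parameters.

        ``method`` is either ``"least_squares"`` (bounded trust-region in
        log space, default) or ``"coordinate"`` (cyclic one-parameter-at-a-
        time refinement).  Deterministic given the dataset and start.
        """
        x0 = self.vector_from_params(self.init_params)
        lo = np.log([self.bounds[n][0] for n in self.free])
        hi = np.log([self.bounds[n][1] for n in self.free])
        trace: list[tuple[np.ndarray, float]] = []

        def resid_vec(x):
            r = self.residuals(self.params_from_vector(x))
            trace.append((x.copy(), float(np.mean(r**2))))
            return r

        if method == "least_squares":
            sol = least_squares(
                resid_vec, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                diff_step=1e-5, max_nfev=max_nfev,
            )
            x_best = sol.x
            success = sol.status > 0
            message = sol.message
        elif method == "coordinate":
            x_best = x0.copy()
            f_best = np.mean(resid_vec(x_best) ** 2)
            for _ in range(n_sweeps):
                improved = False
                for i in range(len(self.free)):
                    def f1(v, i=i):
                        x = x_best.copy()
                        x[i] = v
                        return float(np.mean(resid_vec(x) ** 2))

                    res = minimize_scalar(
                        f1, bounds=(lo[i], hi[i]), method="bounded",
                        options={"xatol": 1e-10},
                    )
                    if res.fun < f_best - 1e-18:
                        f_best = res.fun
                        x_best[i] = res.x
                        improved = True
                if not improved:
                    break
            success = True
            message = "coordinate refinement converged"
        else:
            raise ValueError(f"unknown fit method {method!r}")

        params = self.params_from_vector(x_best)
        if not success:
            raise RuntimeError(
                f"fit did not converge within budget ({message}); "
                f"best-so-far: {params}"
            )
        sim_rel = self.simulate_mn_rel(params)
        perc = percentage_error(sim_rel * self.dataset.mn0,
                                self.dataset.replicate_mean())
        return RodDegradationResults(
            model=self,
            params=params,
            objective=float(np.mean(((sim_rel - self._obs_rel) / self._obs_rel) ** 2)),
            percentage_errors=np.asarray(perc),
            n_evaluations=len(trace),
            trace=trace,
            method=method,
            message=message,
        )


@dataclass
class RodDegradationResults:
    """Fit results: estimates, per-timepoint errors, diagnostics."""

    model: RodDegradationModel
    params: KineticParameters
    objective: float
    percentage_errors: np.ndarray
    n_evaluations: int
    trace: list
    method: str
    message: str

    def simulate(self, times: Iterable[float] | None = None) -> np.ndarray:
        """Forward Mn/Mn0 at the fitted parameters (dataset times by default)."""
        if times is None:
            return self.model.simulate_mn_rel(self.params)
        settings = SolverSettings(
            dt=self.model.settings.dt,
            t_end=float(np.max(list(times))),
            output_times=np.asarray(list(times), dtype=float),
        )
        res = solve_rod_1d(self.model.grid, self.params, settings)
        return res.mn_trajectory(self.params.ce0).mn_rel

    def to_dict(self) -> dict:
        return {
            "k1_per_day": self.params.k1,
            "k2_m3_per_mol_day": self.params.k2,
            "d0_m2_per_day": self.params.d0,
            "temperature_K": self.params.temperature,
            "objective_msre": self.objective,
            "percentage_errors": self.percentage_errors.tolist(),
            "n_evaluations": self.n_evaluations,
            "method": self.method,
        }

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Rod degradation calibration",
            "=" * 60,
            f"method: {self.method}   forward evaluations: {self.n_evaluations}",
            f"temperature: {self.params.temperature:.2f} K   "
            f"replicates: {ds.n_replicates}   timepoints: {len(ds.times)}",
            f"objective (mean squared relative Mn error): {self.objective:.3e}",
            "-" * 60,
            f"{'parameter':<10}{'estimate':>14}{'start':>14}  unit",
        ]
        units = {"k1": "1/day", "k2": "m^3/mol/day", "d0": "m^2/day"}
        for name in ("k1", "k2", "d0"):
            est = getattr(self.params, name)
            start = getattr(self.model.init_params, name)
            tag = "" if name in self.model.free else " (fixed)"
            lines.append(
                f"{name:<10}{est:>14.5e}{start:>14.5e}  {units[name]}{tag}"
            )
        lines.append("-" * 60)
        lines.append("per-timepoint % error (replicate mean):")
        for t, e in zip(ds.times, self.percentage_errors):
            lines.append(f"  t = {t:7.1f} d : {e:6.3f} %")
        return "\n".join(lines)


def fit_parameters(
    dataset: DegradationDataset,
    init: KineticParameters,
    free: Sequence[str] = _FREE_DEFAULT,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    method: str = "least_squares",
    **model_kwargs,
) -> RodDegradationResults:
    """Functional wrapper: build a :class:`RodDegradationModel` and fit it."""
    model = RodDegradationModel(dataset, init, free=free, bounds=bounds, **model_kwargs)
    return model.fit(method=method)


def extrapolate_parameters(
    params_at_tref: KineticParameters,
    ea_set: Mapping[str, float],
    t_target: float,
) -> KineticParameters:
    """Arrhenius transfer of a calibrated set to another temperature.

    ``ea_set`` maps 'k1', 'k2', 'd0' to activation energies in J/mol.  The
    identity holds for ``t_target == params.temperature`` or all-zero Ea.
    """
    if t_target <= 0:
        raise ValueError("target temperature must be positive")
    return arrhenius_transfer(params_at_tref, ea_set, t_target)
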