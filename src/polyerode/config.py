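"""Run configuration: schema-validated YAML configs and the run driver.

One human-editable YAML file describes one reproducible run; unknown keys are
rejected and every numeric key embeds its unit in the name.  ``run`` executes
the configured scenario and writes CSV/VTK/JSON artifacts plus a manifest
with checksums; re-running an identical config reproduces identical CSV and
JSON outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import io as pio
from .geometry import ScaffoldSpec, build_rod
from .kinetics import KineticParameters
from .observables import release_summary
from .scenarios import build_scenario_grid, run_scenario
from .solver import DomainDiffusivities, SolverSettings, solve_rod_1d, solve_well_mixed
from .units import m2_per_second_to_m2_per_day

__all__ = ["RunConfig", "load_config", "run"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParametersCfg(_Strict):
    """Either a packaged set name or an inline parameter block."""

    name: Optional[str] = "plla_50c"
    inline: Optional[dict] = None

    def resolve(self) -> KineticParameters:
        if self.inline is not None:
            return pio.params_from_dict(self.inline)
        return pio.load_parameter_set(self.name)


class SolverCfg(_Strict):
    dt_days: float = 2.0
    t_end_days: float = 420.0
    output_interval_days: float = 30.0
    # default grafted-load fraction: scenario dependent (0 for rod/well_mixed,
    # 1% of Ce0 for the scaffold scenarios) when left unset
    cm0_fraction: Optional[float] = Field(default=None, ge=0.0)
    mass_tolerance: float = 1e-6

    @field_validator("dt_days", "t_end_days", "output_interval_days")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be strictly positive")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "SolverCfg":
        if self.dt_days > self.t_end_days:
            raise ValueError("dt_days must not exceed t_end_days")
        return self

    def settings(self, ce0: float, scenario: str = "rod") -> SolverSettings:
        out = np.arange(0.0, self.t_end_days, self.output_interval_days)
        out = np.append(out, self.t_end_days)
        frac = self.cm0_fraction
        if frac is None:
            frac = 0.01 if scenario in ("bulk", "porous") else 0.0
        scaffold = scenario in ("bulk", "porous")
        if scaffold:
            from .scenarios import scenario_output_times

            out = np.unique(np.concatenate([out, scenario_output_times(self.t_end_days)]))
        return SolverSettings(
            dt=self.dt_days,
            t_end=self.t_end_days,
            output_times=out,
            cm0_polymer=frac * ce0,
            cm0_medium=frac * ce0 if scaffold else 0.0,
            mass_tolerance=self.mass_tolerance,
        )


class GeometryCfg(_Strict):
    thickness_m: float = 0.010
    width_m: float = 0.040
    height_m: float = 0.050
    voxel_size_m: float = 1.0e-3
    environment_margin_m: float = 2.0e-3
    open_channel_mode: Union[str, list] = "ALL"
    pore_layers: Optional[int] = None
    quarter: bool = True

    def spec(self) -> ScaffoldSpec:
        mode = self.open_channel_mode
        if isinstance(mode, list):
            mode = tuple(tuple(p) for p in mode)
        return ScaffoldSpec(
            height=self.height_m,
            width=self.width_m,
            thickness=self.thickness_m,
            environment_margin=self.environment_margin_m,
            open_channel_mode=mode,
            pore_layers=self.pore_layers,
        )


class RodCfg(_Strict):
    radius_m: float = 0.8e-3
    height_m: float = 6.0e-3
    n_radial: int = Field(default=50, ge=4)


class EnvironmentCfg(_Strict):
    medium_diffusivity_m2_per_s: float = 1.0e-9
    environment_diffusivity_m2_per_s: float = 1.0e-9

    def diffusivities(self) -> DomainDiffusivities:
        return DomainDiffusivities(
            pore_medium=m2_per_second_to_m2_per_day(self.medium_diffusivity_m2_per_s),
            environment=m2_per_second_to_m2_per_day(
                self.environment_diffusivity_m2_per_s
            ),
        )


class RunConfig(_Strict):
    scenario: Literal["bulk", "porous", "rod", "well_mixed"]
    parameters: ParametersCfg = ParametersCfg()
    geometry: GeometryCfg = GeometryCfg()
    rod: RodCfg = RodCfg()
    environment: EnvironmentCfg = EnvironmentCfg()
    solver: SolverCfg = SolverCfg()
    out_dir: str = "polyerode_out"
    seed: int = 0
    write_fields: bool = True


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def run(config: RunConfig) -> dict:
    """Execute a validated config; returns a dict of output paths.

    Artifacts: trajectory/release CSVs, VTK field series (3-D scenarios),
    and ``manifest.json`` recording the config, package version and the
    sha256 of every output.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = config.parameters.resolve()
    settings = config.solver.settings(params.ce0, config.scenario)
    meta = pio.params_to_dict(params)
    meta["scenario"] = config.scenario
    outputs: list[Path] = []

    if config.scenario == "well_mixed":
        res = solve_well_mixed(params, settings, closed=True)
        import pandas as pd

        df = pd.DataFrame(
            {"time_days": res.times, "ce_mol_per_m3": res.ce, "cm_mol_per_m3": res.cm}
        )
        path = out_dir / "trajectory.csv"
        with open(path, "w") as fh:
            fh.write(pio._header_block(meta))
            df.to_csv(fh, index=False, float_format="%.12g")
        outputs.append(path)
    elif config.scenario == "rod":
        grid = build_rod(config.rod.radius_m, config.rod.height_m, config.rod.n_radial)
        res = solve_rod_1d(grid, params, settings)
        outputs.append(
            pio.write_release_csv(out_dir / "release.csv", [res.release], meta)
        )
        import pandas as pd

        mn = res.mn_trajectory(params.ce0)
        path = out_dir / "mn.csv"
        with open(path, "w") as fh:
            fh.write(pio._header_block(meta))
            pd.DataFrame({"time_days": mn.times, "mn_rel": mn.mn_rel}).to_csv(
                fh, index=False, float_format="%.12g"
            )
        outputs.append(path)
    else:
        spec = config.geometry.spec()
        grid = build_scenario_grid(
            config.scenario,
            voxel_size=config.geometry.voxel_size_m,
            quarter=config.geometry.quarter,
            spec=spec,
        )
        result = run_scenario(
            scenario=config.scenario,
            params=params,
            settings=settings,
            diffs=config.environment.diffusivities(),
            quarter=config.geometry.quarter,
            grid=grid,
        )
        outputs.append(
            pio.write_release_csv(
                out_dir / "release.csv", list(result.release.values()), meta
            )
        )
        summary = release_summary(list(result.release.values()))
        path = out_dir / "release_summary.csv"
        with open(path, "w") as fh:
            fh.write(pio._header_block(meta))
            summary.to_csv(fh, index=False, float_format="%.12g")
        outputs.append(path)
        if config.write_fields:
            for i, t in enumerate(result.times):
                vtk = out_dir / f"fields_{int(round(t)):05d}d.vtk"
                pio.write_vtk_structured_points(
                    vtk, result.grid, {"ce": result.ce[i], "cm": result.cm[i]}
                )
                outputs.append(vtk)

    manifest = pio.write_manifest(
        out_dir / "manifest.json", config.model_dump(), outputs
    )
    return {"out_dir": out_dir, "outputs": outputs, "manifest": manifest}
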