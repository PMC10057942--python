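"""Solver audits: closed forms, conservation, monotonicity, convergence."""

import copy

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from polyerode.geometry import POLYMER, ScaffoldSpec, build_bulk_scaffold, build_rod
from polyerode.kinetics import monomer_diffusivity
from polyerode.scenarios import scenario_boundary
from polyerode.solver import (
    BoundarySpec,
    DomainDiffusivities,
    SolverSettings,
    solve_rod_1d,
    solve_voxel,
    solve_well_mixed,
)


def settings(**kw):
    return SolverSettings(**kw)


class TestWellMixed:
    def test_closed_form_limit_without_autocatalysis(self, plla):
        p = plla.replace(k2=0.0)
        res = solve_well_mixed(p, settings(dt=1.0, t_end=420.0), closed=True)
        exact_ce = p.ce0 * np.exp(-p.k1 * res.times)
        exact_cm = p.ce0 * (1.0 - np.exp(-p.k1 * res.times))
        assert np.max(np.abs(res.ce - exact_ce) / exact_ce) < 1e-8
        assert np.max(np.abs(res.cm - exact_cm)) / p.ce0 < 1e-8

    def test_closed_mode_conserves_total(self, plga):
        res = solve_well_mixed(plga, settings(dt=1.0, t_end=420.0), closed=True)
        assert np.max(np.abs(res.ce + res.cm - plga.ce0)) / plga.ce0 < 1e-8

    def test_matches_independent_stiff_integrator(self, plga):
        """Cross-check against a separately configured implicit integrator."""
        res = solve_well_mixed(plga, settings(dt=1.0, t_end=420.0), closed=True)

        def rhs(_t, y):
            r = plga.k1 * y[0] + plga.k2 * y[0] * max(y[1], 0.0) ** plga.beta
            return [-r, r]

        oracle = solve_ivp(
            rhs, (0.0, 420.0), [plga.ce0, 0.0], t_eval=res.times,
            method="Radau", rtol=1e-10, atol=1e-8,
        )
        assert np.max(np.abs(res.ce - oracle.y[0])) / plga.ce0 < 1e-6

    def test_open_mode_exports_everything_scissioned(self, plla):
        res = solve_well_mixed(plla, settings(dt=1.0, t_end=100.0), closed=False)
        assert np.allclose(res.exported, plla.ce0 - res.ce)
        assert np.all(res.cm == 0.0)


class TestRod:
    def test_frozen_transport_decouples_nodes(self, plla):
        """With D0 = 0 every interior node follows the closed 0-D trajectory."""
        p = plla.replace(d0=0.0)
        grid = build_rod(0.8e-3, 6e-3, 20)
        rod = solve_rod_1d(grid, p, settings(dt=0.25, t_end=100.0))
        wm = solve_well_mixed(p, settings(dt=1.0, t_end=100.0), closed=True)
        err = np.max(np.abs(rod.ce[:, :-1] - wm.ce[:, None])) / p.ce0
        assert err < 1e-5

    def test_mass_balance_audit(self, plla):
        grid = build_rod(0.8e-3, 6e-3, 50)
        rod = solve_rod_1d(grid, plla, settings(dt=1.0, t_end=420.0))
        assert rod.mass_balance_error < 1e-6
        # recompute the balance independently at the final state
        interior = float(np.sum(rod.grid.volumes * (rod.ce[-1] + rod.cm[-1])))
        initial = plla.ce0 * np.pi * grid.radius**2 * grid.height
        assert interior + rod.release.total == pytest.approx(initial, rel=1e-9)

    def test_ester_is_pointwise_nonincreasing(self, plla):
        rod = solve_rod_1d(build_rod(0.8e-3, 6e-3, 30), plla,
                           settings(dt=1.0, t_end=200.0))
        assert np.all(np.diff(rod.ce, axis=0) <= 1e-12)
        assert np.all(rod.cm >= 0.0)
        assert np.all(rod.release.flux >= 0.0)
        assert np.all(np.diff(rod.release.cumulative) >= 0.0)

    def test_diffusivity_nondecreasing_along_trajectory(self, plla):
        rod = solve_rod_1d(build_rod(0.8e-3, 6e-3, 30), plla,
                           settings(dt=1.0, t_end=420.0))
        d = np.array([monomer_diffusivity(ce, cm, plla)
                      for ce, cm in zip(rod.ce, rod.cm)])
        assert np.all(np.diff(d, axis=0) >= -1e-25)

    def test_grid_refinement_convergence(self, plla):
        s = settings(dt=1.0, t_end=420.0)
        coarse = solve_rod_1d(build_rod(0.8e-3, 6e-3, 50), plla, copy.deepcopy(s))
        fine = solve_rod_1d(build_rod(0.8e-3, 6e-3, 100), plla, copy.deepcopy(s))
        cm_f = np.interp(coarse.grid.nodes, fine.grid.nodes, fine.cm[-1])
        rel = np.linalg.norm(coarse.cm[-1] - cm_f) / np.linalg.norm(cm_f)
        assert rel < 0.01

    def test_temporal_convergence(self, plla):
        grid = build_rod(0.8e-3, 6e-3, 40)
        a = solve_rod_1d(grid, plla, settings(dt=2.0, t_end=200.0))
        b = solve_rod_1d(grid, plla, settings(dt=1.0, t_end=200.0))
        rel = np.linalg.norm(a.cm[-1] - b.cm[-1]) / np.linalg.norm(b.cm[-1])
        assert rel < 0.01

    def test_sealed_rod_conserves(self, plla):
        grid = build_rod(0.8e-3, 6e-3, 20)
        rod = solve_rod_1d(grid, plla, settings(dt=1.0, t_end=100.0),
                           sink_surface=False)
        total = (rod.ce + rod.cm) @ grid.volumes
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-12

    def test_rod_mn_bounded_below_by_closed_trajectory(self, plla):
        """Monomer escape weakens autocatalysis, so the rod degrades no
        faster than the closed well-mixed system."""
        s_rod = settings(dt=1.0, t_end=420.0)
        rod = solve_rod_1d(build_rod(0.8e-3, 6e-3, 40), plla, s_rod)
        wm = solve_well_mixed(plla, settings(dt=1.0, t_end=420.0), closed=True)
        mn_rod = rod.mn_trajectory(plla.ce0).mn_rel
        mn_wm = wm.mn_trajectory(plla.ce0).mn_rel
        assert np.all(mn_rod >= mn_wm - 1e-6)
        assert np.all(np.diff(mn_rod) <= 1e-12)


@pytest.fixture(scope="module")
def small_spec():
    return ScaffoldSpec(height=0.008, width=0.008, thickness=0.004,
                        environment_margin=0.002)


class TestVoxel:
    def test_conservation_with_sinks(self, plla, small_spec):
        grid = build_bulk_scaffold(small_spec, 1e-3)
        res = solve_voxel(
            grid, plla, DomainDiffusivities(),
            settings(dt=1.0, t_end=60.0, output_times=[0, 10, 30, 60],
                     cm0_polymer=173.0, cm0_medium=173.0),
            scenario_boundary(grid, "bulk"),
        )
        assert res.mass_balance_error < 1e-4
        # independent recomputation at the final output
        gap = res.interior_total(-1) + res.total_exported(-1) - res.initial_total_mol
        assert abs(gap) / res.initial_total_mol < 1e-9

    def test_sealed_system_conserves_and_exports_nothing(self, plla, small_spec):
        grid = build_bulk_scaffold(small_spec, 1e-3)
        res = solve_voxel(
            grid, plla, DomainDiffusivities(),
            settings(dt=1.0, t_end=30.0, output_times=[0, 10, 30],
                     cm0_polymer=100.0, cm0_medium=100.0),
            scenario_boundary(grid, "sealed"),
        )
        assert res.total_exported(-1) == 0.0
        gap = res.interior_total(-1) - res.initial_total_mol
        assert abs(gap) / res.initial_total_mol < 1e-9

    def test_fields_stay_physical(self, plla, small_spec):
        grid = build_bulk_scaffold(small_spec, 1e-3)
        res = solve_voxel(
            grid, plla, DomainDiffusivities(),
            settings(dt=1.0, t_end=60.0, output_times=[0, 30, 60]),
            scenario_boundary(grid, "bulk"),
        )
        poly = grid.labels == POLYMER
        for i in range(len(res.times)):
            assert np.all(res.cm[i] >= 0.0)
            assert np.all(res.ce[i][~poly] == 0.0)
        ce_series = np.array([c[poly] for c in res.ce])
        assert np.all(np.diff(ce_series, axis=0) <= 1e-12)

    def test_temporal_convergence(self, plla, small_spec):
        grid = build_bulk_scaffold(small_spec, 1e-3)
        bc = scenario_boundary(grid, "bulk")
        out = [0, 30, 60]
        a = solve_voxel(grid, plla, DomainDiffusivities(),
                        settings(dt=2.0, t_end=60.0, output_times=out,
                                 cm0_polymer=173.0, cm0_medium=173.0), bc)
        b = solve_voxel(grid, plla, DomainDiffusivities(),
                        settings(dt=1.0, t_end=60.0, output_times=out,
                                 cm0_polymer=173.0, cm0_medium=173.0), bc)
        rel = np.linalg.norm(a.cm[-1] - b.cm[-1]) / np.linalg.norm(b.cm[-1])
        assert rel < 0.01

    def test_uncovered_surface_group_rejected(self, plla, small_spec):
        grid = build_bulk_scaffold(small_spec, 1e-3)
        bad = BoundarySpec(sink_groups={"contact"}, noflux_groups={"symmetry_x"})
        with pytest.raises(ValueError):
            solve_voxel(grid, plla, DomainDiffusivities(),
                        settings(dt=1.0, t_end=10.0, output_times=[0, 10]), bad)

    def test_grid_without_polymer_rejected(self, plla, small_spec):
        grid = build_bulk_scaffold(small_spec, 1e-3)
        grid.labels[grid.labels == POLYMER] = 3  # environment
        with pytest.raises(ValueError):
            solve_voxel(grid, plla, DomainDiffusivities(),
                        settings(dt=1.0, t_end=10.0, output_times=[0, 10]),
                        scenario_boundary(grid, "bulk"))


class TestSettings:
    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            SolverSettings(dt=-1.0, t_end=10.0)
        with pytest.raises(ValueError):
            SolverSettings(dt=20.0, t_end=10.0)

    def test_output_times_validated(self):
        with pytest.raises(ValueError):
            SolverSettings(dt=1.0, t_end=10.0, output_times=[0, 20])
        s = SolverSettings(dt=1.0, t_end=10.0, output_times=[5, 10])
        assert s.output_times[0] == 0.0  # t = 0 always included
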