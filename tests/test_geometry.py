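"""Voxelisation of rods and scaffolds: counts, groups, symmetry, connectivity."""

import numpy as np
import pytest
from scipy import ndimage

from polyerode.geometry import (
    ENVIRONMENT,
    POLYMER,
    PORE_MEDIUM,
    ScaffoldSpec,
    build_bulk_scaffold,
    build_porous_scaffold,
    build_rod,
    mirror_quarter,
)


class TestRodGrid:
    def test_canonical_rod_nodes(self):
        grid = build_rod(0.8e-3, 6e-3, 50)
        assert grid.nodes.shape == (50,)
        assert grid.nodes[0] == 0.0
        assert grid.nodes[-1] == pytest.approx(0.8e-3)

    def test_uniform_spacing(self):
        grid = build_rod(0.8e-3, 6e-3, 37)
        gaps = np.diff(grid.nodes)
        assert gaps.max() - gaps.min() < 1e-12 * grid.radius

    def test_minimal_grid_accepted(self):
        assert build_rod(1e-3, 1e-3, 4).n_radial == 4

    def test_control_volumes_fill_the_cylinder(self):
        grid = build_rod(0.8e-3, 6e-3, 23)
        assert grid.volumes.sum() == pytest.approx(np.pi * grid.radius**2 * grid.height)

    @pytest.mark.parametrize("kwargs", [dict(radius=0.0), dict(radius=1e-3, n_radial=3)])
    def test_degenerate_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_rod(**{"height": 6e-3, **kwargs})


class TestBulkScaffold:
    def test_quarter_polymer_voxel_count(self):
        # 10 mm block at 1 mm voxels: quarter = (W/2) x (H/2) x T voxels
        grid = build_bulk_scaffold(ScaffoldSpec(thickness=0.010), 1e-3)
        counts = grid.counts()
        assert counts["polymer"] == 20 * 25 * 10
        assert "pore_medium" not in counts  # scenario 1 has no pores

    def test_surface_groups_tile_boundary(self):
        grid = build_bulk_scaffold(ScaffoldSpec(thickness=0.010), 1e-3)
        grid.validate_surface_cover()
        assert len(grid.surface_groups["contact"]) == 20 * 25
        assert len(grid.surface_groups["symmetry_x"]) > 0

    def test_builds_are_deterministic(self):
        a = build_bulk_scaffold(ScaffoldSpec(thickness=0.010), 1e-3)
        b = build_bulk_scaffold(ScaffoldSpec(thickness=0.010), 1e-3)
        assert np.array_equal(a.labels, b.labels)
        for name in a.surface_groups:
            assert np.array_equal(a.surface_groups[name], b.surface_groups[name])

    def test_too_coarse_voxels_rejected(self):
        with pytest.raises(ValueError):
            build_bulk_scaffold(ScaffoldSpec(thickness=0.010), 4e-3)

    def test_refinement_changes_polymer_volume_little(self):
        spec = ScaffoldSpec(thickness=0.010)
        v1 = build_bulk_scaffold(spec, 1e-3).polymer_volume()
        v2 = build_bulk_scaffold(spec, 0.5e-3).polymer_volume()
        assert abs(v2 - v1) / v1 < 0.05


class TestMirror:
    def test_mirrored_polymer_volume_quadruples(self):
        quarter = build_bulk_scaffold(ScaffoldSpec(thickness=0.010), 1e-3)
        full, _ = mirror_quarter(quarter)
        assert full.polymer_volume() == pytest.approx(4 * quarter.polymer_volume())

    def test_mirror_then_restrict_is_identity(self):
        quarter = build_bulk_scaffold(ScaffoldSpec(thickness=0.010), 1e-3)
        full, _ = mirror_quarter(quarter)
        nx, ny, _ = quarter.dims
        assert np.array_equal(full.labels[nx:, ny:, :], quarter.labels)

    def test_mirror_matches_direct_full_build(self):
        spec = ScaffoldSpec(height=0.008, width=0.008, thickness=0.004,
                            environment_margin=0.002)
        quarter = build_bulk_scaffold(spec, 1e-3, quarter=True)
        full_direct = build_bulk_scaffold(spec, 1e-3, quarter=False)
        full_mirror, _ = mirror_quarter(quarter)
        assert np.array_equal(full_mirror.labels, full_direct.labels)

    def test_mirror_requires_symmetry_planes(self):
        spec = ScaffoldSpec(height=0.008, width=0.008, thickness=0.004)
        full = build_bulk_scaffold(spec, 1e-3, quarter=False)
        with pytest.raises(ValueError):
            mirror_quarter(full)


class TestPorousScaffold:
    def test_pore_voxel_count_against_brute_force_oracle(self):
        """Single-ellipsoid voxel count matches an independent centre-in-
        ellipsoid loop and the analytic volume within 10%."""
        h = 0.25e-3
        spec = ScaffoldSpec(thickness=0.010)
        grid = build_porous_scaffold(spec, h)
        a, b, c = spec.pore_semiaxes
        cx, cy, cz = 2.5e-3, 3.0e-3, 5.0e-3  # innermost quarter pore centre
        xs, ys, zs = grid.centres()
        count = 0
        for i in np.flatnonzero(np.abs(xs - cx) <= a + h):
            for j in np.flatnonzero(np.abs(ys - cy) <= b + h):
                for k in np.flatnonzero(np.abs(zs - cz) <= c + h):
                    inside = (
                        ((xs[i] - cx) / a) ** 2
                        + ((ys[j] - cy) / b) ** 2
                        + ((zs[k] - cz) / c) ** 2
                    ) <= 1.0
                    if inside:
                        count += 1
                        assert grid.labels[i, j, k] == PORE_MEDIUM
        analytic = 4.0 / 3.0 * np.pi * a * b * c / h**3
        assert abs(count - analytic) / analytic < 0.10

    def test_four_central_mode_opens_one_quarter_channel(self):
        grid = build_porous_scaffold(
            ScaffoldSpec(thickness=0.010, open_channel_mode="FOUR_CENTRAL"), 0.75e-3
        )
        assert len(grid.meta["open_channel_centres"]) == 1
        assert len(grid.surface_groups["open_channels_central"]) > 0
        assert len(grid.surface_groups["open_channels_outer"]) == 0
        assert len(grid.surface_groups["closed_channels"]) > 0

    def test_none_mode_has_no_open_channels(self):
        grid = build_porous_scaffold(
            ScaffoldSpec(thickness=0.010, open_channel_mode="NONE"), 0.75e-3
        )
        assert len(grid.surface_groups["open_channels_central"]) == 0
        assert len(grid.surface_groups["open_channels_outer"]) == 0

    def test_surface_groups_tile_boundary(self):
        grid = build_porous_scaffold(ScaffoldSpec(thickness=0.010), 0.75e-3)
        grid.validate_surface_cover()

    def test_pore_network_connected_to_open_channels(self):
        """Every pore-medium component reaches an open delivery aperture."""
        grid = build_porous_scaffold(
            ScaffoldSpec(thickness=0.010, open_channel_mode="ALL"), 0.75e-3
        )
        comp, n = ndimage.label(grid.labels == PORE_MEDIUM)
        aperture_cells = np.vstack(
            [
                grid.surface_groups["open_channels_central"][:, :3],
                grid.surface_groups["open_channels_outer"][:, :3],
            ]
        )
        reached = {comp[i, j, k] for i, j, k in aperture_cells}
        assert set(range(1, n + 1)) <= reached

    def test_two_pore_layers_in_thick_block(self):
        spec = ScaffoldSpec(thickness=0.020)
        assert spec.n_pore_layers == 2
        centres = spec.pore_centres()
        assert len(np.unique(centres[:, 2])) == 2

    def test_refinement_changes_polymer_volume_little(self):
        spec = ScaffoldSpec(thickness=0.010)
        v1 = build_porous_scaffold(spec, 0.5e-3).polymer_volume()
        v2 = build_porous_scaffold(spec, 0.25e-3).polymer_volume()
        assert abs(v2 - v1) / v1 < 0.05

    def test_unresolvable_pores_rejected(self):
        with pytest.raises(ValueError):
            build_porous_scaffold(ScaffoldSpec(thickness=0.010), 1e-3)

    def test_block_too_small_for_lattice(self):
        spec = ScaffoldSpec(height=0.006, width=0.006, thickness=0.010)
        with pytest.raises(ValueError):
            build_porous_scaffold(spec, 0.5e-3)


class TestScaffoldSpec:
    def test_canonical_flag(self):
        assert ScaffoldSpec(thickness=0.010).canonical
        assert ScaffoldSpec(thickness=0.020).canonical
        assert not ScaffoldSpec(thickness=0.008).canonical

    def test_two_layers_require_thick_block(self):
        with pytest.raises(ValueError):
            ScaffoldSpec(thickness=0.010, pore_layers=2)

    def test_unknown_channel_mode_rejected(self):
        with pytest.raises(ValueError):
            ScaffoldSpec(open_channel_mode="SOME")
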