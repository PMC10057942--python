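"""Labelled voxel grids for rod samples and C-block scaffolds.

Two sample families are supported:

* calibration rods (1.6 mm diameter, 6 mm height), reduced to a 1-D
  axisymmetric radial grid;
* C-block scaffolds (50 x 40 x 10/20 mm bounding box), voxelised as a
  rectangular block, either bulk (scenario 1) or with an interconnected
  ellipsoidal macropore lattice and delivery channels (scenario 2).

The block has two mid-planes of symmetry (width and height); canonical runs
use the quarter geometry with zero-flux symmetry planes.  The full-block
coordinate frame is x in [-W/2, W/2] (width), y in [-H/2, H/2] (height),
z in [0, T] (thickness), with the bone-contact plane at z = 0 and an
environment margin wrapping the remaining outward faces.

Voxels take the label of the domain containing their centre.  Label fields are
deterministic functions of (spec, voxel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "EXTERIOR",
    "POLYMER",
    "PORE_MEDIUM",
    "ENVIRONMENT",
    "RodGrid",
    "ScaffoldSpec",
    "VoxelGrid",
    "build_rod",
    "build_bulk_scaffold",
    "build_porous_scaffold",
    "mirror_quarter",
]

EXTERIOR = 0
POLYMER = 1
PORE_MEDIUM = 2
ENVIRONMENT = 3

LABEL_NAMES = {
    EXTERIOR: "exterior",
    POLYMER: "polymer",
    PORE_MEDIUM: "pore_medium",
    ENVIRONMENT: "environment",
}


# --------------------------------------------------------------------------
# 1-D axisymmetric rod grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RodGrid:
    """Uniform radial node grid on [0, R] for the 1-D axisymmetric solver.

    Node 0 sits on the symmetry axis, the last node on the sink surface r = R.
    """

    radius: float
    height: float
    n_radial: int

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.radius, self.n_radial)

    @property
    def spacing(self) -> float:
        return self.radius / (self.n_radial - 1)

    @property
    def volumes(self) -> np.ndarray:
        """Control volume of each node (m^3), cylindrical shells of height H."""
        h = self.spacing
        r = self.nodes
        inner = np.maximum(r - h / 2.0, 0.0)
        outer = np.minimum(r + h / 2.0, self.radius)
        return np.pi * (outer**2 - inner**2) * self.height


def build_rod(radius: float, height: float = 6e-3, n_radial: int = 50) -> RodGrid:
    """Radial grid for a cylindrical rod sample.

    Defaults match the calibration samples (0.8 mm radius, 6 mm height).
    """
    if radius <= 0:
        raise ValueError("rod radius must be positive")
    if height <= 0:
        raise ValueError("rod height must be positive")
    if n_radial < 4:
        raise ValueError("need at least 4 radial nodes")
    return RodGrid(radius=float(radius), height=float(height), n_radial=int(n_radial))


# --------------------------------------------------------------------------
# Scaffold specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldSpec:
    """Geometric specification of the C-block scaffold (metres).

    The block curvature is not modelled; the scaffold is voxelised as a
    rectangular block of the stated bounding dimensions.  Macropores are
    ellipsoids with semi-axes ``pore_semiaxes`` on a regular lattice of pitch
    (pore extent + channel length), centred in the block; neighbouring pores
    are connected by cylindrical channels, and each lowest-layer pore carries
    a delivery channel to the contact face.  Lateral hydrogel-fill channels
    run from the outermost pore columns toward the lateral faces and are
    sealed by one voxel of polymer (they are closed during operation).
    """

    height: float = 0.050
    width: float = 0.040
    thickness: float = 0.010
    pore_semiaxes: tuple[float, float, float] = (1.5e-3, 2.0e-3, 1.5e-3)
    channel_diameter: float = 2.0e-3
    channel_length: float = 2.0e-3
    fill_channel_diameter: float = 2.0e-3
    fill_channel_length: float = 1.0e-3
    pore_layers: int | None = None
    open_channel_mode: str | tuple = "ALL"
    environment_margin: float = 2.0e-3

    def __post_init__(self) -> None:
        for name in ("height", "width", "thickness", "channel_diameter",
                     "channel_length", "environment_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.pore_semiaxes):
            raise ValueError("pore semi-axes must be positive")
        if self.pore_layers is not None and self.pore_layers not in (1, 2):
            raise ValueError("pore_layers must be 1 or 2")
        if self.pore_layers == 2 and self.thickness < 0.020:
            raise ValueError("two pore layers require the 20 mm thickness")
        if isinstance(self.open_channel_mode, str):
            if self.open_channel_mode not in ("ALL", "FOUR_CENTRAL", "NONE"):
                raise ValueError(
                    "open_channel_mode must be ALL, FOUR_CENTRAL, NONE or an "
                    "explicit list of (x, y) channel centres"
                )

    @property
    def canonical(self) -> bool:
        """True for the two study thicknesses (10 and 20 mm)."""
        return self.thickness in (0.010, 0.020)

    @property
    def n_pore_layers(self) -> int:
        if self.pore_layers is not None:
            return self.pore_layers
        return 2 if self.thickness >= 0.020 else 1

    # Lattice pitch per axis: pore extent plus the connector-channel length.
    @property
    def pitch(self) -> tuple[float, float, float]:
        a, b, c = self.pore_semiaxes
        L = self.channel_length
        return (2 * a + L, 2 * b + L, 2 * c + L)

    def pore_centres(self) -> np.ndarray:
        """Pore-centre coordinates in the full-block frame, shape (n, 3).

        The lattice is centred: centres sit at +/-(pitch/2 + k*pitch) in x
        and y, so counts are even and the "four central" channels are the
        innermost ring (one per quarter).
        """
        a, b, c = self.pore_semiaxes
        px, py, pz = self.pitch
        half_w, half_h = self.width / 2.0, self.height / 2.0

        def _axis(half_extent: float, semi: float, pitch: float) -> np.ndarray:
            kmax = int(np.floor((half_extent - semi - pitch / 2.0) / pitch))
            if kmax < 0:
                raise ValueError("block too small to host a centred pore lattice")
            pos = pitch / 2.0 + pitch * np.arange(kmax + 1)
            return np.concatenate([-pos[::-1], pos])

        xs = _axis(half_w, a, px)
        ys = _axis(half_h, b, py)
        if self.n_pore_layers == 1:
            zs = np.array([self.thickness / 2.0])
        else:
            zs = self.thickness / 2.0 + pz / 2.0 * np.array([-1.0, 1.0])
        if np.any(zs - c < 0) or np.any(zs + c > self.thickness):
            raise ValueError("pore layer does not fit within the block thickness")
        grid = np.array([(x, y, z) for z in zs for y in ys for x in xs])
        return grid


# --------------------------------------------------------------------------
# Voxel grid container
# --------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Labelled structured voxel grid with named exterior surface groups.

    ``labels`` has shape ``dims``; ``origin`` is the coordinate of the corner
    of voxel (0,0,0) in the full-block frame.  ``surface_groups`` maps group
    names to integer arrays of shape (n, 5) with columns (i, j, k, axis,
    side): the face of cell (i,j,k) in direction ``axis`` (0..2) on side
    ``side`` (-1 or +1).  Every face between an active cell and EXTERIOR
    belongs to exactly one group.
    """

    dims: tuple[int, int, int]
    spacing: float
    origin: tuple[float, float, float]
    labels: np.ndarray
    surface_groups: dict[str, np.ndarray]
    symmetry: tuple[bool, bool] = (False, False)
    meta: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return {LABEL_NAMES[int(v)]: int(c) for v, c in zip(vals, cnt)}

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def polymer_volume(self) -> float:
        return float(np.count_nonzero(self.labels == POLYMER)) * self.voxel_volume

    def centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.spacing
        return tuple(
            self.origin[a] + (np.arange(self.dims[a]) + 0.5) * h for a in range(3)
        )

    def validate_surface_cover(self) -> None:
        """Check the surface groups tile the exterior boundary exactly once."""
        seen = {}
        for name, faces in self.surface_groups.items():
            for row in np.atleast_2d(faces).reshape(-1, 5):
                key = tuple(int(v) for v in row)
                if key in seen:
                    raise ValueError(
                        f"face {key} in both {seen[key]!r} and {name!r}"
                    )
                seen[key] = name
        expected = {tuple(int(v) for v in row) for row in _boundary_faces(self.labels)}
        if set(seen) != expected:
            missing = expected - set(seen)
            extra = set(seen) - expected
            raise ValueError(
                f"surface groups do not tile the boundary: {len(missing)} missing, "
                f"{len(extra)} spurious faces"
            )


def _boundary_faces(labels: np.ndarray) -> np.ndarray:
    """All (i,j,k,axis,side) faces between active cells and EXTERIOR."""
    padded = np.pad(labels, 1, constant_values=EXTERIOR)
    active = labels > EXTERIOR
    rows = []
    for axis in range(3):
        for side in (-1, 1):
            shifted = np.roll(padded, -side, axis=axis)[1:-1, 1:-1, 1:-1]
            mask = active & (shifted == EXTERIOR)
            idx = np.argwhere(mask)
            if idx.size:
                cols = np.column_stack(
                    [idx, np.full(len(idx), axis), np.full(len(idx), side)]
                )
                rows.append(cols)
    if not rows:
        return np.empty((0, 5), dtype=int)
    return np.vstack(rows).astype(int)


# --------------------------------------------------------------------------
# Builders
# --------------------------------------------------------------------------

def _axis_counts(extent: float, h: float) -> int:
    """Voxel count along one axis; the extent must divide within one voxel.

    The rounding is absorbed by the environment margin (the polymer box is
    defined in coordinates, not voxel counts).
    """
    n = int(round(extent / h))
    if n < 1 or abs(n * h - extent) > h + 1e-12:
        raise ValueError(
            f"voxel size {h} does not divide extent {extent} within one voxel"
        )
    return n


def _frame(spec: ScaffoldSpec, h: float, quarter: bool):
    """Domain box, dims and origin for quarter or full geometry.

    The full frame mirrors the quarter counts so quarter and full grids have
    exactly aligned cells (required by the mirror/full-solve equivalence).
    """
    m = spec.environment_margin
    hw, hh = spec.width / 2.0, spec.height / 2.0
    half = (_axis_counts(hw + m, h), _axis_counts(hh + m, h))
    nz = _axis_counts(spec.thickness + m, h)
    if quarter:
        origin = (0.0, 0.0, 0.0)
        dims = (half[0], half[1], nz)
    else:
        origin = (-half[0] * h, -half[1] * h, 0.0)
        dims = (2 * half[0], 2 * half[1], nz)
    return origin, dims


def _label_block(spec: ScaffoldSpec, h: float, quarter: bool):
    origin, dims = _frame(spec, h, quarter)
    xs = origin[0] + (np.arange(dims[0]) + 0.5) * h
    ys = origin[1] + (np.arange(dims[1]) + 0.5) * h
    zs = origin[2] + (np.arange(dims[2]) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    hw, hh = spec.width / 2.0, spec.height / 2.0
    in_polymer = (np.abs(X) < hw) & (np.abs(Y) < hh) & (Z < spec.thickness)
    labels = np.full(dims, ENVIRONMENT, dtype=np.int8)
    labels[in_polymer] = POLYMER
    return origin, dims, labels, (X, Y, Z)


def _carve_pores(spec: ScaffoldSpec, labels, coords, h: float):
    """Mark macropores, connector/delivery/fill channels as PORE_MEDIUM.

    Returns the pore centres and the delivery-channel (x, y) axes (lowest
    pore layer).  Channels are carved only where the block is polymer, so
    pores cannot leak into the environment margin.
    """
    X, Y, Z = coords
    a, b, c = spec.pore_semiaxes
    centres = spec.pore_centres()
    if np.any(np.abs(centres[:, 0]) + a > spec.width / 2.0) or np.any(
        np.abs(centres[:, 1]) + b > spec.height / 2.0
    ):
        raise ValueError("pore lattice overlaps the block boundary")
    polymer = labels == POLYMER
    pore = np.zeros_like(polymer)
    for cx, cy, cz in centres:
        pore |= (
            ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2
        ) <= 1.0

    r = spec.channel_diameter / 2.0
    px, py, pz = spec.pitch
    cset = {tuple(np.round(cc, 12)) for cc in centres}

    def _seg(axis, c1, c2):
        """Cylinder of radius r between centres c1 and c2 along axis."""
        lo = np.minimum(c1, c2)
        hi = np.maximum(c1, c2)
        if axis == 0:
            return (X >= lo[0]) & (X <= hi[0]) & ((Y - c1[1]) ** 2 + (Z - c1[2]) ** 2 <= r**2)
        if axis == 1:
            return (Y >= lo[1]) & (Y <= hi[1]) & ((X - c1[0]) ** 2 + (Z - c1[2]) ** 2 <= r**2)
        return (Z >= lo[2]) & (Z <= hi[2]) & ((X - c1[0]) ** 2 + (Y - c1[1]) ** 2 <= r**2)

    chan = np.zeros_like(polymer)
    offsets = [(0, np.array([px, 0, 0])), (1, np.array([0, py, 0])),
               (2, np.array([0, 0, pz]))]
    for cc in centres:
        for axis, off in offsets:
            nb = cc + off
            if tuple(np.round(nb, 12)) in cset:
                chan |= _seg(axis, cc, nb)

    # Delivery channels: lowest layer down to the contact face z = 0.
    zmin = centres[:, 2].min()
    delivery = centres[np.isclose(centres[:, 2], zmin)]
    for cx, cy, cz in delivery:
        chan |= (Z <= cz) & ((X - cx) ** 2 + (Y - cy) ** 2 <= r**2)

    # Lateral fill channels: outermost pore columns toward the +/-x faces,
    # stopped one voxel short of the surface (polymer-sealed, no flux).
    rf = spec.fill_channel_diameter / 2.0
    xmax = centres[:, 0].max()
    seal = spec.width / 2.0 - h
    for cx, cy, cz in centres:
        if np.isclose(abs(cx), xmax):
            sgn = np.sign(cx)
            lo, hi = sorted((cx, sgn * seal))
            chan |= (X >= lo) & (X <= hi) & ((Y - cy) ** 2 + (Z - cz) ** 2 <= rf**2)

    labels[(pore | chan) & polymer] = PORE_MEDIUM
    return centres, delivery[:, :2]


def _group_faces(labels, origin, h, quarter, delivery_xy=None, open_mode="ALL"):
    """Assign every exterior-adjacent face to a named surface group."""
    faces = _boundary_faces(labels)
    groups: dict[str, list] = {"contact": [], "far_field": []}
    if quarter:
        groups["symmetry_x"] = []
        groups["symmetry_y"] = []
    porous = delivery_xy is not None and len(delivery_xy) > 0
    open_centres: list[tuple[float, float]] = []
    if porous:
        groups["open_channels_central"] = []
        groups["open_channels_outer"] = []
        groups["closed_channels"] = []
        dxy = np.asarray(delivery_xy, dtype=float)
        # innermost ring = smallest |x| and |y| among delivery axes
        cx0 = np.min(np.abs(dxy[:, 0]))
        cy0 = np.min(np.abs(dxy[:, 1]))
        central = np.isclose(np.abs(dxy[:, 0]), cx0) & np.isclose(np.abs(dxy[:, 1]), cy0)
        if isinstance(open_mode, str):
            if open_mode == "ALL":
                is_open = np.ones(len(dxy), dtype=bool)
            elif open_mode == "FOUR_CENTRAL":
                is_open = central.copy()
            else:  # NONE
                is_open = np.zeros(len(dxy), dtype=bool)
        else:
            req = np.asarray(open_mode, dtype=float).reshape(-1, 2)
            is_open = np.zeros(len(dxy), dtype=bool)
            for pt in req:
                d2 = np.sum((dxy - pt) ** 2, axis=1)
                is_open[int(np.argmin(d2))] = True
        open_centres = [tuple(map(float, dxy[i])) for i in np.flatnonzero(is_open)]

    for row in faces:
        i, j, k, axis, side = (int(v) for v in row)
        lab = labels[i, j, k]
        if quarter and axis == 0 and side == -1 and i == 0:
            groups["symmetry_x"].append(row)
        elif quarter and axis == 1 and side == -1 and j == 0:
            groups["symmetry_y"].append(row)
        elif axis == 2 and side == -1 and k == 0:
            if lab == POLYMER:
                groups["contact"].append(row)
            elif lab == PORE_MEDIUM and porous:
                x = origin[0] + (i + 0.5) * h
                y = origin[1] + (j + 0.5) * h
                d2 = np.sum((dxy - np.array([x, y])) ** 2, axis=1)
                ch = int(np.argmin(d2))
                if not is_open[ch]:
                    groups["closed_channels"].append(row)
                elif central[ch]:
                    groups["open_channels_central"].append(row)
                else:
                    groups["open_channels_outer"].append(row)
            else:
                groups["far_field"].append(row)
        else:
            groups["far_field"].append(row)

    out = {
        name: (np.array(rows, dtype=int).reshape(-1, 5) if rows else
               np.empty((0, 5), dtype=int))
        for name, rows in groups.items()
    }
    return out, open_centres


def build_bulk_scaffold(
    spec: ScaffoldSpec, voxel_size: float, quarter: bool = True
) -> VoxelGrid:
    """Voxelise the bulk (non-porous) scaffold with its environment shell.

    The polymer slab is wrapped by an ENVIRONMENT margin on the outward faces;
    the bone-side face (z = 0) of the polymer forms the "contact" group, the
    environment outer boundary the "far_field" group, and (for the quarter
    geometry) the two mid-planes the symmetry groups.
    """
    if voxel_size > spec.thickness / 4.0:
        raise ValueError("voxel size too coarse: must resolve thickness/4")
    origin, dims, labels, _ = _label_block(spec, voxel_size, quarter)
    groups, _ = _group_faces(labels, origin, voxel_size, quarter)
    return VoxelGrid(
        dims=dims, spacing=voxel_size, origin=origin, labels=labels,
        surface_groups=groups, symmetry=(quarter, quarter),
        meta={"spec": spec, "scenario": "bulk", "canonical": spec.canonical},
    )


def build_porous_scaffold(
    spec: ScaffoldSpec, voxel_size: float, quarter: bool = True
) -> VoxelGrid:
    """Voxelise the macroporous scaffold (ellipsoidal pores + channels).

    Delivery-channel apertures on the contact face are grouped as
    "open_channels_central" / "open_channels_outer" according to
    ``spec.open_channel_mode``; sealed apertures form "closed_channels"
    (no-flux).  In FOUR_CENTRAL mode the quarter geometry exposes exactly one
    open channel.
    """
    if voxel_size > min(spec.pore_semiaxes) / 2.0:
        raise ValueError("voxel size too coarse: pores must be resolvable")
    origin, dims, labels, coords = _label_block(spec, voxel_size, quarter)
    centres, delivery_xy = _carve_pores(spec, labels, coords, voxel_size)
    groups, open_centres = _group_faces(
        labels, origin, voxel_size, quarter,
        delivery_xy=delivery_xy, open_mode=spec.open_channel_mode,
    )
    if quarter:
        keep = (delivery_xy[:, 0] > 0) & (delivery_xy[:, 1] > 0)
        delivery_xy = delivery_xy[keep]
    return VoxelGrid(
        dims=dims, spacing=voxel_size, origin=origin, labels=labels,
        surface_groups=groups, symmetry=(quarter, quarter),
        meta={
            "spec": spec, "scenario": "porous", "canonical": spec.canonical,
            "pore_centres": centres, "delivery_channel_axes": delivery_xy,
            "open_channel_centres": [
                c for c in open_centres if c[0] > 0 and c[1] > 0
            ] if quarter else open_centres,
        },
    )


def mirror_quarter(
    grid: VoxelGrid, fields: dict[str, np.ndarray] | None = None
) -> tuple[VoxelGrid, dict[str, np.ndarray]]:
    """Reflect a quarter grid (and optional cell fields) to the full geometry.

    Intended for validation and visualisation; symmetry groups disappear and
    the remaining surface groups are remapped to the mirrored indices.
    """
    if not (grid.symmetry[0] and grid.symmetry[1]):
        raise ValueError("grid does not declare two symmetry planes")

    def _mirror_array(arr: np.ndarray) -> np.ndarray:
        arr = np.concatenate([arr[::-1], arr], axis=0)
        return np.concatenate([arr[:, ::-1], arr], axis=1)

    nx, ny, _ = grid.dims
    labels = _mirror_array(grid.labels)
    out_fields = {k: _mirror_array(v) for k, v in (fields or {}).items()}

    groups: dict[str, np.ndarray] = {}
    for name, faces in grid.surface_groups.items():
        if name.startswith("symmetry"):
            continue
        rows = []
        for i, j, k, axis, side in np.atleast_2d(faces).reshape(-1, 5):
            for fx in (False, True):
                for fy in (False, True):
                    ii = nx - 1 - i if fx else nx + i
                    jj = ny - 1 - j if fy else ny + j
                    ss = side
                    if (axis == 0 and fx) or (axis == 1 and fy):
                        ss = -side
                    rows.append((ii, jj, k, axis, ss))
        groups[name] = np.array(rows, dtype=int).reshape(-1, 5)

    hw = grid.origin[0] + grid.dims[0] * grid.spacing
    hh = grid.origin[1] + grid.dims[1] * grid.spacing
    full = VoxelGrid(
        dims=(2 * nx, 2 * ny, grid.dims[2]), spacing=grid.spacing,
        origin=(-hw, -hh, grid.origin[2]), labels=labels,
        surface_groups=groups, symmetry=(False, False),
        meta=dict(grid.meta, mirrored=True),
    )
    return full, out_fields
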