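"""Time integration of the coupled ester/monomer system.

Three settings share one physics: the ester field evolves by local reaction
only (ester groups do not diffuse), the monomer field by reaction plus
diffusion with state-dependent diffusivity in the polymer and constant
diffusivity in the aqueous/pore domains.

Discretisation is finite-volume (radial shells in 1-D, uniform voxels in
3-D), which makes the discrete mass balance exact: at every step,
interior(Ce + Cm) plus the cumulative export through sink faces equals the
initial total up to linear-solver round-off.  Time stepping is IMEX: backward
Euler for diffusion with the diffusivity lagged one step (the polymer/medium
diffusivity contrast spans ~8 orders of magnitude, so explicit diffusion is
infeasible), explicit midpoint (RK2) for the non-stiff reaction.  Face
diffusivities are harmonic means, the correct flux-continuity average across
the sharp polymer/medium contrast.  Sink surfaces impose a ghost-face
Dirichlet Cm = 0 (perfect washout); symmetry planes and sealed channels are
zero-normal-flux.

Tiny negative concentrations from round-off are clamped to zero before rate
evaluation; the clamped mass is tracked and must stay below 1e-10 * Ce0 per
step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from . import geometry
from .geometry import POLYMER, PORE_MEDIUM, ENVIRONMENT, RodGrid, VoxelGrid
from .kinetics import KineticParameters, monomer_diffusivity
from .observables import ReleaseRecord, mn_from_state, MnTrajectory
from .units import AQUEOUS_DIFFUSIVITY_M2_PER_DAY

__all__ = [
    "SolverSettings",
    "DomainDiffusivities",
    "BoundarySpec",
    "FieldState",
    "WellMixedResult",
    "RodResult",
    "VoxelResult",
    "solve_well_mixed",
    "solve_rod_1d",
    "solve_voxel",
]

_CLAMP_LIMIT = 1e-10  # allowed clamped negative mass per step, relative to Ce0


def _harmonic(a, b):
    """Harmonic-mean face value, zero when either side is zero."""
    s = a + b
    return np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)


@dataclass
class SolverSettings:
    """Time-integration settings (days)."""

    dt: float = 1.0
    t_end: float = 420.0
    output_times: np.ndarray | None = None
    cm0_polymer: float = 0.0   # initial monomer concentration in polymer, mol/m^3
    cm0_medium: float = 0.0    # initial monomer in pore medium / environment
    mass_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.dt <= self.t_end:
            raise ValueError("require 0 < dt <= t_end")
        if self.output_times is None:
            out = np.arange(0.0, self.t_end, 30.0)
            self.output_times = np.append(out, self.t_end)
        else:
            out = np.unique(np.asarray(self.output_times, dtype=float))
            if out.min() < 0 or out.max() > self.t_end:
                raise ValueError("output_times must lie in [0, t_end]")
            if out[0] != 0.0:
                out = np.insert(out, 0, 0.0)
            self.output_times = out

    def step_times(self) -> np.ndarray:
        """Monotone step schedule hitting every output time exactly.

        Times are rounded to 1e-9 days so an output time never creates a
        spurious near-zero sub-step next to a regular step.
        """
        base = np.arange(0.0, self.t_end, self.dt)
        ts = np.concatenate([base, self.output_times, [self.t_end]])
        return np.unique(np.round(ts, 9))


@dataclass(frozen=True)
class DomainDiffusivities:
    """Constant monomer diffusivities outside the polymer, m^2/day.

    Defaults are 1e-9 m^2/s (aqueous medium / surrounding tissue) converted
    to per-day; the polymer value is state dependent and not stored here.
    """

    pore_medium: float = AQUEOUS_DIFFUSIVITY_M2_PER_DAY
    environment: float = AQUEOUS_DIFFUSIVITY_M2_PER_DAY

    def __post_init__(self) -> None:
        if self.pore_medium <= 0 or self.environment <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass
class BoundarySpec:
    """Condition per surface group: perfect sink (Cm = 0) or zero flux."""

    sink_groups: frozenset = frozenset()
    noflux_groups: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.sink_groups = frozenset(self.sink_groups)
        self.noflux_groups = frozenset(self.noflux_groups)
        if self.sink_groups & self.noflux_groups:
            raise ValueError("a group cannot be both sink and no-flux")

    def validate_cover(self, grid: VoxelGrid) -> None:
        names = set(grid.surface_groups)
        covered = self.sink_groups | self.noflux_groups
        missing = {n for n in names - covered if len(grid.surface_groups[n])}
        if missing:
            raise ValueError(f"surface groups without a boundary condition: {missing}")


@dataclass
class FieldState:
    """Concentration fields at one time point (mol/m^3)."""

    ce: np.ndarray
    cm: np.ndarray
    time: float


# --------------------------------------------------------------------------
# shared reaction step
# --------------------------------------------------------------------------

def _reaction_step(ce, cm, params: KineticParameters, dt: float):
    """Explicit midpoint step of the local scission reaction.

    Returns (ce_new, produced) where ``produced`` (>= 0) is the monomer
    concentration generated during the step; callers add it to Cm or divert
    it to export at Dirichlet nodes.  Also returns the clamped negative mass.
    """
    k1, k2, beta = params.k1, params.k2, params.beta

    def rate(ce_, cm_):
        return k1 * ce_ + k2 * ce_ * np.clip(cm_, 0.0, None) ** beta

    r0 = rate(ce, cm)
    r1 = rate(ce - 0.5 * dt * r0, cm + 0.5 * dt * r0)
    produced = dt * r1
    ce_new = ce - produced
    clamped = float(np.sum(np.clip(-ce_new, 0.0, None)))
    np.clip(ce_new, 0.0, None, out=ce_new)
    produced = ce - ce_new  # keep production exactly equal to ester loss
    return ce_new, produced, clamped


def _check_clamp(clamped: float, ce0: float) -> None:
    if clamped > _CLAMP_LIMIT * ce0:
        raise RuntimeError(
            f"negative-concentration clamp {clamped:.3e} exceeded "
            f"{_CLAMP_LIMIT:.0e} * Ce0; reduce dt"
        )


# --------------------------------------------------------------------------
# 0-D well-mixed
# --------------------------------------------------------------------------

@dataclass
class WellMixedResult:
    times: np.ndarray
    ce: np.ndarray
    cm: np.ndarray
    exported: np.ndarray   # cumulative mol/m^3 removed (open mode only)
    closed: bool

    def mn_trajectory(self, ce0: float, mn0: float = 1.0) -> MnTrajectory:
        return MnTrajectory(self.times, self.ce / ce0, mn0)


def solve_well_mixed(
    params: KineticParameters, settings: SolverSettings, closed: bool = True
) -> WellMixedResult:
    """Integrate the space-free two-state reduction of the model.

    In closed mode no monomer leaves, so Ce + Cm = Ce0 + Cm(0) at all times.
    In open mode the monomer is washed out instantly (Cm = 0) and the removed
    amount is reported as ``exported``.  Uses a high-order adaptive integrator
    (DOP853) at tight tolerance; the reaction is non-stiff at these rates.
    """
    t_eval = settings.output_times
    ce0 = params.ce0

    if closed:
        def rhs(_t, y):
            ce, cm = y
            r = params.k1 * ce + params.k2 * ce * max(cm, 0.0) ** params.beta
            return [-r, r]

        sol = solve_ivp(
            rhs, (0.0, settings.t_end), [ce0, settings.cm0_polymer],
            t_eval=t_eval, method="DOP853", rtol=1e-11, atol=1e-8,
        )
        if not sol.success:
            raise RuntimeError(f"well-mixed integration failed: {sol.message}")
        ce, cm = sol.y
        exported = np.zeros_like(ce)
    else:
        def rhs(_t, y):
            return [-params.k1 * y[0]]

        sol = solve_ivp(
            rhs, (0.0, settings.t_end), [ce0], t_eval=t_eval,
            method="DOP853", rtol=1e-11, atol=1e-8,
        )
        if not sol.success:
            raise RuntimeError(f"well-mixed integration failed: {sol.message}")
        ce = sol.y[0]
        cm = np.zeros_like(ce)
        exported = ce0 - ce + settings.cm0_polymer

    return WellMixedResult(
        times=np.asarray(t_eval), ce=ce, cm=cm, exported=exported, closed=closed
    )


# --------------------------------------------------------------------------
# 1-D axisymmetric rod
# --------------------------------------------------------------------------

@dataclass
class RodResult:
    grid: RodGrid
    times: np.ndarray
    ce: np.ndarray       # (n_out, n_radial)
    cm: np.ndarray
    release: ReleaseRecord
    mass_balance_error: float   # max relative deviation over outputs

    @property
    def volumes(self) -> np.ndarray:
        return self.grid.volumes

    def states(self) -> list[FieldState]:
        return [
            FieldState(self.ce[i], self.cm[i], t) for i, t in enumerate(self.times)
        ]

    def mn_trajectory(self, ce0: float, mn0: float = 1.0) -> MnTrajectory:
        rel = np.array(
            [mn_from_state(c, ce0, weights=self.volumes)[0] for c in self.ce]
        )
        return MnTrajectory(self.times, rel, mn0)


def solve_rod_1d(
    grid: RodGrid,
    params: KineticParameters,
    settings: SolverSettings,
    sink_surface: bool = True,
) -> RodResult:
    """Finite-volume integration on the radial rod grid.

    The surface node (r = R) is a perfect sink (Cm = 0, "monomers reaching
    the surface are immediately washed out"); the axis is a symmetry point.
    ``sink_surface=False`` seals the rod (no-flux everywhere) for audits.
    Ester groups never diffuse: each node's Ce changes only by local reaction.
    """
    n = grid.n_radial
    h = grid.spacing
    r = grid.nodes
    V = grid.volumes
    # interior face areas between nodes j and j+1, at radius r_j + h/2
    A = 2.0 * np.pi * (r[:-1] + h / 2.0) * grid.height

    ce = np.full(n, params.ce0)
    cm = np.full(n, settings.cm0_polymer)
    if sink_surface:
        cm[-1] = 0.0

    initial_total = float(np.sum(V * (ce + cm)))
    step_times = settings.step_times()
    out_times = settings.output_times
    out_set = {round(t, 9) for t in out_times}

    ce_hist, cm_hist = [ce.copy()], [cm.copy()]
    flux_hist, cum_hist = [0.0], [0.0]
    cumulative = 0.0
    max_err = 0.0

    for t_prev, t_next in zip(step_times[:-1], step_times[1:]):
        dt = t_next - t_prev
        ce, produced, clamped = _reaction_step(ce, cm, params, dt)
        _check_clamp(clamped, params.ce0)
        export_react = 0.0
        if sink_surface:
            # monomer created at the sink node is washed out immediately
            export_react = produced[-1] * V[-1]
            produced = produced.copy()
            produced[-1] = 0.0
        cm = cm + produced

        D = monomer_diffusivity(ce, cm, params)
        Df = _harmonic(D[:-1], D[1:])
        c_face = Df * A / h      # mol/day per unit concentration difference

        m = n - 1 if sink_surface else n
        diag = V[:m] / dt
        lower = np.zeros(m)
        upper = np.zeros(m)
        diag[:-1] += c_face[: m - 1]
        diag[1:] += c_face[: m - 1]
        upper[1:] = -c_face[: m - 1]
        lower[:-1] = -c_face[: m - 1]
        if sink_surface:
            diag[m - 1] += c_face[m - 1]   # ghost Dirichlet 0 at node n-1
        ab = np.vstack([upper, diag, lower])
        cm_new = solve_banded((1, 1), ab, V[:m] / dt * cm[:m])
        flux_diff = c_face[m - 1] * cm_new[m - 1] if sink_surface else 0.0
        cm = np.append(cm_new, 0.0) if sink_surface else cm_new
        np.clip(cm, 0.0, None, out=cm)

        cumulative += flux_diff * dt + export_react
        flux_now = flux_diff + (export_react / dt)

        if round(t_next, 9) in out_set:
            ce_hist.append(ce.copy())
            cm_hist.append(cm.copy())
            flux_hist.append(flux_now)
            cum_hist.append(cumulative)
            total = float(np.sum(V * (ce + cm))) + cumulative
            max_err = max(max_err, abs(total - initial_total) / initial_total)

    if max_err > settings.mass_tolerance:
        raise RuntimeError(f"rod mass balance violated: {max_err:.3e}")

    release = ReleaseRecord(
        group="surface",
        times=out_times,
        flux=np.array(flux_hist),
        cumulative=np.array(cum_hist),
    )
    return RodResult(
        grid=grid, times=out_times, ce=np.array(ce_hist), cm=np.array(cm_hist),
        release=release, mass_balance_error=max_err,
    )


# --------------------------------------------------------------------------
# 3-D voxel multi-domain
# --------------------------------------------------------------------------

@dataclass
class VoxelResult:
    grid: VoxelGrid
    times: np.ndarray
    ce: list[np.ndarray]    # full 3-D arrays at output times
    cm: list[np.ndarray]
    release: dict[str, ReleaseRecord]
    mass_balance_error: float
    initial_total_mol: float

    def interior_total(self, i: int) -> float:
        active = self.grid.labels > geometry.EXTERIOR
        v = self.grid.voxel_volume
        return float(np.sum((self.ce[i] + self.cm[i])[active]) * v)

    def total_exported(self, i: int) -> float:
        return float(sum(rec.cumulative[i] for rec in self.release.values()))

    def mn_trajectory(self, ce0: float, mn0: float = 1.0) -> MnTrajectory:
        mask = self.grid.labels == POLYMER
        rel = np.array([mn_from_state(c[mask], ce0)[0] for c in self.ce])
        return MnTrajectory(self.times, rel, mn0)


def solve_voxel(
    grid: VoxelGrid,
    params: KineticParameters,
    diffs: DomainDiffusivities,
    settings: SolverSettings,
    bc: BoundarySpec,
) -> VoxelResult:
    """IMEX finite-volume integration on a labelled voxel grid.

    The monomer field lives on every non-EXTERIOR cell with a spatially
    varying diffusivity (state-dependent in POLYMER, constant elsewhere);
    reaction acts only in POLYMER.  Concentration continuity across domain
    interfaces follows from the shared field with harmonic-mean face
    diffusivities.  Per-group flux and cumulative release are returned for
    every surface group carrying a sink condition.
    """
    labels = grid.labels
    if not np.any(labels == POLYMER):
        raise ValueError("grid contains no polymer cells")
    bc.validate_cover(grid)

    h = grid.spacing
    vol = grid.voxel_volume
    active = labels > geometry.EXTERIOR
    n_active = int(np.count_nonzero(active))
    index = -np.ones(labels.shape, dtype=np.int64)
    index[active] = np.arange(n_active)

    lab_a = labels[active]
    poly = lab_a == POLYMER
    d_const = np.zeros(n_active)
    d_const[lab_a == PORE_MEDIUM] = diffs.pore_medium
    d_const[lab_a == ENVIRONMENT] = diffs.environment

    # neighbour pairs (p, q) for each axis
    pairs = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        both = active[tuple(sl_a)] & active[tuple(sl_b)]
        p = index[tuple(sl_a)][both]
        q = index[tuple(sl_b)][both]
        pairs.append((p, q))
    P = np.concatenate([p for p, _ in pairs])
    Q = np.concatenate([q for _, q in pairs])

    # sink faces -> (active cell index) per group; no-flux faces need nothing
    sink_cells: dict[str, np.ndarray] = {}
    for name in sorted(bc.sink_groups):
        faces = grid.surface_groups.get(name)
        if faces is None or len(faces) == 0:
            sink_cells[name] = np.empty(0, dtype=np.int64)
            continue
        f = np.atleast_2d(faces).reshape(-1, 5)
        sink_cells[name] = index[f[:, 0], f[:, 1], f[:, 2]]

    ce = np.zeros(n_active)
    cm = np.full(n_active, settings.cm0_medium)
    ce[poly] = params.ce0
    cm[poly] = settings.cm0_polymer

    initial_total = float(np.sum(ce + cm) * vol)
    step_times = settings.step_times()
    out_times = settings.output_times
    out_set = {round(t, 9) for t in out_times}

    def expand(v: np.ndarray) -> np.ndarray:
        full = np.zeros(labels.shape)
        full[active] = v
        return full

    ce_hist, cm_hist = [expand(ce)], [expand(cm)]
    cum = {name: 0.0 for name in sink_cells}
    flux_hist = {name: [0.0] for name in sink_cells}
    cum_hist = {name: [0.0] for name in sink_cells}
    max_err = 0.0

    # fixed sparsity pattern (identity + symmetric neighbour couplings):
    # build the CSR skeleton once, then refresh only the values each step
    ident = np.arange(n_active)
    rows = np.concatenate([ident, P, Q])
    cols = np.concatenate([ident, Q, P])
    skel = coo_matrix(
        (np.arange(rows.size, dtype=float) + 1.0, (rows, cols)),
        shape=(n_active, n_active),
    ).tocsr()
    csr_perm = (skel.data - 1.0).astype(np.int64)
    M = skel

    for t_prev, t_next in zip(step_times[:-1], step_times[1:]):
        dt = t_next - t_prev
        ce_p, produced, clamped = _reaction_step(ce[poly], cm[poly], params, dt)
        _check_clamp(clamped, params.ce0)
        ce[poly] = ce_p
        cm[poly] += produced

        d_cell = d_const.copy()
        d_cell[poly] = monomer_diffusivity(ce[poly], cm[poly], params)

        w = dt / h**2 * _harmonic(d_cell[P], d_cell[Q])
        diag = np.ones(n_active)
        diag += np.bincount(P, weights=w, minlength=n_active)
        diag += np.bincount(Q, weights=w, minlength=n_active)
        sink_w = {}
        for name, cells in sink_cells.items():
            wv = dt / h**2 * 2.0 * d_cell[cells]
            diag += np.bincount(cells, weights=wv, minlength=n_active)
            sink_w[name] = wv
        vals = np.concatenate([diag, -w, -w])
        M.data = vals[csr_perm]

        # backward Euler solve: the matrix is SPD and diagonally dominant, so
        # Jacobi-preconditioned CG converges quickly; warm start from cm
        inv_diag = 1.0 / diag
        precond = LinearOperator(
            (n_active, n_active), matvec=lambda v: inv_diag * v
        )
        cm_new, info = cg(M, cm, x0=cm, rtol=1e-12, atol=0.0, M=precond)
        if info != 0:
            raise RuntimeError(f"diffusion solve failed to converge (info={info})")
        cm = cm_new
        np.clip(cm, 0.0, None, out=cm)

        for name, cells in sink_cells.items():
            # flux (mol/day) through each sink face: D*(cm-0)/(h/2)*h^2
            flux = float(np.sum(sink_w[name] * cm[cells])) * vol / dt
            cum[name] += flux * dt
            if round(t_next, 9) in out_set:
                flux_hist[name].append(flux)
                cum_hist[name].append(cum[name])

        if round(t_next, 9) in out_set:
            ce_hist.append(expand(ce))
            cm_hist.append(expand(cm))
            total = float(np.sum(ce + cm) * vol) + sum(cum.values())
            max_err = max(max_err, abs(total - initial_total) / initial_total)

    if max_err > settings.mass_tolerance:
        raise RuntimeError(f"voxel mass balance violated: {max_err:.3e}")

    release = {
        name: ReleaseRecord(
            group=name,
            times=out_times,
            flux=np.array(flux_hist[name]),
            cumulative=np.array(cum_hist[name]),
        )
        for name in sink_cells
    }
    return VoxelResult(
        grid=grid, times=out_times, ce=ce_hist, cm=cm_hist, release=release,
        mass_balance_error=max_err, initial_total_mol=initial_total,
    )
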