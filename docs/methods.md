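# Methods

## Model and assumptions

The degradation model is a two-field reaction–diffusion system for the molar
concentration of cleavable ester groups `Ce` (mol/m³, immobile) and of the
mobile hydrolysis products `Cm` (mol/m³):

    dCe/dt = -(k1·Ce + k2·Ce·Cm^β)
    dCm/dt = +(k1·Ce + k2·Ce·Cm^β) + ∇·(D ∇Cm)
    D(Ce, Cm) = D0·(1 + α·p),   p = 1 - (Ce + Cm)/Ce0

Assumptions inherited with the model: water is abundant everywhere (its
transport is not rate limiting and does not appear in the equations); chain
and oligomer size distributions are collapsed into the two fields (every
scission produces exactly one mobile monomer); the degree of crystallinity
is constant.  The literature uses "ester end groups" and "ester bonds"
interchangeably for `Ce`; the rate laws are agnostic, provided `Ce0` is the
same quantity used during calibration.

Internal units are metre / day / mol / kelvin.  Rate constants are sometimes
quoted per second elsewhere; all shipped sets are per-day and `units.py`
converts at the interface.

### Parameters

| name | meaning | unit | PLLA 50 °C default | why |
|------|---------|------|--------------------|-----|
| k1   | non-catalytic scission rate | 1/day | 2.0e-3 | calibrated against rod GPC data |
| k2   | autocatalytic scission rate | m³/mol/day | 1.2e-7 | calibrated |
| D0   | intrinsic monomer diffusivity in polymer | m²/day | 6.5e-12 | calibrated |
| β    | dissociation exponent of the acid products | – | 0.5 | standard choice for polyesters |
| α    | porosity–diffusivity slope | – | 4.5 | standard choice |
| Ce0  | initial ester concentration | mol/m³ | 17300 | literature value for these polyesters |
| D_medium | product diffusivity in hydrogel/tissue | m²/s | 1e-9 | literature range for small proteins in aqueous media |

A PLGA literature set (k1 = k2 = 2e-3, D0 = 1e-12 m²/day) is packaged for
cross-checks; PLGA's strong autocatalysis exercises the nonlinear term.

k2 = 0 (no autocatalysis) and D0 = 0 (frozen transport) are accepted as
analytic limits; the solvers reduce to closed forms there and the test suite
audits them.

### Arrhenius transfer

(k1, k2, D0) are temperature dependent.  Calibration at elevated temperature
(50 °C, accelerated ageing) is transferred to 37 °C via
`k(T) = A·exp(-Ea/(R·T))`, with `A` reconstructed from the calibrated value
at the reference temperature.  The activation energies shipped in
`data/parameter_sets.yaml` (k1, k2: 78 kJ/mol; D0: 130 kJ/mol) are
**placeholders** from typical polyester hydrolysis and matrix-diffusion
ranges — material-specific values are not public and must be supplied for
quantitative temperature transfer.  With the placeholder Ea for D0, the
transferred 37 °C matrix diffusivity is ~1e-17 m²/s, the order used in the
characteristic-time analysis.

## Geometries

*Rod* (calibration sample): 1.6 mm diameter × 6 mm cylinder, reduced to a
1-D axisymmetric radial node grid (uniform nodes on [0, R]; default 40–50
nodes); the surface is a perfect sink (products washed out by the buffer),
the axis a symmetry point.

*C-block scaffold*: the curved block is voxelised as a rectangular block of
the stated bounding dimensions (50 × 40 × 10/20 mm); curvature is secondary
to through-thickness transport at these scales.  A voxel takes the label of
the domain containing its centre.  The two mid-planes (width, height) are
exploited: canonical runs use the quarter geometry with zero-flux symmetry
planes, verified against full-grid solves.  An environment margin (default
2 mm, representing the surrounding periosteum/tissue) wraps the outward
faces; its outer boundary is a far-field sink.  The bone-contact plane is
z = 0.

*Macropores*: ellipsoids with semi-axes 1.5 / 2 / 1.5 mm on a centred
lattice of pitch (pore extent + 2 mm), connected by 2 mm-diameter
cylindrical channels along all axes (two pore layers in the 20 mm block).
Each lowest-layer pore carries a 2 mm delivery channel to the contact face;
apertures are grouped as central (innermost four of the full block, one per
quarter) vs outer.  Sealed apertures carry no-flux ("closed channels").
Lateral hydrogel-fill channels run from the outermost pore columns toward
the lateral faces and are sealed by one voxel of polymer — they are closed
during operation.  The exact pore count and placement are a package choice
(the lattice is parameterised); the pitch rule reproduces the stated
pore/channel dimensions.

## Discretisation

Finite volume everywhere, which makes the discrete mass balance exact by
construction: at every step, interior(Ce+Cm) + cumulative export = initial
total, to linear-solver round-off (~1e-13 relative in practice; the audits
require 1e-4).

Time stepping is IMEX.  Diffusion is backward Euler with the state-dependent
diffusivity lagged one step: the polymer/medium diffusivity contrast is ~8
orders of magnitude, so explicit diffusion is infeasible, while implicit
treatment is unconditionally stable.  The reaction is non-stiff at per-day
steps and integrated by an explicit midpoint (RK2) sub-step; monomer
production is set exactly equal to ester loss so the splitting cannot leak
mass.  Face diffusivities are harmonic means — the correct flux-continuity
average across the sharp polymer/medium interface, and what enforces
concentration continuity between domains on the shared field.  Sink
surfaces are ghost-face Dirichlet `Cm = 0` (perfect washout); symmetry
planes and sealed channels are zero normal flux.

The 3-D linear systems are solved with Jacobi-preconditioned conjugate
gradients (the matrix is SPD and diagonally dominant) with warm starts and a
precomputed sparsity pattern; direct sparse factorisation was an order of
magnitude slower on these grids.  Tiny negative concentrations from
round-off are clamped to zero before rate evaluation; the clamped mass is
tracked and must stay below 1e-10·Ce0 per step.

Default resolutions (a package choice balancing voxelisation error against
grid size): 1 mm voxels for bulk blocks, 0.75 mm for porous blocks (the
builder enforces voxel ≤ min(pore semi-axis)/2), dt = 1–3 days, 420-day
horizon.  Convergence audits: halving dt or the radial spacing changes the
final monomer field by < 1% in L2; refining voxels changes the polymer
volume by < 5%.

## Initial conditions and the release burst

The solvers default to `Ce = Ce0` in polymer and `Cm = 0` everywhere.  The
*scenario runner* additionally seeds a uniform initial monomer concentration
(default 1% of Ce0, `cm0_fraction`) across the whole model volume — polymer,
pore hydrogel and environment — representing the pre-grafted molecule
inventory, homogeneously distributed at t = 0.  This choice is load-bearing
for the release shape: the part of the inventory resident in the fast
aqueous compartments washes out through the delivery surfaces within days
(the initial burst), after which release is sustained by hydrolytic
production and limited by matrix transport.  An inventory confined to the
polymer cannot produce the burst at voxel resolution (and barely in the
continuum limit): polymer-side transport is the rate-limiting step, so the
flux would rise monotonically over the whole 420-day horizon.  The burst
magnitude scales linearly with `cm0_fraction`; 1% of Ce0 is a nominal
grafted load and the qualitative behaviour is insensitive to it.

Delivered release is counted through the grafted surfaces: for the bulk
scaffold (functionalised over its whole external surface) every external
sink counts; for the porous scaffold only the open delivery channels count
(the polymer contact face and closed channels are no-flux, guiding release
through the channels).

The bulk-vs-porous release-kinetics comparison is made on matched runs
*without* the inventory (pure production-driven release): with the
inventory, the comparison mostly measures where the inventory was placed
relative to the sinks rather than the scaffold architecture.  On
production-driven runs the macroporous design reaches a matched released
fraction of its ester inventory ~25% earlier than the bulk design, because
its internal surfaces shorten the transport path out of the polymer.

## Molecular weight mapping

GPC measures the number-average molecular weight; the model's observable is
`Mn(t)/Mn(0) = ⟨Ce⟩/Ce0` (volume-averaged over the polymer).  Rationale:
with end scission, each event removes one monomer from a chain end while the
number of chains is unchanged, consistent with rate laws in which every
scission yields exactly one monomer.  The mapping is a package choice (the
observable-to-field map is not uniquely determined by the model) and is
isolated in `observables.mn_from_state` so alternatives (e.g. random
scission) can be substituted.

## Calibration

`RodDegradationModel` binds a replicate Mn(t) dataset to the 1-D rod forward
model; `fit()` minimises the mean squared *relative* Mn error over
timepoints (replicate-averaged) — scale-free, so Mn unit conversions do not
affect the fit.  Optimisation is a bounded trust-region least-squares in
log-parameter space (deterministic given data and start); a coordinate-wise
"one parameter at a time" refinement is provided as an alternative strategy.

Identifiability at the PLLA parameters: the autocatalytic term contributes
< 1% to the Mn decay over two nominal half-lives, and monomer escape from a
0.8 mm rod perturbs it only in a ~0.07 mm surface shell.  Noiseless
synthetic data therefore pin all three constants only through very small
residual structure — the fit recovers them to machine precision because the
same deterministic discretisation generates and fits the data — but under
replicate noise k1/k2 are collinear and only k1 is practically identifiable.
The noisy-recovery analysis therefore profiles k1 with (k2, D0) fixed at
their starting values; fitting all three under noise inflates the k1 error
to the 10% level by noise-splitting.  Richer designs (more timepoints,
thinner samples, longer horizons) improve k2/D0 identifiability.

The two-timepoint {0, 56 d} sampling mirrors the accelerated-ageing
campaign; parameter-recovery studies use ≥ 6 timepoints over two half-lives
(0–692 d).

## Synthetic data

`generate_degradation_dataset` runs the rod forward model and applies
multiplicative lognormal measurement noise with unit mean and a stated CV
(GPC errors scale with magnitude; default CV 5%, the replicate scatter
plausible for triplicate GPC).  Seeds are mandatory; identical seeds give
bit-identical datasets, and `cv = 0` reproduces the forward trajectory
exactly.  `Mn0` defaults to 1e5 g/mol (typical PLLA); only relative Mn
matters.  What the generator does *not* emulate: chromatogram baselines,
dispersity drift, replicate-correlated batch effects, or any deviation of
real degradation from the model itself — passing recovery tests shows the
estimator is consistent under the model's own assumptions, not that the
model is correct for a given material.

## Characteristic times

Release is governed by three processes with characteristic times
`thickness²/D` (matrix diffusion), `1/k1` (non-catalytic scission) and
`1/(k2·Ce0^β)` (autocatalytic scission), reported in seconds.  The
autocatalytic expression is the dimensionally consistent form (the product
`k2·Ce0^β` is a first-order rate); with the calibrated set it evaluates to
5.5e9 s.  For the 20 mm scaffold at the 37 °C matrix diffusivity the
diffusion time (4e13 s) exceeds both reaction times by 3–6 orders of
magnitude: release is transport limited, which is why architecture (pores
and channels) rather than chemistry controls the release profile.

## Known limitations

- No enzymatic or cell-mediated (osteoclast) degradation; no pH feedback
  beyond the autocatalytic term; no mechanical-property coupling.
- Crystallinity constant; no oligomer size distribution.
- The block curvature and FDM infill microstructure are not modelled.
- The grafted-molecule release is proxied by the monomer field; grafting
  chemistry and protein-specific diffusivity are not modelled beyond the
  medium diffusivity constant.
- Activation energies are placeholders (see above); temperature transfer is
  structural, not material-calibrated.
- The far-field boundary condition (sink at the 2 mm environment margin) is
  a modelling choice; dense tissue would slow the burst washout.
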