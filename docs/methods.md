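# Methods

## Model overview

`trabsim` simulates homeostatic trabecular bone remodeling as a coupled
system of three layers on an isotropic voxel lattice (default 10.5 µm
edge):

1. **tissue** — per-voxel continuous mineral `m` and osteoid `o`
   concentrations in [0, 1] plus a categorical region label (trabecular
   bone, trabecular marrow, cortical shell, intervertebral-disc pad,
   outside). A trabecular voxel belongs to the binary *bone phase* when
   its grayscale density (mineral) is ≥ 0.5, i.e. ≥ 580 mg HA/cm³ on the
   0–1,160 mg HA/cm³ calibration; the continuous concentrations persist
   underneath the binary state. The cortical shell is mechanically present
   but never remodeled.
2. **fields** — a mechanical signal and four cytokine fields (plus the
   solution-phase RANKL–OPG complex) defined on the lattice.
3. **cells** — individual agents of eight kinds with per-cell receptor
   pools.

### Mechanics

One trilinear hexahedral element per voxel; all voxels are meshed (soft
marrow, E = 2 MPa, rather than empty pores; bone 14.8 GPa; disc pads
configurable, default equal to bone; ν = 0.3 throughout). Boundary
conditions emulate axial compression: the proximal face is fixed and the
distal face displaced by 1 % of the model length ("clamped" mode, the
simulation default). A "frictionless" mode (proximal face fixed in z only,
rigid modes pinned at two corner nodes) realizes the laterally free
uniaxial stress state exactly and is used by the validation protocol,
because a fully clamped face constrains lateral contraction and biases the
apparent Poisson ratio on short blocks (0.272 instead of 0.300 on a cube).

The assembled system is solved directly (sparse LU) below ~12,000 free
degrees of freedom and otherwise by Jacobi-preconditioned conjugate
gradients warm-started from the uniform-strain field or the previous
converged solution (relative tolerance 10⁻⁶ in the simulation loop, 10⁻⁸
standalone). Between mechanics refreshes the stiffness matrix is updated
incrementally from the voxels whose material changed. Strains are
evaluated at element centroids (one SED value per voxel, matching the
per-voxel signal the cell model consumes); SED = ½ε:D:ε, and the effective
strain is the standard SED-based scalar EFF = √(2·SED/E) with the voxel's
own modulus. The linear solution is rescaled so the summed axial reaction
on the constrained face equals the physiological 4 N.

The cell-level signal ε is the **Gaussian-dilated** EFF: a grayscale
dilation with Gaussian weights, ε(x) = max_y EFF(y)·exp(−|x−y|²/2σ²) with
σ = 2.5 voxels truncated at 7.5 voxels. Dilation (not smoothing) is the
default because marrow cells near bone must sense bone-borne strain
without attenuation of peak values; a plain truncated-Gaussian smoothing
mode is available as a sensitivity switch. Mechanostat thresholds are
sample-specific: `mechthres_bone = 0.95 · median(ε | trabecular bone)`,
`mechthres_marrow = 0.45 · median(ε | trabecular marrow)`, recomputed at
every mechanics refresh.

### Mechanomics

Every regulated output is a Hill curve of the local dilated strain with
half-max at the compartment's mechanostat threshold: increasing for
anabolic/anti-catabolic outputs (osteoid deposition, OPG), decreasing for
catabolic/anti-anabolic ones (RANKL, sclerostin, resorption). The exact
Hill form (y_max, Hill coefficient h, θ = mechthres) is adopted as the
canonical sigmoid with a named half-max point. Embedded cells (osteocytes)
use the bone threshold; surface and marrow cells the marrow threshold.

### Signaling

OPG, RANKL, Scl and free TGF-β1 diffuse and decay on the domain
*trabecular marrow + bone-surface voxels*; mineralized bone is excluded
(a config switch can include it with its own D). Osteocyte production is
routed to the nearest domain voxel — an implicit stand-in for
canalicular transport — and the cluster analysis samples osteocyte protein
levels the same way. TGF-β1 is also stored in the bone matrix
(proportional to mineral) and released into the free field in proportion
to the matrix fraction resorbed, so resorbing a voxel completely releases
exactly its store.

Time stepping is Strang splitting over the 40-min cell step divided into
ten 4-min substeps: reaction half-step, diffusion full step, reaction
half-step. Diffusion uses an implicit θ-scheme on the 7-point stencil with
no-flux boundaries, factorized once per domain change;
**Crank–Nicolson (θ = ½) is the default** because a first-order inner
propagator (backward Euler) would degrade the split scheme to first order
— the suite verifies observed order ≥ 1.8 on a manufactured nonlinear
problem. Decay of free ligand is applied exactly as exp(−k·dt) (bound
complexes do not decay). Binding ODEs — competitive
RANKL + RANK ⇌ C₁ / RANKL + OPG ⇌ C₂ (tracked per voxel, conserving total
RANKL) and simple Scl–LRP5/6 and TGF-β1 receptor kinetics — are integrated
with RK4 sub-stepped so the fastest rate satisfies rate·Δt < 0.25; the
RANKL–OPG complex is modeled as reversible with its own dissociation rate
and diffuses like OPG.

### Cells

Movement: motile kinds step to a free valid 26-neighbor with a per-kind
probability per step; osteoblasts are biased toward higher and osteoclasts
toward lower ε through a softmax over standardized neighbor signals scaled
by the polarization coefficient. Proliferation/apoptosis are Bernoulli
events with exponential-rate probabilities; TGF-β receptor occupancy above
threshold multiplies the proliferation rate. Differentiation applies, in a
fixed order: preOt→Ot (voxel ≥ 50 % mineral); Ob→preOt (voxel ≥ 50 %
osteoid and an osteocyte in the nearest bone voxel along the descending
distance-to-bone direction, ties preferring face neighbors); Ob→lining
(LRP5/6 occupancy ≥ threshold); HSC→preOc (RANK ≥ threshold); preOc→HSC
(RANK below); preOc→Oc (≥ 3 osteoclastic cells among the 26 neighbors);
MSC→Ob or lining (within 1 voxel of the surface and within 2 voxels of an
osteoclast; fate by LRP5/6 occupancy).

Deposition and resorption follow the mineral-concentration gradient with a
*finish-first* target order: a voxel already under remodeling (0 < value <
1) is completed before a new one is opened. This pit-digging/lamellar-fill
rule is essential at desk scale — a pure max-gradient choice rotates over
equivalent neighbors and smears the budget so thinly that no voxel ever
crosses the phase threshold. Osteoclasts resorb only when clustered (≥ 3
osteoclastic cells including themselves) and RANK-bound above threshold;
they remove equal amounts of mineral and osteoid. Mineralization moves m
toward o by `r·sinh(|o−m|/2)·sgn(o−m)` per step, clamped so m never
crosses o; the update keeps both concentrations in [0, 1]. The sinh
argument `|o−m|/2` is used because the separate sign factor implies an
even inner expression; the `(o−m)²` variant is selectable
(`RuleParams.sinh_form="squared"`).

### Orchestration

Update order within a 40-min step: mechanics refresh (every 12 steps =
8 h, a mechanical-memory interval) → cytokine production → Strang RDD with
binding → differentiation → movement → proliferation/apoptosis →
deposition/resorption (with TGF-β1 release) → mineralization → bone-phase
update. Runs have three phases: 48 frozen-microarchitecture iterations
(spatial equilibration of cells and cytokines), 5 days of active
pre-remodeling (the archived *initial state*), then the experiment
(default 28 days). The sensitivity harness perturbs one osteocyte
production maximum at a time (high/low = basal ± δ) and restarts every arm
from a deep copy of the shared initial state, so arms are paired with
identical random streams. One master seed spawns independent per-purpose
streams (movement, population events); checkpointing drops derived caches
(factorizations) and rebuilds them on resume, which the suite verifies to
be bit-exact.

## Parameter defaults and calibration

Values printed in the source text and adopted verbatim: the density
calibration and 0.5/580 threshold; E = 14.8 GPa / 2 MPa, ν = 0.3, 1 %
displacement, 4 N target force; dilation σ = 2.5 / support 7.5; the
0.95/0.45 median threshold factors; dt_cells-RDD = 40 min with 10
substeps; dt_micro-FE = 8 h; 48 initialization iterations and 5
pre-remodeling days; MSC/HSC seeding at 1.25×10⁷ cells/mL; the ≥ 3-cell
osteoclast cluster rule; the 50 % osteoid/mineral differentiation
thresholds.

The remaining ~40 biological constants (Hill y_max and coefficients,
receptor site counts and kinetic rates, diffusion/decay coefficients,
motility and population rates, thresholds, mineralization rate, seeding
fractions) are not published with the text; the defaults in
`SimulationConfig`, `RuleParams` and `SeedingSpec` were calibrated once,
on 24³ phantoms, for a *balanced active remodeling regime*: basal
occupancies of RANK and LRP5/6 sit in the responsive range of their
thresholds (0.6 / 0.7), osteoclast clusters form and resorb, osteoblasts
deposit, and the basal bone volume fraction drifts slowly (≈ −0.2 %/day at
24³). Kinetic scales (k_f = 1 /conc/min, k_r = 0.01 /min, K_d = 0.01 in
the concentration unit set by the production scale; OPG–RANKL complex
k_r = 0.005) put receptor equilibration at tens of minutes, comparable to
the cell step. With these defaults the one-at-a-time ±0.06 perturbations
of the osteocyte production maxima (basal 0.10) reproduce the expected
directions — OPG positively and RANKL negatively correlated with BV/TV,
sclerostin arms an order of magnitude weaker over short windows because
formation responds through the mineralization lag (~3 days at
r_mineral = 0.01/step) while resorption acts immediately.

## Morphometry definitions

BV/TV by voxel counting over the trabecular region. Bone surface by
marching-cubes triangulation of the lightly smoothed (σ = 1 voxel) binary
field — smoothing suppresses the stair-step area overestimate of raw voxel
surfaces; the digital-ball check holds BS/BV to 3/r within 5 %. Tb.Th and
Tb.Sp by direct sphere-fitting local thickness computed on a 2× upsampled
grid (the half-voxel parity bias of the center-to-center distance
transform cancels there; slabs of odd and even thickness are recovered
exactly, and a 1-voxel formation layer reads 10.5 µm). Tb.N by the
inverse-sum model 1/(Tb.Th + Tb.Sp). Dynamic parameters from the FQR
overlay of two frames: MS (ES) is the fraction of the t₀ bone surface
face-adjacent to Formed (Resorbed) voxels; MAR (MRR) the mean local
thickness of the Formed (Resorbed) clusters divided by the interval
(default 14 days); BFR (BRR) the Formed (Resorbed) volume per t₀ bone
volume per day, in %/day. MS/ES are referred to the t₀ surface; these
referents are stated normatively since image-processing packages differ.

## Cluster analysis

Osteocyte records carry the RANKL/OPG/Scl levels at the osteocyte position
(sampled at the nearest diffusing-domain voxel) at the analysis start,
the strain regime of the position (strict >75th / <25th percentile of ε
over the analysis-region voxels; ties at the percentile stay "medium"),
and the nearest remodeling event in the FQR overlay of the last versus
first frame (exact integer-squared-distance ties → "Multiple"; no events →
"Quiescence"). K-means runs for k = 1…10 at a fixed seed; the knee of the
inertia curve is the maximum-distance point of the normalized flipped
curve (kneedle criterion, implemented in ~15 lines since no knee-detection
package is a dependency). Features are not standardized by default (a
z-scoring flag exists). Percentiles are computed over region voxels, not
osteocyte positions, where the two readings diverge.

## What the synthetic phantoms do and do not emulate

The generator reproduces the *structural setting* of a vertebral body —
a connected trabecular network of tunable volume fraction inside a
cortical shell, with soft pads transmitting the axial load — and the
seeding recipe (random marrow stem cells at a target density, depth-biased
osteocytes, partially bound surface cells). It does not reproduce real
trabecular anisotropy, plate/rod ratios, cortical porosity or any
animal-specific anatomy; absolute strain levels on small phantoms are
higher than in a real vertebra because 4 N crosses a much smaller section.
Passing tests therefore demonstrate internal correctness and directional
behavior of the coupled model, not quantitative agreement with any in vivo
measurement.

## Problem sizes used by the automated checks

The suite exercises the full pipeline at deliberately small scale chosen
as this package's reference desk conditions: mechanics validation on a
64³ homogeneous block; the remodeling study on a 24³ phantom with 24
frozen iterations, 1 pre-remodeling day, 2-day sensitivity arms (±0.06)
and a 4-day basal run for the cluster pipeline (the 4-day horizon lets
formation events appear through the mineralization lag). Longer horizons
and larger phantoms are configuration changes, not code changes.

## Known limitations

- Linear elasticity only; no geometric/material nonlinearity, no
  lacunocanalicular fluid flow (the dilated-strain signal is its proxy).
- No receptor trafficking or internalization; no osteoclast pit/trench
  mode distinction; cortical bone is static.
- The diffusing domain excludes mineralized bone; osteocyte exchange is
  collapsed onto the nearest surface/marrow voxel.
- Concentrations are in model units fixed by the production scale; only
  ratios and directions are meaningful, not absolute serum-level
  comparisons.
- The mobile-cell update iterates agents in list order within a step;
  order effects are mitigated by the small per-step rates but not absent.
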