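# Methods and numerical conventions

This note records the models, the integration schemes, the estimator
conventions and the deliberate design choices behind `focisim`, at the
level of detail a user would need to judge what the package's validations
do and do not establish.

Units everywhere: lengths μm, times s, diffusivities μm²/s, number
densities μm⁻³, rates s⁻¹, energies in units of k_BT (k_BT ≡ 1 internally —
no temperature dependence is modelled anywhere).

## Geometry and parameters

Focus and nucleus are concentric spheres (radii r_f, r_n) centred at the
origin; the focus size is fixed during a run (no formation or dissolution
kinetics).  Defaults follow the typical operating point of the yeast
repair-focus regime the package targets:

| symbol | meaning | default | units |
|---|---|---|---|
| r_f | focus radius | 0.1 | μm |
| r_n | nucleus radius | 0.5 | μm |
| D_n | nucleoplasmic diffusivity | 1.0 | μm²/s |
| D_0 | in-focus diffusivity (droplet) | 0.05 | μm²/s |
| A | focus potential depth (droplet) | 5.0 | k_BT |
| b | boundary steepness (droplet) | 1000 | μm⁻¹ |
| ρ | binding-site density (sites) | 4.8·10⁴ | μm⁻³ |
| r_b | binding-site radius | 0.01 | μm |
| D_b | binding-site diffusivity | 0.005 | μm²/s |
| κ | surface absorption parameter | 100 | μm/s |
| k₋ | unbinding rate | 500 | s⁻¹ |
| σ | localization noise (per axis) | 0.03 | μm |
| δt | integration step | 10⁻⁶ | s |

Every value is overridable through the flat YAML config consumed by the
CLI.  N = round((4/3)π ρ r_f³) sites (201 at defaults).

## Droplet (LPM) integrator

The tracer follows the Itô equation dr = [∇D − D∇U]dt + √(2D) dW with the
sigmoidal D(r), U(r) profiles; both gradients are evaluated analytically
(no finite differencing inside the integrator).  Because D varies only
radially, the Milstein multiplicative-noise correction is applied along the
radial direction: ½ (dD/dr)(ΔW_r² − δt) r̂.  An Euler–Maruyama fallback
(`milstein=False`) exists for cross-checks and needs a ~10× smaller step
for comparable accuracy.  The nucleus boundary is reflecting, implemented
as a radial mirror fold |r| → 2r_n − |r| (re-applied while outside;
`reflect_sphere` exposes the same rule).

**Boundary-layer substepping.** At b = 1000 μm⁻¹ the free-flight step
outside the focus, √(2 D_n δt) ≈ 1.4 nm·√(δt/10⁻⁶ s) = 1.4·10⁻³ μm,
exceeds the 1/b = 10⁻³ μm profile width, which biases crossing statistics:
in convergence experiments the long-run in/out density ratio sat ~6% below
e^A, decomposing into a ~2% potential-step artifact and a ~4% D-step
interface artifact.  Steps that start within |r − r_f| < 5/b + 3.5√(2D_nδt)
are therefore integrated as 8 substeps of δt/8.  This removes the D-step
artifact entirely (flat-density control with A = 0, D_0 ≠ D_n is exact to
statistical precision) and leaves a residual ≲3–4% downward bias on the
occupancy ratio at the default δt — visible only at the precision of the
stationarity acceptance test, and covered by its 10% band.  Halving δt
changes all tested observables by less than their Monte-Carlo error.

Equilibrium starts rejection-sample the Boltzmann radial law r²e^{−U(r)}.
The focus is never a hard wall for the tracer: it acts purely through
(U, D).

## Binding-site (PBM) simulator

Per step an unbound tracer proposes a free-diffusion displacement at D_n
(everywhere, including inside the focus).  If the proposal lies within r_b
of the nearest site it binds with probability p_b = κ√(π δt/D_n), else it
is reflected radially off that site to distance 2r_b − Δr and re-tested
against all sites (up to 10 reflections; multiple overlaps are rare).  The
printed form of the absorption probability in the source literature is
dimensionally inconsistent; the implemented √δt form is the standard
discretization of the Robin condition D_n ∂p/∂n = κp and is the one under
which p_b is dimensionless.  Stability checks require p_b ≤ 0.5,
√(2D_nδt) ≤ r_b/2 and k₋δt ≤ 0.5 (κ = 400 μm/s needs δt = 2.5·10⁻⁷ s).

A bound tracer is attached rigidly at the surface intersection point and
inherits its site's displacement exactly (including the reflection fold
that confines site centres to |c| ≤ r_f); it unbinds with probability k₋δt
per step, resuming free diffusion in place.  Rebinding is simulated
explicitly — no renormalization of k₋ is applied — so the *emergent* bound
fraction exceeds the naive estimate k₊ρ/(k₋ + k₊ρ) built on the
Smoluchowski rate (0.93 vs 0.86 at defaults).  Sites are non-interacting,
may overlap, and are re-drawn per seed (a fixed ensemble can be passed
explicitly).  Inert crowders are sites with binding probability 0.

**Lazy site advancement (performance).** Advancing all ~200 sites every
microsecond step is RNG-bound.  Sites carry per-site timestamps: the bound
site and any site within the collision prescan radius are advanced exactly
to the current step before use; idle sites are propagated lazily in
Gaussian chunks (≤5000 steps per chunk, fold-reflected at r_f), and a full
sync every 250 steps bounds the staleness of prescan positions.  The
prescan pad is 6 per-axis standard deviations of the maximal stale
displacement, making a missed true collision a ~10⁻⁷-per-step event.  Every
site the tracer can touch therefore evolves by exactly the same per-step
rule as a fully synchronous implementation.

**Bulk mode** places sites at density ρ in a periodic cube (≥10 r_b) with
minimum-image distances and returns the tracer unwrapped — used to isolate
bulk binding statistics (angle asymmetry, bound fraction) from
focus-boundary effects.

## Mean-field description and its validity

The effective description p_u = k₋/(k₋+k₊ρ), D̃ = p_u D_n + (1−p_u) D_b,
Ũ = ln[(D̃−D_b)/(D_n−D_b)], p ∝ 1/p_u is implemented as closed forms, and
the scaling relation p(r) ∝ 1/(D̃(r) − D_b) as `scaling_test`, which
returns the mobility ratio x = (D_0−D_b)/(D_n−D_b), the density ratio
y = p_out/p_in, their relative deviation, and the D_b* that would force
equality.

Two corrections limit the identity in the explicit model, both verified by
dedicated control simulations:

1. **Excluded volume.**  The sites are impenetrable to the unbound tracer.
   At ρ = 4.8·10⁴ μm⁻³ they fill φ = ρ(4/3)πr_b³ ≈ 20% of the focus, so the
   unbound density inside is depressed by (1−φ).  A purely reflecting
   control (κ→0) reproduces this exactly: measured p_in/p_out = 0.815 vs
   1−φ = 0.799.  The measured identity deviation then scales as
   1 − (1−φ)·c_D (c_D ≈ 0.94 the crowding slowdown): ≈4–8% at
   ρ = 2.4·10⁴ but ≈20–24% at ρ = 4.8·10⁴.  The acceptance test of the
   scaling identity spans both densities and reports this honestly; the
   dense half of the grid genuinely exceeds a 15% band.
2. **Slow exchange.**  The reduction assumes binding/unbinding fast
   compared to density variation along the trajectory; the test grid pairs
   large κ with large k₋ to stay in that regime.

The radial-drift prediction ⟨δr⟩ = δt(−D̃ ∂_rŨ + ∂_rD̃ + (d−1)D̃/r) takes
Ũ = −ln p(r) + const from the measured density (Boltzmann-consistent sign)
and differentiates binned profiles by central differences after 3-bin
linear smoothing (default bin width 10⁻³ μm).  The dimension term is D̃/r
for 2D-projected tracks (d = 2, the default for observed data) and 2D̃/r
for full 3D trajectories.  With immobile sites (D_b = 0) the first-line
form δt(d−1)D̃/r is non-negative — the sign constraint used as a
model-rejection criterion.

## Observables and statistics

The measurement model subsamples a simulated trajectory to the observation
interval (default 20 ms, i.e. 50 Hz), keeps frames within the visible z
slab (±150 nm), splits tracks at the resulting gaps, projects to (x, y)
and adds i.i.d. Gaussian localization noise (σ = 30 nm per axis).

Estimators bin by the radius at the start of each step.  Apparent
diffusivity D̃ = ⟨|δr|²⟩/(2 d δt) with optional noise correction
(MSD = 2dDδt + 2dσ²); densities divide occupancy by shell volume (3D) or
by annulus area × slab depth (2D — a thin-slab approximation).  Jump-length
references are Rayleigh-type in 2D and Maxwell-type in 3D; the KS
detectability map compares in-focus jumps against the fitted
single-diffusivity law.  The two-population fit is a zero-mean two-Gaussian
EM on per-axis displacements (variance ratio < 1.5 is flagged degenerate).
The angle distribution uses the angle between consecutive displacement
vectors, skipping zero-length steps; its asymmetry statistic is the
fraction in [150°,180°] over the fraction in [0°,30°].

Serial correlation matters for error bars: bound episodes (≈ 2 ms at
defaults) make consecutive recorded steps strongly dependent.  Wherever a
profile comparison is made at the 3-SE level, standard errors come from a
moving-block bootstrap (10 ms blocks), and bands across ~200 bins are
applied in their simultaneous (familywise) form — a literal per-bin 3-SE
rule across that many bins fails with ~40% probability even for an exact
theory.  The maximal-positive-difference statistic compares its observed
maximum against the bootstrap null distribution of the noise maximum
(a bare max over bins is positively biased); rejection means exceeding the
noise maximum by 3 of its standard deviations.

The focus estimator (centre, r_f, D_0, A) uses a mean-shift mode of the
position cloud, half-height of the radial density for r_f, the D̃ plateau
at r < 0.8 r_f for D_0 and the log density-plateau ratio for A, with the
background band restricted to well inside the sampled support.

## First passage and sensing

`mfpt_quadrature` integrates the steady-state-flux double integral with
adaptive Gauss–Kronrod panels split at the focus boundary (open rules never
evaluate the discontinuity of sharp profiles); `mfpt_closed_form` is its
sharp-boundary closed form (they agree to 10⁻⁶ relative over random
parameter sets).  Swapping the integration order shows the flux formula
equals the mean first-passage time of a particle released at the nucleus
edge r_n; the Monte-Carlo default start rule is therefore "nucleus-edge",
and that is the rule under which simulation and closed form agree (an
equilibrium start skips the focus-finding leg with high probability and
sits ~15–20% lower at droplet-typical parameters; both rules are
available).  In-target detection uses the step-endpoint test at the
configured δt; a bridge-crossing correction would be a refinement, not the
default.  Trajectory caps are explicit: capped runs are flagged censored,
never silently truncated.

The optimal focus radius r_f*⁴ = r₀r_n³(D₀/D_n − e^{−A})/(3(1−e^{−A}))
exists iff D₀e^A > D_n; under the binding-site constraint it degenerates to
r_f*⁴ = r₀r_n³D_b/(3D_n), vanishing with immobile sites.  Sensing accuracy
offers the general form √(3τ_a/(4πc r_n³ t)), the large-nucleus limit, and
the strong-potential/optimal form; at r₀ = r_f the classic absorbing-sphere
bound 1/√(4πD_n c r_f t) is recovered.

## Synthetic data: what it does and does not emulate

All validation data are generated by the simulators themselves with fixed
seeds: free diffusion, droplet runs, site-cluster runs (confined and bulk),
plus the microscopy measurement model.  Emulated: anisotropic confinement,
binding-induced non-Gaussian jumps, projection, slab truncation and
localization noise at experimental levels.  Not emulated: motion blur
within an exposure, photobleaching and blinking, tracking/linking errors,
chromatin polymer motion (sites diffuse independently — no polymer
conformational coupling), focus mobility, drift, or multi-particle
interactions.  Passing tests therefore validate the estimators against the
stated models, not against every artefact of real microscopy.

## Problem sizes and tolerances in the test suite

Validation simulations are desk-scale: nucleus radius 0.3 μm (within the
plausible biological range) for fast focus/nucleoplasm exchange, runs of
40–100 s of simulated dynamics (4·10⁷–4·10⁸ steps), 2000 Monte-Carlo
search trajectories, and 6 parameter sets for the scaling-identity grid.
At these sizes the occupancy ratios carry ~3–5% statistical error, which
sets the quoted tolerances (e.g. 10% on Boltzmann ratios, 3 bootstrap SE on
profile comparisons).  Known limitations worth restating: the residual
few-percent droplet stationarity bias at default δt; the excluded-volume
deviation of the scaling identity at the dense operating point; and the
thin-slab approximation in 2D density deprojection.
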