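# focisim

Stochastic single-particle models and tracking observables for membrane-less
nuclear foci.

Nuclear foci (repair foci, transcription condensates, telomere clusters) are
spherical sub-compartments a few hundred nanometres across in which specific
proteins are strongly enriched.  Two microscopic pictures compete to explain
them.  In the **liquid phase model (LPM)** the focus is a droplet formed by
liquid–liquid phase separation: a tracer protein experiences a potential
well of depth *A* (in units of k<sub>B</sub>T) and a reduced diffusivity
*D*<sub>0</sub> inside the focus.  In the **polymer bridging model (PBM)**
the focus is a dense cluster of *N* chromatin-associated binding sites,
modelled as partially absorbing spheres of radius *r*<sub>b</sub> diffusing
at *D*<sub>b</sub>, which transiently trap the tracer.  The two pictures
produce similar-looking trajectories, but they differ in testable ways, and
this package implements both models and the statistics that tell them apart
from single-particle-tracking (SPT) data.  It is aimed at biophysicists
analysing SPT experiments on foci and at modellers exploring the parameter
regimes of either picture.

## The models

An unbound tracer follows the overdamped Itô Langevin equation

```
dr = [∇D(r) − D(r) ∇U(r)/kBT] dt + √(2 D(r)) dW ,
```

with stationary density p(r) ∝ exp(−U(r)/k<sub>B</sub>T).  The LPM uses
sigmoidal profiles centred on the focus radius r_f,

```
D(r) = D0 + (Dn − D0) / (1 + e^(−b(r − r_f))),    U(r) = A / (1 + e^(−b(r − r_f))),
```

so U is low inside (density enhancement e^A).  The PBM simulates explicit
binding: a tracer crossing a site surface binds with the Robin-condition
probability p_b = κ√(πδt/D_n), rides the site until release at rate k₋, and
is otherwise reflected.  The on-rate constant is the partially absorbing
Smoluchowski rate

```
k+ = 4π Dn r_b / (1 + Dn/(r_b κ)) .
```

In the fast-exchange limit the PBM reduces to an effective LPM with

```
pu(r) = k₋/(k₋ + k+ρ(r)),   D̃(r) = pu Dn + (1−pu) Db,   Ũ(r) = kBT ln[(D̃−Db)/(Dn−Db)],
```

which pins the stationary density to the mobility: p(r) ∝ 1/(D̃(r) − D_b).
Concentration and diffusivity cannot vary independently in the PBM — the
package's central discrimination tool (`focisim.meanfield.scaling_test`),
alongside the radial-drift prediction ⟨δr⟩ ≃ δt(−D̃ ∂_r Ũ + ∂_r D̃ +
(d−1) D̃/r) and its "maximal positive difference" rejection statistic.

For a perfectly absorbing target of radius r₀ at the focus centre, the mean
search time is

```
τ_a = ∫_{r0}^{rn} dr r² e^{−U(r)} ∫_{r0}^{r} dr′ e^{U(r′)} / (D(r′) r′²) ,
```

with a sharp-boundary closed form, an optimal focus size
r_f*⁴ = r₀ r_n³ (D₀/D_n − e^{−A}) / (3(1 − e^{−A})) that exists iff
D₀e^A > D_n, and the generalized Berg–Purcell sensing bound
δc/c ∼ √(3τ_a/(4π c r_n³ t)).

## Worked example

```python
import numpy as np
from focisim import Geometry, smoluchowski_k_plus
from focisim.meanfield import p_unbound, effective_diffusivity, scaling_test
from focisim.first_passage import SearchSpec, mfpt_closed_form, optimal_focus_radius

k_plus = smoluchowski_k_plus(Dn=1.0, r_b=0.01, kappa=100.0)
pu = p_unbound(4.8e4, k_plus, 500.0)
print(k_plus, k_plus * 4.8e4, pu, effective_diffusivity(pu, Dn=1.0, Db=0.005))

rep = scaling_test(pin=np.exp(5.5), pout=1.0, D0_meas=0.032, Dn_meas=1.08, Db=0.005)
print(rep.x, rep.y, rep.relative_deviation, rep.consistent_with_pbm())

spec = SearchSpec(r0=0.02, geometry=Geometry(r_f=0.1, r_n=0.5), D0=0.05, Dn=1.0, A=5.0)
print(mfpt_closed_form(spec), optimal_focus_radius(0.02, 0.5, 0.05, 1.0, 5.0))
```

prints (rounded)

```
k+          = 0.0628 um^3/s
k+ rho      = 3016 /s
p_unbound   = 0.1422
D_eff       = 0.1465 um^2/s
mobility ratio x = 0.0251, density ratio y = 0.00409
relative deviation = 5.1 -> consistent with PBM: False
tau_a (closed form) = 0.7508 s
optimal r_f*        = 78 nm
```

Reading: at typical parameters a tracer in the site cluster binds at
k₊ρ ≈ 3000 s⁻¹, is unbound 14% of the time, and shows an effective in-focus
diffusivity of 0.15 μm²/s.  A droplet-like measurement (density enhancement
e^5.5 with D₀ = 0.032 μm²/s) violates the PBM's concentration–mobility
constraint by a factor ~5 — the binding-site picture is rejected for such
data.  The same droplet parameters give a 0.75 s search time to a 20 nm
target and an optimal focus radius of ~80 nm.

Simulation entry points: `focisim.lpm.simulate_lpm`,
`focisim.pbm.simulate_pbm` (and `simulate_pbm_bulk` for an infinite focus),
`focisim.observables.apply_measurement_model` for 50 Hz / 30 nm-noise /
±150 nm-slab microscopy emulation, and `focisim.first_passage.
simulate_first_passage` for Monte-Carlo search times.  A `focisim` CLI
(`simulate-lpm`, `simulate-pbm`, `observe`, `analyze`, `discriminate`,
`fpt`, `fixtures`) wraps the same functions for shell use; every run writes
a JSON manifest with parameters, seed and output digests.

## Limits worth knowing

The mean-field identities are derived for dilute, fast-exchanging binding
sites.  At the typical site density (ρ = 4.8·10⁴ μm⁻³, a 20% volume
fraction) the sites' excluded volume measurably depresses the in-focus
tracer density below the dilute prediction; see `docs/methods.md` for the
quantitative discussion and for all numerical conventions.
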