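# tetherswarm

Collective motion of self-propelled agents in an environment they can
deform: the agents (Vicsek-type alignment, constant speed, short-range
repulsion) move through a pool of obstacles tethered to fixed anchors by
Hookean springs, pushing them aside through a repulsion force.  The
feedback between agents and obstacles produces moving clusters, trails,
travelling bands and honeycomb-like states.  The package is aimed at
researchers in active matter and mathematical biology who want to simulate
the model at both of its levels, predict its patterns analytically, and
quantify how well the two levels agree.

It provides:

* **`tetherswarm.discrete`** — the coupled SDE system for M agents
  (Z_k, α_k) and N tethered obstacles (X_i, Y_i) on the periodic unit
  square, integrated by Euler–Maruyama with periodic k-d-tree neighbour
  search (orientations advanced in angle coordinates, the exact form of the
  projected Stratonovich dynamics on the circle);
* **`tetherswarm.continuum`** — the hydrodynamic limit: a conservation law
  for the agent density ρ_g coupled to a transport–diffusion equation for
  the mean orientation Ω, with the obstacle density slaved to the convolved
  agent density through the stiff-spring closure
  ρ_f/ρ_A = 1 + Δρ̄_g/κ + det H(ρ̄_g)/κ² − (η/κ²)∂_tΔρ̄_g;
* **`tetherswarm.stability`** — the dispersion relation of plane-wave
  perturbations, a Routh–Hurwitz stability test for its complex quadratic,
  and pattern-size/growth-rate predictors.  The key result: uniform states
  are unstable iff the bifurcation parameter b_p = μκ/c₀ is below 1, where
  c₀ = max_z z²φ̂(z)² depends only on the agent–obstacle repulsion kernel
  (c₀ ≈ 5.6 for C_φ = 5, independent of the repulsion radius τ);
* **`tetherswarm.alignment`** — the constants inherited from the alignment
  dynamics (von Mises moments c₁, c₂, c₃, drifts d_i = u₀c_i, orientational
  viscosity γ_s), including the auxiliary boundary-value problem behind c₂;
* **`tetherswarm.patterns`, `tetherswarm.compare`** — measured pattern
  sizes from the 2-D density spectrum, and a translation-invariant
  discrete-vs-continuum distance: particle-in-cell deposition on an
  optimally chosen grid, histogram signatures, and the earth mover's
  distance solved as a transportation linear program.

## Worked example

Predict and then measure the patterns at a moderately unstable point
(κ = 1000, ζ = 0.5, μ = 2×10⁻³, C_φ = 5, τ = 0.15, d_s/ν = 0.01):

```python
import math, numpy as np
from tetherswarm import ModelParams, compute_bp, pattern_prediction
from tetherswarm.continuum import Grid, ContinuumConfig, run_continuum
from tetherswarm.patterns import measured_sizes

p = ModelParams(kappa=1000.0, zeta=0.5, mu=2e-3, ds=0.02, nu=2.0, rA=0.15)
print(f"b_p = {compute_bp(p):.4f}")
pred = pattern_prediction(p)
print(f"alpha_max_par = {pred.alpha_max_par:.3f}  alpha_max_perp = {pred.alpha_max_perp:.3f}")
print(f"S1_th = {pred.S1_th:.4f}  S2_th = {pred.S2_th:.4f}")

res = run_continuum(p, Grid(96), ContinuumConfig(T=10.0, seed=1))
Om0 = (math.cos(math.pi/4), math.sin(math.pi/4))
S1, S2 = measured_sizes(np.clip(res.final.rho_g, 1e-12, None), Om0)
print(f"run status = {res.status.value} at t = {res.final.t:.2f}")
print(f"measured S1 = {S1:.4f}  S2 = {S2}")
```

prints

```
b_p = 0.3571
alpha_max_par = 3.865  alpha_max_perp = 2.348
S1_th = 0.2453  S2_th = 0.2546
run status = stop_negative_rho_f at t = 1.88
measured S1 = 0.2357  S2 = 0.2
```

Read: b_p < 1, so the uniform state is unstable; perturbations grow in both
directions (α_max > 0) with predicted wavelengths ≈ 0.25 of the domain
edge.  The nonlinear run concentrates until the obstacle-density closure
leaves its validity range (the model's intrinsic blow-up; the last valid
state is kept), and the sizes measured from the density spectrum at that
state, S₁ ≈ 0.24 and S₂ = 0.2, sit close to the linear prediction.  At
μ = 4×10⁻³ the same pipeline yields bands (S₁ finite, S₂ absent), and at
μ = 6×10⁻³ (b_p ≈ 1.07) the perturbation decays and no pattern forms.

The same physics can be run at the discrete level and compared:

```sh
tetherswarm run-discrete --seed 1 --t-final 10 --outdir out_d
tetherswarm run-continuum --seed 1 --nx 150 --outdir out_c
tetherswarm stability-scan --n-mu 25 --outdir out_scan
tetherswarm compare --seed 1 --n-agents 500 --outdir out_cmp
```

`compare` runs the full micro–macro pipeline: it rescales the discrete
parameters along the ε-ladder (r_R, r_A → εr_R, εr_A and d_s, ν → d_s/ε,
ν/ε), deposits both solutions on the optimal particle-in-cell grid, and
reports the signature EMD for each ε; the distance shrinks as ε → 0, where
the continuum limit applies.

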