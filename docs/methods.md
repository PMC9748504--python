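# Methods

`tetherswarm` implements a two-level model of collective motion in a
deformable environment: self-propelled agents with Vicsek-type alignment
move through a pool of passive obstacles, each tethered to a fixed anchor
by a Hookean spring, on the periodic unit square.  Agents repel each other
and the obstacles; obstacles are displaced by the agents and pulled back by
their springs.  The feedback between the two populations produces moving
clusters, trails, travelling bands and honeycomb-like states depending on
three forces: agent–agent repulsion (intensity μ), agent–obstacle repulsion
(intensity C_φ) and the spring stiffness κ.

## Discrete level

State: obstacle positions X_i with anchors Y_i (i = 1..N), agent positions
Z_k and unit orientations α_k = (cos θ_k, sin θ_k) (k = 1..M).  Dynamics:

    dX_i = −(κ/η)(X_i − Y_i) dt − (1/(ηM)) Σ_k ∇φ(X_i − Z_k) dt + √(2d₀) dB_i
    dZ_k = u₀ α_k dt − (1/(ζN)) Σ_i ∇φ(Z_k − X_i) dt
                     − (1/(ζM)) Σ_{l≠k} ∇ψ(Z_k − Z_l) dt
    dα_k = P_{α_k⊥} ∘ [ν ᾱ_k dt + √(2d_s) dW_k]   (Stratonovich)

where ᾱ_k normalises the mean flux J_k = Σ_{|Z_j−Z_k|≤r_A} α_j (self
included).  The kernels are compactly supported bumps

    ψ(r) = (6μ/(π r_R²)) (1 − r/r_R)₊²,    φ(r) = (3C_φ/(2πτ)) (1 − r/τ)₊²

normalised so ∫ψ = μ and ∫|∇φ| = C_φ.

Numerical choices:

* **Orientation update in angle coordinates.**  The projected Stratonovich
  equation on the circle is exactly dθ = ν sin(θ̄ − θ) dt + √(2d_s) dW; the
  angle form keeps |α| = 1 without renormalisation drift.
* **Euler–Maruyama, nominal dt = 1e-3** at the reference parameter scales
  (stiffest deterministic rate κ/η ≤ 1000).  The per-step displacement is
  monitored against the neighbour cell size; when cluster-rim forces (order
  ρ_local · C_φ ≈ 10²) transiently exceed what the nominal step supports,
  the step is rejected and retried at half the dt, relaxing back afterwards.
  A run aborts only if dt would fall below 1/1024 of nominal (effectively
  singular states).
* **Neighbour search** with periodic k-d trees (`scipy.spatial.cKDTree`,
  `boxsize=L`) for the three radii r_A, r_R, τ; all displacements use the
  minimum-image convention, including the tether spring (an obstacle pushed
  across the periodic seam must still feel the short-way pull).
* **Initial condition**: positions i.i.d. uniform, all orientations at π/4,
  obstacles starting on their anchors (one uniform draw realises uniform
  obstacles *and* uniform anchors with a relaxed spring; an independent
  draw is available via a flag).
* Tie-break: if |J_k| < 1e-12 (exact cancellation, measure zero) the agent
  keeps its orientation.

## Continuum level

In the regime of many particles, stiff springs (γ = η/κ ≪ 1), low obstacle
noise, localized repulsion/alignment (r_R, r_A = O(ε)) and fast alignment
(ν, d_s = O(1/ε)), the agent density ρ_g and mean orientation Ω obey

    ∂_t ρ_g + ∇·(U ρ_g) = 0,
    ρ_g ∂_t Ω + ρ_g (V·∇)Ω + d₃ P_{Ω⊥} ∇ρ_g = γ_s P_{Ω⊥} Δ(ρ_g Ω),
    U = d₁Ω − (1/ζ)∇ρ̄_f − (μ/ζ)∇ρ_g,   V = d₂Ω − (1/ζ)∇ρ̄_f − (μ/ζ)∇ρ_g,

with the obstacle density slaved to ρ̄_g = ρ_g ∗ φ:

    ρ_f/ρ_A = 1 + Δρ̄_g/κ + det H(ρ̄_g)/κ² − (η/κ²) ∂_t Δρ̄_g  (+ higher orders, dropped)

and ρ̄_f = ρ_f ∗ φ.  The transport speeds are d_i = u₀ c_i where c₁ is the
first moment of the von Mises distribution m(θ) ∝ exp(cos θ/(d_s/ν)), c₃ =
d_s/ν, and c₂ is a quadrature ratio weighted by the generalised collision
invariant h = g/sin θ, with g solving g'' + (ν/d_s) sin θ g' = sin θ on
[0, π].  The orientational viscosity is γ_s = (r_A²/8)(d_s/ν + c₂).

### Alignment-constant chain

* The h-equation is a linear two-point boundary value problem.  Boundary
  conditions g(0) = g(π) = 0 follow from requiring h = g/sin θ bounded
  (any bounded h forces g to vanish where sin θ does); this is recorded as
  an assumption: it is the unique choice compatible with a bounded h, and
  the full functional-analytic setting is not reproduced here.  Discretisation: second-order central differences on a
  uniform grid (default 8001 nodes), direct tridiagonal solve, endpoint h
  by L'Hôpital.  c₂ is converged to ~1e-8 at the default grid; halving the
  spacing moves it by < 1e-4.
* All von Mises quadratures use the shifted weight exp((cos θ − 1)/r) so
  nothing overflows down to the hard floor r = d_s/ν ≥ 1e-4; below that the
  boundary layers (width √r) are no longer resolved and callers are told to
  use the concentrated limit c₁ = c₂ = 1.
* Independent oracle: c₁ = I₁(1/r)/I₀(1/r) (modified Bessel functions),
  matched to 1e-6 in the tests.
* At the reference point r_A = 0.15, d_s/ν = 0.01: c₁ ≈ 0.99499,
  c₂ ≈ 0.98765, γ_s ≈ 2.806e-3.

### PDE solver

Cell-centred periodic grid (reference resolution 150² for production runs;
64²–96² in the validation suite — the sizes are chosen so the full
validation chain runs at desk scale).  All derivatives and the two
convolutions are spectral (FFT); the φ kernel is sampled on the
displacement lattice and rescaled so its discrete integral equals the
analytic ∫φ = C_φτ/4 exactly.  Time stepping is explicit Euler with the
fluxes in conservative form, so the total agent mass is conserved to
round-off; |Ω| = 1 is enforced by node-wise projection of the full
right-hand side onto Ω⊥ followed by renormalisation.

* **Advection scheme.**  The default computes ∇·(Uρ_g) pseudo-spectrally.
  A first-order upwind variant exists (`scheme="upwind"`), but upwinding's
  numerical diffusion (|U|h/2 · k² ≈ 2.8 at 64² for the fastest-growing
  modes) is the same order as the physical growth rates (≈ 2.5), which
  would mask the very dispersion behaviour the solver is validated against;
  the spectral form reproduces the linear growth/decay rates to < 3%.
* **Closure time derivative.**  ∂_t Δρ̄_g is a backward difference across
  one time level (zero at the first step).  The term is kept ON by default:
  it is what produces the G(z) ≥ 1 denominator of the dispersion relation,
  and at κ = 100 it changes growth rates by ~30%.  A flag disables it.
* **CFL.** Steps satisfy dt·max|U|/h < 0.5 and dt·max(μρ_g/ζ, γ_s)/h² <
  0.25; `run_continuum` adapts dt each step (cap 5e-3) and `step_continuum`
  raises with a suggested dt if handed a violating step.
* **Blow-up.**  Concentration is intrinsic to the model: runs stop, keeping
  the last valid state, when ρ_f goes negative or max ρ_g exceeds 50× its
  mean, or when the state stops being finite.  Deeply unstable parameter
  points (b_p ≪ 1) terminate well before t = 10 by design, exactly as the
  physical model predicts.
* **Vacuum.**  The Ω equation divides by ρ_g; nodes with ρ_g < 1e-8 freeze
  their orientation (orientation is meaningless in vacuum).
* **Initial data**: ρ_g = 1 + a·ξ with ξ band-limited white noise (modes
  |n| ≤ 8), normalised to max|ξ| = 1, default amplitude a = 1e-2, then
  rescaled to unit mass; Ω uniform at π/4.

## Linear stability

Plane-wave perturbations of the uniform state (ρ₀, Ω₀) have growth rates α
solving (with F, G as in `stability.F_of`/`G_of`, k₀ = k·Ω₀, k₁ = k·Ω₀⊥)

    (G α − F + i d₁k₀)(α + i d₂k₀ + |k|²γ_s) + d₁d₃k₁² = 0.

For k ∥ Ω₀ the factors give a density branch α₁ = (F − i d₁k₀)/G and an
orientation branch α₂ = −i d₂k₀ − |k|²γ_s; otherwise the quadratic is
solved with a cancellation-safe formula.  The factored determinant is taken
as the authoritative form and the expanded quadratic is cross-validated
against the closed-form Routh–Hurwitz conditions; the algebraic criterion
agrees with the root-sign oracle on 10³ random draws in the tests.  The
uniform state is unstable iff some z > 0 has z²φ̂(z)² > μκ, i.e. iff

    b_p = μκ/c₀ < 1,   c₀ = max_z z²φ̂(z)²,

with φ̂ the radial (order-zero Hankel) transform of φ, evaluated by
Gauss–Legendre quadrature on the compact support.  c₀ is found by a
2000-point scan of z ∈ (0, 40/τ] plus bounded refinement (the first
spectral lobe contains the maximum for this kernel family); the
self-similarity τ|k|φ̂(τ=1) makes c₀ independent of τ, and c₀ scales as
C_φ².  For C_φ = 5, c₀ ≈ 5.601.

Pattern predictors maximise Re α along Ω₀ and Ω₀⊥ over continuous
wavenumbers (lattice modes k = 2πn are used when validating against
periodic simulations); sizes are S_i = 2π/|k_i|, reported absent when no
positive growth exists in that direction.  One reading note: the maximal
perpendicular growth is defined as a maximum, not an argmax, and at the
reference band point (κ=1000, ζ=0.5, μ=4e-3) the *linear* perpendicular
growth is weakly positive (≈ 0.08 vs ≈ 1.5 parallel); pure S₂ = 0 band
signatures appear in the linear theory slightly above that μ, while the
nonlinear PDE run at μ = 4e-3 does select bands (S₂ below the spectral
noise floor).

## Pattern measurement and micro–macro comparison

Realized sizes are read from the 2-D DFT of the density: the
modulus-maximising lattice mode within 10° of Ω₀ (resp. Ω₀⊥) gives
S = 2π/|k|; a direction is absent when its best mode does not exceed 5×
the mean nonzero-mode modulus.  The 10° tolerance accommodates the π/4
reference frame, where exactly-parallel lattice modes are sparse.

Discrete point clouds and continuum fields are compared via:

1. **Optimal PIC grid**: sample N points from the continuum density (one
   realisation — the patterns are robust across realisations, and the
   comparison is defined that way), deposit with periodic cloud-in-cell
   weights at candidate spacings h ∈ {1/n : n = 5..100}, interpolate back,
   and pick the h̃ minimising the discrete ℓ² error.  Clustered references
   drive h̃ down as N grows; smooth references favour coarse grids.
2. **Signatures**: histogram of density values with p_k = k·max(ρ)/n_b,
   half-open bins (last closed) so the weights partition the grid cells;
   n_b from the Freedman–Diaconis rule (width 2·IQR/n^{1/3}; an n^{3/2}
   variant is available behind a flag for comparison with other
   conventions).  Micro and macro fields share the macro-derived n_b.
3. **EMD**: the transportation linear program between two signatures
   (supplies ω, demands v, ground distance |p_k − q_l|, total flow
   min(Σω, Σv)), solved with `scipy.optimize.linprog` (HiGHS); the
   normalised optimal cost equals the balanced 1-D Wasserstein-1 distance
   when the totals match (verified against the closed form to 1e-8).
   Value histograms discard spatial phase, so translated patterns compare
   as identical — the property needed to compare stochastic realisations.

The ε-scaling ladder r̃_R = εr_R, r̃_A = εr_A, d̃_s = d_s/ε, ν̃ = ν/ε moves
the discrete model toward the continuum regime; the EMD between the two
levels decreases along ε = 1, 0.5, 0.1 in the reference comparison
(κ = 100, μ = 2e-3, ζ = 0.5, N = M = 500 — scaled down from the
production N = M = 3000 so the whole ladder runs at desk scale).

## What the validation does and does not show

The test suite validates: exact structural invariants (mass, |Ω| = 1,
uniform steadiness, kernel normalisations), the alignment chain against a
Bessel-function oracle, the dispersion machinery against brute-force root
finding, the PDE solver against the dispersion relation in the linear
regime, the EMD against its closed form, and the qualitative phase
behaviour (clusters / bands / uniform) against the b_p predictor.  The
synthetic initial conditions are small random perturbations of uniform
states; the suite therefore demonstrates internal consistency of the two
model levels and their analysis, not agreement with any experimental
system.  Discrete-level results are single stochastic realisations at
desk-scale particle numbers; continuum runs at deeply unstable parameters
end at the model's intrinsic blow-up rather than a steady state, and all
pattern measurements there describe the last valid state.

## Known limitations

* L ≠ 1 domains are supported in the API but untested extrapolation; all
  reference values assume the unit square.
* Only the quadratic-bump kernel family ships; the radial-transform and
  c₀ machinery assumes compact support.
* The continuum solver has no positivity limiter; fidelity near blow-up is
  limited to detecting it.
* The h-BVP boundary conditions are the bounded-h choice documented above.
* d_s/ν < 1e-4 is rejected rather than switched to asymptotics
  automatically.
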