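# Methods

This note records the model equations, parameter conventions, numerical
choices, and study-condition decisions behind `wolbnet`.  All rates are per
day, all distances in meters, populations in individuals (densities per
meter for the 1-D reaction-diffusion variant).

## 1. Two-compartment habitat model

Per habitat, carriers `x` and non-carriers `y`:

    dx/dt = (b_I − δ_I) x − d·x(x + y)
    dy/dt = b_U y²/(x + y) − δ_U y − d·y(x + y)

- `b_I, b_U`: carrier / non-carrier birth rates; `δ_I, δ_U`:
  density-independent death rates; `d`: density-dependent death rate.
- The non-carrier birth term `b_U y²/(x+y)` encodes cytoplasmic
  incompatibility: a non-carrier female's eggs are viable only when her
  mate is also a non-carrier, probability `y/(x+y)` in a well-mixed
  habitat.  The term is extended by 0 at `x + y = 0` (it has limit 0).
- Consistency constraints (checked by `validate_params`):
  `b_I > d + δ_I`, `b_U > d + δ_U`, `b_U ≥ b_I`, `δ_I ≥ δ_U`.

Under the constraints the system has two stable equilibria — carrier-only
`((b_I−δ_I)/d, 0)` and non-carrier-only `(0, (b_U−δ_U)/d)` — and a
coexistence saddle whose components sum to the carrier-only population.
The saddle's stable manifold is exactly the line `y = c·x` with

    c = (b_I − δ_I + δ_U) / (b_U − b_I + δ_I − δ_U),

which therefore separates the two basins: initial ratios `y/x < c` lead to
carrier fixation, ratios above `c` to carrier loss, and the ratio `y/x` is
a conserved quantity on the line itself (verified to `1e-6` drift over 200
days in the test suite).  `equilibria_1hab` double-checks every analytic
stability label against the Jacobian eigenvalues at runtime.

### Habitat networks

Habitats are coupled diffusively: habitat `j` gains
`Σ_k m_jk (x_k − x_j)` (and likewise in `y`) with a symmetric,
zero-diagonal coefficient matrix, so coupling conserves the summed
population.  Carrying capacities may replace death rates via

    d_j = (1/K_j) · (b_U − δ_U + Σ_k m_jk (K_k/K_j − 1)),

the unique choice making "non-carriers at capacity" an exact equilibrium of
the coupled system (equilibrium residual `< 1e-10` in the tests).  For two
habitats the derived `d_j` stay positive iff
`m < (b_U − δ_U)/(1 − K_min/K_max)` (`migration_upper_bound`); violations
raise `MigrationBoundError`.

### Default rate sets (fixtures)

| set | b_I | b_U | δ_I | δ_U | use |
|---|---|---|---|---|---|
| baseline | 0.285 | 0.300 | 0.079 | 0.071 | field-estimate scenarios (`fig2`, `fig3`, `fig5`, `fig6a`) |
| demo | 0.45 | 0.55 | 0.05 | 0.048 | phase-portrait / placement demos (`fig1`, `fig7`, `fig8`) |
| sweep | 0.42 | 0.57 | 0.05 | 0.048 | bifurcation sweep (`fig6b`) |

## 2. Nine-compartment habitat model

Compartments per habitat, in canonical order: `A_u, A_w` (aquatic),
`F_u, F_w` (unmated females), `F_pu, F_pw` (pregnant females), `M_u, M_w`
(males), `F_ps` (sterile pregnant females from CI matings); `u`/`w` denote
uninfected / *Wolbachia*-infected.  Key structure:

- Aquatic recruitment is logistic with shared capacity `K`:
  eggs enter `A_u` at `(φ_u F_pu + v_u φ_w F_pw)(1 − (A_u+A_w)/K)` and
  `A_w` at `v_w φ_w F_pw (1 − (A_u+A_w)/K)` (imperfect maternal
  transmission: a fraction `v_u` of infected mothers' eggs are uninfected).
- CI mating split: unmated uninfected females become productive (`F_pu`)
  with probability `M_u/(M_u+M_w)` and sterile (`F_ps`) otherwise; with no
  males both fractions are defined as 0.  Infected females mate
  productively regardless of the male (`F_w → F_pw` at rate σ).
- In networks, diffusion `Σ_k m_jk (C_k − C_j)` applies to all seven adult
  compartments with the same coefficient; aquatic stages do not migrate.
- The habitat carrier proportion is `(F_w + F_pw + M_w)` over all adults
  (including `F_ps` by default).

Baseline constants: `b_f = b_m = 0.5`, `σ = 1`, `φ_u = 13`, `v_u = 0.05`,
`v_w = 0.95`, `ψ = 0.114`, `μ_a = 0.02`, `μ_fu = 0.0571`, `μ_fw = 0.0633`,
`μ_mu = μ_mw = 0.0952`, `K = 2·10⁵`.  The infected egg-laying rate `φ_w`
is scenario-dependent (11 or 13); the two-habitat experiments here use
**φ_w = 11**, the fecundity-cost case that the coupling-threshold
experiments address (`model2_baseline` forces an explicit choice).

## 3. Dispersal kernels and migration coefficients

A kernel is the probability density of the distance an individual ends up
from its release point after the MRR period `t` (default 7 days).  A
habitat is a disk of radius `r*` enclosing a fraction `q` (default 0.95) of
dispersers.  The migration coefficient between habitats `x*` apart is

    m(x*) = 1/(2π t) ∫∫_disk p(D)/D dA,

the per-day probability of landing in the destination disk under isotropic
dispersal whose distance marginal is `p`.

- **Exponential**: `p(r) = e^(−r/ξ)/ξ`, `r* = −ξ ln(1−q)`.  No shape
  parameter, so coefficients are independent of the reported MRR standard
  deviation.
- **Log-normal**: two (M, S) parameterizations are provided.
  `LognormalKernel.from_mrr` uses `M = ln(ξ²/√(ξ²+σ²))`,
  `S = √(ln(1+(ξ/σ)²))` — the convention under which the published
  Singapore MRR coefficient tables reproduce to printed precision (and the
  package default).  `from_moments` is the strict moment match
  (distribution mean ξ, sd σ, i.e. `S = √(ln(1+(σ/ξ)²))`).  The two differ
  because the source tables were evidently computed with the first
  convention; both are exposed so users can choose explicitly.

**Numerics.**  `migration_rate` reduces the double integral exactly to one
dimension: in polar coordinates centered on the source, the `1/D` factor
cancels and `m = 1/(2πt) ∫ p(ρ)·2α(ρ) dρ`, where `2α(ρ)` is the angular
measure of the source-centered circle of radius ρ inside the destination
disk.  This remains accurate when the disks overlap and even when the
source center lies inside the destination disk (the `1/D` singularity is
integrable); such geometries emit `OverlapWarning` rather than an error,
because published coefficient tables themselves include them.  Two
independent cross-checks are provided: the literal 2-D adaptive quadrature
(`migration_rate_quad2d`, agreeing to `1e-7` relative on non-overlapping
geometry) and a Monte-Carlo landing-probability oracle
(`monte_carlo_transfer`, agreeing within 3 standard errors at 10⁶ samples).

## 4. Reaction-diffusion variant

The two-compartment reactions on a 1-D interval with diffusion `D`
(m²/day), discretized by method of lines (second-order central Laplacian,
zero-flux boundaries by default, 400 nodes).  The standard demonstration
releases `x(s,0) = 40·e^(−s²)` into a background `y = 200` with baseline
rates and `d = 0.001`.

Because the dynamics are bistable, this ~1 m-wide pulse must exceed a
critical nucleus whose size scales with the interface width `√(D/g)`
(`g = b_I − δ_I ≈ 0.206`).  Empirically the wave forms for `D ≲ 0.02` and
the pulse dies out for larger `D`; the defaults are **D = 0.01 m²/day on
[−10, 30] m** (front speed 0.0271 m/day, position-fit R² = 1.000).  The
front spans ~13 grid nodes at the default spacing; `wave_speed` warns
(`GridResolutionWarning`) when the tracked front spans fewer than 5 nodes,
and halving the grid changes the measured speed by 0.34% (< 2%).  `D` and
the domain are configuration choices, not published values; wave existence
depends on `D` (for this initial condition), the speed scales as `√D`
(verified in tests), and the qualitative amplitude dichotomy (wave at
amplitude 40, extinction at 0.4) holds at the defaults.

## 5. Experiments and classification

- Integration: SciPy `solve_ivp` with LSODA, `rtol = atol = 1e-9`
  (`1e-8` for the nine-compartment model), horizon 2000 days (2500 for the
  nine-compartment model), doubled up to twice if the terminal derivative
  residual exceeds `1e-8` relative to the state scale.  Outputs are clipped
  at zero (adaptive integrators can produce ~1e-12 negative populations).
- Two-compartment outcomes per habitat: `carrier_fixation` /
  `carrier_loss` / `coexistence` with a population floor of `1e-3` times
  the habitat's non-carrier reference population (its capacity, or
  `(b_U−δ_U)/d_j`).  Nine-compartment outcomes use the adult carrier
  proportion (fixation above 0.5).
- `minimal_release` integer-bisects the single-habitat release size on the
  fixation-everywhere predicate, reporting both the largest failing and
  smallest succeeding integers (for the 400/600, m = 0.006 network: 50/51
  in habitat A, 59/60 in habitat B, matching the continuous basin
  intercepts 50.15 and 59.17).
- `migration_sweep` brackets qualitative outcome changes in the coupling by
  bisection (default resolution `1e-5`); the coexistence-loss bifurcation
  of the sweep rate set with `d = 0.001` lies at `m ≈ 0.0128`.
- `model2_sweep` locates the jump of habitat B's steady carrier proportion
  across 0.5 (resolution `1e-6`); with φ_w = 11 and the standard initial
  conditions the threshold is `m ≈ 0.0018`.

### Study-condition choices

- **φ_w = 11** for all two-habitat nine-compartment experiments (the
  fecundity-cost case); `φ_w = 13` remains available.
- The three-habitat chain (`fig7`) treats its per-habitat "300" as initial
  non-carrier populations with `d = 0.001` supplied directly, since
  interpreting them as capacities would contradict the stated death rate.
- The "small habitat surrounded by large ones" scenario (`fig8`) realizes a
  geometry described only qualitatively in its source: small `K = 150` at
  the origin, large `K = 600` at (200, 0), (400, 0), (200, 200).  The
  placement effect (the same 300-carrier release fails in the small habitat
  but fixes the whole system from any large one) is the claim being
  reproduced, not the specific coordinates.

## 6. Limitations

- Steady states are asserted by long-horizon integration plus a derivative
  residual test, not by continuation; near-threshold releases linger near
  the saddle and are reported with `converged = False` rather than
  misclassified.
- The capacity-to-death-rate conversion assumes the shared birth/death
  constants; habitat-specific `b`/`δ` are out of scope.
- The disk-transfer migration model assumes isotropic dispersal,
  equal-radius circular habitats, and ignores landscape heterogeneity.
- The reaction-diffusion variant is 1-D with uniform `D`; transit times
  (unlike wave existence and the amplitude threshold) depend on the chosen
  `D` and domain.
- The nine-compartment network shares all rate constants across habitats
  except the aquatic capacity.
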