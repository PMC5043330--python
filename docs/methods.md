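# Methods

## Model class

`rdhybrid` simulates mass-action reaction–diffusion systems on a uniform
compartment lattice (a 1-D chain or a 2-D rectangle of square cells of width
`h`, reflective boundaries).  Molecules are well mixed within a compartment;
diffusion of species `i` is a first-order jump to a nearest neighbour at the
per-molecule rate `D_i / h²`.  The state is the integer copy-number vector
`X(t)` over (compartment, species); its law obeys the reaction–diffusion
master equation (RDME).  Copy numbers and macroscopic concentrations are
linked per species by `Λ_i` (molecules per unit concentration per
compartment), the system-size parameter.

### Stochastic mass-action convention

Rate constants are *macroscopic* (concentration units).  The propensity of
reaction `j` in compartment `k` is

    a_kj = Λ_ref γ_j V_j(k) Π_i ff(X_ki, s_ij) / Λ_i^{s_ij},

with `ff` the falling factorial over the reactant stoichiometry `s_ij`,
`V_j` an optional per-compartment profile (e.g. a localized production
region), and `Λ_ref` the smallest `Λ` among the species the reaction
changes.  One firing changes species `i` by `(s^p_ij − s^r_ij) Λ_i/Λ_ref`
molecules; the ratios must be integers (validated).  This is the unique
integer-preserving bookkeeping whose large-`Λ` mean reproduces the
deterministic PDE term for *every* species even when reaction partners carry
different `Λ` (in the morphogen–receptor systems `Λ_M/Λ_R = 90`, so one
binding event consumes one receptor and 90 morphogen molecules).  A
consequence accepted here: when the high-`Λ` species drops below the ratio,
an event can overdraw it; counts are clamped at zero and the clamped mass is
logged (`clamp_loss`).  Both simulators share the convention, so method
comparisons are unaffected.

Production regions are defined by compartment centres: a compartment
produces iff its centre lies inside the stated interval (width 14 µm at
h = 2 µm ⇒ 7 compartments; the central 94–106 µm region ⇒ 6 compartments).

## Reference simulator: spatial SSA

The direct-method Gillespie SSA over all reaction and jump channels is exact
for the RDME and is the validation oracle throughout.  The compiled kernel
groups propensities by compartment (two-level selection, incremental totals
with periodic refresh against float drift).  A readable pure-Python engine
(optionally recording every event) cross-checks the kernel on small systems.

## Hybrid continuous–discrete method

Each step advances from `t0` to the next reaction time `t`:

1. **Reaction time.** `P_R(t) = exp(−Σ_lj ᾱ_lj(t))`, where `ᾱ_lj`
   integrates the propensity along the *mean* diffusion trajectory
   (diffusive species at `Λ m(τ)` with `m` the deterministic compartment
   concentrations, others frozen).  `t` solves `P_R(t) = r1` by bracketing
   from the constant-propensity guess `−ln r1 / a_tot(t0)` plus doubling,
   then safeguarded Newton to a relative tolerance of 1e-6.  Integrals use
   composite trapezoid with `quadrature_points` nodes (default 33).  If the
   cumulative propensity cannot reach `−ln r1` before the step cap, the step
   is a diffusion-only update flagged *no reaction*.
2. **Adaptive split.** Per diffusive species the expected directed jump
   counts `Λφ(t)` are computed; compartments where they fall to the cut-off
   `T_A` (default 10, where the Poisson and Normal(µ, µ) densities differ by
   < 0.01) are simulated by the diffusion-only SSA behind a reflective
   wall.  Modes: `monotone` (SSA from the first compartment below `T_A`),
   `central_peak` (largest above-threshold interval around the flux peak),
   `none` (Gaussian everywhere), `ssa` (Gaussian nowhere); a mapping
   configures the mode per species.  In 2-D the rule is applied to
   x-direction fluxes summed over each column of compartments, and whole
   columns switch regime.
3. **Gaussian diffusion update.** Over the Gaussian region the cumulative
   jump counts are `n_e = Λφ_e + √Λ ξ_e` with `Φ` solving `dΦ/dt = AΦ + C`
   (equivalently `dφ_e/dt = (D/h²) m_src(e)`) and `Ξ` zero-mean Gaussian
   with covariance `ρ` from the Lyapunov ODE `dρ/dt = Aρ + ρAᵀ + B(t)`,
   `B = diag(dΦ/dt)`.  Edges whose source lies in the Gaussian region are
   sampled; the flux entering across the interface is applied at its mean
   (`Λφ`), exactly the printed interface bookkeeping.  Updated counts are
   rounded to the nearest non-negative integers; the (mean-zero) rounding
   residual and any clamped mass are logged.
4. **Reaction.** One reaction `(q, m)` is chosen with probability
   `ᾱ_qm / Σᾱ` (compartment-major order, first channel reaching
   `r2 Σᾱ`) and applied.  Steps repeat until the horizon.

The expansion is re-centred at every step: `Φ`, `ρ` and the split are
recomputed from the current state, which is what allows zero-copy initial
states (the first steps simply run as pure SSA).

### Reduced Gaussian sampling in the compiled engine

The state update consumes `Ξ` only through (i) the net per-compartment
combinations `w = NΞ` (`N` the signed incidence map) and (ii) the few
individual fluxes crossing the region interface.  Because
`dξ_e/dt = (D/h²) w_src(e) + η_e` and `dw/dt = Lw + Nη`, the joint vector
`(w, ξ_interface)` obeys a `(K + n_interface)`-dimensional Lyapunov ODE
driven by the same noise, and sampling it is *distribution-identical* to
sampling the `(2K−2)`-dimensional `ρ` submatrix and projecting — at a
fraction of the cost.  The compiled trajectory kernel uses this reduced
form; the reference `hybrid_step` implements the literal edge-space route
through the public `flux` API.  The tests verify the projection identity
numerically and the statistical equivalence of both engines.

### Numerical choices

- **Mean fluxes** are evaluated exactly in the eigenbasis of the (symmetric)
  lattice Laplacian, diagonalized once per model.
- **Covariance**: the public `flux_covariance` integrates the Lyapunov ODE
  with an adaptive solver (rtol 1e-6); the explicit propagator integral
  (trapezoid, ≥64 nodes, `scipy.linalg.expm`) is retained as an independent
  cross-check.  The trajectory kernel uses fixed-step RK4 with the substep
  count tied to the spectral radius (`r·|λ_min|·Δt ≤ 0.4` per substep),
  which keeps the covariance error below ~0.1% over the step sizes the
  method takes; this is validated against the adaptive route in the tests.
- **PSD repair**: sampling first attempts Cholesky with a `1e-12·max(diag)`
  jitter; on failure the matrix is eigendecomposed and eigenvalues in
  `[−1e-10·λ_max, 0)` are clipped to zero (more negative values are counted
  as repairs in the diagnostics; the public API raises instead).
- **Ties and degenerate cases**: equality of the cumulative sum with
  `r2 Σᾱ` selects the earlier channel; `kg = 2` leaves a single sampled
  edge; `kg ≤ 1` bypasses the Gaussian machinery entirely; a single
  compartment or a reaction-free model reduces to the homogeneous SSA or to
  pure diffusion steps.
- **Sampling times**: hybrid steps never straddle a requested sample time —
  the remaining horizon caps the step and a capped step performs the
  diffusion update only.  Snapshots are therefore exact states at the
  requested times; the SSA records the state after the last event at or
  before each sample time.
- **Seeding**: replicate `r` of an ensemble uses a stream derived from
  `SeedSequence((master_seed, r))`; compiled kernels are seeded once per
  replicate, making every trajectory bit-reproducible.

## Benchmarks and generated data

All inputs are generated programmatically from published parameter sets
(`examples.PARAMETERS`): the 1-D morphogen gradient with linear degradation
(`example1`), the morphogen–receptor system (`example2`), the two-diffusive
species "bucket brigade" variant (`example3`), a 50×5-compartment 2-D strip
(`example4_2d`), a centrally produced non-monotone gradient
(`example5_central`), and the normalized activator–substrate Turing system
(`example6_turing`, Gaussian approximation applied to the fast substrate
only).  `fixture_generator` produces random small valid models for property
tests.  These synthetic systems exercise localized production, steep and
non-monotone gradients, mixed `Λ` bookkeeping and multiple diffusive
species, but they are idealized: strictly mass-action kinetics, uniform
`D` and `h`, reflective boundaries, no irregular geometry — agreement here
does not certify behaviour beyond that class.

## Ensemble comparisons and problem sizes

Method agreement is summarized by the per-compartment relative differences
`(M_SSA − M_hybrid)/M_SSA` of ensemble means and SDs, restricted to
compartments with SSA mean ≥ 5 molecules (ratios at near-empty compartments
are noise-dominated; the floor is a CLI flag).  The package's own
acceptance runs use:

- the linear-degradation gradient at `D_M = 40 µm²/s` on a 50-compartment
  domain (the production region kept at 7 compartments), 800 SSA / 500
  hybrid replicates, `t = 100 s`;
- the central-production gradient on the full 100-compartment domain,
  1000 SSA / 500 hybrid replicates, `t = 20 s`.

The sampling error of an ensemble SD is `≈ 1/√(2(n−1))` relative (larger
at low-occupancy compartments, where Poisson kurtosis inflates it), so the
*maximum* relative difference over 50–130 included statistics is
noise-floored near 0.1–0.13 even for a perfect method at these replicate
counts; fewer replicates would push the statistic's noise floor above the
0.15 agreement bound being checked.  The central-production benchmark gets
the larger ensembles because its symmetric domain includes roughly twice
as many low-occupancy compartments.

## Known limitations

- The interface scheme injects the whole interval's mean influx at the end
  of the step; for the short steps the reaction rate dictates this is
  accurate, but single long reaction-free windows across a low-copy
  interface lose some within-window mixing (visible as a small bias just
  inside the SSA region when a large `max_step` is forced by hand).
- Compartment counts in the SSA region do not receive the *noise* of the
  outgoing interface flux (its mean only), slightly under-dispersing the
  first SSA compartment; empirically the effect is within the method's
  overall few-percent SD accuracy at `T_A = 10`.
- Mixed-`Λ` overdraw clamping (above) makes the low-concentration tail of a
  high-`Λ` species approximate.
- Wall-clock comparisons between the SSA and hybrid engines are reported in
  run metadata but are hardware-dependent and not part of any test.
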