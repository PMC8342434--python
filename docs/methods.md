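# Methods

## Scope and data

The package models the solubility of a heavy, thermally fragile solid —
vitamin A (retinol, C₂₀H₃₀O, M = 286.45 g/mol) — in supercritical CO₂.
The bundled dataset holds 27 isothermal records (11 at 303.15 K, 9 at
313.15 K, 7 at 323.15 K; 90–245 bar), each a (T, P, y, ρ, S) tuple where
the mole fraction y, the solvent density ρ (g/L) and the solubility S
(g/L) are mutually redundant through

    y = (S/M_A) / (S/M_A + ρ/M_C),      M_C = 44.01 g/mol.

That redundancy is the transcription check: `validate_dataset` recomputes
y from (S, ρ) for every row and flags deviations above 1.5 % relative,
sized for values printed to three significant figures.  The bundled table
passes with a maximum deviation of 0.04 %.  Isotherm temperatures are
stored once, as 303.15/313.15/323.15 K.  One record (313.15 K, 130→140
bar) shows a non-monotone y step; it is internally consistent and is
treated as data, not error.

The measurement equations tie the tabulated quantities to the sampling
procedure: with vial concentration C_A, vial volume V_A, circuit volume
V_l, the solute moles are n_A = C_A·V_A/M_A, the solvent moles
n_C = V_l·ρ/M_C, y = n_A/(n_A + n_C) and S = C_A·V_A/V_l.  (The combined
single-fraction form of this relation is implemented from the mole-balance
definitions, which fix its dimensionally consistent arrangement.)

## Equation-of-state engine

All four supported families are members of the generalized two-parameter
cubic

    P = RT/(v − b) − a(T)/[(v + δ₁b)(v + δ₂b)],
    a_i = Ω_a R²T_c²/P_c · α(T_r),   b_i = Ω_b RT_c/P_c,

with registry entries

| family | δ₁ | δ₂ | Ω_a | Ω_b | α |
|---|---|---|---|---|---|
| SRK | 1 | 0 | 0.42748 | 0.08664 | Soave, m = 0.480 + 1.574ω − 0.176ω² |
| PR | 1+√2 | 1−√2 | 0.45724 | 0.07780 | m = 0.37464 + 1.54226ω − 0.26992ω² |
| SV | 1+√2 | 1−√2 | 0.45724 | 0.07780 | Stryjek–Vera κ(κ₀(ω), κ₁, T_r) |
| DPTG | 2 | 0 | 0.43586 | 0.06865 | PR-type m(ω) |

The DPTG entry is registered with denominator constants (2, 0) and
Ω coefficients derived from the critical-point constraints
(∂P/∂v = ∂²P/∂v² = 0 at T_c), the same constraints that reproduce the SRK
and PR literature constants to 2×10⁻⁵ (a unit test).  Every entry —
including DPTG — is replaceable at runtime through `register_eos`, so a
different parameterization of the perturbation-theory family can be
swapped in without code changes.

In reduced variables A = aP/(RT)², B = bP/RT, s = δ₁+δ₂, p = δ₁δ₂, the
compressibility cubic is

    Z³ + [(s−1)B − 1]Z² + [(p−s)B² − sB + A]Z − [pB³ + pB² + AB] = 0,

solved in closed form (trigonometric branch for three real roots) with two
Newton polish steps; roots with v ≤ b are discarded and the supercritical
phase takes the largest remaining root, with a Gibbs-energy comparison
breaking near-ties.  `numpy.roots` serves as the independent oracle in
tests, never in the solver.

Mixtures use van der Waals rules: a = ΣΣ x_i x_j √(a_i a_j)(1 − k_ij) with
either b = Σ x_i b_i (vdW1) or b = ΣΣ x_i x_j (1 − l_ij)(b_i + b_j)/2
(vdW2).  Component fugacity coefficients come from the single closed form

    ln φ̂_i = (b̄_i/b)(Z−1) − ln(Z−B)
              + A/((δ₁−δ₂)B) · (b̄_i/b − ā_i/a) · ln[(Z+δ₁B)/(Z+δ₂B)],

ā_i = 2Σ_j x_j √(a_i a_j)(1−k_ij), b̄_i = 2Σ_j x_j b_ij − b, written to
remain finite as a→0, b→0 or δ₁→δ₂.  Mole-fraction weighting recovers the
mixture ln φ identically (Euler consistency, asserted to 10⁻¹⁰), and the
whole expression is checked against a central finite difference of
n·ln φ_mix on 1000 randomized states to 10⁻⁶.  A scalar binary-path
duplicate of this formula backs the solubility fixed point (no array
allocation in the inner regression loop); the two paths are asserted equal
to machine precision.

## Solute properties

The critical properties of retinol have never been measured; every choice
here is explicit configuration with a logged default:

- T_b, T_c, P_c — Joback group contributions over the decomposition
  {5×CH₃, 1×CH₂(OH-bearing), 6×=CH–, 2×=C<, ring: 3×CH₂, 1×>C<, 2×=C<,
  1×OH}, giving T_b ≈ 795 K, T_c ≈ 1003 K, P_c ≈ 15.1 bar.  Joback is
  known to overestimate T_b for large molecules; the bias propagates into
  T_c and ω and is the main reason absolute reproduction of literature
  interaction-parameter values cannot be expected (see Limitations).
- ω ≈ 0.984 — Lee–Kesler corresponding states from the estimated T_b.
- V_s = M/ρ_solid with ρ_solid = 0.95 g/cm³ → 301.5 cm³/mol; enters only
  the Poynting factor, so sensitivity is modest.
- CO₂: T_c = 304.18 K, P_c = 73.8 bar, ω = 0.225, Stryjek–Vera
  κ₁ = 0.04285.

All constants: R = 8.31446 J/(mol K) (83.1446 cm³ bar/(mol K) in the EOS
layer); pressures are bar and temperatures kelvin at every interface.

Two sublimation-pressure models support seeding and sensitivity work: the
constant-enthalpy Clausius–Clapeyron curve anchored at the triple point
(T_t ≈ T_f, ΔH^s = ΔH^v + ΔH^f), and an extended-Antoine (Yaws-type)
correlation ln P = A + B/(T+C) + D·lnT + E·T fitted by least squares in
ln P (full five-coefficient form for ≥ 5 points, a three-coefficient
Antoine reduction otherwise).

## Equilibrium solver

y = (P_sub/P)·E(y) is solved by direct iteration from the ideal estimate
y₀ = P_sub/P, with step doubling while updates keep their sign and 0.5
damping on oscillation, relative tolerance 10⁻¹², 200-iteration cap, and a
bisection fallback on g(y) = y − (P_sub/P)E(y) over (10⁻¹², 0.5).
Compositions below 10⁻¹² are clamped for EOS evaluation (the fugacity
coefficient is composition-insensitive in that limit).  φ_A^sub = 1 by
default.  The fixed-point map can possess a second, larger crossing where
the fluid-phase fugacity turns over with composition; iteration from below
converges to the physical dilute root, and the test-suite oracle brackets
the first sign change accordingly.

## Regression

Per isotherm the adjustable set is (k_ij, P_sub) for vdW1 and
(k_ij, l_ij, P_sub) for vdW2 — P_sub is isotherm-level because no measured
value exists.  The objective is AARD% on mole fractions.  Search proceeds
in two stages:

1. **Profiled scan.**  In the dilute limit y is proportional to P_sub, so
   for any (k_ij[, l_ij]) the AARD-optimal scale is the weighted median of
   the experimental/model ratios — an exact, convex 1D subproblem.  A
   seeded Latin-hypercube over the interaction parameters (≥ 64 points) is
   scored this way.
2. **Polish.**  Bounded Nelder–Mead (xatol 10⁻⁷) on the full parameter
   vector from the best 16 scan candidates; all starts are logged.

Default bounds: k_ij, l_ij ∈ [−1, 1.5]; P_sub ∈ [10⁻¹⁴, 10] bar on a
log₁₀ scale.  The wide lower P_sub bound matters: under the Joback-derived
solute attraction the fitted sublimation-pressure scale is far smaller
than literature-style values, and a tighter bound becomes active and
distorts the interaction parameters.  P_sub here is best read as an
effective scale parameter confounded with the property set, not as a
thermophysical measurement.

Temperature trends k_ij = A₁T + A₂ and l_ij = A₃T + A₄ are ordinary least
squares against kelvin temperatures.

## Synthetic data

The generator draws each record from the same equilibrium solver with
known per-isotherm (k_ij, l_ij, P_sub), then applies multiplicative noise
y·(1+ε), ε ~ N(0, cv) truncated at ±3σ, and recomputes S from the noisy y
so each record stays internally consistent.  Densities come from a lookup
table (default: the bundled fixture's ρ column), mirroring the practice of
taking solvent density from a dedicated reference correlation rather than
from the cubic EOS.  The `table2-like` preset copies the fixture's full
(T, P) design and defaults to cv = 0.06, matching the stated < 6 %
experimental uncertainty; its default truth parameters (k_ij = 0.52,
l_ij = 0.47, P_sub = 2×10⁻⁸ bar) put generated mole fractions in the
measured 10⁻⁵–2×10⁻⁴ range.

What the generator does **not** emulate: heteroscedastic or
pressure-correlated measurement error, density uncertainty, co-solvent
effects, or model misspecification (data are generated from the same EOS
family that is fitted).  Passing recovery tests therefore demonstrate the
correctness and identifiability of the estimation machinery, not the
physical adequacy of cubic EOSs for real systems.

## Verified behavior (computed by the tests and acceptance script)

- Noise-free synthetic fits return the generating (k_ij, l_ij, P_sub) to
  ~10⁻¹⁰ and AARD ~10⁻⁹ %.
- At 5 % noise, kij recovery is rule-dependent: the vdW1 study's median
  |k̂_ij − k_ij*| is ~0.003 over 60 per-isotherm fits, while under vdW2
  the k_ij–l_ij collinearity lets noisy optima genuinely beat the truth
  parameters on the objective, setting an intrinsic spread of ~0.03 that
  no optimizer effort removes (verified by exhaustive restarts).
- On the measured dataset, vdW2 fits land within 2 AARD points of
  literature-grade correlation quality (≈ 4–6 % per isotherm); vdW1,
  with its single shape parameter, is far more property-set sensitive and
  fits at 11–19 % under the default Joback set.  vdW2 never fits worse
  than vdW1 on the same isotherm, as its parameter space contains vdW1.
- Fitted models predict y strictly increasing with pressure on every
  isotherm grid.

## Limitations

- Absolute values of fitted k_ij, l_ij and P_sub are conditional on the
  solute property set; only solubility predictions and AARD levels are
  comparable across property sets.  The property set is explicit,
  overridable configuration and is echoed into fit artifacts.
- The DPTG registry entry is a critically-consistent parameterization of
  the (2, 0) denominator family with a PR-type α; users holding a
  different parameterization of the perturbation-theory EOS should
  register it and refit.
- Binary system only: no co-solvent (ternary) bookkeeping, no volume
  translation, no liquid-phase flash, no melting-point depression, and no
  solid-solution solubility of CO₂ in the solid phase.
- The Clausius–Clapeyron sublimation model assumes temperature-independent
  sublimation enthalpy.
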