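# Methods

## Scope and model

`helfand` computes electrical conductivities and self-diffusion
coefficients of 1:1 electrolyte solutions from equilibrium particle
trajectories. Three estimators are implemented on a common footing:

1. **Einstein–Helfand dipole route.** The itinerant dipole of the ions,
   M(t) = Σᵢ qᵢrᵢ(t), performs an effective random walk; its mean-square
   displacement (MSDD) grows linearly at long times and
   σ = slope/(6 V k_B T). This is exact within linear response. Solvent
   molecules are neutral and excluded. The dipole is origin-independent
   only for an electroneutral charge set, which is enforced.
2. **Onsager-coefficient route.** Expanding |ΔM|² into group–group
   displacement correlations gives
   σ = (N e²/(V k_B T))(z₊²Λ₊₊ + z₋²Λ₋₋ + 2z₊z₋Λ₊₋) with
   Λ_AB = (1/6N) d/dτ Σ_{i∈A}Σ_{j∈B}⟨Δrᵢ·Δrⱼ⟩, N the total ion count.
   Normalisation note: published forms of these coefficients differ by
   constant factors; this package fixes the convention by the hard
   requirement that the Onsager route reproduce the dipole route
   *identically* (the two are the same algebraic quantity). With the
   per-N normalisation above and the N e²/(V k_B T) prefactor, the two
   routes agree to machine precision on the same trajectory, sampling
   plan and fit window — this identity is enforced in the test suite at
   1e-10 relative. Λ₊₋ and Λ₋₊ come from the same averaged series and are
   equal by construction.
3. **Nernst–Einstein.** σ_NE = ρ q²(D₊+D₋)/(k_B T) keeps only the i = j
   terms of the pairwise sum. It is implemented both through fitted
   diffusivities and as the literal self-terms-only restriction of the
   dipole series; the two are the same expression term by term, and the
   suite asserts that identity exactly. NE neglects distinct-ion
   correlations, which in pairing electrolytes are anticorrelations, so
   σ_NE ≥ σ_EH physically.

**Dual charge sets.** Scaled-charge (electronic-continuum) force fields
use reduced ionic charges (±0.75 e) for the potential-energy surface while
the charge transported by a field remains the formal integer. The package
therefore carries two named charge sets, `pes` and `dms`, per species;
conductivity defaults to the `dms` set. Because the MSDD is quadratic in
charge, switching sets is an exact λ² rescaling — also asserted in tests.

**Yeh–Hummer correction.** Self-diffusion in a periodic cubic box of edge
L is depressed by hydrodynamic self-interaction; the analytic correction
ΔD = ξ k_B T/(6πηL) with ξ = 2.837 is added when a shear viscosity η is
supplied (η is always an *input*, never computed here). For conductivity
the correction collapses to σ_NE+YH = σ_NE + q²ρξ/(3πηL), since both ions
receive the same increment. The rough-estimate rule σ_EH ≈ 0.7·σ_NE+YH is
provided as an explicitly `approximate`-flagged convenience; the bundled
benchmark table yields a mean printed ratio of 0.717 ± 0.054 (sd) over 18
states, which the acceptance script recomputes.

## Units, constants, conventions

Internal working units are MD-native: nm, ps, e, K. Conversion to SI
(S/m, m²/s) happens once, inside the transport estimators. Physical
constants are the 2019-SI exact values (k_B = 1.380649e-23 J/K,
e = 1.602176634e-19 C, N_A = 6.02214076e23 /mol), defined once in
`core.py`. Boxes are orthorhombic only; triclinic input is rejected at
parse time (unwrapping stays exact and the supported benchmark systems
are cubic). Positions are continuous vectors with the origin at the box
corner; no re-centering is applied (displacement statistics are
translation invariant). Default molar masses: H₂O 18.015, NaCl 58.443,
KCl 74.551 g/mol, overridable in configuration. Only symmetric 1:1
electrolytes are supported; validation rejects mixed charge magnitudes.

## Correlation estimation

All correlation functions are multiple-time-origin averages. The default
lag grid is the blocked (order-n) grid — every lag from 1 to 9 frames,
then multiples of 10, then of 100, … — giving logarithmic coverage at
linear cost; an exhaustive `linear` grid exists for oracle comparisons.
Origins default to every frame (`origin_stride = 1`): collective series
(dipole, group sums) cost O(F) per lag regardless of ion count because
group sums are formed per frame first, and the per-particle MSD kernel is
chunked to bound memory. This group-sum formulation also makes the
identity MSDD = Σ_AB z_A z_B N C_AB hold at machine precision rather than
approximately. Accumulations use numpy's pairwise-summing float64
reductions, which controls cancellation growth in the k²-growing dipole
terms.

Centre-of-mass drift of the ion subsystem is *not* removed: the intended
inputs are thermostatted NVT trajectories whose drift is negligible, and
silent re-centering would change displacement statistics invisibly. (The
trajectory containers make such a preprocessing step easy to add
explicitly if an input demands it.)

Unwrapping wrapped coordinates accumulates per-step minimum-image
displacements (exact for orthorhombic boxes when sampling is frequent
enough that no particle moves half a box edge between frames; violations
raise). LAMMPS image flags, when present, are used directly and
cross-checked against the minimum-image reconstruction.

## Slope fitting and uncertainties

Slopes are unweighted ordinary least squares over an inclusive lag window
(≥ 10 points required). The default window is 50–1000 ps, the protocol
under which the bundled benchmark conductivities were produced; every
estimate records its window, so alternative windows are reproducible.
Origin-count weighting is deliberately not the default (the benchmark
protocol fitted unweighted), and no autocorrelation-aware single-run
error model is attempted: the supported uncertainty model is replicate
scatter, mean ± sd(n−1)/√n over independent runs. Single-run OLS slope
standard errors are reported but underestimate the true sampling error of
correlated residuals — tests that need a defensible confidence interval
(e.g. "σ_EH consistent with 0 for rigid pairs") use replicate scatter
with the appropriate Student-t quantile.

A curvature diagnostic guards against fitting non-diffusive data: a
quadratic is fitted alongside, and the fit is flagged nonlinear when the
quadratic term is both large relative to the slope (> 0.2 over the window
span) and statistically significant (> 4 standard errors). Ballistic
input trips the flag; correlated diffusive noise, which shows a few
percent apparent curvature, does not.

## Synthetic-data generator

The generator produces overdamped (position-Langevin) Brownian dynamics:
per step each coordinate receives an independent Gaussian increment of
variance 2D·dt. This matches the Einstein relation exactly at *every*
lag — there is no ballistic regime and no hydrodynamic memory — so short
fit windows are unbiased and carry the least time-averaging noise; tests
exploit this deliberately.

* **free**: independent ions; the exact conductivity equals the NE value.
* **rigid_pair**: each ± pair is a rigid neutral dumbbell. The pair
  centre diffuses with the composite diffusivity D₊D₋/(D₊+D₋) (frictions
  add); the orientation is resampled uniformly on the sphere each frame,
  i.e. the infinite-rotational-diffusion limit. This keeps the bond exact
  to machine precision and makes the rotational MSD contribution a
  constant offset (no slope bias). The dipole is bounded, so σ_EH = 0
  while each ion still diffuses (σ_NE > 0).
* **harmonic_pair**: partners coupled by a zero-rest-length spring k
  (kJ/mol/nm²), integrated by explicit Euler–Maruyama; the dimensionless
  step μk·dt must stay below 0.5 (raised otherwise). The pair separation
  is an Ornstein–Uhlenbeck process with relaxation time
  k_B T/((D₊+D₋)k); on windows short against it the system conducts like
  free ions, on long windows like rigid pairs, and in between
  0 < σ_EH < σ_NE. k = 0 is accepted as an alias of the free mode. The
  spring force needs a temperature to convert k into a drift;
  `SyntheticSpec.temperature` defaults to 298.15 K. Pairs start at the
  tether's equilibrium separation distribution, so the process is
  stationary from frame 0.

Randomness is drawn from the counter-based Philox generator keyed per
(seed, stream-index) with disjoint key spaces for ions and pairs:
changing particle counts or modes never reshuffles another particle's
stream, and a (seed, spec) pair fixes the trajectory bit for bit through
the writers.

What the generator does **not** emulate: electrostatics, hydrodynamic
coupling, solvent structure, inertia, finite-size effects. Passing the
oracle tests therefore demonstrates the *estimators* are correct
(normalisations, unit chains, sampling, limits), not that any force field
is accurate; conclusions about real electrolytes require real
trajectories.

## Benchmark table and known inconsistency

`data/benchmark_tables.csv` transcribes published room-temperature
(298.15 K, 1 bar) conductivities of aqueous NaCl and KCl solutions —
printed densities, viscosities, exact (EH) and NE conductivities with and
without YH corrections, for two independent groups and several system
sizes. `run_benchmark` recomputes the derived columns from the printed
inputs: box edge L = (total mass/ρ)^{1/3}, YH increment, σ_NE+YH and the
0.7-rule estimate. Six rows reproduce their printed σ_NE+YH to within
0.15 S/m (last-digit rounding plus molar-mass/constant choices) and serve
as worked-example targets. One row (Madrid KCl 4 m) does not: under the
stated viscosity and composition the YH increment is ≈ 3.0 S/m, not the
printed gap of 2.6 S/m. The source of that inconsistency is unknown; the
row is kept in the fixture for transparency, flagged `excluded_from_ci`,
and left out of consistency checks. The printed-ratio statistic (t7)
uses all 18 nonzero-molality rows, including that one, since it involves
only printed values.

## Problem sizes in tests

Stochastic validations run at sizes chosen to keep statistical tolerances
honest while the whole suite stays interactive: free-ion conductivity at
200 ions × 2·10⁴ steps (10% tolerance against the analytic value),
diffusivity recovery at 500 particles × 10⁴ steps (3%), rigid-pair and
harmonic-pair confidence intervals from 3–5 replicate seeds. Exact
identities (route equivalence, charge scaling, brute-force equality) are
tested on small randomized trajectories at 1e-10–1e-12 relative
tolerance. All seeds are fixed in the tests.

## Known limitations

* 1:1 electrolytes and orthorhombic (cubic) boxes only.
* Viscosity is a required input for YH corrections, never computed.
* No Green–Kubo (velocity autocorrelation) route; the Einstein–Helfand
  forms are standardized on.
* No NPT support: the volume is one fixed scalar per analysis.
* Replicate scatter is the only supported uncertainty model; single-run
  error bars from OLS are indicative only.
* The 0.7 rule is an empirical convenience with a typical error of
  5–8% on the benchmark systems; results produced with it are flagged
  approximate.
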