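# Methods

## Kinetic model

The cascade is modelled as a fixed-topology mass-action network. Species:
the 5-hydroxymethyl substrate (5hm), the 5-formyl intermediate (5f), its
geminal-diol hydrate (5dhm), the 5-carboxyl product (5ca), the iron(IV)-oxido
oxidant (TM1) and its spent form (TM2). All oxidation steps are elementary
second-order reactions, each consuming one TM1 and releasing one TM2; no
attempt is made to resolve the underlying two-electron chemistry. The
oxidant additionally self-deactivates by a first-order path with rate
constant k_TM (default 1.75·10⁻⁵ s⁻¹, from independent oxidant-decay
measurements).

Three variants of the second oxidation step are provided:

* **DIRECT** — the aldehyde is oxidized (k_f); no hydrate species exists.
* **HYDRATE_ROUTE** — only the hydrate is oxidized (k_dhm), fed through the
  hydration equilibrium `5f + H2O <=> 5dhm`; k_f is forced to zero.
* **DUAL** — both channels are carried. It is retained for completeness but
  flagged as ill-conditioned: from a single experiment, k_f and k_dhm trade
  off almost perfectly through the equilibrium, so the pathway comparison
  never fits them jointly.

Water is held constant at 55.5 mol/L and excluded from the dynamic state;
this convention reproduces the standard relations between K and hydrate
content (K = 4.5·10⁻³ L/mol ↔ 20%, 9.0·10⁻² ↔ 83%). The hydration
equilibrium constant follows the K = k_for/k_rev convention with the forward
rate law first order in water. k_for defaults to 1000 L mol⁻¹ s⁻¹ —
fast enough that equilibration is complete on a sub-second timescale — and
k_rev is always derived as k_for/K, never set independently. For the lowest
K bundled (2.64·10⁻⁵ L/mol), k_rev reaches ≈3.8·10⁷ s⁻¹ while the oxidation
itself evolves over a day: the system spans >10 orders of magnitude in rate
and requires a stiff integrator.

### Numerical integration

`scipy.integrate.solve_ivp` with LSODA (stiffness-switching) at
rtol = 10⁻⁸, atol = 10⁻¹² mol/L. Both conservation laws (total nucleobase;
TM1 + TM2) are linear first integrals of the right-hand side, which
Runge–Kutta and multistep methods preserve to round-off independent of the
tolerance — measured drift is ≲10⁻¹² relative. Small negative excursions
(|x| < 100·atol = 10⁻¹⁰ mol/L) on decaying species are clipped to zero after
integration; anything larger raises an error instead of being silently
truncated.

### Rapid-pre-equilibrium reduction

Because hydration equilibrates orders of magnitude faster than oxidation,
the 5f/5dhm pair can be replaced by a single pool state partitioned
algebraically by the equilibrium hydrate fraction f = K[H₂O]/(1 + K[H₂O]),
with effective oxidation constant k_dhm·f + k_f·(1−f). Reduced and explicit
trajectories agree within 10⁻⁴ relative for every bundled parameter set
(verified in the test suite). The reduced model is non-stiff and is the
default engine inside the fitting loops; the explicit model is the default
for forward simulation and data generation, so fits are never checked
against the same discretization that produced the data.

## Fitting protocol

Observed species are compared to the simulated trajectory on the sample
grid; residuals are normalized by the largest observed concentration
(a single common scale, so the normalization does not affect relative
weighting between species).

* **Step 1** fits the first-step constant k_hm plus a free initial substrate
  concentration against the substrate decay alone. The free initial value
  absorbs the slight spread of effective starting concentrations between
  runs; it is bounded to [0.5, 2]× the first observed point, which also
  excludes a degenerate branch on information-free (flat) data in which a
  large initial excess titrates the oxidant away instantly.
* **Step 2** fixes k_hm and fits the second-step constant (k_f or k_dhm)
  against all tracked nucleobase species except the final acid.
* **Iteration.** The two steps are alternated to a fixed point (relative
  change <10⁻⁶, typically 3–4 rounds). A single pass would bias k_hm by
  about −3%: the second oxidation also consumes oxidant, and the substrate
  decay is coupled to [TM1]. At the fixed point the noiseless recovery of
  the generating constants is exact to the solver tolerance.
* **Exclusions.** Samples with t ≥ 86,400 s are dropped from every objective
  (configurable `t_cut`); at such long times the accumulated signal loss
  makes the measurements unrepresentative. The acid is excluded by default
  because its quantification suffers disproportionately from the work-up;
  both exclusions are recorded explicitly in every `FitResult`.
* **Optimizer.** Bound-constrained trust-region least squares
  (`scipy.optimize.least_squares`, bounds [0, 10⁴] L mol⁻¹ s⁻¹) with three
  log-spaced starts (10⁻², 1, 10²) to guard against local minima, and tight
  termination (ftol = xtol = gtol = 10⁻¹⁴) so recovered constants are
  limited by the data, not the optimizer.
* **Uncertainties.** δk from the linearized Gauss–Newton covariance
  s²(JᵀJ)⁻¹ with s² the residual variance — what COPASI-class tools report.
  A numerically rank-deficient Jacobian (e.g. fitting a second-step constant
  when no intermediate ever forms) flags the fit as non-converged and the
  δk as unavailable rather than returning a number.

**RMSD_tot** is defined as the square root of the mean squared concentration
residual pooled over all included species and non-excluded time points. All
species share the mol/L scale, so no per-species normalization is applied.

**Pathway comparison** fits DIRECT and HYDRATE_ROUTE independently and ranks
them by RMSD_tot; ties at six significant figures go to the variant with the
smaller state space (DIRECT). Per-variant failures are reported in the
ranking rather than aborting it.

**Unresolved-hydrate convention.** When a time course contains no hydrate
column (the hydrate was never spectroscopically resolved), hydrate-aware
fits compare the observed formyl signal against the total formyl pool
(5f + 5dhm) rather than the aldehyde component alone. The two readings
differ by the factor 1−f; the convention only ever applies where f is below
the detection threshold (f ≲ 2%), i.e. where the distinction is smaller than
the integral noise. Without it, a spurious structural residual of order f
contaminates the pathway comparison in the low-hydration regime where the
two routes are physically indistinguishable.

## Synthetic data generator

The generator emulates the statistical structure of quantitative ¹H-NMR
kinetics on this cascade:

* design defaults: 0.2 mM substrate, 1.0 mM oxidant (five-fold excess),
  25 °C label, 12 log-spaced samples in [60 s, 86,400 s] (the experimental
  sampling times are not tabulated in the source data, so the grid is a
  package choice, recorded in the output metadata);
* quantification against a pyrazine internal standard (4 protons) with
  per-species proton multiplicities (5hm: 2, others: 1);
* signal loss as a species-uniform exponential "recovery" factor, default
  rate chosen so that ≈70% of the material is still accounted for at one
  day. Uniform loss preserves species ratios, so the observed hydrate
  fraction remains unbiased while totals decline — matching the observation
  of a constant diol fraction under falling totals. A per-species override
  exists for the acid to emulate its poor work-up recovery (off by default).
  The true magnitude and species dependence of experimental loss are not
  quantified anywhere; these defaults are plausible placeholders.
* multiplicative lognormal noise on each integral (mean-one
  parameterization, default CV 2%), because NMR integral error scales with
  signal;
* a detection floor on the back-converted concentration scale (default
  2·10⁻⁶ mol/L, 1% of substrate) below which values read zero.

What the generator does **not** emulate: lineshapes and chemical shifts
(integral level only), baseline/phasing artefacts, pH- or
temperature-dependent hydration, and any species-specific loss chemistry
beyond the acid override. Passing recovery tests on these synthetics
therefore demonstrates the estimator's self-consistency under the stated
noise model, not the absence of systematic error in real spectra.

## Free-energy correlation

Ordinary least squares of ln k on calculated BDE(C–H) within user-selected
series; R² is the squared Pearson correlation. ln k is always recomputed
from k at full precision — regressing on the rounded two-decimal ln k
column of the bundled table changes R² in the third decimal. Rate constants
in the bundled table that were back-calculated through a hydration
equilibrium rather than measured directly are flagged `inferred`. The
methyl-series records from earlier work ship for context under the
`methyl_prev` tag and are excluded from the headline regressions. For the
formyl-uracil record the average of the direct and indirect measurements
(0.46 L mol⁻¹ s⁻¹) is bundled.

## Problem sizes and determinism

Recovery and discrimination tests run on the 12-point default grid; the
pathway-discrimination study uses 50 seeded noisy replicates, and
uncertainty calibration uses 50 replicates against a closed-form standard
error for pseudo-first-order decay. All randomness flows through
`numpy.random.default_rng` seeds (spawned via `SeedSequence` in batch
studies), so identical inputs and seeds give bit-identical outputs,
including serialized fit reports.

## Known limitations

* The anion speciation of the oxidant ("mixed anion system") has no kinetic
  representation; TM1 is a single species.
* No pH or temperature dependence of the hydration equilibrium.
* No global multi-experiment fitting across substrates and no Bayesian
  posterior sampling; each cascade is fit separately.
* The DUAL variant's two rate constants are not jointly identifiable from a
  single time course; it is reported only with an explicit warning.
* BDE values are consumed as inputs; their computation is out of scope.
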