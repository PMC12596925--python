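# oxcascade

Microkinetic analysis of sequential nucleobase side-chain oxidation by a
TET-biomimetic iron(IV)-oxido complex.

## The problem

Ten-eleven translocation (TET) enzymes erase DNA methylation by stepwise
oxidation of 5-methylcytosine through 5-hydroxymethyl (5hm), 5-formyl (5f)
and 5-carboxyl (5ca) stages. A long-standing mechanistic question for the
second oxidation step is whether the oxidant abstracts hydrogen from the
aldehyde itself or from its geminal-diol hydrate (5dhm), which coexists with
the aldehyde through the hydration equilibrium

```
5f + H2O  <=>  5dhm        K = [5dhm] / ([5f][H2O])   (L/mol)
```

Model experiments replace the enzyme with the iron(IV)-oxido complex
[FeIV(O)(Py5Me2H)]2+ (TM1) and follow the cascade by quantitative 1H NMR.
This package provides the numerical machinery for such experiments:

* **model** — the cascade reaction networks (direct, hydrate-route and dual
  second-step topologies) and their stiff ODE integration, including the
  oxidant's slow first-order self-deactivation (k_TM) and a
  rapid-pre-equilibrium reduction of the hydration step;
* **hydration** — arithmetic between K, hydrate:aldehyde ratios and hydrate
  fractions, f = K[H2O]/(1 + K[H2O]);
* **fitting** — staged nonlinear least-squares estimation of the second-order
  rate constants from time courses, parameter standard deviations from the
  Gauss-Newton covariance, pooled RMSD_tot, and pathway discrimination by
  residual comparison;
* **correlation** — linear free-energy analysis, ln k versus calculated
  BDE(C–H);
* **synthdata** — a generator of NMR-style synthetic time courses (internal
  standard quantification, multiplicative integral noise, progressive signal
  loss, detection floor) so the whole pipeline is testable without any
  external data;
* **io / cli** — CSV/YAML/JSON interfaces, bundled reference tables, and the
  `oxcascade` command-line tool.

The kinetic scheme (second-order oxidation steps, one TM1 consumed per
event; water constant at 55.5 mol/L):

```
TM1            -> TM2                 d[TM1]/dt = -k_TM [TM1] - ...
5hm  + TM1     -> 5f   + TM2          rate = k_hm  [TM1][5hm]
5f   + H2O     <=> 5dhm               k_for [5f][H2O]  /  k_rev [5dhm],  k_rev = k_for/K
5f   + TM1     -> 5ca  + TM2          rate = k_f   [TM1][5f]     (direct route)
5dhm + TM1     -> 5ca  + TM2 + H2O    rate = k_dhm [TM1][5dhm]   (hydrate route)
```

## Worked example

Simulate a noisy 6-aza-uracil-like cascade (high hydration, K = 0.09 L/mol)
and refit its rate constants with the staged protocol:

```python
from oxcascade import RateParameters, build_cascade, fit_staged
from oxcascade.synthdata import ExperimentDesign, NoiseLossModel, generate_timecourse

model = build_cascade(
    "hydrate_route",
    RateParameters(k_TM=1.75e-5, k_hm=1.87, k_dhm=0.24, k_for=1000.0),
    K=9.0e-2,
)
tc, integrals = generate_timecourse(
    model, ExperimentDesign(), NoiseLossModel(integral_cv=0.02), seed=42
)
step1, step2 = fit_staged(tc, "hydrate_route", 1.75e-5, 9.0e-2, oxidant_init=1.0e-3)
print(f"k(5hm -> 5f)  = {step1.value('k_hm'):.3f} +/- {step1.fitted['k_hm'].sd:.3f} L/mol/s")
print(f"k(5dhm -> 5ca) = {step2.value('k_dhm'):.3f} +/- {step2.fitted['k_dhm'].sd:.3f} L/mol/s")
print(f"RMSD_tot = {step2.rmsd_tot:.2e} mol/L over species {step2.included_species}")
```

prints

```
k(5hm -> 5f)  = 1.878 +/- 0.041 L/mol/s
k(5dhm -> 5ca) = 0.245 +/- 0.003 L/mol/s
RMSD_tot = 1.24e-06 mol/L over species ['5hm', '5f', '5dhm']
```

The generating truths (1.87 and 0.24 L mol⁻¹ s⁻¹) are recovered within the
reported uncertainties despite 2% integral noise and a signal recovery that
decays to 70% over the day-long run; RMSD_tot is the pooled per-point
concentration residual of the final fit.

The same operations are available from the shell:

```bash
$ oxcascade hydration --K 9.0e-2
K = 0.09 L/mol
hydrate:aldehyde ratio = 4.995
hydrate content = 83% (0.833194)
[H2O] = 55.5 mol/L

$ oxcascade correlate --series hm
n = 3 (5hmC, 5hmU, 5hm6aU)
slope = -0.0444315 per kJ/mol
intercept = 15.6204
R^2 = 0.997
```

The negative slope is the expected free-energy relationship: weaker C–H
bonds (lower BDE) are oxidized faster, consistent with rate-limiting
hydrogen-atom transfer. Subcommands `synth`, `simulate`, `fit`, `compare`
and `report` cover the rest of the pipeline; see `oxcascade --help`.

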