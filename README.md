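# antcomp

Measuring intra- and interspecific competition coefficients in an ant
community — and modelling why the intraspecific one is bigger.

Competition coefficients are the basic currency of coexistence theory, yet
they are almost never measured for terrestrial animals in the field.
`antcomp` implements a complete analysis pipeline for a study design that
makes the measurement possible in ants: whole colonies of a ground-nesting
ponerine ant (*Diacamma* cf. *indicum*, which nests in bamboo-tube traps and
can be marked individually) are released at mapped field points for one
week and recaptured, while the local density of conspecific and
heterospecific competitors around each release point is recorded from nest
maps and pitfall traps.

## What the package computes

**Colony demography.** From each colony census (marked workers before
release `W1`, marked survivors `W2`, total workers at recapture `W3`, brood
fresh weights `B1..B4` excluding/including cocoons, mean adult weight `M`):

    S  = W2 / W1                                  per-worker survival
    P  = (B2 − B1) / W1                           brood production (mg/worker)
    G  = [(M·W3 + B4) − (M·W1 + B3)] / W1         net colony growth (mg/worker)
    Gw = G / M                                    growth per worker weight

**Density dependence.** Survival is analysed at the individual-worker
level (binomial, colony random intercept, with a *squared* standardized
conspecific colony-density term), brood production and net growth at the
colony level (colony size as offset, study-month random effect), with
downward stepwise AIC model selection, likelihood-ratio term tests, and
Fisher's combined test across heterospecific species.

**Lotka–Volterra coefficients.** Regressing `Gw` on standardized con- and
heterospecific densities reads off the competition coefficients of
`(1/N_i) dN_i/dt = r_i (1 − α_ii N_i − α_ij N_j)`; the intra/inter ratio is
the quantity of interest for stable coexistence (coexistence requires
intraspecific competition to exceed interspecific competition).

**Theory.** Two small models explain how a dominant exploitative competitor
can still coexist with subordinates:

* `coexistence`: a chemostat consumer–resource community in which the
  dominant (lowest-`R*`) species suffers conspecific density-dependent
  excess mortality `δ N^θ` (interference, e.g. territorial fighting).
  Below a closed-form `δ_crit` the dominant excludes everyone; above it a
  feasible, locally stable interior equilibrium appears.
* `aggression`: an inclusive-fitness decision model for a worker meeting a
  conspecific alien at distance `d` from its nest. Fighting pays iff
  `p(d)·q·r_b·V > μ·v_w`, which makes aggression a step function of
  distance with threshold `d* = (1/λ) ln(p0 q r_b V / (μ v_w))`.

A synthetic field-experiment generator (`antcomp.synthetic`) produces
complete censuses, pitfall tables and nest counts with known ground-truth
effect sizes, so every inference stage can be validated by parameter
recovery.

## Worked example

```python
from antcomp.synthetic import TrueParameters, generate_experiment, generate_growth_table
from antcomp.pipeline import prepare_analysis_table, survival_model_spec
from antcomp.inference import stepwise_aic, estimate_lv

exp = generate_experiment(n_colonies=500, truth=TrueParameters(), seed=42)
table = prepare_analysis_table(exp.censuses, exp.densities)

selected, fit, path = stepwise_aic(survival_model_spec(), table)
print("selected survival terms:", selected.terms)
for term in selected.terms:
    print(f"  {term:16s} {fit.coefficients[term]:+.3f} "
          f"(SE {fit.standard_errors[term]:.3f})")

lv = estimate_lv(generate_growth_table(500, TrueParameters(), seed=43))
print(f"alpha_intra = {lv.alpha_ii_std:.4f}, alpha_inter = {lv.alpha_ij_std:.4f}, "
      f"ratio = {lv.ratio:.2f}")
```

prints

```
selected survival terms: ('z_nest', 'z_nest^2', 'z_het', 'z_nest^2:z_het')
  z_nest           +0.080 (SE 0.040)
  z_nest^2         -0.332 (SE 0.023)
  z_het            +0.063 (SE 0.030)
  z_nest^2:z_het   +0.335 (SE 0.023)
alpha_intra = -0.0615, alpha_inter = -0.0139, ratio = 4.43
```

The stepwise-selected survival model keeps the squared conspecific
colony-density term (strongly negative: survival drops at an accelerating
rate as conspecific neighbours accumulate) and its positive interaction
with heterospecific biomass, close to the generating values (−0.29 and
+0.30). The standardized Lotka–Volterra slopes recover the generating
−0.06 / −0.013, i.e. intraspecific competition roughly 4–5 times the
interspecific one.

The same steps are available from the shell:

```sh
antcomp simulate --n 500 --seed 42 --out data/
antcomp demography --data data/ --out rates.csv
antcomp fit-density --data data/ --response survival --out survival.json
antcomp fit-lv --data data/ --out lv.json
antcomp coexist --config coexist.yaml --out coexist.json
antcomp aggression --config aggression.yaml --out profile.csv
```

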