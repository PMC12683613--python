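# Methods

This note records the models implemented in `antcomp`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter for reproducing results.

## Demographic estimators

A census of one released colony carries worker counts (`W1` marked before
release, `W2` marked survivors at recapture, `W3` all workers at recapture
including newly emerged ones) and brood fresh weights in mg. Cocoons are
book-kept separately because pre-release cocoons are destined to emerge
rather than to grow: `B1` excludes cocoons, `B2` includes newly pupated
ones, `B3`/`B4` include all cocoons before/after. The four weekly rates —
survival `S = W2/W1`, brood production `P = (B2−B1)/W1`, net colony growth
`G = [(M·W3+B4) − (M·W1+B3)]/W1` and its per-weight form `Gw = G/M` — are
pure functions of a census; all weights are carried in mg (instrument
precision 0.01 mg) and counts as exact integers. Censuses violating the
bookkeeping invariants (`W2 > W1`, negative weights, `B3 < B1`) are
rejected at load time with row-level diagnostics rather than dropped
silently.

Local competitor pressure around a release point is summarised by (a) the
number of conspecific nests present within a 5-m radius on *every* day of
the 7-day window (set intersection across daily observations; both radius
and window are configurable), and (b) per-species pitfall biomass proxies,
trapped count × mean wet weight per individual, with the heterospecific
total summed over the designated six non-focal species.

## Density-dependence models

* **Survival** is modelled at the individual-worker level: recaptured-or-not
  as a binomial outcome with a colony-level Gaussian random intercept.
  Because the data suggest an accelerating decline of survival with
  conspecific crowding, the conspecific colony-density predictor enters
  squared, alongside its linear term, heterospecific biomass, colony size,
  and interactions in the full model.
* **Brood production and net growth** are colony-level Gaussian models with
  a study-month random intercept and colony size `W1` as offset.

**Offset semantics.** An identity-link "offset" is ill-defined for a weight
response, so the default mode divides the absolute response by `W1` and fits
the per-worker response directly (this matches the axes on which such data
are usually plotted and the per-worker scale of the reported coefficients).
A `log_offset` mode (log-link Gaussian GLM with `log W1` offset) is
available behind a flag for users who prefer the multiplicative reading;
neither mode is asserted to be uniquely correct.

**Standardization.** All explanatory variables are z-scored (n−1
denominator) on the analysis sample after any filtering; squared and
interaction columns are built *from the standardized columns*, so the
quadratic density term is z² and coefficients are per-SD effects.

**Estimation.** OLS/WLS and binomial IRLS are implemented in-package and
verified against normal-equations and likelihood-grid oracles. The
random-intercept logistic model is fitted by maximum likelihood with
*adaptive* Gauss–Hermite quadrature (25 nodes, centred at each cluster's
conditional mode and scaled by the local curvature). Adaptivity matters
here: whole colonies make binomial denominators of 30–300, so each
cluster's integrand is much narrower than the random-effect scale and
fixed-node quadrature visibly underestimates the sampling variance.
Standard errors come from the inverse numerical Hessian of the marginal
log-likelihood. The Gaussian random-intercept (month) models are delegated
to `statsmodels.MixedLM`, fitted by ML (not REML) so AIC values are
comparable across fixed-effect structures; if the default optimizer fails
or returns a non-finite likelihood, BFGS and Powell are tried in turn.
Complete separation in the logistic model (perfect classification,
log-likelihood numerically zero, or diverging estimates) raises an error
instead of returning a degenerate fit.

**Stepwise selection.** Downward stepwise on AIC: repeatedly drop the
single term whose removal lowers AIC most, until no removal lowers AIC.
Marginality is respected — a main effect cannot be dropped while an
interaction containing it remains — but a squared term carries no such
guard for its linear part, so the quadratic density effect may survive
alone (this configuration does occur in practice and is the scientifically
interesting one). AIC ties (Δ < 1e-9) are broken by dropping the later term
in the declared ordering; the full visited-model path is logged.
Term-level tests are χ² likelihood-ratio tests (df = 1); no
multiple-testing correction is applied except Fisher's combined test
(−2Σln p ~ χ²(2k)) for the joint heterospecific-species effect.

**Lotka–Volterra coefficients.** `estimate_lv` regresses `Gw` on the
standardized conspecific metric (persistent nest count by default, pitfall
worker biomass as the alternative) and standardized heterospecific biomass,
by plain OLS — the growth regression is a colony-level linear model with no
random effect, the simplest reading of a linear-model fit for this step.
The standardized slopes are reported as the competition coefficients
(negative = suppressive) together with their intra/inter ratio; raw-scale
`α` values are also derived via `Gw = r_i(1 − α_ii N_i − α_ij N_j)`, i.e.
`α = −slope_raw / r_i`. The standardized slopes are invariant to affine
rescaling of the raw predictor units.

## Synthetic-data generator

The generator emulates the field design: colonies of 30–300 workers
released for one week over three month blocks, six heterospecific species,
pitfall counts and nest counts drawn per colony. Its three response models
are exactly the structures the inference stage assumes:

* survival — per-worker Bernoulli with colony random intercept (SD 0.5)
  and logit-scale effects −0.29·z_nest², +0.10·z_het, +0.30·z_nest²·z_het
  around intercept 1.5;
* brood — per-worker brood change 0.5 − 0.36·z_conbio − 0.29·z_het
  − 0.29·z_conbio·z_het mg/worker/week, month random effect SD 0.2, noise
  SD 0.5;
* growth — `Gw = 0.10 − 0.06·z_nest − 0.013·z_het` (+ noise SD 0.05),
  generated directly for the Lotka–Volterra recovery route, since in the
  census-bookkeeping route `Gw` is a composite of survival, brood and
  emergence rather than an independently settable response.

Effect sizes are defined on the realized-sample standardized scale — the
same scale on which fits report them — so recovery is a direct comparison;
`truth_to_standardized` re-derives the standardization from the generated
tables and returns the coefficients an unbiased fit should recover.

Field quantities whose distributions are not dictated by any response
model are drawn from documented defaults chosen for plausibility: nest
counts Poisson-gamma with mean 2; pitfall counts per species Poisson-gamma
(gamma shape 1.5, right-skewed) with means 30 (focal, mean wet weight
10 mg) and 80 (each heterospecific species, weights 0.10–1.10 mg); brood
baseline ~3 mg/worker eggs+larvae plus ~1 mg/worker cocoons; emergence
0.05 workers per cocoon-mg per week, capped by the available cocoon mass.
These only set predictor spread and test power.

Brood weights are floored at zero when a large negative draw would exceed
the standing brood; floored colonies are flagged (`clamped_ids`) so
analyses can exclude them — the floored response no longer follows the
linear generating model, and leaving such colonies in biases the
interaction coefficient toward zero. Typically ~0.7% of colonies are
flagged at the default effect sizes.

What the generator does **not** emulate: spatially explicit foraging,
heterospecific colony dynamics, detection failure in recapture, colony
budding/fusion, or any dependence of predictors on the focal colony
itself. Passing recovery tests therefore show that the estimators are
correct for the assumed response structure, not that real field data meet
those assumptions.

## Consumer–resource coexistence model

The community is a chemostat: `dR/dt = D(S_supply − R) − Σ c_i f_i(R) N_i`,
`dN_i/dt = N_i [g_i f_i(R) − m_i − δ_i N_i^θ_i]`, with Monod uptake
`f(R) = R/(K+R)` by default and a linear mode (`f(R) = R`) behind a flag;
the exponent θ (default 1) lets the conspecific excess mortality
accelerate. These functional forms are this package's reconstruction of
the standard exploitative-competition-with-interference setup; quantitative
agreement with any particular published figure is not claimed, only the
qualitative exclusion-to-coexistence switch. `R*` (Monod: `mK/(g−m)`) is
the minimum resource requirement; with all δ = 0 the lowest-`R*` species
excludes the rest. With δ₁ > 0 on the dominant and θ = 1 the interior
equilibrium is closed-form (`R̂ = R*₂`, `N̂₁ = (g₁f₁(R̂) − m₁)/δ₁`, `N̂₂`
from the resource balance) and becomes feasible exactly at
`δ_crit = c₁ f₁(R*₂)(g₁ f₁(R*₂) − m₁)/(D(S_supply − R*₂))`; the sweep
routine confirms the boundary by bisection on the joint
feasible-and-stable predicate using numerical Jacobian eigenvalues.

Numerics: LSODA with rtol 1e-8 / atol 1e-10; extinction threshold 1e-6 ×
initial density; stability tolerance 1e-8 on eigenvalue real parts;
densities below the absolute tolerance are clipped to zero, larger
negativity is treated as a solver failure. Outcomes where the trajectory
has not settled, or where an eigenvalue's real part sits within tolerance
of zero (e.g. the neutral line of two identical species), are reported
with the label withheld and a reason, never as coexistence. Time is in
weeks to match the field experiment's census interval; the unit is purely
conventional.

## Aggression model

A worker meeting a conspecific alien at distance `d` from its nest
compares two expected inclusive-fitness outcomes. Avoiding loses the
defended resources (value `V`, devalued by relatedness `r_b` to the brood)
whenever the alien would steal or usurp, probability `p(d)`; fighting
repels the alien with probability `q` but kills the worker (residual value
`v_w`) with probability `μ`. The net gain of fighting is
`p(d)·q·r_b·V − μ·v_w`, so with `p(d) = p0·e^{−λd}` (exponential decay is
a documented choice; a normalised logistic form is available behind a
flag) the optimal rule is a step: fight for `d < d*`,
`d* = (1/λ)·ln(p0 q r_b V/(μ v_w))` clamped to [0, ∞). Ties resolve to
avoid — the risk-free default, and a measure-zero event. Heterospecific
encounters are modelled by zeroing the stealable value `V` (other species
cannot exploit this ant's brood or nest as social resources), which makes
avoidance optimal everywhere and reproduces the observed contrast between
violent conspecific and mild heterospecific encounters. With plausible
magnitudes (resource value an order of magnitude above a worker's residual
value, moderate death risk, λ ≈ 1/m) the threshold falls near 2–3 m,
consistent with the observed few-metre defense radius; this calibration is
a demonstration, not a fitted result.

## Test and script problem sizes

Parameter-recovery checks run 100 replicate experiments of 500 colonies
(survival GLMM and brood LMM, each coefficient within 3 SE in ≥95% of
replicates); the estimator-bias check uses 1000 replicates of the cheap
growth/OLS route because at 100 replicates the Monte-Carlo error of a bias
estimate equals the 10%-of-SD criterion being tested; the null-calibration
check uses 1500 replicates of 60 colonies. The acceptance script runs one
500-colony experiment per seed for the survival/brood fits and a
5000-colony direct growth table for the Lotka–Volterra route, since the
intra/inter ratio is a quotient of two noisy slopes and needs the larger
sample for a stable value. These sizes were chosen so the full suite
completes in well under a minute of simulation time while keeping
Monte-Carlo noise far from the asserted margins.

## Known limitations

* The colony-level brood/growth models are unweighted in per-worker form;
  if per-worker noise scaled as 1/√W1 (count-like), weights ∝ W1 would be
  more efficient. The generator's noise is homoskedastic per colony, so
  the unweighted fit is the matched estimator here.
* Month random effects are estimated from only three levels, as in the
  field design; the variance component is poorly identified (often
  estimated at zero) but fixed-effect estimates and SEs are unaffected in
  the fitted ML parameterisation.
* The stepwise procedure is deterministic given data and term ordering,
  but AIC selection itself is noisy at field sample sizes; the selected
  model should be read together with the logged AIC path.
* Species-by-species heterospecific models are supported through the
  generic single-predictor machinery; no curated per-species defaults ship
  as code.
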