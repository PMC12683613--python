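"""Synthetic field experiments with known ground truth.

Generates complete mark-release-recapture experiments — colony censuses,
pitfall-trap species counts, and persistent nest counts — whose responses
follow exactly the statistical structure the inference stage assumes:

* per-worker survival: independent Bernoulli draws with a colony-level
  Gaussian random intercept and, on the logit scale, a *squared*
  standardized conspecific-colony-density effect, a standardized
  heterospecific-biomass effect, and their interaction;
* colony brood production: per-worker brood-weight change linear in
  standardized con-/heterospecific pitfall biomass with an interaction, a
  study-month random effect, and Gaussian noise;
* per-worker-weight net growth: linear in standardized conspecific colony
  density and heterospecific biomass (a direct generator for the
  Lotka-Volterra recovery route).

Effect coefficients are specified on the realized-sample standardized scale
— the scale on which the fits report them — so an unbiased fit recovers a
generating coefficient directly.  Nest counts are Poisson-gamma (negative
binomial-like); pitfall counts per species are likewise overdispersed, and
biomasses follow as count x species mean wet weight, so they are
non-negative and right-skewed.  Defaults mirror the field study's design:
colonies of 30-300 workers, one-week releases over three months, six
heterospecific species.

Cocoon bookkeeping: the cocoon compartment is tracked separately, so brood
weight before release excludes cocoons (``B1``) or includes them (``B3``),
and at recapture includes newly pupated cocoons (``B2``) or all cocoons
(``B4``).  New adults emerge from the pre-release cocoon mass at
``emergence_rate`` workers per cocoon-mg per week.  Colonies whose brood
weight had to be floored at zero are flagged so tests can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .demography import ColonyCensus, LocalDensity

__all__ = [
    "DensityModel",
    "TrueParameters",
    "SyntheticExperiment",
    "generate_experiment",
    "generate_growth_table",
    "truth_to_standardized",
    "DEFAULT_SPECIES_WEIGHTS",
    "FOCAL_SPECIES",
]

FOCAL_SPECIES = "Diacamma_cf_indicum"

#: Mean wet weight per individual (mg) of the focal species and the six
#: most abundant heterospecific species at the site (synthetic defaults).
DEFAULT_SPECIES_WEIGHTS: dict[str, float] = {
    FOCAL_SPECIES: 10.0,
    "Anoplolepis_gracilipes": 1.10,
    "Tetramorium_bicarinatum": 0.60,
    "Pheidole_parva": 0.15,
    "Monomorium_chinense": 0.10,
    "Nylanderia_ryukyuensis": 0.20,
    "Ochetellus_glaber": 0.25,
}


@dataclass(frozen=True)
class DensityModel:
    """Distributions of local competitor densities around a release point.

    Nest counts are Poisson with a gamma-distributed mean (negative
    binomial); pitfall counts per species likewise.  ``dispersion`` is the
    gamma shape — smaller means more right-skewed.
    """

    nest_mean: float = 2.0
    con_count_mean: float = 30.0     # focal-species workers per trap set
    het_count_mean: float = 80.0     # per heterospecific species
    dispersion: float = 1.5

    def __post_init__(self) -> None:
        for name in ("nest_mean", "con_count_mean", "het_count_mean",
                     "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"density_model.{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters; effect coefficients on the standardized scale.

    Survival effects are logit-scale per SD of the (squared) predictor;
    brood effects are mg per worker per week per SD; growth effects are
    per-worker-weight growth (dimensionless/week) per SD.  Defaults are the
    study-condition values: brood −0.36 (conspecific biomass), −0.29
    (heterospecific biomass), −0.29 (interaction); survival −0.29 (squared
    conspecific colony density), +0.10 (heterospecific main effect), +0.30
    (interaction); growth slopes −0.06 / −0.013.
    """

    survival_intercept: float = 1.5
    survival_beta_cd2: float = -0.29
    survival_beta_het: float = 0.10
    survival_beta_cd2_x_het: float = 0.30
    colony_random_sd: float = 0.5
    brood_intercept: float = 0.5
    brood_beta_con: float = -0.36
    brood_beta_het: float = -0.29
    brood_beta_int: float = -0.29
    brood_noise_sd: float = 0.5
    month_random_sd: float = 0.2
    growth_intercept: float = 0.10
    growth_alpha_con: float = -0.06
    growth_alpha_het: float = -0.013
    growth_noise_sd: float = 0.05
    mean_adult_weight: float = 10.0
    emergence_rate: float = 0.05     # emerged workers per cocoon-mg per week
    n_months: int = 3
    density_model: DensityModel = field(default_factory=DensityModel)

    def __post_init__(self) -> None:
        for name in ("colony_random_sd", "brood_noise_sd", "month_random_sd",
                     "growth_noise_sd", "emergence_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.mean_adult_weight <= 0:
            raise ValueError(
                f"mean_adult_weight must be > 0, got {self.mean_adult_weight}")
        if self.n_months < 1:
            raise ValueError(f"n_months must be >= 1, got {self.n_months}")


@dataclass
class SyntheticExperiment:
    """One generated experiment plus its ground truth and audit trail."""

    censuses: list[ColonyCensus]
    densities: list[LocalDensity]
    truth: TrueParameters
    seed: int
    pitfall_counts: pd.DataFrame       # colony_id, species, count
    species_weights: dict[str, float]
    clamped_ids: list[str]             # colonies whose B2 was floored at 0
    designs: dict[str, pd.DataFrame]   # standardized design tables used


def _safe_z(x: np.ndarray) -> np.ndarray:
    """z-score; all-zero when the vector is constant or a single value."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _nb_counts(rng: np.random.Generator, mean: float, shape: float,
               n: int) -> np.ndarray:
    """Poisson-gamma (negative binomial) counts with the given mean."""
    lam = rng.gamma(shape, mean / shape, size=n)
    return rng.poisson(lam)


def generate_experiment(n_colonies: int, truth: TrueParameters = TrueParameters(),
                        seed: int = 0) -> SyntheticExperiment:
    """Generate a complete synthetic release-recapture experiment.

    Regeneration with the same seed and parameters is bit-for-bit identical.
    """
    if n_colonies < 1:
        raise ValueError(f"n_colonies must be >= 1, got {n_colonies}")
    rng = np.random.default_rng(seed)
    dm = truth.density_model
    het_species = [s for s in DEFAULT_SPECIES_WEIGHTS if s != FOCAL_SPECIES]
    ids = [f"C{i + 1:04d}" for i in range(n_colonies)]

    W1 = rng.integers(30, 301, size=n_colonies)
    month_of = np.minimum(np.arange(n_colonies) * truth.n_months // n_colonies,
                          truth.n_months - 1)
    month_labels = [f"month-{m + 1:02d}" for m in month_of]
    month_effects = rng.normal(0.0, truth.month_random_sd, size=truth.n_months)

    nest_counts = _nb_counts(rng, dm.nest_mean, dm.dispersion, n_colonies)
    counts = {FOCAL_SPECIES: _nb_counts(rng, dm.con_count_mean, dm.dispersion,
                                        n_colonies)}
    for sp in het_species:
        counts[sp] = _nb_counts(rng, dm.het_count_mean, dm.dispersion,
                                n_colonies)
    biomass = {sp: counts[sp] * DEFAULT_SPECIES_WEIGHTS[sp] for sp in counts}
    het_total = sum(biomass[sp] for sp in het_species)

    # standardized predictors, computed on the realized sample: the scale on
    # which both the generating coefficients and the fits are expressed
    z_nest = _safe_z(nest_counts)
    z_conbio = _safe_z(biomass[FOCAL_SPECIES])
    z_het = _safe_z(het_total)

    # --- per-worker survival (individual Bernoulli -> binomial by colony) --
    u_colony = rng.normal(0.0, truth.colony_random_sd, size=n_colonies)
    logit_p = (truth.survival_intercept
               + truth.survival_beta_cd2 * z_nest ** 2
               + truth.survival_beta_het * z_het
               + truth.survival_beta_cd2_x_het * z_nest ** 2 * z_het
               + u_colony)
    W2 = rng.binomial(W1, expit(logit_p))

    # --- brood compartments -----------------------------------------------
    B1 = W1 * rng.gamma(5.0, 0.6, size=n_colonies)       # eggs+larvae, mg
    C1 = W1 * rng.gamma(2.0, 0.5, size=n_colonies)       # cocoons, mg
    P = (truth.brood_intercept
         + truth.brood_beta_con * z_conbio
         + truth.brood_beta_het * z_het
         + truth.brood_beta_int * z_conbio * z_het
         + month_effects[month_of]
         + rng.normal(0.0, truth.brood_noise_sd, size=n_colonies))
    B2_raw = B1 + W1 * P
    clamped = B2_raw < 0
    B2 = np.maximum(B2_raw, 0.0)

    # --- emergence from the pre-release cocoon mass ------------------------
    unit = truth.mean_adult_weight
    max_emerge = np.floor(C1 / unit).astype(int)
    emerged = np.minimum(rng.poisson(truth.emergence_rate * C1), max_emerge)
    C2 = C1 - emerged * unit
    W3 = W2 + emerged
    M = np.clip(rng.normal(truth.mean_adult_weight,
                           0.02 * truth.mean_adult_weight, size=n_colonies),
                0.5 * truth.mean_adult_weight, None)

    # round compartments to instrument precision (0.01 mg) first, then form
    # the sums from the rounded parts so B3 >= B1 and B4 >= B2 survive rounding
    B1r = np.round(B1, 2)
    C1r = np.round(C1, 2)
    B2r = np.round(B2, 2)
    C2r = np.round(C2, 2)
    censuses = [
        ColonyCensus(ids[i], month_labels[i], int(W1[i]), int(W2[i]),
                     int(W3[i]), float(B1r[i]), float(B2r[i]),
                     round(float(B1r[i] + C1r[i]), 2),
                     round(float(B2r[i] + C2r[i]), 2),
                     round(float(M[i]), 2))
        for i in range(n_colonies)
    ]
    densities = [
        LocalDensity(ids[i], int(nest_counts[i]),
                     {sp: float(biomass[sp][i]) for sp in het_species},
                     float(biomass[FOCAL_SPECIES][i]))
        for i in range(n_colonies)
    ]
    pitfall = pd.DataFrame(
        [(ids[i], sp, int(counts[sp][i]))
         for i in range(n_colonies) for sp in counts],
        columns=["colony_id", "species", "count"],
    )
    designs = {
        "survival": pd.DataFrame({
            "colony_id": ids,
            "z_nest^2": z_nest ** 2,
            "z_het": z_het,
            "z_nest^2:z_het": z_nest ** 2 * z_het,
        }),
        "brood": pd.DataFrame({
            "colony_id": ids,
            "z_conbio": z_conbio,
            "z_het": z_het,
            "z_conbio:z_het": z_conbio * z_het,
        }),
    }
    return SyntheticExperiment(
        censuses=censuses, densities=densities, truth=truth, seed=seed,
        pitfall_counts=pitfall, species_weights=dict(DEFAULT_SPECIES_WEIGHTS),
        clamped_ids=[ids[i] for i in np.nonzero(clamped)[0]],
        designs=designs,
    )


def generate_growth_table(n_colonies: int,
                          truth: TrueParameters = TrueParameters(),
                          seed: int = 0,
                          noise_sd: Optional[float] = None) -> pd.DataFrame:
    """Per-colony growth table generated directly from the linear model.

    Per-worker-weight net growth ``Gw`` is drawn as
    ``growth_intercept + alpha_con * z(nest count) + alpha_het * z(het
    biomass) + noise``, bypassing the census bookkeeping.  This is the
    matched generator for Lotka-Volterra coefficient recovery; set
    ``noise_sd=0`` for a noise-free table.
    """
    if n_colonies < 3:
        raise ValueError(f"n_colonies must be >= 3, got {n_colonies}")
    rng = np.random.default_rng(seed)
    dm = truth.density_model
    het_species = [s for s in DEFAULT_SPECIES_WEIGHTS if s != FOCAL_SPECIES]
    nest_counts = _nb_counts(rng, dm.nest_mean, dm.dispersion, n_colonies)
    con_bio = (_nb_counts(rng, dm.con_count_mean, dm.dispersion, n_colonies)
               * DEFAULT_SPECIES_WEIGHTS[FOCAL_SPECIES])
    het_total = sum(
        _nb_counts(rng, dm.het_count_mean, dm.dispersion, n_colonies)
        * DEFAULT_SPECIES_WEIGHTS[sp] for sp in het_species)
    sd = truth.growth_noise_sd if noise_sd is None else noise_sd
    gw = (truth.growth_intercept
          + truth.growth_alpha_con * _safe_z(nest_counts)
          + truth.growth_alpha_het * _safe_z(het_total)
          + rng.normal(0.0, sd, size=n_colonies))
    return pd.DataFrame({
        "colony_id": [f"C{i + 1:04d}" for i in range(n_colonies)],
        "conspecific_nest_count": nest_counts,
        "conspecific_worker_biomass": con_bio,
        "heterospecific_total_biomass": het_total,
        "Gw": gw,
    })


def truth_to_standardized(truth: TrueParameters,
                          experiment: SyntheticExperiment
                          ) -> dict[str, dict[str, float]]:
    """Map generating coefficients onto the standardized-predictor scale.

    Recomputes the standardization from the experiment's realized density
    tables and checks it reproduces the design the generator used (they must
    agree because effects are defined on the realized-sample z scale); the
    returned values are the coefficients an unbiased fit should recover.
    """
    if experiment.truth != truth:
        raise ValueError("experiment was not generated from these parameters")
    nest = np.array([d.conspecific_nest_count for d in experiment.densities],
                    dtype=float)
    conbio = np.array([d.conspecific_worker_biomass
                       for d in experiment.densities])
    het = np.array([d.heterospecific_total_biomass
                    for d in experiment.densities])
    z_nest, z_conbio, z_het = _safe_z(nest), _safe_z(conbio), _safe_z(het)
    stored = experiment.designs["survival"]
    if not (np.allclose(stored["z_nest^2"], z_nest ** 2, atol=1e-10)
            and np.allclose(stored["z_het"], z_het, atol=1e-10)):
        raise ValueError("realized tables do not reproduce the generator's "
                         "standardized design")
    return {
        "survival": {
            "z_nest^2": truth.survival_beta_cd2,
            "z_het": truth.survival_beta_het,
            "z_nest^2:z_het": truth.survival_beta_cd2_x_het,
        },
        "brood": {
            "z_conbio": truth.brood_beta_con,
            "z_het": truth.brood_beta_het,
            "z_conbio:z_het": truth.brood_beta_int,
        },
        "growth": {
            "z_nest": truth.growth_alpha_con,
            "z_het": truth.growth_alpha_het,
        },
    }
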