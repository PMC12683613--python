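"""Assembly of the field analysis: tidy table construction and model menus.

Glue between the demography estimators and the inference machinery: builds
the per-colony analysis table with standardized predictor columns, and
declares the full models from which downward stepwise AIC selection starts
for each response.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from .demography import ColonyCensus, LocalDensity, rates_table
from .inference import ModelSpec, standardize

__all__ = [
    "prepare_analysis_table",
    "survival_model_spec",
    "brood_model_spec",
    "growth_model_spec",
]

_Z_MAP = {
    "W1": "z_W1",
    "conspecific_nest_count": "z_nest",
    "conspecific_worker_biomass": "z_conbio",
    "heterospecific_total_biomass": "z_het",
}


def prepare_analysis_table(censuses: Iterable[ColonyCensus],
                           densities: Iterable[LocalDensity]) -> pd.DataFrame:
    """Per-colony table with rates, absolute responses and z-scored predictors.

    Standardization happens here, on the analysis sample; squared and
    interaction columns are later built from these z columns by the design
    builder, so a quadratic density term is z².
    """
    df = rates_table(censuses, densities)
    df["brood_abs"] = df["P"] * df["W1"]    # B2 − B1
    df["growth_abs"] = df["G"] * df["W1"]
    for col, zcol in _Z_MAP.items():
        df[zcol] = standardize(df[col].to_numpy())
    return df


def survival_model_spec() -> ModelSpec:
    """Full worker-survival model: individual recapture as binomial outcome.

    Fixed effects: colony size, linear and squared conspecific colony
    density, heterospecific biomass, and the density x biomass interactions;
    colony identity as random intercept.  Stepwise selection may retain the
    squared density term without its linear part.
    """
    return ModelSpec(
        response=("W2", "W1"),
        terms=("z_W1", "z_nest", "z_nest^2", "z_het",
               "z_nest:z_het", "z_nest^2:z_het"),
        family="binomial",
        random="colony_id",
    )


def brood_model_spec(link_mode: str = "per_worker") -> ModelSpec:
    """Full brood-production model: B2 − B1 with colony size as offset,
    con-/heterospecific pitfall biomass and their interaction, month random
    effect."""
    return ModelSpec(
        response="brood_abs",
        terms=("z_conbio", "z_het", "z_conbio:z_het"),
        family="gaussian",
        random="month",
        offset="W1",
        link_mode=link_mode,
    )


def growth_model_spec(link_mode: str = "per_worker") -> ModelSpec:
    """Full net-colony-growth model: conspecific colony density and
    heterospecific biomass with interaction, colony size as offset, month
    random effect."""
    return ModelSpec(
        response="growth_abs",
        terms=("z_nest", "z_het", "z_nest:z_het"),
        family="gaussian",
        random="month",
        offset="W1",
        link_mode=link_mode,
    )
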