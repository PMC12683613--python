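"""Colony-level demographic estimators and local-density metrics.

A whole ant colony is marked, released in the field for one week, and
recaptured.  The census bookkeeping distinguishes marked workers present
before release (``W1``) from marked survivors at recapture (``W2``) and from
the total worker count at recapture including newly emerged adults (``W3``).
Brood fresh weights are recorded both excluding and including cocoons, because
cocoons present before release are destined to emerge rather than to grow:

* ``B1`` — eggs + larvae before release (cocoons excluded),
* ``B2`` — eggs + larvae + *newly pupated* cocoons at recapture,
* ``B3`` — eggs + larvae + cocoons before release,
* ``B4`` — eggs + larvae + all cocoons at recapture.

From one census three weekly per-worker rates follow:

* survival            ``S  = W2 / W1``
* brood production    ``P  = (B2 - B1) / W1``            [mg / worker]
* net colony growth   ``G  = ((M*W3 + B4) - (M*W1 + B3)) / W1``   [mg / worker]

where ``M`` is the mean fresh weight of an adult.  ``G / M`` is the
dimensionless per-worker-weight growth rate used for Lotka-Volterra
coefficient estimation.

Local competitor density around a release point is summarised two ways:
persistent conspecific nest counts within a fixed radius (nests present on
every observation day), and per-species worker biomass proxies from pitfall
traps (trapped count x mean wet weight per individual).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CensusError",
    "ColonyCensus",
    "DemographicRates",
    "LocalDensity",
    "per_worker_survival",
    "brood_production",
    "net_colony_growth",
    "per_worker_weight_growth",
    "demographic_rates",
    "pitfall_biomass",
    "persistent_nest_count",
    "rates_table",
]

#: Default observation window (days) for persistent nest counts.
DEFAULT_WINDOW_DAYS = 7
#: Default radius (m) of the local-density neighbourhood (the foraging zone).
DEFAULT_RADIUS_M = 5.0


class CensusError(ValueError):
    """A colony census violates a bookkeeping invariant."""


@dataclass(frozen=True)
class ColonyCensus:
    """One released colony's before/after counts and brood weights.

    Counts are exact integers; weights are fresh weights in mg.
    """

    colony_id: str
    month: str
    W1: int
    W2: int
    W3: int
    B1: float
    B2: float
    B3: float
    B4: float
    M: float

    def __post_init__(self) -> None:
        errs = []
        if self.W1 < 1:
            errs.append(f"W1 must be >= 1, got {self.W1}")
        if not 0 <= self.W2 <= self.W1:
            errs.append(
                f"W2 must satisfy 0 <= W2 <= W1 (marked workers cannot be "
                f"gained), got W2={self.W2}, W1={self.W1}"
            )
        if self.W3 < self.W2:
            errs.append(f"W3 must be >= W2, got W3={self.W3}, W2={self.W2}")
        for name in ("B1", "B2", "B3", "B4"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.B3 < self.B1:
            errs.append(
                f"B3 (brood incl. cocoons) must be >= B1, got B3={self.B3}, "
                f"B1={self.B1}"
            )
        if self.M <= 0:
            errs.append(f"M (mean adult weight) must be > 0, got {self.M}")
        if errs:
            raise CensusError(
                f"census {self.colony_id!r}: " + "; ".join(errs)
            )


@dataclass(frozen=True)
class DemographicRates:
    """Weekly per-worker rates derived from one census."""

    colony_id: str
    S: float   # survival probability, in [0, 1]
    P: float   # brood production, mg/worker
    G: float   # net colony growth, mg/worker
    Gw: float  # net colony growth per worker weight, dimensionless


@dataclass(frozen=True)
class LocalDensity:
    """Competitor density around one release point.

    ``species_biomass`` maps heterospecific species names to pitfall biomass
    (mg); the heterospecific total is their sum and is recomputed rather than
    stored, so it cannot fall out of sync.
    """

    colony_id: str
    conspecific_nest_count: int
    species_biomass: Mapping[str, float] = field(default_factory=dict)
    conspecific_worker_biomass: float = 0.0

    def __post_init__(self) -> None:
        if self.conspecific_nest_count < 0:
            raise ValueError(
                f"nest count must be >= 0, got {self.conspecific_nest_count}"
            )
        if self.conspecific_worker_biomass < 0:
            raise ValueError("conspecific worker biomass must be >= 0")
        for sp, b in self.species_biomass.items():
            if b < 0:
                raise ValueError(f"biomass of {sp!r} must be >= 0, got {b}")

    @property
    def heterospecific_total_biomass(self) -> float:
        return float(sum(self.species_biomass.values()))


def per_worker_survival(census: ColonyCensus) -> float:
    """Weekly per-worker survival probability ``S = W2 / W1``."""
    return census.W2 / census.W1


def brood_production(census: ColonyCensus) -> float:
    """Brood production per worker, ``P = (B2 - B1) / W1`` (mg/worker).

    Negative values indicate net brood loss over the week.
    """
    return (census.B2 - census.B1) / census.W1


def net_colony_growth(census: ColonyCensus) -> float:
    """Net colony growth per worker (mg/worker).

    ``G = ((M*W3 + B4) - (M*W1 + B3)) / W1`` — the change in total colony
    fresh weight (adults valued at ``M`` each, plus all brood) per initial
    worker.
    """
    c = census
    return ((c.M * c.W3 + c.B4) - (c.M * c.W1 + c.B3)) / c.W1


def per_worker_weight_growth(census: ColonyCensus) -> float:
    """Dimensionless weekly growth rate ``Gw = G / M``.

    Equals ``((M*W3 + B4) - (M*W1 + B3)) / (M * W1)``; this is the response
    used for Lotka-Volterra competition-coefficient estimation.
    """
    return net_colony_growth(census) / census.M


def demographic_rates(census: ColonyCensus) -> DemographicRates:
    """Compute all four weekly rates for one census."""
    g = net_colony_growth(census)
    return DemographicRates(
        colony_id=census.colony_id,
        S=per_worker_survival(census),
        P=brood_production(census),
        G=g,
        Gw=g / census.M,
    )


def pitfall_biomass(count: int, mean_wet_weight: float) -> float:
    """Biomass proxy: trapped individuals x mean wet weight per individual (mg)."""
    if count < 0:
        raise ValueError(f"trap count must be >= 0, got {count}")
    if mean_wet_weight <= 0:
        raise ValueError(f"mean wet weight must be > 0, got {mean_wet_weight}")
    return count * mean_wet_weight


def persistent_nest_count(daily_observations: Sequence[Set[str]]) -> int:
    """Number of nests present on *every* observation day.

    Only nests observed within the radius on all days of the window count as
    persistent neighbours; a nest absent on even one day is excluded.
    """
    if len(daily_observations) == 0:
        raise ValueError("need at least one day of nest observations")
    persistent = set(daily_observations[0])
    for day in daily_observations[1:]:
        persistent &= set(day)
    return len(persistent)


def rates_table(
    censuses: Iterable[ColonyCensus],
    densities: Iterable[LocalDensity],
) -> pd.DataFrame:
    """Tidy per-colony table joining demographic rates with local densities.

    One row per colony; raises if a census lacks a matching density record.
    """
    dens = {d.colony_id: d for d in densities}
    rows = []
    for c in censuses:
        if c.colony_id not in dens:
            raise KeyError(f"no LocalDensity record for colony {c.colony_id!r}")
        d = dens[c.colony_id]
        r = demographic_rates(c)
        rows.append(
            {
                "colony_id": c.colony_id,
                "month": c.month,
                "W1": c.W1,
                "W2": c.W2,
                "S": r.S,
                "P": r.P,
                "G": r.G,
                "Gw": r.Gw,
                "conspecific_nest_count": d.conspecific_nest_count,
                "conspecific_worker_biomass": d.conspecific_worker_biomass,
                "heterospecific_total_biomass": d.heterospecific_total_biomass,
            }
        )
    return pd.DataFrame(rows)
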