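"""File formats for the pipeline: census / pitfall / nest CSVs, JSON sidecars.

All tables are plain UTF-8 CSV with a header row and '.' decimal point;
weights are serialized at 0.01 mg precision (the microbalance's resolution),
counts as exact integers.  Loaders validate every row and report all
violations together with their row numbers instead of failing on the first.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .demography import CensusError, ColonyCensus, LocalDensity, pitfall_biomass
from .synthetic import (DensityModel, SyntheticExperiment, TrueParameters,
                        FOCAL_SPECIES)

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_censuses",
    "write_censuses",
    "read_weights",
    "read_pitfall",
    "read_nests",
    "write_experiment",
    "load_experiment_dir",
]

CENSUS_COLUMNS = ["colony_id", "month", "W1", "W2", "W3",
                  "B1_mg", "B2_mg", "B3_mg", "B4_mg", "M_mg"]


class ValidationError(ValueError):
    """One or more rows of an input table failed validation."""

    def __init__(self, path, row_errors: Sequence[tuple[int, str]]):
        self.row_errors = list(row_errors)
        lines = "\n".join(f"  row {i}: {msg}" for i, msg in self.row_errors)
        super().__init__(f"{path}: {len(self.row_errors)} invalid row(s):\n{lines}")


@dataclass
class RunConfig:
    """Resolved run settings, echoed alongside every output."""

    seed: int = 0
    radius_m: float = 5.0
    window_days: int = 7
    link_mode: str = "per_worker"       # "per_worker" | "log_offset"
    ode_mode: str = "monod"             # "monod" | "linear"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2)
                              + "\n")


def read_censuses(path) -> list[ColonyCensus]:
    """Load and validate a census table; collects row-level errors."""
    df = pd.read_csv(path)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(path, [(0, f"missing columns: {missing}")])
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            records.append(ColonyCensus(
                colony_id=str(row["colony_id"]), month=str(row["month"]),
                W1=int(row["W1"]), W2=int(row["W2"]), W3=int(row["W3"]),
                B1=float(row["B1_mg"]), B2=float(row["B2_mg"]),
                B3=float(row["B3_mg"]), B4=float(row["B4_mg"]),
                M=float(row["M_mg"])))
        except (CensusError, ValueError, TypeError) as e:
            errors.append((int(i), str(e)))
    if errors:
        raise ValidationError(path, errors)
    return records


def write_censuses(censuses: Sequence[ColonyCensus], path) -> None:
    rows = [{
        "colony_id": c.colony_id, "month": c.month,
        "W1": c.W1, "W2": c.W2, "W3": c.W3,
        "B1_mg": f"{c.B1:.2f}", "B2_mg": f"{c.B2:.2f}",
        "B3_mg": f"{c.B3:.2f}", "B4_mg": f"{c.B4:.2f}",
        "M_mg": f"{c.M:.2f}",
    } for c in censuses]
    pd.DataFrame(rows, columns=CENSUS_COLUMNS).to_csv(path, index=False)


def read_weights(path) -> dict[str, float]:
    """Species mean wet weights: CSV with species,mean_wet_weight_mg."""
    df = pd.read_csv(path)
    for col in ("species", "mean_wet_weight_mg"):
        if col not in df.columns:
            raise ValidationError(path, [(0, f"missing column {col!r}")])
    return {str(r["species"]): float(r["mean_wet_weight_mg"])
            for _, r in df.iterrows()}


def read_nests(path) -> dict[str, int]:
    """Persistent conspecific nest counts: CSV with colony_id,conspecific_nest_count."""
    df = pd.read_csv(path)
    for col in ("colony_id", "conspecific_nest_count"):
        if col not in df.columns:
            raise ValidationError(path, [(0, f"missing column {col!r}")])
    return {str(r["colony_id"]): int(r["conspecific_nest_count"])
            for _, r in df.iterrows()}


def read_pitfall(path, weights_path,
                 nest_counts: Optional[Mapping[str, int]] = None,
                 focal_species: str = FOCAL_SPECIES,
                 het_species: Optional[Sequence[str]] = None,
                 ) -> list[LocalDensity]:
    """Build per-colony local densities from pitfall counts and weights.

    Biomass per species is trapped count x mean wet weight.  The
    heterospecific total is summed over *het_species* (default: every
    non-focal species in the table).  Species absent from the weights table
    are a validation error.
    """
    df = pd.read_csv(path)
    for col in ("colony_id", "species", "count"):
        if col not in df.columns:
            raise ValidationError(path, [(0, f"missing column {col!r}")])
    weights = read_weights(weights_path)
    errors = []
    for i, row in df.iterrows():
        if str(row["species"]) not in weights:
            errors.append((int(i), f"species {row['species']!r} missing from "
                                   f"weights table"))
        elif int(row["count"]) < 0:
            errors.append((int(i), f"negative count {row['count']}"))
    if errors:
        raise ValidationError(path, errors)
    nest_counts = nest_counts or {}
    densities = []
    for cid, grp in df.groupby("colony_id", sort=True):
        per_species: dict[str, float] = {}
        con_bio = 0.0
        for _, row in grp.iterrows():
            sp = str(row["species"])
            b = pitfall_biomass(int(row["count"]), weights[sp])
            if sp == focal_species:
                con_bio += b
            elif het_species is None or sp in het_species:
                per_species[sp] = per_species.get(sp, 0.0) + b
        densities.append(LocalDensity(str(cid), int(nest_counts.get(str(cid), 0)),
                                      per_species, con_bio))
    return densities


def write_experiment(exp: SyntheticExperiment, outdir) -> None:
    """Write a synthetic experiment in the pipeline's input schemas.

    Emits censuses.csv, pitfall.csv, weights.csv, nests.csv and a truth.json
    sidecar holding the generating parameters, seed, and clamped colonies.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_censuses(exp.censuses, out / "censuses.csv")
    exp.pitfall_counts.to_csv(out / "pitfall.csv", index=False)
    pd.DataFrame(
        {"species": list(exp.species_weights),
         "mean_wet_weight_mg": [f"{w:.2f}" for w in exp.species_weights.values()]}
    ).to_csv(out / "weights.csv", index=False)
    pd.DataFrame(
        {"colony_id": [d.colony_id for d in exp.densities],
         "conspecific_nest_count": [d.conspecific_nest_count
                                    for d in exp.densities]}
    ).to_csv(out / "nests.csv", index=False)
    truth = dataclasses.asdict(exp.truth)
    truth["density_model"] = dataclasses.asdict(exp.truth.density_model)
    (out / "truth.json").write_text(json.dumps(
        {"seed": exp.seed, "truth": truth, "clamped_ids": exp.clamped_ids},
        indent=2) + "\n")


def load_experiment_dir(datadir
                        ) -> tuple[list[ColonyCensus], list[LocalDensity]]:
    """Read back an experiment directory written by :func:`write_experiment`."""
    d = Path(datadir)
    censuses = read_censuses(d / "censuses.csv")
    nests = read_nests(d / "nests.csv")
    densities = read_pitfall(d / "pitfall.csv", d / "weights.csv",
                             nest_counts=nests)
    return censuses, densities


def load_truth(datadir) -> TrueParameters:
    raw = json.loads((Path(datadir) / "truth.json").read_text())["truth"]
    raw["density_model"] = DensityModel(**raw["density_model"])
    return TrueParameters(**raw)
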