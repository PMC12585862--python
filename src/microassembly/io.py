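"""Config parsing and delimited-text / JSON serialization.

Tables are tab-delimited with a header row; abundance tables carry one
replicate per row with species labels as columns. Scenario configurations
are YAML mappings that round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analytics import AbundanceDistribution
from .model import AssemblyModel, SpeciesTraits
from .simulate import EnsembleResult

__all__ = [
    "ScenarioSpec",
    "read_config",
    "write_config",
    "write_ensemble_table",
    "read_ensemble_table",
    "write_distribution",
    "write_histogram",
    "write_json",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits in all text tables

_SCHEMA_KEYS = {
    "name",
    "labels",
    "division_rates",
    "dispersal_rates",
    "death_rates",
    "carrying_capacity",
    "saturated_dispersal",
    "n_replicates",
    "seed",
}
_REQUIRED_KEYS = {"division_rates", "dispersal_rates", "carrying_capacity"}


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully-specified simulation scenario (model + ensemble + seed)."""

    division_rates: tuple[float, ...]
    dispersal_rates: tuple[float, ...]
    carrying_capacity: int
    death_rates: tuple[float, ...] | None = None
    labels: tuple[str, ...] | None = None
    saturated_dispersal: bool = True
    n_replicates: int = 1000
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        s = len(self.division_rates)
        if len(self.dispersal_rates) != s:
            raise ValueError("division_rates and dispersal_rates lengths differ")
        if self.death_rates is not None and len(self.death_rates) != s:
            raise ValueError("death_rates length differs from species count")
        if self.labels is not None and len(self.labels) != s:
            raise ValueError("labels length differs from species count")

    def model(self) -> AssemblyModel:
        s = len(self.division_rates)
        labels = self.labels or tuple(
            chr(ord("A") + i) if s <= 26 else f"sp{i}" for i in range(s)
        )
        deaths = self.death_rates or (0.0,) * s
        species = tuple(
            SpeciesTraits(
                label=labels[i],
                division_rate=self.division_rates[i],
                dispersal_rate=self.dispersal_rates[i],
                death_rate=deaths[i],
            )
            for i in range(s)
        )
        return AssemblyModel(
            species=species,
            carrying_capacity=int(self.carrying_capacity),
            saturated_dispersal=self.saturated_dispersal,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d.items()
            if v is not None
        }

    @staticmethod
    def from_dict(d: dict) -> "ScenarioSpec":
        unknown = set(d) - _SCHEMA_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = _REQUIRED_KEYS - set(d)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        d = dict(d)
        for key in ("division_rates", "dispersal_rates", "death_rates", "labels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return ScenarioSpec(**d)


def read_config(path: str | Path) -> ScenarioSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return ScenarioSpec.from_dict(data)


def write_config(spec: ScenarioSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)


def write_ensemble_table(ensemble: EnsembleResult, path: str | Path) -> None:
    """One replicate per row, species labels as header, tab-delimited."""
    df = pd.DataFrame(ensemble.abundances, columns=ensemble.model.labels)
    df.to_csv(path, sep="\t", index=False)


def read_ensemble_table(path: str | Path, carrying_capacity: int | None = None):
    """Read a replicate-by-species abundance table.

    Returns ``(abundances, labels)``. ``carrying_capacity`` defaults to the
    largest row total, so user tables need no extra metadata.
    """
    df = pd.read_csv(path, sep="\t")
    a = df.to_numpy(dtype=np.int64)
    if a.ndim != 2 or a.shape[1] < 1:
        raise ValueError(f"{path}: expected a replicate-by-species table")
    return a, list(df.columns)


def ensemble_from_table(path: str | Path) -> EnsembleResult:
    """Wrap a user abundance table as an :class:`EnsembleResult`.

    A nominal model is reconstructed from the header (unit rates, K = max
    row total) so that the metrics layer can be applied to external data.
    """
    a, labels = read_ensemble_table(path)
    K = int(a.sum(axis=1).max())
    species = tuple(
        SpeciesTraits(label=str(lab), division_rate=1.0, dispersal_rate=1.0)
        for lab in labels
    )
    model = AssemblyModel(species=species, carrying_capacity=K)
    has_death = bool(np.any(a.sum(axis=1) != K))
    if has_death:
        # mark the model as death-enabled so row totals below K validate
        species = tuple(
            SpeciesTraits(str(lab), 1.0, 1.0, death_rate=0.5) for lab in labels
        )
        model = AssemblyModel(species=species, carrying_capacity=K)
    return EnsembleResult(abundances=a, model=model, master_seed=-1, seeds=())


def write_distribution(dist: AbundanceDistribution, path: str | Path) -> None:
    """Two-column table: abundance N_A and its probability."""
    df = pd.DataFrame(
        {"abundance": dist.support, "probability": dist.probabilities}
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_histogram(counts: np.ndarray, edges: np.ndarray, path: str | Path) -> None:
    """Two-column table: left bin edge and replicate count."""
    df = pd.DataFrame({"bin_left": edges[:-1], "count": counts})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
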