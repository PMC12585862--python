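"""Core domain types for stochastic community assembly.

A community assembles from a fixed external species pool. Each species is
characterised by a division rate ``r`` (logistic, per capita), a dispersal
rate ``c`` (arrival-and-establishment from the pool) and an optional death
rate ``d``. Community size ``N`` is bounded by a carrying capacity ``K``;
both division and (by default) dispersal propensities carry the logistic
saturation factor ``(1 - N/K)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesTraits",
    "AssemblyModel",
    "TraitContrast",
    "CommunityState",
    "Timescales",
    "Propensities",
    "event_propensities",
    "selection_and_ratio",
    "timescales",
]


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species rates.

    Parameters
    ----------
    label
        Short unique identifier, e.g. ``"A"``.
    division_rate
        Logistic per-capita division rate r (> 0), per unit time.
    dispersal_rate
        Rate c of arrival from the external pool (>= 0), per unit time.
    death_rate
        Per-capita death rate d (>= 0, default 0). Only the d < r regime
        is supported: at d >= r the community declines to extinction.
    """

    label: str
    division_rate: float
    dispersal_rate: float
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.division_rate > 0:
            raise ValueError(f"division_rate must be > 0, got {self.division_rate}")
        if self.dispersal_rate < 0:
            raise ValueError(f"dispersal_rate must be >= 0, got {self.dispersal_rate}")
        if self.death_rate < 0:
            raise ValueError(f"death_rate must be >= 0, got {self.death_rate}")
        if self.death_rate > 0 and not self.death_rate < self.division_rate:
            raise ValueError(
                "death_rate must be < division_rate (only the d < r regime "
                f"is supported), got d={self.death_rate}, r={self.division_rate}"
            )


@dataclass(frozen=True)
class AssemblyModel:
    """A species pool plus carrying capacity.

    ``saturated_dispersal`` controls whether dispersal propensities carry the
    logistic factor ``(1 - N/K)``. Even when unsaturated, dispersal is
    disallowed at ``N = K`` so that assembly terminates.
    """

    species: tuple[SpeciesTraits, ...]
    carrying_capacity: int
    saturated_dispersal: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if len(self.species) < 1:
            raise ValueError("species pool must contain at least one species")
        labels = [sp.label for sp in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError(f"species labels must be unique, got {labels}")
        if not (isinstance(self.carrying_capacity, (int, np.integer)) and self.carrying_capacity >= 1):
            raise ValueError(f"carrying_capacity must be an integer >= 1, got {self.carrying_capacity}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def labels(self) -> list[str]:
        return [sp.label for sp in self.species]

    @property
    def division_rates(self) -> np.ndarray:
        return np.array([sp.division_rate for sp in self.species])

    @property
    def dispersal_rates(self) -> np.ndarray:
        return np.array([sp.dispersal_rate for sp in self.species])

    @property
    def death_rates(self) -> np.ndarray:
        return np.array([sp.death_rate for sp in self.species])

    @property
    def has_death(self) -> bool:
        return bool(np.any(self.death_rates > 0))


@dataclass(frozen=True)
class TraitContrast:
    """Pairwise trait comparison: selection coefficient and dispersal ratio.

    ``selection_coefficient`` is the division-rate difference s = r_A - r_B;
    a positive value means the first species is favoured within communities.
    ``dispersal_ratio`` is c_A/c_B, or None when c_B = 0 (kept undefined
    rather than infinite so downstream metrics stay finite).
    """

    selection_coefficient: float
    dispersal_ratio: float | None


@dataclass
class CommunityState:
    """Counts per species plus elapsed time."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.time < 0:
            raise ValueError("time must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Timescales:
    """Dispersal vs growth timescales and the regime-boundary dispersal rate.

    ``growth_time_exact`` is the mean time for logistic growth from a single
    founder to K without further dispersal, summing mean inter-division times:
    T_r = sum_{N=1}^{K-1} 1 / [r (1 - N/K) N]. ``growth_time_asymptotic`` is
    the large-K form 2 ln(K) / r. ``c_lim = r / (2 ln K)`` is the dispersal
    rate at which dispersal and growth timescales coincide: above it assembly
    is dispersal-driven, below it division-driven.
    """

    dispersal_time: float
    growth_time_exact: float
    growth_time_asymptotic: float
    c_lim: float


@dataclass(frozen=True)
class Propensities:
    """Per-species event propensities at a given state."""

    division: np.ndarray
    dispersal: np.ndarray
    death: np.ndarray

    @property
    def total(self) -> float:
        return float(self.division.sum() + self.dispersal.sum() + self.death.sum())


def event_propensities(state: CommunityState, model: AssemblyModel) -> Propensities:
    """Propensities of division, dispersal and death events.

    Division of species i: ``r_i (1 - N/K) n_i``. Dispersal of species i:
    ``c_i (1 - N/K)`` (or bare ``c_i`` when the model's dispersal is
    unsaturated, except at N = K where dispersal is always forbidden).
    Death of species i: ``d_i n_i``.

    Raises
    ------
    ValueError
        If the state total exceeds the carrying capacity.
    """
    K = model.carrying_capacity
    n = state.counts
    N = state.total
    if len(n) != model.n_species:
        raise ValueError(f"state has {len(n)} species, model has {model.n_species}")
    if N > K:
        raise ValueError(f"invalid state: total {N} exceeds carrying capacity {K}")
    sat = 1.0 - N / K
    division = model.division_rates * sat * n
    if model.saturated_dispersal:
        dispersal = model.dispersal_rates * sat
    else:
        dispersal = model.dispersal_rates * (0.0 if N == K else 1.0)
    death = model.death_rates * n
    return Propensities(division=division, dispersal=dispersal, death=death)


def selection_and_ratio(a: SpeciesTraits, b: SpeciesTraits) -> TraitContrast:
    """Selection coefficient s = r_a - r_b and dispersal ratio c_a/c_b."""
    ratio = a.dispersal_rate / b.dispersal_rate if b.dispersal_rate > 0 else None
    return TraitContrast(
        selection_coefficient=a.division_rate - b.division_rate,
        dispersal_ratio=ratio,
    )


def timescales(r: float, c: float, K: int) -> Timescales:
    """Dispersal time 1/c, exact and asymptotic logistic growth times, c_lim.

    Parameters
    ----------
    r, c
        Division and dispersal rates (both > 0).
    K
        Carrying capacity, >= 2 (the growth sum is empty below that).
    """
    if not (r > 0 and c > 0):
        raise ValueError("r and c must be positive")
    if K < 2:
        raise ValueError(f"K must be >= 2 for the growth time to be defined, got {K}")
    N = np.arange(1, K)
    exact = float(np.sum(1.0 / (r * (1.0 - N / K) * N)))
    return Timescales(
        dispersal_time=1.0 / c,
        growth_time_exact=exact,
        growth_time_asymptotic=2.0 * math.log(K) / r,
        c_lim=r / (2.0 * math.log(K)),
    )
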