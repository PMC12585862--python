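"""Stochastic simulation of community assembly.

Two simulation paths are provided:

* A full Gillespie algorithm with exponential waiting times
  (:func:`assemble_one`, :func:`assemble_with_death`), required when event
  times matter — trajectories, or models with explicit death.
* A fast embedded-jump-chain path (:func:`assemble_ensemble` with
  ``fast_path=True``, death-free only). Every death-free event increments
  the community size by one, and the identity of each successive recruit is
  species i with probability (r_i n_i + c_i) / sum_j (r_j n_j + c_j) — the
  saturation factor cancels. Sampling K recruits is therefore
  distribution-identical to Gillespie for final compositions, at O(K) per
  replicate, which makes carrying capacities of 1e5 routine.

Reproducibility: a master seed spawns one independent child stream per
replicate (numpy ``SeedSequence``), so ensembles are bit-for-bit
reproducible and each replicate's randomness is independent of how the
ensemble is batched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .model import AssemblyModel, CommunityState, event_propensities

__all__ = [
    "EnsembleResult",
    "TrajectoryEvent",
    "assemble_one",
    "assemble_ensemble",
    "assemble_with_death",
    "equilibrium_size",
]

_CHUNK = 8192  # uniforms drawn per replicate stream at a time (fast path)


@dataclass(frozen=True)
class TrajectoryEvent:
    """One recorded event: time, event label, post-event counts."""

    time: float
    event: str  # e.g. "division:A", "dispersal:B", "death:A"
    counts: tuple[int, ...]


@dataclass(frozen=True)
class EnsembleResult:
    """Replicate-by-species matrix of final abundances.

    Rows are replicate communities, columns follow ``model.species`` order.
    Without death every row sums exactly to the carrying capacity.
    """

    abundances: np.ndarray
    model: AssemblyModel
    master_seed: int
    seeds: tuple[int, ...]  # spawn keys of the per-replicate streams

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=np.int64)
        if a.ndim != 2 or a.shape[1] != self.model.n_species:
            raise ValueError("abundances must be (n_replicates, n_species)")
        if np.any(a < 0):
            raise ValueError("abundances must be non-negative")
        totals = a.sum(axis=1)
        if np.any(totals > self.model.carrying_capacity):
            raise ValueError("replicate total exceeds carrying capacity")
        if not self.model.has_death and np.any(totals != self.model.carrying_capacity):
            raise ValueError("death-free replicates must sum to K")
        object.__setattr__(self, "abundances", a)

    @property
    def n_replicates(self) -> int:
        return self.abundances.shape[0]

    def relative_abundances(self) -> np.ndarray:
        """Per-replicate composition n_i / N; zero-total rows yield NaN."""
        totals = self.abundances.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.abundances / totals, np.nan)


def _rng_for(master_seed: int, replicate: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))
    )


def _gillespie(
    model: AssemblyModel,
    rng: np.random.Generator,
    stop: Callable[[CommunityState], bool],
    record_trajectory: bool,
) -> tuple[CommunityState, list[TrajectoryEvent]]:
    state = CommunityState(counts=np.zeros(model.n_species, dtype=np.int64))
    trajectory: list[TrajectoryEvent] = []
    labels = model.labels
    while not stop(state):
        prop = event_propensities(state, model)
        rates = np.concatenate([prop.division, prop.dispersal, prop.death])
        total = rates.sum()
        if total == 0:
            if state.total == 0:
                raise RuntimeError(
                    "stuck at the empty community: total dispersal rate is zero"
                )
            break  # absorbing state (e.g. N = K with no death)
        state.time += rng.exponential(1.0 / total)
        k = rng.choice(rates.size, p=rates / total)
        kind, sp = divmod(k, model.n_species)
        if kind == 2:  # death
            state.counts[sp] -= 1
        else:
            state.counts[sp] += 1
        if record_trajectory:
            trajectory.append(
                TrajectoryEvent(
                    time=state.time,
                    event=f"{('division', 'dispersal', 'death')[kind]}:{labels[sp]}",
                    counts=tuple(int(x) for x in state.counts),
                )
            )
    return state, trajectory


def assemble_one(
    model: AssemblyModel,
    seed: int,
    record_trajectory: bool = False,
) -> CommunityState | tuple[CommunityState, list[TrajectoryEvent]]:
    """Assemble a single death-free community by full Gillespie simulation.

    Starts from the empty community and runs until N = K. Returns the final
    state, or ``(state, trajectory)`` when ``record_trajectory`` is set.
    """
    if model.has_death:
        raise ValueError("model has death rates; use assemble_with_death")
    if model.dispersal_rates.sum() == 0:
        raise RuntimeError("stuck at the empty community: total dispersal rate is zero")
    rng = _rng_for(seed, 0)
    K = model.carrying_capacity
    state, traj = _gillespie(model, rng, lambda s: s.total >= K, record_trajectory)
    return (state, traj) if record_trajectory else state


def _ensemble_fast(
    model: AssemblyModel, n_replicates: int, master_seed: int
) -> np.ndarray:
    """Embedded-chain sampling of final compositions, vectorized over replicates."""
    K = model.carrying_capacity
    S = model.n_species
    r = model.division_rates
    c = model.dispersal_rates
    rngs = [_rng_for(master_seed, i) for i in range(n_replicates)]
    counts = np.zeros((n_replicates, S), dtype=np.int64)
    rows = np.arange(n_replicates)
    u_chunk = np.empty((n_replicates, 0))
    pos = _CHUNK  # force an initial refill
    for _ in range(K):
        if pos >= u_chunk.shape[1]:
            u_chunk = np.stack([g.random(_CHUNK) for g in rngs])
            pos = 0
        u = u_chunk[:, pos]
        pos += 1
        w = counts * r + c  # recruit weights, (n, S)
        cw = np.cumsum(w, axis=1)
        target = u * cw[:, -1]
        idx = (cw <= target[:, None]).sum(axis=1)
        counts[rows, idx] += 1
    return counts


def assemble_ensemble(
    model: AssemblyModel,
    n_replicates: int,
    master_seed: int,
    fast_path: bool = True,
) -> EnsembleResult:
    """Assemble ``n_replicates`` independent communities.

    ``fast_path`` uses the embedded jump chain (final compositions only;
    death-free models). With ``fast_path=False`` each replicate runs the
    full Gillespie algorithm — identical in distribution, far slower.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if model.dispersal_rates.sum() == 0:
        raise RuntimeError("stuck at the empty community: total dispersal rate is zero")
    if fast_path:
        if model.has_death:
            raise ValueError(
                "the embedded-chain fast path is only valid without death; "
                "use fast_path=False"
            )
        if not model.saturated_dispersal:
            # without the shared saturation factor the recruit-identity
            # probability depends on N/K and the chain shortcut is invalid
            raise ValueError(
                "the embedded-chain fast path requires saturated dispersal; "
                "use fast_path=False"
            )
        abundances = _ensemble_fast(model, n_replicates, master_seed)
    else:
        rows = []
        for i in range(n_replicates):
            rng = _rng_for(master_seed, i)
            if model.has_death:
                state, _ = _gillespie(
                    model, rng, _equilibrium_stop(model), record_trajectory=False
                )
            else:
                K = model.carrying_capacity
                state, _ = _gillespie(model, rng, lambda s: s.total >= K, False)
            rows.append(state.counts)
        abundances = np.stack(rows)
    return EnsembleResult(
        abundances=abundances,
        model=model,
        master_seed=master_seed,
        seeds=tuple(range(n_replicates)),
    )


def equilibrium_size(model: AssemblyModel) -> int:
    """Equilibrium community size ceil(K (1 - d/r)) under logistic growth.

    Uses the largest d_i/r_i ratio in the pool; equals K when death-free.
    """
    ratio = float(np.max(model.death_rates / model.division_rates))
    return int(np.ceil(model.carrying_capacity * (1.0 - ratio)))


def _equilibrium_stop(model: AssemblyModel) -> Callable[[CommunityState], bool]:
    target = equilibrium_size(model)
    return lambda s: s.total >= target


def assemble_with_death(
    model: AssemblyModel,
    seed: int,
    stop: Literal["equilibrium"] | tuple[Literal["time"], float] = "equilibrium",
) -> CommunityState:
    """Assemble one community with explicit death rates (full Gillespie).

    Stopping rules:

    * ``"equilibrium"`` (default) — first passage of N to
      ceil(K (1 - max_i d_i/r_i)), the logistic equilibrium size.
    * ``("time", T)`` — fixed elapsed time T.

    Extinction is possible and is reported as-is (a zero-count state); the
    replicate is never silently resampled. With all death rates zero this
    reduces exactly to :func:`assemble_one`.
    """
    if model.dispersal_rates.sum() == 0:
        raise RuntimeError("stuck at the empty community: total dispersal rate is zero")
    rng = _rng_for(seed, 0)
    if stop == "equilibrium":
        stop_fn = _equilibrium_stop(model)
    elif isinstance(stop, tuple) and len(stop) == 2 and stop[0] == "time":
        horizon = float(stop[1])
        if horizon <= 0:
            raise ValueError("time horizon must be positive")
        stop_fn = lambda s: s.time >= horizon
    else:
        raise ValueError(f"unknown stopping rule: {stop!r}")
    state, _ = _gillespie(model, rng, stop_fn, record_trajectory=False)
    return state
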