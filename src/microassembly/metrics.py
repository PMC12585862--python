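"""Empirical diagnostics on replicate-by-species abundance tables.

These operate on simulated ensembles (:class:`~microassembly.simulate.EnsembleResult`)
or on user-supplied tables, and mirror the analytic quantities: the
bimodality coefficient BC = (skewness^2 + 1)/kurtosis of the abundance
fluctuation distribution, mean relative abundances, monodominance and
co-occurrence fractions, and mean pairwise Bray-Curtis dissimilarity
between communities.

Regime diagnostics: BC above 5/9 signals a bimodal AFD (low-dispersal,
division-driven assembly: monodominant communities, high between-community
dissimilarity); BC near 5/9 a uniform AFD (intermediate); BC below 5/9 a
unimodal AFD (high-dispersal: co-occurrence, low dissimilarity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis as _sample_kurtosis
from scipy.stats import skew as _sample_skew

from .analytics import MomentSummary
from .simulate import EnsembleResult

__all__ = [
    "RegimeMetrics",
    "empirical_moments",
    "bimodality_coefficient",
    "mean_relative_abundance",
    "richness",
    "cooccurrence_fraction",
    "monodominance_fractions",
    "dissimilarity",
    "afd_histogram",
    "regime_metrics",
    "classify_regime",
    "estimate_dispersal_ratio",
    "UNIFORM_BC",
]

#: BC of a uniform AFD — the boundary between bimodal and unimodal regimes.
UNIFORM_BC = 5.0 / 9.0

_EXACT_PAIR_LIMIT = 2000  # replicates above which pairwise Bray-Curtis is subsampled


def empirical_moments(values, weights=None) -> MomentSummary:
    """Population-moment estimators (divide-by-n) of a sample.

    ``weights`` turns the input into a weighted sample, so an exact
    probability vector over its support yields the distribution's exact
    moments. Kurtosis is non-excess, matching Sarle's BC convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, same shape, positive sum")
        w = w / w.sum()
    raw = [float(w @ x**n) for n in (1, 2, 3, 4)]
    return MomentSummary.from_raw(*raw)  # raises on zero variance


def bimodality_coefficient(values, bias_corrected: bool = False) -> float:
    """Sarle's bimodality coefficient of a sample.

    Default uses population moments, BC = (skewness^2 + 1)/kurtosis, directly
    comparable with the analytic closed forms. ``bias_corrected`` applies the
    finite-sample Sarle variant
    (g^2 + 1) / (k + 3 (n-1)^2 / ((n-2)(n-3))) with bias-corrected sample
    skewness g and excess kurtosis k.
    """
    x = np.asarray(values, dtype=float)
    if not bias_corrected:
        return empirical_moments(x).bimodality_coefficient
    n = x.size
    if n < 4:
        raise ValueError("bias-corrected BC needs at least 4 values")
    if np.var(x) == 0:
        raise ValueError("zero variance: BC undefined")
    g = _sample_skew(x, bias=False)
    k = _sample_kurtosis(x, fisher=True, bias=False)
    return float((g**2 + 1.0) / (k + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def _nonzero_rel(ensemble: EnsembleResult) -> tuple[np.ndarray, int]:
    """Relative abundances of replicates with positive total, plus excluded count."""
    totals = ensemble.abundances.sum(axis=1)
    keep = totals > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} extinct (zero-total) replicate(s) "
            "from relative-abundance metrics",
            stacklevel=3,
        )
    rel = ensemble.abundances[keep] / totals[keep, None]
    return rel, n_excluded


def mean_relative_abundance(ensemble: EnsembleResult) -> np.ndarray:
    """Mean over replicates of n_i/N per species; extinct replicates excluded."""
    rel, _ = _nonzero_rel(ensemble)
    if rel.shape[0] == 0:
        raise ValueError("all replicates are extinct")
    return rel.mean(axis=0)


def richness(counts) -> int:
    """Number of species present (count >= 1) in one replicate."""
    return int(np.count_nonzero(np.asarray(counts)))


def cooccurrence_fraction(ensemble: EnsembleResult) -> float:
    """Fraction of replicates in which at least two species co-occur."""
    return float(
        np.mean(np.count_nonzero(ensemble.abundances, axis=1) >= 2)
    )


def monodominance_fractions(ensemble: EnsembleResult) -> np.ndarray:
    """Per-species fraction of replicates populated by that species alone."""
    a = ensemble.abundances
    mono = (np.count_nonzero(a, axis=1) == 1)[:, None] & (a > 0)
    return mono.mean(axis=0)


def dissimilarity(
    ensemble: EnsembleResult,
    *,
    max_exact: int = _EXACT_PAIR_LIMIT,
    n_pairs: int = 200_000,
    seed: int = 0,
) -> float:
    """Mean pairwise Bray-Curtis dissimilarity between final compositions.

    Exact over all replicate pairs up to ``max_exact`` replicates; above
    that, a uniform random subsample of ``n_pairs`` pairs is averaged.
    Computed on relative abundances, so 0 means identical compositions and
    1 disjoint ones.
    """
    rel, _ = _nonzero_rel(ensemble)
    n = rel.shape[0]
    if n < 2:
        raise ValueError("need at least two (non-extinct) replicates")
    if n <= max_exact:
        return float(pdist(rel, metric="braycurtis").mean())
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # distinct partner, uniform over pairs
    d = np.abs(rel[i] - rel[j]).sum(axis=1) / (rel[i] + rel[j]).sum(axis=1)
    return float(d.mean())


def afd_histogram(
    ensemble: EnsembleResult, n_bins: int = 20, species: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the focal species' relative abundance across replicates.

    Bins partition [0, 1] half-open with the last bin closed; returns
    ``(counts, bin_edges)`` with counts summing to the number of
    (non-extinct) replicates.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rel, _ = _nonzero_rel(ensemble)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(rel[:, species], bins=edges)
    return counts, edges


def estimate_dispersal_ratio(mean_rel_abundance: float) -> float:
    """Dispersal-rate ratio c_A/c_B implied by a mean relative abundance.

    In the neutral model the mean relative abundance of species A is
    m = c_A/(c_A + c_B) in every regime, so c_A/c_B = m/(1 - m).
    """
    if not 0 < mean_rel_abundance < 1:
        raise ValueError("mean relative abundance must lie strictly in (0, 1)")
    return mean_rel_abundance / (1.0 - mean_rel_abundance)


def classify_regime(bc: float, tol: float = 0.05) -> str:
    """Assembly regime implied by a bimodality coefficient.

    ``"low-dispersal"`` (bimodal AFD) above 5/9 + tol, ``"high-dispersal"``
    (unimodal) below 5/9 - tol, ``"intermediate"`` within the band.
    """
    if bc > UNIFORM_BC + tol:
        return "low-dispersal"
    if bc < UNIFORM_BC - tol:
        return "high-dispersal"
    return "intermediate"


@dataclass(frozen=True)
class RegimeMetrics:
    """Summary diagnostics of one replicate ensemble (focal species first)."""

    bimodality_coefficient: float
    mean_relative_abundance: tuple[float, ...]
    p_only_A: float
    p_only_B: float
    cooccurrence_fraction: float
    mean_pairwise_dissimilarity: float
    n_replicates: int
    n_excluded: int
    regime: str

    def to_dict(self) -> dict:
        return {
            "bimodality_coefficient": self.bimodality_coefficient,
            "mean_relative_abundance": list(self.mean_relative_abundance),
            "p_only_A": self.p_only_A,
            "p_only_B": self.p_only_B,
            "cooccurrence_fraction": self.cooccurrence_fraction,
            "mean_pairwise_dissimilarity": self.mean_pairwise_dissimilarity,
            "n_replicates": self.n_replicates,
            "n_excluded": self.n_excluded,
            "regime": self.regime,
        }


def regime_metrics(ensemble: EnsembleResult, focal_species: int = 0) -> RegimeMetrics:
    """Compute the full diagnostic summary of an ensemble.

    BC is computed on the focal species' relative abundance across
    replicates; p_only_A / p_only_B are the monodominance fractions of the
    first two species (for two species they and the co-occurrence fraction
    partition the non-extinct replicates).
    """
    rel, n_excluded = _nonzero_rel(ensemble)
    bc = bimodality_coefficient(rel[:, focal_species])
    mono = monodominance_fractions(ensemble)
    return RegimeMetrics(
        bimodality_coefficient=bc,
        mean_relative_abundance=tuple(rel.mean(axis=0)),
        p_only_A=float(mono[0]),
        p_only_B=float(mono[1]) if mono.size > 1 else 0.0,
        cooccurrence_fraction=cooccurrence_fraction(ensemble),
        mean_pairwise_dissimilarity=dissimilarity(ensemble),
        n_replicates=ensemble.n_replicates,
        n_excluded=n_excluded,
        regime=classify_regime(bc),
    )
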