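"""Exact and closed-form analytics for the two-species assembly process.

The abundance fluctuation distribution (AFD) — the distribution of one
species' abundance across replicate communities — is governed by the master
equation

    P(N_A, N+1) = alpha(N_A - 1, N) P(N_A - 1, N)
                  + (1 - alpha(N_A, N)) P(N_A, N),

with P(0, 0) = 1, where alpha(N_A, N) is the probability that the next
recruit (the event taking N to N+1, whether a division or a dispersal) is of
species A:

    alpha = (r_A N_A + c_A) / (r_A N_A + c_A + r_B (N - N_A) + c_B).

This module provides a forward dynamic-programming solution of the master
equation, numerically stable closed forms for the boundary probabilities
P(0, N) and P(N, N) (Pochhammer ratios evaluated via log-gamma), the
co-occurrence probability, the high-dispersal binomial limit, the neutral
moment recursion, analytic bimodality coefficients, and the S-species
low/high-dispersal limit descriptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .model import SpeciesTraits

__all__ = [
    "AbundanceDistribution",
    "MomentSummary",
    "AFD_EXACT_DEFAULT_CAP",
    "alpha",
    "afd_exact",
    "prob_all_A",
    "prob_all_B",
    "prob_cooccurrence",
    "afd_binomial_limit",
    "afd_uniform_solution",
    "neutral_moments",
    "bc_symmetric",
    "bc_symmetric_limit",
    "bc_asymmetric",
    "monodominance_probs",
    "multinomial_limit",
]

#: Default community-size cap for the O(N^2) dynamic-programming solver.
#: Larger sizes are served by the O(N) closed forms and moment recursion.
AFD_EXACT_DEFAULT_CAP = 5000


@dataclass(frozen=True)
class MomentSummary:
    """First four raw moments and derived shape statistics.

    ``kurtosis`` is non-excess (a Gaussian has kurtosis 3), the convention
    entering Sarle's bimodality coefficient BC = (skewness^2 + 1)/kurtosis.
    """

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    raw_moments: tuple[float, float, float, float]

    @property
    def bimodality_coefficient(self) -> float:
        return (self.skewness**2 + 1.0) / self.kurtosis

    @staticmethod
    def from_raw(m1: float, m2: float, m3: float, m4: float) -> "MomentSummary":
        var = m2 - m1**2
        if var <= 0:
            raise ValueError("variance is zero: skewness and kurtosis undefined")
        mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
        mu4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
        sd = math.sqrt(var)
        return MomentSummary(
            mean=m1,
            variance=var,
            skewness=mu3 / sd**3,
            kurtosis=mu4 / var**2,
            raw_moments=(m1, m2, m3, m4),
        )


@dataclass(frozen=True)
class AbundanceDistribution:
    """P(N_A, N): probability vector over N_A = 0..N at community size N."""

    community_size: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.community_size + 1,):
            raise ValueError(
                f"need {self.community_size + 1} probabilities, got shape {p.shape}"
            )
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        # exact normalization so downstream sums satisfy the 1e-12 invariant
        object.__setattr__(self, "probabilities", np.clip(p, 0.0, None) / total)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.community_size + 1)

    def moments(self) -> MomentSummary:
        k = self.support.astype(float)
        p = self.probabilities
        return MomentSummary.from_raw(
            float(p @ k), float(p @ k**2), float(p @ k**3), float(p @ k**4)
        )

    def mean(self) -> float:
        return float(self.probabilities @ self.support)

    def total_variation(self, other: "AbundanceDistribution") -> float:
        if other.community_size != self.community_size:
            raise ValueError("community sizes differ")
        return 0.5 * float(np.abs(self.probabilities - other.probabilities).sum())


def _rates(traits: tuple[SpeciesTraits, SpeciesTraits]) -> tuple[float, float, float, float]:
    a, b = traits
    return a.division_rate, a.dispersal_rate, b.division_rate, b.dispersal_rate


def alpha(n_a, n, traits: tuple[SpeciesTraits, SpeciesTraits]):
    """Probability that the recruit taking N to N+1 is of species A.

    Accepts scalar or array ``n_a``. Valid for any density dependence: the
    saturation factor cancels between numerator and denominator.
    """
    r_a, c_a, r_b, c_b = _rates(traits)
    n_a = np.asarray(n_a, dtype=float)
    num = r_a * n_a + c_a
    den = num + r_b * (n - n_a) + c_b
    if np.any(den == 0):
        raise ValueError("all rates zero: recruit probability undefined")
    out = num / den
    return float(out) if out.ndim == 0 else out


def afd_exact(
    N: int,
    traits: tuple[SpeciesTraits, SpeciesTraits],
    *,
    max_size: int = AFD_EXACT_DEFAULT_CAP,
) -> AbundanceDistribution:
    """Solve the master equation forward from P(0,0)=1 up to size ``N``.

    O(N^2) time, O(N) memory (rolling vector). For N beyond ``max_size``
    use the closed forms (:func:`prob_all_A`, :func:`prob_all_B`), the
    neutral moment recursion, or the limit distributions, all O(N) or O(1).
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    if N > max_size:
        raise ValueError(
            f"N={N} exceeds the DP cap ({max_size}); use the closed-form "
            "boundary probabilities, neutral_moments, or the limit "
            "distributions, or raise max_size explicitly"
        )
    p = np.array([1.0])
    for n in range(N):
        a = alpha(np.arange(n + 1), n, traits)
        nxt = np.zeros(n + 2)
        nxt[:-1] += (1.0 - a) * p
        nxt[1:] += a * p
        p = nxt
    return AbundanceDistribution(community_size=N, probabilities=p)


def _log_pochhammer(x: float, m: int) -> float:
    """log of the rising factorial (x)_m = x(x+1)...(x+m-1)."""
    if m == 0:
        return 0.0
    return float(gammaln(x + m) - gammaln(x))


def prob_all_B(N: int, traits: tuple[SpeciesTraits, SpeciesTraits]) -> float:
    """P(0, N): probability the community of size N holds no species-A microbe.

    Closed form  c_B/(c_A+c_B) * (1 + c_B/r_B)_{N-1} / (1 + (c_A+c_B)/r_B)_{N-1},
    evaluated in log space so it stays finite at N ~ 1e5.
    """
    r_a, c_a, r_b, c_b = _rates(traits)
    if N < 1:
        raise ValueError("N must be >= 1")
    if c_a + c_b == 0:
        raise ValueError("c_A + c_B = 0: no assembly possible")
    if c_b == 0:
        return 0.0
    log_p = (
        math.log(c_b / (c_a + c_b))
        + _log_pochhammer(1.0 + c_b / r_b, N - 1)
        - _log_pochhammer(1.0 + (c_a + c_b) / r_b, N - 1)
    )
    return math.exp(log_p)


def prob_all_A(N: int, traits: tuple[SpeciesTraits, SpeciesTraits]) -> float:
    """P(N, N): probability the community of size N holds only species A."""
    a, b = traits
    return prob_all_B(N, (b, a))


def prob_cooccurrence(K: int, traits: tuple[SpeciesTraits, SpeciesTraits]) -> float:
    """Probability both species are present when the community reaches K.

    1 - P(0,K) - P(K,K), clipped into [0,1] against floating-point residue.
    """
    p = 1.0 - prob_all_B(K, traits) - prob_all_A(K, traits)
    return float(min(1.0, max(0.0, p)))


def afd_binomial_limit(N: int, c_a: float, c_b: float) -> AbundanceDistribution:
    """Very-high-dispersal AFD: Binomial(N, c_A/(c_A+c_B)).

    When dispersal vastly outpaces division, every recruit is a disperser
    and recruit identities are iid with probability c_A/(c_A+c_B).
    """
    if c_a + c_b <= 0:
        raise ValueError("c_A + c_B must be positive")
    p = c_a / (c_a + c_b)
    return AbundanceDistribution(
        community_size=N, probabilities=stats.binom.pmf(np.arange(N + 1), N, p)
    )


def afd_uniform_solution(N: int) -> AbundanceDistribution:
    """Intermediate-dispersal AFD at c_A = c_B = r_A = r_B: uniform on {0..N}.

    With all four rates equal, alpha reduces to (N_A + 1)/(N + 2), and the
    flat vector with entries 1/(N+1) solves the master equation exactly.
    """
    return AbundanceDistribution(
        community_size=N, probabilities=np.full(N + 1, 1.0 / (N + 1))
    )


def neutral_moments(N: int, r: float, c_a: float, c_b: float) -> MomentSummary:
    """First four moments of the AFD in the neutral case (r_A = r_B = r).

    With equal division rates, alpha is linear in N_A:
    alpha = (r N_A + c_A)/(r N + c_A + c_B), so the one-step update of the
    n-th raw moment,

        <N_A^n(N+1)> = <N_A^n(N)> + <alpha * ((N_A+1)^n - N_A^n)>,

    expands exactly over lower-order moments via the binomial theorem.
    O(N) time; valid at N ~ 1e5 and beyond. Non-neutral traits have no such
    closure — use :func:`afd_exact` there.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if r <= 0 or c_a < 0 or c_b < 0 or c_a + c_b == 0:
        raise ValueError("need r > 0 and c_A + c_B > 0 with non-negative rates")
    binom = [[math.comb(n, k) for k in range(n)] for n in range(5)]
    m = [1.0, 0.0, 0.0, 0.0, 0.0]  # raw moments <N_A^k>, k = 0..4, at size 0
    for n_size in range(N):
        den = r * n_size + c_a + c_b
        delta = [0.0] * 5
        for n in range(1, 5):
            acc = 0.0
            for k in range(n):
                acc += binom[n][k] * (r * m[k + 1] + c_a * m[k])
            delta[n] = acc / den
        for n in range(1, 5):
            m[n] += delta[n]
    return MomentSummary.from_raw(m[1], m[2], m[3], m[4])


def bc_symmetric(N: int, r: float, c: float) -> float:
    """Bimodality coefficient of the neutral AFD with c_A = c_B = c, finite N.

    BC = N (2c + 3r)(2c + rN) / [(2c + r)(3 r N^2 + 2c (3N - 2))].
    Decreases from 1 (c << r, Bernoulli: monodominant communities) through
    5/9 (c = r, uniform) to 1/3 (c >> r, binomial).
    """
    if N < 2:
        raise ValueError("N must be >= 2 for kurtosis to be defined")
    if r <= 0 or c <= 0:
        raise ValueError("r and c must be positive")
    return (N * (2 * c + 3 * r) * (2 * c + r * N)) / (
        (2 * c + r) * (3 * r * N**2 + 2 * c * (3 * N - 2))
    )


def bc_symmetric_limit(r: float, c: float) -> float:
    """Large-N limit of :func:`bc_symmetric`: (2c + 3r) / (3 (2c + r))."""
    if r <= 0 or c <= 0:
        raise ValueError("r and c must be positive")
    return (2 * c + 3 * r) / (3 * (2 * c + r))


def bc_asymmetric(r: float, c_a: float, c_b: float) -> float:
    """Large-N bimodality coefficient, neutral case with unequal dispersal.

    Closed form in r, c_A, c_B; reduces to :func:`bc_symmetric_limit` at
    c_A = c_B and to 1/3 as r -> 0 (binomial limit).
    """
    if r <= 0 or c_a + c_b <= 0 or c_a < 0 or c_b < 0:
        raise ValueError("need r > 0 and non-negative c_A, c_B with c_A + c_B > 0")
    cs = c_a + c_b
    q = c_a**2 - c_a * c_b + c_b**2
    num = (cs + 3 * r) * (
        4 * r * (c_a**3 + c_b**3) + 4 * r**2 * q + c_a * c_b * cs**2
    )
    den = 3 * (cs + r) * (cs + 2 * r) * (2 * r * q + c_a * c_b * cs)
    return num / den


def monodominance_probs(c: np.ndarray) -> np.ndarray:
    """Very-low-dispersal S-species limit: each community is monodominant.

    The founder species wins; species i monodominates with probability
    c_i / sum_j c_j.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or c.sum() <= 0:
        raise ValueError("dispersal rates must be non-negative with positive sum")
    return c / c.sum()


def multinomial_limit(c: np.ndarray, K: int):
    """Very-high-dispersal S-species limit: Multinomial(K, c_i / sum c_j).

    Returns a frozen ``scipy.stats.multinomial`` distribution.
    """
    p = monodominance_probs(c)  # same normalized dispersal weights
    return stats.multinomial(K, p)
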