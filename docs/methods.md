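# Methods

## Model

A community assembles on the integer lattice of species counts
(n_1, …, n_S), starting empty. Events and propensities:

* division of species i: r_i (1 − N/K) n_i
* dispersal of species i from the pool: c_i (1 − N/K)
* death of species i (optional): d_i n_i

with N = Σ n_i and carrying capacity K. The logistic factor on dispersal
models density-dependent establishment resistance; setting
`saturated_dispersal=False` removes it (dispersal is still forbidden at
N = K so assembly terminates — without that cut-off the death-free process
would never stop). Inter-specific interactions beyond shared saturation
(facilitation, inhibition) are out of scope, as are non-logistic density
dependencies: the recruit-identity probability α is insensitive to the
density-dependence form, so only logistic propensities are implemented.

Assumptions worth stating explicitly: the pool is infinite and constant
(dispersal never depletes it); traits are identical across replicate
communities; replicates are independent; the death model is only supported
for d < r — at d ≥ r the community declines to extinction and no
stationary assembly endpoint exists, so the constructor rejects it.

## Exact analytics

Because every death-free event increases N by exactly one, the embedded
chain of recruit identities fully determines the final composition. For
two species the master equation over P(N_A, N) is solved by forward DP
from P(0,0) = 1 in O(N²) time and O(N) memory (`afd_exact`). The DP is
capped at N = 5000 by default (overridable): a K = 10⁵ DP is ~10¹⁰ cell
updates, and every large-K quantity of interest has a cheap alternative —
boundary probabilities, co-occurrence, moments, limit distributions, all
O(N) or O(1).

The boundary probabilities are products of one-term recurrences and
reduce to Pochhammer-symbol ratios, e.g.

    P(0,N) = c_B/(c_A+c_B) · (1 + c_B/r_B)_{N−1} / (1 + (c_A+c_B)/r_B)_{N−1}.

These are evaluated as differences of log-gamma values and exponentiated
once; direct products overflow near N ~ 10⁵. P_cooc = 1 − P(0,K) − P(K,K)
is clipped into [0,1] to absorb ~1e−16 rounding residue.

In the neutral case (r_A = r_B = r) α is linear in N_A, which closes the
moment hierarchy: the n-th raw moment obeys

    ⟨N_A^n(N+1)⟩ = ⟨N_A^n(N)⟩ + ⟨α · ((N_A+1)^n − N_A^n)⟩,

expanded exactly over lower-order moments via the binomial theorem
(`neutral_moments`, O(N) for the first four moments). No such closure
exists off-neutrality; the non-neutral exact route is the DP. Kurtosis is
non-excess package-wide, matching Sarle's BC = (γ²+1)/κ.

The uniform solution at c_A = c_B = r_A = r_B assigns mass 1/(N+1) to
each of the N+1 states; this is verified against the DP to 1e−12 in the
tests (the flat vector satisfies the recursion with α = (N_A+1)/(N+2)
exactly).

## Simulation

Two paths produce statistically identical final compositions:

* **Full Gillespie** — exponential waiting times, categorical event
  selection over all 3S propensities. Needed when event times matter:
  trajectories, death models, unsaturated dispersal, fixed-time stopping.
* **Embedded jump chain** (default for death-free ensembles) — each of
  the K recruits is assigned to species i with probability
  (r_i n_i + c_i)/Σ_j (r_j n_j + c_j). The saturation factor cancels
  between numerator and denominator, so this is exact, O(K) per
  replicate, and vectorized across replicates; K = 10⁵ ensembles are
  routine. The cancellation requires division and dispersal to share the
  saturation factor, so the fast path refuses unsaturated-dispersal
  models (and death models, where N is not monotone).

Randomness: one master seed spawns a `numpy` `SeedSequence` child per
replicate, so ensembles are bit-for-bit reproducible and each replicate's
stream is independent of batching. The fast path consumes each
replicate's uniforms in fixed-size chunks (8192) purely as an
implementation detail; results depend only on the master seed.

Death model: the stopping rule must be chosen explicitly because first
passage to the logistic equilibrium ⌈K(1 − max_i d_i/r_i)⌉ (the default)
and a fixed elapsed time answer different questions; both are provided.
With ±1 steps the first-passage rule stops at exactly the equilibrium
size. Extinct replicates are reported as zero rows, never resampled, and
are excluded (with a warning and a count) from relative-abundance
metrics.

## Metrics and diagnostics

Empirical moments use population (divide-by-n) estimators so that
empirical and analytic BC values are directly comparable; a
finite-sample-corrected Sarle variant is available behind an explicit
flag. Regime classification thresholds BC against 5/9 (uniform AFD) with
a ±0.05 indifference band. Between-community dissimilarity is mean
pairwise Bray–Curtis on relative abundances — a representative, not
canonical, choice of β-diversity metric — exact up to 2000 replicates and
pair-subsampled above. The dispersal-ratio estimator ĉ_A/ĉ_B = m/(1−m)
exploits the regime-independence of the neutral mean relative abundance.

## Numerical and design choices

* The simulator-vs-master-equation agreement test uses total variation on
  the 20-bin relative-abundance histogram (the AFD plotting convention).
  Raw per-state TV over all K+1 support points has a sampling floor of
  ≈ 0.5 Σ √(2p_i/(πn)) — about 0.08 at K = 200, n = 5000 even for a
  perfect sampler — and therefore measures sample size, not agreement.
* Dispersal-grid sweeps use closed forms at K = 10⁵; simulated scenario
  presets default to K = 10³ and n = 10³ replicates, which keeps the full
  suite under half a minute while leaving Monte-Carlo standard errors
  (≈ 1% on means, ≈ 0.05 on BC) well inside the effects being detected.
  Paper-scale K is a flag away thanks to the O(K) fast path.
* `TraitContrast` reports c_A/c_B as undefined (None) when c_B = 0 rather
  than infinity, keeping downstream summaries finite.
* c_lim = r/(2 ln K) uses the natural logarithm (it derives from the
  large-K asymptote of the logistic growth time T_r ≈ 2 ln(K)/r). The
  exact T_r sum and the asymptote agree within 15% for K ≥ 10⁴; no
  ordering between them is asserted.
* Stochastic tests are seeded and compared at 3 Monte-Carlo/binomial
  standard errors, or by KS/chi-square goodness-of-fit at α = 0.01.

## What the synthetic ensembles do and do not show

The generator emulates the idealised study conditions: clonal replicate
habitats, a fixed pool, neutral or weakly contrasted traits, no
interactions. Passing tests demonstrate internal consistency
(simulation ≡ master equation ≡ closed forms) and that the diagnostics
recover known regimes and trait ratios under those conditions. They do
not establish robustness to features of real data — pool depletion,
fluorescence-label artefacts, host-to-host environmental variation,
interactions, or measurement noise. The heuristic BC thresholding also
inherits BC's known blind spots (a strongly skewed unimodal distribution
can exceed 5/9).

## Known limitations

* Non-neutral exact results are DP-only (capped by default at N = 5000);
  there is no analytic non-neutral AFD.
* The S-species co-occurrence probability is provided only as a
  simulation estimate (richness fractions), not in closed form.
* The death model supports d ≪ r; d ~ r behaviour is genuinely hard to
  predict and deliberately unsupported.
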