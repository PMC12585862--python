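# microassembly

Stochastic assembly of microbial communities from a fixed species pool:
simulation, exact analytics, and regime diagnostics.

## The problem

When replicate communities (worm guts, sterile micro-habitats, culture
wells) are colonized from the same environmental pool, they typically do
*not* end up alike. Whether replicates converge or diverge is set by the
race between two processes: **dispersal** of microbes from the pool into
the community (rate *c* per species) and **division** inside the community
(logistic, per-capita rate *r*(1 − *N*/*K*) up to a carrying capacity *K*).
This package implements a minimal stochastic model of that race for *S*
species (optionally with a death rate *d* ≪ *r*), and computes the
**abundance fluctuation distribution (AFD)** — the distribution of one
species' final abundance *across* replicate communities — exactly and by
simulation.

It is aimed at microbial ecologists running bottom-up assembly experiments
who want to (i) identify which assembly regime their data sit in and
(ii) detect trait asymmetries (dispersal or division advantages) from
replicate abundance tables.

## The model in brief

For two species A and B, each event increases the community size by one,
and the probability that the recruit is an A is

  α(N_A, N) = (r_A N_A + c_A) / (r_A N_A + c_A + r_B (N − N_A) + c_B),

independent of the form of density dependence. Iterating the master
equation P(N_A, N+1) = α P(N_A−1, N) + (1−α) P(N_A, N) from the empty
community gives the exact AFD at *N* = *K*. Closed forms exist for the
boundary probabilities (Pochhammer ratios, evaluated in log space), the
co-occurrence probability P_cooc = 1 − P(0,K) − P(K,K), and — in the
neutral case r_A = r_B — for the first four moments and Sarle's
**bimodality coefficient** BC = (γ² + 1)/κ.

Three regimes emerge, separated by c_lim = r/(2 ln K):

| regime | AFD | BC | diversity |
|---|---|---|---|
| low dispersal (c ≪ r) | Bernoulli (monodominance) | → 1 | low α, high β |
| intermediate (c = r) | uniform | 5/9 | high α, high β |
| high dispersal (c ≫ r) | binomial around c_A/(c_A+c_B) | → 1/3 | high α, low β |

In every regime the neutral mean relative abundance of A is
c_A/(c_A + c_B), so a dispersal ratio is recoverable from data as
ĉ_A/ĉ_B = m/(1 − m).

## Worked example

Simulate 1000 replicate communities at the intermediate regime
(r = c = 1, K = 1000) and summarise them:

```
$ microassembly simulate -r 1 -c 1 -r 1 -c 1 -K 1000 -n 1000 --seed 42 --name neutral -o out/
wrote out/neutral_ensemble.tsv
```

`out/neutral_metrics.json` then contains (abridged):

```
bimodality_coefficient      0.5248
mean_relative_abundance     [0.4942, 0.5058]
p_only_A                    0.002
p_only_B                    0.0
cooccurrence_fraction       0.998
mean_pairwise_dissimilarity 0.3214
regime                      "intermediate"
```

BC ≈ 0.52 sits at the uniform-AFD landmark 5/9 ≈ 0.556 (the finite-K,
finite-sample value scatters around it), the mean relative abundance is
50% as neutrality predicts, and nearly all communities contain both
species. The same quantities are available analytically over a dispersal
grid:

```
$ microassembly analytic -r 1 -K 100000 --n-grid 9 -o curves.tsv
$ cut -f1,4,5 curves.tsv
c       Pcooc             BC
0.0001  0.00120825845891  0.999866693328
0.01    0.113662422263    0.986928104575
1       0.9999800002      0.555555555556
100     1                 0.336650082919
10000   1                 0.333366665
```

P_cooc rises from 0 to 1 (crossing ½ near c_lim = 1/(2 ln 10⁵) ≈ 0.0434)
while BC falls from 1 through 5/9 (at c = r) towards ⅓.

The same diagnostics run on any user-supplied replicate-by-species table
(`microassembly metrics table.tsv`), and `microassembly scenario` ships
named presets (`neutral-sweep`, `dispersal-asymmetry`, `selection-sweep`,
`host-experiment`) at desk-scale K.

As a library:

```python
from microassembly import SpeciesTraits, afd_exact, bc_symmetric_limit

traits = (SpeciesTraits("A", 1.0, 1.0), SpeciesTraits("B", 1.0, 1.0))
afd_exact(2, traits).probabilities   # array([1/3, 1/3, 1/3])
bc_symmetric_limit(r=1.0, c=1.0)     # 0.5555... = 5/9
```

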