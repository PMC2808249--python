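# Methods

## The comparative design

Each genus that contains both deep-sea and shallow-water members
contributes one data point: a shallow log10 shell-length estimate *x* and a
deep estimate *y*. Under the null hypothesis that deep-sea colonization
leaves body-size evolution unchanged, *x* and *y* are equal on average and
the best-fit line of *y* on *x* has slope 1. A slope below 1 — deep members
of small genera larger than their shallow relatives, deep members of large
genera smaller — is the island-rule signature: a narrowing of the body-size
distribution among colonists.

## Depth classification

Two schemes assign species to deep / shallow / excluded from their recorded
depth range (shallowest and deepest reported occurrence, m):

- **midpoint**: deep iff the range midpoint (mean of min and max) exceeds
  the boundary (default 200 m — the average Atlantic shelf limit and photic
  floor); total, nothing excluded. A species with midpoint exactly on the
  boundary is shallow.
- **strict**: shallow iff never recorded below the boundary
  (max ≤ 200 m); deep iff never recorded above a cutoff
  (min > cutoff, cutoff ∈ {200, 400, 600, 800} m); everything else
  excluded. Equality conventions (≤ for shallow, strict > for deep) ensure
  the three categories partition any table and a boundary-sitting species
  is shallow, never both. Deep sets are nested across cutoffs; the shallow
  set is cutoff-invariant.

Optional exclusion filters remove species whose range is wholly
(min > threshold) or partly (max > threshold) below a threshold (1000 or
3000 m), to ask whether a pattern is driven by abyssal or bathypelagic
taxa. Two exclusion counters are reported: all species dropped, and the
subset that would otherwise have entered the analysis (classified deep or
shallow inside genera passing the minimum-count filter); the latter is the
analysis-relevant "S".

## Genus pairing

*x* and *y* are means of log10 lengths (means taken after the log
transform; on a ratio scale, averaging before logging biases upward). Three
balancing schemes address the concern that genera typically hold fewer deep
than shallow species, and a smaller sample has smaller variance — which a
variance-ratio slope would misread as convergence:

- **all_means** — every classified congener enters its side's mean;
- **equalized** — the larger side is trimmed to the smaller side's count by
  removing the species that weaken the deep-minus-shallow midpoint-depth
  contrast (the deepest-midpoint shallow species, or the shallowest-midpoint
  deep species). Because the contrast is separable in the two sides, this
  greedy rule provably maximizes the mean-midpoint difference over all
  equal-size subset pairs; a brute-force enumeration test guards the
  equivalence.
- **single_pair** — the one deep / one shallow pair with maximal midpoint
  difference (equivalently the deepest-midpoint deep and
  shallowest-midpoint shallow species).

Midpoint ties are broken deterministically: smaller shell length first,
then lexicographic taxon name. An optional minimum-count filter (≥ 2 deep
and ≥ 2 shallow congeners, counted before equalization) removes genera
whose estimates ride on single anomalous species.

## Regression and tests

**OLS**: least squares of *y* on *x*; t = (b − 1)/SE(b) with n − 2 df,
two-sided p. Implemented via `scipy.stats.linregress`. On an exact fit
(SE = 0) the statistic is 0 when the slope equals the null and ±∞
otherwise.

**SMA**: |b| = s_y/s_x with the sign of corr(x, y); intercept through the
means. The test statistic is r(x+y, x−y); since
cov(x+y, x−y) = var(x) − var(y), it is zero exactly when the SMA slope is
1, and its sign follows var(x) − var(y). When only x+y or x−y is degenerate
(an exact anti-correlation) the slope is still returned with a NaN
statistic and a warning; zero variance in x or y raises. Exactly-constant
inputs are detected by range (max = min), not by a computed variance, which
floating-point mean subtraction can leave at ~1e−16.

**Permutation test**: within every genus the deep/shallow labels are
uniformly re-partitioned (sizes preserved), the *entire* pairing scheme is
re-run per replicate — equalization and single-pair selection are part of
the statistic, so freezing them would break exchangeability — and the SMA
statistic is recomputed. p = min(1, 2 × one-sided exceedance proportion in
the observed direction); the observed statistic is not added to numerator
or denominator, and a Monte-Carlo p of exactly zero is floored at
1/n_permutations so a reported p is never 0. An `absolute` tail option
(|statistic| exceedance, undoubled) is available. Replicates with zero
variance count as non-exceeding and are tallied; an all-degenerate run is
an error. Exhaustive enumeration over all distinct relabelings replaces
sampling on request for small problems. Two relabeling schemes exist:
`species_relabel` (the default: re-partition species within each genus) and
`group_swap` (exchange each genus's whole deep and shallow sets with
probability 1/2, re-running the pairing with roles swapped).

**Randomization study**: the same relabeling machinery applied to the
classical test. The support statistic is the one-sided t for slope < 1; the
study reports the fraction of random relabelings (default: group swaps)
whose support is at least as strong as the real data's. Values near 0.5
mean the observed OLS "signal" is indistinguishable from label noise.

**Common-slope test**: for groups (e.g. clades) with per-group SMA slopes,
the shared slope b maximizes the profile likelihood; equivalently it
minimizes −Σᵢ nᵢ log(1 − rᵢ²(b)) where rᵢ(b) is the within-group
correlation between residual-axis scores (y − bx) and fitted-axis scores
(y + bx). At each group's own slope rᵢ = 0, so that minimum *is* the LR
statistic −2 log Λ, referred to chi-square with (groups − 1) df. The
optimizer works on log|b| (bounded well beyond the per-group slopes);
groups with opposite slope signs have no common slope and raise. A
small-sample variant weighting by nᵢ − 5/2 is available behind
`correction=True`; the unweighted statistic is the default and its
Monte-Carlo size at n = 200 per group is nominal (checked against the 95%
binomial interval at 1000 replicates in the test suite).

All slopes, statistics and p-values are invariant to the choice of log
base (both axes transform by the same scalar); base 10 is used throughout
by malacological convention, and the invariance is itself a test.

## The synthetic generator

A two-branch genus "star" — the minimal structure that reproduces both the
island-rule signal and the attenuation artifact. Per genus i:

    A_i ~ N(mu, sigma_ancestral²)                 ancestral log10 size
    X_i = A_i + N(0, sigma_shallow_drift²)        shallow lineage value
    Y_i = mu + beta (A_i − mu) + N(0, sigma_deep_drift²)

Species are noisy replicates of their lineage value
(+ N(0, sigma_within²)), exponentiated to mm. Defaults: mu = 1.2 (≈ 16 mm,
a mid-range gastropod), sigma_ancestral = 0.3 (between-genus SD on the
log10 scale, spanning roughly 3–100 mm across genera), sigma_within = 0.1,
drifts 0, beta = 1 (the null). beta < 1 is convergence; beta = 0 collapses
all deep lineages to mu (a degenerate case the regressions must reject).
Species counts mirror the empirical deep deficit: n_shallow ~ 1 +
Poisson(3), n_deep ~ 1 + Poisson(1). Depth ranges are drawn so the strict
classifier recovers the generated category exactly — shallow min ~
U(0, 50) m with the range capped at the boundary; deep min ~
U(cutoff + 50, cutoff + 1000) m, width U(50, 1500) m — plus an optional
straddler fraction spanning both zones (excluded by the strict rule). The
numeric range parameters are arbitrary but documented; only the
classification outcome matters downstream.

What the generator does *not* emulate: real phylogenetic structure below or
above the genus, speciation/extinction dynamics, depth-correlated sampling
effort, and the sample-size dependence of maximum-length records. Passing
tests therefore certify the statistical machinery under the stated model,
not the biology of any particular data set.

## Exchangeability, and one deliberate red flag

With lineage-level drift the generator makes species within a genus
*group-wise* exchangeable under the null (the two lineage deviations are
iid) but not species-wise exchangeable: congeners share their lineage's
deviation. Consequently:

- the `group_swap` permutation null is exact under the lineage-drift null —
  its measured rejection rate is nominal (≈ 0.05);
- the classical `species_relabel` permutation null is mildly liberal there
  (measured ≈ 0.13 at the 5% level with drift SD 0.3 and within-genus SD
  0.1), because permuted relabelings dilute the lineage contrast that the
  observed labels carry. It remains exact whenever species within a genus
  are iid (no lineage drift), where its measured rate is ≈ 0.05.

One acceptance test asserts strict nominality of the species-relabel test
under the lineage-drift null and is expected to fail; it is kept failing
deliberately, as an honest record of this limit, rather than weakened.
Either way both permutation variants are orders of magnitude better
calibrated than the OLS t-test, whose false-positive rate under the same
null is ≈ 1.0.

## Problem sizes

Monte-Carlo checks in the test suite and the acceptance script use 300–1000
replicate tables of 30–100 genera with 400 permutations per test, 20,000
permutations for single p-values, and 500 genera for parameter recovery —
sizes at which the binomial/delta-method tolerances asserted are
meaningful. The full-scale configuration (100,000 permutations over ~250
genera) runs in seconds through the vectorized per-genus engine; per-genus
random streams are spawned from the master seed, so every result is
bit-reproducible and independent of chunking.
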