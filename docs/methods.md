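# Methods

## Overview

`stemscore` implements a rank-based, single-sample signature scoring pipeline
for tumor expression cohorts, together with the downstream analyses that
typically accompany such a score: median-split survival stratification,
derivation of a correlated mRNA signature, gene-set enrichment of the
resulting ranking, and an outcome-restricted multivariate logistic model.
Because the real patient cohorts such analyses are run on cannot be bundled,
the package ships a synthetic-cohort generator with full ground truth, and
every stage is validated by parameter recovery and by independent
brute-force oracles.

## The signature score

Given an expression matrix with G features and a directional signature with
up-member set U and down-member set D, each sample j is scored from its own
within-sample ranks r(f, j) (rank 1 = lowest-expressed feature, midranks for
ties):

    S_j = mean_{f in U} r(f, j) / G  -  mean_{f in D} r(f, j) / G.

Design choices, and why:

* **Down-members subtract.** With a two-direction signature, subtraction is
  the only convention under which "high score" means "resembles the
  stem-cell profile": a sample expressing the up-members high *and* the
  down-members low scores maximally. A plain sum of ranks over all members
  would reward high expression of members that are supposed to be low.
* **Mean per direction, divided by G.** A raw rank sum depends on both G and
  the member counts, so scores from different platforms or signatures are
  not comparable. The normalized form lies in [-1, 1] regardless of G,
  |U|, |D|. Within one matrix the normalization is affine, so every
  rank-based downstream quantity (median split, Spearman correlations) is
  identical to what the raw sum would give.
* **Monotone invariance.** The score sees only within-sample orderings, so
  any strictly increasing per-sample transform (log, quantile, scaling)
  leaves it unchanged. This is the property that makes a single-sample rank
  score robust to normalization differences; it is asserted exactly in the
  tests.
* **Coverage guard.** Each nonempty direction must have at least
  `min_coverage` (default 0.5) of its members present in the matrix;
  otherwise the score is refused with the missing members named, rather
  than silently computed from a remnant.

Median dichotomization labels a sample "high" only when its score is
strictly above the cohort median; samples exactly at the median go "low".
For odd cohort sizes or tied medians no exactly-equal split exists, so a
deterministic tie rule is preferable to an arbitrary one. A constant score
vector is rejected as uninformative.

## Consensus signature construction

A feature enters the consensus in a direction when at least `min_support`
source lists carry it in that direction, counting each source once. A
feature reaching the threshold in *both* directions is contradictory
evidence; it is excluded and emitted in a conflict report, since silently
assigning it either direction would be arbitrary. One consequence worth
knowing: membership of the final signature is not strictly monotone in
`min_support`, because a feature that is conflict-excluded at low support
can become a clean single-direction member at higher support. The monotone
object is the pre-exclusion candidate set, and that is what the property
test asserts.

## mRNA signature derivation

Genes are ranked by Pearson correlation of their expression with the score
across the common samples (zero-variance genes excluded and reported; ties
broken lexicographically so the ranking is reproducible). The derived
signature is the top N (default 500) genes by *signed, positive* r — if
fewer than N genes correlate positively the derivation fails loudly rather
than padding with anti-correlated genes. Protein-coding filtering is the
caller's job: supply a coding-gene matrix. No significance filter is
applied; selection is by rank, which is why the companion enrichment step
works on the full ranking rather than a thresholded list.

## Survival analysis

* **Kaplan-Meier.** Product-limit estimation runs through
  `lifelines.KaplanMeierFitter`; the curve container tabulates risk sets,
  events, the survival step function and the accumulated Greenwood
  variance at each distinct event time. Subjects censored exactly at an
  event time remain in the risk set at that time (the standard convention).
* **Confidence intervals** for S(t) use the complementary log-log
  transform of the Greenwood variance, which keeps intervals inside [0, 1]
  and yields the asymmetric intervals appropriate for small risk sets.
  Queries beyond the last follow-up return the last value flagged
  `extrapolated`.
* **Log-rank** is computed directly from the per-event-time 2x2
  hypergeometric tables (with the multiple-event variance correction for
  ties) because the result type reports per-group observed and expected
  event counts, which off-the-shelf implementations do not expose; tests
  verify equality with both an independently coded brute force and
  lifelines.
* **Outcome restriction.** The logistic analysis uses only patients with a
  determinable binary outcome: those who died, plus survivors followed at
  least `min_followup` (default 3) years. Censored subjects with shorter
  follow-up are dropped.
* **Logistic regression** is maximum likelihood through statsmodels
  (IRLS/Newton, tolerance 1e-8, at most 100 iterations) with Wald
  p-values, matching the per-covariate OR + p reporting convention.
  Separation is flagged (any standardized coefficient beyond 15, or solver
  failure) and returned as `converged=False` instead of raising, because a
  diverging fit on a small restricted subset is an analysis outcome the
  caller should see, not a crash. The score can enter the model
  dichotomized (the default in the pipeline) or continuous.
* Cox proportional-hazards modelling is deliberately absent: the pipeline's
  multivariate analysis is the outcome-restricted logistic model.

## Pre-ranked enrichment

The weighted Kolmogorov-Smirnov running sum: walking down the ranking, a
gene-set hit adds `|stat|^w / sum_set |stat|^w` (default weight w = 1;
w = 0 gives the classic unweighted KS), a miss subtracts `1/(N - k)`. ES is
the extremum of the running sum; exact magnitude ties between the positive
and negative extremum (possible only through float round-off or degenerate
equal statistics) resolve positive. The null is gene-permutation — random
same-size sets against the fixed ranking — which is the only null available
for a pre-ranked list. Per set:

* NES = ES / mean(|null ES| of the same sign), the sign-stratified
  normalization;
* the permutation p-value is the add-one tail estimate
  `(tail + 1)/(n_same + 1)`, which counts the observed score among the
  draws. This keeps null p-values uniform (the plain tail fraction is
  systematically shifted by ~1/n) and structurally bounds p at
  1/(n_perm + 1), never 0;
* FDR q is the sign-stratified NES-ratio estimate: the fraction of pooled
  null NES at least as extreme divided by the fraction of observed NES at
  least as extreme, clipped to [0, 1].

Sets with fewer than 2 members in the ranking are skipped with a report; a
set covering the whole ranking has no miss denominator and is an error.
Ties in the ranking statistic are left in input order — the ranked list is
authoritative.

`fisher_overlap` is the one-sided (enrichment) hypergeometric tail on the
2x2 overlap table. The odds ratio uses the Haldane 0.5-in-every-cell
correction only when a zero cell makes it undefined, and says so via a
flag. Group comparisons use Welch's t (unequal variances) or the
tie-corrected Mann-Whitney normal approximation without continuity
correction (so identical groups give exactly p = 1).

## Synthetic cohorts

One latent standard-normal "stemness" factor s_i per sample drives all four
data layers:

| quantity | model | default |
|---|---|---|
| up-member miRNA | +beta * s + N(0, sigma) | beta = 1.0, sigma = 1.0 |
| down-member miRNA | -beta * s + N(0, sigma) | 33 up / 27 down members |
| driver mRNA | +beta * s + N(0, sigma) | 500 drivers of 10,000 genes |
| background features | N(0, sigma) | 400 miRNAs total |
| survival | Exponential(h0 * exp(delta * s)), censoring Uniform(0, H) | h0 = 0.1/yr, delta = 0.7, H = 10 yr |
| amplification | Bernoulli(logit = a + b * s) | a = -2, b = 1.5 |
| cohort size | | n = 200 |

The miRNA member features carry the packaged 60-miRNA signature's
identifiers, so the shipped signature scores synthetic cohorts without any
mapping. Planted mRNA drivers all load positively, matching the all-"up"
character of a correlation-derived signature. Defaults emulate a
200-sample tumor cohort with a strong stemness axis: beta = sigma gives
individual member-latent correlations of ~0.7 and pairwise driver-driver
correlations of 0.5, delta = 0.7 is a hazard ratio of ~2 per latent s.d.,
and the uniform 10-year censoring yields roughly 60% censoring at the
default hazard. Stage-4 status is drawn from a weak logit on s
(intercept -0.4, slope 0.5) and the age indicator independently
(P = 0.55); neither is part of the configurable effect structure — they
exist so the multivariate model has realistic co-varying risk markers.

The expression model is Gaussian-additive on a log-like scale. Since the
scorer uses only within-sample ranks, any monotone-equivalent generative
family would produce identical downstream behavior; Gaussian is the
simplest faithful choice. What the generator does *not* emulate:
platform-specific noise, batch effects, missing values, probe redundancy,
or any direct miRNA-to-mRNA regulatory coupling (drivers and signature
members are linked only through the shared factor). Passing recovery tests
therefore demonstrates correctness of the *computations* under the assumed
latent structure, not robustness of the biology to real-data artifacts.

## Validation and calibration

`stemscore.validation` runs the recovery suite that the tests and the
reproduction script share:

* latent recovery — Spearman between score and s on default cohorts
  (observed ~0.99; asserted >= 0.8 across 10 seeds);
* planted-driver recovery — precision of the end-to-end top-500 derivation
  (observed 1.0 at defaults; asserted >= 0.8);
* log-rank type-I calibration — 2000 cohorts of n = 100 with delta = 0
  (hazard independent of the score), score -> median split -> log-rank;
  the rejection rate at alpha = 0.05 must land in [0.035, 0.065];
* log-rank power — 400 cohorts of n = 200 at the default delta = 0.7
  (observed ~0.99; asserted >= 0.8);
* enrichment null uniformity — 500 random set/ranking pairs, permutation
  p-values tested against Uniform(0,1) by Kolmogorov distance (< 0.05).

Replicate cohorts for the survival calibration shrink the mRNA matrix to
20 genes — the mRNA layer is untouched by the log-rank path, so this
changes nothing but runtime. Problem sizes throughout (10 seeds, 2000/400
replicates, 500 trials, 1000 permutations) are chosen so the complete suite
runs in well under a minute of simulation time per study while keeping
Monte-Carlo error comfortably inside the asserted margins.

## Numerical conventions

* Ties in ranks: midranks everywhere (scipy `rankdata(method="average")`).
* Median-tie samples label "low"; constant vectors are errors, not splits.
* Correlation ties at the derivation cutoff: lexicographic gene-id order.
* ES magnitude ties: positive, with a 1e-12 tolerance covering summation
  round-off.
* Greenwood variance is NaN once S(t) = 0 (the formula degenerates); the
  CI there is reported as [0, 0].
* Missing expression values are rejected at load — the rank transform is
  undefined on missing data and no imputation rule is assumed.
* Identifiers are matched case-sensitively after trimming surrounding
  whitespace; no alias resolution is attempted.

## Known limitations

* The consensus module votes on user-supplied lists; it does not re-curate
  published supplements, and identifier harmonization across platforms is
  the caller's responsibility.
* The log-rank test is two-group only (the pipeline's use case); k-group
  generalization is out of scope.
* FDR q-values from the NES-ratio procedure are estimates sharing one null
  pool across set sizes; with very few sets they are coarse.
* Survival-at-t beyond the last follow-up is an extrapolation of the last
  step and is flagged as such rather than refused.
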