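# stemscore

Rank-based stem-cell signature scoring and survival stratification for
tumor expression cohorts.

Aggressive embryonal tumors such as neuroblastoma can retain regulatory
programs of embryonic stem cells (ESCs), and tumors with a strong stemness
phenotype tend to resist therapy. `stemscore` implements the in-silico
pipeline for quantifying that phenotype from expression data:

1. **Consensus signature construction** — vote directional miRNA/gene lists
   from multiple publications into one signature by minimum support. A
   transcribed 60-miRNA ESC signature (33 up-, 27 down-regulated members,
   including the full miR-302/367 cluster and the let-7 family) ships with
   the package.
2. **Single-sample rank-sum scoring** — within each sample, all G features
   are ranked (1 = lowest); the score is
   `S_j = mean(rank of up-members)/G − mean(rank of down-members)/G`,
   a statistic in [−1, 1] that is exactly invariant under any strictly
   increasing per-sample transform of the data.
3. **Survival stratification** — median split of the score, Kaplan–Meier
   curves with Greenwood/log-log confidence intervals, the two-group
   log-rank test, and a multivariate logistic model on the
   outcome-restricted subset (died of disease, or survived ≥ 3 years)
   with the usual risk covariates (MYCN amplification, stage 4, age ≥ 1 y).
4. **Correlated mRNA signature derivation** — rank all coding genes by
   Pearson correlation with the miRNA score; the top 500 positively
   correlated genes form the derived mRNA signature.
5. **Pre-ranked enrichment** — weighted-KS enrichment scores with a
   gene-permutation null (NES, permutation p, sign-stratified FDR), plus
   Fisher-exact list overlap and two-group score comparisons.
6. **Synthetic cohorts** — a generator in which one latent stemness factor
   drives signature-member expression, a planted driver-gene set,
   proportional-hazards survival and an amplification label, with full
   ground truth, so every stage above is verified by parameter recovery.

## Worked example

Generate a default 200-sample synthetic cohort and run the full analysis:

```sh
python analysis/01_simulate_cohort.py      # writes scratch/cohort/
python analysis/02_score_and_survival.py   # scores + survival tables -> results/
python analysis/03_derive_mrna_signature.py
python analysis/04_enrichment.py
```

Output of the default run (seed 17):

```
scored 200 samples with 33+27 signature members; Spearman(score, latent) = 0.990
  high-score group: 100 samples, 51 deaths, 5y survival 45.4% (33.7-56.4%)
  low-score group: 100 samples, 25 deaths, 5y survival 67.3% (54.5-77.2%)
  log-rank chi2 = 22.52, p = 2.08e-06
  restricted logistic (n=154): score-high OR = 2.80, p = 0.00742
ranked 10000 genes over 200 samples; r range [-0.254, 0.788]
top-500 signature: 500/500 planted drivers recovered (precision 1.000, recall 1.000)
planted driver set: ES=1.000, FDR q=0 (10 sets tested, 1000 permutations)
```

Reading this: the rank-sum score almost perfectly recovers the latent
stemness factor the generator planted (Spearman 0.99); the high-score half
of the cohort has markedly worse survival (45% vs 67% alive at 5 years,
log-rank p ≈ 2e-6); the score remains associated with death after
adjusting for amplification, stage and age (odds ratio 2.8); and the
top-500 correlation-derived gene list recovers exactly the planted driver
set, which then dominates the enrichment ranking.

The same stages are available as a CLI over your own files
(`stemscore score|survive|derive|enrich|consensus|simulate|run|demo`), e.g.

```sh
stemscore score --matrix expr.tsv --dichotomize --out scores.tsv
stemscore run --config pipeline.yaml     # end-to-end with a run manifest
```

## File formats

All inputs are UTF-8, tab-separated text:

* **Expression matrix** — first column feature ids, first row sample ids,
  numeric body (no missing values); `--transpose` accepts samples-in-rows.
* **Signature** — two columns: `feature_id`, `up`/`down`. The packaged
  example is `src/stemscore/data/esc_mirna_signature.tsv`.
* **Clinical table** — header `sample_id os_time os_event mycn_amplified
  stage4 age_ge_1y`; empty covariate cells mean unknown.
* **Gene sets** — standard GMT (`name`, description, members...).

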