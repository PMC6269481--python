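"""Parameter-recovery and calibration checks over synthetic cohorts.

These routines validate the pipeline against its own generator's ground
truth: how well the rank-sum score recovers the latent stemness factor, how
precisely the derived top-N gene list recovers the planted drivers, whether
the log-rank test holds its nominal type-I level on null cohorts and reaches
useful power at the default hazard effect, and whether the enrichment
permutation p-values are uniform under a null ranking.  They are the basis
of both the test suite's end-to-end checks and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest, spearmanr

from .derive import RankedGeneList, correlate_genes_with_score, derive_top_signature
from .enrichment import preranked_enrichment
from .io import GeneSetCollection, load_packaged_signature
from .scoring import dichotomize_by_median, signature_score
from .simulate import RecoveryReport, SimulationConfig, SyntheticDataset, generate, truth_recovery_report
from .survival import LogrankResult, logrank_test

__all__ = [
    "score_latent_correlation",
    "latent_recovery",
    "planted_driver_recovery",
    "score_group_logrank",
    "logrank_null_rejection_rate",
    "logrank_power",
    "enrichment_null_ks_distance",
]

# survival-only replicate cohorts do not touch the mRNA matrix; keep it tiny
_SURVIVAL_ONLY = {"n_mrna": 20, "n_driver_genes": 5}


def score_latent_correlation(dataset: SyntheticDataset) -> float:
    """Spearman correlation between the miRNA signature score and the latent factor."""
    scores = signature_score(dataset.mirna, load_packaged_signature(), min_coverage=0.0)
    return float(spearmanr(scores.score, dataset.truth.latent).statistic)


def latent_recovery(seeds, config_kwargs: dict | None = None) -> np.ndarray:
    """Score-latent Spearman correlation across independently seeded default cohorts."""
    kwargs = config_kwargs or {}
    return np.array(
        [
            score_latent_correlation(generate(SimulationConfig(seed=int(s), **kwargs)))
            for s in seeds
        ]
    )


def planted_driver_recovery(dataset: SyntheticDataset, top_n: int = 500) -> RecoveryReport:
    """End-to-end derive step measured against the planted driver genes."""
    scores = signature_score(dataset.mirna, load_packaged_signature(), min_coverage=0.0)
    ranked = correlate_genes_with_score(dataset.mrna, scores)
    derived = derive_top_signature(ranked, n=top_n)
    return truth_recovery_report(dataset, derived)


def score_group_logrank(dataset: SyntheticDataset) -> LogrankResult:
    """Median-split the signature score and log-rank test the two groups."""
    scores = signature_score(dataset.mirna, load_packaged_signature(), min_coverage=0.0)
    groups = dichotomize_by_median(scores)
    clin = dataset.clinical.data
    return logrank_test(
        clin["os_time"].to_numpy(float),
        clin["os_event"].to_numpy(int),
        np.array(groups.label),
    )


def _rejection_rate(n_replicates, n_samples, hazard_log_ratio, alpha, seed) -> float:
    rejections = 0
    for i in range(n_replicates):
        ds = generate(
            SimulationConfig(
                n_samples=n_samples,
                hazard_log_ratio=hazard_log_ratio,
                seed=(int(seed) + i) % (2**31),
                **_SURVIVAL_ONLY,
            )
        )
        if score_group_logrank(ds).p < alpha:
            rejections += 1
    return rejections / n_replicates


def logrank_null_rejection_rate(
    n_replicates: int = 2000, n_samples: int = 100, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I rate of the score-split log-rank test on null cohorts.

    Null cohorts keep the default expression effect but have hazard
    independent of the latent factor, so any rejection is a false positive.
    """
    return _rejection_rate(n_replicates, n_samples, 0.0, alpha, seed)


def logrank_power(
    n_replicates: int = 400,
    n_samples: int = 200,
    hazard_log_ratio: float = 0.7,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical power of the score-split log-rank test at the default hazard effect."""
    return _rejection_rate(n_replicates, n_samples, hazard_log_ratio, alpha, seed)


def enrichment_null_ks_distance(
    n_trials: int = 500,
    list_size: int = 100,
    set_size: int = 10,
    n_perm: int = 500,
    seed: int = 0,
) -> float:
    """Kolmogorov distance of null permutation p-values from Uniform(0, 1).

    Each trial draws a fresh random ranking statistic and a random gene set,
    so the set carries no signal; the resulting permutation p-values should
    be (discretely) uniform.
    """
    rng = np.random.default_rng(seed)
    genes = tuple(f"g{i}" for i in range(list_size))
    pvals = []
    for _ in range(n_trials):
        stats = np.sort(rng.normal(size=list_size))[::-1]
        ranked = RankedGeneList(gene_ids=genes, statistic=stats, n_samples_used=10)
        members = set(rng.choice(list_size, size=set_size, replace=False))
        report = preranked_enrichment(
            ranked,
            GeneSetCollection({"null": {f"g{i}" for i in members}}),
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        pvals.append(report.results[0].p_perm)
    return float(kstest(pvals, "uniform").statistic)
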