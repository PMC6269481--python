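"""Gene-set enrichment against ranked lists, plus overlap and group-difference tests.

``preranked_enrichment`` implements the weighted Kolmogorov-Smirnov running
sum used for pre-ranked enrichment analysis: walking down the ranked list,
hits increment the sum by ``|stat|^weight`` (normalized over the set) and
misses decrement it by ``1/(N - k)``; the enrichment score (ES) is the
running sum's maximum deviation from zero.  The null distribution comes from
random gene-set permutations of the same size (the pre-ranked convention —
there are no phenotype labels to permute).  The normalized score (NES)
divides ES by the mean magnitude of same-sign null scores, the permutation
p-value is the add-one same-sign null tail fraction (hence at least
``1/(n_perm + 1)``, never 0), and the false-discovery q-value is the sign-stratified ratio of
null to observed NES tail fractions.

``fisher_overlap`` is the one-sided (enrichment) hypergeometric test on a
2x2 gene-list overlap table; ``two_group_test`` compares values between two
groups by Welch's t or the tie-corrected Mann-Whitney normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .derive import RankedGeneList
from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "EnrichmentReport",
    "OverlapResult",
    "preranked_enrichment",
    "fisher_overlap",
    "two_group_test",
]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: tuple[str, ...]


@dataclass(frozen=True)
class EnrichmentReport:
    results: tuple[EnrichmentResult, ...]
    skipped: dict[str, str]  # set name -> reason

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)


def _running_extrema(positions: np.ndarray, weights: np.ndarray, n: int):
    """Extrema of the weighted-KS running sum given sorted 0-based hit positions.

    Returns (max after-hit value, min before-hit value, argmax hit index,
    argmin hit index).  The running sum's local maxima occur just after a
    hit and local minima just before one, so these cover the global extrema.
    """
    k = positions.shape[-1]
    miss_step = 1.0 / (n - k)
    total = weights.sum(axis=-1, keepdims=True)
    frac = np.where(total > 0, weights / np.where(total == 0, 1.0, total), 1.0 / k)
    cum_hit = np.cumsum(frac, axis=-1)
    i = np.arange(k)
    misses_through = (positions - i) * miss_step  # misses seen up to each hit
    after = cum_hit - misses_through
    before = after - frac
    return after.max(axis=-1), before.min(axis=-1), after.argmax(axis=-1), before.argmin(axis=-1)


def _es_from_extrema(pos_max, neg_min):
    """Signed ES: the extremum of larger magnitude.

    Magnitude ties (within 1e-12, covering float round-off between
    summation orders) resolve to the positive extremum.
    """
    return np.where(pos_max + 1e-12 >= -neg_min, pos_max, neg_min)


def preranked_enrichment(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentReport:
    """Score every gene set against the ranked list with a permutation null.

    Sets overlapping the list in fewer than 2 genes are skipped (reported in
    ``skipped``); a set covering the entire list has no misses and is an
    error.  ``weight_exponent=0`` reduces the hit increment to the classic
    unweighted KS statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = np.array(ranked.gene_ids, dtype=object)
    stat_w = np.abs(ranked.statistic) ** weight_exponent
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    evaluated: list[tuple[str, np.ndarray]] = []
    skipped: dict[str, str] = {}
    for name, members in sets.items():
        positions = np.sort([index[g] for g in members if g in index])
        if len(positions) < 2:
            skipped[name] = f"only {len(positions)} members in ranked list (need >= 2)"
            continue
        if len(positions) == n:
            raise ValueError(
                f"gene set {name!r} covers the entire ranked list; ES undefined"
            )
        evaluated.append((name, positions))

    # group sets by size so null draws are shared per size
    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
            draws.sort(axis=1)
            pos_max, neg_min, _, _ = _running_extrema(draws, stat_w[draws], n)
            null_cache[k] = _es_from_extrema(pos_max, neg_min)
        return null_cache[k]

    floor = 1.0 / (n_perm + 1)
    records = []
    for name, positions in evaluated:
        w = stat_w[positions]
        if w.sum() == 0 and weight_exponent != 0:
            raise ValueError(
                f"gene set {name!r}: all member statistics are zero under "
                f"weight_exponent={weight_exponent}"
            )
        pos_max, neg_min, i_max, i_min = _running_extrema(positions, w, n)
        es = float(_es_from_extrema(pos_max, neg_min))
        if es >= 0:
            leading = tuple(genes[positions[: int(i_max) + 1]])
        else:
            leading = tuple(genes[positions[int(i_min):]])

        nulls = null_es(len(positions))
        same_sign = nulls >= 0 if es >= 0 else nulls < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = floor
            nes = np.nan
            null_nes = np.array([])
        else:
            # add-one permutation p: counts the observed score among the
            # draws, which keeps the null p uniform and bounds it away from 0
            tail = int((np.abs(nulls[same_sign]) >= abs(es)).sum())
            p = (tail + 1) / (n_same + 1)
            mean_pos = nulls[nulls >= 0].mean() if (nulls >= 0).any() else np.nan
            mean_neg = np.abs(nulls[nulls < 0]).mean() if (nulls < 0).any() else np.nan
            nes = es / mean_pos if es >= 0 else es / mean_neg
            scale = np.where(nulls >= 0, mean_pos, mean_neg)
            null_nes = nulls / scale
        records.append((name, positions, es, float(nes), float(p), leading, null_nes))

    # sign-stratified NES-ratio false-discovery estimate across all sets
    all_null_nes = (
        np.concatenate([r[6] for r in records]) if records else np.array([])
    )
    obs_nes = np.array([r[3] for r in records])
    results = []
    for name, positions, es, nes, p, leading, _ in records:
        if not np.isfinite(nes):
            q = np.nan
        elif nes >= 0:
            null_frac = (all_null_nes >= nes).mean() if all_null_nes.size else 0.0
            obs_frac = (obs_nes[np.isfinite(obs_nes)] >= nes).mean()
            q = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else 0.0
        else:
            null_frac = (all_null_nes <= nes).mean() if all_null_nes.size else 0.0
            obs_frac = (obs_nes[np.isfinite(obs_nes)] <= nes).mean()
            q = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else 0.0
        results.append(
            EnrichmentResult(
                set_name=name,
                size=len(positions),
                es=es,
                nes=nes,
                p_perm=p,
                fdr_q=float(q),
                leading_edge=leading,
            )
        )
    return EnrichmentReport(results=tuple(results), skipped=skipped)


@dataclass(frozen=True)
class OverlapResult:
    """One-sided hypergeometric enrichment test on a 2x2 overlap table."""

    table: tuple[tuple[int, int], tuple[int, int]]  # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    p: float
    universe_size: int
    haldane_corrected: bool


def fisher_overlap(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Test whether two gene lists overlap more than chance within a universe.

    The p-value is the upper hypergeometric tail (enrichment direction).  The
    odds ratio comes from the 2x2 table; when a zero cell makes it undefined
    the Haldane 0.5 correction is applied to every cell and flagged.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a or not set_b:
        raise ValueError("both gene sets must be nonempty")
    stray = sorted((set_a | set_b) - universe)
    if stray:
        raise ValueError(f"genes outside the universe: {stray}")
    m = len(universe)
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = m - a - b - c
    p = float(stats.hypergeom.sf(a - 1, m, len(set_a), len(set_b)))
    haldane = 0 in (a, b, c, d)
    if haldane:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return OverlapResult(
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        p=min(p, 1.0),
        universe_size=m,
        haldane_corrected=haldane,
    )


def two_group_test(values, labels, method: str = "t") -> tuple[float, float]:
    """Compare values between two labeled groups.

    ``method="t"`` is Welch's unequal-variance t-test; ``method="mannwhitney"``
    is the rank-sum test with tie-corrected normal approximation.  Groups are
    taken in sorted label order: the statistic refers to the first level
    versus the second.  Returns (statistic, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {list(levels)}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if method == "t":
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            raise ValueError("zero variance in both groups; t-test undefined")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "mannwhitney":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return float(res.statistic), float(min(res.pvalue, 1.0))
    raise ValueError(f"unknown method {method!r} (expected 't' or 'mannwhitney')")
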