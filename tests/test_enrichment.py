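import numpy as np
import pytest
from scipy.stats import hypergeom

from stemscore.derive import RankedGeneList
from stemscore.enrichment import fisher_overlap, preranked_enrichment, two_group_test
from stemscore.io import GeneSetCollection


def make_ranked(stats):
    stats = np.asarray(stats, float)
    return RankedGeneList(
        gene_ids=tuple(f"g{i}" for i in range(len(stats))),
        statistic=stats, n_samples_used=10,
    )


def brute_es(stats, member_positions, weight=1.0):
    """Independent running-sum enumeration over the full list."""
    n, hits = len(stats), set(member_positions)
    k = len(hits)
    w_sum = sum(abs(stats[i]) ** weight for i in hits)
    run, values = 0.0, []
    for i in range(n):
        if i in hits:
            run += abs(stats[i]) ** weight / w_sum
        else:
            run -= 1.0 / (n - k)
        values.append(run)
    pos, neg = max(max(values), 0.0), min(min(values), 0.0)
    return pos if pos + 1e-12 >= -neg else neg  # magnitude ties resolve positive


class TestPrerankedEnrichment:
    def test_worked_example_top_set_reaches_one(self):
        ranked = make_ranked([5, 4, 3, 2, 1])
        report = preranked_enrichment(
            ranked, GeneSetCollection({"top": {"g0", "g1"}}), n_perm=50, seed=0
        )
        r = report.results[0]
        assert r.es == pytest.approx(1.0, abs=1e-12)
        assert r.leading_edge == ("g0", "g1")
        assert np.sign(r.nes) == np.sign(r.es)

    def test_mirror_symmetry_with_equal_stats(self):
        ranked = make_ranked([2.0] * 8)
        report = preranked_enrichment(
            ranked,
            GeneSetCollection({"top2": {"g0", "g1"}, "bottom2": {"g6", "g7"}}),
            n_perm=20, seed=0,
        )
        by_name = {r.set_name: r for r in report.results}
        assert by_name["bottom2"].es == pytest.approx(-by_name["top2"].es, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            n = int(rng.integers(6, 40))
            stats = np.sort(rng.normal(size=n))[::-1]
            ranked = make_ranked(stats)
            k = int(rng.integers(2, n - 1))
            members = rng.choice(n, size=k, replace=False)
            weight = float(rng.choice([0.0, 1.0, 2.0]))
            report = preranked_enrichment(
                ranked,
                GeneSetCollection({"S": {f"g{i}" for i in members}}),
                weight_exponent=weight, n_perm=2, seed=1,
            )
            expected = brute_es(stats, members, weight)
            assert report.results[0].es == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= report.results[0].es <= 1.0

    def test_es_matches_independent_reference_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 50
        stats = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        for trial in range(3):
            members = list(rng.choice(genes, 8, replace=False))
            ref = gseapy.prerank(
                rnk=pd.DataFrame({"gene": genes, "stat": stats}),
                gene_sets={"S": members}, permutation_num=5, outdir=None,
                seed=1, min_size=2, max_size=100, weight=1.0, no_plot=True,
            ).res2d
            mine = preranked_enrichment(
                make_ranked(stats), GeneSetCollection({"S": set(members)}),
                n_perm=5, seed=1,
            ).results[0]
            assert mine.es == pytest.approx(float(ref["ES"].iloc[0]), abs=1e-5)

    def test_small_overlap_skipped_full_overlap_rejected(self):
        ranked = make_ranked([3, 2, 1])
        report = preranked_enrichment(
            ranked, GeneSetCollection({"tiny": {"g0", "absent"}}), n_perm=5, seed=0
        )
        assert not report.results and "tiny" in report.skipped
        with pytest.raises(ValueError, match="entire"):
            preranked_enrichment(
                ranked, GeneSetCollection({"all": {"g0", "g1", "g2"}}), n_perm=5, seed=0
            )

    def test_p_value_floor_never_zero(self):
        ranked = make_ranked(np.linspace(10, 1, 50))
        report = preranked_enrichment(
            ranked, GeneSetCollection({"top": {"g0", "g1", "g2"}}), n_perm=99, seed=4
        )
        assert report.results[0].p_perm >= 1 / 100

    def test_fdr_of_planted_set_beats_decoys(self, small_dataset):
        from stemscore.derive import correlate_genes_with_score
        from stemscore.io import load_packaged_signature
        from stemscore.scoring import signature_score

        scores = signature_score(small_dataset.mirna, load_packaged_signature(),
                                 min_coverage=0.0)
        ranked = correlate_genes_with_score(small_dataset.mrna, scores)
        rng = np.random.default_rng(0)
        sets = {"planted": set(small_dataset.truth.driver_genes)}
        for i in range(4):
            sets[f"decoy{i}"] = set(
                rng.choice(small_dataset.mrna.feature_ids, 40, replace=False)
            )
        report = preranked_enrichment(
            ranked, GeneSetCollection(sets), n_perm=200, seed=5
        )
        by_name = {r.set_name: r for r in report.results}
        assert by_name["planted"].fdr_q < 0.05
        # no null draw beats the planted set: p sits at its lower bound
        assert by_name["planted"].p_perm <= 1 / 100


class TestFisherOverlap:
    def test_no_association_table(self):
        # universe {1..4}, A={1,2}, B={1,3}: 2x2 = [[1,1],[1,1]]
        res = fisher_overlap({"1", "2"}, {"1", "3"}, {"1", "2", "3", "4"})
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(float(hypergeom.sf(0, 4, 2, 2)), abs=1e-12)

    def test_perfect_overlap_point_mass(self):
        universe = set(range(10))
        a = set(range(5))
        res = fisher_overlap(a, a, universe)
        assert res.p == pytest.approx(1 / 252, abs=1e-15)
        assert res.haldane_corrected  # off-diagonal cells are zero

    def test_disjoint_halves_least_enriched(self):
        universe = set(range(10))
        res = fisher_overlap(set(range(5)), set(range(5, 10)), universe)
        assert res.p == pytest.approx(1.0)

    def test_exhaustive_hypergeometric_tail_small_universes(self):
        for m in (5, 8, 12):
            universe = set(range(m))
            for na in range(1, m + 1):
                for nb in range(1, m + 1):
                    a_set = set(range(na))
                    b_set = set(range(m - nb, m))
                    res = fisher_overlap(a_set, b_set, universe)
                    a = len(a_set & b_set)
                    assert res.p == pytest.approx(
                        float(hypergeom.sf(a - 1, m, na, nb)), abs=1e-12
                    )

    def test_empty_set_and_stray_gene_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(set(), {"a"}, {"a", "b"})
        with pytest.raises(ValueError, match="zzz"):
            fisher_overlap({"zzz"}, {"a"}, {"a", "b"})


class TestTwoGroupTest:
    def test_identical_groups_null(self):
        values = [1.0, 2, 3, 1, 2, 3]
        labels = [0, 0, 0, 1, 1, 1]
        stat_t, _ = two_group_test(values, labels, "t")
        _, p_mw = two_group_test(values, labels, "mannwhitney")
        assert stat_t == pytest.approx(0.0, abs=1e-12)
        assert p_mw == pytest.approx(1.0)

    def test_fully_separated_groups_extreme_u(self):
        u, p = two_group_test([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1], "mannwhitney")
        assert u == 0.0
        assert p < 0.05  # exact enumeration tail is 2 * 1/20 = 0.1; normal approx below

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=20)
        labels = np.array([0] * 10 + [1] * 10)
        t1, p1 = two_group_test(values, labels, "t")
        t2, p2 = two_group_test(values, 1 - labels, "t")
        assert t2 == pytest.approx(-t1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_small_group_and_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0, 2, 3], [0, 0, 1], "t")
        with pytest.raises(ValueError, match="variance"):
            two_group_test([1.0, 1, 2, 2], [0, 0, 1, 1], "t")
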