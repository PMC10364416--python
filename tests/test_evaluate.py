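import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score

from epilink.evaluate import (
    EnrichmentCounts,
    ValidationLinkSet,
    aupr_against,
    average_precision,
    baseline_links,
    enrichment_or,
    intervals_overlap_any,
    overlap_enrichment,
    overlap_fisher,
    points_in_intervals,
    qtl_enrichment,
    restricted_universe,
)
from epilink.io import ActivityMatrix, GenomicInterval, PromoterAnnotation


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.1], [True, True, False]) == 1.0

    def test_false_above_true_two_pairs(self):
        assert average_precision([0.9, 0.1], [False, True]) == pytest.approx(0.5)

    def test_matches_sklearn_without_ties(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(200) / 200.0
        labels = rng.random(200) < 0.3
        assert average_precision(scores, labels) == pytest.approx(
            average_precision_score(labels, scores)
        )

    def test_tie_blocks_are_order_independent(self):
        scores = [0.5, 0.5, 0.5, 0.1]
        labels = [True, False, True, False]
        perm = [2, 1, 0, 3]
        assert average_precision(scores, labels) == pytest.approx(
            average_precision([scores[i] for i in perm], [labels[i] for i in perm])
        )

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(100)
        labels = rng.random(100) < 0.25
        assert average_precision(scores, labels) == pytest.approx(
            average_precision(np.exp(3 * scores), labels)
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="recall"):
            average_precision([0.5], [False])


class TestAuprAgainst:
    def test_unscored_pairs_rank_last(self):
        universe = [("E1", "G1"), ("E2", "G1")]
        truth = ValidationLinkSet(frozenset({("E2", "G1")}))
        assert aupr_against({("E1", "G1"): 0.9}, truth, universe) == pytest.approx(0.5)

    def test_random_ranker_matches_prevalence(self):
        rng = np.random.default_rng(2)
        universe = [(f"E{i}", "G") for i in range(2000)]
        truth = set(universe[:400])  # prevalence 0.2
        auprs = [
            aupr_against({p: rng.random() for p in universe}, truth, universe)
            for _ in range(40)
        ]
        assert np.mean(auprs) == pytest.approx(0.2, abs=0.02)

    def test_empty_truth_in_universe_rejected(self):
        with pytest.raises(ValueError, match="recall"):
            aupr_against({}, ValidationLinkSet(frozenset({("X", "Y")})), [("E", "G")])


class TestBaselines:
    def setup_method(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.promoters = [
                PromoterAnnotation("G1", "chr1", 1_000_000, "+"),
                PromoterAnnotation("G2", "chr1", 1_040_000, "+"),
            ]
        self.enhancers = [GenomicInterval("chr1", 1_009_800, 1_010_200, "E1")]

    def test_closest_links_nearest_promoter(self):
        links = baseline_links("closest", self.enhancers, self.promoters)
        assert set(links) == {("E1", "G1")}

    def test_max_corr_links_highest_correlation(self):
        samples = [f"s{i}" for i in range(10)]
        x = np.arange(10, dtype=float)
        enh = ActivityMatrix(pd.DataFrame([x], index=["E1"], columns=samples))
        proms = ActivityMatrix(pd.DataFrame(
            [x[::-1], x + np.array([0, 1, 0, 0, 1, 0, 0, 1, 0, 0])],
            index=["G1", "G2"], columns=samples))
        links = baseline_links("max_corr", self.enhancers, self.promoters,
                               activity=(enh, proms))
        assert set(links) == {("E1", "G2")}

    def test_random_is_seeded(self):
        a = baseline_links("random", self.enhancers, self.promoters, seed=3)
        b = baseline_links("random", self.enhancers, self.promoters, seed=3)
        assert a == b

    def test_enhancer_without_promoter_in_reach_is_skipped(self):
        orphan = [GenomicInterval("chr9", 0, 400, "EX")]
        assert baseline_links("closest", orphan, self.promoters) == {}

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            baseline_links("best", self.enhancers, self.promoters)


class TestEnrichmentOr:
    def test_hand_arithmetic(self):
        assert enrichment_or(EnrichmentCounts(10, 5, 100, 100)) == pytest.approx(2.0)

    def test_equal_proportions_give_unity(self):
        assert enrichment_or(EnrichmentCounts(7, 7, 13, 13)) == pytest.approx(1.0)

    def test_zero_numerator(self):
        assert enrichment_or(EnrichmentCounts(0, 5, 10, 10)) == 0.0

    def test_undefined_counts_named(self):
        with pytest.raises(ZeroDivisionError, match="b"):
            enrichment_or(EnrichmentCounts(1, 0, 1, 1))
        with pytest.raises(ZeroDivisionError, match="c"):
            enrichment_or(EnrichmentCounts(1, 1, 0, 1))


def _variants(rng, n, chrom="chr1", span=1_000_000):
    return pd.DataFrame({
        "snp_id": [f"v{i}" for i in range(n)],
        "chrom": chrom,
        "pos": rng.integers(0, span, size=n),
        "maf": rng.uniform(0.01, 0.5, size=n),
    })


class TestQtlEnrichment:
    def test_exchangeable_variants_give_unit_odds(self):
        rng = np.random.default_rng(5)
        real = _variants(rng, 400)
        pool = _variants(rng, 8000)
        pool["snp_id"] = "p" + pool["snp_id"]
        cres = [GenomicInterval("chr1", i * 50_000, i * 50_000 + 10_000, f"C{i}")
                for i in range(20)]
        baseline = [GenomicInterval("chr1", 0, 1_000_000, "B")]
        or_mean, or_sd = qtl_enrichment(real, cres, baseline, pool, seed=0)
        assert abs(or_mean - 1.0) <= 2 * or_sd

    def test_planted_placement_gives_large_odds(self):
        rng = np.random.default_rng(6)
        cres = [GenomicInterval("chr1", 0, 100_000, "C")]
        baseline = [GenomicInterval("chr1", 0, 1_000_000, "B")]
        real = _variants(rng, 300, span=100_000)  # all inside the CRE
        pool = _variants(rng, 8000)
        pool["snp_id"] = "p" + pool["snp_id"]
        or_mean, _ = qtl_enrichment(real, cres, baseline, pool, seed=0)
        assert or_mean > 5

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        real = _variants(rng, 200)
        pool = _variants(rng, 5000)
        pool["snp_id"] = "p" + pool["snp_id"]
        cres = [GenomicInterval("chr1", 0, 200_000, "C")]
        baseline = [GenomicInterval("chr1", 0, 1_000_000, "B")]
        assert qtl_enrichment(real, cres, baseline, pool, seed=4) == qtl_enrichment(
            real, cres, baseline, pool, seed=4
        )

    def test_empty_maf_bin_is_reported(self):
        real = pd.DataFrame({"snp_id": ["a"], "chrom": ["chr1"], "pos": [10],
                             "maf": [0.49]})
        pool = pd.DataFrame({"snp_id": ["b"], "chrom": ["chr1"], "pos": [20],
                             "maf": [0.01]})
        cres = [GenomicInterval("chr1", 0, 100, "C")]
        with pytest.raises(ValueError, match="MAF bins"):
            qtl_enrichment(real, cres, cres, pool, seed=0)

    def test_fine_mapped_filter_requires_pp_column(self):
        rng = np.random.default_rng(8)
        real = _variants(rng, 10)
        cres = [GenomicInterval("chr1", 0, 100, "C")]
        with pytest.raises(ValueError, match="pp"):
            qtl_enrichment(real, cres, cres, real, pp_threshold=0.8)


class TestOverlapEnrichment:
    def _interval(self, i, chrom="chr1"):
        return GenomicInterval(chrom, i * 1000, i * 1000 + 500, f"I{chrom}{i}")

    def test_identical_query_and_active_give_unit_odds(self):
        ivs = [self._interval(i) for i in range(6)]
        or_value, p = overlap_enrichment(ivs, ivs, ivs, ivs)
        assert or_value == pytest.approx(1.0)
        assert p <= 1.0

    def test_hypergeometric_tail_small_case(self):
        background = [self._interval(i) for i in range(10)]
        active = background[:5]
        query = background[:4]  # all four overlap the active set
        _, p = overlap_enrichment(query, active, background, background)
        assert p == pytest.approx(5 / 210)

    def test_brute_force_enumeration_oracle(self):
        # enumerate all 4-subsets of a 10-interval universe with 5 actives
        N, K, n, k = 10, 5, 4, 4
        count = sum(
            1 for subset in itertools.combinations(range(N), n)
            if sum(1 for i in subset if i < K) >= k
        )
        assert count / math.comb(N, n) == pytest.approx(5 / 210)

    def test_zero_overlap_gives_unit_pvalue(self):
        background = [self._interval(i) for i in range(10)]
        active = background[:5]
        query = background[8:]
        _, p = overlap_enrichment(query, active, background, background)
        assert p == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        iv = [self._interval(0)]
        with pytest.raises(ValueError):
            overlap_enrichment(iv, iv, [], iv)


class TestOverlapFisher:
    def test_sample_odds_ratio(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(5, 15)}
        odds, p = overlap_fisher(a, b, universe)
        assert odds == pytest.approx((5 * 85) / (5 * 5))
        assert 0 < p <= 1

    def test_disjoint_sets_have_zero_odds(self):
        universe = {f"g{i}" for i in range(20)}
        odds, _ = overlap_fisher({"g0", "g1"}, {"g2", "g3"}, universe)
        assert odds == 0.0

    def test_brute_force_enumeration_matches_exact_test(self):
        universe = set(range(12))
        a, b = {0, 1, 2, 3}, {2, 3, 4, 5, 6}
        _, p = overlap_fisher(a, b, universe)
        # enumerate all sets of |a| given the margins; two-sided by probability mass
        n11 = len(a & b)
        probs = {}
        for k in range(0, min(len(a), len(b)) + 1):
            probs[k] = (math.comb(len(b), k)
                        * math.comb(12 - len(b), len(a) - k)
                        / math.comb(12, len(a)))
        p_brute = sum(v for v in probs.values() if v <= probs[n11] * (1 + 1e-12))
        assert p == pytest.approx(p_brute)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_fisher(set(), set(), set())

    def test_sets_must_be_in_universe(self):
        with pytest.raises(ValueError):
            overlap_fisher({"x"}, set(), {"y"})


class TestIntervalMachinery:
    def test_points_in_merged_union(self):
        ivs = [GenomicInterval("chr1", 0, 100, "a"),
               GenomicInterval("chr1", 50, 150, "b"),
               GenomicInterval("chr2", 10, 20, "c")]
        hits = points_in_intervals(
            ["chr1", "chr1", "chr1", "chr2", "chr3"], [0, 149, 150, 15, 15], ivs
        )
        assert hits.tolist() == [True, True, False, True, False]

    def test_interval_overlap_mask(self):
        targets = [GenomicInterval("chr1", 100, 200, "t")]
        query = [GenomicInterval("chr1", 150, 160, "q1"),
                 GenomicInterval("chr1", 200, 300, "q2"),
                 GenomicInterval("chr2", 100, 200, "q3")]
        assert intervals_overlap_any(query, targets).tolist() == [True, False, False]

    def test_restricted_universe_filters_enhancers(self, small_dataset):
        validated = {small_dataset.enhancers[0].id}
        pairs = restricted_universe(small_dataset.enhancers, small_dataset.promoters,
                                    validated)
        assert pairs and all(e == small_dataset.enhancers[0].id for e, _ in pairs)
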