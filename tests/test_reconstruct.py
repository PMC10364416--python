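import warnings

import numpy as np
import pandas as pd
import pytest

from epilink.io import ActivityMatrix, PromoterAnnotation, SampleTable, GenomicInterval
from epilink.reconstruct import (
    AbcParams,
    EpiModel,
    PipelineConfig,
    abc_quantify,
    activate_per_sample,
    aggregate_state,
    candidate_links,
    correlation_filter,
    lasso_select,
    null_rho_threshold,
    quantile_threshold,
    ratio_threshold,
    reconstruct_all,
    spearman_many,
    usage_from_activity,
    CandidateLink,
    EpiRecord,
)
from epilink.synth import SynthConfig, simulate_dataset


def _enh(chrom, midpoint, eid):
    return GenomicInterval(chrom, midpoint - 200, midpoint + 200, eid)


class TestCandidateLinks:
    def setup_method(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.prom = PromoterAnnotation("G1", "chr1", 2_000_000, "+")

    def test_one_megabase_boundary(self):
        enh = [
            _enh("chr1", 2_000_000 + 999_999, "in"),
            _enh("chr1", 2_000_000 + 1_000_001, "out"),
            _enh("chr2", 2_000_000, "trans"),
        ]
        links = candidate_links(self.prom, enh)
        assert [l.enhancer_id for l in links] == ["in"]

    def test_sorted_by_distance(self):
        enh = [_enh("chr1", 2_500_000, "far"), _enh("chr1", 2_010_000, "near")]
        links = candidate_links(self.prom, enh)
        assert [l.enhancer_id for l in links] == ["near", "far"]


class TestLassoSelect:
    def test_recovers_driver_and_ignores_noise(self):
        rng = np.random.default_rng(1)
        e1 = rng.normal(size=40)
        e2 = rng.normal(size=40)
        y = 2.0 * e1 + 0.05 * rng.normal(size=40)
        X = np.column_stack([e1, e2])
        betas = lasso_select(y, X, seed=0)
        # OLS on the same draw as the independent oracle for the sign/size
        ols = np.linalg.lstsq(np.column_stack([X, np.ones(40)]), y, rcond=None)[0]
        assert ols[0] > 1.5 and abs(ols[1]) < 0.2
        assert betas[0] > 0 and betas[1] <= 0

    def test_negative_driver_not_retained(self):
        rng = np.random.default_rng(2)
        e1 = rng.normal(size=40)
        y = -1.0 * e1 + 0.05 * rng.normal(size=40)
        betas = lasso_select(y, e1[:, None], seed=0)
        assert betas[0] <= 0

    def test_constant_promoter_selects_nothing(self):
        X = np.random.default_rng(3).normal(size=(20, 4))
        betas = lasso_select(np.ones(20), X, seed=0)
        assert (betas == 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            lasso_select(np.ones(5), np.ones((5, 2)), seed=0)


class TestCorrelationThresholds:
    def test_quantile_rule_on_stub_null(self):
        stub = np.arange(0.0, 1.01, 0.1)
        assert quantile_threshold(stub, 0.05) == pytest.approx(0.95)
        assert quantile_threshold(stub, 0.5) == pytest.approx(0.5)

    def test_null_threshold_is_calibrated_for_independent_pairs(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=20)
        pool = rng.normal(size=(10_000, 20))
        thr = null_rho_threshold(y, pool, n_null=10_000, fdr=0.05, seed=1)
        fresh = rng.normal(size=(20_000, 20))
        exceed = float(np.mean(spearman_many(y, fresh) > thr))
        assert exceed == pytest.approx(0.05, abs=0.01)

    def test_small_pool_samples_with_replacement_and_warns(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="replacement"):
            thr = null_rho_threshold(rng.normal(size=12), rng.normal(size=(50, 12)),
                                     n_null=1000, seed=0)
        assert -1 <= thr <= 1

    def test_strictly_greater_retention(self):
        links = [CandidateLink("E1", "G", 10, rho=0.9),
                 CandidateLink("E2", "G", 10, rho=0.8)]
        kept = correlation_filter(links, 0.8)
        assert [l.enhancer_id for l in kept] == ["E1"]
        assert correlation_filter([], 0.5) == []

    def test_ratio_threshold_reading(self):
        null = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        observed = np.array([0.35, 0.45, 0.9, 0.95])
        thr = ratio_threshold(null, observed, fdr=0.5)
        assert np.isfinite(thr)
        frac_null = np.mean(null > thr)
        frac_obs = np.mean(observed > thr)
        assert frac_null / frac_obs <= 0.5


class TestActivation:
    def _usage(self, table):
        return usage_from_activity(ActivityMatrix(pd.DataFrame(table)))

    @pytest.mark.parametrize(
        "enh_tpm,prom_tpm,expected",
        [(5.0, 5.0, True), (5.0, 0.5, False), (0.5, 0.5, False)],
    )
    def test_both_endpoints_must_be_in_usage(self, enh_tpm, prom_tpm, expected):
        enh_usage = self._usage({"s1": pd.Series({"E1": enh_tpm})})
        prom_usage = self._usage({"s1": pd.Series({"G1": prom_tpm})})
        (rec,) = activate_per_sample([CandidateLink("E1", "G1", 10)],
                                     enh_usage, prom_usage, "s1")
        assert rec.active is expected

    def test_unknown_id_names_the_id(self):
        enh_usage = self._usage({"s1": pd.Series({"E1": 5.0})})
        prom_usage = self._usage({"s1": pd.Series({"G1": 5.0})})
        with pytest.raises(KeyError, match="E9"):
            activate_per_sample([CandidateLink("E9", "G1", 10)],
                                enh_usage, prom_usage, "s1")


class TestAbc:
    def test_single_enhancer_takes_full_share(self):
        scores = abc_quantify(np.array([1000.0]), np.array([4.0]), 9.0)
        assert scores[0] == pytest.approx(1.0)

    def test_symmetry_of_equal_enhancers(self):
        scores = abc_quantify(np.array([5000.0, 5000.0]), np.array([4.0, 4.0]), 9.0)
        assert scores == pytest.approx([0.5, 0.5])

    def test_distance_decay_two_thirds_one_third(self):
        params = AbcParams(gamma=1.0, d0=0.0, background=0.0)
        scores = abc_quantify(np.array([10_000.0, 20_000.0]),
                              np.array([4.0, 4.0]), 9.0, params)
        assert scores == pytest.approx([2 / 3, 1 / 3])

    def test_background_share_completes_the_unit(self):
        params = AbcParams(gamma=1.0, d0=5000.0, background=0.01)
        d = np.array([10_000.0, 50_000.0])
        a = np.array([4.0, 2.0])
        scores = abc_quantify(d, a, 9.0, params)
        contrib = np.sqrt(a * 9.0) * params.contact(d)
        bg_share = params.background / (contrib.sum() + params.background)
        assert scores.sum() + bg_share == pytest.approx(1.0)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_monotone_in_own_activity(self):
        d = np.array([10_000.0, 20_000.0])
        base = abc_quantify(d, np.array([4.0, 4.0]), 9.0)
        bumped = abc_quantify(d, np.array([6.0, 4.0]), 9.0)
        assert bumped[0] >= base[0]

    def test_empty_denominator_yields_empty(self):
        assert abc_quantify(np.array([]), np.array([]), 9.0).size == 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AbcParams(gamma=-1.0)


class TestAggregation:
    def _table(self):
        return SampleTable(pd.DataFrame({
            "sample_id": ["r1", "r2"], "state": ["s", "s"],
            "group": ["g", "g"], "life_stage": ["adult", "adult"],
        }))

    def test_max_abc_across_replicates(self):
        records = {
            "r1": [EpiRecord("E1", "G1", "r1", True, 0.3)],
            "r2": [EpiRecord("E1", "G1", "r2", True, 0.5)],
        }
        net = aggregate_state(records, self._table(), "s")
        assert net.edges[("E1", "G1")] == 0.5
        assert sorted(net.provenance[("E1", "G1")]) == ["r1", "r2"]

    def test_union_rule_single_replicate(self):
        records = {
            "r1": [EpiRecord("E1", "G1", "r1", True, 0.4)],
            "r2": [EpiRecord("E1", "G1", "r2", False, 0.0)],
        }
        net = aggregate_state(records, self._table(), "s")
        assert net.edges[("E1", "G1")] == 0.4

    def test_inactive_everywhere_is_absent(self):
        records = {"r1": [EpiRecord("E1", "G1", "r1", False)],
                   "r2": [EpiRecord("E1", "G1", "r2", False)]}
        net = aggregate_state(records, self._table(), "s")
        assert len(net) == 0

    def test_unknown_state_rejected(self):
        with pytest.raises(KeyError):
            aggregate_state({}, self._table(), "nope")

    def test_brute_force_cross_check(self):
        rng = np.random.default_rng(4)
        samples = [f"r{i}" for i in range(4)]
        table = SampleTable(pd.DataFrame({
            "sample_id": samples, "state": ["s"] * 4,
            "group": ["g"] * 4, "life_stage": ["adult"] * 4,
        }))
        records = {
            s: [EpiRecord("E1", "G1", s, bool(rng.integers(2)), float(rng.random()))]
            for s in samples
        }
        net = aggregate_state(records, table, "s")
        active = [r[0] for r in records.values() if r[0].active and r[0].abc > 0]
        if active:
            assert net.edges[("E1", "G1")] == max(r.abc for r in active)
        else:
            assert ("E1", "G1") not in net.edges


class TestPipeline:
    def test_determinism(self, small_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = reconstruct_all(small_dataset, seed=5)
            b = reconstruct_all(small_dataset, seed=5)
        pd.testing.assert_frame_equal(a.edges_dataframe(), b.edges_dataframe())
        pd.testing.assert_frame_equal(a.links_table, b.links_table)

    def test_empty_enhancer_set_gives_empty_networks(self, small_dataset):
        model = EpiModel([],
                         small_dataset.promoters,
                         ActivityMatrix(small_dataset.enh_activity.data.iloc[:0]),
                         small_dataset.prom_activity,
                         small_dataset.samples)
        results = model.fit(seed=0)
        assert all(len(net) == 0 for net in results.networks.values())

    def test_noiseless_planted_links_recovered_in_active_states(self):
        cfg = SynthConfig(n_enh=150, n_prom=15, chrom_length=3_000_000,
                          noise_sd=0.0, enh_obs_sigma=0.0,
                          links_per_promoter=(1, 1), enhancer_sharing=0.0,
                          domain_coupling=0.0, coregulation=0.0, seed=13)
        ds = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reconstruct_all(ds, seed=13)
        recovered = set(res.edge_scores())
        missing = ds.truth.link_pairs - recovered
        # noiseless single-link world: nearly all planted links recovered
        assert len(missing) <= 0.2 * len(ds.truth.link_pairs)

    def test_summary_reports_funnel(self, default_results):
        text = default_results.summary()
        assert "candidate pairs" in text and "LASSO-retained" in text

    def test_abc_scores_within_unit_interval(self, default_results):
        for net in default_results.networks.values():
            for w in net.edges.values():
                assert 0 < w <= 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(fdr=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(fdr_mode="bogus")
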