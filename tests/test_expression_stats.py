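import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom

from pitanga.expression_stats import (
    DETestResult, bh_adjust, call_degs, nb_fit, nb_loglik, nb_lrt_two_group,
    size_factors, venn_partition,
)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_column_gives_factor_ratio_two(self):
        m = pd.DataFrame({"a": [10, 20, 30, 40, 50], "b": [20, 40, 60, 80, 100]})
        sf = size_factors(m)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_hand_computed_median_of_ratios(self):
        m = pd.DataFrame({"a": [4, 9, 25, 1, 16], "b": [1, 4, 9, 16, 25],
                          "c": [2, 6, 15, 4, 20]})
        gm = np.exp(np.log(m.to_numpy()).mean(axis=1))
        expected = [np.median(m[c].to_numpy() / gm) for c in m]
        assert np.allclose(size_factors(m), expected)

    def test_zero_gene_excluded_from_reference(self):
        m = pd.DataFrame({"a": [0, 10, 20], "b": [100, 10, 20]})
        # the zero-containing gene must not poison the geometric mean
        assert np.allclose(size_factors(m), 1.0)

    def test_all_genes_with_zero_rejected(self):
        m = pd.DataFrame({"a": [0, 1], "b": [1, 0]})
        with pytest.raises(ValueError):
            size_factors(m)


class TestNBFit:
    def test_constant_counts_hit_poisson_boundary(self):
        fit = nb_fit([5, 5, 5, 5])
        assert fit.mu == pytest.approx(5.0)
        assert fit.alpha == 0.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        r = 1 / 0.2
        x = rng.negative_binomial(r, r / (r + 50), 5000)
        fit = nb_fit(x)
        assert fit.mu == pytest.approx(50, rel=0.05)
        assert fit.alpha == pytest.approx(0.2, rel=0.20)

    def test_loglik_matches_independent_pmf(self):
        rng = np.random.default_rng(1)
        x = rng.negative_binomial(5, 5 / (5 + 30), 200)
        fit = nb_fit(x)
        r = 1 / fit.alpha
        oracle = nbinom.logpmf(x, r, r / (r + fit.mu)).sum()
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-8)

    def test_all_zero_counts(self):
        fit = nb_fit([0, 0, 0])
        assert fit.mu == 0.0
        assert fit.log_likelihood == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_fit([1, -2, 3])


class TestLRT:
    def test_identical_groups_give_zero_stat(self):
        stat, df, p = nb_lrt_two_group([7, 7, 7, 7, 7, 7], [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(2)
        r = 1 / 0.05
        y = np.concatenate([rng.negative_binomial(r, r / (r + 20), 6),
                            rng.negative_binomial(r, r / (r + 200), 6)])
        _, _, p = nb_lrt_two_group(y, np.repeat([0, 1], 6))
        assert p < 0.001

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(30, 10)
        labels = np.array([0] * 5 + [1] * 5)
        s1, _, p1 = nb_lrt_two_group(y, labels)
        s2, _, p2 = nb_lrt_two_group(y, 1 - labels)
        assert s1 == pytest.approx(s2)
        assert 0 < p1 <= 1 and p1 == pytest.approx(p2)

    def test_empty_group_named(self):
        with pytest.raises(ValueError):
            nb_lrt_two_group([1, 2, 3], [0, 0, 0])

    def test_separate_dispersion_mode_df2(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(30, 12)
        _, df, p = nb_lrt_two_group(y, np.repeat([0, 1], 6),
                                    shared_dispersion=False)
        assert df == 2
        assert 0 < p <= 1

    def test_offsets_absorb_library_size(self):
        # doubling one group's library sizes must not fake an effect
        rng = np.random.default_rng(5)
        base = rng.poisson(100, 6)
        y = np.concatenate([base, 2 * rng.poisson(100, 6)])
        off = np.array([1.0] * 6 + [2.0] * 6)
        _, _, p = nb_lrt_two_group(y, np.repeat([0, 1], 6), offsets=off)
        assert p > 0.05


class TestCallDegs:
    def test_direction_thresholds(self, toy_counts):
        counts, sheet = toy_counts
        results = call_degs(counts, sheet, "RE")
        for r in results:
            if r.direction == "up":
                assert r.fold_change >= 1.5 and r.p < 0.05
            elif r.direction == "down":
                assert r.fold_change <= 1 / 1.5 and r.p < 0.05
            else:
                assert not (r.fold_change >= 1.5 and r.p < 0.05)
                assert not (r.fold_change <= 1 / 1.5 and r.p < 0.05)

    def test_threshold_degeneracy_marks_every_gene(self, toy_counts):
        counts, sheet = toy_counts
        results = call_degs(counts, sheet, "RF", fc_threshold=1.0, p_deg=1.0)
        assert all(r.direction in ("up", "down")
                   for r in results if r.p < 1.0)

    def test_insufficient_replicates_rejected(self, toy_counts):
        counts, sheet = toy_counts
        crippled = sheet.drop(index=["RE_drought_1", "RE_drought_2"])
        with pytest.raises(ValueError):
            call_degs(counts[list(crippled.index)], crippled, "RE")

    def test_planted_truth_recovery(self):
        """Planted 3-fold effects are mostly recovered; planted nulls are
        rejected at close to the nominal rate; FDP stays moderate.

        At 3 replicates per condition a calibrated NB test has limited
        power against a 2-fold change, so recovery is asserted for the
        strong (3-fold) planted genes.
        """
        from pitanga.synthetic_data import SimParams, sample_names, simulate_counts

        params = SimParams(n_genes=400, de_fraction=0.10, fc_grid=(3.0,))
        counts, sheet, truth = simulate_counts(params, seed=11)
        planted = {g for g, pop, fc, d in truth.de_genes if pop == "RE"}
        results = call_degs(counts, sheet, "RE")
        called = {r.gene_id for r in results if r.direction != "ns"}
        sensitivity = len(called & planted) / len(planted)
        null_genes = [r for r in results if r.gene_id not in planted]
        null_fpr = np.mean([r.p < 0.05 for r in null_genes])
        assert sensitivity >= 0.5
        assert null_fpr < 0.10
        if called:
            assert len(called - planted) / len(called) < 0.4


class TestVenn:
    def _res(self, gene, direction):
        return DETestResult(gene, 2.0 if direction == "up" else 0.5,
                            0.01, None, direction)

    def test_shared_and_unique(self):
        re = [self._res(g, "up") for g in "abc"]
        rf = [self._res(g, "up") for g in "bcd"]
        out = venn_partition(re, rf)
        assert out["shared_up"] == {"b", "c"}
        assert out["unique_RE_up"] == {"a"}
        assert out["unique_RF_up"] == {"d"}

    def test_discordant_bin(self):
        out = venn_partition([self._res("a", "up")], [self._res("a", "down")])
        assert out["discordant"] == {"a"}
        assert out["shared_up"] == set() and out["shared_down"] == set()

    def test_partition_sums_to_union(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(60)]
        re, rf = [], []
        for g in genes:
            for res, r in ((re, rng.random()), (rf, rng.random())):
                if r < 0.3:
                    res.append(self._res(g, "up"))
                elif r < 0.5:
                    res.append(self._res(g, "down"))
        out = venn_partition(re, rf)
        union = {r.gene_id for r in re} | {r.gene_id for r in rf}
        assert sum(len(v) for v in out.values()) == len(union)
        all_bins = [g for v in out.values() for g in v]
        assert len(all_bins) == len(set(all_bins))


class TestBH:
    def test_step_up_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_against_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        def brute(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(m)
            for rank_pos, idx in enumerate(order):
                candidates = [p[order[j]] * m / (j + 1)
                              for j in range(rank_pos, m)]
                q[idx] = min(1.0, min(candidates))
            return q

        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ours = bh_adjust(p)
            assert np.allclose(ours, brute(p))
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
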