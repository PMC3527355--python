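"""Overdispersion and generalized Wald tests: exact identities, invariances,
and small null-calibration simulations (the full-size calibrations live in
the acceptance suite)."""

import numpy as np
import pytest
from scipy import stats

from dmtaxa import DMParams, GroupedTables, TaxaCountTable, dm_sample, pairwise_comparisons
from dmtaxa import test_one_sample as one_sample_test
from dmtaxa import test_overdispersion as overdispersion_test
from dmtaxa import test_several_samples as several_samples_test
from dmtaxa import test_two_samples as two_samples_test


def make_groups(params_list, subjects, reads, rng, labels=None):
    labels = labels or [f"g{i + 1}" for i in range(len(params_list))]
    return GroupedTables.from_tables(
        (lab, dm_sample(p, subjects, reads, seed=rng))
        for lab, p in zip(labels, params_list)
    )


class TestOverdispersion:
    def test_identical_samples_give_zero_statistic(self):
        table = TaxaCountTable.from_counts([[50, 50], [50, 50]])
        res = overdispersion_test(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_equal_reads_chi_square_df(self):
        table = dm_sample(DMParams(np.array([0.4, 0.3, 0.3]), 0.0), 24, 1000, seed=1)
        res = overdispersion_test(table)
        assert res.df == (24 - 1) * (3 - 1)
        assert res.notes["scale"] == 1.0

    def test_unequal_reads_moment_matched_null(self, rng):
        reads = rng.integers(800, 1201, 24)
        table = dm_sample(DMParams(np.array([0.4, 0.3, 0.3]), 0.0), 24, reads, seed=2)
        res = overdispersion_test(table)
        assert "moment-matched" in res.notes["null"]
        # matched df stays near the equal-reads value for mildly uneven reads
        assert res.df == pytest.approx((24 - 1) * (3 - 1), rel=0.05)
        assert res.notes["statistic_normalized"] == pytest.approx(
            res.statistic / res.notes["scale"]
        )

    def test_bootstrap_null_agrees_with_analytic(self, rng):
        reads = rng.integers(500, 2001, 20)
        table = dm_sample(DMParams(np.array([0.5, 0.3, 0.2]), 0.0), 20, reads, seed=3)
        analytic = overdispersion_test(table)
        boot = overdispersion_test(table, null_moments="bootstrap", seed=9)
        assert boot.df == pytest.approx(analytic.df, rel=0.10)
        assert boot.p_value == pytest.approx(analytic.p_value, abs=0.05)

    def test_detects_strong_overdispersion(self, rng):
        reads = rng.integers(800, 1201, 24)
        table = dm_sample(DMParams(np.array([0.4, 0.3, 0.3]), 0.05), 24, reads, seed=4)
        assert overdispersion_test(table).p_value < 1e-6

    def test_null_calibration_unequal_reads(self):
        rng = np.random.default_rng(501)
        n = 400
        rej = 0
        for _ in range(n):
            reads = rng.integers(800, 1201, 24)
            table = dm_sample(
                DMParams(np.array([0.4, 0.3, 0.3]), 0.0), 24, reads, seed=rng
            )
            rej += overdispersion_test(table).p_value <= 0.05
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rej / n - 0.05) < 3 * se

    def test_all_zero_taxon_dropped_with_note(self):
        table = TaxaCountTable.from_counts([[40, 60, 0], [55, 45, 0]])
        res = overdispersion_test(table)
        assert res.notes["dropped_taxa"] == ["taxon_3"]


class TestOneSample:
    def test_statistic_zero_when_proportions_match_pi0(self):
        table = TaxaCountTable.from_counts([[60, 40], [60, 40]])
        res = one_sample_test(table, [0.6, 0.4])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_df_is_k_minus_one(self, rng):
        pi = np.full(12, 1 / 12)
        table = dm_sample(DMParams(pi, 0.02), 10, 2000, seed=rng)
        assert one_sample_test(table, pi).df == 11

    def test_pi0_validation(self, toy_table):
        with pytest.raises(ValueError, match="length"):
            one_sample_test(toy_table, [0.5, 0.3, 0.2])
        with pytest.raises(ValueError, match="probability"):
            one_sample_test(toy_table, [0.7, 0.7])

    def test_null_calibration(self):
        rng = np.random.default_rng(502)
        params = DMParams(np.array([0.5, 0.3, 0.2]), 0.02)
        n = 400
        rej = sum(
            one_sample_test(dm_sample(params, 25, 2000, seed=rng), params.pi).p_value
            <= 0.05
            for _ in range(n)
        )
        assert abs(rej / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


class TestTwoSamples:
    def test_identical_groups_give_zero_statistic(self):
        t = TaxaCountTable.from_counts([[30, 20, 10], [25, 20, 15]])
        res = two_samples_test(GroupedTables((("a", t), ("b", t))))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_df_eleven_for_twelve_taxa(self, rng):
        pi = np.full(12, 1 / 12)
        g = make_groups([DMParams(pi, 0.02)] * 2, 10, 2000, rng)
        assert two_samples_test(g).df == 11

    def test_requires_two_groups_of_two(self, rng):
        pi = DMParams(np.array([0.5, 0.5]), 0.02)
        one = dm_sample(pi, 1, 100, seed=rng)
        two = dm_sample(pi, 3, 100, seed=rng)
        with pytest.raises(ValueError, match="2 samples"):
            two_samples_test(GroupedTables((("a", one), ("b", two))))

    def test_all_zero_column_removed_and_df_reduced(self, rng):
        pi = DMParams(np.array([0.6, 0.4, 0.0]), 0.02)
        g = make_groups([pi, pi], 10, 1000, rng)
        res = two_samples_test(g)
        assert res.df == 1
        assert res.notes["removed_taxa"] == ["taxon_3"]

    def test_taxon_permutation_invariance(self, rng):
        p1 = DMParams(np.array([0.5, 0.3, 0.2]), 0.03)
        p2 = DMParams(np.array([0.4, 0.35, 0.25]), 0.03)
        g = make_groups([p1, p2], 15, 1500, rng)
        base = two_samples_test(g)
        perm = [2, 0, 1]
        shuffled = g.map_tables(lambda t: t.select_taxa(perm))
        res = two_samples_test(shuffled)
        assert res.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_sample_order_invariance(self, rng):
        p = DMParams(np.array([0.5, 0.3, 0.2]), 0.03)
        g = make_groups([p, p], 15, 1500, rng)
        order = list(np.random.default_rng(1).permutation(15))
        shuffled = g.map_tables(lambda t: t.select_samples(order))
        assert two_samples_test(shuffled).statistic == pytest.approx(
            two_samples_test(g).statistic, rel=1e-12
        )

    def test_null_p_values_uniform(self):
        # Kolmogorov-Smirnov check of the p-value distribution under the null
        rng = np.random.default_rng(503)
        params = DMParams(np.array([0.5, 0.3, 0.2]), 0.03)
        pvals = [
            two_samples_test(make_groups([params, params], 25, 2000, rng)).p_value
            for _ in range(1000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_heterogeneous_dispersion_does_not_inflate_size(self):
        # groups with different within-group variability: type-I error stays
        # at the nominal level (the parametric advantage over permutation)
        rng = np.random.default_rng(504)
        pi = np.array([0.5, 0.3, 0.2])
        n = 400
        rej = 0
        for _ in range(n):
            g = GroupedTables.from_tables(
                [
                    ("low", dm_sample(DMParams(pi, 0.01), 25, 2000, seed=rng)),
                    ("high", dm_sample(DMParams(pi, 0.08), 25, 2000, seed=rng)),
                ]
            )
            rej += two_samples_test(g).p_value <= 0.05
        assert abs(rej / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


class TestSeveralSamples:
    def test_identical_groups_give_zero_statistic(self):
        t = TaxaCountTable.from_counts([[30, 20, 10], [25, 20, 15]])
        g = GroupedTables((("a", t), ("b", t), ("c", t)))
        assert several_samples_test(g).statistic == pytest.approx(0.0, abs=1e-10)

    def test_df_twenty_two_for_three_groups_twelve_taxa(self, rng):
        pi = np.full(12, 1 / 12)
        g = make_groups([DMParams(pi, 0.02)] * 3, 10, 2000, rng)
        assert several_samples_test(g).df == 22

    def test_j_equal_two_matches_two_sample_test(self, rng):
        p1 = DMParams(np.array([0.5, 0.3, 0.2]), 0.03)
        p2 = DMParams(np.array([0.45, 0.3, 0.25]), 0.03)
        g = make_groups([p1, p2], 20, 1500, rng)
        res_two = two_samples_test(g)
        res_many = several_samples_test(g)
        assert res_many.statistic == pytest.approx(res_two.statistic, rel=1e-8)
        assert res_many.df == res_two.df
        assert res_many.p_value == pytest.approx(res_two.p_value, rel=1e-8)

    def test_group_with_single_sample_rejected(self, rng):
        p = DMParams(np.array([0.5, 0.5]), 0.02)
        g = GroupedTables(
            (
                ("a", dm_sample(p, 3, 100, seed=rng)),
                ("b", dm_sample(p, 1, 100, seed=rng)),
                ("c", dm_sample(p, 3, 100, seed=rng)),
            )
        )
        with pytest.raises(ValueError, match="2 samples"):
            several_samples_test(g)


class TestPairwise:
    def test_bonferroni_reproduces_worked_adjustment(self, rng):
        # three groups -> three pairwise tests; p = 0.0007 becomes 0.0021
        assert min(1.0, 0.0007 * 3) == pytest.approx(0.0021)
        p = DMParams(np.array([0.5, 0.3, 0.2]), 0.02)
        g = make_groups([p, p, p], 8, 800, rng)
        results = pairwise_comparisons(g)
        assert len(results) == 3
        for res in results:
            assert res.p_value == pytest.approx(
                min(1.0, res.notes["p_unadjusted"] * 3)
            )

    def test_adjusted_p_capped_at_one(self, rng):
        p = DMParams(np.array([0.5, 0.3, 0.2]), 0.02)
        g = make_groups([p, p, p], 10, 800, rng)
        results = pairwise_comparisons(g)
        big = [r for r in results if r.notes["p_unadjusted"] > 1 / 3]
        assert big, "null groups should yield at least one large p-value"
        assert all(r.p_value == 1.0 for r in big)

    def test_requires_three_groups(self, rng):
        p = DMParams(np.array([0.5, 0.5]), 0.02)
        g = make_groups([p, p], 5, 500, rng)
        with pytest.raises(ValueError, match="3 or more"):
            pairwise_comparisons(g)

    def test_pair_pooling_recomputed_per_pair(self, rng):
        pis = [
            DMParams(np.array([0.6, 0.3, 0.095, 0.005]), 0.02),
            DMParams(np.array([0.6, 0.3, 0.095, 0.005]), 0.02),
            DMParams(np.array([0.6, 0.3, 0.05, 0.05]), 0.02),
        ]
        g = make_groups(pis, 20, 5000, rng)
        results = pairwise_comparisons(g, pool_threshold=0.01)
        assert len(results) == 3
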