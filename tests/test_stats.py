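import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from epigrain import (ShapeCensus, binomial_g_statistic, bootstrap_compare,
                      joint_binomial_lr, shape_frequencies, synthetic_census,
                      trinomial_reduce)


class TestShapeFrequencies:
    def test_direct_division(self):
        df = shape_frequencies(ShapeCensus({5: 12, 6: 48}))
        freq = dict(zip(df.polygon_class, df.frequency))
        assert freq == {5: pytest.approx(0.2), 6: pytest.approx(0.8)}

    def test_frequencies_sum_to_one(self):
        df = shape_frequencies(ShapeCensus({4: 7, 5: 11, 6: 23, 7: 9}))
        assert df.frequency.sum() == pytest.approx(1.0)

    def test_single_class_census(self):
        df = shape_frequencies(ShapeCensus({6: 10}))
        assert df.frequency.tolist() == [1.0]

    def test_replicates_get_standard_errors(self, rng):
        reps = synthetic_census({5: 0.2, 6: 0.8}, 100, 5, rng)
        df = shape_frequencies(reps)
        assert np.isfinite(df.se).all()

    def test_empty_census_rejected(self):
        with pytest.raises(ValueError):
            shape_frequencies(ShapeCensus({}))


class TestTrinomialReduction:
    def test_second_class_from_pooled_non_hexagons(self):
        table = trinomial_reduce(
            {"a": [ShapeCensus({5: 15, 6: 80, 7: 5})]})
        assert table.second_class == 5
        assert table.counts[0].tolist() == [80.0, 15.0, 5.0]

    def test_counts_conserved(self):
        censuses = {"a": [ShapeCensus({4: 3, 5: 10, 6: 50, 7: 8})],
                    "b": [ShapeCensus({5: 20, 6: 40, 8: 6})]}
        table = trinomial_reduce(censuses)
        assert table.counts.sum() == 71 + 66

    def test_tie_broken_toward_smaller_class_and_logged(self):
        table = trinomial_reduce({"a": [ShapeCensus({5: 10, 6: 30, 7: 10})]})
        assert table.second_class == 5
        assert table.tie_logged

    def test_all_hexagon_data_rejected(self):
        with pytest.raises(ValueError):
            trinomial_reduce({"a": [ShapeCensus({6: 50})]})


class TestJointBinomialLR:
    def test_identical_distributions_give_null_result(self):
        c = {"a": [ShapeCensus({5: 20, 6: 60, 7: 20})],
             "b": [ShapeCensus({5: 20, 6: 60, 7: 20})]}
        res = joint_binomial_lr(trinomial_reduce(c))
        assert res.lr_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n_conditions,df", [(2, 2), (5, 8), (7, 12)])
    def test_degrees_of_freedom_rule(self, rng, n_conditions, df):
        censuses = {
            f"c{i}": synthetic_census({5: 0.2, 6: 0.6, 7: 0.2}, 200, 1, rng,
                                      condition=f"c{i}")
            for i in range(n_conditions)}
        res = joint_binomial_lr(trinomial_reduce(censuses))
        assert res.df == df == 2 * (n_conditions - 1)
        assert sum(c["df"] for c in res.components) == df

    @given(st.integers(2, 10))
    @settings(max_examples=20, deadline=None)
    def test_df_always_twice_conditions_minus_one(self, n):
        rng = np.random.default_rng(n)
        censuses = {
            f"c{i}": synthetic_census({5: 0.3, 6: 0.5, 7: 0.2}, 150, 1, rng,
                                      condition=f"c{i}")
            for i in range(n)}
        res = joint_binomial_lr(trinomial_reduce(censuses))
        assert res.df == 2 * (n - 1)

    def test_lr_adds_over_the_two_nested_binomial_components(self):
        c = {"a": [ShapeCensus({5: 15, 6: 80, 7: 5})],
             "b": [ShapeCensus({5: 25, 6: 45, 7: 30})]}
        res = joint_binomial_lr(trinomial_reduce(c))
        assert res.lr_statistic == pytest.approx(
            sum(comp["lr"] for comp in res.components))

    def test_matches_independent_g_test_oracle(self):
        # two conditions with trinomial counts (80,15,5) and (45,25,30):
        # the joint LR must equal the sum of two scipy G-tests on the
        # corresponding 2x2 tables
        c = {"A": [ShapeCensus({5: 15, 6: 80, 7: 5})],
             "B": [ShapeCensus({5: 25, 6: 45, 7: 30})]}
        res = joint_binomial_lr(trinomial_reduce(c))
        t1 = np.array([[80, 20], [45, 55]])
        t2 = np.array([[15, 5], [25, 30]])
        g1 = sps.chi2_contingency(t1, correction=False,
                                  lambda_="log-likelihood")[0]
        g2 = sps.chi2_contingency(t2, correction=False,
                                  lambda_="log-likelihood")[0]
        assert res.lr_statistic == pytest.approx(g1 + g2, abs=1e-9)

    def test_exhaustive_small_table_sweep_against_scipy(self):
        # every 2x2 success/failure table with margins in 1..6 and at
        # least one success and one failure per column family
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            table = np.array([[a, b], [c, d]], float)
            g, df = binomial_g_statistic(table)
            ref = sps.chi2_contingency(table, correction=False,
                                       lambda_="log-likelihood")[0]
            assert g == pytest.approx(ref, abs=1e-9)
            assert df == 1

    def test_zero_margin_condition_dropped_with_df_reduction(self):
        c = {"a": [ShapeCensus({5: 15, 6: 80, 7: 5})],
             "b": [ShapeCensus({5: 25, 6: 45, 7: 30})],
             "empty": [ShapeCensus({6: 40})]}  # no non-hexagons
        res = joint_binomial_lr(trinomial_reduce(c))
        # first component keeps 3 conditions (df 2); second drops one (df 1)
        assert res.df == 3
        assert res.warnings

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            joint_binomial_lr(trinomial_reduce(
                {"a": [ShapeCensus({5: 10, 6: 30})]}))

    def test_type_one_error_is_calibrated(self):
        # identical multinomials in both conditions: rejection rate at
        # alpha = 0.05 must fall in the binomial 99% CI over 2000 tests
        rng = np.random.default_rng(2024)
        p = {4: 0.05, 5: 0.25, 6: 0.45, 7: 0.18, 8: 0.07}
        n_sim, alpha, rejections = 2000, 0.05, 0
        for _ in range(n_sim):
            ca = synthetic_census(p, 300, 1, rng, condition="a")
            cb = synthetic_census(p, 300, 1, rng, condition="b")
            res = joint_binomial_lr(trinomial_reduce({"a": ca, "b": cb}))
            rejections += res.p_value < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rejections / n_sim - alpha) < 2.576 * se

    def test_power_against_a_large_hexagon_shift(self):
        # 80% vs 45% hexagons at 300 cells/condition: essentially always
        # detected
        rng = np.random.default_rng(7)
        pa = {5: 0.13, 6: 0.80, 7: 0.07}
        pb = {4: 0.06, 5: 0.25, 6: 0.45, 7: 0.17, 8: 0.07}
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            ca = synthetic_census(pa, 300, 1, rng, condition="a")
            cb = synthetic_census(pb, 300, 1, rng, condition="b")
            res = joint_binomial_lr(trinomial_reduce({"a": ca, "b": cb}))
            rejections += res.p_value < 0.05
        assert rejections / n_sim > 0.99


class TestBootstrap:
    def test_identical_conditions_intervals_contain_zero(self, rng):
        p = {5: 0.2, 6: 0.6, 7: 0.2}
        c = {"a": synthetic_census(p, 200, 6, rng, condition="a"),
             "b": synthetic_census(p, 200, 6, rng, condition="b")}
        df = bootstrap_compare(c, 500, rng)
        hex_rows = df[df.polygon_class == 6]
        assert ((hex_rows.ci_low <= 0) & (hex_rows.ci_high >= 0)).all()

    def test_large_hexagon_difference_excludes_zero(self, rng):
        c = {"narrow": synthetic_census({5: 0.15, 6: 0.8, 7: 0.05}, 300, 6,
                                        rng, condition="narrow"),
             "broad": synthetic_census({5: 0.3, 6: 0.45, 7: 0.25}, 300, 6,
                                       rng, condition="broad")}
        df = bootstrap_compare(c, 2000, rng)
        row = df[(df.polygon_class == 6) & (df.condition == "broad")].iloc[0]
        assert row.ci_high < 0

    def test_preconditions(self, rng):
        c = {"a": synthetic_census({6: 1.0}, 50, 2, rng),
             "b": synthetic_census({6: 1.0}, 50, 2, rng)}
        with pytest.raises(ValueError):
            bootstrap_compare(c, 0, rng)
        c_bad = {"a": c["a"], "b": c["b"][:1]}
        with pytest.raises(ValueError):
            bootstrap_compare(c_bad, 100, rng)


class TestSyntheticCensus:
    def test_degenerate_distribution_is_all_hexagons(self, rng):
        (c,) = synthetic_census({5: 0.0, 6: 1.0}, 500, 1, rng)
        assert c.counts == {6: 500}

    def test_large_sample_frequencies_match_probabilities(self, rng):
        p = {5: 0.10, 6: 0.80, 7: 0.10}
        (c,) = synthetic_census(p, 10000, 1, rng)
        for k, pk in p.items():
            sigma = np.sqrt(pk * (1 - pk) / 10000)
            assert abs(c.counts.get(k, 0) / 10000 - pk) < 3 * sigma + 1e-9

    def test_zero_overdispersion_has_multinomial_variance(self, rng):
        p = {5: 0.3, 6: 0.7}
        reps = synthetic_census(p, 400, 400, rng, overdispersion=0.0)
        freqs = np.array([c.counts.get(6, 0) / 400 for c in reps])
        expected_var = 0.7 * 0.3 / 400
        # variance of sample variance: allow a wide but informative band
        assert expected_var * 0.7 < freqs.var(ddof=1) < expected_var * 1.4

    def test_overdispersion_inflates_between_replicate_variance(self, rng):
        p = {5: 0.3, 6: 0.7}
        reps = synthetic_census(p, 400, 400, rng, overdispersion=0.4)
        freqs = np.array([c.counts.get(6, 0) / 400 for c in reps])
        assert freqs.var(ddof=1) > 2 * 0.7 * 0.3 / 400

    def test_invalid_probability_vector_rejected(self, rng):
        with pytest.raises(ValueError):
            synthetic_census({5: 0.5, 6: 0.6}, 10, 1, rng)
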