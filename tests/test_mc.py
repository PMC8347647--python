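"""Monte-Carlo engine: resampling, quantiles, planning, exact oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockplan.mc import (
    PlanRequest,
    SimulationConfig,
    build_upl_table,
    convergence_check,
    exact_totals_quantile,
    incremental_upl,
    percentile,
    plan_series_time,
    simulate_totals,
)
from blockplan.records import DurationSample


def _sample(values, block_type="spinal"):
    return DurationSample(block_type, np.asarray(values, dtype=float))


CFG = SimulationConfig(n_sims=20_000, seed=3)


class TestSimulateTotals:
    def test_degenerate_sample_gives_constant_totals(self):
        totals = simulate_totals(_sample([5.0]), 3, CFG)
        assert np.all(totals == 15.0)

    def test_k1_is_a_bootstrap_resample(self, spinal_sample):
        cfg = SimulationConfig(n_sims=100_000, seed=4)
        totals = simulate_totals(spinal_sample, 1, cfg)
        se = spinal_sample.durations.std(ddof=1) / np.sqrt(cfg.n_sims)
        assert totals.mean() == pytest.approx(
            spinal_sample.durations.mean(), abs=3 * se
        )
        assert set(np.unique(totals)) <= set(spinal_sample.durations)

    def test_mean_of_sums_matches_expectation(self):
        totals = simulate_totals(_sample([1, 2, 3]), 2, SimulationConfig(n_sims=200_000, seed=5))
        # E[sum of 2 draws from uniform {1,2,3}] = 4; MC SE ~ 0.0026
        assert totals.mean() == pytest.approx(4.0, abs=0.02)

    def test_seed_determinism_bit_identical(self, spinal_sample):
        a = simulate_totals(spinal_sample, 4, CFG)
        b = simulate_totals(spinal_sample, 4, CFG)
        assert np.array_equal(a, b)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            simulate_totals(_sample([1.0]), 0, CFG)


class TestPercentile:
    def test_linear_median_of_one_to_ten(self):
        assert percentile(np.arange(1, 11), 0.5, "linear") == pytest.approx(5.5)

    def test_nearest_rank_median_of_one_to_ten(self):
        assert percentile(np.arange(1, 11), 0.5, "nearest_rank") == 5.0

    def test_constant_vector_any_p(self):
        v = np.full(100, 7.25)
        for p in (0.1, 0.5, 0.9, 0.99):
            assert percentile(v, p) == 7.25

    def test_enumerated_sum_q90_nearest_rank(self):
        # sums of two draws from uniform {1,2,3}: CDF at 5 is 8/9 < 0.9
        sums = np.array([a + b for a in (1, 2, 3) for b in (1, 2, 3)], float)
        assert percentile(sums, 0.9, "nearest_rank") == 6.0

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            percentile(np.arange(5), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=60),
        st.floats(0.01, 0.99),
    )
    def test_nearest_rank_is_an_order_statistic(self, values, p):
        v = np.asarray(values)
        q = percentile(v, p, "nearest_rank")
        assert q in v
        assert v.min() <= q <= v.max()
        # monotone in p
        assert q <= percentile(v, min(p + 0.01, 0.995), "nearest_rank")


class TestExactOracle:
    def test_point_mass(self):
        assert exact_totals_quantile({5.0: 1.0}, 3, 0.42) == 15.0

    @pytest.mark.parametrize("p, expected", [(0.9, 6.0), (0.5, 4.0)])
    def test_uniform_three_support(self, p, expected):
        dist = {1.0: 1 / 3, 2.0: 1 / 3, 3.0: 1 / 3}
        assert exact_totals_quantile(dist, 2, p) == expected

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            exact_totals_quantile({1.0: 0.5, 2.0: 0.4}, 2, 0.5)

    def test_enumeration_guard(self):
        dist = {float(i): 1 / 50 for i in range(50)}
        with pytest.raises(ValueError, match="guard"):
            exact_totals_quantile(dist, 8, 0.5)

    def test_mc_converges_to_oracle(self):
        """Resampled quantiles agree with exact convolution on a small
        discrete distribution (tolerance: one support-grid step)."""
        vals = np.array([2.0, 3.0, 5.0, 5.0])  # duplicated atom -> p = 1/2
        dist = {2.0: 0.25, 3.0: 0.25, 5.0: 0.5}
        cfg = SimulationConfig(n_sims=1_000_000, seed=6)
        for k in (2, 3):
            totals = simulate_totals(_sample(vals), k, cfg)
            for p in (0.5, 0.8, 0.9, 0.95):
                mc_q = percentile(totals, p, "nearest_rank")
                exact_q = exact_totals_quantile(dist, k, p)
                assert abs(mc_q - exact_q) <= 1.0


class TestUPLTable:
    def test_degenerate_sample_row(self):
        table = build_upl_table(_sample([10.0]), 4, CFG)
        row = table.row(4)
        assert all(row[c] == 40.0 for c in ("median", "mean", "upl80", "upl90", "upl95"))

    def test_k1_mean_matches_sample_mean(self, spinal_sample):
        table = build_upl_table(spinal_sample, 2, CFG)
        se = spinal_sample.durations.std(ddof=1) / np.sqrt(CFG.n_sims)
        assert table.row(1)["mean"] == pytest.approx(
            spinal_sample.durations.mean(), abs=4 * se
        )

    def test_columns_strictly_increase_in_k(self, spinal_sample):
        table = build_upl_table(spinal_sample, 6, CFG)
        for col in (table.median, table.mean, table.upl80, table.upl90, table.upl95):
            assert np.all(np.diff(col) > 0)

    def test_upl_increases_in_p_within_rows(self, spinal_sample):
        table = build_upl_table(spinal_sample, 4, CFG)
        for k in table.k:
            row = table.row(k)
            assert row["median"] <= row["upl80"] <= row["upl90"] <= row["upl95"]

    def test_mean_additivity(self, spinal_sample):
        cfg = SimulationConfig(n_sims=100_000, seed=7)
        totals = simulate_totals(spinal_sample, 5, cfg)
        mu = spinal_sample.durations.mean()
        mc_se = totals.std(ddof=1) / np.sqrt(cfg.n_sims)
        assert totals.mean() == pytest.approx(5 * mu, abs=4 * mc_se)

    def test_bracket_property(self, spinal_sample):
        """The series UPL sits between additive means and additive UPLs."""
        cfg = SimulationConfig(n_sims=50_000, seed=8)
        table = build_upl_table(spinal_sample, 5, cfg)
        mu = spinal_sample.durations.mean()
        upl1 = table.row(1)["upl90"]
        for k in range(2, 6):
            upl_k = table.row(k)["upl90"]
            assert k * mu < upl_k < k * upl1


class TestPlanning:
    def test_bonferroni_per_person_coverage(self):
        req = PlanRequest(n_blocks=6, n_anesthesiologists=2, coverage=0.90)
        assert req.per_person_coverage == pytest.approx(0.95)
        assert req.blocks_per_person == 3

    def test_single_anesthesiologist_identity(self):
        req = PlanRequest(n_blocks=4, n_anesthesiologists=1, coverage=0.90)
        assert req.per_person_coverage == 0.90
        assert req.blocks_per_person == 4

    def test_uneven_split_uses_max_load(self):
        assert PlanRequest(n_blocks=7, n_anesthesiologists=2).blocks_per_person == 4

    def test_surplus_staff_uses_one_block_each(self):
        assert PlanRequest(n_blocks=2, n_anesthesiologists=5).blocks_per_person == 1

    def test_plan_equals_adjusted_percentile(self, spinal_sample):
        req = PlanRequest(n_blocks=6, n_anesthesiologists=2, coverage=0.90)
        planned = plan_series_time(spinal_sample, req, CFG)
        totals = simulate_totals(spinal_sample, 3, CFG, stream=3)
        assert planned == percentile(totals, 0.95, CFG.quantile_rule)

    def test_two_parallel_plan_exceeds_single_90(self, spinal_sample):
        one = plan_series_time(
            spinal_sample, PlanRequest(n_blocks=3, n_anesthesiologists=1), CFG
        )
        two = plan_series_time(
            spinal_sample, PlanRequest(n_blocks=6, n_anesthesiologists=2), CFG
        )
        assert two > one


class TestIncrements:
    def test_increments_telescope(self, spinal_sample):
        table = build_upl_table(spinal_sample, 5, CFG)
        inc = incremental_upl(table, 0.9)
        assert inc.sum() == pytest.approx(table.row(5)["upl90"])

    def test_second_increment_below_first(self, spinal_sample):
        cfg = SimulationConfig(n_sims=100_000, seed=9)
        table = build_upl_table(spinal_sample, 3, cfg)
        inc = incremental_upl(table, 0.9)
        assert inc[1] < inc[0]

    def test_degenerate_sample_constant_increments(self):
        table = build_upl_table(_sample([10.0]), 4, CFG)
        assert np.allclose(incremental_upl(table, 0.9), 10.0)

    def test_requires_two_rows(self, spinal_sample):
        table = build_upl_table(spinal_sample, 1, CFG)
        with pytest.raises(ValueError):
            incremental_upl(table, 0.9)


class TestConvergence:
    def test_near_full_subset_has_tiny_difference(self, spinal_sample):
        cfg = SimulationConfig(n_sims=20_000, seed=10)
        rep = convergence_check(spinal_sample, 3, cfg, m_subset=19_999)
        assert rep.max_diff_seconds < 5.0

    def test_degenerate_sample_is_exactly_stable(self):
        rep = convergence_check(_sample([10.0]), 3, CFG, m_subset=10_000)
        assert rep.max_diff_seconds == 0.0

    def test_subset_must_be_smaller(self, spinal_sample):
        with pytest.raises(ValueError):
            convergence_check(spinal_sample, 2, CFG, m_subset=CFG.n_sims)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_sims=0)
    with pytest.raises(ValueError):
        SimulationConfig(quantile_rule="excel")
    with pytest.raises(ValueError):
        SimulationConfig(percentiles=(0.5, 1.5))
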