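"""Per-shift performance statistics: identities, oracle, ECDF, bias table."""

import math

import numpy as np
import pytest

from posturesim import (
    PerformanceRecord,
    SamplingStrategy,
    ShiftRecording,
    ecdf_across_shifts,
    generate_iid_shift,
    median_bias_table,
    performance_record,
    population_performance,
    true_value,
    window_values,
)
from posturesim.performance import CORE_VARIABLES


def brute_force_quantile(values, q):
    s = sorted(values)
    rank = 1 + q * (len(s) - 1)
    lo, hi = int(math.floor(rank)) - 1, int(math.ceil(rank)) - 1
    frac = rank - math.floor(rank)
    return s[lo] + frac * (s[hi] - s[lo])


def brute_force_record(shift, window_min, variable):
    """Independent recomputation with explicit loops, no shared code."""

    def evaluate(seq):
        seq = list(seq)
        if variable == "mean_angle":
            return sum(seq) / len(seq)
        if variable == "range_10_90":
            return brute_force_quantile(seq, 0.9) - brute_force_quantile(seq, 0.1)
        q = {"p10": 0.1, "p50": 0.5, "p90": 0.9}[variable]
        return brute_force_quantile(seq, q)

    rate = shift.sample_rate
    angles = list(shift.angles)
    n_min = len(angles) // rate
    estimates = []
    for start in range(1, n_min - window_min + 2):
        lo = (start - 1) * rate
        estimates.append(evaluate(angles[lo : lo + window_min * rate]))
    m = evaluate(angles)
    n = len(estimates)
    mu = sum(estimates) / n
    s = math.sqrt(sum((e - mu) ** 2 for e in estimates) / (n - 1)) if n > 1 else math.nan
    p_lo = brute_force_quantile(estimates, 0.025) if n > 1 else math.nan
    p_hi = brute_force_quantile(estimates, 0.975) if n > 1 else math.nan
    return m, n, mu, s, mu - m, p_lo, p_hi, p_lo - m, p_hi - m


class TestPerformanceRecord:
    def test_toy_shift_hand_computed_statistics(self, toy_shift):
        rec = performance_record(toy_shift, SamplingStrategy(2), "mean_angle")
        assert rec.M == 20.0
        assert rec.mu_y == 24.0
        assert rec.B == pytest.approx(4.0)
        assert rec.s_y == pytest.approx(math.sqrt(630.0))
        assert rec.n_windows == 5

    def test_constant_shift_has_zero_bias_and_spread(self, constant_shift):
        for variable in ("p10", "p90", "range_10_90", "mean_angle"):
            rec = performance_record(constant_shift, SamplingStrategy(10), variable)
            assert rec.B == 0.0
            assert rec.s_y == 0.0
            assert rec.D2_5 == 0.0 and rec.D97_5 == 0.0

    def test_whole_shift_window_unbiased_with_undefined_spread(self, small_population):
        shift = small_population[0]
        rec = performance_record(shift, SamplingStrategy(shift.duration_min), "p50")
        assert rec.n_windows == 1
        assert rec.B == 0.0
        assert math.isnan(rec.s_y) and math.isnan(rec.D2_5) and math.isnan(rec.D97_5)

    def test_unknown_variable_errors(self, constant_shift):
        with pytest.raises(ValueError, match="unknown variable"):
            performance_record(constant_shift, SamplingStrategy(5), "p95")

    def test_unknown_sector_errors(self, constant_shift):
        with pytest.raises(ValueError, match="unknown sector"):
            window_values(constant_shift, SamplingStrategy(5), "sector_overhead")

    @pytest.mark.parametrize("variable", ["p10", "p50", "p90", "range_10_90", "mean_angle"])
    @pytest.mark.parametrize("window_min", [2, 7, 15])
    def test_matches_independent_brute_force_on_short_shifts(self, variable, window_min):
        rng = np.random.default_rng(window_min * 100 + len(variable))
        shift = ShiftRecording("S", "D", 2, rng.uniform(0, 90, 2 * 30))
        rec = performance_record(shift, SamplingStrategy(window_min), variable)
        m, n, mu, s, b, p_lo, p_hi, d_lo, d_hi = brute_force_record(shift, window_min, variable)
        assert rec.M == pytest.approx(m, abs=1e-9)
        assert rec.n_windows == n
        assert rec.mu_y == pytest.approx(mu, abs=1e-9)
        assert rec.s_y == pytest.approx(s, abs=1e-9)
        assert rec.B == pytest.approx(b, abs=1e-9)
        assert rec.P2_5 == pytest.approx(p_lo, abs=1e-9)
        assert rec.P97_5 == pytest.approx(p_hi, abs=1e-9)
        assert rec.D2_5 == pytest.approx(d_lo, abs=1e-9)
        assert rec.D97_5 == pytest.approx(d_hi, abs=1e-9)

    def test_dispersion_limits_cover_95_percent_of_estimates(self):
        # continuous-valued estimates (window means of an iid series have
        # no exact ties), so coverage is 95% up to quantile granularity
        shift = generate_iid_shift("uniform", 300, low=0, high=90, seed=14)
        rec = performance_record(shift, SamplingStrategy(20), "mean_angle")
        y = window_values(shift, SamplingStrategy(20), "mean_angle")
        inside = np.mean((y >= rec.P2_5) & (y <= rec.P97_5))
        assert inside == pytest.approx(0.95, abs=1.0 / rec.n_windows + 1e-9)


class TestPopulationPerformance:
    def test_cardinality_shifts_times_strategies_times_variables(self, small_population):
        recs = population_performance(
            small_population, [SamplingStrategy(5), SamplingStrategy(60)], CORE_VARIABLES
        )
        assert len(recs) == len(small_population) * 2 * 4

    def test_identity_suite_exact_per_record(self, small_population):
        recs = population_performance(
            small_population,
            [SamplingStrategy(5), SamplingStrategy(40)],
            ("p10", "p90", "range_10_90"),
        )
        by_key = {(r.subject_id, r.shift_id, r.strategy, r.variable): r for r in recs}
        for r in recs:
            assert r.B == r.mu_y - r.M
            assert r.D2_5 == r.P2_5 - r.M and r.D97_5 == r.P97_5 - r.M
            assert r.P2_5 <= r.P97_5
        for (subj, sid, strat, var), r in by_key.items():
            if var == "range_10_90":
                b10 = by_key[(subj, sid, strat, "p10")].B
                b90 = by_key[(subj, sid, strat, "p90")].B
                assert r.B == pytest.approx(b90 - b10, abs=1e-9)

    def test_skip_policy_drops_short_shift_with_warning(self, caplog):
        short = ShiftRecording("S", "D", 1, np.full(100, 20.0))
        with caplog.at_level("WARNING"):
            recs = population_performance([short], [SamplingStrategy(240)], ("p50",))
        assert recs == []
        assert "skipping shift" in caplog.text

    def test_strict_policy_raises(self):
        short = ShiftRecording("S", "D", 1, np.full(100, 20.0))
        with pytest.raises(ValueError, match="exceeds shift"):
            population_performance([short], [SamplingStrategy(240)], ("p50",), policy="strict")


class TestEcdfAndBiasTable:
    def test_ecdf_definition(self):
        recs = [
            PerformanceRecord("S", str(i), SamplingStrategy(5), "p10", 0, 10, v, 1, v, 0, 0, 0, 0)
            for i, v in enumerate([3.0, 1.0, 2.0])
        ]
        curve = ecdf_across_shifts(recs, "B")
        np.testing.assert_array_equal(curve.values, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.probabilities, [1 / 3, 2 / 3, 1.0])

    def test_ecdf_median_matches_quantile_convention(self):
        values = [5.0, 1.0, 4.0, 2.0]
        recs = [
            PerformanceRecord("S", str(i), SamplingStrategy(5), "p10", 0, 10, v, 1, v, 0, 0, 0, 0)
            for i, v in enumerate(values)
        ]
        assert ecdf_across_shifts(recs, "B").median() == float(np.quantile(values, 0.5))

    def test_ecdf_empty_input_errors(self):
        with pytest.raises(ValueError):
            ecdf_across_shifts([], "B")

    def test_median_bias_table_definitions(self):
        recs = [
            PerformanceRecord("S", str(i), SamplingStrategy(5), "p10", 0, 10, b, 1, b, 0, 0, 0, 0)
            for i, b in enumerate([-2.0, 0.0, 6.0])
        ]
        tab = median_bias_table(recs)
        row = tab.iloc[0]
        assert row["median_bias"] == 0.0
        assert row["mean_bias"] == pytest.approx(4.0 / 3.0)
        assert row["n_shifts"] == 3

    def test_single_shift_median_equals_mean(self):
        recs = [PerformanceRecord("S", "D", SamplingStrategy(5), "p10", 0, 10, 2.5, 1, 2.5, 0, 0, 0, 0)]
        tab = median_bias_table(recs)
        assert tab.iloc[0]["median_bias"] == tab.iloc[0]["mean_bias"] == 2.5

    def test_median_corrected_estimates_have_zero_median_residual(self, small_population):
        strat = SamplingStrategy(5)
        recs = population_performance(small_population, [strat], ("p10",))
        correction = float(median_bias_table(recs).iloc[0]["median_bias"])
        residual = np.median([r.B - correction for r in recs])
        # subtracting the median bias re-centres the population's bias at 0
        assert residual == pytest.approx(0.0, abs=1e-9)


class TestPrecisionLaw:
    def test_iid_shift_follows_sqrt_duration_law(self):
        ratios = []
        for seed in range(8):
            shift = generate_iid_shift("uniform", 480, low=0, high=90, seed=300 + seed)
            s10 = performance_record(shift, SamplingStrategy(10), "mean_angle").s_y
            s40 = performance_record(shift, SamplingStrategy(40), "mean_angle").s_y
            ratios.append(s10 / s40)
        assert np.median(ratios) == pytest.approx(2.0, abs=0.2)
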