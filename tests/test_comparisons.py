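"""t-tests, Spearman correlation (exact small-n p), sample-size rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirvar.comparisons import (
    SampleSizeSpec,
    compare_protocols,
    correlate,
    order_of_draw_test,
    paired_sample_size,
)
from mirvar.errors import DegenerateVarianceError
from mirvar.quantification import normalize_table
from mirvar.synthetic_data import SyntheticConfig, generate_centrifugation_experiment


def levels_frame(dual, single, assay="miR-92a", strategy="spike"):
    rows = []
    for protocol, vals in (("dual", dual), ("single", single)):
        start = 1 if protocol == "dual" else 2
        for i, v in enumerate(vals):
            rows.append({"assay": assay, "strategy": strategy,
                         "protocol": protocol, "draw_order": start + 2 * i,
                         "level": v})
    return pd.DataFrame(rows)


class TestCompareProtocols:
    def test_identical_groups_no_difference(self):
        frame = levels_frame([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        res = compare_protocols(frame).iloc[0]
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_separated_groups_tiny_p(self):
        frame = levels_frame([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert compare_protocols(frame).iloc[0]["p_value"] < 0.001

    def test_four_plus_four_closed_form(self):
        # x = {1,2,3,4}, y = {2,4,6,8}: pooled var 25/6,
        # t = -2.5 / sqrt(25/12) = -sqrt(3), df = 6
        frame = levels_frame([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        res = compare_protocols(frame).iloc[0]
        assert res["statistic"] == pytest.approx(-math.sqrt(3.0))
        assert res["p_value"] == pytest.approx(
            2 * stats.t.sf(math.sqrt(3.0), 6))

    def test_paired_by_adjacent_tube(self):
        dual = [1.0, 2.0, 3.0, 4.0]
        single = [v + 0.5 + 0.01 * i for i, v in enumerate(dual)]
        frame = levels_frame(dual, single)
        res = compare_protocols(frame, "paired_by_adjacent_tube").iloc[0]
        assert res["test_kind"] == "student_t_paired"
        d = np.array(dual) - np.array(single)
        t_hand = d.mean() / (d.std(ddof=1) / 2.0)
        assert res["statistic"] == pytest.approx(t_hand)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_protocols(levels_frame([1.0], [1.0, 2.0]))


class TestOrderOfDraw:
    @staticmethod
    def _levels(seed, trend=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for tube in range(1, 31):
            rows.append({"assay": "miR-92a", "strategy": "spike",
                         "protocol": "dual" if tube % 2 else "single",
                         "draw_order": tube,
                         "level": math.exp(rng.normal(0.0, 0.2))
                         + trend * tube})
        return pd.DataFrame(rows)

    def test_null_p_values_calibrated(self):
        # no order effect -> p approximately uniform: mean ~ 0.5
        ps = [order_of_draw_test(self._levels(seed)).iloc[0]["p_value"]
              for seed in range(200)]
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_strong_trend_detected(self):
        res = order_of_draw_test(self._levels(0, trend=0.5)).iloc[0]
        assert res["p_value"] < 0.01
        assert res["n_first"] == 10 and res["n_last"] == 10

    def test_constant_unequal_groups_degenerate(self):
        frame = self._levels(0)
        frame["level"] = np.where(frame["draw_order"] <= 15, 1.0, 2.0)
        with pytest.raises(DegenerateVarianceError):
            order_of_draw_test(frame)

    def test_missing_draw_order_rejected(self):
        frame = self._levels(0)
        frame.loc[0, "draw_order"] = np.nan
        with pytest.raises(ValueError):
            order_of_draw_test(frame)

    def test_no_order_effect_in_default_generator(self, study_config):
        levels = normalize_table(
            generate_centrifugation_experiment(study_config), "spike")
        res = order_of_draw_test(levels)
        assert (res["n_first"] == 10).all()


class TestCorrelate:
    def test_monotone_map_gives_rho_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        y = [math.exp(v) for v in x]
        res = correlate(x, y)
        assert res.rho == pytest.approx(1.0)
        assert res.label == "good"

    def test_reversed_ranks_give_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = correlate(x, x[::-1])
        assert res.rho == pytest.approx(-1.0)

    def test_exact_permutation_p_at_n6(self):
        # brute force: all 720 orderings of the y-ranks
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        res = correlate(x, y)
        rho_obs = stats.spearmanr(x, y).statistic
        count = 0
        for perm in itertools.permutations(range(6)):
            r = stats.spearmanr(x, y[list(perm)]).statistic
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 720, abs=0.01)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = correlate(x, y)
        expected = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(expected.statistic)
        assert res.p_value == pytest.approx(expected.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = correlate(x, y).rho
        assert correlate(np.exp(x), y).rho == pytest.approx(base)
        assert correlate(x, 3 * y + 7).rho == pytest.approx(base)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            correlate([1.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])

    @pytest.mark.parametrize("rho,label", [(0.1, "none"), (0.5, "intermediate"),
                                           (0.95, "good")])
    def test_labels(self, rho, label):
        rng = np.random.default_rng(6)
        # construct vectors with approximately the wanted rho
        n = 200
        x = rng.normal(size=n)
        y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
        res = correlate(x, y)
        assert res.label == label


class TestPairedSampleSize:
    def test_study_parameters_give_twelve(self):
        assert paired_sample_size(SampleSizeSpec()) == 12

    def test_large_effect_floor(self):
        spec = SampleSizeSpec(relative_difference=0.80)  # d ~ 7.3
        assert 2 <= paired_sample_size(spec) <= 3

    def test_monotone_in_difference_sd_and_correlation(self):
        base = paired_sample_size(SampleSizeSpec())
        assert paired_sample_size(
            SampleSizeSpec(relative_difference=0.20)) <= base
        assert paired_sample_size(SampleSizeSpec(relative_sd=0.40)) >= base
        assert paired_sample_size(
            SampleSizeSpec(pair_correlation=0.95)) <= base
        assert paired_sample_size(
            SampleSizeSpec(pair_correlation=0.50)) >= base

    def test_monte_carlo_power_reaches_target(self):
        spec = SampleSizeSpec()
        n = paired_sample_size(spec)
        rng = np.random.default_rng(42)
        mean = 10.0
        sd_diff = spec.relative_sd * mean * math.sqrt(
            2 * (1 - spec.pair_correlation))
        reps = 10_000
        diffs = rng.normal(spec.relative_difference * mean, sd_diff,
                           size=(reps, n))
        t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / math.sqrt(n))
        crit = stats.t.ppf(1 - spec.alpha / 2, n - 1)
        power = float(np.mean(np.abs(t) > crit))
        assert power >= 0.8

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            paired_sample_size(SampleSizeSpec(pair_correlation=1.0))
        with pytest.raises(ValueError):
            paired_sample_size(SampleSizeSpec(relative_difference=0.0))


def test_protocol_null_p_uniform_over_simulations():
    """Kolmogorov-Smirnov sanity check: under a true null the
    protocol-comparison p-values are ~Uniform(0,1)."""
    ps = []
    for seed in range(500):
        rng = np.random.default_rng(seed)
        dual = np.exp(rng.normal(0.0, 0.2, size=15))
        single = np.exp(rng.normal(0.0, 0.2, size=15))
        frame = levels_frame(dual, single)
        ps.append(compare_protocols(frame).iloc[0]["p_value"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01
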