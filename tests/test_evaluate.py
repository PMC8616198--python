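"""Paired statistics, population DVHs, confidence bands, angle histograms."""

import numpy as np
import pytest

import lexiplan as lp
from lexiplan.evaluate import (
    PairedComparison,
    beam_angle_distribution,
    comparison_to_frame,
    metrics_table,
    paired_dvh_difference_ci,
    population_average_dvh,
    wilcoxon_signed_rank,
)
from lexiplan.metrics import DVHCurve

import oracles
from test_metrics import make_plan


class TestWilcoxon:
    def test_three_positive_pairs_exact_p(self):
        stat, p = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(0.25)

    def test_identical_samples_give_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            stat, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle_at_n10(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1.0, 10)
        y = rng.normal(0.0, 1.0, 10)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(
            oracles.wilcoxon_exact_enumeration(x - y), abs=1e-12
        )

    def test_handles_tied_absolute_differences(self):
        x = np.array([3.0, 1.0, 4.0, 6.0, 2.0])
        y = np.array([1.0, 3.0, 2.0, 4.0, 1.0])  # |d| = 2,2,2,2,1
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(
            oracles.wilcoxon_exact_enumeration(x - y), abs=1e-12
        )

    def test_large_n_uses_tie_corrected_normal_approximation(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.normal(0.4, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        _, p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x - y, correction=False, method="approx").pvalue
        assert p == pytest.approx(float(ref), rel=1e-12)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


def flat_dvh(level, structure="heart", top=60.0):
    axis = np.arange(0.0, top, 0.5)
    return DVHCurve(axis, np.full_like(axis, float(level)), structure)


def step_curve(d_step, top=60.0):
    axis = np.arange(0.0, top, 0.5)
    return DVHCurve(axis, np.where(axis <= d_step, 100.0, 0.0), "x")


class TestPopulationDVH:
    def test_identical_curves_average_to_themselves(self):
        c = step_curve(20.0)
        avg = population_average_dvh([c, c, c])
        np.testing.assert_allclose(avg.volume_at(c.dose_Gy), c.volume_pct)

    def test_two_steps_average_to_half_plateau(self):
        avg = population_average_dvh([step_curve(10.0), step_curve(30.0)])
        assert avg.volume_at(20.0) == pytest.approx(50.0)

    def test_singleton_mean_is_identity(self):
        c = step_curve(25.0)
        avg = population_average_dvh([c])
        np.testing.assert_allclose(avg.volume_pct, c.volume_at(avg.dose_Gy))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            population_average_dvh([])


class TestPairedCI:
    def test_identical_cohorts_give_zero_width_band(self):
        a = [step_curve(20.0) for _ in range(5)]
        mean, lo, hi = paired_dvh_difference_ci(a, list(a))
        assert np.abs(mean.volume_pct).max() == 0.0
        assert np.abs(hi - lo).max() == 0.0

    def test_constant_offset_band_centers_on_offset(self):
        a = [flat_dvh(50.0) for _ in range(6)]
        b = [flat_dvh(42.0) for _ in range(6)]
        mean, lo, hi = paired_dvh_difference_ci(a, b)
        np.testing.assert_allclose(mean.volume_pct, 8.0)
        np.testing.assert_allclose(lo, 8.0)
        np.testing.assert_allclose(hi, 8.0)

    def test_bootstrap_band_tracks_t_interval_on_normal_differences(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        n = 26
        diffs = rng.normal(2.0, 3.0, n)
        a = [flat_dvh(30.0 + d) for d in diffs]
        b = [flat_dvh(30.0) for _ in range(n)]
        mean, lo, hi = paired_dvh_difference_ci(a, b, n_boot=4000, seed=1)
        se = diffs.std(ddof=1) / np.sqrt(n)
        t = stats.t.ppf(0.975, n - 1)
        t_lo, t_hi = diffs.mean() - t * se, diffs.mean() + t * se
        assert lo[0] == pytest.approx(t_lo, abs=0.5 * se)
        assert hi[0] == pytest.approx(t_hi, abs=0.5 * se)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="two subjects"):
            paired_dvh_difference_ci([flat_dvh(1)], [flat_dvh(1)])


class TestBeamAngleDistribution:
    def plan_with_angles(self, angles):
        import dataclasses

        base = make_plan({"PTV": np.full(3, 66.0)})
        return dataclasses.replace(base, angles_deg=np.asarray(angles, float))

    def test_unit_bins_for_distinct_angles(self):
        hist = beam_angle_distribution([self.plan_with_angles([0.0, 90.0, 180.0])])
        assert hist == {0.0: 1, 90.0: 1, 180.0: 1}

    def test_rounding_to_nearest_bin_with_wrap(self):
        hist = beam_angle_distribution([self.plan_with_angles([182.0, 357.6])])
        assert hist == {0.0: 1, 180.0: 1}

    def test_total_count_is_conserved(self):
        plans = [
            self.plan_with_angles([10.0, 20.0]),
            self.plan_with_angles([20.0, 30.0, 40.0]),
        ]
        hist = beam_angle_distribution(plans)
        assert sum(hist.values()) == 5


class TestMetricsTable:
    def cohort(self, heart_scale=1.0, n=8):
        rng = np.random.default_rng(2)
        plans = []
        for _ in range(n):
            plans.append(
                make_plan(
                    {
                        "PTV": np.full(20, 66.0) + rng.normal(0, 0.2, 20),
                        "lungs": rng.random(50) * 22.0,
                        "heart": rng.random(30) * 35.0 * heart_scale,
                        "esophagus": rng.random(15) * 40.0,
                    }
                )
            )
        return plans

    def test_identical_cohorts_all_p_one(self):
        a = self.cohort()
        table = metrics_table(a, a)
        assert all(c.p_value == 1.0 for c in table)
        assert all(np.median(c.differences) == 0.0 for c in table)

    def test_halved_heart_dose_detected_as_significant(self):
        a = self.cohort(heart_scale=1.0)
        b = self.cohort(heart_scale=0.5)
        # same seed stream: b's heart doses are exactly half of a's
        table = {c.metric: c for c in metrics_table(b, a)}
        heart = table["heart D_mean"]
        assert heart.p_value <= 0.05
        assert np.median(heart.differences) < 0

    def test_iqr_of_constant_metric_is_zero(self):
        a = [make_plan({"PTV": np.full(5, 66.0)}) for _ in range(4)]
        table = metrics_table(a, a, metric_panel=[("PTV", "D_mean")])
        assert table[0].iqr_a == 0.0

    def test_missing_structure_skipped_with_log(self, caplog):
        a = [make_plan({"PTV": np.full(5, 66.0)}) for _ in range(3)]
        with caplog.at_level("INFO", logger="lexiplan.evaluate"):
            table = metrics_table(a, a, metric_panel=[("heart", "D_mean")])
        assert table == []
        assert any("heart" in r.message for r in caplog.records)

    def test_frame_layout(self):
        a = self.cohort()
        frame = comparison_to_frame(metrics_table(a, a))
        assert list(frame.columns) == [
            "metric", "median_A", "IQR_A", "median_B", "IQR_B", "median_diff", "p",
        ]

    def test_subject_reordering_invariance(self):
        a = self.cohort()
        b = self.cohort(heart_scale=0.8)
        t1 = metrics_table(a, b)
        perm = [3, 1, 0, 2, 7, 5, 6, 4]
        t2 = metrics_table([a[i] for i in perm], [b[i] for i in perm])
        for c1, c2 in zip(t1, t2):
            assert c1.p_value == pytest.approx(c2.p_value)
            assert c1.median_a == pytest.approx(c2.median_a)
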