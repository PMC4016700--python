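import math

import numpy as np
import pytest
from scipy import stats

from iqrray import (
    ArrayIntensities,
    ArraySimSpec,
    ControlPair,
    IntegrityError,
    average_background,
    percent_present,
    pm_mm_ttest,
    quality_report,
    rna_degradation_slope,
    scaling_factor,
    simulate_array,
    three_five_ratio,
)
from iqrray.qc_metrics import signed_rank_p_greater

from conftest import build_layout, toy_array


def paired_values(layout, pm, mm):
    values = np.empty(layout.n_probes)
    values[layout.pm_mask] = pm
    values[~layout.pm_mask] = mm
    return toy_array(layout, values)


class TestPmMmTtest:
    def test_textbook_example(self, paired_layout):
        arr = paired_values(paired_layout, [10, 12, 14], [8, 9, 10])
        # d = (2, 3, 4): t = 3 / (1 / sqrt(3))
        assert pm_mm_ttest(arr, paired_layout) == pytest.approx(3 * math.sqrt(3))

    def test_identical_pm_mm_gives_zero(self, paired_layout):
        arr = paired_values(paired_layout, [5, 6, 7], [5, 6, 7])
        assert pm_mm_ttest(arr, paired_layout) == 0.0

    def test_symmetric_differences_give_zero(self, paired_layout):
        arr = paired_values(paired_layout, [5, 4, 6], [4, 5, 6])
        assert pm_mm_ttest(arr, paired_layout) == 0.0

    def test_shift_invariance_and_sign_flip(self, paired_layout):
        arr = paired_values(paired_layout, [10.0, 12.0, 17.0], [8.0, 9.5, 11.0])
        t = pm_mm_ttest(arr, paired_layout)
        shifted = toy_array(paired_layout, arr.values + 100.0)
        assert pm_mm_ttest(shifted, paired_layout) == pytest.approx(t)
        swapped = paired_values(paired_layout, [8.0, 9.5, 11.0], [10.0, 12.0, 17.0])
        assert pm_mm_ttest(swapped, paired_layout) == pytest.approx(-t)

    def test_zero_variance_nonzero_mean_is_signed_infinity(self, paired_layout):
        arr = paired_values(paired_layout, [5, 6, 7], [4, 5, 6])
        assert pm_mm_ttest(arr, paired_layout) == math.inf

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(11)
        rows = []
        for j in range(40):
            rows.append((f"pm{j}", j, 0, "S", True, f"mm{j}", math.nan))
            rows.append((f"mm{j}", j, 1, "S", False, f"pm{j}", math.nan))
        layout = build_layout(rows)
        for _ in range(100):
            pm = rng.lognormal(5, 1, 40)
            mm = rng.lognormal(4.5, 1, 40)
            t = pm_mm_ttest(paired_values(layout, pm, mm), layout)
            expected = stats.ttest_1samp(pm - mm, 0.0).statistic
            assert t == pytest.approx(expected, rel=1e-10)


class TestBackgroundAndScaling:
    def test_two_percent_of_hundred_cells(self):
        layout = build_layout(
            [(f"p{i}", i % 10, i // 10, None, True, None, math.nan) for i in range(100)]
        )
        arr = toy_array(layout, np.arange(1.0, 101.0))
        assert average_background(arr) == 1.5
        # trimmed mean discards cells 1,2 and 99,100
        assert scaling_factor(arr) == pytest.approx(500 / np.mean(np.arange(3, 99)))

    def test_constant_cells(self, toy_layout):
        arr = toy_array(toy_layout, [100.0] * 4)
        assert average_background(arr) == 100.0
        assert scaling_factor(arr, target=500) == 5.0

    def test_small_array_clamps_to_one_cell(self):
        layout = build_layout(
            [(f"p{i}", i, 0, None, True, None, math.nan) for i in range(10)]
        )
        arr = toy_array(layout, np.arange(10.0, 0.0, -1.0))
        assert average_background(arr, fraction=0.02) == 1.0

    def test_scale_equivariance(self, toy_layout):
        arr = toy_array(toy_layout, [10.0, 30.0, 50.0, 70.0])
        doubled = toy_array(toy_layout, arr.values * 2)
        assert scaling_factor(doubled) == pytest.approx(scaling_factor(arr) / 2)

    def test_match_brute_force_oracles(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(60, 400))
            layout = build_layout(
                [(f"p{i}", i % 64, i // 64, None, True, None, math.nan) for i in range(n)]
            )
            arr = toy_array(layout, rng.lognormal(5, 1.5, n))
            srt = np.sort(arr.values)
            m = max(1, math.floor(0.02 * n))
            assert average_background(arr) == pytest.approx(
                srt[:m].mean(), rel=1e-12
            )
            assert scaling_factor(arr) == pytest.approx(
                500 / stats.trim_mean(arr.values, 0.02), rel=1e-10
            )


class TestDegradationSlope:
    def _positional_layout(self, n_sets=2, k=3):
        rows = []
        for s in range(n_sets):
            for j in range(k):
                rows.append((f"s{s}p{j}", s * k + j, 0, f"s{s}", True, None, float(j)))
        return build_layout(rows)

    def test_known_position_means(self):
        layout = self._positional_layout()
        arr = toy_array(layout, [5, 15, 25, 15, 25, 35])  # means (10, 20, 30)
        assert rna_degradation_slope(arr, layout) == pytest.approx(10.0)

    def test_flat_positions_give_zero(self):
        layout = self._positional_layout()
        arr = toy_array(layout, [7, 7, 7, 9, 9, 9])
        assert rna_degradation_slope(arr, layout) == 0.0

    def test_reversed_positions_negate_slope(self):
        layout = self._positional_layout(n_sets=3, k=4)
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 0.5, 12)
        base = rna_degradation_slope(toy_array(layout, vals), layout)
        rev = layout.probes.copy()
        rev["position_index"] = 3.0 - rev["position_index"]
        from iqrray import ChipLayout

        layout_rev = ChipLayout("t", rev, [], layout.n_rows, layout.n_cols)
        assert rna_degradation_slope(toy_array(layout_rev, vals), layout_rev) == (
            pytest.approx(-base)
        )

    def test_only_modal_size_sets_participate(self):
        rows = []
        for s, k in enumerate((3, 3, 5)):
            for j in range(k):
                rows.append((f"s{s}p{j}", 10 * s + j, 0, f"s{s}", True, None, float(j)))
        layout = build_layout(rows)
        vals = np.concatenate([[5, 15, 25], [15, 25, 35], [1e4] * 5])
        assert rna_degradation_slope(toy_array(layout, vals), layout) == (
            pytest.approx(10.0)
        )

    def test_matches_polyfit_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n_sets, k = int(rng.integers(2, 8)), int(rng.integers(3, 12))
            layout = self._positional_layout(n_sets, k)
            vals = rng.lognormal(4, 1, n_sets * k)
            means = vals.reshape(n_sets, k).mean(axis=0)
            expected = np.polyfit(np.arange(k), means, 1)[0]
            got = rna_degradation_slope(toy_array(layout, vals), layout)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_zero_in_distribution_without_positional_effect(self):
        slopes = []
        for rep in range(50):
            layout, arr = simulate_array(
                ArraySimSpec(n_probe_sets=60, probes_per_set=8, corruption=1.0, seed=600 + rep)
            )
            slopes.append(rna_degradation_slope(arr, layout))
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se + 1e-12

    def test_degraded_arrays_have_positive_slope(self):
        layout, arr = simulate_array(
            ArraySimSpec(n_probe_sets=80, probes_per_set=8, degradation_strength=1.0, seed=2)
        )
        assert rna_degradation_slope(arr, layout) > 0


class TestThreeFiveRatio:
    def _control_layout(self):
        rows = []
        for s, name in enumerate(("act3", "act5")):
            for j in range(3):
                rows.append((f"{name}_{j}", 3 * s + j, 0, name, True, None, math.nan))
        return build_layout(rows, control_pairs=[ControlPair("actin", "act3", "act5")])

    def test_ratio_and_reciprocity(self):
        layout = self._control_layout()
        arr = toy_array(layout, [150, 200, 250, 50, 100, 150])
        assert three_five_ratio(arr, layout, "actin") == pytest.approx(2.0)
        swapped = toy_array(layout, [50, 100, 150, 150, 200, 250])
        assert three_five_ratio(swapped, layout, "actin") == pytest.approx(0.5)

    def test_identical_sets_give_one(self):
        layout = self._control_layout()
        arr = toy_array(layout, [10, 20, 30, 10, 20, 30])
        assert three_five_ratio(arr, layout, "actin") == pytest.approx(1.0)

    def test_unknown_label_is_error(self):
        layout = self._control_layout()
        arr = toy_array(layout, np.ones(6))
        with pytest.raises(IntegrityError, match="nope"):
            three_five_ratio(arr, layout, "nope")


class TestPercentPresent:
    def _pairs_layout(self, n_sets, k=11):
        rows = []
        for s in range(n_sets):
            for j in range(k):
                rows.append((f"s{s}pm{j}", s * k + j, 0, f"s{s}", True, f"s{s}mm{j}", math.nan))
                rows.append((f"s{s}mm{j}", s * k + j, 1, f"s{s}", False, f"s{s}pm{j}", math.nan))
        return build_layout(rows)

    def test_strong_shift_is_present(self):
        layout = self._pairs_layout(1)
        arr = paired_values(layout, np.full(11, 300.0), np.full(11, 100.0))
        # every R = 0.5 >> tau; exact signed-rank p = 2^-11 < 0.04
        assert percent_present(arr, layout) == 100.0

    def test_pm_equal_mm_is_absent(self):
        layout = self._pairs_layout(1)
        arr = paired_values(layout, np.full(11, 100.0), np.full(11, 100.0))
        assert percent_present(arr, layout) == 0.0

    def test_half_present(self):
        layout = self._pairs_layout(2)
        pm = np.concatenate([np.full(11, 300.0), np.full(11, 100.0)])
        mm = np.full(22, 100.0)
        assert percent_present(paired_values(layout, pm, mm), layout) == 50.0

    def test_simulated_extremes(self):
        layout = self._pairs_layout(40)
        rng = np.random.default_rng(17)
        mm = rng.lognormal(4, 1, 440)
        arr = paired_values(layout, mm + rng.uniform(200, 400, 440), mm)
        assert percent_present(arr, layout) == 100.0
        arr = paired_values(layout, mm, mm)
        assert percent_present(arr, layout) == 0.0

    def test_detection_is_scale_dependent(self):
        # the discrimination score is ratio-based, so nonlinear monotone
        # transforms legitimately change the calls
        layout, arr = simulate_array(
            ArraySimSpec(n_probe_sets=150, pm_mm_shift=1.0, corruption=0.3, seed=100)
        )
        base = percent_present(arr, layout)
        logged = ArrayIntensities(
            arr.array_id, arr.platform_id, arr.probe_ids, np.log1p(arr.values)
        )
        assert percent_present(logged, layout) != base

    def test_signed_rank_tail_matches_scipy(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = int(rng.integers(5, 24))
            d = rng.normal(0.2, 1.0, n)
            assert signed_rank_p_greater(d) == pytest.approx(
                stats.wilcoxon(d, alternative="greater", method="exact").pvalue,
                rel=1e-12,
            )
        for _ in range(10):
            d = rng.normal(0.1, 1.0, 60)
            assert signed_rank_p_greater(d) == pytest.approx(
                stats.wilcoxon(
                    d, alternative="greater", method="approx", correction=True
                ).pvalue,
                rel=1e-9,
            )


class TestQualityReport:
    def test_composes_all_metrics_with_directions(self):
        layout, arr = simulate_array(
            ArraySimSpec(n_probe_sets=60, pm_mm_shift=1.0, degradation_strength=0.5, seed=23)
        )
        rep = quality_report(arr, layout)
        expected = {
            "iqrray_all_probes": "ascending",
            "iqrray_pm_only": "ascending",
            "pm_mm_ttest": "ascending",
            "average_background": "descending",
            "scaling_factor": "descending",
            "rna_degradation_slope": "ascending",
            "percent_present": "ascending",
        }
        for name, direction in expected.items():
            assert rep.direction[name] == direction
            assert math.isfinite(rep.metrics[name])

    def test_missing_metrics_carry_reasons(self, toy_layout):
        arr = toy_array(toy_layout, [1, 2, 3, 4])
        rep = quality_report(arr, toy_layout)
        assert "pm_mm_ttest" in rep.missing  # no PM/MM pairs on this layout
        assert "percent_present" in rep.missing
        assert "iqrray_all_probes" in rep.metrics
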