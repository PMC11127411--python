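"""Bland-Altman agreement, pairing rule, and t-test behaviour."""

import numpy as np
import pytest
from scipy import stats

from conftest import first_principles_bland_altman, first_principles_welch
from do2mon.agreement import (
    PairedReading,
    bland_altman,
    bland_altman_plot_data,
    pair_readings,
    unpaired_t,
)


def pairs_from_diffs(diffs, lab=12.0):
    return [PairedReading(t=60.0 * i, sphb=lab + d, lab_hb=lab) for i, d in enumerate(diffs)]


class TestPairing:
    def test_nearest_in_time_wins(self):
        sphb = [(98.0, 11.0), (103.0, 12.0)]
        pairs = pair_readings(sphb, [(100.0, 11.5)])
        assert len(pairs) == 1
        assert pairs[0].sphb == 11.0  # t=98 is 2 s away, t=103 is 3 s away

    def test_outside_window_dropped(self):
        pairs = pair_readings([(500.0, 11.0)], [(100.0, 11.5)], window_s=300.0)
        assert pairs == []

    def test_empty_lab_list(self):
        assert pair_readings([(0.0, 11.0)], []) == []

    def test_one_sphb_value_may_serve_many_labs(self):
        pairs = pair_readings([(100.0, 11.0)], [(90.0, 11.5), (110.0, 12.5)])
        assert [p.sphb for p in pairs] == [11.0, 11.0]


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman(pairs_from_diffs([0.0, 0.0, 0.0]))
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.loa_upper == res.loa_lower == 0.0
        assert res.t_bias_p == 1.0

    def test_known_differences(self):
        # differences {0, 1, 2}: bias 1, SD 1, limits 1 +/- 1.96
        res = bland_altman(pairs_from_diffs([0.0, 1.0, 2.0]))
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_upper == pytest.approx(2.96)
        assert res.loa_lower == pytest.approx(-0.96)

    def test_constant_nonzero_differences(self):
        res = bland_altman(pairs_from_diffs([1.0, 1.0, 1.0]))
        assert res.bias == 1.0 and res.sd_diff == 0.0
        assert res.loa_upper == res.loa_lower == 1.0
        assert res.t_bias_p == 0.0

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(pairs_from_diffs([0.5]))

    def test_limits_are_bias_pm_1_96_sd(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            diffs = rng.normal(0, 1.5, size=n)
            res = bland_altman(pairs_from_diffs(list(diffs)))
            assert res.loa_upper == res.bias + 1.96 * res.sd_diff
            assert res.loa_lower == res.bias - 1.96 * res.sd_diff

    def test_first_principles_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 50))
            sphb = rng.uniform(8, 15, size=n)
            lab = sphb + rng.normal(0.1, 1.0, size=n)
            res = bland_altman(
                [PairedReading(float(i), float(s), float(l)) for i, (s, l) in enumerate(zip(sphb, lab))]
            )
            bias, sd, t = first_principles_bland_altman(sphb, lab)
            assert res.bias == pytest.approx(bias, rel=1e-12, abs=1e-12)
            assert res.sd_diff == pytest.approx(sd, rel=1e-12)
            p_oracle = 2 * stats.t.sf(abs(t), n - 1)
            assert res.t_bias_p == pytest.approx(p_oracle, rel=1e-9)

    def test_paired_and_one_sample_tests_identical(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 30))
            sphb = rng.uniform(8, 15, size=n)
            lab = sphb + rng.normal(0, 1.2, size=n)
            res = bland_altman(
                [PairedReading(float(i), float(s), float(l)) for i, (s, l) in enumerate(zip(sphb, lab))]
            )
            assert res.t_paired_p == pytest.approx(res.t_bias_p, rel=1e-12)

    def test_bias_recovery_on_synthetic_pairs(self, rng):
        beta, sigma, n = -0.3, 1.0, 400
        lab = rng.uniform(9, 14, size=n)
        sphb = lab + beta + rng.normal(0, sigma, size=n)
        res = bland_altman(
            [PairedReading(float(i), float(s), float(l)) for i, (s, l) in enumerate(zip(sphb, lab))]
        )
        assert abs(res.bias - beta) <= 4 * sigma / np.sqrt(n)


class TestUnpairedT:
    def test_identical_groups(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_unequal_means(self):
        res = unpaired_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert res.p_value == 0.0
        assert res.t_stat == -np.inf

    def test_degenerate_group_size(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])

    def test_welch_matches_first_principles(self, rng):
        for _ in range(50):
            a = rng.normal(5, 1, size=int(rng.integers(3, 40)))
            b = rng.normal(5.5, 2, size=int(rng.integers(3, 40)))
            res = unpaired_t(a, b)
            t, df = first_principles_welch(list(a), list(b))
            assert res.t_stat == pytest.approx(t, rel=1e-12)
            assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-9)

    def test_student_variant_pools_variance(self, rng):
        a = list(rng.normal(5, 1, size=12))
        b = list(rng.normal(6, 1, size=9))
        res = unpaired_t(a, b, equal_var=True)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t_stat == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))


class TestPlotData:
    def test_points_are_mean_and_difference(self):
        points, lines = bland_altman_plot_data(
            [PairedReading(0.0, 10.0, 9.0), PairedReading(60.0, 10.0, 10.0)]
        )
        assert points[0] == (pytest.approx(9.5), pytest.approx(1.0))
        assert points[1] == (pytest.approx(10.0), pytest.approx(0.0))
        assert set(lines) == {"bias", "loa_upper", "loa_lower"}

    def test_empty(self):
        assert bland_altman_plot_data([]) == ([], {})
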