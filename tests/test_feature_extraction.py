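import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrneglect.feature_extraction import (
    extract_features,
    filter_rt_outliers,
    hemispace_contrast_accuracy,
    hemispace_contrast_rt,
    set_size_slope,
)
from vrneglect.synthetic_cohort import PROFILE_LIBRARY, simulate_player

from conftest import make_session


def oracle_fences(values):
    """Independent quartile fences: statistics.quantiles inclusive method
    (linear interpolation between order statistics)."""
    q1, _, q3 = statistics.quantiles(values, n=4, method="inclusive")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


class TestRtOutlierFilter:
    def test_constant_values_kept(self):
        assert list(filter_rt_outliers([2, 2, 2, 2])) == [2, 2, 2, 2]

    def test_single_extreme_removed(self):
        assert list(filter_rt_outliers([1, 1, 1, 1, 10])) == [1, 1, 1, 1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filter_rt_outliers([])

    def test_below_four_returns_input_with_warning(self):
        with pytest.warns(UserWarning):
            out = filter_rt_outliers([1.0, 5.0, 9.0])
        assert list(out) == [1.0, 5.0, 9.0]

    @given(
        st.lists(st.floats(min_value=0.05, max_value=60.0), min_size=4, max_size=60)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_fences_and_is_idempotent(self, rts):
        kept = filter_rt_outliers(rts)
        lo, hi = oracle_fences(rts)
        expected = [r for r in rts if lo <= r <= hi]
        assert list(kept) == pytest.approx(expected)
        assert list(filter_rt_outliers(kept)) == pytest.approx(
            list(filter_rt_outliers(list(kept)))
        )

    def test_value_exactly_on_fence_kept(self):
        # fences of [1,2,3,4]: q1=1.75, q3=3.25, iqr=1.5 -> [-0.5, 5.5]
        vals = [1.0, 2.0, 3.0, 4.0, 5.5]
        assert 5.5 in filter_rt_outliers(vals)


class TestSetSizeSlope:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([50.0, 40.0, 30.0], (30.0 - 50.0) / 16),
            ([10.0, 10.0, 10.0], 0.0),
            ([1.0, 1.5, 2.0], 0.0625),
        ],
    )
    def test_closed_form_on_equally_spaced_set_sizes(self, values, expected):
        assert set_size_slope([8, 16, 24], values) == pytest.approx(expected)

    def test_two_points_supported_one_is_missing(self):
        assert set_size_slope([8, 24], [1.0, 2.0]) == pytest.approx(1.0 / 16)
        assert math.isnan(set_size_slope([8], [1.0]))

    def test_matches_polyfit_oracle(self, rng):
        for _ in range(25):
            x = rng.choice([8, 16, 24], size=3, replace=False)
            y = rng.normal(size=3)
            assert set_size_slope(x, y) == pytest.approx(
                np.polyfit(x, y, 1)[0], abs=1e-9
            )


class TestHemispaceContrasts:
    def test_accuracy_contrast_by_direct_counts(self):
        # 10 right trials (9 correct), 8 left (4 correct) -> 90 - 50 = +40
        spec = [(8, 10.0, i < 9, 1.0) for i in range(10)]
        spec += [(8, -10.0, i < 4, 1.0) for i in range(8)]
        s = make_session(trials_spec=spec)
        assert hemispace_contrast_accuracy(s) == pytest.approx(40.0)

    def test_rt_contrast_hand_arithmetic(self):
        spec = [
            (8, -10.0, True, 1.0),
            (8, -10.0, True, 1.2),
            (8, 10.0, True, 0.8),
            (8, 10.0, True, 1.0),
        ]
        s = make_session(trials_spec=spec)
        assert hemispace_contrast_rt(s) == pytest.approx(0.2)

    def test_empty_hemispace_is_missing_not_zero(self):
        s = make_session(trials_spec=[(8, 10.0, True, 1.0)] * 4)
        assert math.isnan(hemispace_contrast_accuracy(s))
        assert math.isnan(hemispace_contrast_rt(s))

    def test_midline_targets_excluded(self):
        spec = [(8, -10.0, True, 1.0), (8, 10.0, False, 1.0), (8, 0.0, True, 1.0)]
        s = make_session(trials_spec=spec)
        assert hemispace_contrast_accuracy(s) == pytest.approx(-100.0)


class TestExtractFeatures:
    def test_configured_slopes_recovered_at_zero_noise(self):
        prof = PROFILE_LIBRARY["control"].replace(
            accuracy_base=1.0,
            accuracy_slope_per_item=0.0,
            angle_noise_sd=0.0,
            rt_noise_log_sd=0.0,
            lapse_rate=0.0,
            lateral_bias_slope=0.5,
            rt_slope_per_item=0.04,
        )
        s = simulate_player(prof, "control", seed=0)
        f = extract_features(s)
        assert f.gaze_slope == pytest.approx(0.5)
        assert f.headset_slope == pytest.approx(0.5)
        assert f.rt_slope == pytest.approx(0.04)
        assert f.accuracy_slope == pytest.approx(0.0)
        assert f.accuracy_subtract == pytest.approx(0.0)

    def test_trial_order_permutation_invariance(self, rng):
        s = simulate_player(PROFILE_LIBRARY["LOC"], "patient", seed=5)
        f1 = extract_features(s)
        shuffled = s.trials.sample(frac=1.0, random_state=1)
        s2 = type(s)(s.player_id, s.group, shuffled, s.orientation_summaries)
        f2 = extract_features(s2)
        for attr in (
            "accuracy_subtract", "rt_subtract", "accuracy_slope", "rt_slope",
            "headset_slope", "gaze_slope", "accuracy_left", "accuracy_right",
        ):
            assert getattr(f1, attr) == pytest.approx(getattr(f2, attr), nan_ok=True)

    def test_mirror_transform_negates_orientation_metrics(self):
        s = simulate_player(PROFILE_LIBRARY["LOC"], "patient", seed=9)
        f = extract_features(s)
        g = extract_features(s.mirrored())
        assert g.accuracy_subtract == pytest.approx(-f.accuracy_subtract)
        assert g.rt_subtract == pytest.approx(-f.rt_subtract)
        assert g.headset_slope == pytest.approx(-f.headset_slope)
        assert g.gaze_slope == pytest.approx(-f.gaze_slope)
        for size in f.gaze_mean:
            assert g.gaze_mean[size] == pytest.approx(-f.gaze_mean[size])
        assert g.accuracy_slope == pytest.approx(f.accuracy_slope)
        assert g.rt_slope == pytest.approx(f.rt_slope)
        assert g.accuracy_left == pytest.approx(f.accuracy_right)

    def test_absent_orientation_summaries_leave_raycast_metrics_missing(self):
        spec = [(s, side, True, 1.0) for s in (8, 16, 24) for side in (-10.0, 10.0)] * 2
        s = make_session(trials_spec=spec)
        f = extract_features(s)
        assert f.headset_mean == {} and math.isnan(f.headset_slope)
        assert math.isfinite(f.accuracy_subtract)

    def test_twelve_trial_fixture_matches_hand_computation(self):
        # per set size: left/right accuracy and RTs chosen for hand checking
        spec = [
            (8, -10.0, True, 1.0), (8, 10.0, True, 1.0),
            (8, -10.0, False, 9.9), (8, 10.0, True, 1.2),
            (16, -10.0, True, 1.4), (16, 10.0, True, 1.2),
            (16, -10.0, False, 9.9), (16, 10.0, True, 1.4),
            (24, -10.0, True, 1.8), (24, 10.0, True, 1.4),
            (24, -10.0, False, 9.9), (24, 10.0, True, 1.6),
        ]
        s = make_session(
            trials_spec=spec,
            orientation=[("gaze", 8, 2.0), ("gaze", 16, 4.0), ("gaze", 24, 6.0)],
        )
        f = extract_features(s)
        # left accuracy 3/6, right 6/6 -> +50 pp
        assert f.accuracy_subtract == pytest.approx(50.0)
        # pooled correct RTs [1.0,1.0,1.2,1.2,1.4,1.4,1.4,1.6,1.8]:
        # q1=1.2, q3=1.4, fences [0.9, 1.7] -> 1.8 removed;
        # left mean (1.0+1.4)/2 = 1.2, right mean 1.3
        assert f.rt_subtract == pytest.approx(1.2 - 1.3)
        # accuracy by set size 75% each -> slope 0
        assert f.accuracy_slope == pytest.approx(0.0)
        # per-set-size correct RT means: (1.0+1.2+1.0)/3 ... etc
        assert f.rt_by_set_size[8] == pytest.approx((1.0 + 1.0 + 1.2) / 3)
        assert f.gaze_slope == pytest.approx(0.25)
        assert f.gaze_mean == {8: 2.0, 16: 4.0, 24: 6.0}
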