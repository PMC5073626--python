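"""Flow-area estimators: window detection, the three slopes, validity screen."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import papwv
from papwv.qa import SystoleWindow


def _curve(times, flow, area):
    return papwv.FlowAreaCurve("MPA", np.asarray(times, float),
                               np.asarray(flow, float),
                               np.asarray(area, float))


def _cumulative(dq, da, q0=0.0, a0=300.0, dt=7.0):
    """Curve whose consecutive increments are exactly (dq, da)."""
    q = np.concatenate([[q0], q0 + np.cumsum(dq)])
    a = np.concatenate([[a0], a0 + np.cumsum(da)])
    return _curve(np.arange(q.size) * dt, q, a)


class TestEarlySystoleWindow:
    def test_simultaneous_increase_run(self):
        curve = _curve([0, 7, 14, 21, 28], [0, 50, 150, 250, 200],
                       [300, 305, 315, 320, 318])
        window = papwv.early_systole_window(curve)
        np.testing.assert_array_equal(window.indices, [0, 1, 2, 3])

    def test_monotone_decreasing_flow_has_no_window(self):
        curve = _curve([0, 7, 14, 21], [100, 80, 60, 40],
                       [320, 315, 310, 305])
        with pytest.raises(papwv.WindowTooShortError):
            papwv.early_systole_window(curve)

    def test_search_is_limited_to_first_200_ms(self, ht_exact, clean_truth):
        curve = papwv.compose_site_curve(clean_truth, "MPA", ht_exact)
        window = papwv.early_systole_window(curve)
        assert np.all(curve.times[window.indices] <= 200.0)

    def test_noise_free_window_is_the_sampled_rising_limb(self, ht_exact, clean_truth):
        # generator truth: flow rises on (onset, onset + systole/2)
        curve = papwv.compose_site_curve(clean_truth, "MPA", ht_exact)
        window = papwv.early_systole_window(curve)
        t = curve.times[window.indices]
        onset = clean_truth.onset_ms
        assert t[0] <= onset + ht_exact.temporal_resolution
        # rises through the whole 200 ms horizon (peak at onset + 150 > 200)
        assert t[-1] == curve.restrict_to(200.0).times[-1]

    def test_short_blip_does_not_displace_the_upstroke(self):
        # one spurious increasing increment in the baseline, then the real rise
        curve = _curve(np.arange(8) * 7.0,
                       [0, 1, 0, 0, 50, 150, 250, 350],
                       [300, 301, 300, 300, 310, 330, 350, 370])
        window = papwv.early_systole_window(curve)
        np.testing.assert_array_equal(window.indices, [3, 4, 5, 6, 7])


class TestEstimators:
    def test_collinear_points_give_unit_slope(self):
        curve = _curve([0, 7, 14], [0, 10, 20], [300, 310, 320])
        window = SystoleWindow(indices=np.arange(3))
        assert papwv.qa_trad(curve, window).value == pytest.approx(1.0)
        assert papwv.qa_three(curve, window).value == pytest.approx(1.0)
        assert papwv.qa_inv(curve, window).value == pytest.approx(1.0)

    def test_constant_area_fails_fit(self):
        curve = _curve([0, 7, 14], [0, 10, 20], [300, 300, 300])
        window = SystoleWindow(indices=np.arange(3))
        for fn in (papwv.qa_trad, papwv.qa_inv):
            with pytest.raises(papwv.FitError):
                fn(curve, window)

    def test_three_point_window_makes_qa3_equal_qatrad(self):
        curve = _curve([0, 7, 14], [0, 12, 30], [300, 311, 323])
        window = SystoleWindow(indices=np.arange(3))
        assert papwv.qa_three(curve, window).value == pytest.approx(
            papwv.qa_trad(curve, window).value)

    def test_late_reflection_leaves_first_three_points_unbiased(self, ht_exact):
        # reflection arrives 42 ms (= 6 frames) after the upstroke starts
        truth = papwv.SyntheticTruth(
            true_pwv=2.5, reflection=papwv.ReflectionSpec(0.3, 42.0))
        curve = papwv.compose_site_curve(truth, "MPA", ht_exact)
        window = papwv.early_systole_window(curve)
        assert papwv.qa_three(curve, window).value == pytest.approx(2.5,
                                                                    rel=1e-9)
        assert papwv.qa_trad(curve, window).value != pytest.approx(2.5,
                                                                   rel=1e-3)

    def test_qa_inv_increment_arithmetic(self):
        curve = _cumulative([10.0, 10.0], [10.0, 10.0])
        window = SystoleWindow(indices=np.arange(3))
        assert papwv.qa_inv(curve, window).value == pytest.approx(1.0)

    def test_orthogonal_reflection_leaves_qa_inv_exact(self):
        # forward increments dA_f=(10,10), dQ_f=(10,10) with c=1; backward
        # component dA_b=(5,-5), dQ_b=(-5,5): observed dA=(15,5), dQ=(5,15)
        curve = _cumulative([5.0, 15.0], [15.0, 5.0])
        window = SystoleWindow(indices=np.arange(3))
        assert papwv.qa_inv(curve, window).value == pytest.approx(1.0,
                                                                  abs=1e-12)
        assert papwv.qa_trad(curve, window).value != pytest.approx(1.0,
                                                                   abs=0.05)

    @given(c=st.floats(0.5, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_reflection_free_identity_for_any_wave_speed(self, c):
        truth = papwv.SyntheticTruth(true_pwv=c)
        prof = dataclasses.replace(papwv.HIGH_TEMPORAL, quantize_area=False)
        curve = papwv.compose_site_curve(truth, "MPA", prof)
        window = papwv.early_systole_window(curve)
        for fn in (papwv.qa_trad, papwv.qa_three, papwv.qa_inv):
            assert fn(curve, window).value == pytest.approx(c, rel=1e-9)

    def test_qa_inv_invariant_under_increment_reversal(self):
        dq, da = [3.0, 7.0, 11.0], [2.0, 6.0, 5.0]
        fwd = papwv.qa_inv(_cumulative(dq, da),
                           SystoleWindow(indices=np.arange(4))).value
        rev = papwv.qa_inv(_cumulative(dq[::-1], da[::-1]),
                           SystoleWindow(indices=np.arange(4))).value
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_qa_trad_invariant_under_constant_offsets(self):
        curve = _cumulative([3.0, 7.0, 11.0], [2.0, 6.0, 5.0])
        shifted = dataclasses.replace(curve, flow=curve.flow + 55.0,
                                      area=curve.area + 40.0)
        window = SystoleWindow(indices=np.arange(4))
        assert papwv.qa_trad(shifted, window).value == pytest.approx(
            papwv.qa_trad(curve, window).value, abs=1e-12)


class TestValidityScreen:
    @pytest.mark.parametrize("value,valid,reason", [
        (-1.2, False, "nonpositive"),
        (2.9, True, "none"),
        (25.0, False, "excessive"),
    ])
    def test_screen_cases(self, value, valid, reason):
        est = papwv.screen_validity(
            papwv.PWVEstimate(method="QA_Trad", value=value), cap=20.0)
        assert est.valid is valid and est.invalid_reason == reason

    def test_estimate_qa_folds_window_failure_into_flag(self):
        t = np.arange(0.0, 100.0, 7.0)
        curve = _curve(t, np.linspace(100, 0, t.size),
                       np.linspace(320, 300, t.size))
        est = papwv.estimate_qa(curve, "QA_Inv")
        assert not est.valid and est.invalid_reason == "window_too_short"
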