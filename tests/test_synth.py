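"""Waveform generator: construction identities, seeding, acquisition emulation."""

import dataclasses

import numpy as np
import pytest

import papwv
from papwv.synth import forward_flow, forward_flow_wave


class TestForwardFlowWave:
    def test_zero_peak_gives_all_zero_curve(self):
        assert not forward_flow_wave(0.0, 300.0, 900.0, 7.0).any()

    def test_closed_form_samples_on_coarse_grid(self):
        # dt=150 lands on sin(0), sin(pi/2), sin(pi)
        q = forward_flow_wave(400.0, 300.0, 1000.0, 150.0)
        assert q[0] == pytest.approx(0.0)
        assert q[1] == pytest.approx(400.0)
        assert q[2] == pytest.approx(0.0, abs=1e-10)
        assert not q[3:].any()  # diastole

    def test_trapezoid_sum_converges_to_analytic_integral(self):
        # continuous integral of the half-sinusoid: 2*peak*T_sys/pi
        q = forward_flow_wave(400.0, 300.0, 900.0, 1.0)
        t = np.arange(q.size) * 1.0
        expected = 2.0 * 400.0 * 300.0 / np.pi
        assert np.trapezoid(q, t) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("bad", [
        dict(systole_duration=0.0), dict(cycle_length=-1.0),
        dict(temporal_resolution=0.0), dict(systole_duration=1000.0),
    ])
    def test_invalid_durations_rejected(self, bad):
        kw = dict(peak_flow=400.0, systole_duration=300.0, cycle_length=900.0,
                  temporal_resolution=7.0)
        kw.update(bad)
        with pytest.raises(papwv.ParameterError):
            forward_flow_wave(**kw)


class TestComposeSiteCurve:
    @pytest.mark.parametrize("site", ["MPA", "RPA", "LPA"])
    @pytest.mark.parametrize("dt", [7.0, 12.0])
    def test_waterhammer_increments_without_reflection(self, clean_truth, site, dt):
        # zero reflection/noise/quantization: dQ = c*dA at every frame pair
        prof = papwv.AcquisitionProfile(dt, 1.25, n_phases=64,
                                        quantize_area=False)
        curve = papwv.compose_site_curve(clean_truth, site, prof)
        np.testing.assert_allclose(np.diff(curve.flow),
                                   clean_truth.true_pwv * np.diff(curve.area),
                                   atol=1e-9)

    def test_branch_curve_is_time_shifted_mpa(self, dense_exact):
        truth = papwv.SyntheticTruth(
            true_pwv=2.5, site_delays={"MPA": 0.0, "RPA": 20.0},
            flow_fractions={"MPA": 1.0, "RPA": 1.0},
        )
        mpa = papwv.compose_site_curve(truth, "MPA", dense_exact)
        rpa = papwv.compose_site_curve(truth, "RPA", dense_exact)
        np.testing.assert_allclose(rpa.flow[20:], mpa.flow[:-20], atol=1e-12)
        np.testing.assert_allclose(rpa.area[20:], mpa.area[:-20], atol=1e-12)

    def test_expansion_reflection_inflates_qa_slope(self, ht_exact):
        truth = papwv.SyntheticTruth(
            true_pwv=2.5, reflection=papwv.ReflectionSpec(0.3, 50.0, "expansion"))
        curve = papwv.compose_site_curve(truth, "MPA", ht_exact)
        window = papwv.early_systole_window(curve)
        assert papwv.qa_trad(curve, window).value > truth.true_pwv * 1.05

    def test_compression_reflection_deflates_qa_slope(self, ht_exact):
        truth = papwv.SyntheticTruth(
            true_pwv=2.5,
            reflection=papwv.ReflectionSpec(0.3, 50.0, "compression"))
        curve = papwv.compose_site_curve(truth, "MPA", ht_exact)
        window = papwv.early_systole_window(curve)
        assert papwv.qa_trad(curve, window).value < truth.true_pwv * 0.95

    def test_seeded_noise_is_bit_reproducible(self):
        truth = papwv.SyntheticTruth(noise_sd_flow=4.0, noise_sd_area=2.0,
                                     seed=42)
        a = papwv.compose_site_curve(truth, "MPA", papwv.HIGH_TEMPORAL)
        b = papwv.compose_site_curve(truth, "MPA", papwv.HIGH_TEMPORAL)
        assert np.array_equal(a.flow, b.flow) and np.array_equal(a.area, b.area)
        c = papwv.compose_site_curve(truth, "MPA", papwv.HIGH_TEMPORAL, seed=43)
        assert not np.array_equal(a.flow, c.flow)

    def test_quantization_error_bounded_by_half_pixel(self, clean_truth):
        exact = papwv.compose_site_curve(
            clean_truth, "MPA",
            dataclasses.replace(papwv.HIGH_TEMPORAL, quantize_area=False))
        quant = papwv.compose_site_curve(clean_truth, "MPA", papwv.HIGH_TEMPORAL)
        bound = 0.5 * papwv.HIGH_TEMPORAL.pixel_area + 1e-9
        assert np.max(np.abs(quant.area - exact.area)) <= bound

    def test_configured_delay_recovered_by_cross_correlation(self, clean_truth):
        prof = dataclasses.replace(papwv.HIGH_TEMPORAL, quantize_area=False)
        truth = dataclasses.replace(clean_truth,
                                    site_delays={"MPA": 0.0, "RPA": 21.0})
        mpa = papwv.compose_site_curve(truth, "MPA", prof)
        rpa = papwv.compose_site_curve(truth, "RPA", prof)
        xc = np.correlate(rpa.flow, mpa.flow, mode="full")
        lag = int(np.argmax(xc)) - (mpa.n_frames - 1)
        assert lag * prof.temporal_resolution == pytest.approx(21.0)

    def test_venc_exceedance_sets_warning_flag(self):
        slow = papwv.SyntheticTruth(peak_flow=400.0)  # peak v ~ 53 cm/s
        fast = papwv.SyntheticTruth(peak_flow=400.0, baseline_area=80.0)
        assert not papwv.compose_site_curve(slow, "MPA", papwv.HIGH_TEMPORAL).venc_exceeded
        assert papwv.compose_site_curve(fast, "MPA", papwv.HIGH_TEMPORAL).venc_exceeded


class TestRenderFrames:
    def test_constant_curve_renders_identical_frames(self):
        curve = papwv.FlowAreaCurve("MPA", [0.0, 7.0, 14.0],
                                    [100.0, 100.0, 100.0],
                                    [312.5, 312.5, 312.5])
        series = papwv.render_phase_contrast_frames(curve, papwv.HIGH_TEMPORAL,
                                                    fov=60.0)
        for k in (1, 2):
            np.testing.assert_array_equal(series.velocity[:, :, k],
                                          series.velocity[:, :, 0])
            np.testing.assert_array_equal(series.masks[:, :, k],
                                          series.masks[:, :, 0])

    def test_velocity_inside_disc_is_q_over_a(self, clean_truth):
        curve = papwv.compose_site_curve(
            clean_truth, "MPA", papwv.HIGH_TEMPORAL).restrict_to(150.0)
        series = papwv.render_phase_contrast_frames(curve, papwv.HIGH_TEMPORAL,
                                                    fov=80.0)
        for k in range(curve.n_frames):
            inside = series.masks[:, :, k] == 1
            expected = 100.0 * curve.flow[k] / curve.area[k]
            np.testing.assert_allclose(series.velocity[:, :, k][inside],
                                       expected, rtol=1e-12)
            assert not series.velocity[:, :, k][~inside].any()

    def test_disc_pixel_count_matches_quantized_area(self, clean_truth):
        curve = papwv.compose_site_curve(
            clean_truth, "MPA", papwv.HIGH_TEMPORAL).restrict_to(100.0)
        series = papwv.render_phase_contrast_frames(curve, papwv.HIGH_TEMPORAL,
                                                    fov=80.0)
        px = papwv.HIGH_TEMPORAL.pixel_area
        counts = series.masks.sum(axis=(0, 1))
        np.testing.assert_array_equal(counts, np.round(curve.area / px))

    def test_vessel_larger_than_fov_rejected(self, clean_truth):
        curve = papwv.compose_site_curve(clean_truth, "MPA", papwv.HIGH_TEMPORAL)
        with pytest.raises(papwv.ParameterError):
            papwv.render_phase_contrast_frames(curve, papwv.HIGH_TEMPORAL,
                                               fov=20.0)


class TestGenerateStudy:
    def _quiet_sampler(self):
        return papwv.TruthSampler(noise_sd_flow=0.0, noise_sd_area=0.0)

    def test_noise_free_replicates_are_identical(self):
        subjects = papwv.generate_study(2, self._quiet_sampler(),
                                        papwv.HIGH_TEMPORAL, replicates=2,
                                        seed=7)
        for s in subjects:
            for site in ("MPA", "RPA", "LPA"):
                np.testing.assert_array_equal(s.replicates[0][site].flow,
                                              s.replicates[1][site].flow)

    def test_same_seed_regenerates_identical_study(self):
        a = papwv.generate_study(3, None, papwv.HIGH_TEMPORAL, replicates=2,
                                 seed=11)
        b = papwv.generate_study(3, None, papwv.HIGH_TEMPORAL, replicates=2,
                                 seed=11)
        for sa, sb in zip(a, b):
            assert sa.truth == sb.truth
            for ra, rb in zip(sa.replicates, sb.replicates):
                for site in ra:
                    assert np.array_equal(ra[site].flow, rb[site].flow)

    def test_noisy_replicate_differences_centre_on_zero(self):
        subjects = papwv.generate_study(20, None, papwv.HIGH_TEMPORAL,
                                        replicates=2, seed=3)
        diffs = np.array([
            (s.replicates[0]["MPA"].flow - s.replicates[1]["MPA"].flow).mean()
            for s in subjects
        ])
        sem = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * sem + 1e-12

    def test_invalid_design_rejected(self):
        with pytest.raises(papwv.ParameterError):
            papwv.generate_study(0, None, papwv.HIGH_TEMPORAL)
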