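"""Waveform, calibration and rendering of the synthetic interferogram generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icefringe as icf
from icefringe.errors import InfeasibleError, ParameterError, SamplingError


def sched(**kw):
    base = dict(face="top", v_min_um_s=0.13, v_max_um_s=0.73, period_s=11.0,
                rise_fraction=1.0, rise_exponent=1.0)
    base.update(kw)
    return icf.GrowthSchedule(**base)


class TestWaveform:
    def test_degenerate_amplitude_is_constant(self):
        wf = icf.make_waveform(sched(v_min_um_s=0.5, v_max_um_s=0.5))
        t = np.linspace(0, 30, 301)
        assert np.allclose(wf(t), 0.5)

    def test_linear_ramp_symmetry(self):
        wf = icf.make_waveform(sched(v_min_um_s=0.0, v_max_um_s=1.0, period_s=10.0))
        assert wf(5.0) == pytest.approx(0.5)
        assert wf.mean == pytest.approx(0.5)

    def test_cycle_mean_matches_numeric_integration(self):
        # closed form mean = v_min + (v_max - v_min)/(1 + p) for full-cycle rise
        from scipy.integrate import quad

        wf = icf.make_waveform(sched(rise_exponent=0.3468))
        numeric = quad(lambda t: float(wf(t)), 0.0, 11.0, limit=200)[0] / 11.0
        assert wf.mean == pytest.approx(0.5755, abs=5e-5)
        assert numeric == pytest.approx(wf.mean, rel=1e-6)

    def test_periodicity_and_bounds(self):
        wf = icf.make_waveform(sched(rise_fraction=0.92, rise_exponent=0.31))
        t = np.linspace(0, 44, 4001)
        v = wf(t)
        assert np.all(v >= 0.13 - 1e-12) and np.all(v <= 0.73 + 1e-12)
        assert np.allclose(wf(t), wf(t + 11.0), atol=1e-9)

    def test_displacement_matches_trapezoid_integral(self):
        wf = icf.make_waveform(sched(rise_fraction=0.92, rise_exponent=0.31, phase0_s=2.5))
        t = np.linspace(0, 37.0, 60_001)
        numeric = np.concatenate([[0.0], np.cumsum((wf(t)[1:] + wf(t)[:-1]) / 2 * np.diff(t))])
        assert np.allclose(wf.displacement(t), numeric, atol=1e-5)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ParameterError):
            sched(v_max_um_s=np.nan)

    @given(
        v_min=st.floats(0.0, 0.5),
        amp=st.floats(0.01, 1.0),
        r=st.floats(0.1, 1.0),
        p=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mean_always_within_bounds(self, v_min, amp, r, p):
        wf = icf.make_waveform(
            sched(v_min_um_s=v_min, v_max_um_s=v_min + amp, rise_fraction=r, rise_exponent=p)
        )
        assert v_min - 1e-12 <= wf.mean <= v_min + amp + 1e-12


class TestCalibrateRiseExponent:
    def test_linear_ramp_target(self):
        assert icf.calibrate_rise_exponent(0.0, 1.0, 0.5, 1.0) == pytest.approx(1.0)

    def test_printed_cycle_statistics_closed_form(self):
        # p = (v_max - mean)/(mean - v_min) for a full-cycle rise
        p = icf.calibrate_rise_exponent(0.13, 0.73, 6.33 / 11.0, 1.0)
        assert p == pytest.approx(0.3469, abs=2e-4)

    def test_infeasible_target_rejected(self):
        with pytest.raises(InfeasibleError):
            icf.calibrate_rise_exponent(0.13, 0.73, 0.74, 1.0)

    @given(
        target=st.floats(0.2, 0.7),
        r=st.floats(0.3, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_reaches_target_mean(self, target, r):
        lo = r * 0.13 + (1 - r) * 0.43
        hi = r * 0.73 + (1 - r) * 0.43
        if not (lo + 1e-3 < target < hi - 1e-3):
            return
        p = icf.calibrate_rise_exponent(0.13, 0.73, target, r)
        wf = icf.make_waveform(sched(rise_fraction=r, rise_exponent=p))
        assert wf.mean == pytest.approx(target, rel=1e-6)


class TestRenderVideo:
    def test_static_interface_gives_identical_frames(self):
        s = sched(v_min_um_s=0.0, v_max_um_s=0.0)
        optics = icf.OpticalConfig()
        geom = icf.CrystalGeometry.from_fringe_spacing(5.0, optics, field_size=(64, 64),
                                                       overlap_roi=(24, 40, 24, 40))
        stack, _ = icf.render_video(s, s, optics, geom, duration_s=1.0, fps=10.0)
        assert np.array_equal(stack.frames[0], stack.frames[-1])

    def test_noise_free_intensity_bounds(self, canonical_case):
        stack, _ = icf.render_video(
            canonical_case.top, canonical_case.bottom, canonical_case.optics,
            canonical_case.geometry, duration_s=2.0, fps=30.0, noise_sd=0.0,
        )
        o = canonical_case.optics
        total = o.fringe_contrast + o.overlap_contrast
        assert stack.frames.min() >= o.baseline - total - 1e-6
        assert stack.frames.max() <= o.baseline + total + 1e-6

    def test_seed_reproducibility(self, canonical_case):
        a, _ = canonical_case.render(2.0, seed=5)
        b, _ = canonical_case.render(2.0, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_truth_displacement_conserves_rate_integral(self, canonical_video):
        _, truth = canonical_video
        t = truth.times_s
        trapz = np.concatenate(
            [[0.0], np.cumsum((truth.v_top_um_s[1:] + truth.v_top_um_s[:-1]) / 2 * np.diff(t))]
        )
        # trapezoid tolerance: the waveform kink makes the quadrature err locally
        assert np.allclose(truth.top_displacement_um, trapz, atol=2e-2)

    def test_spatial_period_matches_tilt_closed_form(self, canonical_case):
        # brute-force FFT peak on a rendered frame vs delta = lambda/(2 n_w tan theta)
        stack, _ = canonical_case.render(0.2, seed=1)
        row = stack.frames[0][10].astype(float)
        row -= row.mean()
        power = np.abs(np.fft.rfft(row * np.hanning(len(row)))) ** 2
        freqs = np.fft.rfftfreq(len(row), d=canonical_case.geometry.pixel_size_um)
        f_peak = freqs[1 + np.argmax(power[1:])]
        delta_expected = canonical_case.geometry.fringe_spacing_um(canonical_case.optics)
        assert 1.0 / f_peak == pytest.approx(delta_expected, rel=0.02)

    def test_center_phase_advance_per_displacement(self):
        # one fringe of migration per lambda/(2 n_w) = 0.2513 um of displacement
        optics = icf.OpticalConfig()
        assert optics.displacement_per_fringe_um == pytest.approx(0.2513, abs=2e-4)
        from scipy.signal import hilbert

        from conftest import render_constant

        (stack, truth), optics, geom = render_constant(0.5, duration_s=2.0)
        y, x = 40, 100
        pix = stack.frames[:, y, x].astype(float)
        # phase of the analytic signal at a fixed pixel advances 4 pi n_w V / lambda per second
        ph = np.unwrap(np.angle(hilbert(pix - pix.mean())))
        rate = np.polyfit(truth.times_s[5:-5], ph[5:-5], 1)[0]
        expected = 4 * np.pi * optics.n_water * 0.5 / optics.lambda_um
        assert abs(rate) == pytest.approx(expected, rel=0.02)

    def test_nyquist_violation_names_minimum_fps(self):
        s = sched(v_min_um_s=2.0, v_max_um_s=2.0)
        optics = icf.OpticalConfig()
        geom = icf.CrystalGeometry.from_fringe_spacing(5.0, optics)
        with pytest.raises(SamplingError) as exc:
            icf.render_video(s, s, optics, geom, duration_s=1.0, fps=10.0)
        assert exc.value.min_fps is not None and exc.value.min_fps > 10.0


class TestOpticalConfig:
    def test_contrast_budget_enforced(self):
        with pytest.raises(ParameterError):
            icf.OpticalConfig(fringe_contrast=0.6, overlap_contrast=0.5, baseline=0.5)

    def test_thickness_per_cycle(self):
        assert icf.OpticalConfig().thickness_per_cycle_um == pytest.approx(0.2557, abs=2e-4)
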