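"""Recording analysis: filters, Hilbert envelope, epoch metrics, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tistim.envelope import (
    analyze_recording,
    bandpass,
    depth_profile,
    envelope,
    interpolate_map,
    modulation_metrics,
    normalize_across_contacts,
)
from tistim.recordings import gaussian_profile, synth_recording

FS = 30_000.0


def two_tone(a1, a2, duration=25.0, noise=0.0, seed=None, fs=FS):
    rec = synth_recording([0.0], [a1], [a2], 2000.0, 2005.0, fs, duration, noise, seed)
    return rec.data[0]


class TestBandpass:
    def test_dc_input_suppressed(self):
        out = bandpass(np.ones(30_000), FS, 500, 5000)
        assert np.abs(out[1000:-1000]).max() < 1e-3

    def test_in_band_tone_barely_attenuated_and_phase_preserved(self):
        t = np.arange(30_000) / FS
        x = np.sin(2 * np.pi * 2000 * t)
        y = bandpass(x, FS, 500, 5000)
        mid = slice(5000, 25_000)
        assert np.abs(y[mid]).max() > 0.9  # < 10% attenuation at 2 kHz
        # zero-phase filtering keeps the peak sample aligned
        seg = slice(14_990, 15_020)
        assert np.argmax(y[seg]) == np.argmax(x[seg])

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.ones(100), FS, 5000, 500)


class TestEnvelope:
    def test_constant_tone_has_unit_envelope(self):
        t = np.arange(int(FS)) / FS
        env = envelope(np.sin(2 * np.pi * 2000 * t), FS)
        interior = env[3000:-3000]
        assert np.allclose(interior, 1.0, atol=0.02)

    def test_two_tone_envelope_matches_beat_closed_form(self):
        # |A e^{i w1 t} + A e^{i w2 t}| = 2A |cos(pi df t)|
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 2000 * t) + np.sin(2 * np.pi * 2005 * t)
        env = envelope(x, FS)
        expected = 2.0 * np.abs(np.cos(np.pi * 5.0 * t))
        interior = slice(6000, -6000)
        assert np.max(np.abs(env[interior] - expected[interior])) < 0.02

    def test_zero_signal_zero_envelope(self):
        assert np.allclose(envelope(np.zeros(10_000), FS), 0.0, atol=1e-12)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.array([]), FS)


class TestModulationMetrics:
    @pytest.mark.parametrize(
        "a1, a2, exp_mod, exp_abs, exp_ratio",
        [
            (1.0, 1.0, 1.0, 2.0, 1.0),
            (3.0, 1.0, 1.0, 4.0, 0.5),
            (2.0, 0.0, 0.0, 2.0, 0.0),
        ],
    )
    def test_noiseless_closed_forms(self, a1, a2, exp_mod, exp_abs, exp_ratio):
        m, a, r = modulation_metrics(two_tone(a1, a2), FS)
        assert m == pytest.approx(exp_mod, abs=0.01 * max(a1, a2))
        assert a == pytest.approx(exp_abs, rel=0.01)
        assert r == pytest.approx(exp_ratio, abs=0.02)

    def test_ratio_equals_two_min_over_sum_across_amplitude_ratios(self):
        for alpha in [0.0, 0.2, 0.5, 0.8, 1.0]:
            _, _, r = modulation_metrics(two_tone(1.0, alpha, duration=5), FS, n_epochs=5)
            expected = 2 * min(1.0, alpha) / (1.0 + alpha)
            assert r == pytest.approx(expected, abs=0.02)

    def test_half_difference_ratio_saturates_at_half(self):
        _, _, r = modulation_metrics(
            two_tone(1.0, 1.0, duration=5), FS, n_epochs=5, ratio_mode="half_difference"
        )
        assert r == pytest.approx(0.5, abs=0.01)

    def test_scaling_linearity(self):
        x = two_tone(1.0, 0.6, duration=5)
        m1, a1, r1 = modulation_metrics(x, FS, n_epochs=5)
        m2, a2, r2 = modulation_metrics(10 * x, FS, n_epochs=5)
        assert m2 == pytest.approx(10 * m1, rel=1e-9)
        assert a2 == pytest.approx(10 * a1, rel=1e-9)
        assert r2 == pytest.approx(r1, abs=1e-6)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            modulation_metrics(two_tone(1, 1, duration=2), FS, n_epochs=25)


class TestNormalizeAcrossContacts:
    def test_divides_by_maximum(self):
        assert np.allclose(normalize_across_contacts([1, 2, 4]), [0.25, 0.5, 1.0])

    def test_all_equal_gives_ones(self):
        assert np.allclose(normalize_across_contacts([3, 3, 3]), 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_across_contacts([0.0, 0.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=10))
    def test_rank_order_preserved(self, values):
        v = np.asarray(values)
        if v.max() <= 0:
            return
        out = normalize_across_contacts(v)
        assert np.array_equal(np.argsort(v, kind="stable"), np.argsort(out, kind="stable"))
        assert out.max() == pytest.approx(1.0)


class TestDepthProfile:
    def test_finite_difference_example(self):
        df = depth_profile([0.0, 1.0, 3.0], [0.0, 2.0, 4.0])
        assert np.allclose(df["field_V_per_m"], [0.5, 1.0])  # 1 mV/mm = 1 V/m
        assert np.allclose(df["depth_mm"], [1.0, 3.0])

    def test_linear_ramp_gives_constant_field(self):
        d = np.arange(0, 40.0, 2.0)
        df = depth_profile(0.3 * d, d)
        assert np.allclose(df["field_V_per_m"], 0.3)

    def test_duplicate_depths_rejected(self):
        with pytest.raises(ValueError):
            depth_profile([0, 1, 2], [0, 2, 2])

    def test_gaussian_bump_recovers_analytic_derivative(self):
        # modulation amplitude per contact follows the weaker pair's bump;
        # the finite-difference field profile matches the analytic |dA/dx|
        depths = np.arange(10.0, 41.0, 2.0)
        a1 = gaussian_profile(depths, 25.0, 8.0, 1.0)
        rec = synth_recording(depths, a1, np.full_like(a1, 5.0), 2000, 2005, FS, 3.0)
        mods = [
            modulation_metrics(tr, FS, n_epochs=3)[0] for tr in rec.data
        ]
        df = depth_profile(np.asarray(mods), depths)
        mid = df["depth_mm"].to_numpy()
        analytic = np.abs((mid - 25.0) / 8.0**2 * gaussian_profile(mid, 25.0, 8.0, 1.0))
        err = np.abs(df["field_V_per_m"].to_numpy() - analytic)
        assert err.max() < 0.05 * analytic.max()


class TestInterpolateMap:
    def test_constant_input_constant_map_with_exact_shape(self):
        vals = np.full((3, 15), 2.5)
        out = interpolate_map(vals, [0.0, 1.0, 2.0])
        assert out.shape == (100, 151)
        assert np.allclose(out, 2.5)

    def test_three_point_moving_average_smooths_spike(self):
        vals = np.array([[0.0, 3.0, 0.0, 0.0, 0.0], [0.0, 3.0, 0.0, 0.0, 0.0]])
        out = interpolate_map(vals, [0.0, 1.0], grid_shape=(2, 5))
        assert out[0, 1] == pytest.approx(1.0)  # (0 + 3 + 0) / 3

    def test_single_contact_rejected(self):
        with pytest.raises(ValueError):
            interpolate_map(np.ones((2, 1)), [0.0, 1.0])


class TestAnalyzeRecording:
    def test_depth_dependent_modulation_ratio(self):
        # deepest contact sees balanced tones (ratio ~1); a shallow contact
        # with A2 = 0.07 A1 gives 2*0.07/1.07 ~ 0.13
        rec = synth_recording(
            [0.0, 30.0], [1.0, 1.0], [0.07, 1.0], 2000, 2005, FS, 25.0
        )
        metrics, _, _ = analyze_recording(rec)
        assert metrics.modulation_ratio[1] == pytest.approx(1.0, abs=0.02)
        assert metrics.modulation_ratio[0] == pytest.approx(2 * 0.07 / 1.07, abs=0.02)
        assert metrics.normalized_modulation.max() == pytest.approx(1.0)

    def test_tacs_band_sine_has_no_beat(self):
        t = np.arange(int(5 * FS)) / FS
        from tistim.recordings import Recording

        rec = Recording(
            data=np.sin(2 * np.pi * 5.0 * t)[None, :].repeat(2, axis=0),
            fs=FS,
            contact_depths_mm=[0.0, 3.0],
        )
        metrics, _, _ = analyze_recording(rec, band="tacs", n_epochs=3)
        assert np.all(metrics.modulation_amplitude_mV < 0.05)

    def test_end_to_end_deterministic(self):
        rec = synth_recording(
            [0.0, 10.0], [1, 0.5], [0.5, 1], 2000, 2005, FS, 5.0, 0.05, seed=3
        )
        a = analyze_recording(rec, n_epochs=5)[0]
        b = analyze_recording(rec, n_epochs=5)[0]
        assert np.array_equal(a.modulation_amplitude_mV, b.modulation_amplitude_mV)
        assert np.array_equal(a.modulation_ratio, b.modulation_ratio)


def test_solver_derived_recording_matches_exposure_metric(
    pair_solutions, default_phantom
):
    """Cross-module consistency: a recording generated from the two pairs'
    projected field amplitudes yields per-contact modulation amplitudes
    equal to half the exposure map's envelope-modulation amplitude
    (the half-difference convention) within 5%."""
    from tistim.exposure import projected_envelope_amplitude
    from tistim.pipeline import depth_electrode_track

    positions, depths, shaft = depth_electrode_track(default_phantom, n_contacts=8)
    idx = np.clip(
        default_phantom.world_to_index(positions), 0, np.array(default_phantom.shape) - 1
    )
    E1 = pair_solutions[0].E[idx[:, 0], idx[:, 1], idx[:, 2]]
    E2 = pair_solutions[1].E[idx[:, 0], idx[:, 1], idx[:, 2]]
    a1 = E1 @ shaft
    a2 = E2 @ shaft
    ok = np.isfinite(a1) & np.isfinite(a2)
    eam = projected_envelope_amplitude(E1[ok], E2[ok], shaft)
    rec = synth_recording(depths[ok], a1[ok], a2[ok], 2000, 2005, FS, 5.0)
    mods = np.array([modulation_metrics(tr, FS, n_epochs=5)[0] for tr in rec.data])
    scale = eam.max()
    assert np.all(np.abs(mods - eam / 2.0) < 0.05 * scale)
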