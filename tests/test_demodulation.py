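"""Lock-in amplification, admittance recovery, DC estimator, moving-average filter."""

import numpy as np
import pytest

from edawave import (
    ExcitationSpec,
    FrontEndConfig,
    LockinConfig,
    SkinRCModel,
    Waveform,
    acquire,
    admittance_at,
    admittance_from_recording,
    dc_conductance,
    lockin,
    moving_average,
    rectified_conductance,
)


def _sine_wave(a, f, phi_deg, rate, duration, noise=0.0, seed=0):
    t = np.arange(int(duration * rate)) / rate
    v = a * np.sin(2 * np.pi * f * t + np.radians(phi_deg))
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise, t.size)
    return Waveform(t=t, v=v, rate=rate)


class TestLockin:
    def test_noiseless_sine_amplitude_and_phase_exact(self):
        w = _sine_wave(0.8, 20.0, 30.0, 2000.0, 2.0)
        t, amp, phase = lockin(w, 20.0)
        assert np.allclose(amp, 0.8, rtol=1e-12)
        assert np.allclose(phase, 30.0, atol=1e-9)

    def test_cosine_reads_90_degrees(self):
        w = _sine_wave(1.0, 20.0, 90.0, 2000.0, 2.0)
        _, amp, phase = lockin(w, 20.0)
        assert np.allclose(phase, 90.0, atol=1e-9)

    def test_noisy_amplitude_within_monte_carlo_band(self):
        """100 seeded replicates: mean estimate within 0.8 ± 0.02."""
        amps = []
        for seed in range(100):
            w = _sine_wave(0.8, 20.0, 30.0, 2000.0, 2.0, noise=0.05, seed=seed)
            _, amp, _ = lockin(w, 20.0)
            amps.append(np.mean(amp))
        assert abs(np.mean(amps) - 0.8) < 0.02
        assert max(abs(a - 0.8) for a in amps) < 0.02

    def test_rate_too_low_rejected(self):
        w = _sine_wave(1.0, 20.0, 0.0, 100.0, 2.0)
        with pytest.raises(ValueError):
            lockin(w, 20.0)

    def test_off_frequency_component_rejected(self):
        """A strong 50 Hz interferer leaves the 20 Hz reading almost untouched."""
        w = _sine_wave(0.5, 20.0, 0.0, 2000.0, 2.0)
        v = w.v + 2.0 * np.sin(2 * np.pi * 50.0 * w.t)
        _, amp, _ = lockin(Waveform(t=w.t, v=v, rate=w.rate), 20.0)
        assert np.mean(amp) == pytest.approx(0.5, rel=1e-6)

    def test_butterworth_variant_agrees_on_steady_sine(self):
        w = _sine_wave(0.8, 20.0, 30.0, 2000.0, 4.0)
        _, amp, phase = lockin(w, 20.0, LockinConfig(lpf_kind="butterworth", settle=1.0))
        assert np.median(amp) == pytest.approx(0.8, rel=1e-3)
        assert np.median(phase) == pytest.approx(30.0, abs=0.1)


class TestAdmittanceFromRecording:
    def test_resistive_10k_reads_100_uS_zero_phase(self, resistive_10k, fe_noiseless, full_ac_20):
        rec, _ = acquire(full_ac_20, resistive_10k, None, fe_noiseless, 5.0, polarization_on=False)
        adm = admittance_from_recording(rec, fe_noiseless, full_ac_20)
        assert np.mean(adm.g) == pytest.approx(100.0, rel=0.02)
        assert abs(np.mean(adm.b)) < 0.5
        assert abs(np.mean(adm.phase)) < 0.5

    @pytest.mark.parametrize("f", [5.0, 20.0, 70.0, 100.0])
    def test_default_model_matches_closed_form(self, default_model, fe_noiseless, f):
        spec = ExcitationSpec(mode="full_ac", frequency=f)
        fe = FrontEndConfig(noise_rms=0.0, fs_acq=200.0 if f >= 50 else 20.0)
        rec, _ = acquire(spec, default_model, None, fe, 5.0, polarization_on=False)
        adm = admittance_from_recording(rec, fe, spec)
        y = admittance_at(default_model, f) * 1e6
        assert np.mean(adm.g) == pytest.approx(y.real, rel=0.02)
        assert np.mean(adm.b) == pytest.approx(y.imag, rel=0.02)

    def test_default_noise_still_within_5_percent(self, default_model, full_ac_20):
        fe = FrontEndConfig(noise_rms=1e-3)
        rec, _ = acquire(full_ac_20, default_model, None, fe, 5.0, seed=1, polarization_on=False)
        adm = admittance_from_recording(rec, fe, full_ac_20)
        y = admittance_at(default_model, 20.0) * 1e6
        assert np.mean(adm.g) == pytest.approx(y.real, rel=0.05)
        assert np.mean(adm.b) == pytest.approx(y.imag, rel=0.05)

    def test_same_subject_higher_g_and_b_at_100_than_5(self, default_model, fe_noiseless):
        out = {}
        for f in (5.0, 100.0):
            spec = ExcitationSpec(mode="full_ac", frequency=f)
            fe = FrontEndConfig(noise_rms=0.0, fs_acq=200.0 if f >= 50 else 20.0)
            rec, _ = acquire(spec, default_model, None, fe, 5.0, polarization_on=False)
            adm = admittance_from_recording(rec, fe, spec)
            out[f] = (np.mean(adm.g), np.mean(adm.b))
        assert out[100.0][0] > out[5.0][0]
        assert out[100.0][1] > out[5.0][1]

    def test_quadrature_identity_g_b_from_magnitude_and_phase(self, default_model, fe_noiseless, full_ac_20):
        rec, _ = acquire(full_ac_20, default_model, None, fe_noiseless, 5.0, polarization_on=False)
        adm = admittance_from_recording(rec, fe_noiseless, full_ac_20)
        phi = np.radians(adm.phase)
        assert np.allclose(adm.g, adm.y_mag * np.cos(phi), rtol=1e-12, atol=1e-12)
        assert np.allclose(adm.b, adm.y_mag * np.sin(phi), rtol=1e-12, atol=1e-12)

    def test_dc_recording_rejected(self, default_model, fe_noiseless):
        spec = ExcitationSpec(mode="dc")
        rec, _ = acquire(spec, default_model, None, fe_noiseless, 5.0)
        with pytest.raises(ValueError):
            admittance_from_recording(rec, fe_noiseless, spec)


class TestDcConductance:
    def test_symmetric_divider_reads_10_uS(self, fe_noiseless):
        m = SkinRCModel(r_series=50e3, r_corneum=100e3, r_duct=100e3, c_epidermal=1e-12)
        spec = ExcitationSpec(mode="dc", amplitude=1.65)
        rec, _ = acquire(spec, m, None, fe_noiseless, 5.0, polarization_on=False)
        _, g = dc_conductance(rec, fe_noiseless, spec)
        assert np.mean(g[10:]) == pytest.approx(10.0, rel=1e-3)

    def test_halfwave_rectified_estimator_tracks_dc_conductance(self, fe_noiseless):
        m = SkinRCModel()
        spec = ExcitationSpec(mode="half_ac", amplitude=3.3, frequency=20.0)
        rec, truth = acquire(spec, m, None, fe_noiseless, 10.0, polarization_on=False)
        _, g = rectified_conductance(rec, fe_noiseless, spec)
        assert np.mean(g[40:]) == pytest.approx(truth.g_dc_uS.mean(), rel=0.05)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(100, 3.5)
        assert np.allclose(moving_average(x, 20.0), 3.5)

    def test_alternating_interior_is_zero(self):
        x = np.tile([1.0, -1.0], 50)
        y = moving_average(x, 2.0, span=1.0)  # window = 2 samples
        assert np.allclose(y[1:], 0.0)

    def test_window_is_200_samples_at_200_hz(self):
        """1 s of data at the elevated 200 Hz rate covers 200 samples."""
        x = np.zeros(1000)
        x[500] = 200.0
        y = moving_average(x, 200.0, span=1.0)
        # the impulse spreads over exactly 200 samples with weight 1/200
        assert np.isclose(y[500], 1.0)
        assert (y > 0).sum() == 200

    def test_mean_preserved_for_linear_series_odd_window(self):
        # symmetric (odd) truncated windows cancel edge bias for linear trends
        x = np.linspace(0.0, 4.0, 81)
        y = moving_average(x, 5.0)  # 5-sample window
        assert y.mean() == pytest.approx(x.mean(), rel=1e-12)

    def test_mean_approximately_preserved_for_smooth_series(self):
        t = np.linspace(0, 10, 400)
        x = 5.0 + 0.5 * np.sin(2 * np.pi * t / 7.0)
        y = moving_average(x, 20.0)
        assert y.mean() == pytest.approx(x.mean(), rel=1e-3)

    def test_output_length_matches_input(self):
        x = np.random.default_rng(0).normal(size=137)
        assert moving_average(x, 20.0).size == 137
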