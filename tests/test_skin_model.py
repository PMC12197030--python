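"""Skin circuit model: admittance closed form, time stepping, polarisation, sudomotor drive."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edawave import (
    PolarizationState,
    SkinRCModel,
    SkinState,
    SudomotorDrive,
    admittance_at,
    apply_sudomotor_drive,
    polarization_step,
    skin_step,
)
from edawave.skin_model import InvalidModelError, StepSizeError, scr_peak, scr_shape


def oracle_admittance(model: SkinRCModel, f: float) -> complex:
    """Independent circuit reduction: parallel of three branch impedances."""
    w = 2 * math.pi * f
    if f == 0:
        z_par = 1.0 / (1.0 / model.r_corneum + 1.0 / model.r_duct)
    else:
        zc = 1.0 / (1j * w * model.c_epidermal)
        z_par = 1.0 / (1.0 / model.r_corneum + 1.0 / model.r_duct + 1.0 / zc)
    return 1.0 / (model.r_series + z_par)


class TestAdmittance:
    def test_dc_limit_is_real(self, default_model):
        y = admittance_at(default_model, 0.0)
        assert y.imag == 0.0
        assert y.real == pytest.approx(1.0 / 210e3, rel=1e-12)
        assert y.real * 1e6 == pytest.approx(4.762, abs=1e-3)

    @pytest.mark.parametrize("f", [5.0, 20.0, 70.0, 100.0])
    def test_matches_independent_circuit_reduction(self, default_model, f):
        y = admittance_at(default_model, f)
        assert y == pytest.approx(oracle_admittance(default_model, f), rel=1e-12)

    def test_frozen_values_at_study_frequencies(self, default_model):
        y100 = admittance_at(default_model, 100.0) * 1e6
        assert y100.real == pytest.approx(7.7353, abs=5e-4)
        assert y100.imag == pytest.approx(16.5633, abs=5e-4)
        y5 = admittance_at(default_model, 5.0) * 1e6
        assert y5.real == pytest.approx(4.7696, abs=5e-4)
        assert y5.imag == pytest.approx(0.8548, abs=5e-4)

    def test_g_and_b_increase_with_frequency_over_study_band(self, default_model):
        ys = admittance_at(default_model, np.array([5.0, 20.0, 70.0, 100.0]))
        assert np.all(np.diff(ys.real) > 0)
        assert np.all(np.diff(ys.imag) > 0)

    def test_negative_frequency_rejected(self, default_model):
        with pytest.raises(ValueError):
            admittance_at(default_model, -1.0)

    def test_nonpositive_elements_rejected(self):
        with pytest.raises(InvalidModelError):
            SkinRCModel(r_duct=-5.0)
        with pytest.raises(InvalidModelError):
            SkinRCModel(c_epidermal=0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        r_s=st.floats(1e3, 50e3),
        r_c=st.floats(50e3, 2e6),
        r_d=st.floats(50e3, 5e6),
        c=st.floats(5e-9, 100e-9),
    )
    def test_parallel_resistance_bounded_and_parts_nonnegative(self, r_s, r_c, r_d, c):
        m = SkinRCModel(r_s, r_c, r_d, c)
        assert m.r_par <= min(r_c, r_d) + 1e-9
        for f in (0.0, 5.0, 100.0):
            y = admittance_at(m, f)
            assert y.real >= 0 and y.imag >= 0


class TestSkinStep:
    def _run(self, model, v_fn, rate, duration):
        state = SkinState()
        n = int(duration * rate)
        t = np.arange(n) / rate
        i = np.empty(n)
        for k in range(n):
            i[k], state = skin_step(model, state, v_fn(t[k]), 1.0 / rate)
        return t, i

    def test_dc_steady_state_current(self, default_model):
        t, i = self._run(default_model, lambda t: 1.65, 1000.0, 0.5)
        assert i[-1] == pytest.approx(1.65 / 210e3, rel=1e-6)

    def test_zero_input_keeps_zero_state(self, default_model):
        i, state = skin_step(default_model, SkinState(), 0.0, 1e-3)
        assert i == 0.0 and state.v_cap == 0.0

    @pytest.mark.parametrize("f", [5.0, 20.0, 70.0, 100.0])
    def test_steady_state_phasor_matches_admittance(self, default_model, f):
        """After >= 5 cycles the demodulated current phasor equals Y(f)·V within 1%."""
        rate = 50.0 * f
        a = 1.65
        t, i = self._run(default_model, lambda tt: a * math.sin(2 * math.pi * f * tt), rate, 8.0 / f)
        spc = int(rate / f)
        tail = i[5 * spc : 8 * spc]
        tt = t[5 * spc : 8 * spc]
        ph_i = 2.0 * np.mean(tail * np.sin(2 * np.pi * f * tt)) + 2j * np.mean(
            tail * np.cos(2 * np.pi * f * tt)
        )
        expected = admittance_at(default_model, f) * a
        assert abs(ph_i - (expected.real + 1j * expected.imag)) / abs(expected) < 0.01

    def test_step_size_contract(self, default_model):
        with pytest.raises(StepSizeError):
            skin_step(default_model, SkinState(), 1.0, dt=0.01, f_excitation=20.0)
        with pytest.raises(StepSizeError):
            skin_step(default_model, SkinState(), 1.0, dt=-1e-3)


class TestPolarization:
    def test_zero_current_decays_exponentially(self):
        st_ = PolarizationState(v_emf=1.0, c_pol=1e-3, r_leak=1e3)
        tau = 1.0  # r_leak * c_pol
        dt = 1e-3
        for _ in range(1000):  # one time constant
            st_ = polarization_step(st_, 0.0, dt)
        assert st_.v_emf == pytest.approx(math.exp(-1.0), rel=1e-2)

    def test_constant_current_rises_to_ir_leak(self):
        st_ = PolarizationState(c_pol=1e-4, r_leak=1e4)
        i0 = 1e-5
        dt = 1e-4
        vals = []
        for _ in range(50000):  # 5 s = 5 time constants
            st_ = polarization_step(st_, i0, dt)
            vals.append(st_.v_emf)
        assert np.all(np.diff(vals) > -1e-15)  # monotone rise
        assert st_.v_emf == pytest.approx(i0 * 1e4, rel=0.01)

    def test_sign_conservation_one_signed_current(self):
        st_ = PolarizationState()
        for k in range(500):
            st_ = polarization_step(st_, 5e-6, 1e-3)
            assert st_.v_emf >= 0.0

    def test_zero_mean_sinusoid_accumulates_little(self):
        """AC current over whole cycles leaves <2% of the EMF of DC at equal RMS."""
        f, dt = 20.0, 1e-4
        n = int(2.0 / dt)
        t = np.arange(n) * dt
        i_rms = 5e-6
        st_ac = PolarizationState()
        st_dc = PolarizationState()
        for k in range(n):
            st_ac = polarization_step(st_ac, i_rms * math.sqrt(2) * math.sin(2 * math.pi * f * t[k]), dt)
            st_dc = polarization_step(st_dc, i_rms, dt)
        assert abs(st_ac.v_emf) < 0.02 * abs(st_dc.v_emf)


class TestSudomotorDrive:
    def test_zero_drive_gives_constant_floor(self, default_model):
        t = np.linspace(0, 10, 201)
        r = apply_sudomotor_drive(default_model, SudomotorDrive(tonic_level=0.0), t, g_min=1e-6, k=1e-6)
        assert np.allclose(r, 1e6)

    def test_single_event_peak_matches_analytic_biexponential(self, default_model):
        tau_r, tau_d, amp, k_gain = 0.75, 2.0, 1.0, 1e-6
        drive = SudomotorDrive(tonic_level=0.0, scr_events=[(1.0, amp, tau_r, tau_d)])
        t = np.linspace(0, 20, 20001)
        r = apply_sudomotor_drive(default_model, drive, t, g_min=1e-6, k=k_gain)
        g = 1.0 / r
        t_pk, v_pk = scr_peak(tau_r, tau_d)
        assert g.max() - 1e-6 == pytest.approx(k_gain * amp * v_pk, rel=1e-4)
        assert t[np.argmax(g)] == pytest.approx(1.0 + t_pk, abs=2e-3)

    def test_nonoverlapping_events_superpose(self, default_model):
        t = np.linspace(0, 60, 6001)
        e1 = (5.0, 0.5, 0.75, 2.0)
        e2 = (40.0, 0.8, 0.75, 2.0)
        both = SudomotorDrive(tonic_level=1.0, scr_events=[e1, e2]).intensity(t)
        d1 = SudomotorDrive(tonic_level=1.0, scr_events=[e1]).intensity(t)
        d2 = SudomotorDrive(tonic_level=0.0, scr_events=[e2]).intensity(t)
        assert np.allclose(both, d1 + d2, atol=1e-12)

    def test_bounds_clamped(self, default_model):
        t = np.linspace(0, 1, 11)
        r = apply_sudomotor_drive(
            default_model, SudomotorDrive(tonic_level=1e6), t, r_duct_bounds=(50e3, 5e6)
        )
        assert np.all(r >= 50e3)

    def test_invalid_event_shapes_rejected(self):
        with pytest.raises(ValueError):
            SudomotorDrive(scr_events=[(0.0, -1.0, 0.75, 2.0)])
        with pytest.raises(ValueError):
            SudomotorDrive(scr_events=[(0.0, 1.0, 2.0, 0.75)])

    def test_shape_zero_before_onset(self):
        assert np.all(scr_shape(np.array([-1.0, -0.01]), 0.75, 2.0) == 0.0)
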