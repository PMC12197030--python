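"""End-to-end acquisition chain: excitation → R0 divider → skin → ADC.

The front end places a current-limiting resistor R0 in series with the skin
and records the voltage across the skin (shifted back into the positive rail
by an output clamper) with the microcontroller ADC.  The forward divider and
its algebraic inversion,

    v_skin = v_ac · z / (r0 + z)          z = v_skin · r0 / (v_ac − v_skin)

are the measurement equations of the device; everything else here is the
honest simulation of what corrupts them: electrode polarisation EMF, front-
end noise, quantisation, and sample-and-hold decimation.

The per-sample circuit integration (time-varying duct resistance, capacitor
state, polarisation feedback) is a sequential recurrence and is JIT-compiled
with numba.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from numba import njit

from .excitation import ExcitationMode, ExcitationSpec, Waveform, make_excitation
from .skin_model import (
    PolarizationState,
    SkinRCModel,
    SudomotorDrive,
    apply_sudomotor_drive,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FrontEndConfig",
    "RawRecording",
    "TruthLog",
    "divider_forward",
    "divider_invert",
    "acquire",
]

#: hard safety limit on skin current from the medical-device standard, A
I_SAFE_LIMIT = 20e-6


@dataclass(frozen=True)
class FrontEndConfig:
    """Analogue front end and ADC constants.

    ``r0`` is the series current limiter (default 100 kΩ → 16.5 µA worst
    case, inside the 20 µA limit); ``fs_acq`` is the output rate of the
    conductance estimates (20 Hz, or 200 Hz for 70/100 Hz carriers);
    ``noise_rms`` is additive Gaussian front-end noise in volts.
    """

    r0: float = 100e3
    v_supply: float = 3.3
    v_ref: float = 1.65
    adc_bits: int = 16
    adc_vref: float = 3.3
    fs_acq: float = 20.0
    noise_rms: float = 1e-3

    def __post_init__(self) -> None:
        if self.r0 < (self.v_supply / 2.0) / I_SAFE_LIMIT:
            raise ValueError(
                f"r0={self.r0:g} Ω violates the {I_SAFE_LIMIT * 1e6:g} µA safety bound "
                f"(needs >= {(self.v_supply / 2.0) / I_SAFE_LIMIT:g} Ω)"
            )
        if not (8 <= self.adc_bits <= 16):
            raise ValueError("adc_bits must lie in [8, 16]")

    @property
    def adc_levels(self) -> int:
        return 2 ** self.adc_bits - 1

    @property
    def lsb(self) -> float:
        return self.adc_vref / self.adc_levels


@dataclass
class RawRecording:
    """ADC-count time series: the boundary between 'device' and 'processing'."""

    counts: np.ndarray
    fs: float
    mode: ExcitationMode
    f_excitation: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.counts.size) / self.fs

    def volts(self, fe: FrontEndConfig) -> np.ndarray:
        """Reconstruct ADC input volts from counts."""
        return self.counts.astype(float) * fe.adc_vref / fe.adc_levels


@dataclass
class TruthLog:
    """Ground-truth model conductances on the output grid (µS)."""

    t: np.ndarray
    g_dc_uS: np.ndarray     # true DC conductance 1/(r_series + r_par(t))
    g_f_uS: np.ndarray      # true Re Y at the excitation frequency
    b_f_uS: np.ndarray      # true Im Y at the excitation frequency


# --------------------------------------------------------------------------
# divider algebra
# --------------------------------------------------------------------------


def divider_forward(v_ac, z, r0: float):
    """Voltage across the skin for drive v_ac and skin impedance z (complex ok)."""
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    denom = r0 + z
    if np.any(np.abs(denom) == 0):
        raise ZeroDivisionError("degenerate divider: z = -r0")
    return v_ac * z / denom


def divider_invert(v_skin, v_ac, r0: float):
    """Skin impedance from the measured divider voltages (exact inverse)."""
    diff = v_ac - v_skin
    if np.any(np.abs(diff) == 0):
        raise ZeroDivisionError("unmeasurable: v_ac equals v_skin (open circuit)")
    return v_skin * r0 / diff


# --------------------------------------------------------------------------
# JIT circuit loop
# --------------------------------------------------------------------------


@njit(cache=True)
def _circuit_loop(v_exc, r_par, dt, r_series, c_e, r0, c_pol, r_leak, pol_on, v_clip):
    """Sequential integration of the divider + skin RC + polarisation chain.

    Same exponential capacitor update as skin_model.skin_step with the
    series resistance r0 + r_series, plus the forward-Euler EMF accumulator.
    Returns (v_skin, i_skin, v_emf) at every internal sample.
    """
    n = v_exc.size
    v_skin = np.empty(n)
    i_skin = np.empty(n)
    v_emf_log = np.empty(n)
    r_tot = r0 + r_series
    v_cap = 0.0
    v_emf = 0.0
    u_old = 0.0
    u_old2 = 0.0
    for k in range(n):
        v_node = v_exc[k] - v_emf if pol_on else v_exc[k]
        u_new = v_node / (r_tot * c_e)
        q = (1.0 / r_tot + 1.0 / r_par[k]) / c_e
        if k == 0:
            u_old = u_new
            u_old2 = u_new
        a = q * dt
        e = np.exp(-a)
        if a < 0.05:
            phi1 = 1.0 - a / 2.0 + a * a / 6.0 - a**3 / 24.0
            phi2 = 0.5 - a / 6.0 + a * a / 24.0 - a**3 / 120.0
            kq = -1.0 / 6.0 + a / 12.0 - a * a / 40.0
        else:
            phi1 = (1.0 - e) / a
            psi2 = (1.0 - (1.0 + a) * e) / (a * a)
            psi3 = (2.0 - (a * a + 2.0 * a + 2.0) * e) / (a ** 3)
            phi2 = phi1 - psi2
            kq = psi3 - psi2
        curv = 0.5 * (u_new - 2.0 * u_old + u_old2)
        v_cap = e * v_cap + dt * (u_old * (phi1 - phi2) + u_new * phi2 + curv * kq)
        i = (v_node - v_cap) / r_tot
        i_skin[k] = i
        # the EMF sits between the tap node and ground (in series with the
        # skin), so the tapped voltage v_exc - i*r0 reads v_emf + v_skin:
        # apparent impedance inflates and the conductance estimate drifts DOWN
        v_skin[k] = v_exc[k] - i * r0
        v_emf = v_emf + dt * (i / c_pol - v_emf / (r_leak * c_pol))
        if v_emf > v_clip:
            v_emf = v_clip
        elif v_emf < -v_clip:
            v_emf = -v_clip
        v_emf_log[k] = v_emf
        u_old2 = u_old
        u_old = u_new
    return v_skin, i_skin, v_emf_log


# --------------------------------------------------------------------------
# acquisition
# --------------------------------------------------------------------------


def acquire(
    spec: ExcitationSpec,
    model: SkinRCModel,
    drive: SudomotorDrive | None,
    fe: FrontEndConfig,
    duration: float,
    seed: int | None = 0,
    polarization_on: bool = True,
    polarization: PolarizationState | None = None,
    duct_map: dict[str, Any] | None = None,
) -> tuple[RawRecording, TruthLog]:
    """Simulate a full acquisition and return the raw recording plus truth log.

    The chain per internal sample: excitation minus accumulated EMF, divider
    with the (time-varying) skin circuit, polarisation update, output
    clamper shift by +v_ref, additive Gaussian noise, quantisation.  The
    recording is kept at the internal (ADC) rate — ≥ 50 samples per carrier
    cycle so lock-in demodulation is well-posed — and ``fe.fs_acq`` is the
    output rate for the demodulated series, stored in the metadata.
    """
    if spec.mode is not ExcitationMode.DC and duration < 5.0 / spec.frequency:
        raise ValueError("duration must cover at least 5 excitation cycles")
    wave = make_excitation(spec, duration)
    t_int = wave.t
    pol = polarization if polarization is not None else PolarizationState()

    if drive is None:
        r_duct = np.full(t_int.size, model.r_duct)
    else:
        r_duct = apply_sudomotor_drive(model, drive, t_int, **(duct_map or {}))
    r_par = model.r_corneum * r_duct / (model.r_corneum + r_duct)

    dt = 1.0 / wave.rate
    v_skin, i_skin, v_emf = _circuit_loop(
        wave.v, r_par, dt, model.r_series, model.c_epidermal,
        fe.r0, pol.c_pol, pol.r_leak, polarization_on, fe.v_supply,
    )

    # The output clamper exists to lift the bipolar full-wave signal into the
    # ADC range; DC and half-wave skin voltages are already non-negative and
    # are digitised as-is (a +v_ref shift would saturate the converter).
    v_shift = fe.v_ref if spec.mode is ExcitationMode.FULL_AC else 0.0
    v_out = v_skin + v_shift
    if fe.noise_rms > 0:
        rng = np.random.default_rng(seed)
        v_out = v_out + rng.normal(0.0, fe.noise_rms, size=v_out.size)
    clipped = (v_out < 0) | (v_out > fe.adc_vref)
    counts = np.clip(np.rint(np.clip(v_out, 0.0, fe.adc_vref) / fe.lsb), 0, fe.adc_levels).astype(np.int64)

    meta: dict[str, Any] = {
        "front_end": asdict(fe),
        "excitation": {
            "mode": spec.mode.value, "amplitude": spec.amplitude,
            "frequency": spec.frequency, "shape": spec.shape,
            "internal_rate": spec.internal_rate, "duty": spec.duty,
            "v_supply": spec.v_supply, "v_ref": spec.v_ref,
        },
        "seed": seed,
        "v_shift": v_shift,
        "polarization_on": polarization_on,
        "fs_out": fe.fs_acq,
        "duration_s": duration,
    }
    sat_frac = float(clipped.mean())
    if sat_frac > 0.01:
        meta["warning"] = f"ADC saturated for {sat_frac:.1%} of samples"
        logger.warning("acquire: %s", meta["warning"])

    # ground truth on the output grid (sample-and-hold from the internal grid)
    n_out = int(round(duration * fe.fs_acq))
    t_out = np.arange(n_out) / fe.fs_acq
    idx = np.minimum((t_out * wave.rate).astype(np.int64), t_int.size - 1)
    r_par_out = r_par[idx]
    g_dc = 1e6 / (model.r_series + r_par_out)
    f_truth = spec.frequency if spec.mode is not ExcitationMode.DC else 0.0
    z_f = model.r_series + r_par_out / (
        1.0 + 1j * 2.0 * np.pi * f_truth * r_par_out * model.c_epidermal
    )
    y_f = 1e6 / z_f
    truth = TruthLog(t=t_out, g_dc_uS=g_dc, g_f_uS=y_f.real, b_f_uS=y_f.imag)

    rec = RawRecording(counts=counts, fs=wave.rate, mode=spec.mode,
                       f_excitation=spec.frequency, meta=meta)
    return rec, truth
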