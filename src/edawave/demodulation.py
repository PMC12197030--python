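"""Lock-in demodulation and admittance decomposition.

A lock-in amplifier recovers the amplitude and phase of a signal at a known
reference frequency by multiplying it with an in-phase sine and a quadrature
cosine and low-pass filtering the products:

    I = LPF(x·sin 2πf t),   Q = LPF(x·cos 2πf t)
    amplitude = 2·sqrt(I² + Q²),   phase = atan2(Q, I)

Everything else at other frequencies — noise, harmonics, the quasi-DC
polarisation EMF — averages to zero.  Applied to both the measured skin
voltage and the regenerated excitation reference, the two phasors invert the
R0 divider to the complex skin impedance, whose reciprocal splits into
conductance G = |Y|·cos ϕ and susceptance B = |Y|·sin ϕ.

The default low-pass is an average over an integer number of reference
cycles, which nulls the 2f mixing product exactly.  PWM excitation is
demodulated at its fundamental (amplitude 4/π of the half-swing); the
lock-in rejects the odd harmonics by construction.

Also here: the plain DC voltage-drop conductance estimator, the
mean-rectified estimator used by half-wave devices, and the 1 s centred
moving-average filter (20 samples at 20 Hz, 200 samples at 200 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .excitation import ExcitationMode, ExcitationSpec, Waveform, make_excitation
from .measurement_chain import FrontEndConfig, RawRecording, divider_invert

logger = logging.getLogger(__name__)

__all__ = [
    "AdmittanceSeries",
    "LockinConfig",
    "lockin",
    "admittance_from_recording",
    "dc_conductance",
    "rectified_conductance",
    "moving_average",
]


@dataclass
class AdmittanceSeries:
    """Demodulated admittance vs time: conductance, susceptance, phase, |Y|."""

    t: np.ndarray
    g: np.ndarray        # µS
    b: np.ndarray        # µS
    phase: np.ndarray    # degrees
    y_mag: np.ndarray    # µS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.t, "g_uS": self.g, "b_uS": self.b,
             "phase_deg": self.phase, "y_uS": self.y_mag}
        )


@dataclass(frozen=True)
class LockinConfig:
    """Lock-in low-pass configuration.

    ``cycle_average`` averages I/Q over ``n_cycles`` whole reference cycles
    (default 4); ``butterworth`` uses a zero-phase 4th-order filter with
    cutoff ``lpf_cutoff`` Hz.  ``settle`` seconds are discarded from the
    head of the output to drop the filter/circuit transient.
    """

    lpf_kind: str = "cycle_average"
    n_cycles: int = 4
    lpf_cutoff: float = 2.0
    settle: float = 0.5

    def __post_init__(self) -> None:
        if self.lpf_kind not in ("cycle_average", "butterworth"):
            raise ValueError(f"unknown lpf_kind {self.lpf_kind!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def lockin(
    x: Waveform, f_ref: float, cfg: LockinConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Demodulate a waveform at f_ref; returns (t, amplitude, phase_deg).

    For ``x = A·sin(2πf_ref·t + φ)`` the noiseless cycle-average output is
    exactly (A, φ) on every block of whole cycles.
    """
    cfg = cfg or LockinConfig()
    if x.rate < 10.0 * f_ref:
        raise ValueError(f"sampling rate {x.rate:g} Hz too low for f_ref={f_ref:g} Hz (needs >= 10x)")
    ref_s = np.sin(2.0 * np.pi * f_ref * x.t)
    ref_c = np.cos(2.0 * np.pi * f_ref * x.t)
    xi = x.v * ref_s
    xq = x.v * ref_c

    if cfg.lpf_kind == "cycle_average":
        spc = x.rate / f_ref
        if abs(spc - round(spc)) > 1e-6:
            raise ValueError("cycle_average needs an integer number of samples per cycle")
        block = int(round(spc)) * cfg.n_cycles
        m = xi.size // block
        if m < 1:
            raise ValueError("record shorter than one lock-in block")
        i_lp = xi[: m * block].reshape(m, block).mean(axis=1)
        q_lp = xq[: m * block].reshape(m, block).mean(axis=1)
        t_out = (np.arange(m) + 0.5) * block / x.rate
    else:
        sos = _signal.butter(4, cfg.lpf_cutoff, fs=x.rate, output="sos")
        i_lp = _signal.sosfiltfilt(sos, xi)
        q_lp = _signal.sosfiltfilt(sos, xq)
        t_out = x.t

    keep = t_out >= cfg.settle
    if not keep.any():
        keep = slice(None)  # record too short to settle; return everything
    amp = 2.0 * np.hypot(i_lp, q_lp)
    phase = np.degrees(np.arctan2(q_lp, i_lp))
    return t_out[keep], amp[keep], phase[keep]


def _hold_resample(t_src: np.ndarray, y_src: np.ndarray, t_out: np.ndarray) -> np.ndarray:
    """Sample-and-hold the most recent estimate onto the output grid."""
    idx = np.searchsorted(t_src, t_out, side="right") - 1
    return y_src[np.clip(idx, 0, t_src.size - 1)]


def _output_grid(rec: RawRecording, fe: FrontEndConfig, t_lo: float) -> np.ndarray:
    duration = rec.counts.size / rec.fs
    t_out = np.arange(int(round(duration * fe.fs_acq))) / fe.fs_acq
    return t_out[t_out >= t_lo]


def admittance_from_recording(
    rec: RawRecording,
    fe: FrontEndConfig,
    spec: ExcitationSpec,
    cfg: LockinConfig | None = None,
) -> AdmittanceSeries:
    """Full lock-in processing: recording → G/B/phase/|Y| series at fs_acq.

    Both the reconstructed skin voltage and a regenerated copy of the
    excitation are demodulated at the carrier with the same lock-in, so the
    divider inversion works on phasors referenced to a common time origin.
    """
    if spec.mode is ExcitationMode.DC:
        raise ValueError("admittance_from_recording requires an AC recording")
    cfg = cfg or LockinConfig()
    v_shift = rec.meta.get("v_shift", fe.v_ref)
    v = rec.volts(fe) - v_shift
    duration = rec.counts.size / rec.fs
    wave_skin = Waveform(t=rec.t, v=v, rate=rec.fs)
    wave_ref = make_excitation(spec, duration)

    t_b, amp_s, ph_s = lockin(wave_skin, spec.frequency, cfg)
    _, amp_r, ph_r = lockin(wave_ref, spec.frequency, cfg)
    n = min(amp_s.size, amp_r.size)
    ph_skin = np.radians(ph_s[:n])
    ph_ref = np.radians(ph_r[:n])
    v_skin_ph = amp_s[:n] * np.exp(1j * ph_skin)
    v_ac_ph = amp_r[:n] * np.exp(1j * ph_ref)

    low = amp_s[:n] < 10.0 * fe.lsb
    if low.any():
        logger.warning("low-signal segments: %d/%d lock-in blocks below 10 LSB", int(low.sum()), n)

    z = divider_invert(v_skin_ph, v_ac_ph, fe.r0)
    y = 1e6 / z  # µS
    t_out = _output_grid(rec, fe, t_b[0])
    g = _hold_resample(t_b[:n], y.real, t_out)
    b = _hold_resample(t_b[:n], y.imag, t_out)
    return AdmittanceSeries(
        t=t_out, g=g, b=b,
        phase=np.degrees(np.arctan2(b, g)),
        y_mag=np.hypot(g, b),
    )


def dc_conductance(
    rec: RawRecording, fe: FrontEndConfig, spec: ExcitationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """DC voltage-drop estimator: (t, conductance µS) at fs_acq.

    Inverts the divider per sample against the *nominal* drive level — the
    device does not know the polarisation EMF, which is exactly how the
    downward drift enters the estimate.
    """
    if spec.mode is not ExcitationMode.DC:
        raise ValueError("dc_conductance requires a DC recording")
    v_shift = rec.meta.get("v_shift", 0.0)
    v_skin = rec.volts(fe) - v_shift
    v_dc = spec.amplitude
    clip = v_skin >= v_dc
    if clip.any():
        logger.warning("dc_conductance: %d samples at/above the drive level, clipped", int(clip.sum()))
        v_skin = np.minimum(v_skin, v_dc - fe.lsb)
    v_skin = np.maximum(v_skin, fe.lsb)  # guard against g -> inf at 0 counts
    z = divider_invert(v_skin, v_dc, fe.r0)
    g = 1e6 / z
    t_out = _output_grid(rec, fe, 0.0)
    idx = np.minimum((t_out * rec.fs).astype(np.int64), v_skin.size - 1)
    return t_out, g[idx]


def rectified_conductance(
    rec: RawRecording,
    fe: FrontEndConfig,
    spec: ExcitationSpec,
    n_cycles: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-rectified conductance for half-wave devices: (t, µS) at fs_acq.

    Averages the skin voltage and the regenerated excitation over blocks of
    whole carrier cycles and inverts the divider on the means — the way a
    DC-style reader sees a unipolar carrier.  Sensitive to the polarisation
    EMF (unlike the lock-in), which reproduces the DC-like drift of
    half-wave recordings.
    """
    if spec.mode is ExcitationMode.DC:
        raise ValueError("rectified_conductance requires an AC recording")
    v_shift = rec.meta.get("v_shift", 0.0)
    v_skin = rec.volts(fe) - v_shift
    duration = rec.counts.size / rec.fs
    v_exc = make_excitation(spec, duration).v
    spc = int(round(rec.fs / spec.frequency))
    block = spc * n_cycles
    m = v_skin.size // block
    vs = v_skin[: m * block].reshape(m, block).mean(axis=1)
    ve = v_exc[: m * block].reshape(m, block).mean(axis=1)
    vs = np.minimum(vs, ve - fe.lsb)
    vs = np.maximum(vs, fe.lsb)
    g = 1e6 / divider_invert(vs, ve, fe.r0)
    t_b = (np.arange(m) + 0.5) * block / rec.fs
    t_out = _output_grid(rec, fe, 0.0)
    return t_out, _hold_resample(t_b, g, t_out)


def moving_average(x: np.ndarray, fs: float, span: float = 1.0) -> np.ndarray:
    """Centred moving mean over round(span·fs) samples, truncated at edges.

    Output length equals input length.  At 20 Hz the 1 s window covers 20
    samples; at 200 Hz, 200 samples.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(span * fs))
    if w < 1:
        raise ValueError("window must cover at least one sample")
    return (
        pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )
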