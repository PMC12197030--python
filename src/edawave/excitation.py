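"""Excitation waveform generation: DC, positive half-wave AC, full-wave AC.

The device drives the skin in one of three ways:

* ``dc`` — a constant voltage (the traditional exosomatic method);
* ``half_ac`` — a rectified sine ``A·max(sin 2πft, 0)``: alternating in
  magnitude but never negative, so its mean is A/π and it polarises
  electrodes much like DC;
* ``full_ac`` — a 0–3.3 V PWM (or sine) source passed through a level
  shift / clamp stage that centres it on the 1.65 V mid-rail; coupled
  through a capacitor it swings ±1.65 V with exactly zero mean over whole
  periods.  The zero mean is the property that suppresses electrode
  polarisation downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ExcitationMode", "ExcitationSpec", "Waveform", "pwm_wave", "clamp_and_couple", "make_excitation"]


class ExcitationMode(str, Enum):
    DC = "dc"
    HALF_AC = "half_ac"
    FULL_AC = "full_ac"


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled voltage waveform."""

    t: np.ndarray
    v: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")


@dataclass(frozen=True)
class ExcitationSpec:
    """Excitation configuration.

    ``amplitude`` is the drive amplitude A (V): the constant level for
    ``dc``, the sine peak for ``half_ac``; ``full_ac`` amplitude is set by
    ``v_supply`` (swing ±v_supply/2 after clamping).  ``internal_rate``
    defaults to 50 samples per excitation cycle (200 Hz for DC).
    """

    mode: ExcitationMode = ExcitationMode.FULL_AC
    amplitude: float = 1.65
    frequency: float = 20.0
    shape: str = "pwm_square"  # or "sine"
    internal_rate: float | None = None
    duty: float = 0.5
    v_supply: float = 3.3
    v_ref: float | None = None

    def __post_init__(self) -> None:
        mode = ExcitationMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is not ExcitationMode.DC and not self.frequency > 0:
            raise ValueError("frequency must be > 0 for AC modes")
        if not (0 < self.duty < 1):
            raise ValueError("duty must lie in (0, 1)")
        if self.shape not in ("sine", "pwm_square"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.v_ref is None:
            object.__setattr__(self, "v_ref", self.v_supply / 2.0)
        if self.internal_rate is None:
            rate = 200.0 if mode is ExcitationMode.DC else 50.0 * self.frequency
            object.__setattr__(self, "internal_rate", rate)
        if mode is not ExcitationMode.DC:
            if self.internal_rate < 50.0 * self.frequency:
                raise ValueError("internal_rate must be >= 50 x frequency")
            spc = self.internal_rate / self.frequency
            if abs(spc - round(spc)) > 1e-9:
                raise ValueError("internal_rate must be an integer multiple of frequency")

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.internal_rate / self.frequency))


def _time_grid(rate: float, duration: float) -> np.ndarray:
    n = int(round(duration * rate))
    return np.arange(n) / rate


def pwm_wave(spec: ExcitationSpec, duration: float) -> Waveform:
    """Raw PWM source: v_supply for the duty fraction of each period, else 0."""
    if spec.shape != "pwm_square":
        raise ValueError("pwm_wave requires a pwm_square shape")
    if duration < 1.0 / spec.frequency:
        raise ValueError("duration must cover at least one PWM period")
    t = _time_grid(spec.internal_rate, duration)
    spc = spec.samples_per_cycle
    k = np.arange(t.size) % spc
    v = np.where(k < spec.duty * spc, spec.v_supply, 0.0)
    return Waveform(t=t, v=v, rate=spec.internal_rate)


def clamp_and_couple(w: Waveform, spec: ExcitationSpec, diode_drop: float = 0.0) -> Waveform:
    """Ideal level shift + capacitive coupling: centre a [0, v_supply] wave on 0 V.

    Output = input − v_ref, clipped at ±v_supply/2 (protection clamp).  A
    non-zero ``diode_drop`` lowers the clip rails, mimicking real diodes.
    """
    half = spec.v_supply / 2.0 - diode_drop
    v = np.clip(w.v - spec.v_ref, -half, half)
    if np.ptp(w.v) == 0:
        logger.warning("clamp_and_couple: constant input, output is a DC level (degenerate)")
    return Waveform(t=w.t, v=v, rate=w.rate)


def make_excitation(spec: ExcitationSpec, duration: float) -> Waveform:
    """Generate the excitation waveform for the configured mode at internal_rate."""
    mode = ExcitationMode(spec.mode)
    if mode is ExcitationMode.DC:
        t = _time_grid(spec.internal_rate, duration)
        return Waveform(t=t, v=np.full(t.size, spec.amplitude), rate=spec.internal_rate)
    if mode is ExcitationMode.HALF_AC:
        t = _time_grid(spec.internal_rate, duration)
        v = spec.amplitude * np.maximum(np.sin(2.0 * np.pi * spec.frequency * t), 0.0)
        return Waveform(t=t, v=v, rate=spec.internal_rate)
    if mode is ExcitationMode.FULL_AC:
        if spec.shape == "pwm_square":
            return clamp_and_couple(pwm_wave(spec, duration), spec)
        t = _time_grid(spec.internal_rate, duration)
        raw = spec.v_ref + (spec.v_supply / 2.0) * np.sin(2.0 * np.pi * spec.frequency * t)
        return clamp_and_couple(Waveform(t=t, v=raw, rate=spec.internal_rate), spec)
    raise ValueError(f"unknown excitation mode {spec.mode!r}")
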