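"""Lumped electrical model of skin and the electrode interface.

The skin is represented by the classic exosomatic EDA equivalent circuit: a
fixed resistor for the stratum corneum in parallel with a variable resistor
for the sweat-gland ducts, that parallel block shunted by an epidermal
capacitor, and the whole thing in series with a deep-tissue resistance.
Sweat-gland (sudomotor) activity modulates the duct resistance, which is what
turns physiology into a conductance signal.

Under a DC drive the capacitor is invisible and the admittance is purely
real.  Under an AC drive the capacitor progressively shorts out the corneum/
duct block as frequency rises, so both the measured conductance G and
susceptance B increase with frequency — the behaviour the device exploits.

The electrode interface is modelled as a first-order charge-accumulation
element: one-signed current deposits charge on the electrode double layer,
building a counter-electromotive force that subtracts from the applied
drive and produces the familiar downward drift of DC recordings.  Zero-mean
excitation leaves the accumulator (almost) undisturbed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SkinRCModel",
    "SkinState",
    "PolarizationState",
    "SudomotorDrive",
    "InvalidModelError",
    "StepSizeError",
    "admittance_at",
    "skin_step",
    "polarization_step",
    "apply_sudomotor_drive",
    "scr_shape",
    "scr_peak",
]


class InvalidModelError(ValueError):
    """Raised when a circuit model has non-physical (non-positive) elements."""


class StepSizeError(ValueError):
    """Raised when an integration step violates the accuracy contract."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SkinRCModel:
    """Series resistance + (corneum ∥ duct ∥ epidermal capacitor) skin circuit.

    Parameters
    ----------
    r_series:
        Deep-tissue / dermis series resistance, Ω.
    r_corneum:
        Fixed stratum-corneum resistance, Ω.
    r_duct:
        Variable sweat-gland duct resistance, Ω (the physiological dial).
    c_epidermal:
        Capacitance in parallel with the corneum/duct block, F.
    """

    r_series: float = 10e3
    r_corneum: float = 250e3
    r_duct: float = 1e6
    c_epidermal: float = 30e-9

    def __post_init__(self) -> None:
        for name in ("r_series", "r_corneum", "r_duct", "c_epidermal"):
            if not (getattr(self, name) > 0) or not math.isfinite(getattr(self, name)):
                raise InvalidModelError(f"{name} must be strictly positive, got {getattr(self, name)!r}")

    @property
    def r_par(self) -> float:
        """Parallel combination of corneum and duct resistances, Ω."""
        return self.r_corneum * self.r_duct / (self.r_corneum + self.r_duct)

    @property
    def g_dc(self) -> float:
        """DC conductance 1/(r_series + r_par), S."""
        return 1.0 / (self.r_series + self.r_par)

    def with_r_duct(self, r_duct: float) -> "SkinRCModel":
        return replace(self, r_duct=r_duct)


@dataclass
class SkinState:
    """Integration state for :func:`skin_step`.

    ``v_cap`` is the voltage across the parallel (corneum/duct/capacitor)
    block; ``v_prev``/``v_prev2`` remember the last two applied voltages so
    the exponential integrator can fit a quadratic through the input.
    """

    v_cap: float = 0.0
    v_prev: float | None = None
    v_prev2: float | None = None


@dataclass
class PolarizationState:
    """Electrode-interface charge accumulator.

    ``v_emf`` is the accumulated counter-electromotive force (V), starting
    at zero; ``c_pol`` the interface accumulation capacitance (F); ``r_leak``
    the self-discharge path (Ω).  Defaults give a ~75 s drift time constant
    against the default front end — a progressive decline over minutes rather
    than an instant collapse.
    """

    v_emf: float = 0.0
    c_pol: float = 500e-6
    r_leak: float = 300e3

    def __post_init__(self) -> None:
        if self.c_pol <= 0 or self.r_leak <= 0:
            raise InvalidModelError("c_pol and r_leak must be strictly positive")


TonicLevel = Union[float, Sequence[float], np.ndarray, Callable[[np.ndarray], np.ndarray]]


@dataclass
class SudomotorDrive:
    """Generative stand-in for sweat-gland activity.

    ``tonic_level`` is a dimensionless baseline trajectory (scalar, array
    aligned with the evaluation grid, or callable of time); ``scr_events``
    is a list of ``(onset_s, amplitude, tau_rise_s, tau_decay_s)`` phasic
    events, each contributing an additive bi-exponential bump.
    """

    tonic_level: TonicLevel = 1.0
    scr_events: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for onset, amp, tau_r, tau_d in self.scr_events:
            if amp < 0:
                raise ValueError(f"SCR amplitude must be >= 0, got {amp}")
            if not (tau_r < tau_d):
                raise ValueError(f"SCR rise constant ({tau_r}) must be < decay constant ({tau_d})")

    def intensity(self, t_grid: np.ndarray) -> np.ndarray:
        """Dimensionless drive d(t) = tonic + Σ events, clipped at 0."""
        t_grid = np.asarray(t_grid, dtype=float)
        if callable(self.tonic_level):
            d = np.asarray(self.tonic_level(t_grid), dtype=float).copy()
            if d.shape != t_grid.shape:
                d = np.broadcast_to(d, t_grid.shape).astype(float)
        else:
            tonic = np.asarray(self.tonic_level, dtype=float)
            if tonic.ndim == 0:
                d = np.full_like(t_grid, float(tonic))
            else:
                if tonic.shape != t_grid.shape:
                    raise ValueError("array tonic_level must match the evaluation grid")
                d = tonic.copy()
        for onset, amp, tau_r, tau_d in self.scr_events:
            d += amp * scr_shape(t_grid - onset, tau_r, tau_d)
        return np.clip(d, 0.0, None)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def scr_shape(dt: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unnormalised bi-exponential SCR shape exp(-t/τd) - exp(-t/τr), 0 before onset."""
    dt = np.asarray(dt, dtype=float)
    out = np.zeros_like(dt)
    m = dt >= 0
    out[m] = np.exp(-dt[m] / tau_decay) - np.exp(-dt[m] / tau_rise)
    return out


def scr_peak(tau_rise: float, tau_decay: float) -> tuple[float, float]:
    """Analytic (time, value) of the bi-exponential maximum past onset."""
    t_pk = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    v_pk = math.exp(-t_pk / tau_decay) - math.exp(-t_pk / tau_rise)
    return t_pk, v_pk


def admittance_at(model: SkinRCModel, f):
    """Complex skin admittance Y(f) = G(f) + iB(f) in siemens.

    Y(f) = 1 / ( r_series + r_par / (1 + i·2πf·r_par·c_epidermal) ).
    At f = 0 this reduces to the purely real DC conductance.  Accepts scalar
    or array frequency (Hz, >= 0).
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("frequency must be >= 0")
    r_par = model.r_par
    z = model.r_series + r_par / (1.0 + 1j * 2.0 * np.pi * f_arr * r_par * model.c_epidermal)
    y = 1.0 / z
    return y if f_arr.ndim else complex(y)


def skin_step(
    model: SkinRCModel,
    state: SkinState,
    v_applied: float,
    dt: float,
    f_excitation: float | None = None,
) -> tuple[float, SkinState]:
    """Advance the skin circuit one step under an applied terminal voltage.

    Exponential-integrator update of the capacitor-block voltage v_cap
    obeying

        C dv/dt = (v_applied - v)/r_series - v/r_par

    The linear ODE is solved analytically over the step with the input
    interpolated quadratically through the last three applied voltages
    (linearly on the first step): third-order local accuracy, and — unlike
    the trapezoidal rule — free of ±1 amplification ringing when the block
    time constant is far below dt (stiff loads, square-wave edges).

    Returns the terminal current ``(v_applied - v_cap)/r_series`` at the new
    time and the updated state.  For a sinusoidal drive at ≥ 50 samples per
    cycle the steady-state current phasor matches :func:`admittance_at`
    within 1% for any valid model.
    """
    if dt <= 0:
        raise StepSizeError("dt must be > 0")
    if f_excitation is not None and dt > 1.0 / (20.0 * f_excitation):
        raise StepSizeError(
            f"dt={dt:g} s exceeds 1/(20·f)={1.0 / (20.0 * f_excitation):g} s accuracy contract"
        )
    c = model.c_epidermal
    q = (1.0 / model.r_series + 1.0 / model.r_par) / c  # 1/τ of the block
    scale = 1.0 / (model.r_series * c)
    v_prev = state.v_prev if state.v_prev is not None else v_applied
    v_prev2 = state.v_prev2 if state.v_prev2 is not None else v_prev
    u_new, u_old, u_old2 = v_applied * scale, v_prev * scale, v_prev2 * scale
    phi1, phi2, kq, decay = _exp_phis(q * dt)
    curv = 0.5 * (u_new - 2.0 * u_old + u_old2)
    v_cap = decay * state.v_cap + dt * (u_old * (phi1 - phi2) + u_new * phi2 + curv * kq)
    i = (v_applied - v_cap) / model.r_series
    return i, SkinState(v_cap=v_cap, v_prev=v_applied, v_prev2=v_prev)


def _exp_phis(a: float) -> tuple[float, float, float, float]:
    """Exponential-integrator moments over one step of the ODE v' = -q v + u.

    Returns (φ1, φ2, K, e^-a) where, with x the fractional position in the
    step, φ1 = ∫e^(-a(1-x))dx, φ2 = ∫x·e^(-a(1-x))dx and K = ∫(x²-x)·
    e^(-a(1-x))dx — the weights of the constant, linear and curvature input
    terms.  Series expansions avoid cancellation for small a.
    """
    e = math.exp(-a)
    if a < 0.05:
        phi1 = 1.0 - a / 2.0 + a * a / 6.0 - a**3 / 24.0
        phi2 = 0.5 - a / 6.0 + a * a / 24.0 - a**3 / 120.0
        kq = -1.0 / 6.0 + a / 12.0 - a * a / 40.0
        return phi1, phi2, kq, e
    phi1 = (1.0 - e) / a
    psi2 = (1.0 - (1.0 + a) * e) / (a * a)
    psi3 = (2.0 - (a * a + 2.0 * a + 2.0) * e) / (a ** 3)
    return phi1, phi1 - psi2, psi3 - psi2, e


def polarization_step(state: PolarizationState, i_skin: float, dt: float) -> PolarizationState:
    """Advance the electrode charge accumulator one step.

    v_emf' = v_emf + dt·( i_skin/c_pol − v_emf/(r_leak·c_pol) ).  The EMF
    opposes the source in the circuit assembly (the acquisition chain
    subtracts it from the drive node).
    """
    if dt <= 0:
        raise StepSizeError("dt must be > 0")
    v = state.v_emf + dt * (i_skin / state.c_pol - state.v_emf / (state.r_leak * state.c_pol))
    return replace(state, v_emf=v)


def apply_sudomotor_drive(
    model: SkinRCModel,
    drive: SudomotorDrive,
    t_grid: np.ndarray,
    g_min: float = 0.2e-6,
    k: float = 2.0e-6,
    r_duct_bounds: tuple[float, float] = (50e3, 5e6),
) -> np.ndarray:
    """Map a sudomotor drive to a duct-resistance trajectory (Ω per sample).

    The duct conductance is affine in the drive intensity,
    ``1/r_duct(t) = g_min + k·d(t)``, and the resulting resistance is clamped
    to ``r_duct_bounds`` (a clamp is logged, not fatal).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    g_duct = g_min + k * drive.intensity(t_grid)
    with np.errstate(divide="ignore"):
        r_duct = 1.0 / g_duct
    lo, hi = r_duct_bounds
    clipped = (r_duct < lo) | (r_duct > hi) | ~np.isfinite(r_duct)
    if np.any(clipped):
        logger.warning(
            "duct resistance clamped to [%g, %g] Ω for %d/%d samples",
            lo, hi, int(clipped.sum()), r_duct.size,
        )
    return np.clip(np.nan_to_num(r_duct, posinf=hi), lo, hi)
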