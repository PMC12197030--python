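"""Virtual-study runner: seeded subject generation and the two study protocols.

A virtual subject is a skin circuit (baseline DC conductance drawn
log-uniformly from 1–20 µS), a sudomotor drive (slow downward tonic drift
plus sparse Poisson SCR events, ~3/min), and jittered electrode-polarisation
parameters.  Everything derives deterministically from (n, seed, config).

Stage 1 replays the short comparison protocol: 65 s of simultaneous DC and
positive half-wave AC at 20 Hz on the *same* sudomotor drive per subject
(the two-hands-at-once recording), then filtering, conductance estimation,
tonic extraction and paired statistics.

Stage 2 replays the stability protocol: 180 s of DC plus full-wave AC at
5/20/70/100 Hz per subject (200 Hz output rate for the 70/100 Hz carriers),
with per-condition SCL summaries, paired DC-vs-AC statistics at 20 Hz and
the median conductance/susceptance frequency-sweep table.

A separate drift study quantifies the polarisation-mitigation effect:
excess drift of each estimator relative to the known ground truth, compared
across DC, half-wave and full-wave excitation on a common population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .decomposition import compare_series, decompose_tonic_phasic
from .demodulation import (
    LockinConfig,
    admittance_from_recording,
    dc_conductance,
    moving_average,
    rectified_conductance,
)
from .excitation import ExcitationMode, ExcitationSpec
from .measurement_chain import FrontEndConfig, acquire
from .skin_model import PolarizationState, SkinRCModel, SudomotorDrive

logger = logging.getLogger(__name__)

__all__ = [
    "TonicTrajectory",
    "VirtualSubject",
    "StageReport",
    "ScenarioConfig",
    "make_population",
    "synthetic_conductance",
    "run_stage1",
    "run_stage2",
    "run_drift_study",
]


@dataclass(frozen=True)
class TonicTrajectory:
    """Dimensionless tonic drive: 1 + slope·t + amp·sin(2πt/period + phase)."""

    slope_per_s: float = -1e-3
    sine_amp: float = 0.03
    sine_period_s: float = 90.0
    sine_phase: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            1.0
            + self.slope_per_s * t
            + self.sine_amp * np.sin(2.0 * np.pi * t / self.sine_period_s + self.sine_phase)
        )


@dataclass
class VirtualSubject:
    """One synthetic participant, fully reproducible from its seed."""

    subject_id: int
    seed: int
    model: SkinRCModel
    drive: SudomotorDrive
    polarization: PolarizationState
    duct_map: dict[str, Any]          # g_min / k / bounds for apply_sudomotor_drive
    baseline_uS: float


@dataclass
class StageReport:
    """Per-subject rows plus paired statistics and population summaries."""

    table: pd.DataFrame
    paired: pd.DataFrame
    summary: dict[str, Any]
    sweep: pd.DataFrame | None = None


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the virtual study; defaults are the study conditions."""

    baseline_range_uS: tuple[float, float] = (1.0, 20.0)
    scr_rate_per_min: float = 3.0
    scr_amp_mean: float = 0.15
    scr_amp_sigma: float = 0.5          # lognormal sigma of SCR amplitudes
    tau_rise_s: float = 0.75
    tau_decay_s: float = 2.0
    tonic_slope_range: tuple[float, float] = (-1.4e-3, -0.3e-3)  # per second
    c_pol_F: float = 500e-6
    r_leak_ohm: float = 300e3
    jitter: float = 0.3                 # relative spread of polarisation params
    duration_s: float = 180.0
    stage1_duration_s: float = 65.0
    noise_rms_V: float = 1e-3
    settle_s: float = 1.0               # head trim before statistics


def _subject_from_seed(i: int, seed: int, cfg: ScenarioConfig, horizon_s: float) -> VirtualSubject:
    rng = np.random.default_rng([seed, i])
    lo, hi = cfg.baseline_range_uS
    g0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) * 1e-6  # S
    r_series = 10e3
    r_par = 1.0 / g0 - r_series
    # split the parallel block: 40% of its conductance through the ducts
    # (sudomotor-controlled), 60% through the fixed corneum path
    g_duct0 = 0.4 / r_par
    r_corneum = r_par / 0.6
    g_min = 0.2e-6
    k_duct = max(g_duct0 - g_min, 1e-8)
    model = SkinRCModel(
        r_series=r_series,
        r_corneum=r_corneum,
        r_duct=1.0 / g_duct0,
        c_epidermal=float(rng.uniform(20e-9, 40e-9)),
    )
    tonic = TonicTrajectory(
        slope_per_s=float(rng.uniform(*cfg.tonic_slope_range)),
        sine_amp=float(rng.uniform(0.01, 0.05)),
        sine_period_s=float(rng.uniform(60.0, 120.0)),
        sine_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
    )
    n_events = rng.poisson(cfg.scr_rate_per_min * horizon_s / 60.0)
    events = []
    for _ in range(n_events):
        onset = float(rng.uniform(0.0, horizon_s))
        amp = float(cfg.scr_amp_mean * rng.lognormal(0.0, cfg.scr_amp_sigma))
        tau_r = float(cfg.tau_rise_s * rng.uniform(0.8, 1.2))
        tau_d = float(cfg.tau_decay_s * rng.uniform(0.8, 1.2))
        if tau_r >= tau_d:
            tau_r = 0.5 * tau_d
        events.append((onset, amp, tau_r, tau_d))
    drive = SudomotorDrive(tonic_level=tonic, scr_events=sorted(events))
    jit = lambda: float(rng.lognormal(0.0, cfg.jitter))  # noqa: E731
    pol = PolarizationState(v_emf=0.0, c_pol=cfg.c_pol_F * jit(), r_leak=cfg.r_leak_ohm * jit())
    return VirtualSubject(
        subject_id=i,
        seed=int(rng.integers(0, 2**31 - 1)),
        model=model,
        drive=drive,
        polarization=pol,
        duct_map={"g_min": g_min, "k": k_duct},
        baseline_uS=g0 * 1e6,
    )


def make_population(n: int, seed: int, cfg: ScenarioConfig | None = None) -> list[VirtualSubject]:
    """Generate n seeded virtual subjects (deterministic given (n, seed, cfg))."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    cfg = cfg or ScenarioConfig()
    horizon = max(cfg.duration_s, cfg.stage1_duration_s)
    return [_subject_from_seed(i, seed, cfg, horizon) for i in range(n)]


def synthetic_conductance(
    sub: VirtualSubject,
    fs: float = 20.0,
    duration: float = 180.0,
    noise_uS: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noisy conductance with known tonic ground truth: (t, g_uS, tonic_uS).

    The observed series carries the subject's full sudomotor drive plus
    Gaussian measurement noise; the returned truth is the conductance the
    skin would show under the tonic drive alone (SCR events removed) — the
    target the tonic extractor should recover.  The default noise level
    matches the per-sample conductance noise the simulated front end
    produces (1 mV RMS at the ADC) for mid-range baselines.
    """
    from .skin_model import apply_sudomotor_drive

    t = np.arange(int(round(duration * fs))) / fs

    def g_of(drive: SudomotorDrive) -> np.ndarray:
        r_duct = apply_sudomotor_drive(sub.model, drive, t, **sub.duct_map)
        r_par = sub.model.r_corneum * r_duct / (sub.model.r_corneum + r_duct)
        return 1e6 / (sub.model.r_series + r_par)

    g_full = g_of(sub.drive)
    tonic = g_of(SudomotorDrive(tonic_level=sub.drive.tonic_level, scr_events=[]))
    rng = np.random.default_rng(sub.seed)
    return t, g_full + rng.normal(0.0, noise_uS, t.size), tonic


# --------------------------------------------------------------------------
# shared pipeline pieces
# --------------------------------------------------------------------------


def _front_end(cfg: ScenarioConfig, fs_acq: float) -> FrontEndConfig:
    return FrontEndConfig(fs_acq=fs_acq, noise_rms=cfg.noise_rms_V)


def _fs_out_for(freq: float) -> float:
    """Output rate: 20 Hz, elevated to 200 Hz for the 70/100 Hz carriers."""
    return 200.0 if freq >= 50.0 else 20.0


def _estimate_conductance(
    sub: VirtualSubject,
    spec: ExcitationSpec,
    fe: FrontEndConfig,
    duration: float,
    seed: int,
    polarization_on: bool = True,
):
    """acquire → mode-appropriate conductance estimator → (t, g_uS, truth, b_uS|None)."""
    rec, truth = acquire(
        spec, sub.model, sub.drive, fe, duration, seed=seed,
        polarization_on=polarization_on,
        polarization=PolarizationState(
            v_emf=0.0, c_pol=sub.polarization.c_pol, r_leak=sub.polarization.r_leak
        ),
        duct_map=sub.duct_map,
    )
    if spec.mode is ExcitationMode.DC:
        t, g = dc_conductance(rec, fe, spec)
        return t, g, truth, None
    if spec.mode is ExcitationMode.HALF_AC:
        t, g = rectified_conductance(rec, fe, spec)
        return t, g, truth, None
    adm = admittance_from_recording(rec, fe, spec, LockinConfig(settle=0.0))
    return adm.t, adm.g, truth, adm.b


def _align(t_a, a, t_b, b, settle: float):
    n = min(a.size, b.size)
    keep = t_a[:n] >= settle
    return a[:n][keep], b[:n][keep]


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------


def run_stage1(pop: list[VirtualSubject], cfg: ScenarioConfig | None = None) -> StageReport:
    """Short DC vs half-wave-AC comparison on a shared drive per subject."""
    if not pop:
        raise ValueError("population must be non-empty")
    cfg = cfg or ScenarioConfig()
    duration = cfg.stage1_duration_s
    fe = _front_end(cfg, 20.0)
    dc_spec = ExcitationSpec(mode=ExcitationMode.DC, amplitude=1.65)
    ac_spec = ExcitationSpec(mode=ExcitationMode.HALF_AC, amplitude=3.3, frequency=20.0, shape="sine")

    rows, paired_rows = [], []
    for sub in pop:
        t_dc, g_dc, _, _ = _estimate_conductance(sub, dc_spec, fe, duration, seed=sub.seed)
        t_ac, g_ac, _, _ = _estimate_conductance(sub, ac_spec, fe, duration, seed=sub.seed + 1)
        g_dc = moving_average(g_dc, fe.fs_acq)
        g_ac = moving_average(g_ac, fe.fs_acq)
        scl_dc = decompose_tonic_phasic(g_dc, fe.fs_acq).scl
        scl_ac = decompose_tonic_phasic(g_ac, fe.fs_acq).scl
        a, b = _align(t_dc, scl_dc, t_ac, scl_ac, cfg.settle_s)
        stats = compare_series(a, b)
        for mode, scl in (("dc", a), ("half_ac", b)):
            rows.append({
                "subject": sub.subject_id, "mode": mode, "frequency_hz": 20.0,
                "scl_mean_uS": float(np.mean(scl)), "scl_std_uS": float(np.std(scl)),
                "seed": sub.seed,
            })
        paired_rows.append({"subject": sub.subject_id, "pearson_r": stats.pearson_r,
                            "rmse_uS": stats.rmse})
    table = pd.DataFrame(rows)
    paired = pd.DataFrame(paired_rows)
    summary = _summarize(table, paired)
    return StageReport(table=table, paired=paired, summary=summary)


def run_stage2(pop: list[VirtualSubject], cfg: ScenarioConfig | None = None) -> StageReport:
    """Long DC + full-wave AC frequency-sweep protocol with SCL summaries."""
    if not pop:
        raise ValueError("population must be non-empty")
    cfg = cfg or ScenarioConfig()
    duration = cfg.duration_s
    freqs = (5.0, 20.0, 70.0, 100.0)

    rows, paired_rows, sweep_rows = [], [], []
    for sub in pop:
        fe20 = _front_end(cfg, 20.0)
        dc_spec = ExcitationSpec(mode=ExcitationMode.DC, amplitude=1.65)
        t_dc, g_dc, _, _ = _estimate_conductance(sub, dc_spec, fe20, duration, seed=sub.seed)
        g_dc_f = moving_average(g_dc, fe20.fs_acq)
        scl_dc = decompose_tonic_phasic(g_dc_f, fe20.fs_acq).scl
        rows.append({
            "subject": sub.subject_id, "mode": "dc", "frequency_hz": 0.0,
            "scl_mean_uS": float(np.mean(scl_dc)), "scl_std_uS": float(np.std(scl_dc)),
            "seed": sub.seed,
        })
        scl_ac20 = None
        t_ac20 = None
        for j, f in enumerate(freqs):
            fs_out = _fs_out_for(f)
            fe = _front_end(cfg, fs_out)
            spec = ExcitationSpec(mode=ExcitationMode.FULL_AC, frequency=f)
            t_ac, g_ac, _, b_ac = _estimate_conductance(sub, spec, fe, duration, seed=sub.seed + 10 + j)
            g_f = moving_average(g_ac, fs_out)
            b_f = moving_average(b_ac, fs_out)
            scl = decompose_tonic_phasic(g_f, fs_out).scl
            rows.append({
                "subject": sub.subject_id, "mode": "full_ac", "frequency_hz": f,
                "scl_mean_uS": float(np.mean(scl)), "scl_std_uS": float(np.std(scl)),
                "seed": sub.seed + 10 + j,
            })
            sweep_rows.append({
                "subject": sub.subject_id, "frequency_hz": f,
                "g_median_uS": float(np.median(g_f)), "b_median_uS": float(np.median(b_f)),
            })
            if f == 20.0:
                scl_ac20, t_ac20 = scl, t_ac
        a, b = _align(t_dc, scl_dc, t_ac20, scl_ac20, cfg.settle_s)
        stats = compare_series(a, b)
        paired_rows.append({"subject": sub.subject_id, "pearson_r": stats.pearson_r,
                            "rmse_uS": stats.rmse})

    table = pd.DataFrame(rows)
    paired = pd.DataFrame(paired_rows)
    per_subj = pd.DataFrame(sweep_rows)
    sweep = (
        per_subj.groupby("frequency_hz")[["g_median_uS", "b_median_uS"]]
        .median()
        .reset_index()
    )
    summary = _summarize(table, paired)
    summary["scl_std_mean_dc_uS"] = float(
        table.query("mode == 'dc'")["scl_std_uS"].mean()
    )
    summary["scl_std_mean_ac_uS"] = float(
        table.query("mode == 'full_ac'")["scl_std_uS"].mean()
    )
    return StageReport(table=table, paired=paired, summary=summary, sweep=sweep)


def _summarize(table: pd.DataFrame, paired: pd.DataFrame) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for mode, grp in table.groupby("mode"):
        q = grp["scl_mean_uS"].quantile([0.25, 0.5, 0.75])
        out[f"scl_mean_{mode}_uS"] = {
            "median": float(q[0.5]), "q1": float(q[0.25]), "q3": float(q[0.75]),
        }
    if len(paired):
        out["pearson_r_median"] = float(paired["pearson_r"].median())
        out["rmse_median_uS"] = float(paired["rmse_uS"].median())
    return out


# --------------------------------------------------------------------------
# drift study
# --------------------------------------------------------------------------


def _excess_drift(t: np.ndarray, est: np.ndarray, truth: np.ndarray, window_s: float = 15.0) -> float:
    """Early-minus-late decline of the estimate beyond the true decline (µS)."""
    n = min(est.size, truth.size)
    t, est, truth = t[:n], est[:n], truth[:n]
    head = t <= t[0] + window_s
    tail = t >= t[-1] - window_s
    err = est - truth
    return float(np.mean(err[head]) - np.mean(err[tail]))


def run_drift_study(
    pop: list[VirtualSubject],
    cfg: ScenarioConfig | None = None,
    duration: float | None = None,
) -> pd.DataFrame:
    """Per-subject excess drift of DC, half-wave and full-wave estimates.

    Excess drift is measured against the ground-truth conductance at the
    estimator's own frequency, so tonic physiology cancels and only the
    polarisation artefact remains.  Returns one row per subject with the
    three drifts (µS), plus attrs ``sign_test_p`` (two-sided sign test of
    half-wave vs DC drift) and ``frac_ac_below_5pct``.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    cfg = cfg or ScenarioConfig()
    duration = duration or cfg.duration_s
    fe = _front_end(cfg, 20.0)
    specs = {
        "dc": ExcitationSpec(mode=ExcitationMode.DC, amplitude=1.65),
        "half_ac": ExcitationSpec(mode=ExcitationMode.HALF_AC, amplitude=3.3,
                                  frequency=20.0, shape="sine"),
        "full_ac": ExcitationSpec(mode=ExcitationMode.FULL_AC, frequency=20.0),
    }
    rows = []
    for sub in pop:
        row: dict[str, Any] = {"subject": sub.subject_id}
        for name, spec in specs.items():
            t, g, truth, _ = _estimate_conductance(sub, spec, fe, duration, seed=sub.seed)
            ref = truth.g_dc_uS if spec.mode is not ExcitationMode.FULL_AC else truth.g_f_uS
            ref = ref[np.searchsorted(truth.t, t).clip(0, truth.t.size - 1)]
            row[f"drift_{name}_uS"] = _excess_drift(t, g, ref)
        rows.append(row)
    df = pd.DataFrame(rows)
    d = df["drift_half_ac_uS"] - df["drift_dc_uS"]
    n_pos = int((d > 0).sum())
    n_eff = int((d != 0).sum())
    df.attrs["sign_test_p"] = float(binomtest(n_pos, n_eff, 0.5).pvalue) if n_eff else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(df["drift_full_ac_uS"]) / np.abs(df["drift_dc_uS"])
    df.attrs["frac_ac_below_5pct"] = float((ratio < 0.05).mean())
    return df
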