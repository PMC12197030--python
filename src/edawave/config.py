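"""YAML run configuration: nested sections, schema-validated, every default overridable.

The configuration mirrors the package's dataclasses section by section:

* ``excitation`` → :class:`~edawave.excitation.ExcitationSpec` (amplitudes in
  volts, frequency in Hz, duty as a fraction)
* ``front_end`` → :class:`~edawave.measurement_chain.FrontEndConfig` (r0 in Ω,
  rates in Hz, noise in V RMS)
* ``skin_model`` → :class:`~edawave.skin_model.SkinRCModel` (Ω and F)
* ``field_solver`` → grid geometry in metres, drive in volts, plus the layer
  stack (per layer: thickness in m, sigma in S/m, eps_r dimensionless; the
  dielectric tables may be keyed by frequency in Hz)
* ``decomposition`` → smoother parameters (lam, asym, iters)
* ``scenario`` → :class:`~edawave.scenarios.ScenarioConfig` (µS, seconds)

Unknown keys anywhere are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .excitation import ExcitationSpec
from .field_solver import LayerSpec, default_layers
from .measurement_chain import FrontEndConfig
from .scenarios import ScenarioConfig
from .skin_model import SkinRCModel

__all__ = ["RunConfig", "ConfigError", "load_config", "DEFAULT_CONFIG_YAML"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_FIELD_SOLVER_KEYS = {
    "width", "dx", "dz", "f", "electrode_width", "electrode_gap",
    "plate_electrodes", "v_drive", "layers",
}
_DECOMPOSITION_KEYS = {"lam", "asym", "iters"}


@dataclasses.dataclass
class RunConfig:
    excitation: ExcitationSpec
    front_end: FrontEndConfig
    skin_model: SkinRCModel
    scenario: ScenarioConfig
    field_solver: dict[str, Any]
    decomposition: dict[str, Any]
    raw_text: str = ""


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    # tuples arrive from YAML as lists
    kwargs = {
        k: tuple(v) if isinstance(v, list) and isinstance(
            next((f for f in dataclasses.fields(cls) if f.name == k)).default, tuple
        ) else v
        for k, v in section.items()
    }
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def _build_field_solver(section: dict) -> dict[str, Any]:
    unknown = set(section) - _FIELD_SOLVER_KEYS
    if unknown:
        raise ConfigError(f"unknown keys in section 'field_solver': {sorted(unknown)}")
    out = dict(section)
    if "layers" in out:
        layers = []
        for entry in out["layers"]:
            extra = set(entry) - {"name", "thickness", "sigma", "eps_r"}
            if extra:
                raise ConfigError(f"unknown keys in layer {entry.get('name')!r}: {sorted(extra)}")
            layers.append(LayerSpec(**entry))
        out["layers"] = layers
    else:
        out["layers"] = default_layers()
    return out


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; missing sections fall back to defaults."""
    if path is None:
        text = DEFAULT_CONFIG_YAML
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    known = {"excitation", "front_end", "skin_model", "field_solver", "decomposition", "scenario"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    exc_section = dict(data.get("excitation", {}))
    return RunConfig(
        excitation=_build(ExcitationSpec, exc_section, "excitation"),
        front_end=_build(FrontEndConfig, dict(data.get("front_end", {})), "front_end"),
        skin_model=_build(SkinRCModel, dict(data.get("skin_model", {})), "skin_model"),
        scenario=_build(ScenarioConfig, dict(data.get("scenario", {})), "scenario"),
        field_solver=_build_field_solver(dict(data.get("field_solver", {}))),
        decomposition={
            k: v for k, v in dict(data.get("decomposition", {})).items()
            if k in _DECOMPOSITION_KEYS or _raise_unknown(k)
        },
        raw_text=text,
    )


def _raise_unknown(key: str):
    raise ConfigError(f"unknown keys in section 'decomposition': ['{key}']")


DEFAULT_CONFIG_YAML = """\
# edawave default run configuration (all values overridable)
excitation:
  mode: full_ac          # dc | half_ac | full_ac
  amplitude: 1.65        # V (dc level or half-wave peak)
  frequency: 20.0        # Hz
  shape: pwm_square      # pwm_square | sine
  duty: 0.5
  v_supply: 3.3          # V
front_end:
  r0: 100000.0           # ohm, current limiter
  adc_bits: 16
  adc_vref: 3.3          # V
  fs_acq: 20.0           # Hz output rate (use 200 for 70/100 Hz carriers)
  noise_rms: 0.001       # V
skin_model:
  r_series: 10000.0      # ohm
  r_corneum: 250000.0    # ohm
  r_duct: 1000000.0      # ohm
  c_epidermal: 3.0e-08   # F
field_solver:
  width: 0.064           # m
  dx: 0.0005             # m
  dz: 1.0e-05            # m
  f: 20.0                # Hz
  electrode_width: 0.008 # m
  electrode_gap: 0.012   # m
  v_drive: 1.65          # V
decomposition:
  asym: 0.01
  iters: 10
scenario:
  duration_s: 180.0
  stage1_duration_s: 65.0
  scr_rate_per_min: 3.0
"""
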