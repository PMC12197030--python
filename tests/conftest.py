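import numpy as np
import pytest

from edawave import ExcitationMode, ExcitationSpec, FrontEndConfig, SkinRCModel


@pytest.fixture
def default_model() -> SkinRCModel:
    """Default skin circuit: 10 kΩ + (250 kΩ ∥ 1 MΩ ∥ 30 nF)."""
    return SkinRCModel()


@pytest.fixture
def resistive_10k() -> SkinRCModel:
    """Nearly pure 10 kΩ resistive load (negligible capacitance)."""
    return SkinRCModel(r_series=9e3, r_corneum=2e3, r_duct=2e3, c_epidermal=1e-12)


@pytest.fixture
def resistive_5M() -> SkinRCModel:
    """Nearly pure 5 MΩ resistive load — the 0.2 µS edge of the device range."""
    return SkinRCModel(r_series=10e3, r_corneum=9.98e6, r_duct=9.98e6, c_epidermal=1e-12)


@pytest.fixture
def fe_noiseless() -> FrontEndConfig:
    return FrontEndConfig(noise_rms=0.0)


@pytest.fixture
def full_ac_20() -> ExcitationSpec:
    return ExcitationSpec(mode=ExcitationMode.FULL_AC, frequency=20.0)
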