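import pytest

from trialcea.data_model import EconConfig
from trialcea.synthetic_trial import (
    apply_dropout,
    generate_trial,
    planted_effect_config,
)


@pytest.fixture(scope="session")
def econ_cfg() -> EconConfig:
    return EconConfig()


@pytest.fixture(scope="session")
def small_trial():
    """Complete 250/250 trial with the planted 2-year ISI effect."""
    cfg = planted_effect_config(seed=101, n_per_arm={"dCBT-I": 250, "PE": 250})
    return cfg, generate_trial(cfg)


@pytest.fixture(scope="session")
def small_trial_dropout(small_trial):
    """Same trial after calibrated MAR dropout (shadow retained)."""
    cfg, ds = small_trial
    return cfg, apply_dropout(ds, cfg)
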