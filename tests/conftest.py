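import numpy as np
import pytest

from attrecho import TrialConfig, apply_missingness, simulate_trial


def null_profiles():
    prof = (-1.6, -3.3, -4.9, -6.5)
    return {"placebo": prof, "vutrisiran": prof}


def make_config(**overrides) -> TrialConfig:
    """A small, fast default config for tests; overrides applied on top."""
    defaults = dict(
        n_per_arm=60,
        seed=0,
        death_hazard=0.0,
        discontinuation_hazard=0.0,
        missingness_mode="none",
    )
    defaults.update(overrides)
    return TrialConfig(**defaults)


@pytest.fixture
def small_complete_trial():
    cfg = make_config(seed=11)
    return simulate_trial(cfg), cfg


@pytest.fixture
def study_like_trial():
    """Full-size trial with deaths, discontinuations and MAR missingness."""
    cfg = TrialConfig(seed=3)
    ds = apply_missingness(simulate_trial(cfg), cfg)
    return ds, cfg
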