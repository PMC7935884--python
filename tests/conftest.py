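import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover
    pass

from wormtrauma.synthetic_data import FlowSimConfig, generate_flow_events


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def separated_flow_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event table whose contaminant classes sit many SDs from the adults.

    Tight lognormal spreads (sigma = 0.02) put every class center >= 4 SD
    from the nearest default gate boundary, the regime in which gating is
    expected to be near-perfect. Returns (events, per-event truth).
    """
    config = FlowSimConfig(
        n_worms=20000,
        adult_tof_sigma=0.02,
        adult_ext_sigma=0.02,
        contaminant_fractions={"larva": 0.10, "bacteria": 0.10, "doublet": 0.05, "curl": 0.05},
        seed=42,
    )
    events, truth = generate_flow_events(config)
    return events, truth.event_truth
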