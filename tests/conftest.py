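import numpy as np
import pandas as pd
import pytest

from stoprace import presets
from stoprace.simulate import TaskDesign, simulate_participant


@pytest.fixture(scope="session")
def rifg_params():
    return presets.parameter_set("rifg_lesion")


@pytest.fixture(scope="session")
def comparison_params():
    return presets.parameter_set("rifg_comparison")


@pytest.fixture(scope="session")
def simulated_session(rifg_params):
    """One full 480-trial staircase session from the high-P(TF) preset."""
    return simulate_participant(rifg_params, TaskDesign(), seed=1234)


@pytest.fixture()
def tiny_trials():
    """Hand-written 10-trial table: 2 incorrect, 1 anticipation, 1 censored."""
    return pd.DataFrame({
        "trial": np.arange(10),
        "trial_type": ["go"] * 7 + ["stop"] * 3,
        "side": ["left", "right"] * 5,
        "ssd_ms": [200.0] * 7 + [250.0, 300.0, 350.0],
        "rt_ms": [300.0, 400.0, 150.0, 500.0, 1100.0, 620.0, 480.0,
                  np.nan, 430.0, np.nan],
        "correct": [True, False, True, True, True, False, True,
                    True, True, True],
        "outcome": ["go_response"] * 7
        + ["successful_stop", "signal_respond", "successful_stop"],
    })
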