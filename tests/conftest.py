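import warnings

import numpy as np
import pandas as pd
import pytest

from inkstone.pipeline import analyze_experiment
from inkstone.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_experiment():
    """A 6-participant × 40-item synthetic experiment shared across tests."""
    cfg = SimulationConfig(seed=42, n_participants=6, n_items=40)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_experiment):
    exp = small_experiment
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_experiment(
            exp.samples, exp.events, exp.decomposition, raters=exp.raters
        )


def make_trial(pressures, xs=None, ys=None, t0=0, step=5, trial_id=1):
    """Build a one-trial sample stream from explicit per-sample values."""
    n = len(pressures)
    xs = list(xs) if xs is not None else list(np.linspace(0.0, 1.0, n))
    ys = list(ys) if ys is not None else [0.0] * n
    return pd.DataFrame(
        {
            "t_ms": t0 + step * np.arange(n),
            "x": xs,
            "y": ys,
            "pressure": pressures,
            "trial_id": trial_id,
        }
    )


def make_event(trial_id=1, participant_id=1, item_number=1, target_char="稻",
               audio_onset=0, audio_offset=1000, space_press=99_000, self_report=0):
    return pd.DataFrame(
        [
            {
                "trial_id": trial_id,
                "participant_id": participant_id,
                "item_number": item_number,
                "target_char": target_char,
                "audio_onset_ms": audio_onset,
                "audio_offset_ms": audio_offset,
                "space_press_ms": space_press,
                "self_report": self_report,
            }
        ]
    )
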