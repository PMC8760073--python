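import numpy as np
import pandas as pd
import pytest

from wmcode.session import SessionRecording
from wmcode.synth import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One drug-on synthetic session with default study conditions."""
    return generate_session(GeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def small_session():
    """A light session for IO / pipeline tests."""
    cfg = GeneratorConfig(n_ns=3, n_bs=6, trials_per_location_per_period=6)
    return generate_session(cfg, seed=5)


def make_manual_session(trials, spikes=None, units=None):
    """Hand-built minimal session for unit tests of single operations."""
    trials = pd.DataFrame(trials)
    if units is None:
        uids = (sorted({s[0] for s in spikes}) if spikes else [0])
        units = pd.DataFrame({
            "unit_id": uids,
            "is_single": True,
            "array_id": 0,
            "sampling_interval_us": 1e6 / 30000.0,
        })
    spikes = pd.DataFrame(spikes or [], columns=["unit_id", "time_ms"])
    empty_fix = pd.DataFrame(columns=["trial_id", "x_px", "y_px",
                                      "start_ms", "end_ms", "epoch"])
    empty_sac = pd.DataFrame(columns=["trial_id", "start_x_px", "start_y_px",
                                      "end_x_px", "end_y_px", "start_ms",
                                      "end_ms"])
    empty_traj = pd.DataFrame(columns=["trial_id", "time_ms", "x", "y"])
    empty_wf = pd.DataFrame(columns=["unit_id", "sample_idx", "voltage"])
    return SessionRecording(
        session_id="manual", condition="ketamine_wm",
        injection_time=1e9,
        trials=trials, units=units, waveforms=empty_wf, spikes=spikes,
        fixations=empty_fix, saccades=empty_sac, trajectories=empty_traj,
    )


def trial_row(trial_id, location, cue_on, outcome="correct", period="pre",
              response_time=4.0):
    from wmcode.session import target_column, target_xy
    x, y = target_xy(location)
    return {
        "trial_id": trial_id, "target_location": location,
        "target_x": x, "target_y": y,
        "target_column": target_column(location),
        "target_side": target_column(location),
        "outcome": outcome, "cue_on": cue_on,
        "delay_on": cue_on + 3000.0, "response_on": cue_on + 5000.0,
        "trial_end": cue_on + 5000.0 + response_time * 1000.0,
        "period": period, "response_time": response_time,
    }
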