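import numpy as np
import pandas as pd
import pytest

from fiberbehav.epochs import EpochedTensor


def make_epochs(
    values,
    fs_hz=16.0,
    window_s=(-5.0, 15.0),
    delays=None,
    outcomes=None,
    zscored=True,
    baseline_window_s=(-5.0, -1.0),
):
    """Build an EpochedTensor directly from a trials x frames array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_trials, n_frames = values.shape
    i_lo = int(round(window_s[0] * fs_hz))
    frame_times = np.arange(i_lo, i_lo + n_frames) / fs_hz
    meta = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "outcome": outcomes if outcomes is not None else ["correct"] * n_trials,
            "delay_s": delays if delays is not None else [12.5] * n_trials,
            "align_time_s": np.zeros(n_trials),
        }
    )
    return EpochedTensor(
        values=values,
        frame_times_s=frame_times,
        fs_hz=fs_hz,
        align_event="trial_start",
        trial_meta=meta,
        baseline_window_s=baseline_window_s,
        zscored=zscored,
    )


def make_events(counts, magazine_latency_s=2.0, delay_s=5.0, iti_s=12.0):
    """Event log with the given outcome counts, regular timing."""
    rows = []
    t = 10.0
    i = 0
    for outcome, n in counts.items():
        for _ in range(n):
            cue = t + delay_s
            resp = np.nan
            mag = np.nan
            reward = np.nan
            if outcome in ("correct", "incorrect"):
                resp = cue + 0.5
                if outcome == "correct":
                    mag = magazine_latency_s
                    reward = resp + mag
            elif outcome == "premature":
                resp = t + delay_s / 2.0
            rows.append(
                {
                    "session_id": "fix",
                    "trial_index": i,
                    "trial_start_s": t,
                    "delay_s": delay_s,
                    "cue_onset_s": cue,
                    "cue_duration_s": 1.0,
                    "response_time_s": resp,
                    "outcome": outcome,
                    "reward_collect_s": reward,
                    "magazine_latency_s": mag,
                }
            )
            t = cue + 3.0 + iti_s
            i += 1
    columns = [
        "session_id", "trial_index", "trial_start_s", "delay_s",
        "cue_onset_s", "cue_duration_s", "response_time_s", "outcome",
        "reward_collect_s", "magazine_latency_s",
    ]
    return pd.DataFrame(rows, columns=columns)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
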