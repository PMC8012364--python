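"""Event-aligned epoching and per-trial baseline z-scoring.

Processed dF/F traces are cut into trials x frames matrices aligned on
trial start, cue onset, or the response, and each trial is z-scored to its
own pre-trial baseline (-5 to -1 s before trial start by default). After
z-scoring, the +2 SD activity threshold used by the delay metrics is
exactly z = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import ProcessedTrace

log = logging.getLogger(__name__)

ALIGN_EVENTS = {
    "trial_start": "trial_start_s",
    "cue_onset": "cue_onset_s",
    "response": "response_time_s",
}


@dataclass
class EpochedTensor:
    """Trials x frames matrix aligned to an event.

    ``values`` is in dF/F units before :func:`zscore_epochs` and z units
    after; ``frame_times_s`` is relative to the alignment event with uniform
    1/fs spacing. ``trial_meta`` carries one row per retained trial
    (outcome, delay, baseline stats once z-scored).
    """

    values: np.ndarray
    frame_times_s: np.ndarray
    fs_hz: float
    align_event: str
    trial_meta: pd.DataFrame
    baseline_window_s: tuple = (-5.0, -1.0)
    zscored: bool = False
    n_dropped: int = 0

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.values.shape[1] != self.frame_times_s.size:
            raise ValueError("frame_times length mismatch")
        if self.values.shape[0] != len(self.trial_meta):
            raise ValueError("trial_meta length mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def baseline_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window_s
        return (self.frame_times_s >= lo) & (self.frame_times_s < hi)

    def window_mask(self, start_s: float, end_s: float) -> np.ndarray:
        return (self.frame_times_s >= start_s) & (self.frame_times_s < end_s)


def epoch_trials(
    trace: ProcessedTrace,
    events: pd.DataFrame,
    align_event: str = "trial_start",
    window_s: tuple = (-5.0, 15.0),
    baseline_window_s: tuple = (-5.0, -1.0),
) -> EpochedTensor:
    """Cut one row per trial whose full window lies inside the recording.

    The alignment frame is the first recorded frame at or after the event
    time (no interpolation); windows are half-open in frame index. Trials
    truncated by the recording edges (or without the alignment event, e.g.
    omissions aligned on response) are dropped and logged.
    """
    if align_event not in ALIGN_EVENTS:
        raise ValueError(f"unknown align_event {align_event!r}")
    col = ALIGN_EVENTS[align_event]
    fs = trace.fs_hz
    i_lo = int(round(window_s[0] * fs))
    i_hi = int(round(window_s[1] * fs))
    n_frames = i_hi - i_lo
    if n_frames <= 0:
        raise ValueError("empty epoch window")
    frame_times = np.arange(i_lo, i_hi) / fs
    rows, meta_rows = [], []
    n_dropped = 0
    for _, ev in events.iterrows():
        t_align = ev[col]
        if not np.isfinite(t_align):
            n_dropped += 1
            continue
        # first frame with time >= alignment event
        i_align = int(np.ceil((t_align - trace.t0_s) * fs - 1e-9))
        a, b = i_align + i_lo, i_align + i_hi
        if a < 0 or b > trace.n_frames:
            n_dropped += 1
            continue
        rows.append(trace.dff[a:b])
        meta_rows.append(
            {
                "trial_index": ev["trial_index"],
                "outcome": ev["outcome"],
                "delay_s": ev["delay_s"],
                "align_time_s": t_align,
            }
        )
    if not rows:
        raise ValueError("no trials fit inside the recording")
    if n_dropped:
        log.info("epoch_trials: dropped %d of %d trials at recording edges",
                 n_dropped, len(events))
    return EpochedTensor(
        values=np.vstack(rows),
        frame_times_s=frame_times,
        fs_hz=fs,
        align_event=align_event,
        trial_meta=pd.DataFrame(meta_rows).reset_index(drop=True),
        baseline_window_s=baseline_window_s,
        n_dropped=n_dropped,
    )


def zscore_epochs(epochs: EpochedTensor, ddof: int = 1) -> EpochedTensor:
    """Z-score every trial to its own baseline window.

    ``z = (x - mu_baseline) / sd_baseline`` per trial; baseline mean and SD
    are stored in ``trial_meta``. Trials with zero baseline SD are excluded
    (flagged and logged), never silently zeroed.
    """
    mask = epochs.baseline_mask()
    if mask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 frames")
    mu = epochs.values[:, mask].mean(axis=1)
    sd = epochs.values[:, mask].std(axis=1, ddof=ddof)
    ok = sd > 0
    if not ok.all():
        log.warning("zscore_epochs: excluding %d trials with zero baseline SD",
                    int((~ok).sum()))
    values = (epochs.values[ok] - mu[ok, None]) / sd[ok, None]
    meta = epochs.trial_meta.loc[ok].reset_index(drop=True).copy()
    meta["baseline_mean"] = mu[ok]
    meta["baseline_sd"] = sd[ok]
    return replace(
        epochs,
        values=values,
        trial_meta=meta,
        zscored=True,
        n_dropped=epochs.n_dropped + int((~ok).sum()),
    )


def select_trials(
    epochs: EpochedTensor,
    outcome: str | list | None = None,
    delay_s: float | list | None = None,
) -> EpochedTensor:
    """Row subset by outcome and/or delay, metadata preserved."""
    keep = np.ones(epochs.n_trials, dtype=bool)
    if outcome is not None:
        outcomes = [outcome] if isinstance(outcome, str) else list(outcome)
        keep &= epochs.trial_meta["outcome"].isin(outcomes).to_numpy()
    if delay_s is not None:
        delays = np.atleast_1d(np.asarray(delay_s, dtype=float))
        trial_delay = epochs.trial_meta["delay_s"].to_numpy(dtype=float)
        keep &= np.isclose(trial_delay[:, None], delays[None, :]).any(axis=1)
    if not keep.any():
        log.warning("select_trials: empty selection")
    return replace(
        epochs,
        values=epochs.values[keep].reshape(int(keep.sum()),
                                           epochs.values.shape[1]),
        trial_meta=epochs.trial_meta.loc[keep].reset_index(drop=True),
    )


def subject_mean_traces(
    epoch_sets: list[EpochedTensor], outcome: str | None = None
) -> np.ndarray:
    """Per-subject mean traces (subjects x frames) on a shared frame grid."""
    rows = []
    for ep in epoch_sets:
        sel = select_trials(ep, outcome=outcome) if outcome else ep
        if sel.n_trials == 0:
            raise ValueError("subject has no trials for this selection")
        rows.append(sel.values.mean(axis=0))
    return np.vstack(rows)
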