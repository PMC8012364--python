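"""Delay-period summary metrics on z-scored, trial-start-aligned epochs.

Per trial: area under the z curve between trial start and cue, the rise
fraction (z at 1 s as a fraction of the delay-window peak), the first
crossing and total time above the +2 SD baseline threshold, the peak z,
and the time to peak defined as the first local maximum above 20 % of the
overall peak. Undefined metrics (no crossing, non-positive peak) propagate
as NaN and are excluded from per-animal means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochedTensor


def _check_aligned(epochs: EpochedTensor):
    if epochs.align_event != "trial_start":
        raise ValueError("delay metrics require trial_start-aligned epochs")
    if not epochs.zscored:
        raise ValueError("delay metrics require z-scored epochs")


def _delay_ends(epochs: EpochedTensor, fixed_window_s: float | None):
    if fixed_window_s is not None:
        return np.full(epochs.n_trials, float(fixed_window_s))
    return epochs.trial_meta["delay_s"].to_numpy(dtype=float)


def delay_auc(
    epochs: EpochedTensor, fixed_window_s: float | None = None
) -> np.ndarray:
    """Trapezoidal integral of z over [0, delay) per trial (z*seconds).

    ``fixed_window_s`` integrates a common [0, fixed_window_s) window
    instead (e.g. 12.5 s, the longest delay) for cross-delay comparisons.
    """
    _check_aligned(epochs)
    t = epochs.frame_times_s
    ends = _delay_ends(epochs, fixed_window_s)
    out = np.full(epochs.n_trials, np.nan)
    for i, end in enumerate(ends):
        m = (t >= 0) & (t < end)
        if m.sum() < 2:
            continue
        out[i] = np.trapezoid(epochs.values[i, m], t[m])
    return out


def rise_fraction_at(
    epochs: EpochedTensor, t_s: float = 1.0,
    fixed_window_s: float | None = None,
) -> np.ndarray:
    """z at the frame nearest ``t_s`` divided by the delay-window peak z.

    Trials whose peak is not positive get NaN (the fraction is undefined).
    """
    _check_aligned(epochs)
    t = epochs.frame_times_s
    j = int(np.argmin(np.abs(t - t_s)))
    ends = _delay_ends(epochs, fixed_window_s)
    out = np.full(epochs.n_trials, np.nan)
    for i, end in enumerate(ends):
        m = (t >= 0) & (t < end)
        if not m.any():
            continue
        peak = epochs.values[i, m].max()
        if peak <= 0:
            continue
        out[i] = epochs.values[i, j] / peak
    return out


def threshold_events(
    epochs: EpochedTensor, k: float = 2.0,
    fixed_window_s: float | None = None,
) -> pd.DataFrame:
    """First crossing and total active time above z > k in the delay window.

    Returns per-trial ``first_crossing_s`` (NaN when the trial never
    crosses), ``active_time_s`` = suprathreshold frame count / fs, and
    ``n_active_frames``. Resolution is one frame; no interpolation.
    """
    _check_aligned(epochs)
    if k <= 0:
        raise ValueError("threshold k must be > 0")
    t = epochs.frame_times_s
    ends = _delay_ends(epochs, fixed_window_s)
    rows = []
    for i, end in enumerate(ends):
        m = (t >= 0) & (t < end)
        above = (epochs.values[i] > k) & m
        n_active = int(above.sum())
        first = t[above][0] if n_active else np.nan
        rows.append(
            {
                "first_crossing_s": first,
                "active_time_s": n_active / epochs.fs_hz,
                "n_active_frames": n_active,
            }
        )
    return pd.DataFrame(rows)


def _first_qualified_local_max(x: np.ndarray, threshold: float) -> int | None:
    """Index of the first local maximum with value > threshold.

    A local maximum is strictly greater than both neighbors; plateaus
    resolve to their earliest frame; the array ends count as -inf.
    """
    n = x.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1  # plateau
        left = x[i - 1] if i > 0 else -np.inf
        right = x[j + 1] if j + 1 < n else -np.inf
        if x[i] > left and x[i] > right and x[i] > threshold:
            return i
        i = j + 1
    return None


def peak_metrics(
    epochs: EpochedTensor, rel_threshold: float = 0.20,
    fixed_window_s: float | None = None,
) -> pd.DataFrame:
    """Peak z and time to peak in the delay window.

    ``peak_z`` is the delay-window maximum; ``time_to_peak_s`` is the time
    of the first local maximum exceeding ``rel_threshold`` x peak_z
    (default 20 %).
    """
    _check_aligned(epochs)
    t = epochs.frame_times_s
    ends = _delay_ends(epochs, fixed_window_s)
    rows = []
    for i, end in enumerate(ends):
        m = (t >= 0) & (t < end)
        if m.sum() < 3:
            raise ValueError("delay window shorter than 3 frames")
        seg = epochs.values[i, m]
        tseg = t[m]
        peak = seg.max()
        idx = _first_qualified_local_max(seg, rel_threshold * peak)
        if idx is None:
            idx = int(np.argmax(seg))
        rows.append({"peak_z": peak, "time_to_peak_s": tseg[idx]})
    return pd.DataFrame(rows)


def compute_delay_metrics(
    epochs: EpochedTensor,
    k: float = 2.0,
    rise_t_s: float = 1.0,
    fixed_window_s: float | None = None,
) -> pd.DataFrame:
    """All per-trial delay metrics as one table (plus trial metadata)."""
    thr = threshold_events(epochs, k=k, fixed_window_s=fixed_window_s)
    pk = peak_metrics(epochs, fixed_window_s=fixed_window_s)
    out = epochs.trial_meta[["trial_index", "outcome", "delay_s"]].copy()
    out["auc_zs"] = delay_auc(epochs, fixed_window_s=fixed_window_s)
    out["rise_fraction_1s"] = rise_fraction_at(
        epochs, t_s=rise_t_s, fixed_window_s=fixed_window_s
    )
    out["first_crossing_s"] = thr["first_crossing_s"].to_numpy()
    out["active_time_s"] = thr["active_time_s"].to_numpy()
    out["peak_z"] = pk["peak_z"].to_numpy()
    out["time_to_peak_s"] = pk["time_to_peak_s"].to_numpy()
    return out


def animal_means(metrics: pd.DataFrame, by: list | None = None) -> pd.DataFrame:
    """Per-animal (or per-group) means, NaN metrics excluded per column."""
    by = by or ["outcome"]
    numeric = metrics.select_dtypes(include=[np.number]).columns.difference(
        ["trial_index"]
    )
    return metrics.groupby(by, observed=True)[list(numeric)].mean().reset_index()
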