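"""5-CSRTT session metrics, block splits, and quantification helpers.

Accuracy = 100 * #correct / (#correct + #incorrect); premature and omission
rates are percentages of all started trials. Trials with a magazine latency
above 10 s are excluded from all tallies before any percentage is computed
(a latency-only exclusion mode is available). Sessions can be split into
five 30-min blocks by trial start time, and the temporal distribution of
premature response latencies is exported as a histogram + empirical CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MAGAZINE_EXCLUSION_S = 10.0


@dataclass
class BehaviorSummary:
    """Session-level behavior metrics. NaN marks undefined quantities."""

    n_started: int
    n_correct: int
    n_incorrect: int
    n_omission: int
    n_premature: int
    n_excluded: int
    accuracy_percent: float
    premature_percent: float
    omission_percent: float
    response_latency_s: float
    magazine_latency_s: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _apply_magazine_exclusion(events, threshold_s, mode):
    lat = events["magazine_latency_s"].to_numpy(dtype=float)
    excl = np.isfinite(lat) & (lat > threshold_s)
    if mode == "trial":
        kept = events.loc[~excl]
    elif mode == "latency_only":
        kept = events.copy()
        kept.loc[excl, "magazine_latency_s"] = np.nan
        excl = np.zeros(len(events), dtype=bool)
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    if excl.any():
        log.info("excluded %d trials with magazine latency > %.1f s",
                 int(excl.sum()), threshold_s)
    return kept, int(excl.sum())


def summarize_session(
    events: pd.DataFrame,
    magazine_threshold_s: float = MAGAZINE_EXCLUSION_S,
    exclusion_mode: str = "trial",
) -> BehaviorSummary:
    """Session summary with the magazine-latency exclusion applied first."""
    kept, n_excl = _apply_magazine_exclusion(
        events, magazine_threshold_s, exclusion_mode
    )
    counts = kept["outcome"].value_counts()
    c = int(counts.get("correct", 0))
    i = int(counts.get("incorrect", 0))
    o = int(counts.get("omission", 0))
    p = int(counts.get("premature", 0))
    n = c + i + o + p
    accuracy = 100.0 * c / (c + i) if (c + i) > 0 else np.nan
    premature = 100.0 * p / n if n > 0 else np.nan
    omission = 100.0 * o / n if n > 0 else np.nan
    resp = (kept["response_time_s"] - kept["cue_onset_s"]).to_numpy(dtype=float)
    responded = kept["outcome"].isin(["correct", "incorrect"]).to_numpy()
    resp_lat = float(np.nanmean(resp[responded])) if responded.any() else np.nan
    mag = kept["magazine_latency_s"].to_numpy(dtype=float)
    mag_lat = float(np.nanmean(mag)) if np.isfinite(mag).any() else np.nan
    return BehaviorSummary(
        n_started=n, n_correct=c, n_incorrect=i, n_omission=o, n_premature=p,
        n_excluded=n_excl, accuracy_percent=accuracy,
        premature_percent=premature, omission_percent=omission,
        response_latency_s=resp_lat, magazine_latency_s=mag_lat,
    )


def summarize_by(events: pd.DataFrame, column: str, **kwargs) -> pd.DataFrame:
    """Per-level summaries (e.g. per delay_s or per cue_duration_s)."""
    rows = []
    for level, grp in events.groupby(column, observed=True):
        row = summarize_session(grp, **kwargs).as_dict()
        row[column] = level
        rows.append(row)
    return pd.DataFrame(rows)


def split_blocks(
    events: pd.DataFrame,
    block_minutes: float = 30.0,
    n_blocks: int = 5,
    session_start_s: float = 0.0,
    **kwargs,
) -> list[BehaviorSummary]:
    """Per-block summaries; trials assigned by trial start, half-open bins.

    A trial starting exactly at a block boundary belongs to the next block.
    Shorter sessions yield trailing empty-block summaries.
    """
    if block_minutes <= 0 or n_blocks <= 0:
        raise ValueError("block size and count must be positive")
    width = block_minutes * 60.0
    starts = events["trial_start_s"].to_numpy(dtype=float)
    out = []
    for b in range(n_blocks):
        lo = session_start_s + b * width
        hi = lo + width
        out.append(summarize_session(events.loc[(starts >= lo) & (starts < hi)],
                                     **kwargs))
    return out


def premature_latency_distribution(
    events: pd.DataFrame,
    delay_s: float | None = None,
    bin_width_s: float = 0.5,
) -> dict:
    """Histogram + empirical CDF of premature response latencies.

    Latency is ``response_time - trial_start`` for premature trials,
    optionally restricted to one delay. Returns a dict with ``latencies``,
    ``bin_edges``, ``counts``, and ``(cdf_x, cdf_y)``.
    """
    sel = events.loc[events["outcome"] == "premature"]
    if delay_s is not None:
        sel = sel.loc[np.isclose(sel["delay_s"].astype(float), delay_s)]
    lat = (sel["response_time_s"] - sel["trial_start_s"]).to_numpy(dtype=float)
    if lat.size == 0:
        log.warning("premature_latency_distribution: empty selection")
        return {"latencies": lat, "bin_edges": np.array([0.0]),
                "counts": np.array([], dtype=int),
                "cdf_x": np.array([]), "cdf_y": np.array([])}
    top = np.ceil(lat.max() / bin_width_s) * bin_width_s
    edges = np.arange(0.0, top + bin_width_s, bin_width_s)
    counts, _ = np.histogram(lat, bins=edges)
    x = np.sort(lat)
    y = np.arange(1, x.size + 1) / x.size
    return {"latencies": lat, "bin_edges": edges, "counts": counts,
            "cdf_x": x, "cdf_y": y}


def double_label_percentage(n_double: int, n_total: int) -> float:
    """Percentage of double-labeled cells, rounded half-to-even to 2 decimals.

    E.g. 6 of 747 cells -> 0.80 %.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_double <= n_total):
        raise ValueError("n_double must lie in [0, n_total]")
    return round(100.0 * n_double / n_total, 2)


def percent_change_vs_baseline(value: float, baseline: float) -> float:
    """Percentage-point difference from a baseline (e.g. saline) condition."""
    return value - baseline


def ratio_vs_baseline(value: float, baseline: float) -> float:
    """Ratio relative to a baseline condition (NaN when baseline is 0)."""
    return value / baseline if baseline != 0 else np.nan
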