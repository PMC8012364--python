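"""File formats, pipeline configuration and the end-to-end driver.

Event logs are CSV with a fixed schema; recordings and epoch tensors live
in an HDF5 container (``/raw/sig470``, ``/raw/sig405`` with ``fs_hz`` and
``t0_s`` attributes, processed dF/F under ``/processed/dff``, injected
ground truth under ``/truth``). Every artifact written by the pipeline is
stamped with the config hash and package version so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import summarize_session
from .epochs import epoch_trials, select_trials, subject_mean_traces, zscore_epochs
from .metrics import compute_delay_metrics
from .preprocess import FilterConfig, ProcessedTrace, preprocess_recording
from .simulate import (
    EVENT_COLUMNS,
    OUTCOMES,
    GroundTruth,
    PhotometryConfig,
    RawPhotometryRecording,
    SessionConfig,
    generate_photometry_recording,
    generate_session_events,
)
from .stats import bootstrap_mean_ci, elevated_windows, permutation_difference_mask

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Event log CSV
# ---------------------------------------------------------------------------

def write_events_csv(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event log missing column(s): {', '.join(missing)}")
    starts = events["trial_start_s"].to_numpy(dtype=float)
    if np.any(np.diff(starts) <= 0):
        bad = int(np.nonzero(np.diff(starts) <= 0)[0][0]) + 1
        raise ValueError(f"non-monotone trial_start_s at row {bad}")
    unknown = set(events["outcome"]) - set(OUTCOMES)
    if unknown:
        raise ValueError(f"unknown outcome value(s): {sorted(unknown)}")
    return events


# ---------------------------------------------------------------------------
# HDF5 trace container
# ---------------------------------------------------------------------------

def write_recording_h5(
    path,
    recording: RawPhotometryRecording,
    truth: GroundTruth | None = None,
    processed: ProcessedTrace | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        raw = f.create_group("raw")
        raw.create_dataset("sig470", data=recording.sig470)
        raw.create_dataset("sig405", data=recording.sig405)
        raw.attrs["fs_hz"] = recording.fs_hz
        raw.attrs["t0_s"] = recording.t0_s
        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset(
                "transient_windows",
                data=np.asarray(truth.transient_windows, dtype=float).reshape(-1, 2),
            )
            tg.attrs["n_trials"] = truth.n_trials
        if processed is not None:
            append_processed_h5(f, processed)


def append_processed_h5(h5file, processed: ProcessedTrace) -> None:
    grp = h5file.require_group("processed")
    if "dff" in grp:
        del grp["dff"]
    ds = grp.create_dataset("dff", data=processed.dff)
    ds.attrs["fs_hz"] = processed.fs_hz
    ds.attrs["t0_s"] = processed.t0_s
    for key, val in processed.provenance.items():
        ds.attrs[str(key)] = val


def read_recording_h5(path) -> tuple[RawPhotometryRecording, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        if "raw" not in f:
            raise ValueError(f"{path}: no /raw group in trace container")
        raw = f["raw"]
        if "fs_hz" not in raw.attrs:
            raise ValueError(f"{path}: fs_hz attribute absent")
        rec = RawPhotometryRecording(
            sig470=raw["sig470"][:],
            sig405=raw["sig405"][:],
            fs_hz=float(raw.attrs["fs_hz"]),
            t0_s=float(raw.attrs.get("t0_s", 0.0)),
        )
        truth = None
        if "truth" in f:
            wins = f["truth"]["transient_windows"][:]
            truth = GroundTruth(
                transient_windows=[tuple(w) for w in wins],
                n_trials=int(f["truth"].attrs.get("n_trials", len(wins))),
            )
    return rec, truth


def read_processed_h5(path) -> ProcessedTrace:
    with h5py.File(path, "r") as f:
        if "processed" not in f or "dff" not in f["processed"]:
            raise ValueError(f"{path}: no /processed/dff dataset")
        ds = f["processed"]["dff"]
        prov = {k: v for k, v in ds.attrs.items() if k not in ("fs_hz", "t0_s")}
        return ProcessedTrace(
            dff=ds[:], fs_hz=float(ds.attrs["fs_hz"]),
            t0_s=float(ds.attrs.get("t0_s", 0.0)), provenance=dict(prov),
        )


def load_session(events_path, traces_path):
    """Validated ``(events, recording)`` pair from a CSV + HDF5 file pair."""
    events = read_events_csv(events_path)
    recording, _ = read_recording_h5(traces_path)
    return events, recording


def write_mask_csv(mask, path) -> None:
    """Significance mask as CSV (frame_time_s or frame index, significant)."""
    t = (mask.frame_times_s if mask.frame_times_s is not None
         else np.arange(mask.mask.size))
    pd.DataFrame({"frame_time_s": t, "significant": mask.mask.astype(int)}).to_csv(
        path, index=False
    )


def write_windows_bed(mask, path, label: str = "") -> None:
    """Windows as a BED-like interval list (start, end, label)."""
    lbl = label or mask.meta.get("comparison", "")
    with open(path, "w") as f:
        for start, end in mask.windows:
            f.write(f"{start}\t{end}\t{lbl}\n")


# ---------------------------------------------------------------------------
# Pipeline configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage parameters of a simulate -> stats run, with one seed.

    Defaults follow the analysis conventions throughout the package:
    5000 resampling iterations, bootstrap alpha 0.001, permutation alpha
    0.01, a -5..-1 s pre-trial baseline, decimation by 64, the +2 SD
    activity threshold and the 10 s magazine-latency exclusion.
    """

    n_subjects: int = 4
    session: dict = field(default_factory=dict)
    photometry: dict = field(default_factory=dict)
    lowpass_hz: float = 1.0
    drift_hz: float = 0.005
    decimation_factor: int = 64
    epoch_window_s: tuple = (-5.0, 15.0)
    baseline_window_s: tuple = (-5.0, -1.0)
    threshold_sd: float = 2.0
    bootstrap_alpha: float = 0.001
    permutation_alpha: float = 0.01
    n_iter: int = 5000
    min_run: int = 2
    seed: int = 0
    out_dir: str = "fiberbehav_out"

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls(**raw)
        cfg.epoch_window_s = tuple(cfg.epoch_window_s)
        cfg.baseline_window_s = tuple(cfg.baseline_window_s)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> preprocess -> epoch -> metrics -> stats, per subject.

    Simulates ``n_subjects`` sessions with per-subject seeds spawned from
    the master seed, processes each through the full photometry chain, and
    runs the bootstrap elevated-window detector on the per-subject correct-
    trial mean traces plus a paired correct-vs-premature permutation test.
    Artifacts are written under ``config.out_dir`` stamped with the config
    hash; reruns with the same config are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        2 * config.n_subjects
    ) % (2**31)
    filt = FilterConfig(lowpass_hz=config.lowpass_hz, drift_hz=config.drift_hz)
    epoch_sets, summaries, metric_tables = [], [], []
    for s in range(config.n_subjects):
        sess_cfg = SessionConfig(
            **{"session_id": f"rat{s:02d}", **config.session,
               "seed": int(seeds[2 * s])}
        )
        events = generate_session_events(sess_cfg)
        phot_cfg = PhotometryConfig(
            **{**config.photometry, "seed": int(seeds[2 * s + 1])}
        )
        recording, truth = generate_photometry_recording(events, phot_cfg)
        trace = preprocess_recording(
            recording, filt_config=filt,
            decimation_factor=config.decimation_factor,
        )
        ep = zscore_epochs(
            epoch_trials(
                trace, events, align_event="trial_start",
                window_s=config.epoch_window_s,
                baseline_window_s=config.baseline_window_s,
            )
        )
        epoch_sets.append(ep)
        summaries.append(summarize_session(events).as_dict())
        mt = compute_delay_metrics(ep, k=config.threshold_sd)
        mt.insert(0, "subject", sess_cfg.session_id)
        metric_tables.append(mt)
        write_events_csv(events, out_dir / f"events_{sess_cfg.session_id}.csv")
        write_recording_h5(
            out_dir / f"traces_{sess_cfg.session_id}.h5", recording, truth,
            processed=trace,
        )
        log.info("subject %s: %d trials, %d epochs (%d dropped)",
                 sess_cfg.session_id, len(events), ep.n_trials, ep.n_dropped)

    correct = subject_mean_traces(epoch_sets, outcome="correct")
    boot = bootstrap_mean_ci(
        correct, n_iter=config.n_iter, alpha=config.bootstrap_alpha,
        seed=int(seeds[0]),
    )
    elevated = elevated_windows(
        boot, frame_times_s=epoch_sets[0].frame_times_s, min_run=config.min_run
    )
    premature = subject_mean_traces(epoch_sets, outcome="premature")
    perm = permutation_difference_mask(
        correct, premature, n_iter=config.n_iter,
        alpha=config.permutation_alpha, paired=True,
        min_run=config.min_run, seed=int(seeds[1]),
    )

    metrics_df = pd.concat(metric_tables, ignore_index=True)
    metrics_df.to_csv(out_dir / "delay_metrics.csv", index=False)
    pd.DataFrame(summaries).to_csv(out_dir / "behavior_summary.csv", index=False)
    write_mask_csv(elevated, out_dir / "elevated_mask.csv")
    write_windows_bed(elevated, out_dir / "elevated_windows.bed", "elevated")
    provenance = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "seed": config.seed,
    }
    with open(out_dir / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=2, sort_keys=True)
    return {
        "epochs": epoch_sets,
        "behavior": summaries,
        "metrics": metrics_df,
        "bootstrap": boot,
        "elevated": elevated,
        "permutation": perm,
        "provenance": provenance,
    }
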