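"""Intrinsic-property and synaptic feature extraction from patch-clamp sweeps.

Implements the quantities reported for the recorded projection-target
neurons: drift-corrected median postsynaptic currents (PSCs) and
paired-pulse ratios from 10 Hz five-pulse trains, PSC latency (80 % of
peak), input resistance from the hyperpolarizing I-V slope, membrane time
constant from first-order exponential fits, capacitance via the tau = R*C
identity, sag percentage, burst/steady firing rates on depolarizing steps,
and ramp rheobase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm


@dataclass
class EphysProtocol:
    """A sweep set: list of ``(stimulus_descriptor, sampled_trace)`` pairs.

    ``mode`` is "voltage_clamp" (traces in pA) or "current_clamp" (mV).
    Stimulus descriptors are dicts with at least a ``kind`` key
    ("step", "ramp" or "psc_train") plus kind-specific metadata.
    """

    sweeps: list
    mode: str
    fs_hz: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        # sweeps of the same stimulus kind must share a length (the ramp may
        # legitimately be longer than the steps)
        by_kind: dict = {}
        for s, tr in self.sweeps:
            by_kind.setdefault(s.get("kind"), set()).add(np.asarray(tr).size)
        for kind, lengths in by_kind.items():
            if len(lengths) > 1:
                raise ValueError(f"sweeps of unequal length (kind {kind!r})")

    def steps(self):
        return [(s, np.asarray(tr)) for s, tr in self.sweeps if s.get("kind") == "step"]

    def ramp(self):
        for s, tr in self.sweeps:
            if s.get("kind") == "ramp":
                return s, np.asarray(tr)
        return None


# ---------------------------------------------------------------------------
# Synaptic features
# ---------------------------------------------------------------------------

def median_psc_trace(protocol: EphysProtocol) -> np.ndarray:
    """Drift-corrected pointwise median across PSC-train sweeps.

    Per sweep, a robust (Huber IRLS) line is fit to baseline samples (before
    the first pulse and after the last response has decayed) and subtracted
    from the whole sweep, then the pointwise median across sweeps is taken.
    """
    train_sweeps = [
        (s, np.asarray(tr, dtype=float))
        for s, tr in protocol.sweeps
        if s.get("kind") == "psc_train"
    ]
    if len(train_sweeps) < 3:
        raise ValueError("need at least 3 sweeps")
    stim = train_sweeps[0][0]
    onsets = np.asarray(stim["pulse_onsets_s"], dtype=float)
    fs = protocol.fs_hz
    n = train_sweeps[0][1].size
    t = np.arange(n) / fs
    base_mask = (t < onsets[0] - 0.002) | (t > onsets[-1] + 0.095)
    if base_mask.sum() < 10:
        raise ValueError("too few baseline samples for drift fit")
    x = sm.add_constant(t[base_mask])
    corrected = []
    for _, tr in train_sweeps:
        fit = sm.RLM(tr[base_mask], x, M=sm.robust.norms.HuberT()).fit()
        b, a = fit.params  # intercept, slope
        corrected.append(tr - (a * t + b))
    return np.median(np.vstack(corrected), axis=0)


def _pulse_peak(trace, fs, onset, window_s=0.09, sign=None):
    i0 = int(np.floor(onset * fs)) + 1
    i1 = int(np.floor((onset + window_s) * fs)) + 1
    seg = trace[i0:i1]
    if seg.size == 0:
        return np.nan
    if sign is None:
        sign = -1.0 if abs(seg.min()) >= abs(seg.max()) else 1.0
    return seg.min() if sign < 0 else seg.max()


def paired_pulse_ratios(
    median_trace: np.ndarray,
    stim_onsets_s,
    fs_hz: float,
    peak_window_s: float = 0.09,
    noise_floor: float = 1.0,
) -> np.ndarray:
    """PPRs PSC_n / PSC_1 for n = 2..5 from a drift-corrected median trace.

    Polarity is auto-detected from the first response (inward currents at
    -60 mV holding are negative); peaks are signed extrema in the
    ``(onset, onset + peak_window_s]`` window and ratios use magnitudes.
    """
    onsets = np.asarray(stim_onsets_s, dtype=float)
    p1 = _pulse_peak(median_trace, fs_hz, onsets[0], peak_window_s)
    if not np.isfinite(p1) or abs(p1) < noise_floor:
        return np.full(len(onsets) - 1, np.nan)
    sign = -1.0 if p1 < 0 else 1.0
    peaks = [
        _pulse_peak(median_trace, fs_hz, on, peak_window_s, sign=sign)
        for on in onsets
    ]
    peaks = np.abs(np.asarray(peaks))
    return peaks[1:] / peaks[0]


def psc_latency(
    median_trace: np.ndarray, light_onset_s: float, fs_hz: float,
    peak_window_s: float = 0.09,
) -> float:
    """Time (ms) from light onset to 80 % of the PSC peak, interpolated."""
    i0 = int(np.floor(light_onset_s * fs_hz)) + 1
    i1 = int(np.floor((light_onset_s + peak_window_s) * fs_hz)) + 1
    seg = np.asarray(median_trace[i0:i1], dtype=float)
    if seg.size == 0:
        return np.nan
    sign = -1.0 if abs(seg.min()) >= abs(seg.max()) else 1.0
    resp = sign * seg  # positive-going response
    peak = resp.max()
    if peak <= 0:
        return np.nan
    target = 0.8 * peak
    above = np.nonzero(resp >= target)[0]
    if above.size == 0:
        return np.nan
    j = above[0]
    if j == 0:
        t_cross = 0.0
    else:
        frac = (target - resp[j - 1]) / (resp[j] - resp[j - 1])
        t_cross = (j - 1 + frac) / fs_hz
    # offset of the first considered sample relative to light onset
    t_first = i0 / fs_hz - light_onset_s
    return 1000.0 * (t_first + t_cross)


# ---------------------------------------------------------------------------
# Intrinsic properties
# ---------------------------------------------------------------------------

def _step_deltas(protocol, lo_pa, hi_pa, ss_window_s=0.2):
    """(I, dV_ss, dV_peak, stim, trace) for steps with lo <= amplitude < hi."""
    fs = protocol.fs_hz
    out = []
    for stim, tr in protocol.steps():
        i_pa = stim["amplitude_pa"]
        if not (lo_pa <= i_pa < hi_pa):
            continue
        on = int(round(stim["onset_s"] * fs))
        off = int(round((stim["onset_s"] + stim["duration_s"]) * fs))
        base = tr[: on].mean() if on else tr[0]
        n_ss = int(round(ss_window_s * fs))
        dv_ss = tr[off - n_ss : off].mean() - base
        seg = tr[on:off] - base
        dv_peak = seg[np.argmax(np.abs(seg))]
        out.append((i_pa, dv_ss, dv_peak, stim, tr))
    return out


def input_resistance(protocol: EphysProtocol) -> float:
    """Input resistance (MOhm): I-V slope of hyperpolarizing steps.

    Uses the steady-state voltage in the last 200 ms of each step in the
    0 to -100 pA range; the regression keeps a free intercept so baseline
    offsets do not bias the slope.
    """
    pts = _step_deltas(protocol, -100.0 - 1e-9, 0.0)
    if len(pts) < 2:
        raise ValueError("need >= 2 negative steps for input resistance")
    i = np.array([p[0] for p in pts])
    dv = np.array([p[1] for p in pts])
    slope = stats.linregress(i, dv).slope  # mV / pA == GOhm
    return slope * 1000.0  # MOhm


def membrane_time_constant(
    protocol: EphysProtocol,
    fit_window_s: float = 0.3,
    max_step_pa: float = 50.0,
    r2_min: float = 0.8,
) -> float:
    """Membrane tau (ms): median of exponential fits on small negative steps.

    Fits ``V(t) = V_inf + A * exp(-t / tau)`` to the first 300 ms of each
    negative step with |I| <= ``max_step_pa``; fits with R^2 <= ``r2_min``
    are discarded. Raises if no fit passes the gate.
    """
    fs = protocol.fs_hz
    taus = []
    for stim, tr in protocol.steps():
        i_pa = stim["amplitude_pa"]
        if i_pa >= 0 or abs(i_pa) > max_step_pa:
            continue
        on = int(round(stim["onset_s"] * fs))
        n_fit = int(round(fit_window_s * fs))
        seg = np.asarray(tr[on : on + n_fit], dtype=float)
        t = np.arange(seg.size) / fs

        def model(tt, v_inf, a, tau):
            return v_inf + a * np.exp(-tt / tau)

        a0 = seg[0] - seg[-1]
        try:
            popt, _ = optimize.curve_fit(
                model, t, seg, p0=(seg[-1], a0, 0.02), maxfev=5000
            )
        except RuntimeError:
            continue
        resid = seg - model(t, *popt)
        ss_tot = np.sum((seg - seg.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        if r2 > r2_min and popt[2] > 0:
            taus.append(popt[2] * 1000.0)
    if not taus:
        raise ValueError("no exponential fit passed the R^2 gate")
    return float(np.median(taus))


def capacitance(r_input_mohm: float, tau_ms: float) -> float:
    """Membrane capacitance (pF) from the tau = R*C identity: C = tau / R."""
    if r_input_mohm <= 0 or tau_ms <= 0:
        raise ValueError("R and tau must be positive")
    return 1000.0 * tau_ms / r_input_mohm


def sag_ratio(protocol: EphysProtocol, target_dv_mv: float = -20.0) -> float:
    """Sag (%) on the negative step whose peak deflection is closest to -20 mV.

    sag% = 100 * (|dV_peak| - |dV_ss|) / |dV_peak|, with the steady state
    taken over the last fifth of the step duration.
    """
    fs = protocol.fs_hz
    candidates = []
    for stim, tr in protocol.steps():
        if stim["amplitude_pa"] >= 0:
            continue
        dur = stim["duration_s"]
        pts = _step_deltas(
            protocol, stim["amplitude_pa"] - 1e-9, stim["amplitude_pa"] + 1e-9,
            ss_window_s=dur / 5.0,
        )
        if pts:
            candidates.append(pts[0])
    if not candidates:
        raise ValueError("no negative steps for sag")
    best = min(candidates, key=lambda p: abs(p[2] - target_dv_mv))
    _, dv_ss, dv_peak, _, _ = best
    if dv_peak == 0:
        return np.nan
    return 100.0 * (abs(dv_peak) - abs(dv_ss)) / abs(dv_peak)


def _spike_times(trace, fs, thresh_mv=0.0):
    tr = np.asarray(trace)
    up = (tr[1:] > thresh_mv) & (tr[:-1] <= thresh_mv)
    return (np.nonzero(up)[0] + 1) / fs


def firing_profile(
    protocol: EphysProtocol,
    burst_window_s: float = 0.05,
    steady_window_s: float = 0.2,
) -> pd.DataFrame:
    """Burst and steady-state firing rate (Hz) per depolarizing step.

    Action potentials are upward 0 mV crossings. Burst rate counts spikes in
    the 50 ms after the first spike; steady rate counts spikes in the last
    200 ms of the step. Steps without spikes report 0 Hz.
    """
    rows = []
    fs = protocol.fs_hz
    for stim, tr in protocol.steps():
        i_pa = stim["amplitude_pa"]
        if i_pa < 0:
            continue
        on, dur = stim["onset_s"], stim["duration_s"]
        spikes = _spike_times(tr, fs)
        spikes = spikes[(spikes >= on) & (spikes < on + dur)]
        if spikes.size:
            t0 = spikes[0]
            burst = np.sum((spikes >= t0) & (spikes <= t0 + burst_window_s))
            burst_rate = burst / burst_window_s
        else:
            burst_rate = 0.0
        t_ss = on + dur - steady_window_s
        steady = np.sum((spikes >= t_ss) & (spikes < on + dur))
        rows.append(
            {
                "amplitude_pa": i_pa,
                "burst_rate_hz": burst_rate,
                "steady_rate_hz": steady / steady_window_s,
            }
        )
    return pd.DataFrame(rows)


def rheobase(protocol: EphysProtocol) -> float:
    """Injected current (pA) at the first spike on the 0->500 pA ramp.

    Returns NaN if the ramp elicits no spike.
    """
    ramp = protocol.ramp()
    if ramp is None:
        raise ValueError("protocol has no ramp sweep")
    stim, tr = ramp
    fs = protocol.fs_hz
    spikes = _spike_times(tr, fs)
    on = stim["onset_s"]
    dur = stim["duration_s"]
    spikes = spikes[(spikes >= on) & (spikes < on + dur)]
    if spikes.size == 0:
        return np.nan
    return stim["slope_pa_per_s"] * (spikes[0] - on)


def extract_features(
    step_protocol: EphysProtocol | None = None,
    psc_protocol: EphysProtocol | None = None,
    light_onset_s: float | None = None,
) -> dict:
    """Convenience bundle: all features defined for the supplied protocols."""
    feats: dict = {}
    if step_protocol is not None:
        feats["r_input_mohm"] = input_resistance(step_protocol)
        feats["tau_ms"] = membrane_time_constant(step_protocol)
        feats["capacitance_pf"] = capacitance(feats["r_input_mohm"], feats["tau_ms"])
        feats["sag_percent"] = sag_ratio(step_protocol)
        feats["firing"] = firing_profile(step_protocol)
        if step_protocol.ramp() is not None:
            feats["rheobase_pa"] = rheobase(step_protocol)
    if psc_protocol is not None:
        med = median_psc_trace(psc_protocol)
        stim = psc_protocol.sweeps[0][0]
        onsets = stim["pulse_onsets_s"]
        feats["ppr"] = paired_pulse_ratios(med, onsets, psc_protocol.fs_hz)
        onset = light_onset_s if light_onset_s is not None else onsets[0]
        feats["psc_latency_ms"] = psc_latency(med, onset, psc_protocol.fs_hz)
    return feats
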