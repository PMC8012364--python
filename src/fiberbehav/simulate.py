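"""Synthetic session, photometry and patch-clamp data with known ground truth.

The generators emulate the statistical structure of a self-paced five-choice
serial reaction time task (5-CSRTT) experiment recorded with two-channel
fiber photometry, plus the slice-electrophysiology protocols used to
characterize the recorded projection neurons:

* variable-delay trial logs (delays 5 / 7.5 / 12.5 s, four outcomes),
* GCaMP-like delay-period calcium transients riding on shared multiplicative
  motion and bleaching artifacts in a 470 nm signal / 405 nm isosbestic pair,
* RC-membrane current-step and ramp sweeps, and
* 10 Hz five-pulse postsynaptic-current trains with short-term plasticity.

Every generator is deterministic given its config seed, and each returns the
ground truth it injected so downstream stages can be verified quantitatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import EphysProtocol

OUTCOMES = ("correct", "incorrect", "omission", "premature")

EVENT_COLUMNS = [
    "session_id",
    "trial_index",
    "trial_start_s",
    "delay_s",
    "cue_onset_s",
    "cue_duration_s",
    "response_time_s",
    "outcome",
    "reward_collect_s",
    "magazine_latency_s",
]


# ---------------------------------------------------------------------------
# Session events
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Parameters of a simulated final-phase 5-CSRTT session.

    ``outcome_probabilities`` maps outcome name -> probability, or
    delay (float) -> {outcome: probability} for delay-conditional mixes.
    The inter-trial interval defaults to 10 s so the photometry baseline
    window (-5..-1 s before trial start) is free of trial-evoked signal.
    """

    n_trials: int = 100
    delay_set_s: tuple = (5.0, 7.5, 12.5)
    cue_duration_s: float = 1.0
    limited_hold_s: float = 2.0
    timeout_s: float = 5.0
    iti_s: float = 10.0
    outcome_probabilities: dict = field(
        default_factory=lambda: {
            "correct": 0.60,
            "incorrect": 0.10,
            "omission": 0.12,
            "premature": 0.18,
        }
    )
    session_length_s: float | None = None
    session_id: str = "sim"
    seed: int = 0

    def probs_for_delay(self, delay: float) -> np.ndarray:
        table = self.outcome_probabilities
        if table and all(isinstance(k, str) for k in table):
            probs = {o: table.get(o, 0.0) for o in OUTCOMES}
        else:
            row = None
            for key, val in table.items():
                if isinstance(key, (int, float)) and np.isclose(float(key), delay):
                    row = val
                    break
            if row is None:
                raise ValueError(f"no outcome probabilities for delay {delay}")
            probs = {o: row.get(o, 0.0) for o in OUTCOMES}
        p = np.array([probs[o] for o in OUTCOMES], dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError(
                f"outcome probabilities for delay {delay} sum to {p.sum():.6f}, not 1"
            )
        if (p < 0).any():
            raise ValueError("negative outcome probability")
        return p

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not self.delay_set_s:
            raise ValueError("delay_set_s must be non-empty")
        for name in ("cue_duration_s", "limited_hold_s", "timeout_s", "iti_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for delay in self.delay_set_s:
            self.probs_for_delay(float(delay))


def generate_session_events(config: SessionConfig) -> pd.DataFrame:
    """Simulate an ordered, non-overlapping trial log.

    Returns a DataFrame with the canonical event-log schema
    (:data:`EVENT_COLUMNS`). Delays are drawn uniformly from the delay set;
    the outcome of each trial is drawn from the delay-conditional outcome
    distribution. Premature responses occur strictly before cue onset,
    correct/incorrect responses within the cue + limited-hold window, and
    omissions carry no response. Magazine latency is populated for rewarded
    (correct) trials only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    t = float(rng.uniform(5.0, 15.0))  # first trial start
    delays = np.asarray(config.delay_set_s, dtype=float)
    for i in range(config.n_trials):
        delay = float(delays[rng.integers(len(delays))])
        p = config.probs_for_delay(delay)
        outcome = OUTCOMES[rng.choice(len(OUTCOMES), p=p)]
        cue_onset = t + delay
        response_time = np.nan
        reward_collect = np.nan
        magazine_latency = np.nan
        resp_window = config.cue_duration_s + config.limited_hold_s
        if outcome in ("correct", "incorrect"):
            # truncated-exponential response latency inside cue + limited hold
            lat = rng.exponential(0.5) + 0.15
            response_time = cue_onset + min(lat, resp_window - 1e-3)
            if outcome == "correct":
                magazine_latency = float(min(rng.lognormal(0.4, 0.5), 30.0))
                reward_collect = response_time + magazine_latency
                trial_end = reward_collect + 5.0
            else:
                trial_end = response_time + config.timeout_s
        elif outcome == "premature":
            # rising hazard through the delay: responses biased late
            frac = rng.beta(2.0, 1.2)
            response_time = t + max(0.1, frac * delay)
            response_time = min(response_time, cue_onset - 1e-3)
            trial_end = response_time + config.timeout_s
        else:  # omission
            trial_end = cue_onset + resp_window + config.timeout_s
        rows.append(
            {
                "session_id": config.session_id,
                "trial_index": i,
                "trial_start_s": t,
                "delay_s": delay,
                "cue_onset_s": cue_onset,
                "cue_duration_s": config.cue_duration_s,
                "response_time_s": response_time,
                "outcome": outcome,
                "reward_collect_s": reward_collect,
                "magazine_latency_s": magazine_latency,
            }
        )
        t = trial_end + config.iti_s + float(rng.uniform(0.0, 2.0))
        if config.session_length_s is not None and t > config.session_length_s:
            break
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

@dataclass
class RawPhotometryRecording:
    """Paired 470 nm (calcium-sensitive) and 405 nm (isosbestic) traces."""

    sig470: np.ndarray
    sig405: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self):
        self.sig470 = np.asarray(self.sig470, dtype=float)
        self.sig405 = np.asarray(self.sig405, dtype=float)
        if self.sig470.shape != self.sig405.shape:
            raise ValueError("channel lengths differ")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if not (np.isfinite(self.sig470).all() and np.isfinite(self.sig405).all()):
            raise ValueError("non-finite samples in recording")

    @property
    def n_samples(self) -> int:
        return self.sig470.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class PhotometryConfig:
    """Signal model for the two-channel recording.

    The raw sampling rate defaults to 1017.25 Hz so that decimation by 64
    yields the ~16 Hz analysis frame rate. Motion and bleaching are
    multiplicative and shared (up to a gain) across both channels, which is
    exactly the artifact structure the isosbestic regression-and-divide
    correction removes. The calcium component is a per-trial saturating rise
    toward ``transient_amplitude * plateau_gain`` that spans the delay period
    and decays after the delay ends (or at a premature response).
    """

    fs_raw_hz: float = 1017.25
    baseline_470: float = 2.0
    baseline_405: float = 1.6
    transient_amplitude: float = 0.05  # fractional dF/F
    rise_tau_s: float = 0.3
    decay_tau_s: float = 0.8
    onset_latency_s: float = 0.2
    plateau_gain: float = 1.0
    omission_gain: float = 0.8
    motion_amplitude: float = 0.02
    motion_channel_gain: float = 1.0  # 405-channel motion gain relative to 470
    bleach_tau_s: float = 3000.0
    noise_sd: float = 0.003
    calcium_noise_sd: float = 0.01  # spontaneous dF/F fluctuations (OU process)
    calcium_noise_tau_s: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.fs_raw_hz <= 0:
            raise ValueError("fs_raw_hz must be > 0")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0 or self.bleach_tau_s <= 0:
            raise ValueError("time constants must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs_raw_hz < 2.0 / self.rise_tau_s:
            raise ValueError("sampling rate too low to resolve rise_tau_s")


@dataclass
class CellParams:
    """Ground-truth intrinsic parameters of a simulated cell."""

    r_mohm: float = 150.0
    tau_ms: float = 20.0
    sag_r_mohm: float = 0.0  # extra transient resistance producing sag
    v_rest_mv: float = -70.0
    v_thresh_mv: float = -40.0

    @property
    def capacitance_pf(self) -> float:
        return 1000.0 * self.tau_ms / self.r_mohm

    @property
    def rheobase_pa(self) -> float:
        return 1000.0 * (self.v_thresh_mv - self.v_rest_mv) / self.r_mohm


@dataclass
class SynapseParams:
    """Per-pulse PSC amplitudes, explicit or via a short-term-plasticity rule."""

    amplitudes_pa: tuple | None = None
    u: float = 0.2
    tau_facil_s: float = 0.5
    tau_rec_s: float = 0.1
    a_max_pa: float = 50.0

    def pulse_amplitudes(self, n_pulses: int = 5, dt_s: float = 0.1) -> np.ndarray:
        if self.amplitudes_pa is not None:
            amps = np.asarray(self.amplitudes_pa, dtype=float)
            if (amps < 0).any():
                raise ValueError("negative PSC amplitudes")
            return amps
        return self.a_max_pa * tm_amplitudes(
            n_pulses, self.u, self.tau_facil_s, self.tau_rec_s, dt_s
        )


@dataclass
class GroundTruth:
    """What the generator injected, for verification of downstream stages."""

    transient_windows: list  # (start_s, end_s) per trial with a transient
    calcium: np.ndarray | None = None  # fractional dF/F at the raw rate
    n_trials: int = 0
    cell: CellParams | None = None
    synapse: SynapseParams | None = None


def tm_amplitudes(
    n_pulses: int, u: float, tau_facil_s: float, tau_rec_s: float, dt_s: float = 0.1
) -> np.ndarray:
    """Analytic per-pulse release amplitudes of a Tsodyks-Markram synapse.

    ``u`` is the baseline release probability increment, ``tau_facil_s`` the
    facilitation decay and ``tau_rec_s`` the vesicle recovery time constant;
    pulses are ``dt_s`` apart. Returns amplitudes normalized so an isolated
    pulse has amplitude ``u``.
    """
    ef = np.exp(-dt_s / tau_facil_s)
    ed = np.exp(-dt_s / tau_rec_s)
    u_k, r_k = u, 1.0
    amps = []
    for _ in range(n_pulses):
        amps.append(u_k * r_k)
        r_next = 1.0 - (1.0 - r_k * (1.0 - u_k)) * ed
        u_next = u + u_k * (1.0 - u) * ef
        u_k, r_k = u_next, r_next
    return np.asarray(amps)


def _motion_trace(n: int, fs: float, amplitude: float, rng: np.random.Generator):
    """Multiplicative motion artifact: a bank of slow sinusoids around 1."""
    if amplitude == 0:
        return np.ones(n)
    t = np.arange(n) / fs
    m = np.zeros(n)
    freqs = rng.uniform(0.05, 2.0, size=5)
    phases = rng.uniform(0, 2 * np.pi, size=5)
    weights = rng.dirichlet(np.ones(5))
    for f, ph, w in zip(freqs, phases, weights):
        m += w * np.sin(2 * np.pi * f * t + ph)
    return 1.0 + amplitude * m


def generate_photometry_recording(
    events: pd.DataFrame, config: PhotometryConfig
) -> tuple[RawPhotometryRecording, GroundTruth]:
    """Render a two-channel recording for a session event log.

    The 405 nm channel carries only baseline x bleach x motion (+ noise); the
    470 nm channel additionally multiplies in ``1 + calcium(t)``. Ground
    truth records the injected per-trial transient windows and the calcium
    trace itself.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    starts = events["trial_start_s"].to_numpy(dtype=float)
    if np.any(np.diff(starts) <= 0):
        raise ValueError("trial starts must be strictly increasing")
    trial_ends = _delay_end_times(events)
    if np.any(starts[1:] < trial_ends[:-1]):
        raise ValueError("overlapping trial windows")
    duration = float(trial_ends[-1] + 20.0) if len(starts) else 60.0
    fs = config.fs_raw_hz
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    calcium = np.zeros(n)
    windows = []
    for start, end, outcome in zip(starts, trial_ends, events["outcome"]):
        t_on = start + config.onset_latency_s
        if end <= t_on:
            continue
        amp = config.transient_amplitude * config.plateau_gain
        if outcome == "omission":
            amp *= config.omission_gain
        if amp == 0:
            continue
        i_on = int(np.ceil(t_on * fs))
        i_off = int(np.ceil(end * fs))
        rise_t = t[i_on:i_off] - t_on
        calcium[i_on:i_off] += amp * (1.0 - np.exp(-rise_t / config.rise_tau_s))
        level = amp * (1.0 - np.exp(-(end - t_on) / config.rise_tau_s))
        decay_t = t[i_off:] - end
        calcium[i_off:] += level * np.exp(-decay_t / config.decay_tau_s)
        windows.append((t_on, float(end)))

    if config.calcium_noise_sd > 0:
        # Ornstein-Uhlenbeck spontaneous activity: in-band dF/F fluctuations
        # that survive filtering, unlike white measurement noise.
        from scipy.signal import lfilter

        a = np.exp(-1.0 / (fs * config.calcium_noise_tau_s))
        w = rng.normal(0, 1.0, n)
        ou = lfilter([np.sqrt(1 - a**2)], [1.0, -a], w)
        calcium = calcium + config.calcium_noise_sd * ou

    bleach = np.exp(-t / config.bleach_tau_s)
    motion = _motion_trace(n, fs, config.motion_amplitude, rng)
    motion405 = 1.0 + config.motion_channel_gain * (motion - 1.0)
    sig405 = config.baseline_405 * bleach * motion405
    sig470 = config.baseline_470 * bleach * motion * (1.0 + calcium)
    if config.noise_sd > 0:
        sig405 = sig405 + rng.normal(0, config.noise_sd, n)
        sig470 = sig470 + rng.normal(0, config.noise_sd, n)
    rec = RawPhotometryRecording(sig470=sig470, sig405=sig405, fs_hz=fs, t0_s=0.0)
    truth = GroundTruth(
        transient_windows=windows, calcium=calcium, n_trials=len(events)
    )
    return rec, truth


def _delay_end_times(events: pd.DataFrame) -> np.ndarray:
    """Delay-period end per trial: cue onset, or the premature response."""
    ends = events["cue_onset_s"].to_numpy(dtype=float).copy()
    premature = (events["outcome"] == "premature").to_numpy()
    resp = events["response_time_s"].to_numpy(dtype=float)
    ends[premature] = resp[premature]
    return ends


# ---------------------------------------------------------------------------
# Electrophysiology protocols
# ---------------------------------------------------------------------------

def generate_current_step_protocol(
    cell: CellParams,
    fs_hz: float = 20000.0,
    neg_steps_pa: tuple = (0.0, -20.0, -40.0, -60.0, -80.0, -100.0),
    pos_steps_pa: tuple = (0.0, 50.0, 100.0, 150.0, 200.0),
    step_duration_s: float = 0.5,
    pre_s: float = 0.1,
    post_s: float = 0.2,
    sag_tau_s: float = 0.05,
    ramp_max_pa: float = 500.0,
    ramp_duration_s: float = 1.0,
    noise_sd_mv: float = 0.0,
    spike_mode: str = "instantaneous",
    refractory_s: float = 0.005,
    seed: int = 0,
) -> EphysProtocol:
    """Current-clamp sweep set: hyperpolarizing and depolarizing steps + ramp.

    Hyperpolarizing sweeps follow the RC closed form
    ``V(t) = V_rest + I*R*(1 - exp(-t/tau))`` with an optional alpha-shaped
    sag component of peak resistance ``cell.sag_r_mohm``. Depolarizing
    sweeps spike via a leaky integrate-and-fire rule; the ramp sweep sweeps
    0 -> ``ramp_max_pa`` for rheobase extraction. ``spike_mode``
    "instantaneous" fires when the steady-state voltage ``V_rest + I*R``
    reaches threshold (so the ramp rheobase equals the analytic value);
    "dynamic" integrates the membrane equation so the measured rheobase lags
    the analytic value by ~ramp_rate*tau.
    """
    if cell.r_mohm <= 0 or cell.tau_ms <= 0:
        raise ValueError("cell R and tau must be > 0")
    if step_duration_s < 5.0 * cell.tau_ms / 1000.0:
        warnings.warn("step shorter than 5*tau; steady state ill-defined")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_hz
    n_pre = int(round(pre_s * fs_hz))
    n_step = int(round(step_duration_s * fs_hz))
    n_post = int(round(post_s * fs_hz))
    n_tot = n_pre + n_step + n_post
    tau_s = cell.tau_ms / 1000.0
    sweeps = []

    def rc_response(i_pa: float) -> np.ndarray:
        v = np.full(n_tot, cell.v_rest_mv)
        ts = np.arange(n_step) * dt
        dv = i_pa * cell.r_mohm / 1000.0  # pA * MOhm -> mV
        v[n_pre : n_pre + n_step] += dv * (1.0 - np.exp(-ts / tau_s))
        if cell.sag_r_mohm:
            alpha = (ts / sag_tau_s) * np.exp(1.0 - ts / sag_tau_s)
            v[n_pre : n_pre + n_step] += (
                i_pa * cell.sag_r_mohm / 1000.0
            ) * alpha
        v_end = v[n_pre + n_step - 1]
        tr = np.arange(n_post) * dt
        v[n_pre + n_step :] = cell.v_rest_mv + (v_end - cell.v_rest_mv) * np.exp(
            -tr / tau_s
        )
        return v

    for i_pa in neg_steps_pa:
        v = rc_response(i_pa)
        if noise_sd_mv > 0:
            v = v + rng.normal(0, noise_sd_mv, n_tot)
        sweeps.append(({"kind": "step", "amplitude_pa": float(i_pa),
                        "onset_s": pre_s, "duration_s": step_duration_s}, v))

    for i_pa in pos_steps_pa:
        i_t = np.zeros(n_tot)
        i_t[n_pre : n_pre + n_step] = i_pa
        v = _spiking_trace(i_t, cell, fs_hz, spike_mode, refractory_s)
        if noise_sd_mv > 0:
            v = v + rng.normal(0, noise_sd_mv, n_tot)
        sweeps.append(({"kind": "step", "amplitude_pa": float(i_pa),
                        "onset_s": pre_s, "duration_s": step_duration_s}, v))

    n_ramp = int(round(ramp_duration_s * fs_hz))
    i_t = np.concatenate(
        [np.zeros(n_pre), np.linspace(0, ramp_max_pa, n_ramp), np.zeros(n_post)]
    )
    v = _spiking_trace(i_t, cell, fs_hz, spike_mode, refractory_s)
    if noise_sd_mv > 0:
        v = v + rng.normal(0, noise_sd_mv, v.size)
    sweeps.append(({"kind": "ramp", "onset_s": pre_s,
                    "duration_s": ramp_duration_s,
                    "slope_pa_per_s": ramp_max_pa / ramp_duration_s,
                    "max_pa": ramp_max_pa}, v))
    return EphysProtocol(sweeps=sweeps, mode="current_clamp", fs_hz=fs_hz)


def _spiking_trace(
    i_pa: np.ndarray,
    cell: CellParams,
    fs_hz: float,
    spike_mode: str,
    refractory_s: float,
) -> np.ndarray:
    """Leaky integrate-and-fire voltage for an arbitrary current waveform."""
    dt = 1.0 / fs_hz
    tau_s = cell.tau_ms / 1000.0
    n = i_pa.size
    v = np.full(n, cell.v_rest_mv)
    n_ref = max(1, int(round(refractory_s * fs_hz)))
    n_spk = max(1, int(round(0.001 * fs_hz)))  # 1 ms spike waveform
    vm = cell.v_rest_mv
    k = 1
    while k < n:
        if spike_mode == "instantaneous":
            vm = cell.v_rest_mv + i_pa[k] * cell.r_mohm / 1000.0
            v[k] = min(vm, cell.v_thresh_mv)
        else:
            vm = vm + dt / tau_s * (
                cell.v_rest_mv - vm + i_pa[k] * cell.r_mohm / 1000.0
            )
            v[k] = vm
        if vm >= cell.v_thresh_mv:
            v[k : k + n_spk] = 30.0  # stereotyped spike crossing 0 mV
            k += n_spk
            if k < n:
                v[k : k + n_ref] = cell.v_rest_mv
            vm = cell.v_rest_mv
            k += n_ref
        else:
            k += 1
    return v


def generate_psc_train(
    synapse: SynapseParams,
    fs_hz: float = 20000.0,
    n_sweeps: int = 10,
    n_pulses: int = 5,
    inter_pulse_s: float = 0.1,
    pre_s: float = 0.1,
    post_s: float = 0.15,
    rise_tau_s: float = 0.0015,
    decay_tau_s: float = 0.012,
    latency_s: float = 0.002,
    polarity: int = -1,
    noise_sd_pa: float = 0.0,
    drift_slope_pa_s: float = 0.0,
    seed: int = 0,
) -> EphysProtocol:
    """Voltage-clamp PSC train: ``n_sweeps`` sweeps of 5 pulses at 10 Hz.

    Each PSC is a difference-of-exponentials kernel scaled to the per-pulse
    peak amplitude from :meth:`SynapseParams.pulse_amplitudes` (inward
    currents are negative by convention at -60 mV holding). Optional
    additive noise and a linear baseline drift exercise the robust drift
    correction downstream.
    """
    amps = synapse.pulse_amplitudes(n_pulses, inter_pulse_s)
    rng = np.random.default_rng(seed)
    duration = pre_s + (n_pulses - 1) * inter_pulse_s + post_s
    n = int(round(duration * fs_hz))
    t = np.arange(n) / fs_hz
    onsets = pre_s + np.arange(n_pulses) * inter_pulse_s
    # normalized difference-of-exponentials kernel (unit peak)
    tk = np.arange(0.0, 8.0 * decay_tau_s, 1.0 / fs_hz)
    kern = np.exp(-tk / decay_tau_s) - np.exp(-tk / rise_tau_s)
    kern /= kern.max()
    sweeps = []
    for _ in range(n_sweeps):
        trace = np.zeros(n)
        for onset, amp in zip(onsets, amps):
            i0 = int(round((onset + latency_s) * fs_hz))
            seg = kern[: max(0, n - i0)]
            trace[i0 : i0 + seg.size] += polarity * amp * seg
        if drift_slope_pa_s != 0.0:
            trace = trace + drift_slope_pa_s * t
        if noise_sd_pa > 0:
            trace = trace + rng.normal(0, noise_sd_pa, n)
        sweeps.append(
            (
                {
                    "kind": "psc_train",
                    "pulse_onsets_s": onsets.tolist(),
                    "pulse_width_s": 0.001,
                    "amplitudes_pa": amps.tolist(),
                },
                trace,
            )
        )
    return EphysProtocol(sweeps=sweeps, mode="voltage_clamp", fs_hz=fs_hz)
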