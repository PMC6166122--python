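"""Synthetic driving-session generator.

Emulates a fixed-base driving-simulator study in which an automated ego car
(100 km/h) repeatedly closes in on a lead truck (80 km/h), brakes very late
(9 m gap) down to a minimum gap of 4.2 m, falls back to 100 m, and repeats —
three approaches per ~3-minute trip.  Participants report discomfort by
pressing a handset lever; the generator emits the handset channel plus the
full multi-rate sensor suite (smartband HR/IBI/skin-resistance/accelerometer/
gyroscope at 10 Hz, eye-tracker pupils/blinks/scene luminance at 60 Hz,
motion-capture shoulder position at 120 Hz, seat-pressure mat at 10 Hz)
with configurable event-locked effect templates.

All randomness flows from a single integer seed; identical (config, seed)
yields bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import signal

KMH_TO_MS = 1.0 / 3.6

#: Native logging rates (Hz) of the five sensor groups.
GROUP_RATES = {
    "simulator": 60.0,
    "band": 10.0,
    "eyetracker": 60.0,
    "motion": 120.0,
    "pressure_mat": 10.0,
}

#: Channel name -> (sensor group, unit).  Event streams are listed separately.
CHANNEL_INVENTORY = {
    "handset": ("simulator", "fraction"),
    "gap": ("simulator", "m"),
    "ego_speed": ("simulator", "m/s"),
    "lead_speed": ("simulator", "m/s"),
    "pupil_left": ("eyetracker", "mm"),
    "pupil_right": ("eyetracker", "mm"),
    "scene_luminance": ("eyetracker", "lum"),
    "hr": ("band", "bpm"),
    "ibi": ("band", "s"),
    "skin_resistance": ("band", "kOhm"),
    "accel_x": ("band", "g"),
    "accel_y": ("band", "g"),
    "accel_z": ("band", "g"),
    "gyro_x": ("band", "deg/s"),
    "gyro_y": ("band", "deg/s"),
    "gyro_z": ("band", "deg/s"),
    "shoulder_x": ("motion", "mm"),
    "shoulder_y": ("motion", "mm"),
    "shoulder_z": ("motion", "mm"),
    **{f"seat_{i}": ("pressure_mat", "au") for i in range(1, 8)},
    "seat_back": ("pressure_mat", "au"),
}

EVENT_STREAMS = {"blinks": ("eyetracker", "s")}


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Longitudinal kinematics of the repeated truck-approach scenario.

    Defaults are the study conditions: ego 100 km/h, lead 80 km/h, automated
    braking from a 9 m gap down to a 4.2 m minimum, fallback to 100 m,
    three approaches in a ~180 s trip sampled at the 60 Hz simulator clock.
    """

    ego_speed_kmh: float = 100.0
    lead_speed_kmh: float = 80.0
    brake_onset_gap_m: float = 9.0
    min_gap_m: float = 4.2
    reset_gap_m: float = 100.0
    approaches_per_trip: int = 3
    trip_duration_s: float = 180.0
    master_rate_hz: float = 60.0
    dwell_s: float = 3.0  # time spent at the minimum gap before falling back

    def __post_init__(self) -> None:
        if self.ego_speed_kmh < self.lead_speed_kmh:
            raise ConfigError("ego_speed must be >= lead_speed")
        if not (0.0 < self.min_gap_m < self.brake_onset_gap_m < self.reset_gap_m):
            raise ConfigError(
                "require 0 < min_gap < brake_onset_gap < reset_gap, got "
                f"{self.min_gap_m}, {self.brake_onset_gap_m}, {self.reset_gap_m}"
            )
        if self.master_rate_hz <= 0:
            raise ConfigError("master_rate must be positive")
        if self.approaches_per_trip < 0:
            raise ConfigError("approaches_per_trip must be non-negative")

    @property
    def closing_speed_ms(self) -> float:
        return (self.ego_speed_kmh - self.lead_speed_kmh) * KMH_TO_MS


@dataclass(frozen=True)
class ResponseConfig:
    """Behavioural and physiological response templates.

    The defaults encode the reported effect structure: presses in
    208/240 ≈ 0.867 of approaches, right-skewed press durations with mean
    8.10 s and SD 5.52 s, blink rates 0.25/0.17/0.37 per second
    before/during/after an episode, HR deceleration plateauing mid-episode
    and recovering ~5 s after release, reduced high-frequency IBI
    variability (RMSSD) during episodes, SCL linear drift with movement
    artifacts, and a pushback (shoulder-z drop, back-sensor pressure rise).
    """

    press_probability: float = 208.0 / 240.0
    press_duration_mean_s: float = 8.10
    press_duration_sd_s: float = 5.52
    press_onset_lag_s: float = -3.0  # relative to brake onset; jittered
    press_onset_jitter_s: float = 0.5
    min_press_duration_s: float = 0.5

    blink_rate_pre: float = 0.25
    blink_rate_during: float = 0.17
    blink_rate_post: float = 0.37
    blink_duration_s: float = 0.120
    post_phase_s: float = 10.0  # elevated blink rate persists this long

    pupil_baseline_mm: float = 3.5
    pupil_dilation_amplitude_mm: float = 0.30
    luminance_coupling_gain: float = 1.5  # mm per luminance unit (operational)
    luminance_base: float = 0.45
    luminance_truck_amplitude: float = 0.15
    luminance_ambient_sd: float = 0.08
    luminance_ambient_tau_s: float = 20.0

    hr_baseline_bpm: float = 72.0
    hr_deceleration_amplitude_bpm: float = 5.0
    hr_recovery_delay_s: float = 5.0
    hr_recovery_ramp_s: float = 2.0

    rmssd_baseline_s: float = 0.045
    rmssd_suppression_factor: float = 0.5  # multiplies HF variability during

    scl_baseline_uS: float = 2.0
    scl_drift_rate_uS_per_s: float = 0.010
    artifact_rate_per_min: float = 2.0
    artifact_duration_s: float = 1.5
    artifact_amplitude_uS: float = 0.6

    pushback_amplitude_mm: float = 15.0
    pressure_baseline: float = 300.0
    pressure_amplitude: float = 50.0

    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "pupil": 0.05,
            "hr": 1.0,
            "scl": 0.02,
            "accel": 0.01,
            "gyro": 1.0,
            "shoulder": 1.0,
            "pressure": 5.0,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.press_probability <= 1.0:
            raise ConfigError("press_probability must lie in [0, 1]")
        if not 0.0 <= self.rmssd_suppression_factor <= 1.0:
            raise ConfigError("rmssd_suppression_factor must lie in [0, 1]")
        for name in ("blink_rate_pre", "blink_rate_during", "blink_rate_post"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ConfigError(f"{f.name} must be finite")

    @classmethod
    def zero_effect(cls, **overrides) -> "ResponseConfig":
        """All event-locked effect amplitudes zeroed: every channel becomes
        stationary baseline + noise (handset presses still occur)."""
        base = dict(
            blink_rate_during=0.25,
            blink_rate_post=0.25,
            pupil_dilation_amplitude_mm=0.0,
            luminance_coupling_gain=0.0,
            luminance_truck_amplitude=0.0,
            hr_deceleration_amplitude_bpm=0.0,
            rmssd_suppression_factor=1.0,
            scl_drift_rate_uS_per_s=0.0,
            artifact_rate_per_min=0.0,
            pushback_amplitude_mm=0.0,
            pressure_amplitude=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class KinematicTrace:
    """Per-master-tick longitudinal kinematics of one trip."""

    time_s: np.ndarray
    gap_m: np.ndarray
    ego_speed_ms: np.ndarray
    lead_speed_ms: np.ndarray
    ttc_s: np.ndarray  # NaN when not closing
    brake_onsets_s: list[float]
    approach_starts_s: list[float]
    config: ScenarioConfig


@dataclass
class Channel:
    """One sensor stream: strictly increasing timestamps and values."""

    name: str
    unit: str
    rate_hz: float
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError(f"channel {self.name}: timestamp/value length mismatch")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"channel {self.name}: timestamps not strictly increasing")
        if self.rate_hz <= 0:
            raise ValueError(f"channel {self.name}: rate must be positive")


@dataclass
class EventStream:
    """Point events with durations (e.g. blinks): onset + duration per event."""

    name: str
    onsets_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)


# ---------------------------------------------------------------------------
# scenario kinematics
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig) -> KinematicTrace:
    """Simulate the repeated approach–brake–fallback cycle.

    The gap trajectory is piecewise analytic: uniform closing at the
    configured relative speed down to the brake-onset gap, then constant
    deceleration chosen so that the relative speed is nulled exactly at the
    minimum gap, a dwell at the minimum, and a symmetric fallback to the
    reset gap.  Sampling the closed form at each master tick keeps the
    trace deterministic and integration-error-free up to tick quantization.
    """
    fs = config.master_rate_hz
    n = int(round(config.trip_duration_s * fs))
    t = np.arange(n) / fs

    v_rel = config.closing_speed_ms
    gap = np.full(n, config.reset_gap_m)
    rel_speed = np.zeros(n)  # ego − lead

    brake_onsets: list[float] = []
    approach_starts: list[float] = []

    if v_rel > 0 and config.approaches_per_trip > 0:
        d_close = config.reset_gap_m - config.brake_onset_gap_m
        t_close = d_close / v_rel
        d_brake = config.brake_onset_gap_m - config.min_gap_m
        a = v_rel**2 / (2.0 * d_brake)  # constant deceleration
        t_brake = v_rel / a
        t_dwell = config.dwell_s
        t_open = (config.reset_gap_m - config.min_gap_m) / v_rel
        cycle = t_close + t_brake + t_dwell + t_open

        for k in range(config.approaches_per_trip):
            t0 = k * cycle
            if t0 >= config.trip_duration_s:
                break
            approach_starts.append(t0)
            brake_onsets.append(t0 + t_close)
            tau = t - t0
            # closing phase
            m = (tau >= 0) & (tau < t_close)
            gap[m] = config.reset_gap_m - v_rel * tau[m]
            rel_speed[m] = v_rel
            # braking phase
            m = (tau >= t_close) & (tau < t_close + t_brake)
            tb = tau[m] - t_close
            gap[m] = config.brake_onset_gap_m - v_rel * tb + 0.5 * a * tb**2
            rel_speed[m] = v_rel - a * tb
            # dwell at minimum gap
            m = (tau >= t_close + t_brake) & (tau < t_close + t_brake + t_dwell)
            gap[m] = config.min_gap_m
            rel_speed[m] = 0.0
            # fallback to reset gap (constant opening speed)
            m = (tau >= t_close + t_brake + t_dwell) & (tau < cycle)
            to = tau[m] - (t_close + t_brake + t_dwell)
            gap[m] = np.minimum(config.min_gap_m + v_rel * to, config.reset_gap_m)
            rel_speed[m] = np.where(
                config.min_gap_m + v_rel * to < config.reset_gap_m, -v_rel, 0.0
            )

    lead = np.full(n, config.lead_speed_kmh * KMH_TO_MS)
    ego = lead + rel_speed
    with np.errstate(divide="ignore", invalid="ignore"):
        ttc = np.where(rel_speed > 0, gap / rel_speed, np.nan)

    return KinematicTrace(
        time_s=t,
        gap_m=gap,
        ego_speed_ms=ego,
        lead_speed_ms=lead,
        ttc_s=ttc,
        brake_onsets_s=brake_onsets,
        approach_starts_s=approach_starts,
        config=config,
    )


# ---------------------------------------------------------------------------
# handset behaviour
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) of a log-normal with the given mean and SD."""
    var = sd**2
    sigma2 = math.log(1.0 + var / mean**2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def simulate_handset(
    kin: KinematicTrace, rc: ResponseConfig, rng: np.random.Generator
) -> Channel:
    """Generate the graded handset-lever channel on the master timeline.

    Each approach elicits, with ``press_probability``, one press episode:
    onset near brake onset plus a jittered lag, log-normal duration
    (truncated above ``min_press_duration_s``), magnitude a smooth
    raised-cosine ramp into (0, 1] and back.
    """
    t = kin.time_s
    fs = kin.config.master_rate_hz
    values = np.zeros_like(t)
    mu, sigma = _lognormal_params(rc.press_duration_mean_s, rc.press_duration_sd_s)

    for brake_t in kin.brake_onsets_s:
        if rng.random() >= rc.press_probability:
            continue
        onset = brake_t + rc.press_onset_lag_s + rng.normal(0.0, rc.press_onset_jitter_s)
        onset = max(onset, 0.0)
        duration = float(rng.lognormal(mu, sigma))
        while duration <= rc.min_press_duration_s:
            duration = float(rng.lognormal(mu, sigma))
        offset = min(onset + duration, t[-1])
        if offset - onset <= rc.min_press_duration_s:
            continue
        m = (t >= onset) & (t <= offset)
        tau = t[m] - onset
        dur = offset - onset
        ramp = min(1.0, dur / 4.0)  # ramp up/down time, s
        mag = np.ones_like(tau)
        up = tau < ramp
        mag[up] = 0.5 - 0.5 * np.cos(np.pi * tau[up] / ramp)
        down = tau > dur - ramp
        mag[down] = 0.5 - 0.5 * np.cos(np.pi * (dur - tau[down]) / ramp)
        # keep clearly above quantization noise over the closed episode so
        # threshold-based extraction recovers the full span
        values[m] = np.maximum(values[m], np.maximum(mag, 0.05))

    return Channel("handset", "fraction", fs, t, values)


def _press_episodes(handset: Channel) -> list[tuple[float, float]]:
    """(onset, offset) spans where the handset channel is positive."""
    pos = handset.values > 0
    if not pos.any():
        return []
    d = np.diff(pos.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if pos[0]:
        starts = np.r_[0, starts]
    if pos[-1]:
        ends = np.r_[ends, pos.size - 1]
    return [(handset.timestamps[s], handset.timestamps[e]) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

def _inverse_u(tau: np.ndarray, duration: float) -> np.ndarray:
    """Smooth 0→1→0 template over an episode (half-sine)."""
    return np.sin(np.pi * np.clip(tau / duration, 0.0, 1.0))


def _hr_template(t: np.ndarray, episodes, rc: ResponseConfig) -> np.ndarray:
    """Deceleration depth in [0, 1]: ramp to a plateau at mid-episode, hold
    until ``hr_recovery_delay_s`` after release, then ramp back."""
    g = np.zeros_like(t)
    for onset, offset in episodes:
        dur = offset - onset
        mid = onset + 0.5 * dur
        hold_end = offset + rc.hr_recovery_delay_s
        ramp_end = hold_end + rc.hr_recovery_ramp_s
        seg = np.zeros_like(t)
        m = (t >= onset) & (t < mid)
        seg[m] = (t[m] - onset) / max(mid - onset, 1e-9)
        seg[(t >= mid) & (t < hold_end)] = 1.0
        m = (t >= hold_end) & (t < ramp_end)
        seg[m] = 1.0 - (t[m] - hold_end) / rc.hr_recovery_ramp_s
        g = np.maximum(g, seg)
    return g


def _blink_onsets(
    trip_end: float, episodes, rc: ResponseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous renewal process via thinning of a dominating Poisson."""
    rates = (rc.blink_rate_pre, rc.blink_rate_during, rc.blink_rate_post)
    rmax = max(rates)
    if rmax <= 0:
        return np.array([])
    onsets = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rmax)
        if t >= trip_end:
            break
        phase = 0
        for onset, offset in episodes:
            if onset <= t < offset:
                phase = 1
                break
            if offset <= t < offset + rc.post_phase_s:
                phase = 2
        if rng.random() < rates[phase] / rmax:
            onsets.append(t)
    return np.asarray(onsets)


def simulate_physiology(
    kin: KinematicTrace,
    handset: Channel,
    rc: ResponseConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, Channel], dict[str, EventStream]]:
    """Generate all physiological channels at their native rates.

    Effects are locked to the handset press episodes: inverse-U pupil
    dilation (plus a luminance-coupled component from the looming truck),
    phase-dependent blink rate, HR deceleration with mid-episode plateau and
    delayed recovery, RMSSD suppression in the beat-to-beat IBI series,
    SCL drift with movement artifacts mirrored in the accelerometer and
    gyroscope, shoulder-z pushback, and back-sensor seat pressure increase.
    """
    cfg = kin.config
    trip_end = float(kin.time_s[-1]) + 1.0 / cfg.master_rate_hz
    episodes = _press_episodes(handset)
    nsd = rc.noise_sd
    channels: dict[str, Channel] = {}

    def grid(rate: float) -> np.ndarray:
        return np.arange(int(round(trip_end * rate))) / rate

    # --- scene luminance (60 Hz, eye-tracker front camera): ambient scene
    # lightness with slow drift plus a truck component affine in 1/gap
    # (the white truck fills more of the view as it looms), on [0, 1].
    t60 = grid(GROUP_RATES["eyetracker"])
    gap60 = np.interp(t60, kin.time_s, kin.gap_m)
    inv = 1.0 / gap60
    lo, hi = 1.0 / cfg.reset_gap_m, 1.0 / cfg.min_gap_m
    truck_shape = np.clip((inv - lo) / (hi - lo), 0.0, 1.0)
    dt = 1.0 / GROUP_RATES["eyetracker"]
    rho = math.exp(-dt / rc.luminance_ambient_tau_s)
    innov = rng.normal(0.0, 1.0, t60.size)
    ambient = signal.lfilter([1.0], [1.0, -rho], innov * math.sqrt(1.0 - rho**2))
    ambient *= rc.luminance_ambient_sd
    lum = np.clip(
        rc.luminance_base + rc.luminance_truck_amplitude * truck_shape + ambient,
        0.0,
        1.0,
    )
    channels["scene_luminance"] = Channel("scene_luminance", "lum", 60.0, t60, lum)

    # --- blinks + binocular pupil diameters (60 Hz)
    blink_on = _blink_onsets(trip_end, episodes, rc, rng)
    blink_dur = np.full(blink_on.size, rc.blink_duration_s)
    events = {"blinks": EventStream("blinks", blink_on, blink_dur)}

    dil = np.zeros_like(t60)
    for onset, offset in episodes:
        m = (t60 >= onset) & (t60 < offset)
        dil[m] = np.maximum(dil[m], _inverse_u(t60[m] - onset, offset - onset))
    pupil_mean = (
        rc.pupil_baseline_mm
        + rc.pupil_dilation_amplitude_mm * dil
        + rc.luminance_coupling_gain * lum
    )
    in_blink = np.zeros(t60.size, dtype=bool)
    for on, du in zip(blink_on, blink_dur):
        in_blink |= (t60 >= on) & (t60 < on + du)
    for side in ("left", "right"):
        v = pupil_mean + rng.normal(0.0, nsd["pupil"], t60.size)
        v[in_blink] = np.nan
        channels[f"pupil_{side}"] = Channel(f"pupil_{side}", "mm", 60.0, t60, v)

    # --- smartband (10 Hz): HR, IBI, skin resistance, accel, gyro
    t10 = grid(GROUP_RATES["band"])
    depth = _hr_template(t10, episodes, rc)
    hr = (
        rc.hr_baseline_bpm
        - rc.hr_deceleration_amplitude_bpm * depth
        + rng.normal(0.0, nsd["hr"], t10.size)
    )
    channels["hr"] = Channel("hr", "bpm", 10.0, t10, hr)

    # per-beat IBI, then logged at 10 Hz with last-value repetition
    beat_times, beat_ibis = [], []
    tb = 0.0
    hf_sd = rc.rmssd_baseline_s / math.sqrt(2.0)
    while tb < trip_end:
        mean_ibi = 60.0 / (
            rc.hr_baseline_bpm
            - rc.hr_deceleration_amplitude_bpm
            * float(np.interp(tb, t10, depth))
        )
        during = any(on <= tb < off for on, off in episodes)
        sd = hf_sd * (rc.rmssd_suppression_factor if during else 1.0)
        ibi = max(mean_ibi + rng.normal(0.0, sd), 0.3)
        beat_times.append(tb)
        beat_ibis.append(ibi)
        tb += ibi
    beat_times_a = np.asarray(beat_times)
    beat_ibis_a = np.asarray(beat_ibis)
    idx = np.searchsorted(beat_times_a, t10, side="right") - 1
    idx = np.clip(idx, 0, beat_ibis_a.size - 1)
    channels["ibi"] = Channel("ibi", "s", 10.0, t10, beat_ibis_a[idx])

    # SCL with drift + step artifacts; log as skin resistance (kOhm)
    scl = (
        rc.scl_baseline_uS
        + rc.scl_drift_rate_uS_per_s * t10
        + rng.normal(0.0, nsd["scl"], t10.size)
    )
    accel = rng.normal(0.0, nsd["accel"], (t10.size, 3))
    accel[:, 2] += 1.0  # gravity
    gyro = rng.normal(0.0, nsd["gyro"], (t10.size, 3))
    n_art = rng.poisson(rc.artifact_rate_per_min * trip_end / 60.0)
    artifact_mask = np.zeros(t10.size, dtype=bool)
    for t_art in np.sort(rng.uniform(0.0, trip_end, n_art)):
        m = (t10 >= t_art) & (t10 < t_art + rc.artifact_duration_s)
        scl[m] += rc.artifact_amplitude_uS * rng.choice([-1.0, 1.0])
        accel[m, 0] += rng.normal(0.5, 0.1)
        gyro[m, 1] += rng.normal(120.0, 20.0)
        artifact_mask |= m
    channels["skin_resistance"] = Channel(
        "skin_resistance", "kOhm", 10.0, t10, 1000.0 / np.maximum(scl, 1e-6)
    )
    for i, ax in enumerate("xyz"):
        channels[f"accel_{ax}"] = Channel(f"accel_{ax}", "g", 10.0, t10, accel[:, i])
        channels[f"gyro_{ax}"] = Channel(f"gyro_{ax}", "deg/s", 10.0, t10, gyro[:, i])

    # --- motion capture (120 Hz): shoulder position, z-axis pushback
    t120 = grid(GROUP_RATES["motion"])
    push = np.zeros_like(t120)
    for onset, offset in episodes:
        m = (t120 >= onset) & (t120 < offset)
        push[m] = np.maximum(push[m], _inverse_u(t120[m] - onset, offset - onset))
    base_xyz = (150.0, -80.0, 1250.0)  # arbitrary rig origin, mm
    for i, ax in enumerate("xyz"):
        amp = -rc.pushback_amplitude_mm if ax == "z" else 0.3 * rc.pushback_amplitude_mm
        v = base_xyz[i] + amp * push + rng.normal(0.0, nsd["shoulder"], t120.size)
        channels[f"shoulder_{ax}"] = Channel(f"shoulder_{ax}", "mm", 120.0, t120, v)

    # --- seat pressure mat (10 Hz): 8 sensors, back sensor carries the effect
    push10 = np.interp(t10, t120, push)
    for name in [f"seat_{i}" for i in range(1, 8)] + ["seat_back"]:
        amp = rc.pressure_amplitude if name == "seat_back" else 0.0
        v = (
            rc.pressure_baseline
            + amp * push10
            + rng.normal(0.0, nsd["pressure"], t10.size)
        )
        channels[name] = Channel(name, "au", 10.0, t10, v)

    return channels, events


# ---------------------------------------------------------------------------
# whole-trip convenience + study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Bookkeeping of the repeated-measures design."""

    participants: int = 40
    sessions_per_participant: int = 2
    approaches_per_trip: int = 3

    @property
    def scheduled_approaches(self) -> int:
        return self.participants * self.sessions_per_participant * self.approaches_per_trip


def simulate_trip(
    scenario: ScenarioConfig | None = None,
    response: ResponseConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, Channel], dict[str, EventStream], KinematicTrace]:
    """Generate one complete trip: kinematics, handset and all sensors."""
    scenario = scenario or ScenarioConfig()
    response = response or ResponseConfig()
    rng = np.random.default_rng(seed)
    kin = simulate_scenario(scenario)
    handset = simulate_handset(kin, response, rng)
    channels, events = simulate_physiology(kin, handset, response, rng)
    channels["handset"] = handset
    channels["gap"] = Channel("gap", "m", scenario.master_rate_hz, kin.time_s, kin.gap_m)
    channels["ego_speed"] = Channel(
        "ego_speed", "m/s", scenario.master_rate_hz, kin.time_s, kin.ego_speed_ms
    )
    channels["lead_speed"] = Channel(
        "lead_speed", "m/s", scenario.master_rate_hz, kin.time_s, kin.lead_speed_ms
    )
    return channels, events, kin


# ---------------------------------------------------------------------------
# session I/O
# ---------------------------------------------------------------------------

def write_session(
    out_dir: str | Path,
    channels: Mapping[str, Channel],
    events: Mapping[str, EventStream] | None = None,
    *,
    participant: str = "p00",
    session: str = "s1",
    seed: int | None = None,
    config: Mapping | None = None,
) -> Path:
    """Write one session: a CSV per channel plus a YAML manifest.

    Channel CSVs have header ``timestamp_s,value``; event streams
    ``onset_s,duration_s``.  The manifest records ids, rates, units, the
    seed and the generator configuration so a session is fully reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "participant": participant,
        "session": session,
        "seed": seed,
        "group_rates_hz": dict(GROUP_RATES),
        "channels": {},
        "event_streams": {},
    }
    if config is not None:
        manifest["config"] = {
            k: (dict(v) if isinstance(v, Mapping) else v) for k, v in config.items()
        }
    for name, ch in channels.items():
        fname = f"{name}.csv"
        pd.DataFrame({"timestamp_s": ch.timestamps, "value": ch.values}).to_csv(
            out / fname, index=False
        )
        manifest["channels"][name] = {
            "file": fname,
            "unit": ch.unit,
            "rate_hz": ch.rate_hz,
        }
    for name, ev in (events or {}).items():
        fname = f"{name}.csv"
        pd.DataFrame({"onset_s": ev.onsets_s, "duration_s": ev.durations_s}).to_csv(
            out / fname, index=False
        )
        manifest["event_streams"][name] = {"file": fname}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def config_as_dict(
    scenario: ScenarioConfig, response: ResponseConfig
) -> dict[str, dict]:
    sc = dataclasses.asdict(scenario)
    rc = dataclasses.asdict(response)
    rc["noise_sd"] = dict(rc["noise_sd"])
    return {"scenario": sc, "response": rc}
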