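"""Sliding-window online discomfort detector (prototype).

Real-time detection cannot z-score whole sequences, so each monitored
channel is standardized against its own recent history: the current value
is compared with the mean and SD of sliding baseline windows (defaults:
10 s ending 3 s before now and 5 s ending 5 s before now).  A channel
contributes binary evidence when its sliding z crosses a directional
threshold (default 0.3 SD, e.g. an HR *decrease* of 0.3 SD-units); the
per-channel evidences are fused by a transparent weighted vote into a
discomfort score, and sustained above-threshold score runs become detected
episodes.  Skin conductance is excluded from the default channel set (it
showed no event-locked change).  The whole chain is causal: output up to
time t never depends on samples after t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ingest import SessionRecording
from .events import DiscomfortInterval


@dataclass(frozen=True)
class ChannelRule:
    """Directional threshold and fusion weight for one monitored channel."""

    direction: int  # +1: evidence when z >= threshold; -1: when z <= -threshold
    threshold_sd: float = 0.3
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.threshold_sd < 0 or self.weight < 0:
            raise ValueError("threshold and weight must be non-negative")


@dataclass
class DetectorConfig:
    """Sliding-window detector parameters.

    ``windows`` are (length_s, onset_before_now_s) baseline windows; a
    channel's evidence fires if its sliding z crosses the rule threshold in
    *any* window.  Weights are normalized to sum to one.  The HR threshold
    (−0.3 SD) follows the reported configuration sketch; the remaining
    directions follow the expected effect table with the same magnitude.
    """

    channels: dict[str, ChannelRule] = field(
        default_factory=lambda: {
            "pupil": ChannelRule(+1, 0.3, 0.25),
            "hr": ChannelRule(-1, 0.3, 0.25),
            "shoulder_z": ChannelRule(-1, 0.3, 0.25),
            "seat_back": ChannelRule(+1, 0.3, 0.25),
        }
    )
    windows: tuple[tuple[float, float], ...] = ((10.0, 3.0), (5.0, 5.0))
    score_threshold: float = 0.5
    min_duration_s: float = 3.0
    refractory_s: float = 20.0
    smooth_s: float = 0.3  # causal (trailing) moving average before z-scoring

    def __post_init__(self) -> None:
        for length, onset in self.windows:
            if length <= 0:
                raise ValueError("window length must be positive")
            if onset < 0:
                raise ValueError("window onset must be non-negative")
        total = sum(r.weight for r in self.channels.values())
        if total <= 0:
            raise ValueError("fusion weights must sum to a positive value")
        self.channels = {
            name: ChannelRule(r.direction, r.threshold_sd, r.weight / total)
            for name, r in self.channels.items()
        }

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "channels": {
                n: {"direction": r.direction, "threshold_sd": r.threshold_sd,
                    "weight": r.weight}
                for n, r in self.channels.items()
            },
            "windows": [list(w) for w in self.windows],
            "score_threshold": self.score_threshold,
            "min_duration_s": self.min_duration_s,
            "refractory_s": self.refractory_s,
            "smooth_s": self.smooth_s,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorConfig":
        doc = yaml.safe_load(Path(path).read_text())
        channels = {
            n: ChannelRule(int(c["direction"]), float(c["threshold_sd"]),
                           float(c["weight"]))
            for n, c in doc["channels"].items()
        }
        return cls(
            channels=channels,
            windows=tuple(tuple(w) for w in doc["windows"]),
            score_threshold=float(doc["score_threshold"]),
            min_duration_s=float(doc["min_duration_s"]),
            refractory_s=float(doc["refractory_s"]),
            smooth_s=float(doc.get("smooth_s", 1.0)),
        )


@dataclass
class DetectedEpisode:
    onset_s: float
    offset_s: float
    peak_score: float
    channels: tuple[str, ...]


@dataclass
class DetectionResult:
    timestamps: np.ndarray
    score: np.ndarray
    episodes: list[DetectedEpisode]


# ---------------------------------------------------------------------------
# sliding-window standardization
# ---------------------------------------------------------------------------

def _window_sums(timestamps, values, lo_times, hi_times):
    """Sums, sums of squares and counts of non-missing samples with
    timestamps in [lo, hi] per query (inclusive bounds, causal use only)."""
    ok = ~np.isnan(values)
    v = np.where(ok, values, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v**2)])
    cn = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    lo = np.searchsorted(timestamps, lo_times, side="left")
    hi = np.searchsorted(timestamps, hi_times, side="right")
    return cs[hi] - cs[lo], cs2[hi] - cs2[lo], cn[hi] - cn[lo]


def sliding_z(
    values: np.ndarray,
    timestamps: np.ndarray,
    window_length_s: float,
    onset_before_now_s: float,
    min_samples: int = 5,
) -> np.ndarray:
    """Standardize each sample against a trailing baseline window.

    The baseline at time t is the span [t − onset − length, t − onset]:
    strictly causal.  Output is missing where the window holds fewer than
    ``min_samples`` non-missing values or where the current value is
    missing; a zero-SD window yields 0 (degenerate rule, as in whole-scope
    z-scoring).
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    lo = t - onset_before_now_s - window_length_s
    hi = t - onset_before_now_s
    s, s2, n = _window_sums(t, v, lo, hi)
    out = np.full(v.size, np.nan)
    ok = (n >= min_samples) & ~np.isnan(v)
    nn = n[ok].astype(float)
    mean = s[ok] / nn
    var = np.maximum(s2[ok] - nn * mean**2, 0.0) / (nn - 1.0)
    sd = np.sqrt(var)
    z = np.zeros(mean.size)
    pos = sd > 0
    z[pos] = (v[ok][pos] - mean[pos]) / sd[pos]
    out[ok] = z
    return out


def causal_smooth(values: np.ndarray, timestamps: np.ndarray, span_s: float) -> np.ndarray:
    """Trailing moving mean over (t − span, t], ignoring missing samples."""
    if span_s <= 0:
        return np.asarray(values, dtype=float).copy()
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    s, _, n = _window_sums(t, v, t - span_s + 1e-12, t)
    out = np.full(v.size, np.nan)
    nz = n > 0
    out[nz] = s[nz] / n[nz]
    return out


# ---------------------------------------------------------------------------
# detection & evaluation
# ---------------------------------------------------------------------------

def prepare_monitor_inputs(rec: SessionRecording) -> pd.DataFrame:
    """Derive the default monitored series from a joined recording.

    pupil = pointwise binocular mean of the two eye columns; hr,
    shoulder_z and seat_back pass through.  All derivations are pointwise,
    keeping the detector chain causal.
    """
    out = {"timestamp_s": rec.timestamps}
    cols = rec.data
    if "pupil_left" in cols and "pupil_right" in cols:
        l = cols["pupil_left"].to_numpy(dtype=float)
        r = cols["pupil_right"].to_numpy(dtype=float)
        n = (~np.isnan(l)).astype(float) + (~np.isnan(r)).astype(float)
        s = np.where(np.isnan(l), 0.0, l) + np.where(np.isnan(r), 0.0, r)
        pupil = np.full(l.shape, np.nan)
        pupil[n > 0] = s[n > 0] / n[n > 0]
        out["pupil"] = pupil
    for name in ("hr", "shoulder_z", "seat_back"):
        if name in cols:
            out[name] = cols[name].to_numpy(dtype=float)
    return pd.DataFrame(out)


def detect(
    rec: SessionRecording | pd.DataFrame, cfg: DetectorConfig | None = None
) -> DetectionResult:
    """Run the sliding-window detector over one recording.

    Accepts a joined recording (monitored series are derived via
    :func:`prepare_monitor_inputs`) or a ready-made DataFrame with a
    ``timestamp_s`` column plus one column per monitored channel.
    """
    cfg = cfg or DetectorConfig()
    if isinstance(rec, SessionRecording):
        data = prepare_monitor_inputs(rec)
    else:
        data = rec
    missing = [c for c in cfg.channels if c not in data.columns]
    if missing:
        raise KeyError(f"monitored channel(s) missing from recording: {missing}")

    t = data["timestamp_s"].to_numpy(dtype=float)
    score = np.zeros(t.size)
    evidence: dict[str, np.ndarray] = {}
    for name, rule in cfg.channels.items():
        x = causal_smooth(data[name].to_numpy(dtype=float), t, cfg.smooth_s)
        ev = np.zeros(t.size, dtype=bool)
        for length, onset in cfg.windows:
            z = sliding_z(x, t, length, onset)
            with np.errstate(invalid="ignore"):
                ev |= np.where(np.isnan(z), False, rule.direction * z >= rule.threshold_sd)
        evidence[name] = ev
        score += rule.weight * ev

    episodes = _score_to_episodes(t, score, evidence, cfg)
    return DetectionResult(timestamps=t, score=score, episodes=episodes)


def _score_to_episodes(t, score, evidence, cfg) -> list[DetectedEpisode]:
    """Trigger/refractory episode extraction.

    A detection fires once the score has stayed at or above the threshold
    for ``min_duration_s`` (the *confirmed* set); after a trigger the
    detector re-arms only ``refractory_s`` later.  Episode onsets are thus
    at least a refractory period apart, and the episode count equals a
    maximal refractory-separated packing of the confirmed set — a set that
    only shrinks as the threshold rises, which makes the count monotone
    non-increasing in the score threshold by construction.  (Simply taking
    maximal above-threshold runs is *not* monotone: lowering the threshold
    merges runs, so run counts can rise with the threshold.)
    """
    hot = score >= cfg.score_threshold
    if not hot.any():
        return []
    # start time of the contiguous hot run covering each tick
    new_run = hot & ~np.r_[False, hot[:-1]]
    run_start = np.maximum.accumulate(np.where(new_run, t, -np.inf))
    confirmed = hot & (t - run_start >= cfg.min_duration_s)
    if not confirmed.any():
        return []

    # greedy packing: earliest confirmed tick, then next one >= refractory later
    conf_idx = np.flatnonzero(confirmed)
    triggers = [conf_idx[0]]
    for i in conf_idx[1:]:
        if t[i] - t[triggers[-1]] >= cfg.refractory_s:
            triggers.append(i)

    # hot run extents for episode spans
    d = np.diff(hot.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if hot[0]:
        starts = np.r_[0, starts]
    if hot[-1]:
        ends = np.r_[ends, hot.size - 1]

    episodes: list[DetectedEpisode] = []
    for k, trig in enumerate(triggers):
        r = np.searchsorted(starts, trig, side="right") - 1
        s, e = starts[r], ends[r]
        onset = max(t[s], t[trig] - cfg.min_duration_s)
        offset = t[e]
        if k + 1 < len(triggers):  # keep episodes non-overlapping
            offset = min(offset, t[triggers[k + 1]] - cfg.min_duration_s)
        lo, hi = np.searchsorted(t, [onset, offset + 1e-12])
        span = slice(lo, hi)
        trig_ch = tuple(name for name, ev in evidence.items() if ev[span].any())
        episodes.append(
            DetectedEpisode(
                onset_s=float(onset),
                offset_s=float(max(offset, onset)),
                peak_score=float(score[span].max()),
                channels=trig_ch,
            )
        )
    return episodes


@dataclass
class DetectionEvaluation:
    hit_rate: float
    false_alarms_per_min: float
    median_latency_s: float
    n_truth: int
    n_detected: int


def evaluate_detection(
    result: DetectionResult,
    truth: list[DiscomfortInterval],
    min_overlap_frac: float = 0.0,
) -> DetectionEvaluation:
    """Score detected episodes against ground-truth intervals.

    A truth interval is *hit* when some detected episode overlaps it by
    more than ``min_overlap_frac`` of the truth duration (0 = any positive
    overlap).  Latency is the first hitting episode's onset minus the truth
    onset.  Episodes overlapping no truth interval are false alarms,
    reported per minute of recording.
    """
    t = result.timestamps
    total_min = (t[-1] - t[0]) / 60.0 if t.size > 1 else float("nan")

    latencies = []
    hits = 0
    matched = set()
    for iv in truth:
        need = max(min_overlap_frac * iv.duration_s, 0.0)
        best = None
        for k, ep in enumerate(result.episodes):
            ov = min(iv.offset_s, ep.offset_s) - max(iv.onset_s, ep.onset_s)
            if ov > need:
                matched.add(k)
                if best is None or ep.onset_s < best:
                    best = ep.onset_s
        if best is not None:
            hits += 1
            latencies.append(best - iv.onset_s)
    # an episode with any positive truth overlap is not a false alarm
    fa = 0
    for k, ep in enumerate(result.episodes):
        if k in matched:
            continue
        if any(
            min(iv.offset_s, ep.offset_s) - max(iv.onset_s, ep.onset_s) > 0
            for iv in truth
        ):
            continue
        fa += 1

    return DetectionEvaluation(
        hit_rate=hits / len(truth) if truth else float("nan"),
        false_alarms_per_min=fa / total_min if total_min else float("nan"),
        median_latency_s=float(np.median(latencies)) if latencies else float("nan"),
        n_truth=len(truth),
        n_detected=len(result.episodes),
    )
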