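"""Discomfort-interval extraction and percent-scale epoching.

A discomfort interval spans from the first handset sample above threshold to
the last, independent of magnitude.  Each interval anchors a *sequence*: the
10 s before onset, the interval itself, and the 10 s after release.  Because
interval durations vary, every sequence is mapped onto a common 0–300%
axis: slices 1–100 cover the pre window (0.1 s each), 101–200 the interval
(duration/100 each), 201–300 the post window (0.1 s each).  All spans are
half-open [start, end), partitioning the timeline without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import SessionRecording

PRE_POST_S = 10.0
N_SLICES = 300

#: Default extraction parameters (fractions of handset full scale / seconds).
PRESS_THRESHOLD = 0.02
MERGE_GAP_S = 0.3
MIN_DURATION_S = 0.5


@dataclass(frozen=True)
class DiscomfortInterval:
    """One handset press episode."""

    onset_s: float
    offset_s: float
    peak: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError("interval offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class Sequence:
    """A discomfort interval with its pre/post windows and channel slices."""

    interval: DiscomfortInterval
    timestamps: np.ndarray          # master ticks in [onset-10, offset+10)
    channels: pd.DataFrame          # channel values at those ticks
    pre_truncated: bool = False
    post_truncated: bool = False
    overlaps_neighbor: bool = False

    @property
    def onset_s(self) -> float:
        return self.interval.onset_s

    @property
    def offset_s(self) -> float:
        return self.interval.offset_s

    def phase_windows(self) -> dict[str, tuple[float, float]]:
        """Half-open time spans of the pre/during/post phases."""
        iv = self.interval
        return {
            "pre": (iv.onset_s - PRE_POST_S, iv.onset_s),
            "during": (iv.onset_s, iv.offset_s),
            "post": (iv.offset_s, iv.offset_s + PRE_POST_S),
        }

    def phase_mask(self, phase: str) -> np.ndarray:
        lo, hi = self.phase_windows()[phase]
        return (self.timestamps >= lo) & (self.timestamps < hi)


@dataclass
class PercentProfile:
    """A channel resampled onto the 300-slice percent axis."""

    channel: str
    values: np.ndarray              # length 300
    interpolated: np.ndarray        # bool mask of filled (originally empty) slices
    interval: DiscomfortInterval
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (N_SLICES,):
            raise ValueError("percent profile must have exactly 300 slices")


def extract_intervals(
    values: np.ndarray,
    timestamps: np.ndarray,
    press_threshold: float = PRESS_THRESHOLD,
    merge_gap_s: float = MERGE_GAP_S,
    min_duration_s: float = MIN_DURATION_S,
) -> list[DiscomfortInterval]:
    """Extract press episodes from the handset channel.

    Maximal runs of values strictly above ``press_threshold`` become
    intervals (onset = first above-threshold sample, offset = last); runs
    separated by less than ``merge_gap_s`` are merged; merged runs shorter
    than ``min_duration_s`` are dropped.
    """
    values = np.asarray(values, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    above = np.nan_to_num(values, nan=0.0) > press_threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size - 1]

    runs = list(zip(starts, ends))
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if timestamps[s] - timestamps[merged[-1][1]] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        onset, offset = timestamps[s], timestamps[e]
        if offset <= onset or offset - onset < min_duration_s:
            continue
        out.append(
            DiscomfortInterval(onset, offset, peak=float(np.nanmax(values[s : e + 1])))
        )
    return out


def interval_descriptives(intervals: list[DiscomfortInterval]) -> dict[str, float]:
    """Count and mean/SD of durations, the per-figure caption bookkeeping."""
    durs = np.array([iv.duration_s for iv in intervals])
    return {
        "n": int(durs.size),
        "mean_duration_s": float(durs.mean()) if durs.size else float("nan"),
        "sd_duration_s": float(durs.std(ddof=1)) if durs.size > 1 else float("nan"),
    }


def build_sequence(
    rec: SessionRecording,
    interval: DiscomfortInterval,
    neighbors: list[DiscomfortInterval] | None = None,
) -> Sequence:
    """Attach the channel slices of [onset−10 s, offset+10 s) to an interval.

    Windows are clipped at trip boundaries (with truncation flags); samples
    that fall inside a neighbouring press are retained but the overlap is
    flagged.
    """
    t = rec.timestamps
    if interval.onset_s < t[0] - 1e-9 or interval.offset_s > t[-1] + 1e-9:
        raise ValueError("interval lies outside the recording span")
    lo = interval.onset_s - PRE_POST_S
    hi = interval.offset_s + PRE_POST_S
    mask = (t >= lo) & (t < hi)
    sub = rec.data.loc[mask].reset_index(drop=True)

    overlaps = False
    for nb in neighbors or []:
        if nb.onset_s == interval.onset_s and nb.offset_s == interval.offset_s:
            continue
        if nb.onset_s < hi and nb.offset_s > lo:
            overlaps = True
    return Sequence(
        interval=interval,
        timestamps=sub["timestamp_s"].to_numpy(),
        channels=sub.drop(columns=["timestamp_s"]),
        pre_truncated=lo < t[0] - 1e-9,
        post_truncated=hi > t[-1] + 1.0 / 60.0 + 1e-9,
        overlaps_neighbor=overlaps,
    )


def slice_edges(interval: DiscomfortInterval) -> np.ndarray:
    """The 301 time edges of the 300 percent slices of one sequence."""
    pre = interval.onset_s - PRE_POST_S + 0.1 * np.arange(101)
    during = interval.onset_s + (interval.duration_s / 100.0) * np.arange(1, 101)
    post = interval.offset_s + 0.1 * np.arange(1, 101)
    return np.concatenate([pre, during, post])


def percent_resample(seq: Sequence, channel: str) -> PercentProfile:
    """Average a channel into the 300 percent slices of a sequence.

    Slice value = mean of non-missing master samples whose timestamps fall
    in the slice's half-open span.  Slices left empty (possible when the
    interval is shorter than 100 master ticks) are filled by linear
    interpolation between the nearest non-empty slices and flagged.
    """
    if channel not in seq.channels.columns:
        raise KeyError(f"channel '{channel}' not present in sequence")
    t = seq.timestamps
    v = seq.channels[channel].to_numpy(dtype=float)
    edges = slice_edges(seq.interval)

    idx = np.searchsorted(edges, t, side="right") - 1
    ok = (idx >= 0) & (idx < N_SLICES) & ~np.isnan(v)
    sums = np.bincount(idx[ok], weights=v[ok], minlength=N_SLICES)
    counts = np.bincount(idx[ok], minlength=N_SLICES)

    values = np.full(N_SLICES, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]

    interpolated = ~nz
    if nz.any() and interpolated.any():
        centers = np.arange(N_SLICES, dtype=float)
        values[interpolated] = np.interp(
            centers[interpolated], centers[nz], values[nz]
        )
    return PercentProfile(
        channel=channel, values=values, interpolated=interpolated, interval=seq.interval
    )


def profiles_to_frame(profiles: list[PercentProfile]) -> pd.DataFrame:
    """Long-format table `sequence_id,channel,slice,value,interpolated`."""
    rows = []
    for p in profiles:
        rows.append(
            pd.DataFrame(
                {
                    "sequence_id": p.sequence_id,
                    "channel": p.channel,
                    "slice": np.arange(1, N_SLICES + 1),
                    "value": p.values,
                    "interpolated": p.interpolated,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def intervals_to_frame(
    intervals: list[DiscomfortInterval], participant: str = "", session: str = ""
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": participant,
            "session": session,
            "onset_s": [iv.onset_s for iv in intervals],
            "offset_s": [iv.offset_s for iv in intervals],
            "duration_s": [iv.duration_s for iv in intervals],
            "peak": [iv.peak for iv in intervals],
        }
    )
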