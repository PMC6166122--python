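"""End-to-end analysis chain: recordings → sequences → profiles → aggregates.

Applies, per sequence, the channel-specific preprocessing and
standardization scopes used throughout the analysis:

==================  =======================================================
output channel      transform chain
==================  =======================================================
pupil_adj_z         binocular mean → ±300 ms moving mean → z per sequence
                    → minus whole-trip luminance z (ambient-light correction)
interblink_timer_z  running time since last blink → z per sequence
hr_z                smartband HR → z per sequence
scl_detrended_z     kΩ→µS → movement masking → z per sequence → residuals
                    of a per-sequence linear fit (removes the warming drift)
shoulder_disp_z     shoulder z-position → displacement from sequence start
                    → z per sequence
seat_back_z         back pressure sensor → z per sequence
==================  =======================================================

Phase metrics (blink rate in events/s, RMSSD in s) are computed per
sequence over the pre / during / post windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import features as ft
from .ingest import SessionRecording
from .profiles import AggregateProfile, aggregate, phase_table

log = logging.getLogger(__name__)

#: Output channels with their expected event-locked direction (+1 elevated
#: during discomfort, −1 depressed, 0 no expected change).
EXPECTED_DIRECTIONS = {
    "pupil_adj_z": +1,
    "interblink_timer_z": +1,
    "hr_z": -1,
    "scl_detrended_z": 0,
    "shoulder_disp_z": -1,
    "seat_back_z": +1,
}


@dataclass
class SequenceFeatures:
    sequence_id: str
    sequence: ev.Sequence
    profiles: dict[str, ev.PercentProfile]
    phase_metrics: list[ft.PhaseSummary]


@dataclass
class AnalysisResult:
    intervals: pd.DataFrame
    descriptives: dict[str, float]
    sequences: list[SequenceFeatures]
    aggregates: dict[str, AggregateProfile]
    phase_summary: pd.DataFrame

    def profiles_for(self, channel: str) -> list[ev.PercentProfile]:
        return [s.profiles[channel] for s in self.sequences if channel in s.profiles]


def derive_trip_channels(rec: SessionRecording) -> pd.DataFrame:
    """Trip-level derived series feeding the per-sequence transforms."""
    data = rec.data
    t = rec.timestamps
    out = {"timestamp_s": t}

    if {"pupil_left", "pupil_right"} <= set(data.columns):
        out["pupil_smooth"] = ft.pupil_preprocess(
            data["pupil_left"].to_numpy(), data["pupil_right"].to_numpy()
        )
    if "scene_luminance" in data.columns:
        out["luminance_z"] = ft.zscore(
            data["scene_luminance"].to_numpy(), scope="trip"
        ).z
    if "blinks" in rec.events:
        timer, _ = ft.interblink_timer(rec.events["blinks"].onsets_s, t)
        out["interblink_timer"] = timer
    if "hr" in data.columns:
        out["hr"] = data["hr"].to_numpy(dtype=float)
    if "skin_resistance" in data.columns:
        scl = ft.scl_convert(data["skin_resistance"].to_numpy())
        accel_cols = [f"accel_{ax}" for ax in "xyz"]
        gyro_cols = [f"gyro_{ax}" for ax in "xyz"]
        if set(accel_cols + gyro_cols) <= set(data.columns):
            mask = ft.movement_mask(
                data[accel_cols].to_numpy(),
                data[gyro_cols].to_numpy(),
                rate_hz=1.0 / float(np.median(np.diff(t))),
            )
            scl = scl.copy()
            scl[mask] = np.nan
        out["scl"] = scl
    if "shoulder_z" in data.columns:
        out["shoulder_z"] = data["shoulder_z"].to_numpy(dtype=float)
    if "seat_back" in data.columns:
        out["seat_back"] = data["seat_back"].to_numpy(dtype=float)
    if "ibi" in data.columns:
        out["ibi"] = data["ibi"].to_numpy(dtype=float)
    return pd.DataFrame(out)


def _sequence_profiles(
    seq: ev.Sequence, trip: pd.DataFrame, lum_z_full: np.ndarray | None
) -> dict[str, ev.PercentProfile]:
    """Apply per-sequence standardization chains and percent-resample."""
    sl = trip.index[np.isin(trip["timestamp_s"].to_numpy(), seq.timestamps)]
    sub = trip.loc[sl]
    profiles: dict[str, ev.PercentProfile] = {}

    def resample(name: str, values: np.ndarray) -> None:
        s2 = ev.Sequence(
            interval=seq.interval,
            timestamps=seq.timestamps,
            channels=pd.DataFrame({name: values}),
            pre_truncated=seq.pre_truncated,
            post_truncated=seq.post_truncated,
        )
        profiles[name] = ev.percent_resample(s2, name)

    def seq_z(col: str) -> np.ndarray | None:
        if col not in sub.columns:
            return None
        v = sub[col].to_numpy(dtype=float)
        if (~np.isnan(v)).sum() < 2:
            return None
        return ft.zscore(v, scope="sequence").z

    pz = seq_z("pupil_smooth")
    if pz is not None and lum_z_full is not None:
        lz = lum_z_full[sl.to_numpy()]
        resample("pupil_adj_z", ft.luminance_adjust(pz, lz))
    tz = seq_z("interblink_timer")
    if tz is not None:
        resample("interblink_timer_z", tz)
    hz = seq_z("hr")
    if hz is not None:
        resample("hr_z", hz)
    sz = seq_z("scl")
    if sz is not None and (~np.isnan(sz)).sum() >= 3:
        resample("scl_detrended_z", ft.detrend_linear(seq.timestamps, sz))
    if "shoulder_z" in sub.columns:
        v = sub["shoulder_z"].to_numpy(dtype=float)
        if (~np.isnan(v)).sum() >= 2:
            disp, _ = ft.displacement_from_start(v)
            resample("shoulder_disp_z", ft.zscore(disp, scope="sequence").z)
    bz = seq_z("seat_back")
    if bz is not None:
        resample("seat_back_z", bz)
    return profiles


def _phase_metrics(
    seq: ev.Sequence, rec: SessionRecording, trip: pd.DataFrame, sid: str
) -> list[ft.PhaseSummary]:
    out: list[ft.PhaseSummary] = []
    t0, t1 = rec.timestamps[0], rec.timestamps[-1]
    windows = {
        p: (max(lo, t0), min(hi, t1)) for p, (lo, hi) in seq.phase_windows().items()
    }
    if "blinks" in rec.events:
        onsets = rec.events["blinks"].onsets_s
        rates = {p: ft.blink_rate(onsets, w) for p, w in windows.items()}
        out.append(ft.PhaseSummary(sid, "blink_rate", rates["pre"], rates["during"], rates["post"]))
    if "ibi" in trip.columns:
        tt = trip["timestamp_s"].to_numpy()
        vals = {}
        for p, (lo, hi) in windows.items():
            m = (tt >= lo) & (tt < hi)
            vals[p] = ft.rmssd(trip["ibi"].to_numpy()[m], collapse=True)
        out.append(ft.PhaseSummary(sid, "rmssd", vals["pre"], vals["during"], vals["post"]))
    return out


def analyze_recordings(
    recs: list[SessionRecording],
    press_threshold: float = ev.PRESS_THRESHOLD,
    merge_gap_s: float = ev.MERGE_GAP_S,
    min_duration_s: float = ev.MIN_DURATION_S,
) -> AnalysisResult:
    """Run the full event-locked analysis over a set of trip recordings."""
    interval_rows = []
    seq_feats: list[SequenceFeatures] = []

    for rec in recs:
        if "handset" not in rec.data.columns:
            log.warning("recording %s/%s has no handset channel; skipped",
                        rec.participant, rec.session)
            continue
        intervals = ev.extract_intervals(
            rec.data["handset"].to_numpy(), rec.timestamps,
            press_threshold, merge_gap_s, min_duration_s,
        )
        interval_rows.append(
            ev.intervals_to_frame(intervals, rec.participant, rec.session)
        )
        trip = derive_trip_channels(rec)
        lum_z = trip["luminance_z"].to_numpy() if "luminance_z" in trip.columns else None

        for k, iv in enumerate(intervals):
            sid = f"{rec.participant}-{rec.session}-{k}"
            seq = ev.build_sequence(rec, iv, neighbors=intervals)
            profiles = _sequence_profiles(seq, trip, lum_z)
            for name, p in profiles.items():
                p.sequence_id = sid
            metrics = _phase_metrics(seq, rec, trip, sid)
            seq_feats.append(SequenceFeatures(sid, seq, profiles, metrics))

    intervals_df = (
        pd.concat(interval_rows, ignore_index=True)
        if interval_rows
        else pd.DataFrame(columns=["participant", "session", "onset_s", "offset_s", "duration_s", "peak"])
    )
    durs = intervals_df["duration_s"].to_numpy(dtype=float)
    descriptives = {
        "n_intervals": int(durs.size),
        "mean_duration_s": float(durs.mean()) if durs.size else float("nan"),
        "sd_duration_s": float(durs.std(ddof=1)) if durs.size > 1 else float("nan"),
    }

    aggregates: dict[str, AggregateProfile] = {}
    for channel in EXPECTED_DIRECTIONS:
        plist = [s.profiles[channel] for s in seq_feats if channel in s.profiles]
        if len(plist) >= 2:
            aggregates[channel] = aggregate(plist)

    summaries = [m for s in seq_feats for m in s.phase_metrics]
    phase_df = phase_table(summaries) if len(summaries) >= 2 else pd.DataFrame()

    return AnalysisResult(
        intervals=intervals_df,
        descriptives=descriptives,
        sequences=seq_feats,
        aggregates=aggregates,
        phase_summary=phase_df,
    )


def simulate_study(
    n_participants: int = 40,
    sessions_per_participant: int = 2,
    scenario=None,
    response=None,
    seed: int = 0,
) -> list[SessionRecording]:
    """Generate joined recordings for a whole simulated study in memory."""
    from . import synthio
    from .ingest import resample_to_master

    recs = []
    base = np.random.SeedSequence(seed)
    seeds = base.generate_state(n_participants * sessions_per_participant)
    k = 0
    for p in range(n_participants):
        for s in range(sessions_per_participant):
            trip_seed = int(seeds[k] % (2**31 - 1))
            k += 1
            channels, events_, _ = synthio.simulate_trip(scenario, response, seed=trip_seed)
            recs.append(
                resample_to_master(
                    channels,
                    channels["handset"],
                    events=events_,
                    participant=f"p{p:02d}",
                    session=f"s{s + 1}",
                )
            )
    return recs
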