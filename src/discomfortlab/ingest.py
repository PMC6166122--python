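"""Session reading and multi-rate synchronization.

All sensors are joined onto the 60 Hz simulator clock by sample-and-hold:
each master tick carries the most recent native sample of every slower (or
faster) stream, mirroring a logger that records "the current value" of each
device at the simulator timestamp.  No interpolation is performed, so every
value in the joined table exists verbatim in some native stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .synthio import Channel, EventStream

MASTER_JITTER_TOL_S = 1e-3


class ManifestError(ValueError):
    """Missing or inconsistent session manifest."""


@dataclass
class SessionRecording:
    """All channels of one trip joined onto the 60 Hz master timeline.

    ``data`` has a ``timestamp_s`` column plus one column per channel;
    event streams are kept as raw onset/duration arrays in ``events``.
    """

    participant: str
    session: str
    data: pd.DataFrame
    events: dict[str, EventStream] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def timestamps(self) -> np.ndarray:
        return self.data["timestamp_s"].to_numpy()

    @property
    def channel_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "timestamp_s"]

    def __post_init__(self) -> None:
        t = self.data["timestamp_s"].to_numpy()
        if t.size > 1:
            dt = np.diff(t)
            if np.ptp(dt) > MASTER_JITTER_TOL_S:
                raise ValueError("master timestamps not uniform within jitter tolerance")


def read_session(session_dir: str | Path) -> tuple[dict[str, Channel], dict[str, EventStream], dict]:
    """Read one session directory written by :func:`synthio.write_session`.

    Channels are typed per the manifest; malformed CSV rows are skipped and
    counted with a warning.  A manifest entry without its file is a hard
    error naming the channel.
    """
    session_dir = Path(session_dir)
    mpath = session_dir / "manifest.yaml"
    if not mpath.exists():
        raise ManifestError(f"no manifest.yaml in {session_dir}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)

    channels: dict[str, Channel] = {}
    for name, meta in (manifest.get("channels") or {}).items():
        fpath = session_dir / meta["file"]
        if not fpath.exists():
            raise ManifestError(f"channel '{name}' listed in manifest but {fpath} is missing")
        ts, vals, bad = _read_two_column_csv(fpath, ("timestamp_s", "value"))
        if bad:
            warnings.warn(f"channel '{name}': skipped {bad} malformed row(s)")
        channels[name] = Channel(name, meta.get("unit", ""), float(meta["rate_hz"]), ts, vals)

    events: dict[str, EventStream] = {}
    for name, meta in (manifest.get("event_streams") or {}).items():
        fpath = session_dir / meta["file"]
        if not fpath.exists():
            raise ManifestError(f"event stream '{name}' listed in manifest but {fpath} is missing")
        on, du, bad = _read_two_column_csv(fpath, ("onset_s", "duration_s"))
        if bad:
            warnings.warn(f"event stream '{name}': skipped {bad} malformed row(s)")
        events[name] = EventStream(name, on, du)

    return channels, events, manifest


def _read_two_column_csv(path: Path, names: tuple[str, str]) -> tuple[np.ndarray, np.ndarray, int]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {missing}")
    a = pd.to_numeric(df[names[0]], errors="coerce").to_numpy()
    b = pd.to_numeric(df[names[1]], errors="coerce").to_numpy()
    bad = int(np.isnan(a).sum())  # a NaN value column entry is legal (missing data)
    keep = ~np.isnan(a)
    return a[keep], b[keep], bad


def sample_and_hold(channel: Channel, master_times: np.ndarray) -> np.ndarray:
    """Value at each master tick = last native sample with timestamp <= tick.

    Ticks before the first native sample are missing (NaN).  Values present
    at native timestamps are preserved exactly; no value is invented.
    """
    idx = np.searchsorted(channel.timestamps, master_times, side="right") - 1
    out = np.full(master_times.size, np.nan)
    ok = idx >= 0
    if channel.values.size:
        out[ok] = channel.values[idx[ok]]
    return out


def resample_to_master(
    channels: Mapping[str, Channel],
    master: Channel | np.ndarray,
    *,
    events: Mapping[str, EventStream] | None = None,
    participant: str = "p00",
    session: str = "s1",
    manifest: dict | None = None,
) -> SessionRecording:
    """Join all channels onto the master timeline by sample-and-hold.

    ``master`` is the 60 Hz simulator clock (a Channel or a timestamp
    array).  Event streams are additionally joined as per-tick onset
    indicator columns (``<name>_onset`` = 1 at the first tick at or after
    each event onset); the running interblink timer is a feature transform,
    not part of the join.
    """
    if isinstance(master, Channel):
        master_times = master.timestamps
    else:
        master_times = np.asarray(master, dtype=float)

    cols: dict[str, np.ndarray] = {"timestamp_s": master_times}
    for name, ch in channels.items():
        col = sample_and_hold(ch, master_times)
        if ch.timestamps.size and ch.timestamps[0] > master_times[-1]:
            warnings.warn(f"channel '{name}' starts after trip end; all-missing column")
        cols[name] = col

    events = dict(events or {})
    for name, ev in events.items():
        ind = np.zeros(master_times.size)
        pos = np.searchsorted(master_times, ev.onsets_s, side="left")
        pos = pos[pos < master_times.size]
        ind[pos] = 1.0
        cols[f"{name}_onset"] = ind

    return SessionRecording(
        participant=participant,
        session=session,
        data=pd.DataFrame(cols),
        events=events,
        manifest=manifest or {},
    )


def load_session(session_dir: str | Path, master_channel: str = "handset") -> SessionRecording:
    """Read a session directory and join it onto the master timeline."""
    channels, events, manifest = read_session(session_dir)
    if master_channel not in channels:
        raise ManifestError(f"master channel '{master_channel}' not in session")
    rec = resample_to_master(
        channels,
        channels[master_channel],
        events=events,
        participant=str(manifest.get("participant", "p00")),
        session=str(manifest.get("session", "s1")),
        manifest=manifest,
    )
    return rec


def write_wide_csv(rec: SessionRecording, path: str | Path) -> None:
    """Emit the joined table as a single wide CSV."""
    rec.data.to_csv(path, index=False, float_format="%.9g")
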