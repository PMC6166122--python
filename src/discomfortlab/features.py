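"""Per-parameter signal transforms.

Physiological signals have a strong individual component, so every channel
is expressed as within-sequence z-scores before aggregation; scene
luminance is z-scored over the whole trip so it can be subtracted from the
pupil z-scores as an ambient-light correction.  The remaining transforms
are the channel-specific preprocessing steps: binocular averaging with a
±300 ms moving mean for pupil diameter, blink rate and the running
interblink timer, RMSSD over beat-to-beat interbeat intervals, kΩ→µS
conversion with movement masking and linear detrending for skin
conductance, and displacement-from-start for motion-capture positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class StandardizedSeries:
    """Z-scored values with the scope the standardization was computed over."""

    channel: str
    timestamps: np.ndarray
    z: np.ndarray
    scope: str  # "sequence" | "trip" | "sliding-window"
    degenerate: bool = False  # constant input -> all zeros


def zscore(
    values: np.ndarray,
    *,
    channel: str = "",
    timestamps: np.ndarray | None = None,
    scope: str = "sequence",
) -> StandardizedSeries:
    """(x − mean) / SD over the full scope, sample SD (ddof=1).

    Missing values are ignored in the moments and propagate to the output.
    A constant series (SD = 0) yields all zeros with the degenerate flag.
    Fewer than two non-missing values is an error.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("z-scoring requires at least 2 non-missing values")
    mean = v[ok].mean()
    sd = v[ok].std(ddof=1)
    # constant input up to float representation counts as degenerate
    if sd <= 1e-12 * max(1.0, abs(mean)):
        z = np.where(ok, 0.0, np.nan)
        return StandardizedSeries(channel, timestamps, z, scope, degenerate=True)
    return StandardizedSeries(channel, timestamps, (v - mean) / sd, scope)


# ---------------------------------------------------------------------------
# pupil diameter & luminance
# ---------------------------------------------------------------------------

def moving_average(values: np.ndarray, half_window: int) -> np.ndarray:
    """Centered moving mean over ±half_window samples, ignoring missing.

    Ticks where the whole window is missing stay missing.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    kernel = np.ones(2 * half_window + 1)
    sums = np.convolve(np.where(ok, v, 0.0), kernel, mode="same")
    counts = np.convolve(ok.astype(float), kernel, mode="same")
    out = np.full(v.size, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def pupil_preprocess(
    left: np.ndarray, right: np.ndarray, rate_hz: float = 60.0, half_window_s: float = 0.3
) -> np.ndarray:
    """Binocular mean followed by a centered ±300 ms moving average.

    At each tick the available eyes are averaged (one eye suffices); ticks
    where both eyes are missing stay missing through the moving mean.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right pupil series must have equal length")
    lok, rok = ~np.isnan(left), ~np.isnan(right)
    counts = lok.astype(float) + rok.astype(float)
    sums = np.where(lok, left, 0.0) + np.where(rok, right, 0.0)
    both = np.full(left.shape, np.nan)
    both[counts > 0] = sums[counts > 0] / counts[counts > 0]
    half = int(round(half_window_s * rate_hz))
    return moving_average(both, half)


def frame_luminance(pixels: np.ndarray) -> float:
    """Mean HSL lightness of a frame: L = (max(R,G,B) + min(R,G,B)) / 2.

    ``pixels`` is an (..., 3) RGB array on the [0, 1] scale.
    """
    px = np.asarray(pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty pixel array")
    if px.shape[-1] != 3:
        raise ValueError("expected RGB pixels in the last axis")
    lightness = (px.max(axis=-1) + px.min(axis=-1)) / 2.0
    return float(lightness.mean())


def luminance_adjust(pupil_z: np.ndarray, luminance_z: np.ndarray) -> np.ndarray:
    """Subtract whole-trip luminance z-scores from per-sequence pupil z-scores."""
    pupil_z = np.asarray(pupil_z, dtype=float)
    luminance_z = np.asarray(luminance_z, dtype=float)
    if pupil_z.shape != luminance_z.shape:
        raise ValueError("pupil and luminance series must have equal length")
    return pupil_z - luminance_z


# ---------------------------------------------------------------------------
# blinks
# ---------------------------------------------------------------------------

def blink_rate(onsets: np.ndarray, window: tuple[float, float]) -> float:
    """Blinks per second: onset count in the half-open window / duration."""
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must have positive duration")
    onsets = np.asarray(onsets, dtype=float)
    n = int(((onsets >= lo) & (onsets < hi)).sum())
    return n / (hi - lo)


def interblink_timer(
    onsets: np.ndarray, timestamps: np.ndarray, window_start: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Running time since the last blink onset, reset to zero at each blink.

    Before the first onset the timer runs from the window start and those
    ticks are flagged (``pre_first`` mask).  Blink duration is not
    excluded; the timer increases with slope one between resets.
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    t = np.asarray(timestamps, dtype=float)
    start = t[0] if window_start is None else window_start
    idx = np.searchsorted(onsets, t, side="right") - 1
    pre_first = idx < 0
    timer = np.empty(t.size)
    timer[pre_first] = t[pre_first] - start
    timer[~pre_first] = t[~pre_first] - onsets[idx[~pre_first]]
    return timer, pre_first


# ---------------------------------------------------------------------------
# heart rate variability
# ---------------------------------------------------------------------------

def collapse_held_ibi(values: np.ndarray) -> np.ndarray:
    """Recover per-beat IBIs from a held device log.

    The smartband logs the latest interbeat interval at a fixed 10 Hz
    cadence, repeating each value until the next beat; consecutive
    duplicates are collapsed to one entry per beat.  (Genuinely identical
    successive beats collapse too — the price of the device-log format.)
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return v
    keep = np.r_[True, np.diff(v) != 0.0]
    return v[keep]


def rmssd(ibi: np.ndarray, *, collapse: bool = False) -> float:
    """Root mean square of successive IBI differences, in seconds.

    With ``collapse=True`` consecutive duplicate log entries are collapsed
    first.  Fewer than 3 IBIs yields NaN (short-window rule).
    """
    v = np.asarray(ibi, dtype=float)
    if collapse:
        v = collapse_held_ibi(v)
    else:
        v = v[~np.isnan(v)]
    if v.size < 3:
        return float("nan")
    d = np.diff(v)
    return float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# skin conductance
# ---------------------------------------------------------------------------

def scl_convert(resistance_kohm: np.ndarray) -> np.ndarray:
    """Skin resistance (kΩ) → skin conductance level (µS): 1000 / R.

    Non-positive resistances become missing.
    """
    r = np.asarray(resistance_kohm, dtype=float)
    out = np.full(r.shape, np.nan)
    ok = r > 0
    out[ok] = 1000.0 / r[ok]
    return out


def movement_mask(
    accel_xyz: np.ndarray,
    gyro_xyz: np.ndarray,
    rate_hz: float,
    accel_threshold_g: float = 0.15,
    gyro_threshold_dps: float = 60.0,
    dilation_s: float = 0.5,
) -> np.ndarray:
    """High-movement mask from wrist accelerometer and gyroscope.

    True where the accelerometer magnitude deviates from 1 g by more than
    the threshold or the gyroscope magnitude exceeds its threshold, dilated
    by ±``dilation_s``.  Masked SCL samples should be treated as missing;
    the mask only removes values, never alters them.
    """
    a = np.asarray(accel_xyz, dtype=float)
    g = np.asarray(gyro_xyz, dtype=float)
    a_mag = np.sqrt(np.nansum(a**2, axis=-1))
    g_mag = np.sqrt(np.nansum(g**2, axis=-1))
    mask = (np.abs(a_mag - 1.0) > accel_threshold_g) | (g_mag > gyro_threshold_dps)
    n = int(round(dilation_s * rate_hz))
    if n > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=np.ones(2 * n + 1, dtype=bool))
    return mask


def detrend_linear(timestamps: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Residuals of a least-squares line fit on (time, value).

    Fit uses non-missing samples only; missing values stay missing.  The
    residuals have zero mean and zero fitted slope by construction.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 3:
        raise ValueError("detrending requires at least 3 non-missing values")
    tt = t[ok]
    if np.ptp(tt) == 0:
        raise ValueError("degenerate fit: constant time axis")
    A = np.column_stack([tt, np.ones(tt.size)])
    coef, *_ = np.linalg.lstsq(A, v[ok], rcond=None)
    out = np.full(v.shape, np.nan)
    out[ok] = v[ok] - (coef[0] * tt + coef[1])
    return out


# ---------------------------------------------------------------------------
# body movements
# ---------------------------------------------------------------------------

def displacement_from_start(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Series minus its first value; the first output is exactly zero.

    If the first value is missing, the first non-missing value is used as
    the reference and the flag in the returned tuple is set.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    flagged = bool(np.isnan(v[0]))
    ok = ~np.isnan(v)
    if not ok.any():
        raise ValueError("all values missing")
    ref = v[np.argmax(ok)]
    return v - ref, flagged


# ---------------------------------------------------------------------------
# phase summaries
# ---------------------------------------------------------------------------

@dataclass
class PhaseSummary:
    """A per-sequence scalar metric evaluated pre / during / post."""

    sequence_id: str
    metric: str  # "blink_rate" (events/s) | "rmssd" (s)
    pre: float
    during: float
    post: float
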