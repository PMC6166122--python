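"""Cross-sequence aggregation: mean curves with pointwise 95% CIs.

Per-sequence percent profiles are averaged slice by slice; around each mean
a pointwise t-based 95% confidence interval is drawn (no multiplicity
correction — the bands support comparison of single points in time, not of
the whole curve).  Non-overlap of two slices' CIs is read as a significant
mean difference (conservatively, at p < 0.01 for 95% intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import N_SLICES, PercentProfile
from .features import PhaseSummary


@dataclass
class AggregateProfile:
    """Per-slice mean, contributing n, and 95% CI bounds for one channel."""

    channel: str
    mean: np.ndarray
    n: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel,
                "slice": np.arange(1, N_SLICES + 1),
                "mean": self.mean,
                "n": self.n,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


def _t_ci(
    mean: np.ndarray, sd: np.ndarray, n: np.ndarray, conf: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise t interval; undefined (NaN) where n < 2."""
    half = np.full(mean.shape, np.nan)
    ok = n >= 2
    tq = stats.t.ppf(0.5 + conf / 2.0, n[ok] - 1)
    half[ok] = tq * sd[ok] / np.sqrt(n[ok])
    return mean - half, mean + half


def aggregate(profiles: list[PercentProfile], conf: float = 0.95) -> AggregateProfile:
    """Slice-wise mean over sequences with a pointwise t-based CI.

    Slices where a profile is missing simply contribute fewer sequences;
    slices missing in every profile are reported missing, not interpolated.
    Requires at least two profiles.
    """
    if len(profiles) < 2:
        raise ValueError("aggregation requires at least 2 profiles")
    channel = profiles[0].channel
    mat = np.vstack([p.values for p in profiles])
    ok = ~np.isnan(mat)
    n = ok.sum(axis=0)
    sums = np.where(ok, mat, 0.0).sum(axis=0)
    mean = np.full(N_SLICES, np.nan)
    mean[n > 0] = sums[n > 0] / n[n > 0]
    dev2 = np.where(ok, (mat - mean) ** 2, 0.0).sum(axis=0)
    sd = np.full(N_SLICES, np.nan)
    sd[n > 1] = np.sqrt(dev2[n > 1] / (n[n > 1] - 1))
    lo, hi = _t_ci(mean, sd, n, conf)
    return AggregateProfile(channel=channel, mean=mean, n=n, ci_lo=lo, ci_hi=hi)


def nonoverlap_significant(agg: AggregateProfile, slice_i: int, slice_j: int) -> bool:
    """True iff the CIs of two slices (1-based) are disjoint.

    A shared endpoint counts as overlap (closed intervals).  Non-overlap of
    95% pointwise CIs implies a significant mean difference at p < 0.01.
    """
    for s in (slice_i, slice_j):
        if not 1 <= s <= N_SLICES:
            raise ValueError(f"slice {s} out of range 1..{N_SLICES}")
        if np.isnan(agg.ci_lo[s - 1]) or np.isnan(agg.ci_hi[s - 1]):
            raise ValueError(f"slice {s} has no confidence interval")
    i, j = slice_i - 1, slice_j - 1
    return bool(agg.ci_hi[i] < agg.ci_lo[j] or agg.ci_hi[j] < agg.ci_lo[i])


def phase_table(summaries: list[PhaseSummary], conf: float = 0.95) -> pd.DataFrame:
    """Per-metric pre/during/post means with pointwise t CIs (descriptive).

    Returns a table `metric,phase,mean,n,ci_lo,ci_hi`.
    """
    if len(summaries) < 2:
        raise ValueError("phase table requires at least 2 summaries")
    rows = []
    df = pd.DataFrame(
        {
            "metric": [s.metric for s in summaries],
            "pre": [s.pre for s in summaries],
            "during": [s.during for s in summaries],
            "post": [s.post for s in summaries],
        }
    )
    for metric, grp in df.groupby("metric", sort=False):
        for phase in ("pre", "during", "post"):
            v = grp[phase].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            n = v.size
            mean = v.mean() if n else float("nan")
            if n >= 2:
                half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * v.std(ddof=1) / np.sqrt(n)
            else:
                half = float("nan")
            rows.append(
                {
                    "metric": metric,
                    "phase": phase,
                    "mean": mean,
                    "n": n,
                    "ci_lo": mean - half,
                    "ci_hi": mean + half,
                }
            )
    return pd.DataFrame(rows)


def plot_aggregate(agg: AggregateProfile, ax=None, title: str | None = None):
    """Render the mean curve with its CI band on the 0–300% axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(1, N_SLICES + 1)
    ax.fill_between(x, agg.ci_lo, agg.ci_hi, color="lightcoral", alpha=0.5,
                    label="95% pointwise CI")
    ax.plot(x, agg.mean, color="tab:blue", lw=1.8, label="mean z")
    for edge in (100, 200):
        ax.axvline(edge, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("sequence time (%)  [1–100 pre | 101–200 during | 201–300 post]")
    ax.set_ylabel("z")
    ax.set_title(title or agg.channel)
    ax.legend(loc="best", fontsize=8)
    return ax
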