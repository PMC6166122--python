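"""Interval extraction, sequence windows and percent-scale resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import discomfortlab as dl
from discomfortlab import events as ev

FS = 60.0


def toy_recording(handset, n=None, extra=None):
    n = n if n is not None else handset.size
    t = np.arange(n) / FS
    cols = {"timestamp_s": t, "handset": handset}
    cols.update(extra or {})
    return dl.SessionRecording("p", "s", pd.DataFrame(cols))


def oracle_extract(values, timestamps, thr, merge_gap, min_dur):
    """Independent linear-scan + merge oracle."""
    runs = []
    cur = None
    for t, v in zip(timestamps, values):
        if v > thr:
            if cur is None:
                cur = [t, t]
            else:
                cur[1] = t
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(a, b) for a, b in merged if b - a >= min_dur]


class TestExtractIntervals:
    def test_all_zero_channel_yields_empty_list(self):
        t = np.arange(600) / FS
        assert ev.extract_intervals(np.zeros(600), t) == []

    def test_single_run_duration_matches_scan_oracle(self):
        t = np.arange(1200) / FS
        v = np.where((t >= 5.0) & (t <= 12.5), 0.8, 0.0)
        ivs = ev.extract_intervals(v, t)
        assert len(ivs) == 1
        assert ivs[0].onset_s == pytest.approx(5.0)
        assert ivs[0].offset_s == pytest.approx(12.5)
        assert ivs[0].duration_s == pytest.approx(7.5)
        assert ivs[0].peak == pytest.approx(0.8)

    def test_presses_within_merge_gap_are_merged(self):
        t = np.arange(1200) / FS
        v = np.zeros(1200)
        v[(t >= 2.0) & (t <= 4.0)] = 1.0
        v[(t >= 4.1) & (t <= 6.0)] = 1.0
        ivs = ev.extract_intervals(v, t, merge_gap_s=0.2)
        assert len(ivs) == 1
        assert ivs[0].duration_s == pytest.approx(4.0, abs=1 / FS)
        # without merging: two intervals
        assert len(ev.extract_intervals(v, t, merge_gap_s=0.05)) == 2

    def test_short_runs_dropped_by_min_duration(self):
        t = np.arange(600) / FS
        v = np.where((t >= 1.0) & (t <= 1.2), 1.0, 0.0)
        assert ev.extract_intervals(v, t, min_duration_s=0.5) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scan_and_merge_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(3000) / FS
        v = np.maximum(rng.normal(-0.3, 0.5, 3000), 0.0)
        got = ev.extract_intervals(v, t, 0.02, 0.3, 0.5)
        want = oracle_extract(v, t, 0.02, 0.3, 0.5)
        assert [(iv.onset_s, iv.offset_s) for iv in got] == [
            (pytest.approx(a), pytest.approx(b)) for a, b in want
        ]

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        runs=st.lists(
            st.tuples(st.integers(1, 40), st.integers(1, 120)), min_size=0, max_size=6
        )
    )
    def test_arbitrary_run_patterns_match_oracle(self, runs):
        # build a trace from alternating gap/press-run lengths (in ticks)
        segments = []
        for gap, press in runs:
            segments += [np.zeros(gap), np.full(press, 0.7)]
        v = np.concatenate(segments) if segments else np.zeros(10)
        v = np.r_[v, 0.0]
        t = np.arange(v.size) / FS
        got = ev.extract_intervals(v, t, 0.02, 0.3, 0.5)
        want = oracle_extract(v, t, 0.02, 0.3, 0.5)
        assert [(iv.onset_s, iv.offset_s) for iv in got] == [
            (pytest.approx(a), pytest.approx(b)) for a, b in want
        ]

    def test_extracted_samples_exceed_threshold(self):
        rng = np.random.default_rng(9)
        t = np.arange(3000) / FS
        v = np.maximum(rng.normal(-0.2, 0.5, 3000), 0.0)
        for iv in ev.extract_intervals(v, t, merge_gap_s=0.0, min_duration_s=0.0):
            m = (t >= iv.onset_s) & (t <= iv.offset_s)
            assert v[m][0] > 0.02 and v[m][-1] > 0.02


class TestBuildSequence:
    def _rec(self, n=60 * 60):
        t = np.arange(n) / FS
        v = np.where((t >= 25.0) & (t <= 33.0), 1.0, 0.0)
        return toy_recording(v, extra={"hr": np.sin(t)})

    def test_centered_interval_has_600_tick_windows(self):
        rec = self._rec()
        iv = ev.extract_intervals(rec.data["handset"].to_numpy(), rec.timestamps)[0]
        seq = ev.build_sequence(rec, iv)
        assert seq.phase_mask("pre").sum() == 600
        assert seq.phase_mask("post").sum() == 600
        assert not seq.pre_truncated and not seq.post_truncated

    def test_early_onset_truncates_pre_window(self):
        t = np.arange(60 * 30) / FS
        v = np.where((t >= 4.0) & (t <= 10.0), 1.0, 0.0)
        rec = toy_recording(v)
        iv = ev.extract_intervals(v, t)[0]
        seq = ev.build_sequence(rec, iv)
        assert seq.pre_truncated
        assert seq.timestamps[0] == pytest.approx(0.0)

    def test_sequence_values_equal_recording_values(self):
        rec = self._rec()
        iv = ev.extract_intervals(rec.data["handset"].to_numpy(), rec.timestamps)[0]
        seq = ev.build_sequence(rec, iv)
        m = np.isin(rec.timestamps, seq.timestamps)
        np.testing.assert_array_equal(
            seq.channels["hr"].to_numpy(), rec.data.loc[m, "hr"].to_numpy()
        )

    def test_interval_outside_recording_rejected(self):
        rec = self._rec(600)
        with pytest.raises(ValueError, match="outside"):
            ev.build_sequence(rec, ev.DiscomfortInterval(50.0, 60.0, 1.0))


class TestPercentResample:
    def _seq(self, channel_values, onset=25.0, offset=33.0, n=60 * 60):
        t = np.arange(n) / FS
        v = np.where((t >= onset) & (t <= offset), 1.0, 0.0)
        rec = toy_recording(v, extra={"x": channel_values(t)})
        iv = ev.extract_intervals(v, t)[0]
        return ev.build_sequence(rec, iv)

    def test_constant_channel_gives_constant_slices(self):
        seq = self._seq(lambda t: np.full(t.size, 3.25))
        p = ev.percent_resample(seq, "x")
        np.testing.assert_allclose(p.values, 3.25)
        assert not p.interpolated.any()

    def test_linear_ramp_during_interval_hits_slice_midpoints(self):
        onset, offset = 25.0, 33.0

        def ramp(t):
            out = np.zeros(t.size)
            m = (t >= onset) & (t < offset)
            out[m] = (t[m] - onset) / (offset - onset)
            return out

        seq = self._seq(ramp, onset, offset)
        p = ev.percent_resample(seq, "x")
        i = np.arange(101, 201)
        expected = (i - 100 - 0.5) / 100.0
        # brute-force per-slice mean oracle tolerance: one sample spacing
        assert np.abs(p.values[100:200] - expected).max() < 1.0 / (
            (offset - onset) * FS / 100.0
        ) / 2 + 1e-9

    def test_matches_brute_force_per_slice_mean_oracle(self, rng):
        seq = self._seq(lambda t: np.sin(t) + rng.normal(0, 0.1, t.size))
        p = ev.percent_resample(seq, "x")
        edges = ev.slice_edges(seq.interval)
        t = seq.timestamps
        v = seq.channels["x"].to_numpy()
        for i in range(300):  # direct mean oracle
            m = (t >= edges[i]) & (t < edges[i + 1])
            if m.any():
                assert p.values[i] == pytest.approx(np.mean(v[m]), abs=1e-9)

    def test_pre_and_post_slice_width_is_tenth_of_second(self):
        seq = self._seq(lambda t: t)
        edges = ev.slice_edges(seq.interval)
        np.testing.assert_allclose(np.diff(edges[:101]), 0.1, atol=1e-12)
        np.testing.assert_allclose(np.diff(edges[200:]), 0.1, atol=1e-12)
        np.testing.assert_allclose(
            np.diff(edges[100:201]), seq.interval.duration_s / 100.0, atol=1e-12
        )

    def test_affine_equivariance(self, rng):
        vals = rng.normal(size=60 * 60)
        seq_x = self._seq(lambda t: vals)
        seq_ax = self._seq(lambda t: 2.5 * vals - 1.0)
        px = ev.percent_resample(seq_x, "x").values
        pax = ev.percent_resample(seq_ax, "x").values
        np.testing.assert_allclose(pax, 2.5 * px - 1.0, atol=1e-9)

    def test_short_interval_empty_slices_interpolated_and_flagged(self):
        # 0.8 s interval: during slices 8 ms wide < master tick
        seq = self._seq(lambda t: np.sin(t), onset=25.0, offset=25.8)
        p = ev.percent_resample(seq, "x")
        assert p.interpolated[100:200].any()
        assert not np.isnan(p.values).any()

    def test_absent_channel_is_error(self):
        seq = self._seq(lambda t: t)
        with pytest.raises(KeyError, match="nope"):
            ev.percent_resample(seq, "nope")


def test_interval_descriptive_bookkeeping():
    ivs = [
        ev.DiscomfortInterval(0.0, 5.0, 1.0),
        ev.DiscomfortInterval(10.0, 17.0, 1.0),
        ev.DiscomfortInterval(30.0, 39.0, 1.0),
    ]
    d = ev.interval_descriptives(ivs)
    assert d["n"] == 3
    assert d["mean_duration_s"] == pytest.approx(7.0)
    assert d["sd_duration_s"] == pytest.approx(2.0)
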