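"""Stage segmentation, stroke extraction, and the 31-variable catalog."""

from __future__ import annotations

import numpy as np
import pytest

from escapekin import (
    FEATURE_NAMES,
    N_FEATURES,
    N_OVERALL,
    N_STAGE_SPECIFIC,
    IncompleteResponseError,
    SmoothingConfig,
    StageConfig,
    StageSegmentation,
    Stroke,
    TrialFeatures,
    aggregate_larva,
    com_kinematics,
    compute_trial_features,
    extract_strokes,
    segment_stages,
)
from escapekin.kinematics import CurvatureSeries, central_difference
from escapekin.stages import features_table
from escapekin.pose_io import TrialMeta

from conftest import straight_recording


def _waveform(onset=10, d1=10, d2=8, a1=60.0, a2=55.0, a3=40.0,
              stroke_ms=6.0, n=90):
    """Piecewise escape-like curvature: half-cosine C-start, cosine power
    swing, steady sinusoidal burst."""
    kappa = np.zeros(n)
    t = np.arange(n, dtype=float)
    m1 = (t >= onset) & (t < onset + d1)
    kappa[m1] = a1 * 0.5 * (1 - np.cos(np.pi * (t[m1] - onset) / d1))
    m2 = (t >= onset + d1) & (t < onset + d1 + d2)
    s = t[m2] - onset - d1
    kappa[m2] = -a2 + (a1 + a2) * 0.5 * (1 + np.cos(np.pi * s / d2))
    m3 = t >= onset + d1 + d2
    s = t[m3] - onset - d1 - d2
    env = a3 + (a2 - a3) * np.exp(-((s / stroke_ms) ** 2))
    kappa[m3] = -env * np.cos(np.pi * s / stroke_ms)
    return kappa


def _brute_zero_crossings(kappa, start, end):
    """Oracle: every sign-change frame by exhaustive scan."""
    out = []
    for f in range(start + 1, end + 1):
        if kappa[f] * kappa[f - 1] < 0 or (kappa[f] != 0 and kappa[f - 1] == 0
                                           and (not out or kappa[f - 1 - 1] * kappa[f] < 0)):
            if np.sign(kappa[f]) != np.sign(kappa[f - 1]):
                out.append(f)
    return out


class TestSegmentation:
    def test_boundaries_at_zero_crossings(self):
        kappa = _waveform()
        seg = segment_stages(kappa, onset=10)
        crossings = [f for f in range(11, seg.window_end + 1)
                     if np.sign(kappa[f]) != np.sign(kappa[f - 1])
                     and kappa[f] != 0]
        # first two crossings after the C-start peak
        after_peak = [f for f in crossings if f > seg.cstart_peak]
        assert seg.s1_end == after_peak[0]
        assert seg.s2_end == after_peak[1]
        assert seg.onset_frame < seg.s1_end < seg.s2_end <= seg.window_end

    def test_counter_bend_flagged_and_ignored(self):
        """A -8 deg dip before a +60 deg C-start is excluded from stage 1."""
        kappa = _waveform(onset=18)
        t = np.arange(kappa.size, dtype=float)
        dip = (t >= 10) & (t < 18)
        kappa[dip] = -8.0 * 0.5 * (1 - np.cos(2 * np.pi * (t[dip] - 10) / 8))
        seg = segment_stages(kappa, onset=10)
        assert seg.counter_bend is not None
        assert kappa[seg.cstart_peak] > 50  # stage 1 anchored on the C-start
        # stage 1 curvature past the counter-bend keeps one sign
        cb_end = seg.counter_bend[1]
        assert np.all(kappa[cb_end + 1 : seg.s1_end] >= 0)

    def test_monotone_curvature_is_incomplete(self):
        kappa = np.zeros(90)
        kappa[10:] = np.linspace(0, 80, 80)  # never reverses
        with pytest.raises(IncompleteResponseError):
            segment_stages(kappa, onset=10)

    def test_flat_curvature_is_incomplete(self):
        with pytest.raises(IncompleteResponseError):
            segment_stages(np.zeros(90), onset=10)

    def test_stage_durations_partition_window(self):
        seg = segment_stages(_waveform(), onset=10)
        d1 = seg.s1_end - seg.onset_frame
        d2 = seg.s2_end - seg.s1_end
        d3 = seg.window_end - seg.s2_end
        assert d1 + d2 + d3 == seg.window_end - seg.onset_frame == 60


class TestStrokes:
    def _series(self, kappa):
        return CurvatureSeries(
            t=np.arange(kappa.size, dtype=float) - 10,
            seg_angle=np.tile(kappa[:, None] / 4, (1, 4)),
            seg_angle_raw=np.tile(kappa[:, None] / 4, (1, 4)),
            kappa_raw=kappa, kappa=kappa,
            omega=central_difference(kappa, 1.0),
            onset_frame=10, sign_standardized=True,
        )

    def test_stage1_and_2_single_strokes(self):
        kappa = _waveform()
        seg = segment_stages(kappa, onset=10)
        strokes = extract_strokes(self._series(kappa), seg)
        assert sum(s.stage == 1 for s in strokes) == 1
        assert sum(s.stage == 2 for s in strokes) == 1

    def test_sinusoid_burst_stroke_count(self):
        """3.5 burst cycles = 7 complete strokes plus a trailing partial."""
        # stage 3 occupies 42 frames; 5.5 ms strokes fit 7 full strokes
        # (38.5 ms) and leave a 3.5 ms partial at the window edge
        kappa = _waveform(d1=10, d2=8, stroke_ms=5.5)
        seg = segment_stages(kappa, onset=10)
        strokes = extract_strokes(self._series(kappa), seg)
        s3 = [s for s in strokes if s.stage == 3]
        assert sum(s.complete for s in s3) == 7
        assert sum(not s.complete for s in s3) == 1

    def test_stage1_amplitude_is_cstart_rise(self):
        kappa = _waveform(a1=60.0)
        seg = segment_stages(kappa, onset=10)
        strokes = extract_strokes(self._series(kappa), seg)
        s1 = next(s for s in strokes if s.stage == 1)
        assert s1.amplitude == pytest.approx(
            abs(kappa[seg.cstart_peak] - kappa[seg.onset_frame]), abs=1e-12
        )
        assert s1.amplitude == pytest.approx(60.0, rel=0.01)

    def test_prominence_rejects_noise_ripples(self):
        """0.3 deg ripples riding a 40 deg stroke leave the count alone."""
        rng = np.random.default_rng(9)
        kappa = _waveform()
        noisy = kappa + 0.3 * np.sin(2 * np.pi * np.arange(kappa.size) / 3.1)
        seg_a = segment_stages(kappa, onset=10)
        seg_b = segment_stages(noisy, onset=10)
        n_a = sum(s.complete and s.stage == 3
                  for s in extract_strokes(self._series(kappa), seg_a))
        n_b = sum(s.complete and s.stage == 3
                  for s in extract_strokes(self._series(noisy), seg_b))
        assert n_a == n_b


class TestFeatures:
    def _full(self, step_mm=0.16, d1=10, d2=8):
        """Straight-line COM at constant speed plus a standard waveform."""
        kappa = _waveform(d1=d1, d2=d2)
        rec = straight_recording(n_frames=kappa.size, step_mm=0.0)
        # constant-speed displacement starting exactly at onset frame 10
        u = np.array([1.0, 0.0])
        for f in range(rec.n_frames):
            rec.xy[f] += max(0, f - 10) * step_mm * u
        com = com_kinematics(rec, onset_frame=10, bl_mm=4.0)
        seg = segment_stages(kappa, onset=10)
        curv = TestStrokes()._series(kappa)
        strokes = extract_strokes(curv, seg)
        return curv, com, seg, strokes

    def test_catalog_is_exactly_31(self):
        curv, com, seg, strokes = self._full()
        feats = compute_trial_features(curv, com, seg, strokes)
        assert len(feats.values) == N_FEATURES == 31
        assert list(feats.values) == list(FEATURE_NAMES)
        assert N_OVERALL == 4 and N_STAGE_SPECIFIC == 27

    def test_constant_speed_distance_arithmetic(self):
        """40 BL/s for 60 ms -> 2.4 BL overall; stage distances follow the
        stage durations and sum back to the overall distance."""
        curv, com, seg, strokes = self._full(step_mm=0.16)  # 0.16mm=0.04BL/ms
        v = compute_trial_features(curv, com, seg, strokes).values
        assert v["overall_distance"] == pytest.approx(2.4, abs=1e-9)
        d1 = seg.s1_end - seg.onset_frame
        assert v["s1_distance"] == pytest.approx(0.04 * d1, abs=1e-9)
        assert (v["s1_distance"] + v["s2_distance"] + v["s3_distance"]
                == pytest.approx(v["overall_distance"], abs=1e-9))
        assert v["s3_avg_speed"] == pytest.approx(40.0, abs=1e-6)
        assert v["s1_duration"] + v["s2_duration"] + v["s3_duration"] == 60.0
        assert v["overall_distance"] >= v["overall_displacement"] - 1e-12

    def test_stroke_frequency_from_complete_strokes(self):
        """6 complete strokes spanning 36 ms -> 166.7 strokes/s."""
        curv, com, seg, _ = self._full()
        strokes = [Stroke(0, 0, 30.0, 6.0, 5.0, True, 3) for _ in range(6)]
        v = compute_trial_features(curv, com, seg, strokes).values
        assert v["s3_n_strokes"] == 6
        assert v["s3_avg_stroke_frequency"] == pytest.approx(1000 * 6 / 36.0,
                                                             rel=1e-9)

    def test_null_features_on_incomplete_trial(self):
        feats = TrialFeatures.null(TrialMeta(), "incomplete segmentation")
        assert not feats.ok
        assert len(feats.values) == 31
        assert all(np.isnan(x) for x in feats.values.values())


class TestAggregation:
    def _trial(self, dist, larva="L1"):
        values = {n: 1.0 for n in FEATURE_NAMES}
        values["overall_distance"] = dist
        return TrialFeatures(values=values, meta=TrialMeta(larva_id=larva))

    def test_mean_of_three_trials(self):
        agg = aggregate_larva([self._trial(3.0), self._trial(3.2), self._trial(3.4)])
        assert agg.values["overall_distance"] == pytest.approx(3.2)
        assert agg.n_trials == 3 and agg.ok and agg.reason == ""

    def test_single_trial_flagged_non_canonical(self):
        agg = aggregate_larva([self._trial(2.0)])
        assert agg.n_trials == 1 and agg.ok
        assert "non-canonical" in agg.reason

    def test_order_invariance(self):
        trials = [self._trial(x) for x in (1.0, 2.0, 4.0)]
        a = aggregate_larva(trials)
        b = aggregate_larva(trials[::-1])
        assert a.values == b.values

    def test_null_trial_propagates(self):
        trials = [self._trial(3.0), TrialFeatures.null(TrialMeta(), "bad")]
        agg = aggregate_larva(trials)
        assert not agg.ok

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_larva([])

    def test_features_table_shape(self):
        tab = features_table([self._trial(3.0), self._trial(3.3, "L2")])
        assert tab.shape[0] == 2
        assert all(n in tab.columns for n in FEATURE_NAMES)
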