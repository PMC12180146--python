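"""Escape-response stage segmentation, tail strokes, and the biomarker table.

An escape response is partitioned into three biomechanical stages on the
sign-standardized tail curvature:

* **stage 1 (C-start)** — onset to the first curvature sign change: the
  initial high-amplitude unilateral bend;
* **stage 2 (power stroke)** — to the second sign change: the rapid
  curvature reversal that produces the first propulsive acceleration;
* **stage 3 (burst swimming)** — the remainder of the 60 ms analysis
  window: rapid alternating tail strokes.

A *tail stroke* is the curvature excursion between two successive local
extremes of smoothed curvature (two strokes = one tail beat cycle).
Stages 1 and 2 each consist of a single stroke; stage 3 of several, with
any trailing partial stroke excluded from per-stroke averages.  A small
counter-bend sometimes precedes the C-start and is ignored.

Each accepted trial yields exactly 31 kinematic variables: 4 describing
overall performance over the 60 ms window and 27 stage-specific ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import COMKinematics, CurvatureSeries, _local_extrema
from .pose_io import TrialMeta


class IncompleteResponseError(RuntimeError):
    """Fewer than two curvature sign changes within the analysis window."""


@dataclass
class StageConfig:
    window_ms: float = 60.0
    #: minimum prominence (degrees) for a curvature extreme to count;
    #: rejects noise ripples riding on a stroke
    prominence: float = 2.0
    #: an initial opposite-signed bend whose peak is below this fraction of
    #: the C-start peak is treated as a counter-bend and ignored
    counter_frac: float = 0.25


@dataclass
class StageSegmentation:
    """Frame indices bounding the three stages (global frame numbers).

    Stage k covers frames [stage_start_k, stage_end_k); ``s1_end`` and
    ``s2_end`` are the first and second post-C-start curvature sign
    changes, ``window_end`` is onset + 60 ms.
    """

    onset_frame: int
    s1_end: int
    s2_end: int
    window_end: int
    cstart_peak: int
    s2_peak: int
    counter_bend: tuple[int, int] | None = None

    def bounds(self) -> list[tuple[int, int]]:
        return [
            (self.onset_frame, self.s1_end),
            (self.s1_end, self.s2_end),
            (self.s2_end, self.window_end),
        ]


@dataclass
class Stroke:
    start_frame: int
    end_frame: int
    amplitude: float        # |delta kappa| peak-to-peak, degrees
    duration_ms: float
    max_abs_omega: float    # degrees/ms
    complete: bool = True
    stage: int = 3


def segment_stages(
    kappa: np.ndarray,
    onset: int,
    dt_ms: float = 1.0,
    cfg: StageConfig | None = None,
) -> StageSegmentation:
    """Partition a sign-standardized smoothed curvature series into stages.

    Raises
    ------
    IncompleteResponseError
        If the C-start or either sign change is missing from the window.
    """
    cfg = cfg or StageConfig()
    kappa = np.asarray(kappa, dtype=float)
    n = kappa.size
    w = int(round(cfg.window_ms / dt_ms))
    window_end = min(onset + w, n - 1)

    win = kappa[onset : window_end + 1]
    peak_abs = float(np.max(np.abs(win))) if win.size else 0.0
    if peak_abs == 0:
        raise IncompleteResponseError("flat curvature: no response in window")

    ext = _local_extrema(win, prominence=cfg.prominence) + onset
    # the C-start: first major positive extremum (series is standardized)
    cstart = None
    counter = None
    for e in ext:
        if kappa[e] > 0 and abs(kappa[e]) >= cfg.counter_frac * peak_abs:
            cstart = int(e)
            break
        if kappa[e] < 0 and abs(kappa[e]) < cfg.counter_frac * peak_abs:
            counter = int(e)  # candidate counter-bend dip
    if cstart is None:
        raise IncompleteResponseError("no C-start extremum found in window")

    counter_bend = None
    if counter is not None and counter < cstart:
        # the ignored initial bend spans onset up to the zero crossing into
        # the C-start
        rise = np.nonzero(kappa[counter : cstart + 1] >= 0)[0]
        end = counter + int(rise[0]) if rise.size else cstart
        counter_bend = (onset, end)

    s1_end = _next_sign_change(kappa, cstart, window_end, falling=True)
    if s1_end is None:
        raise IncompleteResponseError("no curvature sign change after the C-start")
    s2_end = _next_sign_change(kappa, s1_end, window_end, falling=False)
    if s2_end is None:
        raise IncompleteResponseError("no second curvature sign change in window")

    seg2 = kappa[s1_end:s2_end]
    s2_peak = s1_end + int(np.argmin(seg2)) if seg2.size else s1_end

    return StageSegmentation(
        onset_frame=onset,
        s1_end=int(s1_end),
        s2_end=int(s2_end),
        window_end=int(window_end),
        cstart_peak=int(cstart),
        s2_peak=int(s2_peak),
        counter_bend=counter_bend,
    )


def _next_sign_change(
    kappa: np.ndarray, start: int, end: int, falling: bool
) -> int | None:
    """First frame in (start, end] where kappa crosses zero downward
    (falling) or upward."""
    for f in range(start + 1, end + 1):
        if falling and kappa[f] < 0 <= kappa[f - 1]:
            return f
        if not falling and kappa[f] > 0 >= kappa[f - 1]:
            return f
    return None


def extract_strokes(
    curv: CurvatureSeries,
    seg: StageSegmentation,
    cfg: StageConfig | None = None,
) -> list[Stroke]:
    """Tail strokes delimited by successive extremes of smoothed curvature.

    Stage 1 yields one stroke (onset to the C-start peak), stage 2 one
    stroke (C-start peak to the power-stroke peak); stage 3 yields zero or
    more complete strokes between successive extremes after the power-stroke
    peak, plus an optional trailing partial stroke flagged
    ``complete=False``.
    """
    cfg = cfg or StageConfig()
    kappa, omega, dt = curv.kappa, curv.omega, curv.dt_ms

    def make(a: int, b: int, stage: int, complete: bool = True) -> Stroke:
        return Stroke(
            start_frame=a,
            end_frame=b,
            amplitude=float(abs(kappa[b] - kappa[a])),
            duration_ms=(b - a) * dt,
            max_abs_omega=float(np.max(np.abs(omega[a : b + 1]))),
            complete=complete,
            stage=stage,
        )

    strokes = [
        make(seg.onset_frame, seg.cstart_peak, stage=1),
        make(seg.cstart_peak, seg.s2_peak, stage=2),
    ]

    ext = _local_extrema(
        kappa[seg.s2_peak : seg.window_end + 1], prominence=cfg.prominence
    )
    marks = [seg.s2_peak] + [seg.s2_peak + int(e) for e in ext if e > 0]
    for a, b in zip(marks[:-1], marks[1:]):
        strokes.append(make(a, b, stage=3))
    if marks[-1] < seg.window_end:
        strokes.append(make(marks[-1], seg.window_end, stage=3, complete=False))
    return strokes


# ---------------------------------------------------------------------------
# The 31-variable biomarker catalog
# ---------------------------------------------------------------------------

_STAGE_BLOCK = (
    "duration",            # ms
    "distance",            # BL
    "displacement",        # BL
    "avg_speed",           # BL/s
    "exit_speed",          # BL/s (smoothed speed at stage end; 60 ms for stage 3)
    "max_angular_velocity",  # deg/ms, max |omega|
    "max_accel",           # BL/s^2
)

#: Canonical ordered names of the 31 kinematic variables: 4 overall +
#: 3 x 7 per-stage + 6 stage-specific extras = 31 (27 stage-specific).
FEATURE_NAMES: tuple[str, ...] = (
    ("overall_distance", "overall_displacement", "overall_peak_speed",
     "overall_peak_accel")
    + tuple(f"s{k}_{v}" for k in (1, 2, 3) for v in _STAGE_BLOCK)
    + ("s1_final_curvature", "s2_curvature_change", "s3_n_strokes",
       "s3_avg_distance_per_stroke", "s3_avg_stroke_amplitude",
       "s3_avg_stroke_frequency")
)

FEATURE_UNITS: dict[str, str] = {
    **{n: "BL" for n in ("overall_distance", "overall_displacement")},
    "overall_peak_speed": "BL/s",
    "overall_peak_accel": "BL/s^2",
    **{f"s{k}_duration": "ms" for k in (1, 2, 3)},
    **{f"s{k}_distance": "BL" for k in (1, 2, 3)},
    **{f"s{k}_displacement": "BL" for k in (1, 2, 3)},
    **{f"s{k}_avg_speed": "BL/s" for k in (1, 2, 3)},
    **{f"s{k}_exit_speed": "BL/s" for k in (1, 2, 3)},
    **{f"s{k}_max_angular_velocity": "deg/ms" for k in (1, 2, 3)},
    **{f"s{k}_max_accel": "BL/s^2" for k in (1, 2, 3)},
    "s1_final_curvature": "deg",
    "s2_curvature_change": "deg",
    "s3_n_strokes": "count",
    "s3_avg_distance_per_stroke": "BL",
    "s3_avg_stroke_amplitude": "deg",
    "s3_avg_stroke_frequency": "strokes/s",
}

N_FEATURES = len(FEATURE_NAMES)          # 31
N_OVERALL = 4
N_STAGE_SPECIFIC = N_FEATURES - N_OVERALL  # 27


@dataclass
class TrialFeatures:
    """The 31-variable kinematic biomarker vector for one accepted trial."""

    values: dict[str, float]
    meta: TrialMeta = field(default_factory=TrialMeta)
    ok: bool = True
    reason: str = ""
    latency_ms: float | None = None  # stimulus-to-onset; metadata, not a feature

    @classmethod
    def null(cls, meta: TrialMeta, reason: str) -> "TrialFeatures":
        return cls(
            values={n: float("nan") for n in FEATURE_NAMES},
            meta=meta,
            ok=False,
            reason=reason,
        )


def compute_trial_features(
    curv: CurvatureSeries,
    com: COMKinematics,
    seg: StageSegmentation,
    strokes: list[Stroke],
    meta: TrialMeta | None = None,
) -> TrialFeatures:
    """Assemble the canonical 31-variable feature vector from one trial.

    Per-stage ``max_accel`` is the signed maximum of acceleration within the
    stage; ``exit_speed`` the smoothed speed at the stage's final frame.
    Stage-3 per-stroke averages use complete strokes only and are NaN when
    the burst contains no complete stroke.
    """
    onset = seg.onset_frame
    W = seg.window_end - onset
    dt = curv.dt_ms
    bl = com.body_length_mm

    def c(i: int) -> int:  # global frame -> COM-array index
        return i - onset

    v: dict[str, float] = {}
    sl = slice(0, W + 1)
    v["overall_distance"] = float(com.distance[W])
    v["overall_displacement"] = float(com.displacement[W])
    v["overall_peak_speed"] = float(np.max(com.speed[sl]))
    v["overall_peak_accel"] = float(np.max(com.acceleration[sl]))

    for k, (a, b) in enumerate(seg.bounds(), start=1):
        ca, cb = c(a), c(b)
        dur = (b - a) * dt
        dist = float(com.distance[cb] - com.distance[ca])
        disp = float(np.linalg.norm(com.position[cb] - com.position[ca]) / bl)
        v[f"s{k}_duration"] = dur
        v[f"s{k}_distance"] = dist
        v[f"s{k}_displacement"] = disp
        v[f"s{k}_avg_speed"] = dist / (dur / 1000.0) if dur > 0 else float("nan")
        v[f"s{k}_exit_speed"] = float(com.speed[cb])
        v[f"s{k}_max_angular_velocity"] = float(np.max(np.abs(curv.omega[a : b + 1])))
        v[f"s{k}_max_accel"] = float(np.max(com.acceleration[ca : cb + 1]))

    v["s1_final_curvature"] = float(curv.kappa[seg.cstart_peak])
    v["s2_curvature_change"] = float(
        abs(curv.kappa[seg.s2_peak] - curv.kappa[seg.cstart_peak])
    )

    complete3 = [s for s in strokes if s.stage == 3 and s.complete]
    n3 = len(complete3)
    v["s3_n_strokes"] = float(n3)
    if n3 > 0:
        total_dur = sum(s.duration_ms for s in complete3)
        v["s3_avg_distance_per_stroke"] = float(
            sum(com.distance[c(s.end_frame)] - com.distance[c(s.start_frame)]
                for s in complete3) / n3
        )
        v["s3_avg_stroke_amplitude"] = float(
            np.mean([s.amplitude for s in complete3])
        )
        v["s3_avg_stroke_frequency"] = n3 / (total_dur / 1000.0)
    else:
        v["s3_avg_distance_per_stroke"] = float("nan")
        v["s3_avg_stroke_amplitude"] = float("nan")
        v["s3_avg_stroke_frequency"] = float("nan")

    assert set(v) == set(FEATURE_NAMES) and len(v) == N_FEATURES
    return TrialFeatures(values={n: v[n] for n in FEATURE_NAMES}, meta=meta or TrialMeta())


@dataclass
class LarvaFeatures:
    """Per-larva mean of trial feature vectors (the analysis unit)."""

    values: dict[str, float]
    meta: TrialMeta
    n_trials: int
    ok: bool = True
    reason: str = ""


def aggregate_larva(trials: list[TrialFeatures]) -> LarvaFeatures:
    """Collapse a larva's accepted trials into a single mean vector.

    Null-propagating: if any trial is null the larva is flagged excluded.
    Three trials per larva is the canonical design; other counts are
    accepted but noted.
    """
    if not trials:
        raise ValueError("no trials to aggregate")
    meta = trials[0].meta
    if any(not t.ok for t in trials):
        bad = next(t for t in trials if not t.ok)
        return LarvaFeatures(
            values={n: float("nan") for n in FEATURE_NAMES},
            meta=meta,
            n_trials=len(trials),
            ok=False,
            reason=f"null trial: {bad.reason}",
        )
    values = {
        n: float(np.mean([t.values[n] for t in trials])) for n in FEATURE_NAMES
    }
    reason = "" if len(trials) == 3 else f"non-canonical trial count {len(trials)}"
    return LarvaFeatures(values=values, meta=meta, n_trials=len(trials), reason=reason)


def features_table(items: list[TrialFeatures] | list[LarvaFeatures]) -> pd.DataFrame:
    """Wide table: one row per trial (or larva), 31 feature columns + metadata."""
    rows = []
    for it in items:
        row = dict(it.meta.as_dict())
        if isinstance(it, LarvaFeatures):
            row["n_trials"] = it.n_trials
        row["ok"] = it.ok
        row.update(it.values)
        rows.append(row)
    return pd.DataFrame(rows)
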