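"""Tail angular kinematics and center-of-mass linear kinematics.

Tail curvature is the scalar summary of body bend used throughout: the sum
of the four tail segment angles, each measured relative to its proximal
neighbour (tail1 against the trunk axis S1->S2).  By telescoping, the sum
equals the orientation of the tail tip relative to the trunk, so a straight
larva has zero curvature whatever its heading.  Angles are smoothed with
LOESS (span 0.10) before curvature and angular-velocity computation; the
rotation sign is standardized per trial so the first major bend (the
C-start) is positive.

Linear kinematics track keypoint S2 as the center-of-mass proxy.  Distance
and displacement are computed on unfiltered coordinates; instantaneous
speed (the derivative of distance) is additionally LOESS-smoothed
(span 0.7) for exit-speed and peak-speed readouts.  Linear quantities are
normalized to body length (BL, the six segment lengths summed and averaged
over pre-movement frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pose_io import SEGMENTS, TrialRecording

_TAIL_CHAIN = ("S1", "S2", "T1", "T2", "T3", "T4")


class NoMovementError(RuntimeError):
    """No movement onset found within the recording; trial rejected."""


class DegenerateGeometryError(ValueError):
    """Coincident keypoints produce a zero-length segment."""


@dataclass
class SmoothingConfig:
    """LOESS spans for the two smoothing passes (fractions of the series)."""

    angle_span: float = 0.10
    speed_span: float = 0.7

    def __post_init__(self) -> None:
        for s in (self.angle_span, self.speed_span):
            if not 0 < s <= 1:
                raise ValueError(f"LOESS span must be in (0, 1], got {s}")


@dataclass
class OnsetConfig:
    """Movement-onset detection parameters.

    The onset is the first post-stimulus frame whose absolute curvature
    exceeds the preceding frame by 2% and keeps growing.  ``kappa_floor``
    (degrees) guards the rule against the near-zero pre-movement baseline,
    and ``confirm_frames`` subsequent frames of continued growth are
    required so single-frame noise blips are not taken as onset.
    """

    growth_factor: float = 1.02
    kappa_floor: float = 0.5
    confirm_frames: int = 2


@dataclass
class CurvatureSeries:
    """Per-frame tail angular kinematics for one trial.

    ``kappa`` is the LOESS-smoothed, sign-standardized curvature; ``omega``
    its central-difference derivative (degrees/ms).  ``t`` is ms relative to
    movement onset.
    """

    t: np.ndarray
    seg_angle: np.ndarray          # (frames, 4), smoothed, degrees
    seg_angle_raw: np.ndarray      # (frames, 4), degrees
    kappa_raw: np.ndarray
    kappa: np.ndarray
    omega: np.ndarray
    onset_frame: int
    sign_standardized: bool
    sign: float = 1.0
    dt_ms: float = 1.0


@dataclass
class COMKinematics:
    """Per-frame linear kinematics of the S2 center-of-mass proxy.

    All series start at the onset frame.  ``distance`` (path length) and
    ``displacement`` (straight-line offset from the onset position) are in
    BL; ``speed``/``velocity`` in BL/s; ``acceleration`` in BL/s^2.  Speed
    derives from distance and acceleration from displacement via velocity,
    so speed and \\|velocity\\| differ whenever the path curves.
    """

    t: np.ndarray
    position: np.ndarray           # (frames, 2), mm
    distance: np.ndarray
    displacement: np.ndarray
    speed_raw: np.ndarray
    speed: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    body_length_mm: float
    onset_frame: int
    dt_ms: float = 1.0


def _signed_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed planar angle (radians) rotating u onto v, per row."""
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    return np.arctan2(cross, dot)


def segment_angles(rec: TrialRecording) -> np.ndarray:
    """Signed tail segment angles in the relative (joint-angle) convention.

    Returns a (frames, 4) array in degrees.  tail1 is measured against the
    trunk axis S1->S2; each subsequent segment against its proximal
    neighbour.  Each segment's series is temporally unwrapped so tight
    C-starts do not produce +-180 deg jumps between adjacent frames.
    """
    pts = np.stack([rec.keypoint(n) for n in _TAIL_CHAIN], axis=1)  # (F, 6, 2)
    vec = np.diff(pts, axis=1)  # S1->S2, S2->T1, T1->T2, T2->T3, T3->T4
    norms = np.linalg.norm(vec, axis=2)
    if np.any(norms <= 0):
        f, s = np.argwhere(norms <= 0)[0]
        raise DegenerateGeometryError(
            f"zero-length segment {s} at frame {f} (coincident keypoints)"
        )
    ang = _signed_angle(vec[:, :-1, :], vec[:, 1:, :])  # (F, 4) radians
    ang = np.unwrap(ang, axis=0)
    return np.degrees(ang)


def smooth_series(y: np.ndarray, span: float) -> np.ndarray:
    """LOESS (locally estimated scatterplot smoothing) over frame index.

    Local linear fits with tricube weighting; endpoints are handled by the
    fit itself (no padding).  Exactly reproduces constant and linear series.
    """
    if not 0 < span <= 1:
        raise ValueError(f"LOESS span must be in (0, 1], got {span}")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 frames to smooth, got {n}")
    frac = max(span, 3.0 / n)  # a local line needs >= 3 support points
    x = np.arange(n, dtype=float)
    return sm.nonparametric.lowess(y, x, frac=frac, return_sorted=False)


def tail_curvature(angles: np.ndarray) -> np.ndarray:
    """Tail curvature: the per-frame sum of the four tail segment angles."""
    return np.asarray(angles).sum(axis=1)


def standardize_sign(
    kappa: np.ndarray,
    onset_frame: int = 0,
    counter_frac: float = 0.25,
) -> tuple[np.ndarray, float, bool]:
    """Orient curvature so the first major tail bend (the C-start) is positive.

    Some larvae show a small counter-bend before the C-start; extrema whose
    magnitude is below ``counter_frac`` of the trial's curvature maximum are
    ignored when picking the defining bend.  Returns (standardized series,
    sign applied, standardized flag); an all-zero series is returned
    unchanged with the flag False.
    """
    k = np.asarray(kappa, dtype=float)
    post = k[onset_frame:]
    peak = np.max(np.abs(post)) if post.size else 0.0
    if peak == 0:
        return k.copy(), 1.0, False
    ext = _local_extrema(post, prominence=0.0)
    for i in ext:
        if abs(post[i]) >= counter_frac * peak:
            sign = float(np.sign(post[i]))
            return sign * k, sign, True
    sign = float(np.sign(post[np.argmax(np.abs(post))]))
    return sign * k, sign, True


def _local_extrema(y: np.ndarray, prominence: float) -> np.ndarray:
    """Indices of local maxima and minima of y, in order, with prominence."""
    from scipy.signal import find_peaks

    kw = {"prominence": prominence} if prominence > 0 else {}
    hi, _ = find_peaks(y, **kw)
    lo, _ = find_peaks(-y, **kw)
    return np.sort(np.concatenate([hi, lo]))


def central_difference(y: np.ndarray, dt: float) -> np.ndarray:
    """Central finite difference, one-sided first-order at the two ends.

    Exact for polynomial series of degree <= 2 on interior frames.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 frames for a central difference")
    out = np.empty_like(y)
    out[1:-1] = (y[2:] - y[:-2]) / (2.0 * dt)
    out[0] = (y[1] - y[0]) / dt
    out[-1] = (y[-1] - y[-2]) / dt
    return out


def angular_velocity(kappa: np.ndarray, dt_ms: float) -> np.ndarray:
    """Curvature angular velocity omega(t) in degrees/ms."""
    return central_difference(kappa, dt_ms)


def detect_onset(
    kappa_raw: np.ndarray,
    stimulus_frame: int,
    cfg: OnsetConfig | None = None,
) -> int:
    """First post-stimulus frame of sustained curvature growth.

    A frame qualifies when |kappa| exceeds 102% of max(|kappa| on the
    preceding frame, the floor) and |kappa| keeps increasing for
    ``confirm_frames`` further frames.  The rule runs on a 3-frame centered
    median of |kappa|: single-frame tracking outliers cannot fake or mask
    an onset, while a monotone noise-free rise is left untouched (so the
    detected onset is exact there).

    Raises
    ------
    NoMovementError
        If no frame qualifies within the recording.
    """
    cfg = cfg or OnsetConfig()
    a = np.abs(np.asarray(kappa_raw, dtype=float))
    if a.size >= 3:
        med = a.copy()
        med[1:-1] = np.median(
            np.column_stack([a[:-2], a[1:-1], a[2:]]), axis=1)
        a = med
    n = a.size
    for f in range(stimulus_frame + 1, n - cfg.confirm_frames):
        if a[f] < cfg.growth_factor * max(a[f - 1], cfg.kappa_floor):
            continue
        if all(a[f + j] > a[f + j - 1] for j in range(1, cfg.confirm_frames + 1)):
            return f
    raise NoMovementError("no movement onset found within the recording")


def body_length(rec: TrialRecording, onset_frame: int | None = None) -> float:
    """Body length in mm: the six segment lengths summed, averaged over
    pre-movement frames (frames before onset; before the stimulus if onset
    is unknown)."""
    end = rec.stimulus_frame if onset_frame is None else onset_frame
    if end < 1:
        raise ValueError("no pre-movement frames available for body length")
    return float(rec.segment_lengths()[:end].sum(axis=1).mean())


def compute_curvature_series(
    rec: TrialRecording,
    cfg: SmoothingConfig | None = None,
    onset_cfg: OnsetConfig | None = None,
    counter_frac: float = 0.25,
) -> CurvatureSeries:
    """Full angular-kinematics pass: angles -> smoothing -> curvature ->
    onset -> sign standardization -> angular velocity."""
    cfg = cfg or SmoothingConfig()
    raw = segment_angles(rec)
    smoothed = np.column_stack(
        [smooth_series(raw[:, i], cfg.angle_span) for i in range(raw.shape[1])]
    )
    kappa_raw = tail_curvature(raw)
    kappa_s = tail_curvature(smoothed)
    # onset on RAW curvature (LOESS smears the rise backward in time and
    # would bias the detected onset early), referenced to the pre-stimulus
    # baseline so a static tracking offset cannot defeat the growth rule
    baseline = float(np.mean(kappa_raw[: rec.stimulus_frame])) \
        if rec.stimulus_frame > 0 else 0.0
    onset = detect_onset(kappa_raw - baseline, rec.stimulus_frame, onset_cfg)
    kappa_std, sign, ok = standardize_sign(kappa_s, onset, counter_frac)
    omega = angular_velocity(kappa_std, rec.dt_ms)
    t = (np.arange(rec.n_frames) - onset) * rec.dt_ms
    return CurvatureSeries(
        t=t,
        seg_angle=sign * smoothed,
        seg_angle_raw=raw,
        kappa_raw=sign * kappa_raw,
        kappa=kappa_std,
        omega=omega,
        onset_frame=onset,
        sign_standardized=ok,
        sign=sign,
        dt_ms=rec.dt_ms,
    )


def com_kinematics(
    rec: TrialRecording,
    onset_frame: int,
    cfg: SmoothingConfig | None = None,
    bl_mm: float | None = None,
) -> COMKinematics:
    """Linear kinematics of S2 from the onset frame onward.

    Distance is the running sum of consecutive-frame S2 steps and
    displacement the magnitude of the vector from the onset position, both
    on unfiltered coordinates.  Speed is the central difference of distance
    (LOESS span 0.7 for the smoothed variant); velocity the central
    difference of displacement; acceleration the central difference of
    velocity.  Everything is expressed in body lengths (BL) and BL/s.
    """
    cfg = cfg or SmoothingConfig()
    if bl_mm is None:
        bl_mm = body_length(rec, onset_frame)
    pos = rec.keypoint("S2")[onset_frame:]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    distance = np.concatenate([[0.0], np.cumsum(steps)]) / bl_mm
    displacement = np.linalg.norm(pos - pos[0], axis=1) / bl_mm
    dt_s = rec.dt_ms / 1000.0
    speed_raw = central_difference(distance, dt_s)
    speed = smooth_series(speed_raw, cfg.speed_span)
    velocity = central_difference(displacement, dt_s)
    acceleration = central_difference(velocity, dt_s)
    t = np.arange(pos.shape[0]) * rec.dt_ms
    return COMKinematics(
        t=t,
        position=pos,
        distance=distance,
        displacement=displacement,
        speed_raw=speed_raw,
        speed=speed,
        velocity=velocity,
        acceleration=acceleration,
        body_length_mm=bl_mm,
        onset_frame=onset_frame,
        dt_ms=rec.dt_ms,
    )


def kinematics_table(curv: CurvatureSeries, com: COMKinematics) -> pd.DataFrame:
    """Tidy per-frame kinematics table (post-onset frames)."""
    o = curv.onset_frame
    n = com.distance.size
    rows = slice(o, o + n)
    return pd.DataFrame(
        {
            "frame": np.arange(o, o + n),
            "t_ms": curv.t[rows],
            "seg_angle1": curv.seg_angle[rows, 0],
            "seg_angle2": curv.seg_angle[rows, 1],
            "seg_angle3": curv.seg_angle[rows, 2],
            "seg_angle4": curv.seg_angle[rows, 3],
            "kappa": curv.kappa[rows],
            "omega": curv.omega[rows],
            "distance_BL": com.distance,
            "displacement_BL": com.displacement,
            "speed_BLs": com.speed,
            "accel_BLs2": com.acceleration,
        }
    )
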