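"""Reading, calibrating and quality-gating keypoint trajectory tables.

The larva is modelled as seven anatomical landmarks (keypoints) tracked per
video frame by markerless pose estimation, joined head-to-tail into six body
segments:

    TS -- tip of the snout
    S1 -- anterior aspect of the swim bladder
    S2 -- posterior aspect of the swim bladder (center-of-mass proxy)
    T1, T2, T3 -- quarter points along the trunk/tail
    T4 -- tip of the tail

Input tables follow the DeepLabCut output dialect: three header rows
(scorer / bodyparts / coords) and one row per frame with x, y, likelihood
columns per bodypart.  Coordinates are calibrated from pixels to mm on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical keypoint order, head to tail.  Fixed; never reordered.
KEYPOINTS: tuple[str, ...] = ("TS", "S1", "S2", "T1", "T2", "T3", "T4")

#: The six linked body segments as (name, (proximal keypoint, distal keypoint)).
SEGMENTS: tuple[tuple[str, tuple[str, str]], ...] = (
    ("head", ("TS", "S1")),
    ("swim_bladder", ("S1", "S2")),
    ("tail1", ("S2", "T1")),
    ("tail2", ("T1", "T2")),
    ("tail3", ("T2", "T3")),
    ("tail4", ("T3", "T4")),
)

#: Index of each keypoint in the canonical order.
KP_INDEX = {name: i for i, name in enumerate(KEYPOINTS)}

#: The four tail segments whose angles sum to tail curvature.
TAIL_SEGMENTS = ("tail1", "tail2", "tail3", "tail4")

GENOTYPES = ("+/+", "+/-", "-/-")
PHENOTYPES = ("affected", "unaffected", "unknown")


class PoseFormatError(ValueError):
    """Raised when a pose table does not conform to the expected dialect."""


@dataclass
class TrialMeta:
    """Identity and design metadata attached to one escape-response trial."""

    larva_id: str = "unknown"
    strain: str = "other"
    genotype: str = "unknown"
    phenotype: str = "unknown"
    trial_index: int = 0
    dpf: int = 6

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialRecording:
    """A calibrated 7-keypoint trajectory for one escape-response trial.

    Attributes
    ----------
    xy : ndarray, shape (frames, 7, 2)
        Planar keypoint coordinates in mm (image convention, y down).
    likelihood : ndarray, shape (frames, 7)
        Tracking confidence per keypoint in [0, 1].
    fps : float
        Frame rate (frames/s); 1000 in the canonical acquisition.
    px_per_mm : float
        Calibration used to convert the source pixels to mm.
    pre_stimulus_frames : int
        Frames recorded before the stimulus (10 at 1000 fps = 10 ms).
    meta : TrialMeta
    """

    xy: np.ndarray
    likelihood: np.ndarray
    fps: float = 1000.0
    px_per_mm: float = 44.5
    pre_stimulus_frames: int = 10
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (len(KEYPOINTS), 2):
            raise ValueError(f"xy must have shape (frames, 7, 2), got {self.xy.shape}")
        if self.likelihood.shape != self.xy.shape[:2]:
            raise ValueError("likelihood shape must match (frames, 7)")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise ValueError("likelihood values must lie in [0, 1]")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if np.isnan(self.xy).any():
            raise PoseFormatError("missing keypoint coordinates (NaN) in trajectory")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def dt_ms(self) -> float:
        """Frame interval in milliseconds."""
        return 1000.0 / self.fps

    @property
    def stimulus_frame(self) -> int:
        """First post-stimulus frame index (0-based)."""
        return self.pre_stimulus_frames

    def keypoint(self, name: str) -> np.ndarray:
        """Per-frame (x, y) track of one named keypoint, shape (frames, 2)."""
        return self.xy[:, KP_INDEX[name], :]

    def segment_lengths(self) -> np.ndarray:
        """Per-frame lengths of the six body segments, shape (frames, 6), mm."""
        out = np.empty((self.n_frames, len(SEGMENTS)))
        for j, (_, (a, b)) in enumerate(SEGMENTS):
            out[:, j] = np.linalg.norm(self.keypoint(b) - self.keypoint(a), axis=1)
        return out

    def to_tidy(self) -> pd.DataFrame:
        """Normalized long-format table: frame, keypoint, x_mm, y_mm, likelihood."""
        frames = np.repeat(np.arange(self.n_frames), len(KEYPOINTS))
        kps = np.tile(np.array(KEYPOINTS), self.n_frames)
        return pd.DataFrame(
            {
                "frame": frames,
                "keypoint": kps,
                "x_mm": self.xy[:, :, 0].ravel(),
                "y_mm": self.xy[:, :, 1].ravel(),
                "likelihood": self.likelihood.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# DeepLabCut-dialect readers / writers
# ---------------------------------------------------------------------------

def read_pose_table(
    path: str | Path,
    px_per_mm: float,
    fps: float = 1000.0,
    meta: TrialMeta | None = None,
    pre_stimulus_frames: int = 10,
) -> TrialRecording:
    """Read a DeepLabCut-style pose table and calibrate it to mm.

    The table has 3 header rows (scorer / bodyparts / coords) and one row per
    frame with an index column.  Keypoints are mapped by name, so column order
    is irrelevant.  CSV and HDF (pandas-written ``.h5``) layouts are accepted.

    Raises
    ------
    PoseFormatError
        If a keypoint column is absent or the frame index is gapped or
        non-monotone.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf", ".hdf5"}:
        df = pd.read_hdf(path)
    else:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    if df.columns.nlevels != 3:
        raise PoseFormatError(
            "expected 3 header rows (scorer / bodyparts / coords), "
            f"got {df.columns.nlevels}"
        )

    idx = np.asarray(df.index, dtype=float)
    if idx.size and not np.array_equal(idx, idx[0] + np.arange(idx.size)):
        raise PoseFormatError("frame index is non-monotone or gapped")

    bodyparts = df.columns.get_level_values(1)
    coords = df.columns.get_level_values(2)
    n = len(df)
    xy = np.empty((n, len(KEYPOINTS), 2))
    lik = np.ones((n, len(KEYPOINTS)))
    for k, name in enumerate(KEYPOINTS):
        sel = bodyparts == name
        if not sel.any():
            raise PoseFormatError(f"keypoint {name} absent")
        for axis, col in enumerate(("x", "y")):
            cols = df.loc[:, sel & (coords == col)]
            if cols.shape[1] != 1:
                raise PoseFormatError(f"keypoint {name} lacks a unique {col} column")
            xy[:, k, axis] = cols.iloc[:, 0].to_numpy(dtype=float)
        lcols = df.loc[:, sel & (coords == "likelihood")]
        if lcols.shape[1] == 1:
            lik[:, k] = lcols.iloc[:, 0].to_numpy(dtype=float)

    return TrialRecording(
        xy=xy / px_per_mm,
        likelihood=lik,
        fps=fps,
        px_per_mm=px_per_mm,
        pre_stimulus_frames=pre_stimulus_frames,
        meta=meta or TrialMeta(),
    )


def write_pose_table(
    rec: TrialRecording,
    path: str | Path,
    scorer: str = "escapekin",
    float_format: str = "%.6f",
) -> Path:
    """Write a recording back to the DeepLabCut CSV dialect (pixel units)."""
    path = Path(path)
    px = rec.xy * rec.px_per_mm
    data = {}
    for k, name in enumerate(KEYPOINTS):
        data[(scorer, name, "x")] = px[:, k, 0]
        data[(scorer, name, "y")] = px[:, k, 1]
        data[(scorer, name, "likelihood")] = rec.likelihood[:, k]
    df = pd.DataFrame(data)
    df.columns.names = ["scorer", "bodyparts", "coords"]
    df.to_csv(path, float_format=float_format)
    return path


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    """Thresholds for the three per-trial quality gates.

    stationary_tol : mm
        Maximum S2 excursion allowed over the pre-stimulus frames.
    likelihood_floor : dimensionless
        Tracking-confidence threshold below which a frame counts as bad.
    bad_run : frames
        A keypoint with >= this many consecutive sub-threshold frames fails
        the tracking gate; isolated dips pass.
    min_post_onset_ms : ms
        Movement analyzed per trial; at least this much must remain after
        onset.
    """

    stationary_tol: float = 0.05
    likelihood_floor: float = 0.98
    bad_run: int = 3
    min_post_onset_ms: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: raw[k] for k in raw if k in cls.__dataclass_fields__})


@dataclass
class QCCheck:
    name: str
    passed: bool
    detail: str


@dataclass
class QCReport:
    passed: bool
    checks: list[QCCheck]

    def to_json(self) -> str:
        return json.dumps(
            {"passed": self.passed, "checks": [asdict(c) for c in self.checks]},
            indent=2,
        )


def _longest_true_run(mask: np.ndarray) -> int:
    run = best = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def qc_trial(
    rec: TrialRecording,
    cfg: QCConfig | None = None,
    onset_frame: int | None = None,
) -> QCReport:
    """Apply the three acceptance gates to a trial.

    1. *pre_stimulus_stationary* — the larva must not move before the
       stimulus: maximum S2 displacement from its first-frame position over
       the pre-stimulus frames must stay within ``cfg.stationary_tol``.
    2. *tracking_quality* — no keypoint may have a run of ``cfg.bad_run`` or
       more consecutive frames with likelihood below ``cfg.likelihood_floor``
       (the signature of erratic tracking).
    3. *sufficient_duration* — at least ``cfg.min_post_onset_ms`` of movement
       must remain after onset.  If ``onset_frame`` is not yet known the
       stimulus frame is used as a conservative stand-in.

    Failures are reported, never raised.
    """
    cfg = cfg or QCConfig()
    checks: list[QCCheck] = []

    s2 = rec.keypoint("S2")[: rec.pre_stimulus_frames]
    if len(s2) == 0:
        checks.append(QCCheck("pre_stimulus_stationary", False, "no pre-stimulus frames"))
    else:
        excursion = float(np.max(np.linalg.norm(s2 - s2[0], axis=1)))
        checks.append(
            QCCheck(
                "pre_stimulus_stationary",
                excursion <= cfg.stationary_tol,
                f"max S2 excursion {excursion:.4f} mm (tol {cfg.stationary_tol} mm)",
            )
        )

    bad = rec.likelihood < cfg.likelihood_floor
    worst = max((_longest_true_run(bad[:, k]) for k in range(len(KEYPOINTS))), default=0)
    checks.append(
        QCCheck(
            "tracking_quality",
            worst < cfg.bad_run,
            f"longest low-likelihood run {worst} frames (limit {cfg.bad_run})",
        )
    )

    start = rec.stimulus_frame if onset_frame is None else onset_frame
    post_ms = (rec.n_frames - start) * rec.dt_ms
    checks.append(
        QCCheck(
            "sufficient_duration",
            post_ms >= cfg.min_post_onset_ms,
            f"{post_ms:.0f} ms after {'onset' if onset_frame is not None else 'stimulus'}"
            f" (need {cfg.min_post_onset_ms:.0f} ms)",
        )
    )

    return QCReport(passed=all(c.passed for c in checks), checks=checks)


def genotype_concordance(meta: TrialMeta) -> bool | None:
    """Check agreement between muscle phenotype and genotype.

    Affected larvae must genotype as -/- and unaffected larvae as +/+ or +/-;
    discordant trials are excluded from analysis sets.  Returns ``None``
    (indeterminate) when either classification is unknown.
    """
    if meta.phenotype not in ("affected", "unaffected") or meta.genotype not in GENOTYPES:
        return None
    if meta.phenotype == "affected":
        return meta.genotype == "-/-"
    return meta.genotype in ("+/+", "+/-")
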