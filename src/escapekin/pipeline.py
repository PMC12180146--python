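"""End-to-end per-trial analysis and cohort assembly.

Thin orchestration over the analysis modules: QC gate -> angular
kinematics -> onset -> COM kinematics -> stage segmentation -> strokes ->
31-variable feature vector, with failures converted into null feature
rows rather than exceptions so cohort runs never abort on a bad trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import kinematics as kin
from .pose_io import QCConfig, QCReport, TrialRecording, qc_trial
from .stages import (
    IncompleteResponseError,
    StageConfig,
    StageSegmentation,
    Stroke,
    TrialFeatures,
    aggregate_larva,
    compute_trial_features,
    extract_strokes,
    features_table,
    segment_stages,
)


@dataclass
class TrialAnalysis:
    """All per-trial artifacts, populated as far as the trial allowed."""

    features: TrialFeatures
    qc: QCReport
    curvature: kin.CurvatureSeries | None = None
    com: kin.COMKinematics | None = None
    segmentation: StageSegmentation | None = None
    strokes: list[Stroke] | None = None


def analyze_recording(
    rec: TrialRecording,
    qc_cfg: QCConfig | None = None,
    smoothing: kin.SmoothingConfig | None = None,
    onset_cfg: kin.OnsetConfig | None = None,
    stage_cfg: StageConfig | None = None,
) -> TrialAnalysis:
    """Run the full kinematic pipeline on one calibrated recording."""
    qc = qc_trial(rec, qc_cfg)
    if not qc.passed:
        reason = "; ".join(c.name for c in qc.checks if not c.passed)
        return TrialAnalysis(TrialFeatures.null(rec.meta, f"QC: {reason}"), qc)
    try:
        curv = kin.compute_curvature_series(rec, smoothing, onset_cfg)
    except (kin.NoMovementError, kin.DegenerateGeometryError) as err:
        return TrialAnalysis(TrialFeatures.null(rec.meta, str(err)), qc)

    # re-check duration now that the true onset is known
    qc = qc_trial(rec, qc_cfg, onset_frame=curv.onset_frame)
    if not qc.passed:
        reason = "; ".join(c.name for c in qc.checks if not c.passed)
        return TrialAnalysis(
            TrialFeatures.null(rec.meta, f"QC: {reason}"), qc, curvature=curv
        )

    com = kin.com_kinematics(rec, curv.onset_frame, smoothing)
    try:
        seg = segment_stages(curv.kappa, curv.onset_frame, rec.dt_ms, stage_cfg)
        strokes = extract_strokes(curv, seg, stage_cfg)
    except IncompleteResponseError as err:
        return TrialAnalysis(
            TrialFeatures.null(rec.meta, f"incomplete segmentation: {err}"),
            qc, curvature=curv, com=com,
        )
    feats = compute_trial_features(curv, com, seg, strokes, rec.meta)
    feats.latency_ms = (curv.onset_frame - rec.stimulus_frame) * rec.dt_ms
    return TrialAnalysis(feats, qc, curv, com, seg, strokes)


def cohort_features(
    recs: list[TrialRecording], **cfg
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial-level and larva-level feature tables for a set of recordings.

    Trials are grouped by larva id and collapsed to per-larva means (the
    analysis unit for all downstream inference).
    """
    analyses = [analyze_recording(r, **cfg) for r in recs]
    trials = [a.features for a in analyses]
    by_larva: dict[str, list[TrialFeatures]] = {}
    for t in trials:
        by_larva.setdefault(t.meta.larva_id, []).append(t)
    larvae = [aggregate_larva(ts) for ts in by_larva.values()]
    return features_table(trials), features_table(larvae)
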