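"""Shared fixtures: synthetic recordings and geometric helpers."""

from __future__ import annotations

import numpy as np
import pytest

from escapekin import (
    TrialMeta,
    TrialRecording,
    dystrophic_phenotype,
    simulate_trial,
    wt_phenotype,
)


def straight_recording(
    n_frames: int = 80,
    heading_rad: float = 0.0,
    start: tuple[float, float] = (5.0, 5.0),
    step_mm: float = 0.0,
    seg_mm: tuple[float, ...] = (0.5, 0.5, 0.75, 0.75, 0.75, 0.75),
    likelihood: float = 1.0,
) -> TrialRecording:
    """A perfectly straight larva, optionally translating rigidly."""
    seg = np.asarray(seg_mm)
    u = np.array([np.cos(heading_rad), np.sin(heading_rad)])
    offsets = np.concatenate([[0.0], np.cumsum(seg)])  # TS at 0, T4 at BL
    base = np.asarray(start) + np.outer(offsets, u)    # (7, 2)
    xy = np.empty((n_frames, 7, 2))
    for f in range(n_frames):
        xy[f] = base + f * step_mm * u
    return TrialRecording(
        xy=xy,
        likelihood=np.full((n_frames, 7), likelihood),
        meta=TrialMeta(larva_id="straight"),
    )


def arc_pose(total_bend_deg: float, seg_mm: tuple[float, ...] = (0.5, 0.5, 1, 1, 1, 1)):
    """Single-frame pose whose tail bends as a uniform arc.

    Each tail joint carries total_bend_deg / 4 relative rotation, so the
    relative-angle convention should report exactly that per segment.
    """
    seg = np.asarray(seg_mm, dtype=float)
    per_joint = np.radians(total_bend_deg / 4.0)
    pts = [np.array([0.0, 0.0])]
    ang = 0.0
    # head and swim bladder straight along +x
    for L in seg[:2]:
        pts.append(pts[-1] + L * np.array([np.cos(ang), np.sin(ang)]))
    for L in seg[2:]:
        ang += per_joint
        pts.append(pts[-1] + L * np.array([np.cos(ang), np.sin(ang)]))
    return np.asarray(pts)  # (7, 2) TS..T4


def recording_from_pose(pose: np.ndarray, n_frames: int = 20) -> TrialRecording:
    xy = np.repeat(pose[None], n_frames, axis=0)
    return TrialRecording(xy=xy, likelihood=np.ones((n_frames, 7)))


@pytest.fixture(scope="session")
def wt_trial_clean() -> TrialRecording:
    """Noise-free wild-type escape trial."""
    return simulate_trial(wt_phenotype(jitter_sd_um=0.0), seed=11)


@pytest.fixture(scope="session")
def wt_trial_noisy() -> TrialRecording:
    """Wild-type trial with the canonical 64 um keypoint jitter."""
    return simulate_trial(wt_phenotype(), seed=11)


@pytest.fixture(scope="session")
def dys_trial_clean() -> TrialRecording:
    return simulate_trial(dystrophic_phenotype(jitter_sd_um=0.0), seed=12)
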