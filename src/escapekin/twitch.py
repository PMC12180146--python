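"""Isometric twitch analysis for larval tail muscle preparations.

A single supramaximal stimulus elicits a twitch whose force-time record
yields five contractile metrics: peak force (baseline-subtracted),
contraction time (force onset to peak), half-relaxation time (peak to 50%
decay, sub-sample by linear interpolation), and the maximal rates of
tension development and relaxation (extrema of the force derivative).
These five measures feed the same classification machinery as the
kinematic biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import central_difference


class TwitchAnalysisError(RuntimeError):
    """The trace does not contain an analyzable twitch."""


@dataclass
class TwitchTrace:
    """A force-time record; t in ms with 0 at the stimulus, force in mN."""

    t: np.ndarray
    force: np.ndarray
    sample_rate_hz: float
    baseline_window_ms: tuple[float, float] = (-10.0, 0.0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.baseline_window_ms[1] > 0:
            raise ValueError("baseline window must precede the stimulus")

    @classmethod
    def from_csv(cls, path: str | Path, sample_rate_hz: float | None = None,
                 **kw) -> "TwitchTrace":
        """Read a two-column (t_ms, force_mN) comma-separated trace."""
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(dtype=float)
        f = df.iloc[:, 1].to_numpy(dtype=float)
        if sample_rate_hz is None:
            sample_rate_hz = 1000.0 / float(np.median(np.diff(t)))
        return cls(t=t, force=f, sample_rate_hz=sample_rate_hz, **kw)


#: Ordered names of the five contractile metrics.
TWITCH_METRIC_NAMES: tuple[str, ...] = (
    "peak_force",            # mN
    "contraction_time",      # ms
    "half_relaxation_time",  # ms
    "max_dfdt",              # mN/ms
    "max_relax_rate",        # mN/ms (magnitude)
)


@dataclass
class TwitchMetrics:
    peak_force: float
    contraction_time: float
    half_relaxation_time: float
    max_dfdt: float
    max_relax_rate: float

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in TWITCH_METRIC_NAMES}


@dataclass
class TwitchConfig:
    """Onset threshold (baseline + k SD) and derivative pre-smoothing width."""

    onset_sd_k: float = 3.0
    smooth_ms: float = 1.0
    #: reference contraction time to force onset (default) or to the stimulus
    ct_from_stimulus: bool = False


def _moving_mean(y: np.ndarray, width_ms: float, dt_ms: float) -> np.ndarray:
    """Boxcar mean over a fixed time window.

    Edge samples get fractional weight from their overlap with the window,
    so the effective span is exactly ``width_ms`` at any sample rate.
    """
    if width_ms <= dt_ms:
        return y
    half = width_ms / 2.0
    k = int(np.ceil(half / dt_ms + 0.5))
    offsets = np.arange(-k, k + 1) * dt_ms
    lo = np.maximum(offsets - dt_ms / 2.0, -half)
    hi = np.minimum(offsets + dt_ms / 2.0, half)
    w = np.clip(hi - lo, 0.0, None)
    w /= w.sum()
    pad = k
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, w[::-1], mode="same")[pad : pad + y.size]


def analyze_twitch(trace: TwitchTrace, cfg: TwitchConfig | None = None) -> TwitchMetrics:
    """Extract the five contractile metrics from one twitch record.

    Baseline is the mean force over the pre-stimulus window; onset the first
    post-stimulus sample exceeding baseline + k*SD(baseline).  The 50%
    relaxation crossing is located by linear interpolation between the
    bracketing samples.  Rates come from a central difference on a lightly
    smoothed (moving-mean) force.

    Raises
    ------
    TwitchAnalysisError
        If the peak is non-positive or the trace never relaxes to 50%.
    """
    cfg = cfg or TwitchConfig()
    t, f = trace.t, trace.force
    b0, b1 = trace.baseline_window_ms
    base_mask = (t >= b0) & (t <= b1)
    if not base_mask.any():
        raise TwitchAnalysisError("no samples in the baseline window")
    baseline = float(f[base_mask].mean())
    base_sd = float(f[base_mask].std(ddof=0))

    g = f - baseline
    post = t > 0
    if not post.any() or np.max(g[post]) <= 0:
        raise TwitchAnalysisError("non-positive peak force")
    ipk = int(np.argmax(np.where(post, g, -np.inf)))
    peak = float(g[ipk])

    thresh = max(cfg.onset_sd_k * base_sd, 0.0)
    onset_idx = None
    for i in np.nonzero(post)[0]:
        if i > ipk:
            break
        if g[i] > thresh:
            onset_idx = i
            break
    if onset_idx is None:
        onset_idx = int(np.nonzero(post)[0][0])
    # sub-sample onset: interpolate the threshold crossing so contraction
    # time does not quantize with the sample rate
    onset_t = float(t[onset_idx])
    if onset_idx > 0 and g[onset_idx] > g[onset_idx - 1]:
        frac = (thresh - g[onset_idx - 1]) / (g[onset_idx] - g[onset_idx - 1])
        frac = min(max(frac, 0.0), 1.0)
        onset_t = float(t[onset_idx - 1] + frac * (t[onset_idx] - t[onset_idx - 1]))
    ct_ref = 0.0 if cfg.ct_from_stimulus else onset_t
    contraction_time = float(t[ipk] - ct_ref)

    half = 0.5 * peak
    half_t = None
    for i in range(ipk + 1, f.size):
        if g[i] <= half:
            # linear interpolation between samples i-1 and i
            frac = (g[i - 1] - half) / (g[i - 1] - g[i])
            half_t = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    if half_t is None:
        raise TwitchAnalysisError("trace never relaxes to 50% of peak")
    half_relaxation_time = float(half_t - t[ipk])

    dt_ms = 1000.0 / trace.sample_rate_hz
    dfdt = central_difference(_moving_mean(g, cfg.smooth_ms, dt_ms), dt_ms)
    return TwitchMetrics(
        peak_force=peak,
        contraction_time=contraction_time,
        half_relaxation_time=half_relaxation_time,
        max_dfdt=float(np.max(dfdt)),
        max_relax_rate=float(abs(np.min(dfdt))),
    )


def twitch_table(metrics: dict[str, TwitchMetrics]) -> pd.DataFrame:
    """One row per preparation, five metric columns."""
    return pd.DataFrame(
        [{"preparation": k, **m.as_dict()} for k, m in metrics.items()]
    )
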