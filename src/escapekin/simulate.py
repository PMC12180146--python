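"""Forward simulation of escape-response trials and twitch traces.

The generator mirrors the structure of recorded trials: a 10-frame
pre-stimulus hold, a short latency (~7 ms) between stimulus and movement,
then a C-start (half-cosine rise to +A1 over d1), a power stroke (swing to
-A2 over d2), and burst swimming (a sinusoid at the tail-stroke frequency
f, amplitude A3, optionally decaying), sampled at 1 kHz.  The curvature
waveform is C1-continuous at the stage joins (exactly so with no burst
decay).  Keypoints are placed by inverting the analysis-side body model —
curvature is distributed over the four tail segments as relative angles
with fixed weights — so noise-free round trips are exact by construction.

The center of mass advances along the heading with speed proportional to
the magnitude of curvature angular velocity (v = c * |omega|).  This
propulsion proxy contains no hydrodynamics; it simply preserves the
qualitative coupling the pipeline must detect: a slower tail yields a
slower larva.  Isotropic Gaussian keypoint jitter (default SD 64 um)
emulates pose-estimation error.

Phenotype presets encode a dystrophic contrast as *temporal* slowing —
stage durations stretched and stroke frequency reduced by the omega scale
(default 0.6) with near-preserved stroke amplitudes (x 0.95) — so angular
velocities fall while peak-to-peak excursions barely change.  These preset
values are simulator conventions chosen to reproduce the qualitative
phenotype, not measured quantities.

All stochastic draws flow from one seed through ``numpy.random.SeedSequence``
spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import central_difference
from .pose_io import TrialMeta, TrialRecording, write_pose_table
from .twitch import TwitchTrace

#: Fraction of total curvature carried by each tail segment (proximal to
#: distal).  Fixed and invertible: analysis-side relative angles recover
#: exactly these shares of the input curvature.
CURVATURE_WEIGHTS = np.array([0.1, 0.2, 0.3, 0.4])

#: Body segment lengths in mm (head, swim bladder, tail1..4); sum = 4.0 mm,
#: a typical 6 dpf larva.
SEGMENT_LENGTHS_MM = np.array([0.5, 0.5, 0.75, 0.75, 0.75, 0.75])


@dataclass
class EscapePhenotype:
    """Parameters controlling one larva's simulated escape response."""

    latency_ms: float = 7.0
    latency_jitter_ms: float = 1.0
    cstart_amp_deg: float = 120.0     # A1
    cstart_dur_ms: float = 9.0        # d1
    power_amp_deg: float = 110.0      # A2
    power_dur_ms: float = 8.0         # d2
    burst_amp_deg: float = 80.0       # A3
    stroke_freq_per_s: float = 140.0  # f, strokes/s (2 strokes = 1 beat)
    burst_decay: float = 1.0          # amplitude ratio per stroke
    prop_gain: float = 0.0023         # BL per degree of integrated |omega|
    turn_gain: float = 0.45           # heading change per degree of A1
    counter_amp_deg: float = 0.0      # optional pre-C-start counter-bend
    counter_dur_ms: float = 0.0
    jitter_sd_um: float = 64.0

    def validate(self) -> None:
        if min(self.cstart_dur_ms, self.power_dur_ms) <= 0:
            raise ValueError("stage durations must be positive")
        if self.stroke_freq_per_s <= 0:
            raise ValueError("stroke frequency must be positive")
        if min(self.cstart_amp_deg, self.power_amp_deg, self.burst_amp_deg,
               self.jitter_sd_um) < 0:
            raise ValueError("amplitudes and jitter must be non-negative")


def wt_phenotype(**overrides) -> EscapePhenotype:
    """Wild-type preset."""
    return replace(EscapePhenotype(), **overrides)


def dystrophic_phenotype(
    omega_scale: float = 0.6, amp_scale: float = 0.95, **overrides
) -> EscapePhenotype:
    """Dystrophic preset: slowed tail, near-preserved amplitude.

    Stage durations are stretched by 1/omega_scale and the stroke frequency
    multiplied by omega_scale, so maximal angular velocities scale by
    ~omega_scale while peak-to-peak amplitudes only shrink by amp_scale.
    The propulsion gain is unchanged: the distance deficit emerges from the
    slower tail alone.
    """
    wt = EscapePhenotype()
    ph = replace(
        wt,
        cstart_amp_deg=wt.cstart_amp_deg * amp_scale,
        power_amp_deg=wt.power_amp_deg * amp_scale,
        burst_amp_deg=wt.burst_amp_deg * amp_scale,
        cstart_dur_ms=wt.cstart_dur_ms / omega_scale,
        power_dur_ms=wt.power_dur_ms / omega_scale,
        stroke_freq_per_s=wt.stroke_freq_per_s * omega_scale,
    )
    return replace(ph, **overrides)


PRESETS = {"wt": wt_phenotype, "dys": dystrophic_phenotype}


def curvature_waveform(
    ph: EscapePhenotype,
    window_ms: float = 75.0,
    dt_ms: float = 1.0,
    latency_ms: float | None = None,
) -> np.ndarray:
    """Post-stimulus curvature time series kappa(t), degrees.

    t = 0 at the stimulus; the series is zero during the latency, then runs
    counter-bend (optional) -> C-start -> power stroke -> burst until
    ``window_ms``.
    """
    ph.validate()
    lat = ph.latency_ms if latency_ms is None else latency_ms
    t = np.arange(0.0, window_ms + dt_ms / 2, dt_ms)
    kappa = np.zeros_like(t)
    u = t - lat  # time from movement onset
    u0 = 0.0

    if ph.counter_amp_deg > 0 and ph.counter_dur_ms > 0:
        m = (u >= u0) & (u < u0 + ph.counter_dur_ms)
        kappa[m] = -ph.counter_amp_deg * 0.5 * (
            1 - np.cos(2 * np.pi * (u[m] - u0) / ph.counter_dur_ms)
        )
        u0 += ph.counter_dur_ms

    d1, d2 = ph.cstart_dur_ms, ph.power_dur_ms
    a1, a2, a3 = ph.cstart_amp_deg, ph.power_amp_deg, ph.burst_amp_deg
    m1 = (u >= u0) & (u < u0 + d1)
    kappa[m1] = a1 * 0.5 * (1 - np.cos(np.pi * (u[m1] - u0) / d1))
    u0 += d1
    m2 = (u >= u0) & (u < u0 + d2)
    s = u[m2] - u0
    kappa[m2] = -a2 + (a1 + a2) * 0.5 * (1 + np.cos(np.pi * s / d2))
    u0 += d2
    m3 = u >= u0
    s = u[m3] - u0
    stroke_t = 1000.0 / ph.stroke_freq_per_s  # ms per stroke (half cycle)
    env = (a3 + (a2 - a3) * np.exp(-((s / stroke_t) ** 2)))
    env = env * ph.burst_decay ** (s / stroke_t)
    kappa[m3] = -env * np.cos(np.pi * s / stroke_t)
    return kappa


def true_stage_boundaries(ph: EscapePhenotype) -> tuple[float, float]:
    """Closed-form onset-relative stage boundary times (ms) of the waveform.

    The first curvature sign change falls inside the power stroke where the
    half-cosine swing crosses zero: t1 = d1 + (d2/pi) * arccos((A2 - A1) /
    (A1 + A2)).  The second falls a half stroke into the burst:
    t2 = d1 + d2 + T/2 with T the stroke period.
    """
    ph.validate()
    a1, a2 = ph.cstart_amp_deg, ph.power_amp_deg
    t1 = ph.cstart_dur_ms + (ph.power_dur_ms / np.pi) * np.arccos(
        (a2 - a1) / (a1 + a2)
    )
    t2 = ph.cstart_dur_ms + ph.power_dur_ms + 0.5 * 1000.0 / ph.stroke_freq_per_s
    return float(t1), float(t2)


def _rot(v: np.ndarray, ang_rad: float | np.ndarray) -> np.ndarray:
    c, s = np.cos(ang_rad), np.sin(ang_rad)
    return np.stack([c * v[..., 0] - s * v[..., 1],
                     s * v[..., 0] + c * v[..., 1]], axis=-1)


def render_pose(
    kappa_post: np.ndarray,
    ph: EscapePhenotype,
    segment_lengths_mm: np.ndarray | None = None,
    fps: float = 1000.0,
    px_per_mm: float = 44.5,
    pre_stimulus_frames: int = 10,
    heading0_rad: float = 0.0,
    start_xy_mm: tuple[float, float] = (10.0, 10.0),
    latency_ms: float | None = None,
    rng: np.random.Generator | None = None,
    meta: TrialMeta | None = None,
) -> TrialRecording:
    """Place the 7 keypoints frame by frame from a curvature series.

    ``kappa_post`` is the post-stimulus curvature (from
    :func:`curvature_waveform`); pre-stimulus frames are prepended at rest.
    Curvature is split over the tail joints by ``CURVATURE_WEIGHTS``, the
    heading rotates during stage 1 in proportion to the C-start amplitude,
    and the COM advances along the heading at v = prop_gain * |omega| (BL
    per ms).  Isotropic Gaussian jitter of SD ``ph.jitter_sd_um`` is added
    to every keypoint before emitting the calibrated recording.
    """
    seg = SEGMENT_LENGTHS_MM if segment_lengths_mm is None else np.asarray(
        segment_lengths_mm, dtype=float)
    if np.any(seg <= 0):
        raise ValueError("segment lengths must be positive")
    ph.validate()
    dt_ms = 1000.0 / fps
    lat = ph.latency_ms if latency_ms is None else latency_ms
    kappa = np.concatenate([np.zeros(pre_stimulus_frames), kappa_post])
    n = kappa.size
    bl_mm = float(seg.sum())

    omega = central_difference(kappa, dt_ms)
    speed_mm = ph.prop_gain * np.abs(omega) * bl_mm  # mm per ms

    # heading turn ramps over stage 1 and then holds
    t_post = np.arange(n) * dt_ms - pre_stimulus_frames * dt_ms  # ms from stimulus
    ramp = np.clip((t_post - lat) / ph.cstart_dur_ms, 0.0, 1.0)
    theta = heading0_rad + np.radians(ph.turn_gain * ph.cstart_amp_deg) * ramp
    head_dir = np.stack([np.cos(theta), np.sin(theta)], axis=-1)

    pos = np.empty((n, 2))
    pos[0] = start_xy_mm
    for i in range(1, n):
        pos[i] = pos[i - 1] + speed_mm[i - 1] * dt_ms * head_dir[i - 1]

    xy = np.empty((n, 7, 2))
    tailward = -head_dir
    xy[:, 2] = pos                                    # S2
    xy[:, 1] = pos + seg[1] * head_dir                # S1 = S2 + L_sb * head
    xy[:, 0] = xy[:, 1] + seg[0] * head_dir           # TS
    d = tailward.copy()
    joint = np.radians(np.outer(kappa, CURVATURE_WEIGHTS))  # (n, 4)
    prev = pos
    for j in range(4):
        d = _rot(d, joint[:, j])
        nxt = prev + seg[2 + j] * d
        xy[:, 3 + j] = nxt
        prev = nxt

    if ph.jitter_sd_um > 0:
        rng = rng or np.random.default_rng()
        noise = rng.normal(0.0, ph.jitter_sd_um / 1000.0, size=xy.shape)
        # A deterministic pose network viewing a static scene returns the
        # same estimate every frame: while the larva has not yet moved the
        # error is frozen, not redrawn.
        still = np.nonzero(kappa != 0)[0]
        first_move = int(still[0]) if still.size else n
        first_move = min(first_move, n)
        if first_move > 1:
            noise[:first_move] = noise[0]
        xy = xy + noise

    return TrialRecording(
        xy=xy,
        likelihood=np.ones((n, 7)),
        fps=fps,
        px_per_mm=px_per_mm,
        pre_stimulus_frames=pre_stimulus_frames,
        meta=meta or TrialMeta(),
    )


def simulate_trial(
    ph: EscapePhenotype,
    seed: int | np.random.Generator | None = None,
    window_ms: float = 75.0,
    meta: TrialMeta | None = None,
    **render_kw,
) -> TrialRecording:
    """One trial: draw a latency, build the waveform, render the pose."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lat = float(max(3.0, rng.normal(ph.latency_ms, ph.latency_jitter_ms)))
    kappa = curvature_waveform(ph, window_ms=window_ms, latency_ms=lat)
    heading = rng.uniform(0, 2 * np.pi)
    return render_pose(
        kappa, ph, latency_ms=lat, rng=rng, meta=meta,
        heading0_rad=heading, **render_kw,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Design of a simulated cohort.

    ``n_per_genotype`` maps genotype to larva count; each larva receives
    individual phenotype parameters (log-normal variation of scale
    ``between_larva_cv`` around its genotype preset) and
    ``trials_per_larva`` rendered trials with independent latency and
    keypoint noise.
    """

    n_per_genotype: dict[str, int]
    trials_per_larva: int = 3
    strain: str = "sapje"
    presets: dict[str, EscapePhenotype] = field(default_factory=dict)
    between_larva_cv: float = 0.08
    seed: int = 0

    def default_preset(self, genotype: str) -> EscapePhenotype:
        if genotype in self.presets:
            return self.presets[genotype]
        return dystrophic_phenotype() if genotype == "-/-" else wt_phenotype()


def cohort_manifest(*specs: SyntheticCohortSpec) -> pd.DataFrame:
    """Enumerate every (larva, trial) of one or more cohort designs.

    Pure bookkeeping — nothing is rendered.  One row per trial with larva
    id, strain, genotype, phenotype class and trial index.
    """
    rows = []
    for spec in specs:
        for genotype, n in spec.n_per_genotype.items():
            pheno = "affected" if genotype == "-/-" else "unaffected"
            for i in range(n):
                larva = _larva_id(spec.strain, genotype, i)
                for trial in range(spec.trials_per_larva):
                    rows.append({
                        "larva_id": larva,
                        "strain": spec.strain,
                        "genotype": genotype,
                        "phenotype": pheno,
                        "trial_index": trial,
                    })
    return pd.DataFrame(rows)


_VARIED = ("cstart_amp_deg", "power_amp_deg", "burst_amp_deg",
           "cstart_dur_ms", "power_dur_ms", "stroke_freq_per_s")

#: Filesystem-safe genotype tags used in larva ids and file names.
GENOTYPE_TAGS = {"+/+": "pp", "+/-": "pm", "-/-": "mm"}
TAG_GENOTYPES = {v: k for k, v in GENOTYPE_TAGS.items()}


def _larva_id(strain: str, genotype: str, i: int) -> str:
    tag = GENOTYPE_TAGS.get(genotype, genotype.replace("/", ""))
    return f"{strain}_{tag}_{i:03d}"


def generate_cohort(
    spec: SyntheticCohortSpec, **render_kw
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Render a full cohort and its ground-truth parameter table.

    Returns the trial recordings (ordered as in :func:`cohort_manifest`)
    and a truth table with one row per trial carrying the larva's drawn
    phenotype parameters — the targets for parameter-recovery tests.
    """
    root = np.random.SeedSequence(spec.seed)
    recs: list[TrialRecording] = []
    truth_rows = []
    for genotype, n in spec.n_per_genotype.items():
        preset = spec.default_preset(genotype)
        pheno = "affected" if genotype == "-/-" else "unaffected"
        for i in range(n):
            larva = _larva_id(spec.strain, genotype, i)
            lseq = root.spawn(1)[0]
            lrng = np.random.default_rng(lseq)
            ph = preset
            if spec.between_larva_cv > 0:
                draws = {
                    k: getattr(preset, k) * float(
                        lrng.lognormal(0.0, spec.between_larva_cv))
                    for k in _VARIED
                }
                ph = replace(preset, **draws)
            for trial in range(spec.trials_per_larva):
                trng = np.random.default_rng(lseq.spawn(1)[0])
                meta = TrialMeta(
                    larva_id=larva, strain=spec.strain, genotype=genotype,
                    phenotype=pheno, trial_index=trial,
                )
                rec = simulate_trial(ph, seed=trng, meta=meta, **render_kw)
                recs.append(rec)
                truth_rows.append({
                    "larva_id": larva, "strain": spec.strain,
                    "genotype": genotype, "phenotype": pheno,
                    "trial_index": trial,
                    **{k: getattr(ph, k) for k in _VARIED},
                    "prop_gain": ph.prop_gain,
                    "jitter_sd_um": ph.jitter_sd_um,
                })
    return recs, pd.DataFrame(truth_rows)


def write_cohort(recs: list[TrialRecording], out_dir: str | Path) -> list[Path]:
    """Write every trial as a DeepLabCut-dialect CSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recs:
        name = f"{rec.meta.larva_id}_t{rec.meta.trial_index}.csv"
        paths.append(write_pose_table(rec, out / name))
    return paths


def generate_feature_cohort(
    n_per_class: int = 50,
    effect_sizes: dict[str, float] | None = None,
    n_features: int | None = None,
    seed: int = 0,
    strain: str = "sapje",
) -> pd.DataFrame:
    """Larva-level feature table with planted standardized group separations.

    Draws unit-variance Gaussian features for a wild-type and a mutant
    class; features named in ``effect_sizes`` are shifted by the given
    number of standard deviations in the mutant class (default: the five
    linear-kinematic biomarkers separated by 2.4-3.7 SD, matching the
    effect-size range of a strong dystrophic contrast), all other catalog
    features carry no signal.  Used for classifier calibration tests where
    rendering full videos is unnecessary.
    """
    from .stages import FEATURE_NAMES

    if effect_sizes is None:
        effect_sizes = {
            "overall_distance": -3.5,
            "overall_peak_speed": -3.5,
            "s2_exit_speed": -3.0,
            "s3_avg_speed": -2.4,
            "s3_distance": -3.7,
        }
    names = list(FEATURE_NAMES)[:n_features] if n_features else list(FEATURE_NAMES)
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, shift in (("+/+", 0.0), ("-/-", 1.0)):
        X = rng.normal(size=(n_per_class, len(names)))
        for j, nm in enumerate(names):
            X[:, j] += shift * effect_sizes.get(nm, 0.0)
        for i in range(n_per_class):
            rows.append({
                "larva_id": f"{strain}_{genotype}_{i:03d}",
                "strain": strain, "genotype": genotype,
                **dict(zip(names, X[i])),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Twitch traces
# ---------------------------------------------------------------------------

def generate_twitch(
    peak_mn: float = 1.0,
    tau_rise_ms: float = 3.0,
    tau_fall_ms: float = 12.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    sample_rate_hz: float = 10_000.0,
    duration_ms: float = 120.0,
    pre_ms: float = 10.0,
) -> tuple[TwitchTrace, dict[str, float]]:
    """Synthetic isometric twitch F(t) = A (1 - e^(-t/tr)) e^(-t/tf).

    The waveform is scaled so the true peak equals ``peak_mn``.  Returns
    the trace plus the analytically derived truth metrics (peak time/value,
    half-relaxation time, extremal rates), for oracle tests.
    """
    if min(tau_rise_ms, tau_fall_ms) <= 0:
        raise ValueError("time constants must be positive")
    from scipy.optimize import brentq

    tr, tf = tau_rise_ms, tau_fall_ms
    shape = lambda t: (1 - np.exp(-t / tr)) * np.exp(-t / tf)
    t_peak = tr * np.log((tr + tf) / tr)
    amp = peak_mn / shape(t_peak)

    dt = 1000.0 / sample_rate_hz
    t = np.arange(-pre_ms, duration_ms + dt / 2, dt)
    force = np.where(t > 0, amp * shape(np.maximum(t, 0.0)), 0.0)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=force.shape)

    # truth metrics from the closed form
    half = 0.5 * peak_mn
    t_half = brentq(lambda x: amp * shape(x) - half, t_peak, 50 * (tr + tf))
    dshape = lambda x: (np.exp(-x / tr) / tr) * np.exp(-x / tf) - shape(x) / tf
    grid = np.linspace(1e-6, 10 * (tr + tf), 20_000)
    dvals = amp * dshape(grid)
    truth = {
        "peak_force": peak_mn,
        "t_peak": t_peak,
        "half_relaxation_time": t_half - t_peak,
        "max_dfdt": float(dvals.max()),
        "max_relax_rate": float(-dvals.min()),
    }
    return TwitchTrace(t=t, force=force, sample_rate_hz=sample_rate_hz), truth


def generate_twitch_cohort(
    n_wt: int = 24,
    n_mut: int = 24,
    mut_force_scale: float = 0.42,
    between_cv: float = 0.12,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> tuple[dict[str, TwitchTrace], pd.DataFrame]:
    """Twitch traces for a two-genotype cohort.

    Mutant preparations generate ``mut_force_scale`` of the wild-type peak
    force with unchanged time constants (contraction and half-relaxation
    times equal across genotypes; rate metrics scale with force).
    """
    rng = np.random.default_rng(seed)
    traces: dict[str, TwitchTrace] = {}
    rows = []
    for genotype, n, base in (("wt", n_wt, 1.0), ("mut", n_mut, mut_force_scale)):
        for i in range(n):
            peak = base * float(rng.lognormal(0.0, between_cv))
            trace, truth = generate_twitch(
                peak_mn=peak, noise_sd=noise_sd, seed=rng,
            )
            key = f"{genotype}_{i:03d}"
            traces[key] = trace
            rows.append({"preparation": key, "genotype": genotype,
                         "true_peak": peak, **{f"true_{k}": v
                                               for k, v in truth.items()}})
    return traces, pd.DataFrame(rows)
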