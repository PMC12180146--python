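"""Repeatability, bootstrapped effect sizes, and power analysis.

Inference runs on the larva-level feature table (trials collapsed to a
per-larva mean).  Group contrasts are summarized by the raw mean difference
and by Hedges' *g* — the small-sample-corrected standardized mean
difference in pooled-SD units — each with bias-corrected-and-accelerated
(BCa) bootstrap confidence intervals (5000 resamples, 99% by default).
Trial-to-trial consistency is summarized by the repeatability coefficient
2.77 x within-subject SD: the bound that the absolute difference of two
repeated measurements on the same larva exceeds in only 5% of cases.
Prospective power uses the noncentral-t distribution for two-sample and
paired designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class RepeatabilityResult:
    group: str
    within_subject_sd: float
    repeatability_coefficient: float   # 1.96 * sqrt(2) * s_w
    n_larvae: int
    trials_per_larva: float


def repeatability(
    trial_values: Sequence[Sequence[float]] | dict[str, Sequence[float]],
    group: str = "",
) -> RepeatabilityResult:
    """Within-subject SD and repeatability coefficient from repeated trials.

    ``trial_values`` holds each larva's repeated measurements of one
    variable.  The within-subject variance is the pooled within-larva
    variance from the one-way (larva-as-factor) decomposition, weighted by
    (trials - 1); the repeatability coefficient is 1.96*sqrt(2)*s_w ~
    2.77*s_w.  Larvae with a single trial carry no within information and
    are excluded with a warning.
    """
    if isinstance(trial_values, dict):
        trial_values = list(trial_values.values())
    groups = [np.asarray(g, dtype=float) for g in trial_values]
    usable = [g for g in groups if g.size >= 2]
    if len(usable) < len(groups):
        warnings.warn(
            f"excluded {len(groups) - len(usable)} larva(e) with a single trial",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError("need >= 2 larvae with >= 2 trials for repeatability")
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in usable)
    df_within = sum(g.size - 1 for g in usable)
    s_w = float(np.sqrt(ss_within / df_within))
    return RepeatabilityResult(
        group=group,
        within_subject_sd=s_w,
        repeatability_coefficient=1.96 * np.sqrt(2.0) * s_w,
        n_larvae=len(usable),
        trials_per_larva=float(np.mean([g.size for g in usable])),
    )


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def hedges_g(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Hedges' g: standardized mean difference with small-sample correction.

    g = J * (mean_a - mean_b) / s_pooled, with the (n-1)-weighted pooled SD
    and J = 1 - 3 / (4*(n_a + n_b) - 9).  Positive g means group A exceeds
    group B.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2 for Hedges' g")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ZeroDivisionError("pooled SD is zero; standardized effect undefined")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(sp2))


def mean_difference(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    return float(a.mean() - b.mean())


_STATISTICS: dict[str, Callable] = {
    "mean_difference": mean_difference,
    "hedges_g": hedges_g,
}


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    statistic: str
    n_resamples: int
    conf_level: float
    z0: float
    acceleration: float
    degenerate: bool = False


def _boot_distribution_fast(
    a: np.ndarray, b: np.ndarray, statistic: str, n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized bootstrap distribution for the two built-in statistics."""
    ia = rng.integers(0, a.size, size=(n_resamples, a.size))
    ib = rng.integers(0, b.size, size=(n_resamples, b.size))
    ra, rb = a[ia], b[ib]
    ma, mb = ra.mean(axis=1), rb.mean(axis=1)
    if statistic == "mean_difference":
        return ma - mb
    va, vb = ra.var(axis=1, ddof=1), rb.var(axis=1, ddof=1)
    sp = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    j = 1.0 - 3.0 / (4.0 * (a.size + b.size) - 9.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return j * (ma - mb) / sp


def bca_bootstrap(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    statistic: str | Callable = "mean_difference",
    n_resamples: int = 5000,
    conf_level: float = 0.99,
    seed: int | np.random.Generator | None = None,
) -> BootstrapResult:
    """Two-sample BCa (bias-corrected-and-accelerated) bootstrap interval.

    Groups are resampled independently (sampling unit = larva).  The bias
    correction z0 comes from the fraction of the bootstrap distribution
    below the point estimate; the acceleration from the jackknife skewness
    of the statistic; the percentile endpoints are adjusted accordingly.
    Seeded and reproducible.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3 for the bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if callable(statistic):
        stat, stat_name = statistic, getattr(statistic, "__name__", "custom")
    else:
        stat, stat_name = _STATISTICS[statistic], statistic

    theta = float(stat(a, b))
    if not callable(statistic) or statistic in _STATISTICS:
        boot = _boot_distribution_fast(a, b, stat_name, n_resamples, rng)
    else:  # pragma: no cover - generic fallback
        boot = np.empty(n_resamples)
        for i in range(n_resamples):
            boot[i] = stat(a[rng.integers(0, a.size, a.size)],
                           b[rng.integers(0, b.size, b.size)])
    boot = boot[np.isfinite(boot)]

    if boot.size == 0 or np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap distribution; CI collapsed to the "
                      "point estimate", stacklevel=2)
        return BootstrapResult(theta, theta, theta, stat_name, n_resamples,
                               conf_level, 0.0, 0.0, degenerate=True)

    # bias correction: midranked to keep z0 finite at the extremes
    prop = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / boot.size
    prop = min(max(prop, 1.0 / (2 * boot.size)), 1 - 1.0 / (2 * boot.size))
    z0 = float(sps.norm.ppf(prop))

    # acceleration from leave-one-out jackknife over both groups
    jack = []
    for i in range(a.size):
        jack.append(stat(np.delete(a, i), b))
    for i in range(b.size):
        jack.append(stat(a, np.delete(b, i)))
    jack = np.asarray(jack, dtype=float)
    d = jack.mean() - jack
    denom = 6.0 * (np.sum(d**2) ** 1.5)
    accel = float(np.sum(d**3) / denom) if denom > 0 else 0.0

    alpha = (1.0 - conf_level) / 2.0
    za, zb = sps.norm.ppf(alpha), sps.norm.ppf(1.0 - alpha)
    lo = sps.norm.cdf(z0 + (z0 + za) / (1.0 - accel * (z0 + za)))
    hi = sps.norm.cdf(z0 + (z0 + zb) / (1.0 - accel * (z0 + zb)))
    ci = np.quantile(boot, [lo, hi])
    return BootstrapResult(theta, float(ci[0]), float(ci[1]), stat_name,
                           n_resamples, conf_level, z0, accel)


@dataclass
class EffectSizeReport:
    """Bootstrapped raw and standardized contrast for one variable."""

    contrast: str
    raw: BootstrapResult
    standardized: BootstrapResult

    def as_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "raw_diff": self.raw.estimate,
            "raw_ci": [self.raw.ci_low, self.raw.ci_high],
            "hedges_g": self.standardized.estimate,
            "g_ci": [self.standardized.ci_low, self.standardized.ci_high],
            "n_resamples": self.raw.n_resamples,
            "conf_level": self.raw.conf_level,
        }


def effect_size_report(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    contrast: str = "A vs B",
    n_resamples: int = 5000,
    conf_level: float = 0.99,
    seed: int | np.random.Generator | None = None,
) -> EffectSizeReport:
    """Raw mean difference and Hedges' g, both with BCa intervals."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = bca_bootstrap(sample_a, sample_b, "mean_difference",
                        n_resamples, conf_level, rng)
    std = bca_bootstrap(sample_a, sample_b, "hedges_g",
                        n_resamples, conf_level, rng)
    return EffectSizeReport(contrast=contrast, raw=raw, standardized=std)


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

@dataclass
class PowerCurve:
    design: str                    # "two_sample" | "paired"
    effect_d: float                # standardized effect used
    alpha: float
    n_grid: np.ndarray
    power: np.ndarray
    n_required: int | None         # smallest grid n reaching target_power
    target_power: float


def _power_t(d: float, n: int, design: str, alpha: float) -> float:
    """Two-sided t-test power via the noncentral t distribution."""
    if design == "two_sample":
        df, ncp = 2 * n - 2, d * np.sqrt(n / 2.0)
    elif design == "paired":
        df, ncp = n - 1, d * np.sqrt(n)
    else:
        raise ValueError(f"unknown design {design!r}")
    if df < 1:
        return float("nan")
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def power_curve(
    mean: float,
    sd: float,
    rel_effect: float,
    design: str = "two_sample",
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_grid: Sequence[int] | None = None,
) -> PowerCurve:
    """Prospective power for detecting a relative treatment effect.

    The standardized effect is ``d = rel_effect * mean / sd`` — e.g. a 20%
    improvement of a group whose mean/SD ratio is known.  For the paired
    design ``sd`` should be the SD of within-larva differences.  Returns the
    power over the n grid and the smallest n reaching ``target_power``.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = rel_effect * mean / sd
    grid = np.asarray(n_grid if n_grid is not None else np.arange(2, 101), dtype=int)
    power = np.array([_power_t(d, int(n), design, alpha) for n in grid])
    reached = np.nonzero(power >= target_power)[0]
    n_req = int(grid[reached[0]]) if reached.size else None
    return PowerCurve(design=design, effect_d=float(d), alpha=alpha,
                      n_grid=grid, power=power, n_required=n_req,
                      target_power=target_power)
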