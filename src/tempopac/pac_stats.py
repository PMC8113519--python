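"""Statistical inference on coupling estimates.

Covers the surrogate null for coupling strength (block resampling of the
fast-oscillation envelope), z-scores and prevalence across trials,
circular-statistics comparisons of preferred coupling phases between
conditions (two-sample Kuiper, Rayleigh uniformity), the phase-to-
milliseconds conversion along the slow cycle, and the robust regression
of temporal recalibration on the fast-oscillation period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pingouin
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SurrogateResult",
    "block_surrogates",
    "z_and_prevalence",
    "kuiper_statistic",
    "kuiper_two_sample",
    "rayleigh_test",
    "circular_shift_deg",
    "phase_to_ms",
    "robust_regression_tr_vs_period",
    "max_shift_source_selection",
    "critical_z",
    "bonferroni_alpha",
]

TWO_PI = 2.0 * np.pi


def bonferroni_alpha(alpha: float = 0.05, n_comparisons: int = 4) -> float:
    """Bonferroni-corrected per-test threshold."""
    return alpha / n_comparisons


def critical_z(alpha: float = 0.0125) -> float:
    """Upper-tail standard-normal critical value (2.24 at alpha = 0.0125)."""
    return float(stats.norm.ppf(1.0 - alpha))


def block_surrogates(
    envelope_a: np.ndarray,
    phase_p: np.ndarray,
    n_blocks: int = 5,
    n_surr: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Surrogate coupling-strength distribution by envelope block permutation.

    The envelope is split into ``n_blocks`` blocks (equal sample counts,
    remainder to the last block); each surrogate permutes the blocks at
    random (identity permutation excluded) and recomputes the coupling
    strength against the unshuffled phase. Destroys genuine
    envelope-phase alignment while preserving both marginal series.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    env = np.asarray(envelope_a, dtype=float)
    ph = np.asarray(phase_p, dtype=float)
    n = env.size
    if n < n_blocks:
        raise ValueError("window shorter than the number of blocks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base = n // n_blocks
    starts = [i * base for i in range(n_blocks)]
    stops = starts[1:] + [n]  # remainder goes to the last block
    blocks = [np.arange(a, b) for a, b in zip(starts, stops)]

    unit = np.exp(1j * ph)
    rms = np.sqrt(np.mean(env**2))  # order-invariant under permutation
    if rms == 0:
        raise ValueError("all-zero envelope")

    identity = np.arange(n_blocks)
    strengths = np.empty(n_surr)
    for s in range(n_surr):
        while True:
            perm = rng.permutation(n_blocks)
            if not np.array_equal(perm, identity):
                break
        idx = np.concatenate([blocks[j] for j in perm])
        strengths[s] = np.abs(np.mean(env[idx] * unit)) / rms
    return strengths


@dataclass(frozen=True)
class SurrogateResult:
    """Per-trial z-scores of task coupling strength against surrogates."""

    z_scores: np.ndarray
    n_surrogates: int
    prevalence_pct: float
    mean_z: float
    critical_value: float
    significant: bool


def z_and_prevalence(
    task_strengths: np.ndarray,
    surrogate_distributions: np.ndarray,
    alpha: float = 0.0125,
    sd_floor_frac: float = 1e-12,
) -> SurrogateResult:
    """Z-score each trial's coupling strength against its surrogate null.

    ``surrogate_distributions`` is trials x n_surrogates. The region-level
    mean z is tested one-sided against the upper-tail critical value at
    ``alpha`` (2.24 at 0.0125); prevalence is the percentage of trials
    with z > 0. Degenerate surrogate SDs are floored with a warning and
    yield z = 0 when the task strength equals the surrogate mean.
    """
    task = np.asarray(task_strengths, dtype=float)
    surr = np.asarray(surrogate_distributions, dtype=float)
    if surr.ndim != 2 or surr.shape[0] != task.size:
        raise ValueError("surrogate_distributions must be trials x n_surrogates")
    n_surr = surr.shape[1]
    if n_surr < 100:
        raise ValueError("need >= 100 surrogates for reported z-scores")

    mu = surr.mean(axis=1)
    sd = surr.std(axis=1, ddof=1)
    floor = sd_floor_frac * np.maximum(np.abs(task), 1.0)
    degenerate = sd < floor
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} trial(s) with degenerate surrogate SD; "
            "floored",
            stacklevel=2,
        )
        sd = np.where(degenerate, floor, sd)

    z = (task - mu) / sd
    z = np.where(degenerate & np.isclose(task, mu), 0.0, z)
    zc = critical_z(alpha)
    mean_z = float(z.mean())
    return SurrogateResult(
        z_scores=z,
        n_surrogates=n_surr,
        prevalence_pct=float(100.0 * np.mean(z > 0)),
        mean_z=mean_z,
        critical_value=zc,
        significant=bool(mean_z > zc),
    )


def kuiper_statistic(angles1: np.ndarray, angles2: np.ndarray) -> float:
    """Two-sample Kuiper statistic V = D+ + D-.

    V is the sum of the maximal positive and negative deviations between
    the two empirical CDFs on the circle, which makes it invariant to a
    joint rotation of both samples (the circular analogue of the
    two-sample Kolmogorov-Smirnov statistic).
    """
    a = np.sort(np.asarray(angles1, dtype=float) % TWO_PI)
    b = np.sort(np.asarray(angles2, dtype=float) % TWO_PI)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    cdf1 = np.searchsorted(a, pooled, side="right") / n1
    cdf2 = np.searchsorted(b, pooled, side="right") / n2
    d = cdf1 - cdf2
    return float(d.max() - d.min())


def _kuiper_fpp(v: float, n_eff: float) -> float:
    """Asymptotic upper-tail probability with Stephens' correction."""
    lam = (np.sqrt(n_eff) + 0.155 + 0.24 / np.sqrt(n_eff)) * v
    if lam < 0.4:
        return 1.0
    j = np.arange(1, 101)
    a = 2.0 * (4.0 * j**2 * lam**2 - 1.0)
    p = float(np.sum(a * np.exp(-2.0 * j**2 * lam**2)))
    return min(max(p, 0.0), 1.0)


def kuiper_two_sample(
    angles1: np.ndarray,
    angles2: np.ndarray,
    method: str = "auto",
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Rotation-invariant two-sample test for circular data.

    Returns ``(statistic, p)``. The p-value uses the asymptotic series
    with Stephens' small-sample correction; with ``method='permutation'``
    (the default for samples of fewer than 10 angles) it is computed by
    pooled-permutation resampling instead.
    """
    a = np.asarray(angles1, dtype=float)
    b = np.asarray(angles2, dtype=float)
    if a.size < 8 or b.size < 8:
        raise ValueError("need >= 8 angles in each sample")
    v = kuiper_statistic(a, b)

    if method == "auto":
        method = "permutation" if min(a.size, b.size) < 10 else "asymptotic"
    if method == "asymptotic":
        n_eff = a.size * b.size / (a.size + b.size)
        return v, _kuiper_fpp(v, n_eff)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if kuiper_statistic(perm[: a.size], perm[a.size :]) >= v:
                count += 1
        return v, (count + 1) / (n_perm + 1)
    raise ValueError(f"unknown method {method!r}")


def rayleigh_test(angles: np.ndarray) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(z_statistic, p, circular_mean_rad)`` with the usual
    finite-n p approximation; the circular mean is wrapped to [0, 2 pi).
    """
    a = np.asarray(angles, dtype=float) % TWO_PI
    if a.size < 5:
        raise ValueError("need >= 5 angles")
    z, p = pingouin.circ_rayleigh(a)
    mean = float(stats.circmean(a, high=TWO_PI))
    return float(z), float(p), mean


def circular_shift_deg(mean1_deg: float, mean2_deg: float) -> float:
    """Shortest-arc difference between two circular means, in [0, 180] degrees."""
    if not (np.isfinite(mean1_deg) and np.isfinite(mean2_deg)):
        raise ValueError("inputs must be finite")
    d = (mean1_deg - mean2_deg + 180.0) % 360.0 - 180.0
    return float(abs(d))


def phase_to_ms(phi_rad: float, fp_hz: float) -> float:
    """Convert a phase along the slow cycle from radians to milliseconds.

    phi_ms = 1000 * phi_rad / (2 pi fP); one full cycle at 10 Hz is 100 ms.
    """
    if fp_hz <= 0:
        raise ValueError("fp_hz must be positive")
    return 1000.0 * phi_rad / (TWO_PI * fp_hz)


def robust_regression_tr_vs_period(
    tr_ms: np.ndarray,
    period_ms: np.ndarray,
    alpha: float = 0.05 / 12,
) -> dict:
    """Robust linear regression of temporal recalibration on fA period.

    Iteratively reweighted least squares with Tukey bisquare weights.
    Reports the slope ``a``, its two-sided p-value, and r^2 defined as
    the squared Pearson correlation between fitted and observed values,
    evaluated against the corrected threshold for the regression family
    (0.05/12 by default).
    """
    y = np.asarray(tr_ms, dtype=float)
    x = np.asarray(period_ms, dtype=float)
    if y.size < 5:
        raise ValueError("need >= 5 subjects")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient input: predictor is constant")

    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    fitted = np.asarray(fit.fittedvalues)
    r = np.corrcoef(fitted, y)[0, 1] if np.ptp(fitted) > 0 else 0.0
    return {
        "slope": slope,
        "intercept": float(fit.params[0]),
        "p_value": p,
        "r_squared": float(r**2),
        "alpha": alpha,
        "significant": bool(p < alpha),
    }


def max_shift_source_selection(
    source_phases: Mapping[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    **kuiper_kwargs,
) -> dict:
    """Pick the source with the largest significant condition phase shift.

    ``source_phases`` maps source labels to ``(angles_cond1, angles_cond2)``
    for one subject and region. Each source is tested with the two-sample
    Kuiper test; among significant sources the one with the largest
    statistic is selected and its per-condition circular means returned
    (inputs for group-level Rayleigh tests). If no source is significant
    the subject is flagged (``selected=None``) for exclusion from that
    region's group test.
    """
    if len(source_phases) < 1:
        raise ValueError("need at least one labeled source")
    best_label, best_v = None, -np.inf
    per_source = {}
    for label, (a1, a2) in source_phases.items():
        v, p = kuiper_two_sample(a1, a2, **kuiper_kwargs)
        per_source[label] = {"statistic": v, "p_value": p}
        if p < alpha and v > best_v:
            best_label, best_v = label, v

    out = {"per_source": per_source, "selected": best_label}
    if best_label is not None:
        a1, a2 = source_phases[best_label]
        out["circular_mean_cond1"] = float(stats.circmean(a1, high=TWO_PI))
        out["circular_mean_cond2"] = float(stats.circmean(a2, high=TWO_PI))
    return out
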