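"""Psychometric analysis of simultaneity judgments.

Computes percentage-synchronous curves as a function of stimulus onset
asynchrony (SOA), fits a Gaussian psychometric model whose mean is the
point of subjective simultaneity (PSS), quantifies rapid temporal
recalibration (TR) as the PSS difference between trial-history
conditions, and compares asynchronous/synchronous response ratios across
trial-history cells.

Sign convention: positive SOA = visual stimulus leads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "PsychometricFit",
    "percent_synchronous",
    "fit_psychometric",
    "temporal_recalibration",
    "async_sync_ratios",
    "ratio_wilcoxon_tests",
    "filter_analysis_trials",
]

#: SOA magnitudes excluded from analysis: 0 ms is uninformative about
#: recalibration and +/-350 ms lies outside the range of perceived ambiguity.
EXCLUDED_SOA_MS = (0.0, 350.0)

_CONDITION_TO_LEAD = {"t-1:V": "V", "t-1:A": "A"}


@dataclass(frozen=True)
class PsychometricFit:
    """Converged Gaussian fit to a %-synchronous-vs-SOA curve."""

    amplitude_pct: float
    pss_ms: float
    sigma_ms: float
    rss: float
    lapse_pct: float = 0.0

    def predict(self, soa_ms: np.ndarray) -> np.ndarray:
        x = np.asarray(soa_ms, dtype=float)
        return self.lapse_pct + (self.amplitude_pct - self.lapse_pct) * np.exp(
            -((x - self.pss_ms) ** 2) / (2.0 * self.sigma_ms**2)
        )


def filter_analysis_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop trials with |SOA| in {0, 350} ms.

    All other trials are kept irrespective of response correctness (the
    SOAs around the PSS, where responses are often "wrong", carry the
    recalibration signal).
    """
    keep = ~np.isin(np.abs(trials["soa_ms"].to_numpy(dtype=float)), EXCLUDED_SOA_MS)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_analysis_trials: dropped %d trials", dropped)
    return trials.loc[keep].reset_index(drop=True)


def percent_synchronous(
    trials: pd.DataFrame, condition: str
) -> dict[float, float]:
    """Percentage of synchronous responses per SOA for one history condition.

    ``condition`` is ``"t-1:V"`` or ``"t-1:A"``; trials whose previous
    trial was synchronous or absent are excluded from both pools.
    """
    if condition not in _CONDITION_TO_LEAD:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_TO_LEAD)}")
    pool = trials[trials["prev_lead"] == _CONDITION_TO_LEAD[condition]]
    if pool.empty:
        raise ValueError(f"no trials in condition {condition}")
    sync = (pool["response"] == "synchronous").astype(float)
    pct = sync.groupby(pool["soa_ms"].astype(float)).mean() * 100.0
    return {float(k): float(v) for k, v in pct.items()}


def _gauss3(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _gauss4(x, a, mu, sigma, lapse):
    return lapse + (a - lapse) * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_psychometric(
    pct_by_soa: Mapping[float, float], lapse: bool = False
) -> PsychometricFit:
    """Least-squares Gaussian fit; the fitted mean is the PSS.

    The default model has three parameters, A exp(-(x-mu)^2/(2 sigma^2)),
    A in (0, 100], sigma in (1, 1000] ms; ``lapse=True`` adds an optional
    baseline. Requires >= 4 distinct SOA levels and non-flat data.
    """
    x = np.asarray(sorted(pct_by_soa), dtype=float)
    y = np.asarray([pct_by_soa[k] for k in x], dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 distinct SOA levels to fit")
    if np.ptp(y) == 0:
        raise ValueError("degenerate flat data: all percentages equal")

    span = max(np.ptp(x), 1.0)
    a0 = float(np.max(y))
    mu0 = float(x[np.argmax(y)])
    sig0 = float(np.clip(span / 2.0, 1.001, 1000.0))
    if lapse:
        p0 = [max(a0, 1e-3), mu0, sig0, float(np.min(y))]
        bounds = ([1e-6, x.min() - span, 1.0, 0.0],
                  [100.0, x.max() + span, 1000.0, 100.0])
        model = _gauss4
    else:
        p0 = [max(a0, 1e-3), mu0, sig0]
        bounds = ([1e-6, x.min() - span, 1.0], [100.0, x.max() + span, 1000.0])
        model = _gauss3

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"psychometric fit did not converge: {exc}; "
            f"levels={x.tolist()}, data={y.tolist()}"
        ) from exc

    resid = y - model(x, *popt)
    rss = float(resid @ resid)
    if lapse:
        a, mu, sigma, lp = popt
        return PsychometricFit(float(a), float(mu), float(sigma), rss, float(lp))
    a, mu, sigma = popt
    return PsychometricFit(float(a), float(mu), float(sigma), rss)


def temporal_recalibration(
    fit_t1V: PsychometricFit, fit_t1A: PsychometricFit
) -> float:
    """TR in ms: PSS(t-1:V) - PSS(t-1:A)."""
    return fit_t1V.pss_ms - fit_t1A.pss_ms


def async_sync_ratios(trials: pd.DataFrame) -> pd.DataFrame:
    """Ratio of asynchronous to synchronous responses per history cell.

    Cells are {t:A, t:V} x {t-1:A, t-1:V}. Cells with no synchronous
    response get a NaN ratio and a warning (they are excluded from group
    tests downstream).
    """
    rows = []
    for cur in ("A", "V"):
        for prev in ("A", "V"):
            cell = trials[
                (trials["current_lead"] == cur) & (trials["prev_lead"] == prev)
            ]
            n_sync = int((cell["response"] == "synchronous").sum())
            n_async = int((cell["response"] == "asynchronous").sum())
            if n_sync == 0:
                warnings.warn(
                    f"cell t:{cur}/t-1:{prev} has no synchronous responses; "
                    "ratio undefined",
                    stacklevel=2,
                )
                ratio = np.nan
            else:
                ratio = n_async / n_sync
            rows.append(
                {
                    "current": f"t:{cur}",
                    "previous": f"t-1:{prev}",
                    "n_async": n_async,
                    "n_sync": n_sync,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def ratio_wilcoxon_tests(
    subject_ratios: Sequence[pd.DataFrame], alpha: float = 0.0125
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between all ratio cells.

    ``subject_ratios`` holds one :func:`async_sync_ratios` table per
    subject. Tests are evaluated at the Bonferroni-corrected threshold
    (0.05/4 = 0.0125 for the four planned comparisons). Subjects with an
    undefined ratio in either cell of a pair are dropped from that pair.
    """
    cells = [(r["current"], r["previous"]) for _, r in subject_ratios[0].iterrows()]
    mats = np.array(
        [tbl["ratio"].to_numpy(dtype=float) for tbl in subject_ratios]
    )  # subjects x 4 cells
    rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = mats[:, i], mats[:, j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3 or np.all(a[ok] == b[ok]):
                stat, p = np.nan, np.nan
            else:
                stat, p = stats.wilcoxon(a[ok], b[ok])
            rows.append(
                {
                    "cell_1": "/".join(cells[i]),
                    "cell_2": "/".join(cells[j]),
                    "n": int(ok.sum()),
                    "statistic": stat,
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)
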