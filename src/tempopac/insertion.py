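"""Dynamic-insertion model of audiovisual simultaneity perception.

The model posits that each alternation of the fast (fA) oscillation
nested in the slow (fP) cycle opens a sensory registration "slot"
(s1, s2, ...). An audiovisual pair is perceived as synchronous when the
auditory and visual cortical inputs are registered to slots of the same
rank in their respective cortices. With phi the preferred coupling phase
(in ms along the fP cycle), T_A the fA period and alpha a scalar locating
the first slot at phi - alpha T_A, the registration conditions at the
point of subjective simultaneity are

    phi_A - alpha T_AA = PSS + latency_A        (auditory, latency 20 ms)
    phi_V - alpha T_AV = latency_V              (visual, latency 50 ms)

which combine, eliminating alpha, into the closed-form prediction

    PSS = phi_A - (phi_V - latency_V) (T_AA / T_AV) - latency_A.

A stochastic slot-registration simulator operationalizes the same rules
trial by trial and produces synthetic psychometric curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as _behavior

__all__ = [
    "DynamicInsertionParams",
    "SlotModelConfig",
    "predict_pss",
    "predict_tr",
    "slot_index",
    "simulate_synchrony_judgments",
]


@dataclass(frozen=True)
class DynamicInsertionParams:
    """Neurophysiological parameters feeding the model.

    Phases are in ms along the fP cycle; periods are fA periods
    (1000 / fA_hz) in ms; latencies are typical cortical input delays.
    """

    phiA_ms: float
    phiV_ms: float
    T_AA_ms: float
    T_AV_ms: float
    alpha_mult: float = 1.0
    latency_A_ms: float = 20.0
    latency_V_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.T_AA_ms <= 0 or self.T_AV_ms <= 0:
            raise ValueError("fA periods must be positive")
        if self.phiA_ms < 0 or self.phiV_ms < 0:
            raise ValueError("phases must be >= 0")
        if self.latency_A_ms < 0 or self.latency_V_ms < 0:
            raise ValueError("latencies must be >= 0")


@dataclass(frozen=True)
class SlotModelConfig:
    """Slot-registration simulator settings.

    ``slot_mode='full'`` makes each slot one full fA period (default);
    ``'half'`` uses half-cycle slots (subsequent fA half-cycles acting as
    further registration opportunities). ``n_slots * slot duration`` may
    not exceed the fP period.
    """

    fP_hz: float = 10.0
    n_slots: int = 3
    slot_mode: str = "full"

    def __post_init__(self) -> None:
        if self.n_slots < 2:
            raise ValueError("n_slots must be >= 2")
        if self.slot_mode not in ("full", "half"):
            raise ValueError("slot_mode must be 'full' or 'half'")

    def slot_duration_ms(self, T_A_ms: float) -> float:
        return T_A_ms if self.slot_mode == "full" else T_A_ms / 2.0

    @property
    def cycle_ms(self) -> float:
        return 1000.0 / self.fP_hz


def predict_pss(params: DynamicInsertionParams) -> float:
    """Closed-form PSS prediction in ms; independent of alpha_mult."""
    return (
        params.phiA_ms
        - (params.phiV_ms - params.latency_V_ms) * (params.T_AA_ms / params.T_AV_ms)
        - params.latency_A_ms
    )


def predict_tr(
    params_t1V: DynamicInsertionParams, params_t1A: DynamicInsertionParams
) -> float:
    """Predicted temporal recalibration: PSS(t-1:V) - PSS(t-1:A)."""
    return predict_pss(params_t1V) - predict_pss(params_t1A)


def slot_index(
    arrival_ms_in_cycle: float,
    phi_ms: float,
    alpha_mult: float,
    T_A_ms: float,
    n_slots: int,
    slot_duration_ms: float | None = None,
) -> int | None:
    """Rank of the registration slot containing an arrival time, or None.

    Slot 1 opens at ``phi - alpha T_A``; slot k covers the half-open
    interval [s1_start + (k-1) d, s1_start + k d) with d the slot
    duration (default one fA period). Arrivals outside all slots return
    None.
    """
    d = T_A_ms if slot_duration_ms is None else slot_duration_ms
    s1_start = phi_ms - alpha_mult * T_A_ms
    k = int(np.floor((arrival_ms_in_cycle - s1_start) / d)) + 1
    return k if 1 <= k <= n_slots else None


def _registered_slot(
    arrival_ms: float, phi_ms: float, alpha: float, T_A_ms: float,
    n_slots: int, d_ms: float, cycle_ms: float,
) -> int | None:
    # slots live on the fP cycle: try the arrival wrapped into the
    # adjacent cycles so slots straddling the cycle boundary still catch it
    a = arrival_ms % cycle_ms
    for shift in (-cycle_ms, 0.0, cycle_ms):
        k = slot_index(a + shift, phi_ms, alpha, T_A_ms, n_slots, d_ms)
        if k is not None:
            return k
    return None


def simulate_synchrony_judgments(
    config: SlotModelConfig,
    params: DynamicInsertionParams,
    soa_levels_ms,
    n_trials: int = 200,
    phase_jitter_kappa: float | None = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Trial-by-trial slot registration yielding a psychometric curve.

    Per trial the preferred phases of each cortex are jittered (von Mises
    on the phase angle, concentration ``phase_jitter_kappa``; None = no
    jitter), cortical arrival times computed (visual onset at 0 + 50 ms
    latency; auditory onset at SOA + 20 ms latency, positive SOA = visual
    leads), and each input registered to a slot. The trial is
    "synchronous" iff both inputs register to slots of equal rank.
    Returns the %-synchronous-by-SOA table and the Gaussian-fit PSS of
    the simulated curve (NaN if the fit is degenerate).
    """
    if phase_jitter_kappa is not None and not np.isfinite(phase_jitter_kappa):
        raise ValueError("phase_jitter_kappa must be finite (or None)")
    rng = np.random.default_rng(seed)
    cycle = config.cycle_ms
    if config.n_slots * config.slot_duration_ms(max(params.T_AA_ms, params.T_AV_ms)) > cycle + 1e-9:
        raise ValueError("n_slots * slot_duration exceeds the fP period")

    soa_levels = np.asarray(soa_levels_ms, dtype=float)
    d_A = config.slot_duration_ms(params.T_AA_ms)
    d_V = config.slot_duration_ms(params.T_AV_ms)

    def jitter(phi_ms: float, size: int) -> np.ndarray:
        if phase_jitter_kappa is None:
            return np.full(size, phi_ms)
        mu = 2.0 * np.pi * phi_ms / cycle
        draws = rng.vonmises(mu - np.pi, phase_jitter_kappa, size) + np.pi
        return draws * cycle / (2.0 * np.pi)

    rows = []
    for soa in soa_levels:
        phiA = jitter(params.phiA_ms, n_trials)
        phiV = jitter(params.phiV_ms, n_trials)
        arr_A = soa + params.latency_A_ms
        arr_V = params.latency_V_ms
        n_sync = 0
        for i in range(n_trials):
            kA = _registered_slot(
                arr_A, phiA[i], params.alpha_mult, params.T_AA_ms,
                config.n_slots, d_A, cycle,
            )
            kV = _registered_slot(
                arr_V, phiV[i], params.alpha_mult, params.T_AV_ms,
                config.n_slots, d_V, cycle,
            )
            if kA is not None and kA == kV:
                n_sync += 1
        rows.append({"soa_ms": soa, "pct_synchronous": 100.0 * n_sync / n_trials})
    curve = pd.DataFrame(rows)

    pct = dict(zip(curve["soa_ms"], curve["pct_synchronous"]))
    try:
        fit = _behavior.fit_psychometric(pct)
        pss = fit.pss_ms
    except (ValueError, RuntimeError):
        pss = float("nan")
    return curve, pss
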