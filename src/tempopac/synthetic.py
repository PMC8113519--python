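"""Synthetic neural and behavioral data with known ground truth.

Generates (i) single-region epochs containing an alpha-band oscillation
(frequency-for-phase, fP) with a nested fast oscillation (frequency-for-
amplitude, fA) whose envelope is modulated at a controllable preferred
phase along the fP cycle, embedded in 1/f^beta noise, and (ii) Bernoulli
simultaneity-judgment trial tables whose synchronous-response probability
follows a Gaussian of SOA with a trial-history-dependent point of
subjective simultaneity (PSS).

Sign convention, package-wide: positive SOA means the visual stimulus
leads the auditory stimulus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PacGroundTruth",
    "BehaviorGroundTruth",
    "EpochSet",
    "generate_pac_epoch",
    "generate_epoch_set",
    "generate_behavior",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PacGroundTruth:
    """Generative parameters of one phase-amplitude-coupled signal.

    ``preferred_phase_rad`` is the phase of the slow (fP) cycle at which
    the fast (fA) envelope is maximal; phase 0 is the fP peak (Hilbert
    convention for a cosine), pi the trough. ``phase_kappa`` optionally
    adds trial-to-trial von Mises jitter of the preferred phase
    (None = the phase is fixed across trials).
    """

    fP_hz: float = 10.0
    fA_hz: float = 60.0
    modulation_depth: float = 0.9
    preferred_phase_rad: float = np.pi
    alpha_amplitude: float = 1.0
    fast_amplitude: float = 0.5
    noise_exponent: float = 1.0
    snr_db: float | None = 5.0
    phase_kappa: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise ValueError(
                f"modulation_depth must be in [0, 1], got {self.modulation_depth}"
            )
        if self.fA_hz <= 2.0 * self.fP_hz:
            raise ValueError(
                f"fA ({self.fA_hz} Hz) must exceed 2*fP ({2 * self.fP_hz} Hz) "
                "for clean nesting"
            )
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        # wrap the preferred phase into [0, 2*pi)
        object.__setattr__(
            self, "preferred_phase_rad", float(self.preferred_phase_rad) % TWO_PI
        )


@dataclass(frozen=True)
class BehaviorGroundTruth:
    """Generative parameters of a simultaneity-judgment session.

    The synchronous-response probability at a given SOA is
    ``p_max * exp(-(SOA - PSS_cond)^2 / (2 sigma^2))`` where PSS_cond
    depends on the modality lead of the previous trial (t-1:V vs t-1:A).
    ``pss_t1V_ms >= pss_t1A_ms`` encodes positive temporal recalibration.
    """

    pss_t1V_ms: float = 55.0
    pss_t1A_ms: float = 21.0
    sigma_ms: float = 120.0
    p_max: float = 0.95
    soa_levels_ms: tuple = (
        0, 100, -100, 150, -150, 175, -175, 200, -200, 225, -225, 350, -350,
    )
    n_trials_per_cell: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be positive")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("p_max must be in (0, 1]")
        if len(self.soa_levels_ms) == 0:
            raise ValueError("soa_levels_ms must be nonempty")
        levels = set(self.soa_levels_ms)
        nonzero = {s for s in levels if s != 0}
        if {-s for s in nonzero} != nonzero:
            raise ValueError("soa_levels_ms must be symmetric about 0")
        if self.pss_t1V_ms < self.pss_t1A_ms:
            raise ValueError(
                "pss_t1V_ms >= pss_t1A_ms expected (positive recalibration)"
            )


@dataclass
class EpochSet:
    """Trials x samples array of one region's activity plus trial metadata.

    ``time`` is in seconds relative to nominal stimulus onset (t = 0).
    ``trials`` carries one row per trial: trial index, condition label,
    and the ground-truth identifier used to generate it.
    """

    data: np.ndarray
    time: np.ndarray
    fs_hz: float
    trials: pd.DataFrame
    roi_label: str = "sim"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (trials x samples)")
        if self.data.shape[1] != self.time.size:
            raise ValueError("time axis does not match data")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial table does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time", data=self.time)
            f.attrs["fs_hz"] = self.fs_hz
            f.attrs["roi_label"] = self.roi_label

    @classmethod
    def from_hdf5(cls, path: str | Path, trials: pd.DataFrame) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            time = f["time"][()]
            fs = float(f.attrs["fs_hz"])
            roi = str(f.attrs["roi_label"])
        return cls(data=data, time=time, fs_hz=fs, trials=trials, roi_label=roi)

    def write_metadata_csv(self, path: str | Path) -> None:
        self.trials.to_csv(path, index=False)


def _one_over_f_noise(
    n: int, fs_hz: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f^beta power spectrum, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_pac_epoch(
    truth: PacGroundTruth,
    duration_s: float = 4.0,
    fs_hz: float = 300.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phase-amplitude-coupled epoch.

    Returns ``(time, x)`` with time centered on t = 0 (nominal stimulus
    onset; the fP oscillation has phase 0, i.e. a peak, at t = 0).

    The signal is::

        x(t) = A_P cos(2 pi fP t)
             + A_A [1 - m (1 - cos(2 pi fP t - phi_pref)) / 2] cos(2 pi fA t + theta0)
             + noise

    with theta0 a random carrier phase and the 1/f^beta noise scaled so
    the oscillatory component sits at ``snr_db``. The bracketed
    modulator is a true (nonnegative) envelope: m = 1 modulates the fast
    amplitude fully between 0 and A_A, m = 0 not at all. With the same
    seed the output is bit-identical.
    """
    if duration_s < 1.0:
        raise ValueError("duration_s must be >= 1 s")
    if fs_hz < 4.0 * truth.fA_hz:
        raise ValueError(
            f"fs_hz = {fs_hz} too low for fA = {truth.fA_hz} Hz "
            f"(need >= {4 * truth.fA_hz})"
        )
    if rng is None:
        rng = np.random.default_rng(truth.seed)

    n = int(round(duration_s * fs_hz))
    t = (np.arange(n) - n // 2) / fs_hz

    theta0 = rng.uniform(0.0, TWO_PI)
    phi = truth.preferred_phase_rad
    if truth.phase_kappa is not None:
        phi = rng.vonmises(phi - np.pi, truth.phase_kappa) + np.pi  # mean phi

    m = truth.modulation_depth
    slow = truth.alpha_amplitude * np.cos(TWO_PI * truth.fP_hz * t)
    envelope = 1.0 - m * (1.0 - np.cos(TWO_PI * truth.fP_hz * t - phi)) / 2.0
    fast = truth.fast_amplitude * envelope * np.cos(TWO_PI * truth.fA_hz * t + theta0)
    osc = slow + fast

    if truth.snr_db is None or math.isinf(truth.snr_db):
        return t, osc

    noise = _one_over_f_noise(n, fs_hz, truth.noise_exponent, rng)
    p_sig = float(np.mean(osc**2))
    p_noise = p_sig / (10.0 ** (truth.snr_db / 10.0))
    return t, osc + np.sqrt(p_noise) * noise


def generate_epoch_set(
    truth_per_condition: Mapping[str, PacGroundTruth],
    n_trials: int,
    fs_hz: float = 300.0,
    epoch_window_s: tuple[float, float] = (-2.0, 2.0),
    seed: int = 0,
    roi_label: str = "sim",
) -> EpochSet:
    """Generate an interleaved epoch set, ``n_trials`` per condition.

    ``truth_per_condition`` maps condition labels (e.g. ``"t-1:V"``,
    ``"t-1:A"``) to their generative parameters; condition-specific
    preferred phases encode the injected phase shift. Trials are
    interleaved at random (seeded) and per-trial metadata records the
    condition and ground-truth id.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    allowed = {"t-1:V", "t-1:A"}
    if not set(truth_per_condition) <= allowed:
        raise ValueError(f"conditions must be a subset of {allowed}")
    lo, hi = epoch_window_s
    if lo > -0.5 or hi < 0.5:
        raise ValueError("epoch window must cover at least -0.5 to +0.5 s")

    duration = hi - lo
    conditions = sorted(truth_per_condition)
    labels = np.repeat(conditions, n_trials)
    master = np.random.default_rng(seed)
    order = master.permutation(labels.size)
    labels = labels[order]

    seeds = np.random.SeedSequence(seed).spawn(labels.size)
    epochs, rows = [], []
    time = None
    for i, (label, ss) in enumerate(zip(labels, seeds)):
        truth = truth_per_condition[label]
        t, x = generate_pac_epoch(
            truth, duration_s=duration, fs_hz=fs_hz, rng=np.random.default_rng(ss)
        )
        if time is None:
            n = t.size
            time = t + (lo + hi) / 2.0  # recenter on the requested window
        epochs.append(x)
        rows.append(
            {
                "trial": i,
                "condition": label,
                "truth_id": f"{label}/fP={truth.fP_hz}/fA={truth.fA_hz}",
                "seed_id": i,
            }
        )

    trials = pd.DataFrame(rows)
    return EpochSet(
        data=np.vstack(epochs), time=time, fs_hz=fs_hz, trials=trials,
        roi_label=roi_label,
    )


def write_ground_truth_json(
    truth_per_condition: Mapping[str, PacGroundTruth], path: str | Path
) -> None:
    """Ground-truth sidecar for test harnesses."""
    payload = {k: asdict(v) for k, v in truth_per_condition.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def _lead_of(soa_ms: float) -> str:
    if soa_ms > 0:
        return "V"
    if soa_ms < 0:
        return "A"
    return "sync"


def generate_behavior(truth: BehaviorGroundTruth) -> pd.DataFrame:
    """Generate a simultaneity-judgment trial table.

    Allocation is deterministic: exactly ``n_trials_per_cell`` trials per
    SOA level, presented in a seeded random order. The previous-trial
    condition (``prev_lead``) is taken from the realized sequence, and
    each response is Bernoulli with the Gaussian probability of the
    condition the trial actually followed. Trials whose predecessor was
    synchronous (or absent) use the midpoint of the two condition PSS.
    """
    rng = np.random.default_rng(truth.seed)
    soas = np.repeat(np.asarray(truth.soa_levels_ms, dtype=float),
                     truth.n_trials_per_cell)
    soas = soas[rng.permutation(soas.size)]

    prev = np.empty(soas.size, dtype=object)
    prev[0] = "none"
    prev[1:] = [_lead_of(s) for s in soas[:-1]]

    pss = np.where(
        prev == "V",
        truth.pss_t1V_ms,
        np.where(
            prev == "A",
            truth.pss_t1A_ms,
            0.5 * (truth.pss_t1V_ms + truth.pss_t1A_ms),
        ),
    ).astype(float)

    p_sync = truth.p_max * np.exp(-((soas - pss) ** 2) / (2.0 * truth.sigma_ms**2))
    sync = rng.random(soas.size) < p_sync

    return pd.DataFrame(
        {
            "trial": np.arange(soas.size),
            "soa_ms": soas,
            "current_lead": [_lead_of(s) for s in soas],
            "prev_lead": prev,
            "response": np.where(sync, "synchronous", "asynchronous"),
        }
    )
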