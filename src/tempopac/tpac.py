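"""Time-resolved phase-amplitude coupling (tPAC).

The estimator slides a window over an epoch; in each window, for each of
the fast-frequency (fA) sub-bands, the signal is band-pass filtered and
its Hilbert envelope extracted. The slow frequency most coupled to that
envelope (fP*) is the frequency of the largest envelope-spectrum peak in
the slow band that co-occurs with a peak of the raw-signal spectrum. The
signal is then filtered around fP*, its Hilbert phase phi_P extracted,
and coupling measured from the complex vector z(t) = Env_A(t) e^{i phi_P(t)}:

    strength = |mean z| / RMS(Env_A)      (dimensionless, in [0, 1])
    preferred phase = arg(mean z)         (wrapped to [0, 2 pi))

The winning (fP*, fA sub-band) per window is the pair of maximal
strength; ties go to the lower fA sub-band. Filters are even-order
linear-phase FIR (Kaiser design) applied with zero net delay, and edge
ringing is confined outside the analysis window by requiring a signal
buffer containing 99% of the filter's impulse-response energy.

Phase convention: Hilbert phase of the fP*-filtered trace, 0 rad at the
alpha peak and pi at the trough; all phases are wrapped to [0, 2 pi).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

__all__ = [
    "TpacConfig",
    "design_bandpass",
    "buffer_length",
    "buffered_filter",
    "detect_coupled_fp",
    "envelope_modulation",
    "coupling_vector",
    "best_window",
    "tpac_epoch",
    "tpac_epoch_set",
    "trough_locked_map",
    "screen_alpha_peak",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class TpacConfig:
    """Estimator settings; defaults target alpha-nested beta/gamma coupling."""

    fp_band_hz: tuple[float, float] = (8.0, 12.0)
    fa_band_hz: tuple[float, float] = (16.0, 84.0)
    n_fa_bins: int = 18
    window_s: float = 0.5
    overlap: float = 0.5
    n_surrogates: int = 500
    stopband_db: float = 40.0
    transition_frac: float = 0.15
    buffer_energy: float = 0.99
    fp_star_halfwidth_hz: float = 1.5
    cooccur_tol_bins: float = 1.0
    analysis_span_s: tuple[float, float] = (-0.5, 0.5)
    #: bandwidth of the filter applied around each fA sub-band center;
    #: must be at least twice the top of the slow band so the modulation
    #: sidebands (fA +/- fP) survive filtering. None = 2 * fp_band top.
    fa_filter_bandwidth_hz: float | None = None

    def __post_init__(self) -> None:
        if self.n_fa_bins < 2:
            raise ValueError("n_fa_bins must be >= 2")
        if not (0.0 < self.overlap < 1.0):
            raise ValueError("overlap must be in (0, 1)")
        if self.fa_band_hz[0] <= 2.0 * self.fp_band_hz[1]:
            import warnings

            warnings.warn(
                "fA band overlaps twice the fP band; nesting may be unclean",
                stacklevel=2,
            )

    @property
    def fa_edges(self) -> np.ndarray:
        """Edges of the equal-width fA sub-bands."""
        return np.linspace(self.fa_band_hz[0], self.fa_band_hz[1],
                           self.n_fa_bins + 1)

    @property
    def fa_centers(self) -> np.ndarray:
        e = self.fa_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def fa_subband_width_hz(self) -> float:
        return (self.fa_band_hz[1] - self.fa_band_hz[0]) / self.n_fa_bins

    def fa_filter_bands(self) -> list[tuple[float, float]]:
        """Filter band around each sub-band center.

        The bandwidth defaults to twice the top of the slow band (the
        envelope of a narrower band cannot carry the slow modulation);
        the lower edge is clipped above the slow band to keep the slow
        oscillation itself out of the fast envelope.
        """
        bw = self.fa_filter_bandwidth_hz
        if bw is None:
            bw = 2.0 * self.fp_band_hz[1]
        floor = self.fp_band_hz[1] + 1.0
        return [
            (max(fc - bw / 2.0, floor), fc + bw / 2.0) for fc in self.fa_centers
        ]

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)


@lru_cache(maxsize=512)
def _design_bandpass_cached(
    lo_hz: float, hi_hz: float, fs_hz: float, stopband_db: float,
    transition_frac: float,
) -> np.ndarray:
    width_hz = transition_frac * lo_hz
    if lo_hz - width_hz / 2.0 <= 0 or hi_hz + width_hz / 2.0 >= fs_hz / 2.0:
        raise ValueError(
            f"band [{lo_hz}, {hi_hz}] Hz too close to 0 or Nyquist for a "
            f"{width_hz:.2f} Hz transition at fs = {fs_hz} Hz"
        )
    numtaps, beta = signal.kaiserord(stopband_db, width_hz / (0.5 * fs_hz))
    numtaps |= 1  # odd taps = even order, exactly symmetric kernel
    kernel = signal.firwin(
        numtaps, [lo_hz, hi_hz], window=("kaiser", beta),
        pass_zero=False, fs=fs_hz,
    )
    kernel.setflags(write=False)
    return kernel


def design_bandpass(
    lo_hz: float,
    hi_hz: float,
    fs_hz: float,
    stopband_db: float = 40.0,
    transition_frac: float = 0.15,
) -> np.ndarray:
    """Even-order linear-phase FIR band-pass kernel (Kaiser design).

    The kernel is symmetric about its midpoint; applying it centered
    (half-order delay compensation) yields zero-phase, zero-delay
    filtering. The transition width is ``transition_frac`` of the lower
    band edge.
    """
    if not (0.0 < lo_hz < hi_hz < fs_hz / 2.0):
        raise ValueError("need 0 < lo < hi < fs/2")
    return _design_bandpass_cached(
        float(lo_hz), float(hi_hz), float(fs_hz), float(stopband_db),
        float(transition_frac),
    )


def buffer_length(kernel: np.ndarray, energy: float = 0.99) -> int:
    """Samples of buffer needed on each side of the analysis window.

    Smallest half-width L around the kernel center such that the
    cumulative |h|^2 energy within +/-L reaches ``energy`` of the total.
    """
    h2 = kernel**2
    total = h2.sum()
    mid = kernel.size // 2
    cum = h2[mid]
    for L in range(1, mid + 1):
        if cum >= energy * total:
            return L - 1
        cum += h2[mid - L] + h2[mid + L]
    return mid


def _zero_phase_filter(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric odd-length kernel with zero net delay."""
    return signal.fftconvolve(x, kernel, mode="same")


def buffered_filter(
    x: np.ndarray,
    kernel: np.ndarray,
    window: tuple[int, int],
    energy: float = 0.99,
) -> np.ndarray:
    """Zero-phase filtering returning exactly the analysis-window samples.

    ``window`` is the (start, stop) sample range of the analysis window
    within ``x``. The signal must extend beyond the window on both sides
    by at least the 99%-energy buffer of the kernel, so that filter edge
    ringing stays outside the returned samples.
    """
    start, stop = window
    if not (0 <= start < stop <= x.size):
        raise ValueError("invalid analysis window")
    need = buffer_length(kernel, energy)
    if start < need or x.size - stop < need:
        raise ValueError(
            f"insufficient buffer: need {need} samples on each side of the "
            f"analysis window, have {start} before and {x.size - stop} after"
        )
    return _zero_phase_filter(x, kernel)[start:stop]


def _spectrum(x: np.ndarray, fs_hz: float, df_hz: float = 0.25):
    """Hann-tapered, zero-padded magnitude spectrum of a short window."""
    x = x - x.mean()
    w = signal.windows.hann(x.size)
    nfft = max(sp_fft.next_fast_len(x.size), int(round(fs_hz / df_hz)))
    spec = np.abs(np.fft.rfft(x * w, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    return freqs, spec


def detect_coupled_fp(
    window_signal: np.ndarray,
    envelope_a: np.ndarray,
    fp_band: tuple[float, float],
    fs_hz: float,
    tol_hz: float | None = None,
) -> float | None:
    """Frequency in the slow band most coupled to the fast envelope.

    fP* is the frequency of the largest envelope-spectrum peak within
    ``fp_band`` that co-occurs (within ``tol_hz``, default one raw-window
    spectral bin) with a peak of the raw-signal spectrum. Returns None
    when no co-occurring peak exists — absence is a valid outcome.
    """
    if window_signal.size < 2 * fs_hz / fp_band[0]:
        raise ValueError("window shorter than 2 cycles of the slow band")
    if tol_hz is None:
        tol_hz = fs_hz / window_signal.size

    f_env, ps_env = _spectrum(envelope_a, fs_hz)
    f_sig, ps_sig = _spectrum(window_signal, fs_hz)

    env_peaks, _ = signal.find_peaks(ps_env)
    sig_peaks, _ = signal.find_peaks(ps_sig)
    if env_peaks.size == 0 or sig_peaks.size == 0:
        return None

    in_band = (f_env[env_peaks] >= fp_band[0]) & (f_env[env_peaks] <= fp_band[1])
    env_peaks = env_peaks[in_band]
    if env_peaks.size == 0:
        return None

    sig_freqs = f_sig[sig_peaks]
    # candidates co-occurring with a raw-spectrum peak, strongest first
    for k in env_peaks[np.argsort(ps_env[env_peaks])[::-1]]:
        if np.min(np.abs(sig_freqs - f_env[k])) <= tol_hz:
            return float(f_env[k])
    return None


def envelope_modulation(
    envelope_a: np.ndarray,
    fs_hz: float,
    fp_band: tuple[float, float] = (8.0, 12.0),
) -> tuple[float | None, float]:
    """Relative modulation depth of the envelope at its slow-band peak.

    Returns ``(peak_hz, ratio)`` where ratio is the Fourier amplitude of
    the largest slow-band envelope peak divided by the envelope mean
    (the fraction of the mean envelope that oscillates at the candidate
    coupled frequency). An uncoupled envelope has a small ratio even
    when an incidental spectral peak exists; detections with ratio below
    ~0.3 should be treated as weak and left to the surrogate test.
    ``(None, 0.0)`` when no slow-band local maximum exists.
    """
    env = np.asarray(envelope_a, dtype=float)
    e = env - env.mean()
    w = signal.windows.hann(e.size)
    nfft = max(sp_fft.next_fast_len(e.size), int(round(fs_hz / 0.25)))
    coef = np.abs(np.fft.rfft(e * w, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    peaks, _ = signal.find_peaks(coef**2)
    peaks = peaks[(freqs[peaks] >= fp_band[0]) & (freqs[peaks] <= fp_band[1])]
    if peaks.size == 0 or env.mean() <= 0:
        return None, 0.0
    k = peaks[np.argmax(coef[peaks])]
    amp = 2.0 * coef[k] / w.sum()
    return float(freqs[k]), float(amp / env.mean())


def coupling_vector(
    envelope_a: np.ndarray, phase_p: np.ndarray
) -> tuple[float, float]:
    """Coupling strength and preferred phase from Env_A and phi_P.

    strength = |mean(Env_A e^{i phi_P})| / RMS(Env_A), in [0, 1];
    preferred phase = arg(mean(Env_A e^{i phi_P})) wrapped to [0, 2 pi).
    """
    env = np.asarray(envelope_a, dtype=float)
    ph = np.asarray(phase_p, dtype=float)
    if env.shape != ph.shape:
        raise ValueError("envelope and phase must have equal length")
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    rms = np.sqrt(np.mean(env**2))
    if rms == 0:
        raise ValueError("all-zero envelope")
    z = np.mean(env * np.exp(1j * ph))
    return float(np.abs(z) / rms), float(np.angle(z) % TWO_PI)


def _window_slices(
    time: np.ndarray, fs_hz: float, config: TpacConfig
) -> list[tuple[float, int, int]]:
    """(center_s, start_idx, stop_idx) of each sliding window."""
    span_lo, span_hi = config.analysis_span_s
    win = config.window_s
    hop = config.hop_s
    n_win = int(np.floor((span_hi - span_lo - win) / hop + 1e-9)) + 1
    out = []
    n_samp = int(round(win * fs_hz))
    for k in range(n_win):
        t0 = span_lo + k * hop
        start = int(round((t0 - time[0]) * fs_hz))
        out.append((t0 + win / 2.0, start, start + n_samp))
    return out


def _round_fp(fp: float) -> float:
    # quantize fP* for filter-kernel caching; 0.25 Hz is finer than the
    # envelope-spectrum resolution of a 500-ms window
    return round(fp * 4.0) / 4.0


def fp_phase(
    x: np.ndarray, fp_star: float, fs_hz: float, config: TpacConfig
) -> np.ndarray:
    """Hilbert phase of the signal filtered around fP*."""
    fp = _round_fp(fp_star)
    kern = design_bandpass(
        fp - config.fp_star_halfwidth_hz,
        fp + config.fp_star_halfwidth_hz,
        fs_hz,
        config.stopband_db,
        config.transition_frac,
    )
    filt = _zero_phase_filter(x, kern)
    return np.angle(_analytic(filt))


def _analytic(x: np.ndarray) -> np.ndarray:
    n = x.size
    nfft = sp_fft.next_fast_len(n)
    return signal.hilbert(x, N=nfft)[:n]


def tpac_epoch(
    x: np.ndarray,
    time: np.ndarray,
    fs_hz: float,
    config: TpacConfig | None = None,
    keep_series: bool = False,
) -> pd.DataFrame:
    """tPAC over one epoch; one row per sliding window.

    For every window and fA sub-band: band-pass filter, Hilbert envelope,
    detect fP*, filter at fP*, Hilbert phase, coupling vector. The row
    reports the winning (fP*, fA sub-band center) with its strength and
    preferred phase; a window where no sub-band yields a co-occurring fP*
    gives a null (NaN) row. The epoch must extend beyond the analysis
    span by the filter buffers on both sides.

    With ``keep_series=True`` the winning window's envelope and phase
    series are attached (used by the surrogate machinery).
    """
    if config is None:
        config = TpacConfig()
    x = np.asarray(x, dtype=float)
    windows = _window_slices(time, fs_hz, config)

    # filter once per sub-band over the whole epoch, check the buffer on
    # the outermost analysis samples
    first_start = min(w[1] for w in windows)
    last_stop = max(w[2] for w in windows)
    envs = []
    for lo, hi in config.fa_filter_bands():
        kern = design_bandpass(
            lo, hi, fs_hz, config.stopband_db, config.transition_frac
        )
        need = buffer_length(kern, config.buffer_energy)
        if first_start < need or x.size - last_stop < need:
            raise ValueError(
                f"insufficient buffer for sub-band [{lo:.1f}, {hi:.1f}] Hz: "
                f"need {need} samples beyond the analysis span"
            )
        envs.append(np.abs(_analytic(_zero_phase_filter(x, kern))))

    tol = config.cooccur_tol_bins * fs_hz / int(round(config.window_s * fs_hz))
    phase_cache: dict[float, np.ndarray] = {}
    rows = []
    for center, start, stop in windows:
        xw = x[start:stop]
        best = None
        for fa_center, env in zip(config.fa_centers, envs):
            envw = env[start:stop]
            fp_star = detect_coupled_fp(
                xw, envw, config.fp_band_hz, fs_hz, tol_hz=tol
            )
            if fp_star is None:
                continue
            fp_key = _round_fp(fp_star)
            if fp_key not in phase_cache:
                phase_cache[fp_key] = fp_phase(x, fp_star, fs_hz, config)
            phw = phase_cache[fp_key][start:stop]
            strength, phi = coupling_vector(envw, phw)
            cand = (strength, -fa_center, fp_star, phi, envw, phw)
            if best is None or cand[:2] > best[:2]:  # ties -> lower fA
                best = cand
        if best is None:
            row = {
                "window_center_s": center,
                "fp_star_hz": np.nan,
                "fa_star_hz": np.nan,
                "strength": np.nan,
                "phase_rad": np.nan,
            }
        else:
            strength, neg_fa, fp_star, phi, envw, phw = best
            row = {
                "window_center_s": center,
                "fp_star_hz": fp_star,
                "fa_star_hz": -neg_fa,
                "strength": strength,
                "phase_rad": phi,
            }
            if keep_series:
                row["envelope"] = envw
                row["phase"] = phw
        rows.append(row)
    return pd.DataFrame(rows)


def tpac_epoch_set(epochs, config: TpacConfig | None = None,
                   keep_series: bool = False) -> pd.DataFrame:
    """Run :func:`tpac_epoch` over an :class:`~tempopac.synthetic.EpochSet`."""
    frames = []
    for i in range(epochs.n_trials):
        df = tpac_epoch(epochs.data[i], epochs.time, epochs.fs_hz, config,
                        keep_series=keep_series)
        df.insert(0, "trial", epochs.trials["trial"].iloc[i])
        df.insert(1, "condition", epochs.trials["condition"].iloc[i])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def best_window(result: pd.DataFrame) -> pd.DataFrame:
    """Per-trial summary: the window row of maximal coupling strength.

    The final per-trial coupling score is the (fP*, fA*) combination that
    yielded the maximum strength across windows; trials where no window
    produced a coupled pair are dropped.
    """
    valid = result.dropna(subset=["strength"])
    if "trial" not in valid.columns:
        return valid.loc[[valid["strength"].idxmax()]]
    idx = valid.groupby("trial")["strength"].idxmax()
    return valid.loc[idx].reset_index(drop=True)


def write_tpac_csv(result: pd.DataFrame, path) -> None:
    cols = [c for c in ("trial", "condition", "window_center_s", "fp_star_hz",
                        "fa_star_hz", "strength", "phase_rad")
            if c in result.columns]
    result[cols].to_csv(path, index=False)


def _morlet_power(
    x: np.ndarray, fs_hz: float, freqs: np.ndarray, n_cycles: float = 7.0
) -> np.ndarray:
    """Time-frequency power via complex Morlet convolution."""
    out = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (TWO_PI * f)
        half = int(np.ceil(4 * sigma_t * fs_hz))
        t = np.arange(-half, half + 1) / fs_hz
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        out[i] = np.abs(signal.fftconvolve(x, w, mode="same")) ** 2
    return out


def trough_locked_map(
    x: np.ndarray,
    fp_star: float,
    fs_hz: float,
    tf_band: tuple[float, float] = (16.0, 120.0),
    n_freqs: int = 30,
    epoch_s: float = 1.0,
    config: TpacConfig | None = None,
) -> dict:
    """Average time-frequency map locked to troughs of the fP* oscillation.

    Filters the continuous signal around fP*, detects its troughs,
    extracts ``epoch_s``-long epochs centered on each trough and averages
    their Morlet time-frequency decompositions along with the raw traces.
    Needs at least 10 detected troughs.
    """
    if config is None:
        config = TpacConfig()
    kern = design_bandpass(
        fp_star - config.fp_star_halfwidth_hz,
        fp_star + config.fp_star_halfwidth_hz,
        fs_hz, config.stopband_db, config.transition_frac,
    )
    slow = _zero_phase_filter(x, kern)
    min_dist = int(0.8 * fs_hz / fp_star)
    troughs, _ = signal.find_peaks(-slow, distance=min_dist)

    half = int(round(epoch_s * fs_hz / 2))
    buf = buffer_length(kern, config.buffer_energy)
    lo_ok = max(half, buf)
    troughs = troughs[(troughs >= lo_ok) & (troughs < x.size - lo_ok)]
    if troughs.size < 10:
        raise ValueError(f"too few troughs: {troughs.size} < 10")

    freqs = np.linspace(tf_band[0], tf_band[1], n_freqs)
    tf = _morlet_power(x, fs_hz, freqs)
    lags = np.arange(-half, half + 1) / fs_hz
    tf_avg = np.zeros((freqs.size, lags.size))
    trace_avg = np.zeros(lags.size)
    for k in troughs:
        tf_avg += tf[:, k - half : k + half + 1]
        trace_avg += x[k - half : k + half + 1]
    tf_avg /= troughs.size
    trace_avg /= troughs.size
    return {
        "freqs_hz": freqs,
        "lags_s": lags,
        "tf_power": tf_avg,
        "avg_trace": trace_avg,
        "trough_indices": troughs,
    }


def screen_alpha_peak(
    freqs_hz: np.ndarray,
    psd: np.ndarray,
    fp_band: tuple[float, float] = (8.0, 12.0),
    prominence_db: float = 6.0,
) -> tuple[bool, float | None]:
    """Screen a power spectrum for a well-defined alpha peak.

    A well-defined slow-band spectral peak is a prerequisite for
    meaningful coupling estimation; recordings without one are excluded.
    Fits a 1/f background (log-log linear fit over 2-40 Hz, excluding a
    guard band around the slow band) and passes iff a local maximum inside
    ``fp_band`` exceeds the background by ``prominence_db``.

    Returns ``(passed, peak_hz)``; ``peak_hz`` is the in-band local
    maximum of the background-corrected spectrum (None if no local
    maximum exists in band).
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs_hz.min() > 2.0 or freqs_hz.max() < 40.0:
        raise ValueError("PSD must cover 2-40 Hz")

    fit_mask = (
        (freqs_hz >= 2.0)
        & (freqs_hz <= 40.0)
        & ~((freqs_hz >= fp_band[0] - 1.0) & (freqs_hz <= fp_band[1] + 1.0))
        & (psd > 0)
    )
    logf = np.log10(freqs_hz[fit_mask])
    logp = np.log10(psd[fit_mask])
    slope, intercept = np.polyfit(logf, logp, 1)

    band = (freqs_hz >= fp_band[0]) & (freqs_hz <= fp_band[1]) & (freqs_hz > 0)
    idx = np.flatnonzero(band)
    background = 10.0 ** (intercept + slope * np.log10(freqs_hz[idx]))
    excess_db = 10.0 * np.log10(np.maximum(psd[idx] / background, 1e-30))

    # local maxima of the corrected spectrum within the band
    peaks, _ = signal.find_peaks(excess_db)
    if peaks.size == 0:
        return False, None
    k = peaks[np.argmax(excess_db[peaks])]
    passed = bool(excess_db[k] >= prominence_db)
    return passed, float(freqs_hz[idx[k]])
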