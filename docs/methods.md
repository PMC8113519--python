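# Methods

## Signal model and generator

A synthetic epoch is

x(t) = A_P cos(2π f_P t) + A_A [1 − m(1 − cos(2π f_P t − φ))/2] cos(2π f_A t + θ₀) + n(t)

with f_P ∈ 8–12 Hz (alpha; default 10), f_A ∈ 16–84 Hz (default 60),
modulation depth m ∈ [0, 1] (default 0.9), preferred phase φ (the alpha
phase at which the fast envelope peaks; Hilbert convention, 0 = alpha
peak, π = trough), a per-trial random carrier phase θ₀ (so coupling is a
property of the envelope, not of waveform alignment), and n(t) Gaussian
1/f^β noise (β default 1.0) synthesized in the frequency domain and
scaled so that the oscillatory component sits at the requested SNR
(default 5 dB). The bracketed modulator is a true nonnegative envelope:
m = 1 swings the fast amplitude fully between 0 and A_A, m = 0 not at
all. Amplitudes default to A_P = 1, A_A = 0.5 — a dominant alpha rhythm
with a weaker fast component, the regime in which the estimator must
operate. An optional von Mises concentration parameter adds
trial-to-trial jitter of φ; it is off by default because trial-wise
phase variability of real recordings is not characterized well enough
to fix a value.

Behavioral sessions draw, for each trial, a Bernoulli "synchronous"
response with probability p_max·exp(−(SOA − PSS_c)²/(2σ²)), where PSS_c
belongs to the condition realized by the *previous* trial (t-1:V or
t-1:A; trials following a synchronous or absent predecessor use the
midpoint). Defaults: PSS 55/21 ms, σ = 120 ms, p_max = 0.95, the 13
signed SOA levels 0, ±100, ±150, ±175, ±200, ±225, ±350 ms with exactly
n trials per level (deterministic allocation, seeded presentation
order). Sign convention throughout: positive SOA = visual leads.

What the generator does **not** emulate: non-sinusoidal or drifting
alpha (the synthetic rhythm is strictly periodic), multichannel/sensor
geometry, evoked responses, response lapses or bias. Passing tests
therefore demonstrate estimator correctness under the stated generative
assumptions, not robustness to every property of real recordings; the
strict periodicity matters specifically for the surrogate null (below).

## Time-resolved coupling estimation

Epochs are analyzed in 500-ms windows with 50% overlap over −0.5 to
+0.5 s (three windows centered at −250, 0, +250 ms). For each of 18
equal-width fast-frequency sub-bands: the signal is band-pass filtered,
the Hilbert envelope Env_A extracted, and the coupled slow frequency
fP\* identified as the largest envelope-spectrum peak in the slow band
that co-occurs — within ±1 spectral bin of the raw window periodogram,
2 Hz at the default window — with a peak of the raw-signal spectrum
(spectra are Hann-tapered and zero-padded to a ≤0.25 Hz grid; absence of
a co-occurring peak is a valid "no coupling" outcome). The signal is
then filtered at fP\* ± 1.5 Hz, its Hilbert phase φ_P extracted, and

strength = |mean(Env_A e^{iφ_P})| / RMS(Env_A),  preferred phase = arg(mean(Env_A e^{iφ_P})).

RMS normalization guarantees strength ≤ 1 (|mean(Env e^{iφ})| ≤
mean Env ≤ RMS Env) and makes the measure invariant to global amplitude
scaling; mean-power and mean-amplitude normalizations were considered
and RMS chosen for the boundedness argument. The per-trial summary is
the (fP\*, fA sub-band) pair of maximal strength across windows; ties go
to the lower fA sub-band (deterministic).

Two implementation points deserve emphasis:

- **fA filter bandwidth.** The 18 sub-bands (width 3.78 Hz by default)
  define candidate center frequencies, but the filter applied around
  each center has a bandwidth of twice the top of the slow band (24 Hz
  default), lower edge clipped just above the slow band. An envelope
  can only carry modulation at frequencies up to half the filter
  bandwidth; a 3.78-Hz-wide filter would strip the f_A ± f_P sidebands
  and no estimator downstream could see the coupling.
- **Filtering.** All filters are even-order linear-phase FIR kernels
  (Kaiser design, 40 dB stopband, transition width 15% of the lower
  band edge), applied centered so the net delay is zero. Edge ringing
  is confined outside the analysis span by requiring the signal to
  extend on both sides by the half-width containing 99% of the kernel's
  impulse-response energy — for the alpha band at 300 Hz this is ≈0.9 s,
  hence the generator's default ±2 s epochs.

Trough-locked maps (evidence visualization) filter at fP\*, detect
troughs, and average 1-s Morlet time-frequency decompositions centered
on them. Alpha-peak screening fits a log-log linear 1/f background over
2–40 Hz (excluding a guard band around alpha) and requires an in-band
local maximum ≥ 6 dB above it; at that threshold pure 1/f noise passes
< 5% of the time while synthetic alpha signals exceed the threshold by
> 15 dB.

## Surrogate null and its limits

Significance of coupling strength uses block-permutation surrogates:
the window's envelope is split into 5 blocks (equal counts, remainder
to the last), the blocks are permuted (identity excluded; 500 draws),
and strength recomputed against the intact phase series. RMS(Env) is
permutation-invariant, so only the numerator varies. Per-trial z-scores
against the surrogate distribution are summarized as mean z (tested
one-sided against the critical value 2.24, the upper-tail normal
quantile at the Bonferroni-corrected α = 0.0125) and prevalence (% of
trials with z > 0); degenerate surrogate SDs are floored with a warning
and yield z = 0.

Limit worth knowing: with a 500-ms window and a *strictly periodic*
10 Hz rhythm, each block is exactly one alpha cycle and permutation is
a no-op — the surrogate null collapses onto the task value. Real alpha
is nonstationary enough to break this; for synthetic demonstrations the
package's tests use f_P = 9.17 Hz (block length incommensurate with the
cycle) or longer windows. The block scheme is conservative by
construction, and the pipeline's mean-z on perfectly periodic synthetic
alpha at 10 Hz should be read with that in mind.

## Circular statistics and conversions

Condition comparisons of preferred phases use a two-sample Kuiper test
(V = D⁺ + D⁻ on the circle; exactly invariant under joint rotation),
with the asymptotic tail probability under Stephens' small-sample
correction and a pooled-permutation fallback for samples under 10
angles (type-I error at α = 0.0125 verified within the binomial 95% CI
at n = 100 per sample, 2000 replicates). Phase-concentration tests are
Rayleigh tests (`pingouin`), and phase shifts are shortest-arc
differences in [0°, 180°]. Conversion to milliseconds is φ_ms =
1000·φ/(2π f_P). The recalibration-vs-period regression is IRLS with
Tukey bisquare weights (`statsmodels` RLM); r² is the squared Pearson
correlation of fitted vs observed (a robust fit has no canonical r²),
evaluated against 0.05/12. Per-subject source selection takes, among a
region's sources, the one with the largest *significant* Kuiper
difference; subjects with none are flagged and excluded from that
region's group test.

## Dynamic-insertion model

With φ the preferred coupling phase in ms along the alpha cycle, T_A
the fast-oscillation period, and α a scalar placing slot s1 at
φ − αT_A, registration of both inputs to s1 at the PSS gives
φ_A − αT_AA = PSS + 20 and φ_V − αT_AV = 50 (20/50 ms = auditory/visual
cortical latencies), combining to PSS = φ_A − (φ_V − 50)(T_AA/T_AV) − 20,
independent of α. α is assumed equal across cortices. Slots are
half-open intervals of one full fA period by default (a half-cycle mode
exists, motivated by the view that each fast half-cycle transiently
releases inhibition), with n_slots = 3 by default and
n_slots × slot duration bounded by the alpha period. The simulator
jitters φ per trial (von Mises), wraps cortical arrival times into the
alpha cycle (checking adjacent cycles so slots straddling the boundary
still register), declares a trial synchronous iff slot ranks match, and
returns the Gaussian-fit PSS of the resulting curve. Because the visual
registration equation anchors φ_V to the 50-ms arrival, consistency
simulations draw φ_V so that the visual input falls inside s1; the
simulated PSS then matches the closed form to within half a slot width
(the closed form pins the lobe edge, the fitted mean sits inside the
lobe).

## Psychometrics

Percent-synchronous curves are computed per SOA within each
trial-history pool (previous trial V-lead vs A-lead; synchronous/first
trials excluded from both pools). The psychometric model is a
3-parameter Gaussian A·exp(−(x−μ)²/(2σ²)) fit by bounded least squares
(A ∈ (0, 100], σ ∈ (1, 1000] ms; initialization A = max %, μ = argmax
SOA, σ = half the SOA range); a lapse/baseline term is available but
off by default. PSS = μ; TR = PSS(t-1:V) − PSS(t-1:A). Fits use all SOA
levels; the exclusion of 0 and ±350 ms trials (`filter_analysis_trials`)
is applied for the neural analyses, where those SOAs fall outside the
ambiguity range that drives recalibration. Ratio analyses
(asynchronous/synchronous per t × t-1 cell) use paired Wilcoxon
signed-rank tests at 0.05/4; zero-synchronous cells are flagged NaN and
dropped from tests.

At the reference design of 320 trials per SOA level, PSS recovery has a
median absolute error near 2 ms and TR bias below 0.5 ms over 50 seeds.
(For context: with only ~320 trials *in total* per condition pool the
PSS standard error is ~7 ms — parameter-recovery claims at the
few-millisecond level require the per-level design.)

## Problem sizes and numerical choices

Simulation studies use fs = 300 Hz, 4-s epochs, 40 epochs per condition
for the end-to-end run, 50 seeds for recovery suites, 500 surrogates,
and 2000 replicates for type-I calibration — sizes at which every
reported quantity is stable at its stated tolerance and the whole suite
runs in well under a minute. fP\* values are quantized to 0.25 Hz for
filter-kernel caching (finer than the envelope-spectrum resolution of a
500-ms window). All randomness flows from explicit seeds
(`numpy.random.default_rng` / `SeedSequence` substreams per pipeline
stage), making every output byte-reproducible.

## Known limitations

- The estimator's frequency resolution for fP\* is limited by the
  500-ms window (2 Hz raw; sub-bin localization via zero-padding).
- fA\* localization is limited to about one sub-band width: adjacent
  sub-band filters overlap heavily (by design, see bandwidth note).
- The surrogate scheme is conservative and degenerates for strictly
  periodic slow rhythms commensurate with the block length.
- The insertion model's mapping from tPAC preferred phase to φ in ms
  uses the circular mean of the coupling vector; alternative readings
  (e.g. centering on fast-oscillation event midpoints) would shift φ by
  a constant and cancel in condition differences, which are the tested
  quantities.
- Model-level claims are about condition differences and
  self-consistency; absolute PSS predictions inherit the assumed 20/50
  ms latencies.
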