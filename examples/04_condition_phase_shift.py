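"""Circular comparison of preferred coupling phases between trial
histories, and the phase-to-milliseconds conversion.

Injects a 126-degree preferred-phase difference between t-1:A and t-1:V
epochs at fP = 10 Hz, estimates per-trial phases with the coupling
estimator, tests the two circular distributions (Kuiper) and converts
the group shift to milliseconds along the alpha cycle — which should
land near 35 ms, the behavioral recalibration scale.
"""

import numpy as np
from scipy.stats import circmean

from tempopac import pac_stats as pst
from tempopac import synthetic as syn
from tempopac import tpac as tp

truths = {
    "t-1:A": syn.PacGroundTruth(preferred_phase_rad=np.deg2rad(147.6), seed=0),
    "t-1:V": syn.PacGroundTruth(preferred_phase_rad=np.deg2rad(273.6), seed=0),
}
epochs = syn.generate_epoch_set(truths, n_trials=40, fs_hz=300.0, seed=42)
result = tp.tpac_epoch_set(epochs)
valid = result.dropna(subset=["strength"])

phases = {c: valid.loc[valid.condition == c, "phase_rad"].to_numpy()
          for c in truths}
v, p = pst.kuiper_two_sample(phases["t-1:A"], phases["t-1:V"])
means = {c: np.rad2deg(circmean(a, high=2 * np.pi)) for c, a in phases.items()}
shift_deg = pst.circular_shift_deg(means["t-1:A"], means["t-1:V"])
fp_mean = valid["fp_star_hz"].mean()
shift_ms = pst.phase_to_ms(np.deg2rad(shift_deg), fp_mean)

print(f"Kuiper two-sample: V = {v:.3f}, p = {p:.2e}")
for c, m in means.items():
    z, pr, _ = pst.rayleigh_test(phases[c])
    print(f"{c}: circular mean {m:6.1f} deg (Rayleigh p = {pr:.2e})")
print(f"phase shift = {shift_deg:.1f} deg -> {shift_ms:.1f} ms at "
      f"fP* = {fp_mean:.2f} Hz (injected 126 deg = 35 ms)")
# The shift of gamma bursts along the alpha cycle, expressed in ms,
# matches the magnitude of behavioral temporal recalibration.
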