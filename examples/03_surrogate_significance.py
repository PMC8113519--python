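"""Surrogate-based significance of coupling strength.

Compares the coupling strength of a strongly coupled signal against a
null distribution built by permuting 5 blocks of the gamma envelope
(destroying genuine envelope-phase alignment), and repeats the exercise
for pure noise.
"""

import numpy as np
from scipy.signal import hilbert

from tempopac import pac_stats as pst
from tempopac import synthetic as syn
from tempopac import tpac as tp

FS = 300.0
kern = tp.design_bandpass(48.0, 72.0, FS)
cfg = tp.TpacConfig()
window = slice(300, 600)  # 1-s pre-stimulus window


def strength_and_null(truth):
    _, x = syn.generate_pac_epoch(truth, 4.0, FS)
    env = np.abs(hilbert(tp._zero_phase_filter(x, kern)))[window]
    ph = tp.fp_phase(x, truth.fP_hz, FS, cfg)[window]
    task, _ = tp.coupling_vector(env, ph)
    surr = pst.block_surrogates(env, ph, n_surr=500, seed=0)
    return task, surr


coupled = syn.PacGroundTruth(fP_hz=9.17, modulation_depth=0.9, snr_db=None, seed=1)
task, surr = strength_and_null(coupled)
z = (task - surr.mean()) / surr.std(ddof=1)
print(f"coupled signal: strength {task:.3f}, surrogate 97.5th pct "
      f"{np.percentile(surr, 97.5):.3f}, z = {z:.1f}")

noise = syn.PacGroundTruth(modulation_depth=0.0, fast_amplitude=0.0,
                           snr_db=-20.0, seed=2)
task, surr = strength_and_null(noise)
z = (task - surr.mean()) / surr.std(ddof=1)
print(f"uncoupled noise: strength {task:.3f}, surrogate 97.5th pct "
      f"{np.percentile(surr, 97.5):.3f}, z = {z:.1f}")

print(f"critical z at alpha = 0.0125 (one-tailed): {pst.critical_z(0.0125):.2f}")
# Genuine coupling stands far outside its surrogate null; for noise the
# task value is indistinguishable from the permuted distribution.
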