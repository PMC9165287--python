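"""B0 and B1 correction on a miscalibrated voxel.

Shifts a spectrum by a known B0 offset, recovers the shift from the
spline-interpolated spectrum minimum, corrects it, and then corrects a
three-level B1 acquisition with the exponential fit — printing the
recovered values next to the ground truth.
"""
import numpy as np

from cest_subtyper import (AcquisitionParams, FieldMaps, ZStack,
                           apply_b0_correction, correct_b1, estimate_b0,
                           simulate_zspectrum)
from cest_subtyper.synthetic_cohort import nawm_pools

acq = AcquisitionParams(noise_sd=0.0)

# --- B0: recover a +0.30 ppm water-frequency shift ---------------------
true_shift = 0.30
shifted = simulate_zspectrum(nawm_pools(), b0_shift=true_shift,
                             noise_sd=0.003, seed=7, acq=acq)
est = estimate_b0(shifted)
print(f"B0 shift: true {true_shift:+.3f} ppm, "
      f"estimated {est.shift_ppm:+.3f} ppm (edge flag: {est.at_edge})")
corrected = apply_b0_correction(shifted, est.shift_ppm)
ref = simulate_zspectrum(nawm_pools(), noise_sd=0.003, seed=7, acq=acq)
sel = np.abs(ref.offsets_ppm) >= 1.0
print(f"residual |Z - reference| beyond 1 ppm: "
      f"max {np.abs(corrected.signal - ref.signal)[sel].max():.4f}")

# --- B1: exponential fit through three saturation levels ---------------
relb1 = 0.9
offs = acq.offsets
stacks = {lvl: ZStack(np.full((1, 1, offs.size),
                              0.6 + 0.3 * np.exp(-0.8 * lvl * relb1)),
                      offs, b1_uT=lvl) for lvl in (1.7, 2.0, 2.3)}
fm = FieldMaps(np.zeros((1, 1)), np.full((1, 1), relb1))
out = correct_b1(stacks, fm, target_b1=2.0)
print(f"\nB1 correction at relative B1 = {relb1}:")
print(f"  fitted Z at nominal 2.0 uT : {out.signal[0, 0, 0]:.5f}")
print(f"  closed form 0.6+0.3*e^-1.6 : {0.6 + 0.3 * np.exp(-1.6):.5f}")
print("(the voxel was measured at effective 1.53/1.80/2.07 uT; the fit"
      " extrapolates to the nominal level)")
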