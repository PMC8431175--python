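"""Water-fat separation round trip: how well are PDFF and T2* recovered?

Simulates a noiseless and an SNR-50 acquisition of the same phantom and
reconstructs both with the variable-projection estimator.  The noiseless
round trip is exact to numerical precision; under noise the in-mask RMSE
quantifies the estimator's precision.
"""

import numpy as np

import myofat as mf

truth = mf.generate_phantom(shape=(32, 32, 18), seed=1)
union = truth.union_mask

clean = mf.simulate_signal(truth, snr=None)
maps = mf.separate(clean)
err = np.abs(maps.pdff - truth.pdff)[union]
print(f"noiseless: max |PDFF error| = {err.max():.2e} pp")

noisy = mf.simulate_signal(truth, snr=50.0, seed=3)
maps50 = mf.separate(noisy)
diff = (maps50.pdff - truth.pdff)[union]
t2s_err = (maps50.t2star - 1000.0 / truth.r2star)[union]
print(f"SNR 50:    PDFF RMSE = {np.sqrt(np.mean(diff ** 2)):.2f} pp, "
      f"mean bias = {diff.mean():+.3f} pp")
print(f"           T2* mean bias = {np.nanmean(t2s_err):+.2f} ms")
print(f"field map recovered to {np.abs(maps.fieldmap - truth.fieldmap_hz)[union].max():.2e} Hz (noiseless)")
# PDFF errors well under 1 pp mean that regional differences of a few pp
# (the scale of the study's proximal-vs-distal contrasts) are resolvable.
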