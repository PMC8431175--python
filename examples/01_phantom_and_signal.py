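"""Generate a two-muscle digital phantom and its multi-echo MRI signal.

The phantom holds two tubular muscles along the slice axis: a psoas-like
single strand and an erector-like strand pair with an intermuscular fat
streak.  Each muscle's PDFF is prescribed per lengthwise third; the
six-echo bipolar gradient-echo signal is then forward-simulated at 3 T.
"""

import numpy as np

import myofat as mf
from myofat.regional import split_thirds

protocol = mf.AcquisitionProtocol()  # 6 echoes, TE1 1.14 ms, dTE 0.8 ms, 3 T
truth = mf.generate_phantom(shape=(32, 32, 18), protocol=protocol, seed=1)

print("echo times (ms):", np.round(protocol.echo_times * 1000, 2))
for name, mask in truth.masks.items():
    split = split_thirds(mask)
    means = [truth.pdff[s.voxels].mean()
             for s in (split.proximal, split.middle, split.distal)]
    print(f"{name:8s} {mask.n_voxels:5d} voxels, "
          f"true per-third PDFF (prox/mid/dist): "
          f"{means[0]:.1f} / {means[1]:.1f} / {means[2]:.1f} %")

series = mf.simulate_signal(truth, protocol, snr=50.0, seed=2)
print("signal shape (echoes, x, y, z):", series.signal.shape)
print("first-echo in-mask mean |s|:",
      round(float(np.abs(series.signal[0][truth.union_mask]).mean()), 3))
# The per-third PDFF means are the ground truth the reconstruction must
# recover; SNR 50 is a realistic in-vivo magnitude signal-to-noise level.
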