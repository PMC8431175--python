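# myofat

Chemical-shift-encoded MRI analysis of skeletal-muscle composition:
proton-density fat-fraction (PDFF) and T2\* mapping by complex-based
water–fat separation, regional (proximal/middle/distal) muscle metrics from
segmentation masks, longitudinal maximum-change statistics, and
cohort-level correlation analyses — together with a digital-phantom and
synthetic-cohort module that provides ground truth for every stage.

## The problem

Cancer cachexia depletes skeletal muscle, and muscle fat infiltration
(myosteatosis) measured by MRI is a candidate biomarker for monitoring it.
A multi-echo gradient-echo acquisition encodes the chemical shift between
water and fat protons: the complex signal of a voxel at echo time
`TE_n = TE1 + (n-1)ΔTE` is modelled as

```
s_n = (W + F·Σ_p a_p·exp(i2π f_p TE_n)) · exp(i2π ψ TE_n) · exp(−R2*·TE_n)
      · exp(iφ0) · exp(i(−1)^n θ)
```

with `W, F` the water/fat amplitudes, `{f_p, a_p}` a six-peak fat spectrum,
`ψ` the B0 field map (Hz), `R2*` the common effective relaxation rate,
`φ0` an initial phase and `θ` an echo-parity eddy-current phase from the
bipolar readout. Estimation uses variable projection (VARPRO): for each
candidate `(ψ, R2*)` the amplitudes are solved linearly, and the candidate
grid optimum is polished by per-voxel pattern search; a median-filter
consistency pass on `ψ̂` suppresses water–fat swaps. Then

```
PDFF = 100·|F̂| / (|Ŵ| + |F̂|)   [%]        T2* = 1000 / R̂2*   [ms]
```

From a PDFF map and a muscle mask (voxels with T2\* outside [5, 100] ms are
excluded from the PDFF average only), the measurements are

```
total volume   = n_voxels × voxel volume
fat volume     = meanPDFF/100 × total volume
contractile    = total − fat
```

per whole muscle and per lengthwise third of the mask's occupied slice
span. Longitudinally, the **maximum change** versus baseline (largest
magnitude, sign kept; absolute for PDFF, relative for volumes) feeds a
statistical battery: Lilliefors-gated Pearson/Spearman correlations with
maximum BMI change, age-controlled partial correlations, cachectic-vs-non
t-tests (Fearon consensus classification) and per-section ANOVAs.

## Worked example

```python
import numpy as np, myofat as mf

truth = mf.generate_phantom(shape=(32, 32, 18), seed=1)   # known PDFF per third
series = mf.simulate_signal(truth, snr=50.0, seed=3)      # 6-echo bipolar signal
maps = mf.separate(series)                                # water–fat separation
diff = (maps.pdff - truth.pdff)[truth.union_mask]
print(f"PDFF RMSE {np.sqrt(np.mean(diff**2)):.2f} pp, bias {diff.mean():+.3f} pp")
```

prints

```
PDFF RMSE 0.59 pp, bias +0.025 pp
```

i.e. at SNR 50 the reconstruction resolves fat-fraction differences well
below the few-percentage-point regional contrasts of interest (noiselessly
the round trip is exact to ~2e-5 pp). The cohort stage
(`examples/05_cohort_statistics.py`) plants a marginal correlation of
−0.5 between baseline psoas fat volume and maximum BMI change and recovers
it through the full pipeline:

```
planted marginal r = -0.50  recovered r = -0.507 (p = 1.8e-53, method pearson)
planted age-partial r = -0.469  recovered = -0.495 (p = 1.4e-50)
```

Each script in `examples/` demonstrates one capability: phantom + signal
simulation, water–fat separation, mask metrics, longitudinal changes, and
cohort statistics. A thin CLI mirrors the stages
(`myofat simulate|fit|metrics|regional|longitudinal|stats|run`).

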