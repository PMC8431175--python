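"""From PDFF/T2* maps and a segmentation mask to muscle measurements.

Applies the T2* voxel filter (retain [5, 100] ms), splits each muscle into
lengthwise thirds and reports mean PDFF, total volume, fat volume
(= meanPDFF x total) and contractile volume (= total - fat) per section.
"""

import myofat as mf
from myofat.regional import SECTION_NAMES, split_thirds

truth = mf.generate_phantom(shape=(32, 32, 18), seed=1)
series = mf.simulate_signal(truth, snr=50.0, seed=4)
maps = mf.separate(series)

print(f"{'muscle':8s} {'section':9s} {'PDFF %':>7s} {'total mL':>9s} "
      f"{'fat mL':>7s} {'lean mL':>8s} {'vox':>5s}")
for name, mask in truth.masks.items():
    sections = [("total", mask)]
    split = split_thirds(mask)
    sections += [(s, split.sections()[s]) for s in SECTION_NAMES]
    for sec_name, sec_mask in sections:
        filtered = mf.apply_t2star_filter(sec_mask, maps.t2star)
        m = mf.compute_metrics(maps.pdff, sec_mask, filtered, muscle=name, section=sec_name)
        print(f"{name:8s} {sec_name:9s} {m.mean_pdff:7.2f} {m.total_volume_ml:9.2f} "
              f"{m.fat_volume_ml:7.2f} {m.contractile_volume_ml:8.2f} {m.n_voxels_total:5d}")
# Fat + contractile always reconstitute the total volume; the erector-like
# muscle shows its prescribed distal-dominant fat gradient.
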