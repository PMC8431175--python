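"""Longitudinal change metrics and Fearon cachexia classification.

For a subject with several follow-up scans the "maximum change" is the
change versus baseline with the largest magnitude (sign preserved) --
absolute for PDFF (percentage points), relative for volumes (% of
baseline).  Cachexia is classified from windowed weight loss.
"""

import myofat as mf

days = [0, 90, 180, 270]
psoas_volume = [294.1, 280.0, 267.0, 271.5]   # mL
psoas_pdff = [9.7, 10.1, 10.6, 10.4]          # %

vol = mf.max_change(days, psoas_volume, mode="relative", metric="psoas volume")
pdff = mf.max_change(days, psoas_pdff, mode="absolute", metric="psoas PDFF")
print(f"max relative volume change: {vol.relative_change_pct:+.1f} % "
      f"(at day {vol.followup_day:.0f})")
print(f"max absolute PDFF change:   {pdff.absolute_change:+.1f} pp "
      f"(at day {pdff.followup_day:.0f})")

print("BMI for 80 kg / 1.79 m:", round(mf.compute_bmi(80, 1.79), 2), "kg/m2")

# Subject reporting 6 kg lost before baseline, then measured follow-ups:
history = mf.weight_history_from_self_report(74.0, 6.0) + [(90, 71.0), (180, 69.0)]
flag, criterion = mf.classify_cachexia(history, bmi=23.5)
print(f"cachectic: {flag} (criterion: {criterion})")
# The volume loss peaks at day 180 (-9.2%) even though the last scan partly
# recovered -- the maximum-change rule keeps the largest excursion.
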