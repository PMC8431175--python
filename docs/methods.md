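# Methods

## Signal model and estimator

A voxel's complex signal across the six-echo bipolar gradient-echo train is

    s_n = (W + F·c_n) · exp(i2π ψ TE_n) · exp(−R2*·TE_n) · exp(iφ0) · exp(i(−1)^n θ),
    c_n = Σ_p a_p · exp(i2π f_p TE_n),     TE_n = TE1 + (n−1)ΔTE,  n = 1…6.

Defaults follow the acquisition the package emulates: TE1 = 1.14 ms,
ΔTE = 0.8 ms, 3 T, 3×3×6 mm³ voxels, bipolar readout. The fat spectrum is
the standard six-peak triglyceride model (shifts 0.60, −0.39, −1.94, −2.60,
−3.40, −3.80 ppm; weights 0.048, 0.039, 0.004, 0.128, 0.693, 0.087,
normalised to sum 1); peak frequencies are `shift · 42.577 MHz/T · B0`. Any
normalised spectrum can be substituted. The echo-parity eddy phase uses the
convention `exp(i(−1)^n θ)` with 1-based echo index (echo 1 carries −θ).

**Estimation (variable projection).** `W` and `F` are complex — their
shared phase absorbs φ0, and allowing a relative phase keeps the linear
subproblem exactly solvable: for each candidate `(ψ, R2*)` the 2-column
basis `[φ_n, c_n φ_n]`, `φ_n = exp((i2πψ − R2*)TE_n)`, gives the amplitudes
by a closed-form 2×2 Hermitian solve and the projected misfit in closed
form. The nonlinear search is a shared coarse grid (default ψ ∈ [−200, 200]
Hz step 4, R2* ∈ [0, 300] s⁻¹ step 20) scanned vectorised over all voxels,
followed by a per-voxel pattern search (8 neighbours, step halving on
failure, ≤ 40 iterations) whose final resolution is far below 1e-3 Hz.
`fit_voxel` additionally polishes with Nelder–Mead. The refinement can only
improve on the grid optimum, which is the property the brute-force oracle
test checks. PDFF is the magnitude ratio `100|F̂|/(|Ŵ|+|F̂|)`, bounded to
[0, 100] by construction; its small noise bias (the magnitude of a noisy
complex estimate is biased upward) is accepted and measured rather than
corrected — at SNR 50 the mean bias is well under 0.1 pp.

**Swap suppression.** The ψ-likelihood has secondary minima roughly a
water–fat shift away, which flip water and fat. Because the simulated field
maps are smooth, one pass of 3D median filtering (3³ kernel) on ψ̂ flags
voxels deviating by > 30 Hz; those are re-fit with ψ constrained to ±45 Hz
of the local median. This is a deliberate lightweight surrogate for
region-growing field-map methods and is adequate for smooth phantoms; it is
not expected to match scanner implementations on pathological field maps.

**T2\*.** `T2* = 1000/R̂2*` ms. Voxels whose R̂2* lands on a search bound
(including 0) are reported as NaN rather than clamped, so the downstream
[5, 100] ms filter sees honest values.

**Eddy phase.** θ is estimated globally by a bounded 1D scalar
minimisation of the pooled projected misfit over the 96 strongest-signal
voxels (each objective evaluation runs a shortened grid + refinement).
Noiseless accuracy is ~1e-5 rad; a monopolar protocol returns 0 with a
warning. The estimate is invariant to a global φ0 shift because φ0 is
projected out per voxel.

## Phantom

Two tubular "muscles" run along the slice (inferior–superior) axis, low
slice indices proximal: a psoas-like single elliptical strand and an
erector-like pair of strands joined by a ~1-voxel bridge of intermuscular
fat (+45 pp PDFF) emulating the fatty streaks between paraspinal muscle
groups. Per-muscle PDFF is prescribed per lengthwise third (defaults:
psoas 11.2/10.0/9.5 %, erector 14.1/15.2/22.5 % proximal/middle/distal,
the scale of the study population's regional means); a smooth zero-mean
variation (±1.5 pp, shrunk near 0 and 100 so a target of 0 yields pure
water exactly) is added and each third is recentred so its mask-mean PDFF
equals the target exactly. Background tissue has amplitude 0.5 (muscle
1.0) and 3 % PDFF. The field map is a smooth plane-plus-random-blob field
scaled to a 60 Hz peak by default (100 Hz in the acceptance ladder); R2*
is 35 s⁻¹ in muscle (T2* ≈ 28.6 ms, inside the filter band) and 45 s⁻¹
outside. Noise at a requested SNR is circular complex Gaussian with total
complex SD `σ = mean in-mask |s_1| / SNR` (components σ/√2, so
E|n|² = σ²). Every random component flows from one seeded generator;
phantoms are bit-reproducible per seed.

What the phantom does **not** emulate: realistic organ anatomy, k-space
effects, coil sensitivities, motion, partial-volume mixing at boundaries
beyond whole-voxel assignment, and the scanner vendor's (unpublished)
reconstruction. Passing round trips therefore validate the package's own
pipeline — internal consistency, not equivalence with scanner output.

## Muscle metrics and regional split

Volumes are exact voxel counts × voxel volume (no interpolation,
no partial-volume correction). The T2\* filter removes voxels outside
[5, 100] ms *from the PDFF average only* — total volume always uses the
full mask, fat volume is filtered-mean-PDFF/100 × full-mask volume, and
contractile = total − fat, so fat + contractile reconstitutes the total by
construction. Bounds are inclusive (a voxel at exactly 5 or 100 ms is
kept) and configurable, as is a variant that also restricts the volume
factor to filtered voxels.

The lengthwise thirds partition the occupied slice span along the
annotated inferior–superior axis into three contiguous intervals differing
by ≤ 1 slice. Division is by slice count, not voxel terciles or physical
arc length (equivalent at uniform slice thickness); gap slices inside the
span still count toward length. Remainder rule for span 3q+r: r = 1 gives
the extra slice to the middle (configurable to proximal/distal); r = 2
gives one each to proximal and distal. The rule is symmetric, so flipping
the proximal annotation swaps the outer sections exactly. Proximal is the
superior end for both muscles (their anatomical origins are cranial).

## Longitudinal metrics

Maximum change versus baseline is the follow-up change of largest
magnitude with its sign preserved (losses stay negative); ties go to the
earliest follow-up. PDFF changes are ranked absolutely (percentage
points), volume changes relatively (% of baseline; a zero baseline is an
error). Cachexia follows the Fearon consensus over every observation pair
at most 183 days apart ("6 months"): >5 % loss; or >2 % loss with
BMI < 20 kg/m²; or >2 % loss with an externally supplied sarcopenia flag
(appendicular lean-mass indices are out of scope). A self-reported
pre-baseline loss is encoded as a pseudo-observation 183 days before
baseline, mirroring how baseline cachexia status is assessed from intake
information.

## Statistics

Normality gating uses the Lilliefors variant of the Kolmogorov–Smirnov
test (parameters estimated from the sample; statsmodels table p-values,
deterministic) at α = 0.05: raw-normal variables stay raw, log-normal ones
are log-transformed, and Spearman's rank correlation (mid-ranks for ties)
replaces Pearson when either variable is normal on neither scale. The
independent-samples t-test is pooled-variance by default (Welch optional);
ANOVA is classical one-way. The age-controlled association is the
first-order partial correlation
`r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` (identical to the
residual-regression formulation, which the tests exploit as an independent
oracle), with a rank-transformed variant in the Spearman branch; p via the
t approximation with n−3 df. All p-values are two-sided; no multiplicity
correction is applied (the battery is explorative by design); missing data
are deleted pairwise per test. The battery emits one row per muscle ×
section (total + 3) × metric (PDFF, total, fat, contractile) — 32 rows —
plus cachectic-vs-non comparisons and per-section maximum-change ANOVAs.

## Synthetic cohort

Defaults mirror the study population: 56 subjects, age 63.0 ± 11.8 y, BMI
25.4 ± 4.4 kg/m², self-reported pre-baseline loss 4.3 ± 5.5 kg (clipped to
[0, 20]), psoas fat/total volume 28.5 ± 11.1 / 294.1 ± 115.3 mL, erector
804.7 ± 243.4 mL total, 1–4 follow-ups weighted 15/5/1/1 at 44–239-day
first offsets, maximum BMI change −2.11 ± 1.99 kg/m². The planted effect
is constructed from a shared age factor plus a correlated Gaussian pair so
that both the marginal fat-volume/BMI-change correlation (default −0.5)
and the age-partial correlation (derived, exposed as
`CohortSpec.true_partial_corr`) are exact generator parameters. BMI
trajectories interpolate linearly to the drawn maximum change at the last
follow-up, so the pipeline's maximum-change computation recovers the
planted value; muscle volumes shrink at a per-subject rate (7.5 ± 5 % per
100 days) modulated by a section profile (0.6/1.0/1.6
proximal/middle/distal) so regional-change ANOVAs have signal. Known
departures from the study: every synthetic subject receives follow-ups,
and the simple weight trajectory plus the stated self-report distribution
yields a higher baseline cachexia rate (~75 %) than the study's ~40 % —
acceptable because no planted quantity depends on the cachexia rate.

## Problem sizes and numerical choices

The acceptance script uses the 32×32×18 ten-level PDFF ladder (0–45 %,
|ψ| ≤ 100 Hz) for round trips, 100 random voxels against the exhaustive
1 Hz × 2 s⁻¹ oracle grid, 50 random masks for partition conservation, 10⁴
null replicates for the t-test's type-I error and an n = 5000 cohort for
correlation recovery; the suite's property tests use smaller versions of
the same constructions. Tolerances asserted in tests: noiseless round-trip
max error < 0.1 pp, SNR-50 RMSE < 1.5 pp and mean bias < 0.2 pp, T2\* bias
< 2 ms, eddy phase ±0.01 rad, statistics vs brute force 1e-10, type-I in
[0.04, 0.06], marginal recovery in (−0.55, −0.45) and partial recovery
inside the Fisher-z 95 % interval. Degenerate inputs are errors, not
silent defaults: all-zero voxels return unconverged zero fits, empty
filtered masks make mean PDFF undefined, constant samples are rejected by
the normality gate, and collinear controls are rejected by the partial
correlation.
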