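# Methods

## The measurement being emulated

A single-slice 2D CEST acquisition at 3 T: saturation offsets from −4 to
+4 ppm in 0.25 ppm steps (33 images), repeated at three saturation
amplitudes (B1rms = 1.7, 2.0, 2.3 µT; Tsat = 3.5 s, kept as metadata —
the signal model is steady-state), plus an unsaturated S0 image and a
relative-B1 map. All processing is per voxel on the S/S0-normalized
Z-spectrum.

## Synthetic Z-spectrum model

Each voxel's spectrum is a sum of Lorentzian saturation pools:

    Z(Δω) = 1 − Σᵢ Aᵢ(B1) · Lᵢ(Δω − δᵢ − B0) + ε,

with unit-peak Lorentzians L of full width Γᵢ, pool offsets δᵢ, the local
B0 shift (ppm), and Gaussian noise ε (default sd 0.005 of S0). The B1
dependence is a saturating law

    Aᵢ(B1) = aᵢ · g(B1)/g(2.0),   g(b) = b²/(b² + hᵢ²),

so the tabulated amplitude aᵢ is the pool depth at the 2.0 µT reference
and hᵢ ("half-saturation" B1) controls how fast the pool saturates. This
is deliberately not a Bloch-McConnell integration: a Lorentzian-sum with
a monotone saturating B1 law is the simplest model that produces spectra
with the right qualitative structure *and* supports the downstream
exponential-in-B1 correction. Pool parameters at 2.0 µT:

| pool  | δ (ppm) | Γ (ppm) | h (µT) | parenchyma a | fluid a |
|-------|---------|---------|--------|--------------|---------|
| water | 0       | 1.4 / 0.6 (fluid) | 0.7 / 0.6 | 0.40 | 0.85 |
| MT    | 0       | 40      | 1.2    | 0.46 (NAWM), 0.44 (tumour) | 0.03 |
| amide | +3.5    | 1.0     | 1.1    | 0.030 + group offset | 0.006 |
| amine | +2.0    | 1.2     | 1.3    | 0.050 + group offset | 0.010 |
| NOE   | −3.5    | 1.5     | 1.0    | 0.041 | 0.002 |

Constraints behind these numbers: (i) summed pool depths stay below 1 at
every offset up to the highest effective B1 (2.3 µT × 1.15 relB1); (ii)
the NAWM MTRasym spectrum crosses zero near +3 ppm (amide/amine CEST
balancing the NOE contribution, with slight NOE dominance above 3 ppm, as
observed in white matter at 2 µT); (iii) the far-offset NAWM signal sits
near 0.5 of S0 — the MT pedestal real white matter shows — which the
fluid-suppression weight relies on. The semisolid MT pool is modelled
symmetric about 0 ppm; its real slight asymmetry is deliberately omitted
so that asymmetry contrast is attributable to the amide/amine/NOE pools.

The fluid compartment (cysts, microcysts) has a narrow water line, almost
no MT, solute pools ≤ 20% of parenchymal and NOE ≈ 5%: its Z-spectrum
recovers towards 1 away from water — the shape feature fluid suppression
keys on.

## Subject and cohort generation

A subject is a 64×64 slice: an elliptical tumour ROI (~300 voxels), a
contralateral NAWM ROI, NAWM-like background. Fluid voxels occupy a
per-subject fraction of the tumour ROI, split between a compact cyst
(capped at 5% of the tumour, excluded from the "solid tumour" aggregate)
and scattered microcysts that stay inside the solid mask — the mechanism
that makes AB−FS positive in tumour while the cyst itself is excluded
from ROI averages. B0 and relative-B1 maps are smooth low-order cosine
fields; relB1 spans [0.85, 1.15]. The B0 field spans up to ±0.5 ppm, but
each subject draws a shim factor ~ Beta(1.5, 3.5), making typical shifts
~0.15 ppm with occasional near-worst-case subjects — a shimmed-brain
distribution rather than a uniformly worst-case one. This matters: the
edge-hold in B0 correction (below) produces an amide-band error of about
1.2% of S0 per ppm of local B0, and uniformly full-range fields would
inflate between-subject variance far beyond what patient cohorts show.

Four group presets (IDH-wild-type; IDH-mutant 1p/19q-retained with and
without fluid mismatch; codeleted; default sizes 9/15/7/13) set the
tumour amide/amine amplitudes and fluid fractions. They were solved
numerically (given the band-response matrix of the actual mapping code)
so that the *expected* NAWM-normalized metrics equal the reported group
medians — AB amide / AB amine / AB−FS amine of 1.13/0.59/0.015
(wild-type), 1.67/1.19/0.22 (retained with mismatch), 1.02/0.72/0.069
(retained without), 0.99/0.64/0.07 (codeleted) — which induces all the
qualitative orderings: ratio highest in wild-type, amide and amine
highest in retained, AB−FS amine largest in retained-with-mismatch.
Between-subject variability (pool-amplitude sd 0.0010/0.0009, fluid
fraction sd 0.01–0.02, NAWM baseline jitter 0.0005) is somewhat tighter
than the interquartile ranges patient data show; the choice favours
reliable reproduction of the reported group separations at desk-scale
cohort sizes over matching raw dispersion. The T2/FLAIR-mismatch label
is, by default, deterministically tied to the subject's fluid fraction
exceeding 0.21 (midpoint between the retained subgroups' presets);
a Bernoulli mode is available.

## Preprocessing

**Order**: B0 correction of each saturation level first, then the B1 fit
across levels.

**B0 estimate**: the abscissa of the minimum of a cubic-spline
interpolant of the Z-spectrum within ±1 ppm, on a 0.005 ppm grid
(WASSR-style on the spectrum itself, since direct field mapping is not
part of the protocol). The spline interpolates rather than smooths; at
the default noise level smoothing gains nothing measurable. A minimum at
the window edge is returned but flagged unreliable. The estimate is
computed once per subject on the 2.0 µT stack — the physical shift is
level-independent — and applied to all three levels.

**B0 correction**: cubic re-interpolation of the spectrum at
`offsets + shift` (implemented via a shared spline-coefficient array, so
it is exactly the per-voxel CubicSpline result, vectorized). Target
points beyond the sampled ±4 ppm are held at the nearest edge value and
the voxel flagged; this keeps the 1-ppm band grids intact at the cost of
a bias at the outermost band points proportional to the local shift.

**B1 correction**: per voxel and offset, `Z = a − b·exp(−c·B1)` is solved
exactly through the three points at effective B1 = level × relB1 (the
effective levels stay equally spaced because relB1 is a common factor;
the ratio of successive differences gives e^(−cΔ)). The solution exists
when the three points are strictly monotone and decelerating; otherwise —
a small noise-driven fraction of voxel-offsets — the voxel falls back to
monotone piecewise-linear interpolation/extrapolation in B1 and carries a
quality flag. With relB1 = 1 both paths return the measured 2.0 µT value
exactly (the target is a node). Whether the reference method fits per
offset or on a scalar contrast is not documented; this implementation
fits per offset.

## AB and FS contrast

MTRasym is computed by index mirroring on the symmetric grid, reported in
percent of S0; band metrics are unweighted 5-point means (1 ppm at
0.25 ppm spacing) centred at 3.5 and 2.0 ppm. The fluid-suppressed model
is multiplicative: FS = (1 − w)·AB per voxel, with the fluid weight

    w = logistic((f − θ)/σ),   f = 0.6·S_far + 0.4·(1 − Γ/Γ_ref),

where S_far is the mean Z over |ω| ∈ [3.5, 4] ppm (both sides) and Γ the
FWHM of a single-Lorentzian fit (free baseline; grid search over Γ with
closed-form linear least squares, parabolic refinement) to the
direct-saturation line over |ω| ≤ 1.5 ppm. Defaults θ = 0.62, σ = 0.05,
Γ_ref = 1.4 ppm; all configurable. The published fluid-suppression rule
is described only as attenuating fluid signal based on Z-spectrum shape;
this weight is a faithful stand-in built from the two shape features that
distinguish fluid (high far-offset signal; narrow water line). The
construction guarantees |FS| ≤ |AB|, AB−FS = w·AB with the sign of AB,
w ≈ 0 in parenchyma (NAWM AB−FS medians < 0.01%) and w ≈ 1 in fluid.
If the linewidth fit fails (wrong-sign slope), w falls back to the
far-signal feature alone with Γ treated as neutral, flagged. Voxel
failures are always flagged, never raised, so ROI statistics degrade
gracefully.

## Subject metrics and classification

Each band metric is mean(map over tumour∖cyst) − mean(map over NAWM).
Ratios are ratios of these normalized metrics (amide over amine), not
voxelwise ratios; when an amine denominator falls below ε = 0.05 percent
the subject's ratios are NaN and flagged, and flagged subjects drop out
of ratio-based statistics pairwise. A subject is QC-flagged when more
than 20% of its solid-tumour voxels carry processing flags. Binary AB/FS
mismatch is "AB−FS larger than the cut point", strict inequality, on the
amine channel by default (thresholds default to the published 0.039 /
0.18 for amide/amine; rule configurable to amide/either/both).

## Statistics

All implemented in-package and validated against enumeration oracles:
exact two-tailed sign test (doubled binomial tail, ties dropped); exact
Mann-Whitney U (full rank-assignment null by dynamic programming) when
min(n) ≤ 10 without ties, else tie-corrected normal approximation with
continuity correction; tie-corrected Kruskal-Wallis against χ²(k−1);
Conover-Iman rank post hoc on t(N−k), gated on Kruskal-Wallis p < 0.05
(override available, marked non-gated) with Holm adjustment by default;
Fisher's exact test, two-tailed by the probability-mass convention in
exact integer arithmetic; Shapiro-Wilk per Royston's approximation,
logged as a screen only. ROC analysis counts pairs (ties ½), flips
orientation when AUC < 0.5 (recorded), takes candidate thresholds at
midpoints of consecutive distinct scores plus ±∞, and picks the cut point
nearest the (0,1) corner (ties broken towards higher sensitivity, then
lower threshold). The "nearest to (0,1)" criterion is the standard
ROC-corner reading; Youden's J is the natural alternative and the corner
distance is monotone-related to it at these sample sizes.

The comparison report runs, per metric: Mann-Whitney for the two-group
partition (IDH status); Kruskal-Wallis + Conover-Iman for the three- and
four-group partitions; ROC appended for pairs significant after
adjustment. The agreement analysis restricts to the IDH-mutant
1p/19q-retained subgroup (where T2/FLAIR mismatch occurs), derives
per-channel AB−FS cut points by ROC against the T2/FLAIR label, assigns
AB/FS mismatch by the configured rule at those derived cut points
(fixed published thresholds optional), and tests the 2×2 agreement with
Fisher's exact test. Every report embeds the resolved configuration and
the conventions used.

## What the phantom does and does not show

The generator reproduces: the spectral structure (five pools plus fluid),
field inhomogeneity and its correction burden, ROI geometry with
cyst-excluded aggregation, group contrasts in the reported orderings and
magnitudes, and the fluid-mismatch ↔ T2/FLAIR coupling. It does not
emulate: Bloch-McConnell exchange dynamics or Tsat/duty-cycle effects,
Rician noise (Gaussian is used; at sd 0.005 the distinction is
immaterial), MT asymmetry, partial-volume mixing at ROI borders, motion,
or radiological reading variability (the T2/FLAIR label is generated, not
scored from images). Passing tests therefore demonstrate correctness of
the *processing* and the *statistical machinery* under a controlled
model, plus internal consistency of the biomarker logic — not clinical
performance on real gliomas. Numbers that depend on biological dispersion
(AUCs, cut points, Fisher p) are cleaner on the phantom than in patient
data; their orderings, not their magnitudes, are the reproduction target.

## Problem sizes and determinism

Default slice 64×64 (≈300-voxel tumour), 33 offsets, 3 B1 levels, cohort
44 subjects; one cohort simulates and analyses in a few seconds, and the
replicate-cohort acceptance check uses 10 cohorts. All randomness flows
from numpy `default_rng` seeds; per-subject seeds derive from the cohort
seed via `SeedSequence` and are recorded in the labels table, so any
subject can be regenerated in isolation. Identical configuration + seed
reproduces every CSV byte-for-byte.
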