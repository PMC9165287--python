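# cest-subtyper

Quantification of chemical exchange saturation transfer (CEST) MRI
Z-spectra for non-invasive glioma subtyping, together with a synthetic
phantom-cohort generator that makes the whole analysis testable without
patient data.

Gliomas are staged molecularly by IDH mutation and 1p/19q codeletion, but
these labels require tissue. CEST MRI probes exchangeable protons — amide
(–NH, +3.5 ppm from water) and amine (–NH₂, +2 ppm) groups of proteins and
peptides — through the water signal, and the balance of amide and amine
contrast differs between glioma subtypes. This package implements the full
analysis chain for a single-slice, multi-offset, multi-B1 CEST protocol:

1. **Z-spectrum preprocessing** — per-voxel B0 correction (spline minimum
   of the Z-spectrum, WASSR-style) and B1 correction (exponential fit
   `Z = a − b·e^(−c·B1)` through three saturation levels, evaluated at the
   nominal 2.0 µT).
2. **MTR-asymmetry mapping** — `MTRasym(Δω) = (Z(−Δω) − Z(+Δω))` on a
   0–4 ppm grid (step 0.25), in percent of S0; band metrics as 1-ppm
   averages centred at 3.5 ppm (amides, Δ3.5) and 2 ppm (amines, Δ2).
3. **Two contrast models** — asymmetry-based (AB) and fluid-suppressed
   (FS), where FS attenuates voxels whose Z-spectrum has the shape of free
   fluid (high far-offset signal, narrow direct-saturation line). The
   difference AB − FS is the *fluid-mismatch* biomarker.
4. **Nine subject metrics** — amide, amine and amide/amine ratio under AB,
   FS and AB−FS, each normalized by subtracting the contralateral
   normal-appearing white matter (NAWM) ROI mean.
5. **Statistics** — Shapiro-Wilk screen, sign test, exact Mann-Whitney U,
   Kruskal-Wallis with Conover-Iman post hoc (Holm-adjusted), Fisher's
   exact test, and ROC analysis with nearest-to-(0,1) cut points, arranged
   into per-partition comparison reports and the AB/FS-mismatch vs
   T2/FLAIR-mismatch agreement analysis.

Because no patient data ship with the package, a first-class synthetic
module (`cest_subtyper.synthetic_cohort`) generates multi-pool Lorentzian
Z-spectrum stacks — water, symmetric semisolid MT, amide, amine, NOE and a
fluid compartment — with per-voxel B0/relative-B1 fields, ROI masks and
ground-truth labels, calibrated so the cohort-level contrasts reproduce
the orderings reported for the four glioma groups (IDH-wild-type;
IDH-mutant 1p/19q-retained with and without AB/FS mismatch; codeleted).

## Worked example

`examples/04_cohort_statistics.py` simulates the default 44-subject
cohort (9/15/7/13), runs the full pipeline and prints:

```
amide/amine ratio, IDH-wt (n=9) vs IDH-mut (n=35):
  medians 2.08 vs 1.54; Mann-Whitney p = 3.5e-05; AUC = 0.91; cut point = 1.76

amine level, 1p/19q-retained vs codeleted: AUC = 0.99, cut point = 0.70 (sens 100% / spec 92%)

AB/FS mismatch vs T2/FLAIR mismatch (retained subgroup, n=22):
  contingency [[15, 0], [0, 7]], Fisher p = 5.9e-06
  AB-FS amine surrogate cut point = 0.125 (sens 100% / spec 100%)

71 of 90 group-metric comparisons significant after Holm adjustment.
```

Reading: IDH-wild-type tumours carry relatively more amide than amine
signal (higher ratio), so a threshold of ~1.7–1.8 on the NAWM-normalized
ratio separates them from IDH-mutant tumours; amine levels separate the
retained from the codeleted 1p/19q subgroups; and the AB−FS amine metric —
the amount of contrast removed by fluid suppression — tracks the
fluid-rich phenotype that radiologists recognise as T2/FLAIR mismatch.
The other examples show single-voxel spectra (`01`), the B0/B1 correction
with its closed-form check (`02`), and one subject's nine metrics (`03`).

## Command line

```sh
cest-subtyper all --seed 1 --out run/                 # simulate + analyze + stats
cest-subtyper simulate --n-per-group 2 2 2 2 --out run/
cest-subtyper analyze --input-dir run/cohort --out run/
cest-subtyper stats --metrics-csv run/analysis/metrics.csv --out run/
```

Outputs: per-subject NIfTI stacks and maps, `metrics.csv` (one row per
subject, nine metrics plus labels), `comparisons.csv` (test, p, AUC, cut
point, sensitivity/specificity per group pair and metric), `ab_vs_fs.csv`
(sign-test report), `agreement.json` and `run_metadata.json` with every
convention used. Identical config + seed reproduces all CSVs
byte-identically.

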