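"""ROI aggregation: the nine NAWM-normalized subject metrics, group
MTRasym/deltaMTRasym spectra, and the AB/FS-mismatch classifier.

Each band metric is the mean of the corresponding map over the solid
tumour (tumour minus cyst) minus its mean over contralateral NAWM.
Amide/amine ratios are ratios of these normalized band metrics; subjects
whose amine denominator falls below an epsilon guard are flagged and
excluded from ratio-based statistics rather than propagating infinities.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (FLAG_RATIO_GUARD, APTwMapSet, MTRasymSpectrum,
                         ROISet, SubjectLabels, SubjectMetrics)

__all__ = [
    "subject_metrics", "delta_mtr_asym", "group_spectra",
    "classify_abfs_mismatch", "roi_mean_spectrum", "metrics_table",
    "DEFAULT_ABFS_THRESHOLDS", "MISMATCH_RULES",
]

# Reported decision thresholds on the AB-FS amide / amine channels.
DEFAULT_ABFS_THRESHOLDS: Tuple[float, float] = (0.039, 0.18)
MISMATCH_RULES = ("amine", "amide", "either", "both")

QC_FLAG_FRACTION = 0.20      # subject flagged when >20% of solid voxels carry flags
DEFAULT_EPS_RATIO = 0.05     # percent units, guard on the amine denominator


def subject_metrics(maps: APTwMapSet, rois: ROISet,
                    eps_ratio: float = DEFAULT_EPS_RATIO,
                    labels: Optional[SubjectLabels] = None) -> SubjectMetrics:
    """The nine NAWM-normalized metrics for one subject."""
    solid = rois.solid
    if not solid.any():
        raise ValueError("solid tumour mask is empty after cyst exclusion")
    nawm = rois.nawm

    def norm(mapp: np.ndarray) -> float:
        return float(mapp[solid].mean() - mapp[nawm].mean())

    ab_amide = norm(maps.ab_amide)
    ab_amine = norm(maps.ab_amine)
    fs_amide = norm(maps.fs_amide)
    fs_amine = norm(maps.fs_amine)
    abfs_amide = ab_amide - fs_amide
    abfs_amine = ab_amine - fs_amine

    ratio_flagged = (abs(ab_amine) < eps_ratio) or (abs(fs_amine) < eps_ratio)
    if ratio_flagged:
        ab_ratio = fs_ratio = abfs_ratio = float("nan")
    else:
        ab_ratio = ab_amide / ab_amine
        fs_ratio = fs_amide / fs_amine
        abfs_ratio = ab_ratio - fs_ratio

    qc_flagged = bool(maps.flags[solid].astype(bool).mean() > QC_FLAG_FRACTION)
    return SubjectMetrics(
        ab_amide=ab_amide, ab_amine=ab_amine,
        fs_amide=fs_amide, fs_amine=fs_amine,
        abfs_amide=abfs_amide, abfs_amine=abfs_amine,
        ab_ratio=ab_ratio, fs_ratio=fs_ratio, abfs_ratio=abfs_ratio,
        ratio_flagged=ratio_flagged, qc_flagged=qc_flagged,
        nawm_abfs_amide=float(maps.abfs_amide[nawm].mean()),
        nawm_abfs_amine=float(maps.abfs_amine[nawm].mean()),
        labels=labels)


def roi_mean_spectrum(offsets: np.ndarray, asym_values: np.ndarray,
                      mask: np.ndarray) -> MTRasymSpectrum:
    """ROI-mean MTRasym spectrum from per-voxel asymmetry values.

    asym_values: (ny, nx, n_pos) per-voxel asymmetry (percent); mask 2D.
    """
    if not mask.any():
        raise ValueError("empty ROI")
    return MTRasymSpectrum(offsets, asym_values[mask].mean(axis=0))


def delta_mtr_asym(tumour_spec: MTRasymSpectrum,
                   nawm_spec: MTRasymSpectrum) -> MTRasymSpectrum:
    """Tumour-minus-NAWM asymmetry spectrum (pointwise, same grid)."""
    if tumour_spec.offsets_ppm.shape != nawm_spec.offsets_ppm.shape \
            or not np.allclose(tumour_spec.offsets_ppm, nawm_spec.offsets_ppm):
        raise ValueError("spectra are on different offset grids")
    return MTRasymSpectrum(tumour_spec.offsets_ppm,
                           tumour_spec.value - nawm_spec.value)


def group_spectra(spectra: Sequence[MTRasymSpectrum], groups: Sequence[str]
                  ) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-group mean and 25th/75th-percentile spectra.

    ``spectra`` holds one ROI-mean spectrum per subject; percentiles use
    the linear-interpolation convention between order statistics.
    """
    if len(spectra) != len(groups):
        raise ValueError("one group label per spectrum required")
    grid = spectra[0].offsets_ppm
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for g in dict.fromkeys(groups):
        vals = np.array([s.value for s, gg in zip(spectra, groups) if gg == g])
        if vals.shape[0] < 2:
            raise ValueError(f"group '{g}' has fewer than 2 subjects")
        out[g] = {
            "offsets_ppm": grid,
            "mean": vals.mean(axis=0),
            "p25": np.percentile(vals, 25, axis=0),
            "p75": np.percentile(vals, 75, axis=0),
        }
    return out


def classify_abfs_mismatch(metrics: SubjectMetrics,
                           thresholds: Tuple[float, float] = DEFAULT_ABFS_THRESHOLDS,
                           rule: str = "amine") -> bool:
    """Binary AB/FS-mismatch call from the AB-FS band metrics.

    ``thresholds`` is (amide, amine); positivity is strict ("larger than
    the cut point"). The default channel is the amine one, the better
    performing surrogate; ``rule`` can be amine, amide, either or both.
    """
    if rule not in MISMATCH_RULES:
        raise ValueError(f"rule must be one of {MISMATCH_RULES}")
    amide_thr, amine_thr = thresholds
    vals = {"amide": metrics.abfs_amide, "amine": metrics.abfs_amine}
    for v in vals.values():
        if v is None or not np.isfinite(v):
            raise ValueError("AB-FS metrics unset; cannot classify mismatch")
    pos_amide = vals["amide"] > amide_thr
    pos_amine = vals["amine"] > amine_thr
    if rule == "amine":
        return bool(pos_amine)
    if rule == "amide":
        return bool(pos_amide)
    if rule == "either":
        return bool(pos_amide or pos_amine)
    return bool(pos_amide and pos_amine)


METRIC_COLUMNS = ["ab_amide", "fs_amide", "abfs_amide",
                  "ab_amine", "fs_amine", "abfs_amine",
                  "ab_ratio", "fs_ratio", "abfs_ratio"]


def metrics_table(per_subject: Iterable[SubjectMetrics],
                  thresholds: Tuple[float, float] = DEFAULT_ABFS_THRESHOLDS,
                  rule: str = "amine") -> pd.DataFrame:
    """Cohort metrics table, one row per subject (CSV-ready layout)."""
    rows: List[dict] = []
    for m in per_subject:
        lab = m.labels
        mismatch = classify_abfs_mismatch(m, thresholds, rule)
        m.abfs_mismatch = mismatch
        rows.append({
            "subject_id": lab.subject_id if lab else "",
            "group": lab.group if lab else "",
            **{c: getattr(m, c) for c in METRIC_COLUMNS},
            "idh": lab.idh if lab else "",
            "codel": lab.codel if lab else "",
            "t2flair_mismatch": bool(lab.t2flair_mismatch) if lab else False,
            "abfs_mismatch": mismatch,
            "qc_flags": int(m.ratio_flagged) * FLAG_RATIO_GUARD + int(m.qc_flagged),
            "nawm_abfs_amide": m.nawm_abfs_amide,
            "nawm_abfs_amine": m.nawm_abfs_amine,
        })
    return pd.DataFrame(rows)
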