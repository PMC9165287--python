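"""NIfTI + sidecar persistence of subjects and cohorts.

Layout per subject (all images single-slice 2D, stored as NIfTI):

    sub-XXX_zstack_b1-<level>.nii.gz   X x Y x n_offsets (raw signal S)
    sub-XXX_s0.nii.gz                  unsaturated reference image
    sub-XXX_relb1.nii.gz               relative B1 map
    sub-XXX_b0gt.nii.gz                ground-truth B0 map (simulator only)
    sub-XXX_mask-{tumour,cyst,nawm}.nii.gz
    sub-XXX_sidecar.json               offsets_ppm, b1_uT, tsat_s

plus a cohort-level ``labels.csv`` and ``manifest.json``.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import FieldMaps, ROISet, SubjectLabels, ZStack
from .synthetic_cohort import (AcquisitionParams, CohortBundle, SubjectData)

__all__ = ["save_subject", "load_subject", "save_cohort", "load_cohort",
           "save_map"]

_AFFINE = np.diag([1.6, 1.6, 4.0, 1.0])   # in-plane 1.6 mm, 4 mm slice


def _img(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), _AFFINE)


def save_map(path: Path, data: np.ndarray) -> None:
    """Write a single 2D map as NIfTI."""
    nib.save(_img(data), str(path))


def _load(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_subject(out_dir: Path, subject: SubjectData) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject.labels.subject_id
    acq = subject.acq
    for lvl, stack in subject.stacks.items():
        s0 = stack.s0 if stack.s0 is not None else np.ones(stack.shape)
        raw = stack.signal * s0[..., None]
        nib.save(_img(raw), str(out_dir / f"{sid}_zstack_b1-{lvl:g}.nii.gz"))
    s0_map = next(iter(subject.stacks.values())).s0
    nib.save(_img(s0_map), str(out_dir / f"{sid}_s0.nii.gz"))
    nib.save(_img(subject.fieldmaps.relb1), str(out_dir / f"{sid}_relb1.nii.gz"))
    nib.save(_img(subject.fieldmaps.b0_ppm), str(out_dir / f"{sid}_b0gt.nii.gz"))
    for name, mask in (("tumour", subject.rois.tumour),
                       ("cyst", subject.rois.cyst),
                       ("nawm", subject.rois.nawm)):
        nib.save(_img(mask.astype(np.float32)),
                 str(out_dir / f"{sid}_mask-{name}.nii.gz"))
    sidecar = {
        "offsets_ppm": [float(o) for o in acq.offsets_ppm],
        "b1_uT": [float(b) for b in acq.b1_levels_uT],
        "tsat_s": acq.tsat_s,
    }
    (out_dir / f"{sid}_sidecar.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def load_subject(in_dir: Path, subject_id: str,
                 labels: Optional[SubjectLabels] = None) -> SubjectData:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / f"{subject_id}_sidecar.json").read_text())
    offsets = np.asarray(sidecar["offsets_ppm"], dtype=float)
    levels = [float(b) for b in sidecar["b1_uT"]]
    s0 = _load(in_dir / f"{subject_id}_s0.nii.gz")
    stacks: Dict[float, ZStack] = {}
    for lvl in levels:
        raw = _load(in_dir / f"{subject_id}_zstack_b1-{lvl:g}.nii.gz")
        stacks[lvl] = ZStack(raw / s0[..., None], offsets, b1_uT=lvl, s0=s0)
    fieldmaps = FieldMaps(
        b0_ppm=_load(in_dir / f"{subject_id}_b0gt.nii.gz"),
        relb1=_load(in_dir / f"{subject_id}_relb1.nii.gz"))
    rois = ROISet(
        tumour=_load(in_dir / f"{subject_id}_mask-tumour.nii.gz") > 0.5,
        cyst=_load(in_dir / f"{subject_id}_mask-cyst.nii.gz") > 0.5,
        nawm=_load(in_dir / f"{subject_id}_mask-nawm.nii.gz") > 0.5)
    acq = AcquisitionParams(offsets_ppm=tuple(offsets),
                            b1_levels_uT=tuple(levels),
                            tsat_s=float(sidecar["tsat_s"]),
                            shape=s0.shape)
    if labels is None:
        labels = SubjectLabels(subject_id=subject_id, group="", idh="",
                               codel="", t2flair_mismatch=False,
                               fluid_fraction=float("nan"), subject_seed=-1)
    return SubjectData(stacks=stacks, fieldmaps=fieldmaps, rois=rois,
                       labels=labels, acq=acq)


def save_cohort(out_dir: Path, cohort: CohortBundle) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subject in cohort.subjects:
        save_subject(out_dir, subject)
    cohort.table.to_csv(out_dir / "labels.csv", index=False)
    manifest = {
        "n_subjects": len(cohort.subjects),
        "subjects": list(cohort.table["subject_id"]),
        "groups": {g: int((cohort.table["group"] == g).sum())
                   for g in cohort.table["group"].unique()},
        "seed": cohort.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))


def load_cohort(in_dir: Path) -> CohortBundle:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "labels.csv")
    manifest = json.loads((in_dir / "manifest.json").read_text())
    subjects: List[SubjectData] = []
    for _, row in table.iterrows():
        labels = SubjectLabels(
            subject_id=row["subject_id"], group=row["group"],
            idh=row["idh"], codel=row["codel"],
            t2flair_mismatch=bool(row["t2flair_mismatch"]),
            fluid_fraction=float(row["fluid_fraction_gt"]),
            subject_seed=int(row["seed"]))
        subjects.append(load_subject(in_dir, row["subject_id"], labels))
    acq = subjects[0].acq if subjects else AcquisitionParams()
    return CohortBundle(subjects=subjects, table=table, acq=acq,
                        seed=int(manifest.get("seed", -1)))
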