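"""Synthetic multi-pool Z-spectrum phantom cohorts.

Generates 2D single-slice Z-spectrum stacks (one per saturation B1 level),
field maps, ROI masks and ground-truth labels with the statistical structure
the downstream analysis assumes, so that every stage of the pipeline is
testable without patient data.

Model
-----
Each voxel's Z-spectrum is a sum of Lorentzian saturation pools on top of a
unit baseline:

    Z(dw) = 1 - sum_i A_i(B1) * L(dw - off_i - b0; fwhm_i) + noise

with L a unit-peak Lorentzian and a saturating B1 dependence

    A_i(B1) = amplitude_i * g(B1) / g(2.0),   g(b) = b^2 / (b^2 + h_i^2),

so that ``amplitude_i`` is the pool depth at the reference level of 2.0 uT.
Pools: free water (direct saturation), a symmetric semisolid MT pedestal,
amide (+3.5 ppm), amine (+2.0 ppm) and NOE (-3.5 ppm). Fluid-like voxels
(cysts / microcysts) carry a narrow water line, almost no MT and strongly
reduced solute/NOE pools -- the Z-spectrum signature that the downstream
fluid-suppression model keys on.

Tumour-group presets are calibrated so that the cohort-level medians of the
NAWM-normalized metrics reproduce the reported contrast orderings:
amide/amine ratio highest in IDH-wild-type tumours; amide and amine levels
highest in IDH-mutant 1p/19q-retained tumours; and the AB-FS (fluid
mismatch) amine metric largest in the retained subgroup with mismatch.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import FieldMaps, ROISet, SubjectLabels, ZSpectrum, ZStack

__all__ = [
    "PoolParams", "GroupPreset", "AcquisitionParams", "SubjectData",
    "CohortBundle", "GROUPS", "default_presets", "nawm_pools", "fluid_pools",
    "simulate_zspectrum", "simulate_subject", "simulate_cohort",
]

REFERENCE_B1_UT = 2.0

GROUP_WT = "IDH-wildtype"
GROUP_RET_MM = "IDHmut-ret-mismatch"
GROUP_RET_NOMM = "IDHmut-ret-nomismatch"
GROUP_CODEL = "IDHmut-codel"
GROUPS = (GROUP_WT, GROUP_RET_MM, GROUP_RET_NOMM, GROUP_CODEL)


@dataclass(frozen=True)
class PoolParams:
    """One Lorentzian saturation pool.

    amplitude is the peak saturation depth (fraction of S0, in [0, 1)) at
    the reference B1 of 2.0 uT; b1_halfsat (uT) sets how quickly the depth
    saturates with B1.
    """

    name: str
    offset_ppm: float
    amplitude: float
    fwhm_ppm: float
    b1_halfsat: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError(f"pool {self.name}: amplitude must be in [0, 1)")
        if self.fwhm_ppm <= 0:
            raise ValueError(f"pool {self.name}: fwhm_ppm must be positive")
        if self.b1_halfsat <= 0:
            raise ValueError(f"pool {self.name}: b1_halfsat must be positive")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition geometry and noise of the emulated CEST protocol."""

    offsets_ppm: Tuple[float, ...] = tuple(np.round(np.arange(-4.0, 4.0 + 1e-9, 0.25), 4))
    b1_levels_uT: Tuple[float, ...] = (1.7, 2.0, 2.3)
    tsat_s: float = 3.5            # metadata only; the model is steady-state
    noise_sd: float = 0.005        # Gaussian noise on S/S0
    b0_shift_range_ppm: float = 0.5
    relb1_range: Tuple[float, float] = (0.85, 1.15)
    shape: Tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets_ppm, float)
        if not np.allclose(off, -off[::-1]):
            raise ValueError("offset grid must be symmetric about 0")
        for lo, hi in ((3.0, 4.0), (1.5, 2.5)):
            if not ((off >= lo) & (off <= hi)).any():
                raise ValueError(f"offset grid must cover the [{lo},{hi}] ppm band")
        if REFERENCE_B1_UT not in self.b1_levels_uT:
            raise ValueError("2.0 uT must be among the B1 levels")

    @property
    def offsets(self) -> np.ndarray:
        return np.asarray(self.offsets_ppm, dtype=float)


@dataclass(frozen=True)
class GroupPreset:
    """Per-group distributions of the tumour-compartment pool amplitudes.

    ``fluid_fraction`` is the areal fraction of fluid-like voxels inside the
    tumour ROI (a compact cyst plus scattered microcysts in the solid part).
    The T2/FLAIR-mismatch label is, by default, tied deterministically to
    the subject's drawn fluid fraction exceeding ``t2flair_fluid_threshold``.
    """

    group: str
    pool_means: Dict[str, float]
    pool_sds: Dict[str, float]
    fluid_fraction: float
    fluid_fraction_sd: float = 0.03
    t2flair_mismatch_prob: float = 0.0
    t2flair_fluid_threshold: float = 0.21
    t2flair_tied_to_fluid: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fluid_fraction <= 1.0:
            raise ValueError("fluid_fraction must be in [0, 1]")
        if not 0.0 <= self.t2flair_mismatch_prob <= 1.0:
            raise ValueError("t2flair_mismatch_prob must be in [0, 1]")


# --------------------------------------------------------------------------
# Default tissue classes.
#
# NAWM/parenchyma: broad water line (1.4 ppm) on a strong symmetric MT
# pedestal; solute amplitudes put the NAWM MTRasym null near +3 ppm (slight
# NOE dominance above 3 ppm), as observed in white matter at 2 uT.
# Fluid: narrow water line (0.6 ppm), almost no MT, solutes <= 20% of
# parenchymal levels and NOE ~5% (macromolecule-bound pools are absent in
# free fluid).
# --------------------------------------------------------------------------

def nawm_pools() -> Tuple[PoolParams, ...]:
    """Normal-appearing-white-matter pool set (also used for background)."""
    return (
        PoolParams("water", 0.0, 0.40, 1.4, 0.7),
        PoolParams("mt", 0.0, 0.46, 40.0, 1.2),
        PoolParams("amide", 3.5, 0.030, 1.0, 1.1),
        PoolParams("amine", 2.0, 0.050, 1.2, 1.3),
        PoolParams("noe", -3.5, 0.041, 1.5, 1.0),
    )


def fluid_pools() -> Tuple[PoolParams, ...]:
    """Fluid compartment (cyst / microcyst) pool set."""
    return (
        PoolParams("water", 0.0, 0.85, 0.6, 0.6),
        PoolParams("mt", 0.0, 0.03, 40.0, 1.2),
        PoolParams("amide", 3.5, 0.006, 1.0, 1.1),
        PoolParams("amine", 2.0, 0.010, 1.2, 1.3),
        PoolParams("noe", -3.5, 0.002, 1.5, 1.0),
    )


def _tumour_pools(amide: float, amine: float) -> Tuple[PoolParams, ...]:
    return (
        PoolParams("water", 0.0, 0.40, 1.4, 0.7),
        PoolParams("mt", 0.0, 0.44, 40.0, 1.2),
        PoolParams("amide", 3.5, amide, 1.0, 1.1),
        PoolParams("amine", 2.0, amine, 1.2, 1.3),
        PoolParams("noe", -3.5, 0.041, 1.5, 1.0),
    )


def default_presets() -> Dict[str, GroupPreset]:
    """Group presets calibrated to the reported cohort contrast orderings."""
    sds = {"amide": 0.0010, "amine": 0.0009}
    return {
        GROUP_WT: GroupPreset(
            GROUP_WT,
            pool_means={"amide": 0.0446, "amine": 0.0559},
            pool_sds=sds, fluid_fraction=0.054, fluid_fraction_sd=0.010,
            t2flair_mismatch_prob=0.0),
        GROUP_RET_MM: GroupPreset(
            GROUP_RET_MM,
            pool_means={"amide": 0.0510, "amine": 0.0810},
            pool_sds=sds, fluid_fraction=0.308, fluid_fraction_sd=0.02,
            t2flair_mismatch_prob=1.0),
        GROUP_RET_NOMM: GroupPreset(
            GROUP_RET_NOMM,
            pool_means={"amide": 0.0421, "amine": 0.0613},
            pool_sds=sds, fluid_fraction=0.121, fluid_fraction_sd=0.02,
            t2flair_mismatch_prob=0.0),
        GROUP_CODEL: GroupPreset(
            GROUP_CODEL,
            pool_means={"amide": 0.0419, "amine": 0.0602},
            pool_sds=sds, fluid_fraction=0.122, fluid_fraction_sd=0.02,
            t2flair_mismatch_prob=0.0),
    }


DEFAULT_N_PER_GROUP: Dict[str, int] = {
    GROUP_WT: 9, GROUP_RET_MM: 15, GROUP_RET_NOMM: 7, GROUP_CODEL: 13,
}


# --------------------------------------------------------------------------
# Spectrum synthesis
# --------------------------------------------------------------------------

def _lorentz(x: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-peak Lorentzian line shape."""
    hw2 = (0.5 * fwhm) ** 2
    return hw2 / (x * x + hw2)


def _b1_scale(b1: np.ndarray, halfsat: float) -> np.ndarray:
    """Saturating amplitude law, normalized to 1 at the reference B1."""
    b1 = np.asarray(b1, dtype=float)
    g = b1 * b1 / (b1 * b1 + halfsat * halfsat)
    g_ref = REFERENCE_B1_UT ** 2 / (REFERENCE_B1_UT ** 2 + halfsat * halfsat)
    return g / g_ref


def _check_pool_depths(pools: Sequence[PoolParams], b1: float) -> None:
    """Raise if the summed pool depths reach 1 anywhere on a dense grid."""
    centres = [p.offset_ppm for p in pools]
    dense = np.union1d(np.arange(-8.0, 8.0001, 0.02), np.asarray(centres))
    total = np.zeros_like(dense)
    for p in pools:
        amp = p.amplitude * float(_b1_scale(np.asarray(b1), p.b1_halfsat))
        total += amp * _lorentz(dense - p.offset_ppm, p.fwhm_ppm)
    if total.max() >= 1.0:
        raise ValueError(
            f"summed pool depths reach {total.max():.3f} >= 1 at "
            f"{dense[total.argmax()]:+.2f} ppm (B1={b1} uT)")


def _zspectra_matrix(pools: Sequence[PoolParams], offsets: np.ndarray,
                     b1_eff: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """Noiseless Z-spectra for many voxels sharing one pool set.

    b1_eff and b0 are per-voxel arrays (n,); returns (n, n_offsets).
    """
    b1_eff = np.atleast_1d(np.asarray(b1_eff, dtype=float))
    b0 = np.atleast_1d(np.asarray(b0, dtype=float))
    z = np.ones((b0.size, offsets.size))
    for p in pools:
        amp = p.amplitude * _b1_scale(b1_eff, p.b1_halfsat)        # (n,)
        x = offsets[None, :] - p.offset_ppm - b0[:, None]          # (n, m)
        z -= amp[:, None] * _lorentz(x, p.fwhm_ppm)
    return z


def simulate_zspectrum(pools: Sequence[PoolParams], b1: float = REFERENCE_B1_UT,
                       b0_shift: float = 0.0, noise_sd: float = 0.0,
                       seed: Optional[int] = None,
                       acq: Optional[AcquisitionParams] = None) -> ZSpectrum:
    """Simulate a single-voxel Z-spectrum from a Lorentzian pool set.

    The returned signal is clipped to [0, 1.05] (normalized S/S0 with a
    small allowance for noise overshoot). Deterministic under a fixed seed.
    """
    acq = acq or AcquisitionParams()
    offsets = acq.offsets
    if not any(p.offset_ppm == 0.0 and p.name == "water" for p in pools):
        raise ValueError("pool set must include a water pool at 0 ppm")
    _check_pool_depths(pools, b1)
    z = _zspectra_matrix(pools, offsets, np.asarray([b1]), np.asarray([b0_shift]))[0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    return ZSpectrum(offsets, np.clip(z, 0.0, 1.05))


# --------------------------------------------------------------------------
# Subject-level simulation
# --------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything the pipeline sees for one subject."""

    stacks: Dict[float, ZStack]
    fieldmaps: FieldMaps
    rois: ROISet
    labels: SubjectLabels
    acq: AcquisitionParams


@dataclass
class CohortBundle:
    subjects: List[SubjectData]
    table: pd.DataFrame            # one row per subject: labels + ground truth
    acq: AcquisitionParams
    seed: int


def _ellipse_mask(shape: Tuple[int, int], centre: Tuple[float, float],
                  radii: Tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (((yy - centre[0]) / radii[0]) ** 2
            + ((xx - centre[1]) / radii[1]) ** 2) <= 1.0


def _smooth_field(rng: np.random.Generator, shape: Tuple[int, int],
                  lo: float, hi: float, n_modes: int = 2,
                  k_range: Tuple[float, float] = (0.3, 0.9)) -> np.ndarray:
    """Smooth random field spanning [lo, hi], from low-order cosine modes.

    The default mode frequencies keep the field slowly varying at the
    slice scale, as shimmed-brain B0 and transmit-B1 inhomogeneities are.
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    yn, xn = yy / shape[0], xx / shape[1]
    f = np.zeros(shape)
    for _ in range(n_modes):
        ky, kx = rng.uniform(*k_range, size=2)
        phy, phx = rng.uniform(0, 2 * np.pi, size=2)
        f += rng.normal() * np.cos(np.pi * ky * yn + phy) * np.cos(np.pi * kx * xn + phx)
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


CYST_CAP = 0.05                    # compact cyst occupies at most 5% of tumour
MIN_TUMOUR_VOXELS = 40


def _draw_amplitude(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Positive, truncated-at-2.5-sigma normal draw of a pool amplitude."""
    val = mean + np.clip(rng.normal(0.0, 1.0), -2.5, 2.5) * sd
    return float(max(val, 1e-4))


def simulate_subject(preset: GroupPreset, acq: Optional[AcquisitionParams] = None,
                     seed: int = 0, subject_id: str = "sub-000") -> SubjectData:
    """Simulate one subject: Z-stacks per B1 level, field maps, ROIs, labels."""
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    shape = acq.shape
    offsets = acq.offsets

    # --- geometry -----------------------------------------------------
    tumour = _ellipse_mask(shape, (shape[0] * 0.5, shape[1] * 0.70),
                           (shape[0] * 0.14, shape[1] * 0.17))
    nawm = _ellipse_mask(shape, (shape[0] * 0.5, shape[1] * 0.28),
                         (shape[0] * 0.12, shape[1] * 0.15))
    n_t = int(tumour.sum())
    if n_t < MIN_TUMOUR_VOXELS:
        raise ValueError(f"tumour ROI too small ({n_t} voxels)")

    # --- fluid layout: compact cyst + scattered microcysts ------------
    fluid_fraction = float(np.clip(
        preset.fluid_fraction
        + np.clip(rng.normal(0.0, 1.0), -2.5, 2.5) * preset.fluid_fraction_sd,
        0.0, 0.8))
    cyst_frac = CYST_CAP if fluid_fraction >= CYST_CAP else fluid_fraction / 2.0
    n_cyst = int(round(cyst_frac * n_t))
    if fluid_fraction > 0 and n_cyst == 0:
        n_cyst = 1
    t_idx = np.argwhere(tumour)
    # cyst = the n_cyst tumour voxels nearest an off-centre seed point
    cyst = np.zeros(shape, dtype=bool)
    if n_cyst > 0:
        seed_pt = t_idx.mean(axis=0) + np.array([2.0, 3.0])
        order = np.argsort(((t_idx - seed_pt) ** 2).sum(axis=1))
        cyst[tuple(t_idx[order[:n_cyst]].T)] = True
    solid = tumour & ~cyst
    n_scatter = max(int(round(fluid_fraction * n_t)) - n_cyst, 0)
    s_idx = np.argwhere(solid)
    scatter = np.zeros(shape, dtype=bool)
    if n_scatter > 0:
        pick = rng.choice(s_idx.shape[0], size=min(n_scatter, s_idx.shape[0]),
                          replace=False)
        scatter[tuple(s_idx[pick].T)] = True
    fluid_mask = cyst | scatter

    # --- field maps ---------------------------------------------------
    # The configured B0 range is the worst case; a per-subject shim factor
    # makes typical shifts smaller, as in a reasonably shimmed brain.
    b0r = acq.b0_shift_range_ppm
    shim = rng.beta(1.5, 3.5)          # typically ~0.3 of the worst case
    b0 = _smooth_field(rng, shape, -b0r, b0r) * shim
    relb1 = _smooth_field(rng, shape, *acq.relb1_range)
    fieldmaps = FieldMaps(b0_ppm=b0, relb1=relb1)

    # --- tissue parameters --------------------------------------------
    amide = _draw_amplitude(rng, preset.pool_means["amide"],
                            preset.pool_sds.get("amide", 0.0))
    amine = _draw_amplitude(rng, preset.pool_means["amine"],
                            preset.pool_sds.get("amine", 0.0))
    nawm_jitter = rng.normal(0.0, 0.0005, size=2)
    base = {p.name: p for p in nawm_pools()}
    nawm_set = tuple(
        replace(base[n], amplitude=max(base[n].amplitude
                                       + (nawm_jitter[0] if n == "amide" else
                                          nawm_jitter[1] if n == "amine" else 0.0),
                                       1e-4))
        for n in ("water", "mt", "amide", "amine", "noe"))
    solid_set = _tumour_pools(amide, amine)
    fluid_set = fluid_pools()

    # --- label --------------------------------------------------------
    if preset.t2flair_tied_to_fluid:
        t2flair = bool(fluid_fraction > preset.t2flair_fluid_threshold)
    else:
        t2flair = bool(rng.random() < preset.t2flair_mismatch_prob)

    # --- spectra ------------------------------------------------------
    classes = [(solid, solid_set), (fluid_mask, fluid_set),
               (~tumour, nawm_set)]       # NAWM params fill the background too
    for _, pools in classes:
        for lvl in acq.b1_levels_uT:
            _check_pool_depths(pools, lvl * max(acq.relb1_range))

    stacks: Dict[float, ZStack] = {}
    flat_b0 = b0.ravel()
    flat_rb1 = relb1.ravel()
    for lvl in acq.b1_levels_uT:
        sig = np.empty((shape[0] * shape[1], offsets.size))
        for mask, pools in classes:
            idx = np.flatnonzero(mask.ravel())
            sig[idx] = _zspectra_matrix(pools, offsets,
                                        lvl * flat_rb1[idx], flat_b0[idx])
        if acq.noise_sd > 0:
            sig = sig + rng.normal(0.0, acq.noise_sd, size=sig.shape)
        sig = np.clip(sig, 0.0, 1.05).reshape(shape + (offsets.size,))
        stacks[lvl] = ZStack(sig, offsets, b1_uT=lvl,
                             s0=np.full(shape, 1000.0))

    labels = SubjectLabels(
        subject_id=subject_id, group=preset.group,
        idh="wt" if preset.group == GROUP_WT else "mut",
        codel=("n/a" if preset.group == GROUP_WT
               else "codel" if preset.group == GROUP_CODEL else "ret"),
        t2flair_mismatch=t2flair, fluid_fraction=fluid_fraction,
        subject_seed=seed, fluid_mask=fluid_mask,
        pool_amplitudes={"amide": amide, "amine": amine})
    rois = ROISet(tumour=tumour, cyst=cyst, nawm=nawm)
    return SubjectData(stacks=stacks, fieldmaps=fieldmaps, rois=rois,
                       labels=labels, acq=acq)


def _subject_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-subject seed below 2^31 derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_cohort(n_per_group: Optional[Dict[str, int]] = None,
                    acq: Optional[AcquisitionParams] = None, seed: int = 0,
                    presets: Optional[Dict[str, GroupPreset]] = None
                    ) -> CohortBundle:
    """Simulate a cohort; deterministic (bit-identical) under a fixed seed."""
    acq = acq or AcquisitionParams()
    presets = presets or default_presets()
    counts = dict(DEFAULT_N_PER_GROUP)
    if n_per_group:
        unknown = set(n_per_group) - set(counts)
        if unknown:
            raise ValueError(f"unknown group(s): {sorted(unknown)}")
        counts.update(n_per_group)
    if any(n < 0 for n in counts.values()):
        raise ValueError("group sizes must be non-negative")

    subjects: List[SubjectData] = []
    rows = []
    index = 0
    for group in GROUPS:
        for _ in range(counts[group]):
            sid = f"sub-{index:03d}"
            sseed = _subject_seed(seed, index)
            subj = simulate_subject(presets[group], acq, seed=sseed,
                                    subject_id=sid)
            subjects.append(subj)
            lab = subj.labels
            rows.append({
                "subject_id": sid, "group": group, "idh": lab.idh,
                "codel": lab.codel, "t2flair_mismatch": lab.t2flair_mismatch,
                "fluid_fraction_gt": lab.fluid_fraction, "seed": sseed,
            })
            index += 1
    table = pd.DataFrame(rows)
    return CohortBundle(subjects=subjects, table=table, acq=acq, seed=seed)
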