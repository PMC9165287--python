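"""Shared in-memory containers for the CEST subtyping pipeline.

Everything downstream of acquisition works on these small dataclasses:
a :class:`ZSpectrum` is one voxel's normalized saturation spectrum, a
:class:`ZStack` is a 2D slice of them at one nominal B1 level, and the
map/metric containers hold the derived amide/amine contrasts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Per-voxel quality flag bits (uint8 maps, OR-combined as processing proceeds).
FLAG_B0_EDGE = 1        # B0 minimum found at the edge of the search window
FLAG_EXTRAPOLATED = 2   # B0 correction needed out-of-range values (edge hold)
FLAG_B1_FALLBACK = 4    # exponential B1 fit unavailable; linear fallback used
FLAG_FLUID_FIT = 8      # direct-saturation linewidth fit failed
FLAG_RATIO_GUARD = 16   # amide/amine ratio denominator below epsilon


@dataclass
class ZSpectrum:
    """Normalized saturation signal S/S0 on a signed offset grid (ppm)."""

    offsets_ppm: np.ndarray
    signal: np.ndarray
    s0: float = 1.0

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.offsets_ppm.ndim != 1 or self.signal.shape != self.offsets_ppm.shape:
            raise ValueError("offsets and signal must be 1D arrays of equal length")
        if not np.all(np.diff(self.offsets_ppm) > 0):
            raise ValueError("offsets_ppm must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")

    def has_symmetric_grid(self, tol: float = 1e-9) -> bool:
        """True if every positive offset has a mirrored negative partner."""
        return bool(np.allclose(self.offsets_ppm, -self.offsets_ppm[::-1], atol=tol))


@dataclass
class ZStack:
    """A 2D slice of Z-spectra at one nominal B1 level.

    ``signal`` has shape (ny, nx, n_offsets) and is S/S0-normalized.
    ``flags`` is a uint8 per-voxel quality bitfield (see FLAG_* constants).
    """

    signal: np.ndarray
    offsets_ppm: np.ndarray
    b1_uT: float
    s0: Optional[np.ndarray] = None
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.signal.ndim != 3 or self.signal.shape[-1] != self.offsets_ppm.size:
            raise ValueError("signal must be (ny, nx, n_offsets) matching the grid")
        if self.flags is None:
            self.flags = np.zeros(self.signal.shape[:2], dtype=np.uint8)

    @property
    def shape(self) -> tuple:
        return self.signal.shape[:2]

    def spectrum(self, iy: int, ix: int) -> ZSpectrum:
        s0 = 1.0 if self.s0 is None else float(self.s0[iy, ix])
        return ZSpectrum(self.offsets_ppm, self.signal[iy, ix], s0=s0)


@dataclass
class FieldMaps:
    """Per-voxel B0 shift (ppm) and relative B1 (fraction of nominal)."""

    b0_ppm: np.ndarray
    relb1: np.ndarray

    def __post_init__(self) -> None:
        self.b0_ppm = np.asarray(self.b0_ppm, dtype=float)
        self.relb1 = np.asarray(self.relb1, dtype=float)
        if self.b0_ppm.shape != self.relb1.shape:
            raise ValueError("b0 and relb1 maps must share geometry")
        if np.any(self.relb1 <= 0):
            raise ValueError("relative B1 must be positive everywhere")


@dataclass
class ROISet:
    """Tumour / cyst / NAWM masks on the slice grid.

    The "solid tumour" aggregate used for the subject metrics is
    tumour minus cyst; the cyst ROI is kept for QC only.
    """

    tumour: np.ndarray
    cyst: np.ndarray
    nawm: np.ndarray

    def __post_init__(self) -> None:
        self.tumour = np.asarray(self.tumour, dtype=bool)
        self.cyst = np.asarray(self.cyst, dtype=bool)
        self.nawm = np.asarray(self.nawm, dtype=bool)
        if not (self.tumour.shape == self.cyst.shape == self.nawm.shape):
            raise ValueError("masks must share geometry")
        if not self.tumour.any():
            raise ValueError("tumour mask is empty")
        if not self.nawm.any():
            raise ValueError("NAWM mask is empty")
        if (self.tumour & self.nawm).any():
            raise ValueError("tumour and NAWM masks overlap")

    @property
    def solid(self) -> np.ndarray:
        return self.tumour & ~self.cyst


@dataclass
class MTRasymSpectrum:
    """MTR asymmetry per positive offset, in percent units (x100)."""

    offsets_ppm: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if np.any(self.offsets_ppm < 0):
            raise ValueError("asymmetry is defined only for non-negative offsets")


@dataclass
class APTwMapSet:
    """Per-voxel amide/amine maps for the AB and FS models (percent units)."""

    ab_amide: np.ndarray
    ab_amine: np.ndarray
    fs_amide: np.ndarray
    fs_amine: np.ndarray
    fluid_weight: np.ndarray
    abfs_amide: np.ndarray
    abfs_amine: np.ndarray
    flags: np.ndarray


@dataclass
class SubjectLabels:
    """Ground-truth / reference labels carried with each subject."""

    subject_id: str
    group: str
    idh: str                     # "wt" | "mut"
    codel: str                   # "ret" | "codel" | "n/a"
    t2flair_mismatch: bool
    fluid_fraction: float
    subject_seed: int
    fluid_mask: Optional[np.ndarray] = None
    pool_amplitudes: dict = field(default_factory=dict)


@dataclass
class SubjectMetrics:
    """The nine NAWM-normalized scalar metrics for one subject.

    Band metrics are in percent of S0; ratios are dimensionless.
    ``ab_ratio``/``fs_ratio`` are ratios of the normalized band metrics
    (amide over amine) and are NaN + flagged when the denominator falls
    below the epsilon guard.
    """

    ab_amide: float
    ab_amine: float
    fs_amide: float
    fs_amine: float
    abfs_amide: float
    abfs_amine: float
    ab_ratio: float
    fs_ratio: float
    abfs_ratio: float
    ratio_flagged: bool
    qc_flagged: bool
    nawm_abfs_amide: float
    nawm_abfs_amine: float
    labels: Optional[SubjectLabels] = None
    abfs_mismatch: Optional[bool] = None

    BAND_METRICS = (
        "ab_amide", "fs_amide", "abfs_amide",
        "ab_amine", "fs_amine", "abfs_amine",
    )
    NINE_METRICS = BAND_METRICS + ("ab_ratio", "fs_ratio", "abfs_ratio")


@dataclass
class ComparisonResult:
    """One Table-1-shaped row: a metric compared between two groups."""

    metric: str
    group_a: str
    group_b: str
    p: float
    auc: float = np.nan
    cut_point: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    direction: str = ""


@dataclass
class AgreementResult:
    """AB/FS-mismatch vs T2/FLAIR-mismatch agreement (2x2 + Fisher)."""

    contingency: np.ndarray
    fisher_p: float
    channels: dict
    rule: str
    n: int
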