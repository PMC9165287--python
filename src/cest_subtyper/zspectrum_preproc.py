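"""B0 and B1 correction of Z-spectrum stacks.

Order of operations follows the acquisition convention: each voxel's
spectra are first corrected for the local water-frequency (B0) shift, then
the three saturation-level acquisitions are combined into a single
B1-corrected stack at the nominal 2.0 uT by an exponential fit in B1.

The B0 shift is estimated WASSR-style on the Z-spectrum itself: the
abscissa of the minimum of a cubic-spline interpolant within a +/-1 ppm
search window, at 0.005 ppm resolution. The B1 fit Z = a - b*exp(-c*B1)
is solved exactly from the three (equally spaced) effective-B1 points when
they are strictly monotone and decelerating; otherwise the voxel falls
back to monotone piecewise-linear interpolation in B1 and is flagged.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import (FLAG_B0_EDGE, FLAG_B1_FALLBACK, FLAG_EXTRAPOLATED,
                         FieldMaps, ZSpectrum, ZStack)

__all__ = [
    "B0Estimate", "estimate_b0", "estimate_b0_map",
    "apply_b0_correction", "apply_b0_correction_stack",
    "correct_b1", "preprocess_subject",
]

DEFAULT_B0_WINDOW_PPM = 1.0
DEFAULT_B0_RESOLUTION_PPM = 0.005


@dataclass(frozen=True)
class B0Estimate:
    shift_ppm: float
    at_edge: bool      # True when the minimum sits at the window edge


def _b0_from_matrix(offsets: np.ndarray, signals: np.ndarray,
                    window: float, resolution: float
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized spline-minimum B0 search. signals: (nvox, n_offsets)."""
    sel = np.abs(offsets) <= window + 1e-9
    if sel.sum() < 4 or offsets[sel].min() > -window + 0.26 \
            or offsets[sel].max() < window - 0.26:
        raise ValueError("offset grid must cover the B0 search window")
    xw = offsets[sel]
    spl = CubicSpline(xw, signals[:, sel], axis=1)
    dense = np.arange(xw[0], xw[-1] + resolution / 2, resolution)
    vals = spl(dense)                              # (nvox, ndense)
    imin = np.argmin(vals, axis=1)
    shift = dense[imin]
    at_edge = (imin == 0) | (imin == dense.size - 1)
    return shift, at_edge


def estimate_b0(zspec: ZSpectrum, search_window_ppm: float = DEFAULT_B0_WINDOW_PPM,
                resolution_ppm: float = DEFAULT_B0_RESOLUTION_PPM) -> B0Estimate:
    """Estimate the voxel's B0 shift (ppm) from the Z-spectrum minimum.

    An estimate at the edge of the search window is returned but flagged
    ``at_edge`` (the true minimum may lie outside the window).
    """
    shift, edge = _b0_from_matrix(zspec.offsets_ppm, zspec.signal[None, :],
                                  search_window_ppm, resolution_ppm)
    return B0Estimate(float(shift[0]), bool(edge[0]))


def estimate_b0_map(stack: ZStack, search_window_ppm: float = DEFAULT_B0_WINDOW_PPM,
                    resolution_ppm: float = DEFAULT_B0_RESOLUTION_PPM
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-voxel B0 estimate over a stack. Returns (b0_map, edge_flag_map)."""
    ny, nx, noff = stack.signal.shape
    shift, edge = _b0_from_matrix(stack.offsets_ppm,
                                  stack.signal.reshape(-1, noff),
                                  search_window_ppm, resolution_ppm)
    return shift.reshape(ny, nx), edge.reshape(ny, nx)


def _shift_spectra(offsets: np.ndarray, signals: np.ndarray,
                   shifts: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic re-interpolation of each spectrum at ``offsets + shift``.

    Exactly reproduces a per-voxel ``CubicSpline`` evaluation, vectorized
    through the shared spline-coefficient array. Out-of-range target points
    are held at the nearest edge value and flagged.

    signals: (nvox, n_offsets); shifts: (nvox,). Returns (corrected, extrap_flag).
    """
    signals = np.atleast_2d(signals)
    shifts = np.atleast_1d(shifts).astype(float)
    nvox, noff = signals.shape
    spl = CubicSpline(offsets, signals.T, axis=0)   # c: (4, noff-1, nvox)
    c = spl.c
    x_new = offsets[None, :] + shifts[:, None]      # (nvox, noff)
    below = x_new < offsets[0]
    above = x_new > offsets[-1]
    x_eval = np.clip(x_new, offsets[0], offsets[-1])
    k = np.clip(np.searchsorted(offsets, x_eval, side="right") - 1, 0, noff - 2)
    dx = x_eval - offsets[k]
    v = np.arange(nvox)[:, None]
    out = ((c[0][k, v] * dx + c[1][k, v]) * dx + c[2][k, v]) * dx + c[3][k, v]
    out = np.where(below, signals[:, [0]], out)
    out = np.where(above, signals[:, [-1]], out)
    extrap = below.any(axis=1) | above.any(axis=1)
    return out, extrap


def apply_b0_correction(zspec: ZSpectrum, b0_shift: float,
                        max_shift_ppm: float = DEFAULT_B0_WINDOW_PPM) -> ZSpectrum:
    """Re-interpolate one spectrum onto its grid after removing a B0 shift."""
    if abs(b0_shift) > max_shift_ppm + 1e-9:
        raise ValueError(f"|b0_shift| exceeds the correction window "
                         f"({b0_shift:+.3f} vs {max_shift_ppm} ppm)")
    corrected, _ = _shift_spectra(zspec.offsets_ppm, zspec.signal[None, :],
                                  np.asarray([b0_shift]))
    return ZSpectrum(zspec.offsets_ppm, corrected[0], s0=zspec.s0)


def apply_b0_correction_stack(stack: ZStack, b0_map: np.ndarray,
                              edge_map: Optional[np.ndarray] = None) -> ZStack:
    """B0-correct every voxel of a stack with its own shift."""
    ny, nx, noff = stack.signal.shape
    corrected, extrap = _shift_spectra(stack.offsets_ppm,
                                       stack.signal.reshape(-1, noff),
                                       np.asarray(b0_map, float).ravel())
    flags = stack.flags.copy()
    flags[extrap.reshape(ny, nx)] |= FLAG_EXTRAPOLATED
    if edge_map is not None:
        flags[np.asarray(edge_map, bool)] |= FLAG_B0_EDGE
    return ZStack(corrected.reshape(ny, nx, noff), stack.offsets_ppm,
                  b1_uT=stack.b1_uT, s0=stack.s0, flags=flags)


def correct_b1(stacks: Dict[float, ZStack], fieldmaps: FieldMaps,
               target_b1: float = 2.0) -> ZStack:
    """Combine three B1-level stacks into one corrected stack at target_b1.

    Per voxel and offset the model Z = a - b*exp(-c*B1) is solved exactly
    through the three points at effective B1 = level * relb1(voxel). The
    closed form requires the three effective levels to be equally spaced
    (they are whenever the nominal levels are, since relb1 is a common
    factor) and the signal to be strictly monotone and decelerating in B1;
    other voxels/offsets use monotone piecewise-linear interpolation /
    end-slope extrapolation in B1 and carry a quality flag.
    """
    if len(stacks) != 3:
        raise ValueError("B1 correction requires exactly three levels")
    levels = np.asarray(sorted(stacks), dtype=float)
    spacings = np.diff(levels)
    if not np.allclose(spacings[0], spacings[1], rtol=1e-6):
        raise ValueError("nominal B1 levels must be equally spaced")
    relb1 = np.asarray(fieldmaps.relb1, dtype=float)
    if np.any(relb1 <= 0):
        raise ValueError("relative B1 must be positive")
    ref = stacks[levels[1]] if levels[1] in stacks else next(iter(stacks.values()))
    ny, nx, noff = ref.signal.shape

    y = np.stack([stacks[lvl].signal.reshape(-1, noff) for lvl in levels])  # (3, nvox, noff)
    rb1 = relb1.ravel()[None, :, None]
    b_eff = levels[:, None, None] * rb1                                     # (3, nvox, 1)

    d1 = y[1] - y[0]
    d2 = y[2] - y[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = d2 / d1
    ok = np.isfinite(r) & (d1 * d2 > 0) & (r > 0) & (r < 1)

    db = b_eff[1] - b_eff[0]                                               # (nvox, 1)
    out = np.empty_like(y[0])
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        c = -np.log(np.where(ok, r, 0.5)) / db
        be1 = d1 / (1.0 - np.where(ok, r, 0.5))      # b * exp(-c*B1_eff[0])
        a = y[0] + be1
        fitted = a - be1 * np.exp(-c * (target_b1 - b_eff[0]))
    # fallback: piecewise-linear in effective B1 with end-slope extrapolation
    t = (target_b1 - b_eff[0]) / db                   # position in level units
    lin_lo = y[0] + (y[1] - y[0]) * t
    lin_hi = y[1] + (y[2] - y[1]) * (t - 1.0)
    linear = np.where(t <= 1.0, lin_lo, lin_hi)
    out = np.where(ok, fitted, linear)

    flags = ref.flags.copy()
    for lvl in levels:
        flags |= stacks[lvl].flags
    fallback_vox = (~ok).any(axis=1).reshape(ny, nx)
    flags[fallback_vox] |= FLAG_B1_FALLBACK
    return ZStack(out.reshape(ny, nx, noff), ref.offsets_ppm, b1_uT=target_b1,
                  s0=ref.s0, flags=flags)


def preprocess_subject(stacks: Dict[float, ZStack], fieldmaps: FieldMaps,
                       search_window_ppm: float = DEFAULT_B0_WINDOW_PPM,
                       target_b1: float = 2.0,
                       reference_level: float = 2.0
                       ) -> Tuple[ZStack, np.ndarray]:
    """Full preprocessing chain: B0 estimate + correction, then B1 fit.

    The B0 map is estimated once on the reference (2.0 uT) stack — the
    physical shift is the same at every saturation level — and applied to
    all three. Returns the corrected stack and the estimated B0 map.
    """
    if reference_level not in stacks:
        raise ValueError(f"reference level {reference_level} uT missing")
    b0_map, edge_map = estimate_b0_map(stacks[reference_level],
                                       search_window_ppm=search_window_ppm)
    corrected = {lvl: apply_b0_correction_stack(st, b0_map, edge_map)
                 for lvl, st in stacks.items()}
    return correct_b1(corrected, fieldmaps, target_b1=target_b1), b0_map
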