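"""Slice-wise translational alignment of the artery mask to the PET frame.

The angiography and the PET acquisition are minutes apart, so the animal may
have sunk/rolled slightly in between.  Arteries run axially, so only
in-plane (x, y) motion matters: per axial slice, the mask's center of
gravity is compared to the position of the PET maximum near it; the
resulting per-slice shifts are smoothed by a quadratic fit over slice
position and applied with cubic-spline interpolation.  Finally the
(fractional) mask is projected onto the coarse PET grid, yielding a
partial-volume coefficient in [0, 1] per PET voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .artery_segmentation import ArteryMask
from .core_io import Volume3D

__all__ = [
    "SliceShiftSeries",
    "ShiftPolynomial",
    "estimate_slice_shifts",
    "fit_shift_polynomial",
    "apply_shift",
    "project_to_pet_grid",
    "align_mask",
    "soft_dice",
]

log = logging.getLogger(__name__)

DEFAULT_SEARCH_RADIUS_MM = 20.0  # ~3x a typical PET FWHM


@dataclass
class SliceShiftSeries:
    """Per-axial-slice in-plane shifts (mm) between mask COG and PET maximum."""

    slice_indices: np.ndarray  # MRA slice index
    z_mm: np.ndarray           # world z of the slice
    dx: np.ndarray
    dy: np.ndarray
    valid: np.ndarray          # bool; False where mask or PET gave no signal

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ShiftPolynomial:
    """dx(z), dy(z) as polynomials in world z (mm), degree <= 2.

    Coefficients are in :func:`numpy.polyval` order (highest power first).
    """

    coeff_x: np.ndarray
    coeff_y: np.ndarray
    degree: int = 2

    def __call__(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.asarray(z, dtype=np.float64)
        return np.polyval(self.coeff_x, z), np.polyval(self.coeff_y, z)

    @classmethod
    def zero(cls) -> "ShiftPolynomial":
        return cls(np.zeros(1), np.zeros(1), degree=0)


def _parabolic_refine(profile: np.ndarray, i: int) -> float:
    """Sub-voxel offset of a maximum from a 3-point parabola, clamped to +-0.5."""
    if i <= 0 or i >= len(profile) - 1:
        return 0.0
    denom = profile[i - 1] - 2.0 * profile[i] + profile[i + 1]
    if denom >= 0:  # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (profile[i - 1] - profile[i + 1]) / denom, -0.5, 0.5))


def estimate_slice_shifts(mask: ArteryMask, pet_reference: Volume3D,
                          search_radius_mm: float = DEFAULT_SEARCH_RADIUS_MM,
                          refine: bool = True,
                          smooth_sigma_mm: float = 1.4) -> SliceShiftSeries:
    """Per-slice shift = (PET in-plane maximum position) - (mask in-plane COG).

    The PET maximum is searched in the PET slice nearest in world z, within
    ``search_radius_mm`` of the mask COG (so catheter or other hot spots
    outside the artery's neighborhood cannot capture the estimate).  The
    slice is pre-smoothed with a small in-plane Gaussian
    (``smooth_sigma_mm``, 0 disables): the blurred artery cross-section is
    symmetric, so smoothing suppresses noise-driven jitter of the argmax
    without displacing the peak.  With ``refine`` the maximum position is
    interpolated to sub-voxel precision by a 3-point parabola per axis.
    """
    mvals = mask.mask.values
    nz = mvals.shape[2]
    xs = mask.mask.axis_coords(0)
    ys = mask.mask.axis_coords(1)
    zs = mask.mask.axis_coords(2)
    px = pet_reference.axis_coords(0)
    py = pet_reference.axis_coords(1)

    smoothed_cache: dict[int, np.ndarray] = {}

    def pet_slice(kp: int) -> np.ndarray:
        if kp not in smoothed_cache:
            sl = pet_reference.values[:, :, kp]
            if smooth_sigma_mm > 0:
                sl = ndimage.gaussian_filter(
                    sl, sigma=[smooth_sigma_mm / s for s in pet_reference.spacing[:2]],
                    mode="nearest")
            smoothed_cache[kp] = sl
        return smoothed_cache[kp]

    idx, z_mm, dxs, dys, valid = [], [], [], [], []
    for k in range(nz):
        sl = mvals[:, :, k]
        if not sl.any():
            continue
        ii, jj = np.nonzero(sl)
        cogx, cogy = xs[ii].mean(), ys[jj].mean()
        idx.append(k)
        z_mm.append(zs[k])

        kp = int(round((zs[k] - pet_reference.origin[2]) / pet_reference.spacing[2]))
        ok = 0 <= kp < pet_reference.shape[2]
        if ok:
            pet_sl = pet_slice(kp)
            dist2 = (px[:, None] - cogx) ** 2 + (py[None, :] - cogy) ** 2
            windowed = np.where(dist2 <= search_radius_mm**2, pet_sl, -np.inf)
            ok = np.isfinite(windowed).any() and np.nanmax(windowed) > 0
        if not ok:
            dxs.append(np.nan)
            dys.append(np.nan)
            valid.append(False)
            continue

        imax, jmax = np.unravel_index(np.argmax(windowed), windowed.shape)
        xmax, ymax = px[imax], py[jmax]
        if refine:
            prof_x = pet_sl[:, jmax]
            prof_y = pet_sl[imax, :]
            xmax += _parabolic_refine(prof_x, imax) * pet_reference.spacing[0]
            ymax += _parabolic_refine(prof_y, jmax) * pet_reference.spacing[1]
        dxs.append(xmax - cogx)
        dys.append(ymax - cogy)
        valid.append(True)

    if not idx:
        raise ValueError("mask intersects no axial slice")
    series = SliceShiftSeries(
        np.asarray(idx), np.asarray(z_mm), np.asarray(dxs), np.asarray(dys),
        np.asarray(valid, dtype=bool),
    )
    if series.n_valid == 0:
        raise ValueError("no valid slices: PET reference empty around the mask")
    return series


def fit_shift_polynomial(series: SliceShiftSeries,
                         edge_trim_mm: float = 7.0) -> ShiftPolynomial:
    """Independent unweighted least-squares quadratics dx(z), dy(z).

    Slices within ``edge_trim_mm`` of the mask's axial extremes are
    excluded from the fit (not from evaluation): near the tube ends the
    axial PSF mixes in-plane positions from neighboring slices, which
    biases the per-slice maximum.  The default is about one PET FWHM.
    With fewer than 3 usable slices the fit falls back to the mean shift
    (degree 0) with a warning.
    """
    use = series.valid.copy()
    if use.any() and edge_trim_mm > 0:
        z_all = series.z_mm[use]
        trimmed = use & (series.z_mm >= z_all.min() + edge_trim_mm) \
                      & (series.z_mm <= z_all.max() - edge_trim_mm)
        if trimmed.sum() >= 3:
            use = trimmed
    z = series.z_mm[use]
    dx = series.dx[use]
    dy = series.dy[use]
    if len(z) < 3:
        log.warning("only %d valid slices; falling back to mean shift", len(z))
        return ShiftPolynomial(np.array([dx.mean()]), np.array([dy.mean()]), degree=0)
    return ShiftPolynomial(np.polyfit(z, dx, 2), np.polyfit(z, dy, 2), degree=2)


def apply_shift(mask: ArteryMask, poly: ShiftPolynomial) -> Volume3D:
    """Translate each mask slice in-plane by (dx(z), dy(z)) mm.

    Cubic-spline interpolation; the result is a fractional mask clamped to
    [0, 1] (interpolation ringing must not leak into partial-volume
    coefficients); regions shifted in from outside the grid are zero.
    """
    vol = mask.mask
    out = np.zeros_like(vol.values)
    zs = vol.axis_coords(2)
    for k in range(vol.shape[2]):
        sl = vol.values[:, :, k]
        dx, dy = poly(zs[k])
        if abs(dx) < 1e-12 and abs(dy) < 1e-12:
            out[:, :, k] = sl  # exact identity, skip spline round-off
            continue
        if not sl.any():
            continue
        shifted = ndimage.shift(
            sl, (dx / vol.spacing[0], dy / vol.spacing[1]),
            order=3, mode="constant", cval=0.0, prefilter=True,
        )
        out[:, :, k] = np.clip(shifted, 0.0, 1.0)
    return vol.with_values(out)


def _overlap_matrix(n_to: int, s_to: float, o_to: float,
                    n_fr: int, s_fr: float, o_fr: float) -> np.ndarray:
    """(n_to, n_fr) matrix of 1-D interval-overlap lengths between voxel
    footprints of two axis-aligned grids."""
    to_lo = o_to + (np.arange(n_to) - 0.5) * s_to
    to_hi = to_lo + s_to
    fr_lo = o_fr + (np.arange(n_fr) - 0.5) * s_fr
    fr_hi = fr_lo + s_fr
    lo = np.maximum(to_lo[:, None], fr_lo[None, :])
    hi = np.minimum(to_hi[:, None], fr_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def project_to_pet_grid(fractional_mask: Volume3D, pet_grid: Volume3D) -> Volume3D:
    """Exact volume-weighted average of the fractional mask over each PET
    voxel's world-space footprint (box-overlap, separable per axis).

    Space not covered by the MRA grid counts as zero, so the integral of
    the output times the PET voxel volume equals the mask volume whenever
    the mask lies inside the PET field of view (mass conservation).
    """
    mats = [
        _overlap_matrix(pet_grid.shape[a], pet_grid.spacing[a], pet_grid.origin[a],
                        fractional_mask.shape[a], fractional_mask.spacing[a],
                        fractional_mask.origin[a])
        for a in range(3)
    ]
    if any(m.sum() == 0 for m in mats):
        raise ValueError("MRA and PET grids do not overlap")
    acc = np.tensordot(mats[0], fractional_mask.values, axes=(1, 0))
    acc = np.tensordot(mats[1], acc, axes=(1, 1)).transpose(1, 0, 2)
    acc = np.tensordot(mats[2], acc, axes=(1, 2)).transpose(1, 2, 0)
    pv = acc / pet_grid.voxel_volume
    return Volume3D(np.clip(pv, 0.0, 1.0), pet_grid.spacing, pet_grid.origin)


def align_mask(mask: ArteryMask, pet_reference: Volume3D, pet_grid: Volume3D,
               align: bool = True,
               search_radius_mm: float = DEFAULT_SEARCH_RADIUS_MM,
               refine: bool = True):
    """End-to-end: estimate -> fit -> shift -> project.

    With ``align=False`` the unshifted mask is projected directly (the
    "Unshifted" comparison arm).  Returns (pv_map, polynomial, series);
    the latter two are None when alignment is disabled.
    """
    if not align:
        return project_to_pet_grid(mask.mask, pet_grid), None, None
    series = estimate_slice_shifts(mask, pet_reference, search_radius_mm, refine)
    poly = fit_shift_polynomial(series)
    shifted = apply_shift(mask, poly)
    return project_to_pet_grid(shifted, pet_grid), poly, series


def soft_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap generalized to fractional maps: 2*sum(min)/(sum(a)+sum(b))."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.minimum(a, b).sum() / denom)
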