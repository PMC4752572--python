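"""PET point-spread-function calibration from a syringe (cylinder) phantom.

A syringe of known diameter is scanned and each transaxial slice is fitted
with ``amplitude * (disk ⊛ Gaussian)`` using the downhill simplex
(Nelder-Mead) algorithm over four parameters: in-plane disk position,
amplitude, and the Gaussian FWHM.  The disk-Gaussian convolution is radial
and evaluated analytically through the noncentral-chi-square CDF

    (disk_R ⊛ G_sigma)(r) = P[ chi2(df=2, nc=(r/sigma)^2) <= (R/sigma)^2 ],

interpolated onto a 4x oversampled pixel grid and box-averaged back to
voxel resolution, so the model represents voxel-integrated samples rather
than point samples (naive center evaluation biases small-FWHM fits).

The same phantom series also yields the frame-duration bias curve: the
mask-mean activity per frame normalized to its time average.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.stats import ncx2

from .artery_segmentation import histogram_threshold
from .core_io import DynamicSeries, FrameSchedule, Volume3D

__all__ = [
    "DiskGaussianFit",
    "PSFModel",
    "FrameBiasCurve",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "disk_gaussian_profile",
    "render_disk_gaussian",
    "fit_disk_gaussian_slice",
    "estimate_psf",
    "frame_bias",
]

log = logging.getLogger(__name__)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
DEFAULT_SYRINGE_DIAMETER_MM = 4.7
OVERSAMPLE = 4


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_PER_SIGMA


@dataclass
class DiskGaussianFit:
    """Result of one disk-Gaussian slice fit."""

    center: tuple[float, float]  # mm, world coordinates
    amplitude: float             # kBq/mL
    fwhm: float                  # mm
    residual_rms: float
    converged: bool


@dataclass
class PSFModel:
    """Isotropic Gaussian point-spread model parameterized by FWHM (mm)."""

    fwhm: float
    per_slice_fwhm: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")

    @property
    def sigma(self) -> float:
        return fwhm_to_sigma(self.fwhm)

    @property
    def fwhm_sd(self) -> float | None:
        """Across-slice standard deviation; None when < 2 slices were fitted."""
        if len(self.per_slice_fwhm) < 2:
            return None
        return float(np.std(self.per_slice_fwhm, ddof=1))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"fwhm_mm": self.fwhm, "sigma_mm": self.sigma,
                 "per_slice_fwhm_mm": list(self.per_slice_fwhm)},
                fh, indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PSFModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(float(d["fwhm_mm"]), [float(v) for v in d.get("per_slice_fwhm_mm", [])])


@dataclass
class FrameBiasCurve:
    """Per-frame mask-mean activity normalized to its time average (= 1)."""

    values: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.schedule):
            raise ValueError("bias curve length must match the schedule")


# ---------------------------------------------------------------------------
# Disk ⊛ Gaussian forward model
# ---------------------------------------------------------------------------

def disk_gaussian_profile(r: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    """Radial profile of a unit disk convolved with an isotropic Gaussian."""
    r = np.asarray(r, dtype=np.float64)
    if sigma <= 0:
        return (r <= radius).astype(np.float64)
    return ncx2.cdf((radius / sigma) ** 2, 2, (r / sigma) ** 2)


def render_disk_gaussian(xs: np.ndarray, ys: np.ndarray, spacing: tuple[float, float],
                         cx: float, cy: float, amplitude: float, fwhm: float,
                         diameter: float, oversample: int = OVERSAMPLE) -> np.ndarray:
    """Voxel-integrated disk-Gaussian image on pixel centers (xs x ys).

    The analytic radial profile is sampled on ``oversample``^2 sub-pixel
    points per voxel and box-averaged.
    """
    sigma = fwhm_to_sigma(fwhm)
    offs_x = (np.arange(oversample) + 0.5) / oversample - 0.5
    x_os = (xs[:, None] + offs_x[None, :] * spacing[0]).ravel()
    y_os = (ys[:, None] + offs_x[None, :] * spacing[1]).ravel()
    r = np.sqrt((x_os[:, None] - cx) ** 2 + (y_os[None, :] - cy) ** 2)
    rgrid = np.linspace(0.0, float(r.max()) + 1e-9, 512)
    prof = disk_gaussian_profile(rgrid, diameter / 2.0, sigma)
    vals = np.interp(r, rgrid, prof)
    vals = vals.reshape(len(xs), oversample, len(ys), oversample).mean(axis=(1, 3))
    return amplitude * vals


def fit_disk_gaussian_slice(slice_image: np.ndarray, spacing: tuple[float, float],
                            diameter: float = DEFAULT_SYRINGE_DIAMETER_MM,
                            origin: tuple[float, float] = (0.0, 0.0),
                            crop_radius_mm: float = 25.0,
                            oversample: int = OVERSAMPLE) -> DiskGaussianFit:
    """Nelder-Mead fit of (cx, cy, amplitude, fwhm) to one transaxial slice.

    Initialization: center = argmax of a lightly smoothed copy of the slice
    (robust to noise, unlike a whole-slice centroid), amplitude = max
    intensity, FWHM = 2x in-plane voxel size.  The sum of squared residuals
    is minimized within ``crop_radius_mm`` of the initial center (the
    phantom cross-section plus the PSF tails); one restart from a perturbed
    start is attempted if the simplex stalls or hits the FWHM bounds.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    img = np.asarray(slice_image, dtype=np.float64)
    xs = origin[0] + spacing[0] * np.arange(img.shape[0])
    ys = origin[1] + spacing[1] * np.arange(img.shape[1])
    if img.max() <= 0:
        raise ValueError("slice contains no signal to fit")
    smoothed = ndimage.gaussian_filter(img, sigma=2.0, mode="nearest")
    imax, jmax = np.unravel_index(np.argmax(smoothed), img.shape)
    cx0, cy0 = float(xs[imax]), float(ys[jmax])

    keep_x = np.abs(xs - cx0) <= crop_radius_mm
    keep_y = np.abs(ys - cy0) <= crop_radius_mm
    sub = img[np.ix_(keep_x, keep_y)]
    sub_xs, sub_ys = xs[keep_x], ys[keep_y]

    fwhm_lo, fwhm_hi = 0.2, 40.0

    def objective(theta):
        cx, cy, amp, fwhm = theta
        model = render_disk_gaussian(sub_xs, sub_ys, spacing, cx, cy, amp, fwhm,
                                     diameter, oversample)
        return float(((model - sub) ** 2).sum())

    x0 = np.array([cx0, cy0, float(img.max()), 2.0 * max(spacing)])
    bounds = [(None, None), (None, None), (0.0, None), (fwhm_lo, fwhm_hi)]
    best = None
    for attempt in range(2):
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-6, "fatol": 1e-10 * max(1.0, float((sub**2).sum())),
                     "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
        at_bound = not (fwhm_lo * 1.01 < res.x[3] < fwhm_hi * 0.99)
        if res.success and not at_bound:
            break
        x0 = res.x * np.array([1.0, 1.0, 1.05, 1.3]) + np.array([0.3, -0.3, 0.0, 0.5])
        x0[3] = np.clip(x0[3], fwhm_lo * 2, fwhm_hi / 2)

    cx, cy, amp, fwhm = best.x
    in_slice = (sub_xs[0] - spacing[0] <= cx <= sub_xs[-1] + spacing[0]
                and sub_ys[0] - spacing[1] <= cy <= sub_ys[-1] + spacing[1])
    if not in_slice:
        raise RuntimeError("disk fit drifted outside the slice")
    rms = float(np.sqrt(best.fun / sub.size))
    return DiskGaussianFit((float(cx), float(cy)), float(amp), float(fwhm), rms,
                           converged=bool(best.success))


def estimate_psf(data: Volume3D | DynamicSeries,
                 diameter: float = DEFAULT_SYRINGE_DIAMETER_MM,
                 slice_range: tuple[int, int] | None = None,
                 oversample: int = OVERSAMPLE) -> PSFModel:
    """Average the per-slice disk-Gaussian FWHM over central syringe slices.

    ``slice_range`` is a half-open (start, stop) index pair along the axial
    axis selecting slices free of cylinder-end edge effects; by default the
    central half of the volume is used.  Slices whose fit fails are dropped
    with a warning; if all fail, an error is raised.
    """
    vol = data.mean_over_time() if isinstance(data, DynamicSeries) else data
    nz = vol.shape[2]
    if slice_range is None:
        slice_range = (nz // 4, nz - nz // 4)
    lo, hi = slice_range
    if not (0 <= lo < hi <= nz):
        raise ValueError(f"invalid slice range {slice_range} for {nz} slices")

    fits = []
    for k in range(lo, hi):
        try:
            fit = fit_disk_gaussian_slice(
                vol.values[:, :, k], vol.spacing[:2], diameter,
                origin=(vol.origin[0], vol.origin[1]), oversample=oversample,
            )
            fits.append(fit.fwhm)
        except (ValueError, RuntimeError) as exc:
            log.warning("slice %d dropped from PSF fit: %s", k, exc)
    if not fits:
        raise RuntimeError("all slice fits failed; no PSF estimate")
    return PSFModel(float(np.mean(fits)), per_slice_fwhm=fits)


def frame_bias(series: DynamicSeries, mask: Volume3D | None = None) -> FrameBiasCurve:
    """Reconstruction bias versus frame duration on a static phantom.

    Per frame, activity is averaged over the phantom mask (derived with the
    same histogram-minimum threshold as the artery segmentation when not
    supplied) and normalized to the unweighted mean over frames.  Decay
    correction is assumed to have been applied upstream.
    """
    if mask is None:
        mean_vol = series.mean_over_time()
        thr = histogram_threshold(mean_vol)
        mask = mean_vol.with_values((mean_vol.values > thr).astype(np.float64))
    binary = mask.values > 0
    if not binary.any():
        raise ValueError("empty phantom mask")
    per_frame = series.values[binary, :].mean(axis=0)
    return FrameBiasCurve(per_frame / per_frame.mean(), series.schedule)
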