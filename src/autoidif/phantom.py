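"""Digital phantoms with known ground truth for the whole IDIF pipeline.

Three synthetic acquisitions are emulated:

* a TOF-MRA-like volume: two bright artery tubes (in-plane position
  quadratic in z) inside a homogeneous "neck" on a fine anisotropic grid,
  degraded by a smooth multiplicative bias field (coil profile) and
  additive Gaussian noise;
* a dynamic PET series: the arteries carry a gamma-variate arterial input
  function, the rest of the field of view a one-tissue-compartment
  response, plus an optional injection-catheter tube with constant residual
  activity; the scene is displaced by a quadratic slice-dependent motion
  polynomial relative to the MRA, blurred with an isotropic Gaussian PSF,
  averaged over each frame, and degraded with Gaussian noise whose variance
  scales as mean/duration (short frames are noisier, as in counting
  statistics);
* blood samples: the true input function delayed and dispersed (single
  exponential), sampled on the clinical schedule with multiplicative noise.

Everything is reproducible from (config, seed), and the generator records
the ground truth (curves, masks, motion, steady-state intra/extraarterial
ratio) needed to validate every downstream stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import (
    BloodSampleSeries,
    DynamicSeries,
    FrameSchedule,
    TimeActivityCurve,
    Volume3D,
    default_frame_schedule,
)
from .psf_calibration import fwhm_to_sigma

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "gamma_variate_aif",
    "tissue_response",
    "generate_angio",
    "generate_dynamic_pet",
    "generate_syringe",
    "generate_subject",
    "cylinder_volume",
]

DENSE_DT = 0.1  # s, internal time resolution for curve generation


def _centered_origin(shape, spacing):
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))


@dataclass
class PhantomConfig:
    """Geometry, kinetics and noise of one synthetic subject.

    Grids mirror the acquisition: MRA 96x96x64 at 0.5x0.5x0.7 mm, PET
    64x64x32 at 1.40x1.40x2.03 mm, both centered on the world origin.  The
    two arteries (radius 3 mm) run axially at diagonal in-plane offsets
    ~27 mm apart with a small quadratic bow; the catheter lies beyond the
    second artery so the PET center of gravity is pulled toward that side.
    """

    # grids
    mra_shape: tuple[int, int, int] = (96, 96, 64)
    mra_spacing: tuple[float, float, float] = (0.5, 0.5, 0.7)
    pet_shape: tuple[int, int, int] = (64, 64, 32)
    pet_spacing: tuple[float, float, float] = (1.40, 1.40, 2.03)
    # arteries: in-plane offset at z=0 and quadratic bow amplitude (mm at the
    # axial extremes), per artery
    artery_radius: float = 3.0
    artery_offsets: tuple = ((-9.5, -9.5), (9.5, 9.5))
    artery_bow: tuple = ((1.5, -1.0), (-1.2, 1.3))
    # MRA appearance
    vessel_intensity: float = 1.0
    tissue_intensity: float = 0.08
    neck_radius_mm: float = 20.0
    mra_bias_amplitude: float = 0.2
    mra_noise_sigma: float = 0.02
    # PET physics
    psf_fwhm: float = 6.86
    pet_noise_scale: float = 1.0  # sigma = scale * sqrt(mean/duration)
    # MRA->PET motion: dx(z), dy(z) = c0 + c1*u + c2*u^2, u = z/z_half
    motion_x: tuple[float, float, float] = (1.5, 1.0, 0.8)
    motion_y: tuple[float, float, float] = (-1.0, 0.0, 0.6)
    # catheter (residual activity of the injection line); activity 0 disables
    catheter_side: int = 1
    catheter_offset: tuple[float, float] = (6.0, 5.0)
    catheter_radius: float = 1.5
    catheter_activity: float = 40.0
    # input function (gamma variate + recirculation plateau)
    aif_peak: float = 40.0       # kBq/mL at the bolus peak
    aif_t0: float = 10.0         # s, appearance time
    aif_alpha: float = 3.0
    aif_beta: float = 5.0        # s
    aif_recirc: float = 0.25     # plateau fraction of the peak
    # tissue kinetics (shape only; amplitude is set by ia_ea_ratio)
    tissue_k1: float = 0.4       # mL/min/mL
    tissue_k2: float = 0.9       # 1/min
    ia_ea_ratio: float = 3.0     # steady-state intra/extraarterial target
    # blood sampling
    blood_delay: float = 10.0        # s
    blood_dispersion_tau: float = 8.0  # s
    blood_noise_rel: float = 0.03
    blood_scale: float = 1.0         # true blood/image scale factor
    steady_window: tuple[float, float] = (150.0, 300.0)
    schedule: FrameSchedule = field(default_factory=default_frame_schedule)

    def __post_init__(self) -> None:
        if self.artery_radius <= 0:
            raise ValueError("artery radius must be positive")
        half_x = (self.mra_shape[0] - 1) / 2.0 * self.mra_spacing[0]
        half_y = (self.mra_shape[1] - 1) / 2.0 * self.mra_spacing[1]
        for (ox, oy), (bx, by) in zip(self.artery_offsets, self.artery_bow):
            if (abs(ox) + abs(bx) + self.artery_radius > half_x
                    or abs(oy) + abs(by) + self.artery_radius > half_y):
                raise ValueError("artery centerline does not fit inside the MRA grid")

    # --- derived grid helpers -------------------------------------------------
    @property
    def mra_origin(self):
        return _centered_origin(self.mra_shape, self.mra_spacing)

    @property
    def pet_origin(self):
        return _centered_origin(self.pet_shape, self.pet_spacing)

    @property
    def mra_z_half(self) -> float:
        return (self.mra_shape[2] - 1) / 2.0 * self.mra_spacing[2]

    def artery_center(self, artery: int, z, shifted: bool = False):
        """In-plane centerline (mm) of one artery at axial position z (mm)."""
        z = np.asarray(z, dtype=np.float64)
        u2 = (z / self.mra_z_half) ** 2
        (ox, oy), (bx, by) = self.artery_offsets[artery], self.artery_bow[artery]
        cx = ox + bx * u2
        cy = oy + by * u2
        if shifted:
            dx, dy = self.motion_shift(z)
            cx, cy = cx + dx, cy + dy
        return cx, cy

    def motion_shift(self, z):
        """True MRA->PET in-plane displacement (mm) at axial position z."""
        u = np.asarray(z, dtype=np.float64) / self.mra_z_half
        c = self.motion_x
        d = self.motion_y
        return (c[0] + c[1] * u + c[2] * u**2, d[0] + d[1] * u + d[2] * u**2)

    def motion_poly_coeffs(self):
        """True shift polynomials as polyval coefficients in world z (mm)."""
        zh = self.mra_z_half
        cx = np.array([self.motion_x[2] / zh**2, self.motion_x[1] / zh, self.motion_x[0]])
        cy = np.array([self.motion_y[2] / zh**2, self.motion_y[1] / zh, self.motion_y[0]])
        return cx, cy

    @property
    def selected_artery(self) -> int:
        """Index of the artery contralateral to the catheter."""
        return 1 - self.catheter_side if self.catheter_activity > 0 else 0

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["schedule"] = {"starts": self.schedule.starts.tolist(),
                         "durations": self.schedule.durations.tolist()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            d = json.load(fh)
        sched = d.pop("schedule", None)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v) \
                    if isinstance(v, list) else v
        if sched is not None:
            kwargs["schedule"] = FrameSchedule(np.asarray(sched["starts"]),
                                               np.asarray(sched["durations"]))
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Everything a test needs to score the pipeline against the phantom."""

    config: PhantomConfig
    dense_times: np.ndarray
    aif: np.ndarray               # true input function on dense_times
    tissue: np.ndarray            # true extraarterial curve on dense_times
    frame_aif: np.ndarray         # frame-averaged true AIF
    frame_tissue: np.ndarray
    mra_masks: list[np.ndarray]   # per-artery binary masks, MRA grid, MRA position
    pet_artery_frac: list[np.ndarray]  # per-artery fractional maps, PET grid, PET position
    catheter_frac: np.ndarray | None
    shift_coeff_x: np.ndarray     # true dx(z) polyval coefficients, z in mm
    shift_coeff_y: np.ndarray
    ia_ea_true: float
    selected_artery: int

    def true_aif_tac(self) -> TimeActivityCurve:
        return TimeActivityCurve(self.dense_times, self.aif)

    def frame_aif_tac(self, schedule: FrameSchedule) -> TimeActivityCurve:
        return TimeActivityCurve(schedule.mid_times, self.frame_aif)


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def gamma_variate_aif(A: float, t0: float, alpha: float, beta: float,
                      recirc: float, times: np.ndarray) -> TimeActivityCurve:
    """Normalized gamma-variate bolus with an optional recirculation plateau.

    C(t) = A * ((t-t0)/(alpha*beta))^alpha * exp(alpha - (t-t0)/beta) for
    t > t0 (zero before), peaking at exactly A when t = t0 + alpha*beta,
    plus recirc*A*(1 - exp(-(t-t0)/60)) modeling recirculated tracer.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if not 0 <= recirc < 1:
        raise ValueError("recirc must be in [0, 1)")
    times = np.asarray(times, dtype=np.float64)
    dt = times - t0
    pos = dt > 0
    vals = np.zeros_like(times)
    x = np.where(pos, dt / (alpha * beta), 1.0)
    vals[pos] = A * (x[pos] ** alpha) * np.exp(alpha - dt[pos] / beta)
    vals[pos] += recirc * A * (1.0 - np.exp(-dt[pos] / 60.0))
    return TimeActivityCurve(times, vals)


def tissue_response(aif: TimeActivityCurve, K1: float, k2: float) -> TimeActivityCurve:
    """One-tissue-compartment response C_T = K1 * (C_a ⊛ exp(-k2 t)).

    K1 in mL/min/mL and k2 in 1/min; the input curve must be on a uniform
    time grid (discrete convolution).
    """
    if K1 < 0 or k2 <= 0:
        raise ValueError("require K1 >= 0 and k2 > 0")
    dt = np.diff(aif.times)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("tissue_response requires a uniform time grid")
    step = float(dt[0])
    k1s, k2s = K1 / 60.0, k2 / 60.0
    kern = np.exp(-k2s * (aif.times - aif.times[0]))
    kern[0] *= 0.5  # trapezoid endpoint: rectangle rule biases the plateau
    conv = np.convolve(aif.values, kern)[: len(aif.times)] * step
    return TimeActivityCurve(aif.times, k1s * conv)


def _window_mean(times, values, window):
    keep = (times >= window[0]) & (times <= window[1])
    return float(values[keep].mean())


def _true_curves(config: PhantomConfig):
    end = float(config.schedule.ends[-1])
    times = np.arange(0.0, end + DENSE_DT / 2, DENSE_DT)
    aif = gamma_variate_aif(config.aif_peak, config.aif_t0, config.aif_alpha,
                            config.aif_beta, config.aif_recirc, times)
    tis = tissue_response(aif, config.tissue_k1, config.tissue_k2)
    # the compartment model fixes the shape; the configured steady-state
    # intra/extraarterial ratio fixes the amplitude
    scale = _window_mean(times, aif.values, config.steady_window) / (
        config.ia_ea_ratio * _window_mean(times, tis.values, config.steady_window)
    )
    tissue = tis.values * scale
    return times, aif.values, tissue


def _frame_average(times: np.ndarray, values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    out = np.empty(len(schedule))
    for i, (s, e) in enumerate(zip(schedule.starts, schedule.ends)):
        keep = (times >= s) & (times < e)
        out[i] = values[keep].mean()
    return out


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _bias_field(shape, rng, amplitude):
    """Smooth multiplicative field 1 +- amplitude from a random low-order
    (quadratic) polynomial in normalized coordinates."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    basis = [X, Y, Z, X * Y, X * Z, Y * Z, X**2 - 0.5, Y**2 - 0.5, Z**2 - 0.5]
    coef = rng.normal(size=len(basis))
    f = sum(c * b for c, b in zip(coef, basis))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak * amplitude
    return 1.0 + f


def generate_angio(config: PhantomConfig, seed: int) -> tuple[Volume3D, GroundTruth]:
    """Render the TOF-MRA-like volume and initialize the ground truth.

    Tubes are binary at the vessel intensity (voxel center inside the
    radius), the neck is a homogeneous in-plane disk at the tissue
    intensity, air is zero; bias field and noise are applied after the
    ground-truth masks are recorded.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = config.mra_shape, config.mra_spacing
    origin = config.mra_origin
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])

    vol = np.zeros(shape)
    neck = (xs[:, None] ** 2 + ys[None, :] ** 2) <= config.neck_radius_mm**2
    vol += config.tissue_intensity * neck[:, :, None]

    masks = []
    for a in range(len(config.artery_offsets)):
        cx, cy = config.artery_center(a, zs)  # (nz,) each
        d2 = ((xs[:, None, None] - cx[None, None, :]) ** 2
              + (ys[None, :, None] - cy[None, None, :]) ** 2)
        mask = d2 <= config.artery_radius**2
        masks.append(mask)
        vol[mask] = config.vessel_intensity

    vol = vol * _bias_field(shape, rng, config.mra_bias_amplitude)
    if config.mra_noise_sigma > 0:
        vol = vol + rng.normal(scale=config.mra_noise_sigma, size=shape)

    times, aif, tissue = _true_curves(config)
    cx_poly, cy_poly = config.motion_poly_coeffs()
    truth = GroundTruth(
        config=config,
        dense_times=times,
        aif=aif,
        tissue=tissue,
        frame_aif=_frame_average(times, aif, config.schedule),
        frame_tissue=_frame_average(times, tissue, config.schedule),
        mra_masks=masks,
        pet_artery_frac=[],    # filled by generate_dynamic_pet
        catheter_frac=None,
        shift_coeff_x=cx_poly,
        shift_coeff_y=cy_poly,
        ia_ea_true=config.ia_ea_ratio,
        selected_artery=config.selected_artery,
    )
    return Volume3D(vol, spacing, origin), truth


def _fine_grid(shape, spacing, origin, osf):
    f_shape = tuple(n * o for n, o in zip(shape, osf))
    f_spacing = tuple(s / o for s, o in zip(spacing, osf))
    f_origin = tuple(og - s * (o - 1) / (2 * o) for og, s, o in zip(origin, spacing, osf))
    return f_shape, f_spacing, f_origin


def _box_average(fine: np.ndarray, osf) -> np.ndarray:
    n0, n1, n2 = (n // o for n, o in zip(fine.shape, osf))
    return fine.reshape(n0, osf[0], n1, osf[1], n2, osf[2]).mean(axis=(1, 3, 5))


def _tube_fraction(xs, ys, zs, cx, cy, radius, edge):
    """Anti-aliased in-plane tube occupancy; cx, cy are per-z centerlines."""
    d = np.sqrt((xs[:, None, None] - cx[None, None, :]) ** 2
                + (ys[None, :, None] - cy[None, None, :]) ** 2)
    return np.clip(0.5 + (radius - d) / edge, 0.0, 1.0)


def generate_dynamic_pet(config: PhantomConfig, truth: GroundTruth,
                         seed: int) -> tuple[DynamicSeries, BloodSampleSeries]:
    """Render the dynamic PET series and the blood-sample table.

    The continuous scene (arteries at their motion-shifted positions
    carrying the AIF, tissue filling the rest of the FOV, the catheter
    tube) is rasterized on a 2x oversampled PET grid, blurred with the
    Gaussian PSF, box-averaged to PET voxels, averaged per frame, and
    degraded with duration-dependent Gaussian noise.  Arteries span the
    axial extent of the MRA volume.  ``truth`` is updated in place with the
    unblurred PET-grid artery/catheter occupancy maps.
    """
    rng = np.random.default_rng(seed)
    osf = (2, 2, 2)
    f_shape, f_spacing, f_origin = _fine_grid(config.pet_shape, config.pet_spacing,
                                              config.pet_origin, osf)
    xs = f_origin[0] + f_spacing[0] * np.arange(f_shape[0])
    ys = f_origin[1] + f_spacing[1] * np.arange(f_shape[1])
    zs = f_origin[2] + f_spacing[2] * np.arange(f_shape[2])
    edge = float(np.mean(f_spacing[:2]))

    # axial extent of the arteries = the MRA slab (keeps mask and scene consistent)
    z_half = config.mra_z_half + config.mra_spacing[2] / 2.0
    z_frac = np.clip(0.5 + (z_half - np.abs(zs)) / f_spacing[2], 0.0, 1.0)

    sigma_vox = [fwhm_to_sigma(config.psf_fwhm) / s for s in f_spacing]

    def blur(a):
        return ndimage.gaussian_filter(a, sigma=sigma_vox, mode="nearest", truncate=6.0)

    art_frac_pet, art_weight_pet = [], []
    for a in range(len(config.artery_offsets)):
        cx, cy = config.artery_center(a, zs, shifted=True)
        frac = _tube_fraction(xs, ys, zs, cx, cy, config.artery_radius, edge)
        frac *= z_frac[None, None, :]
        art_frac_pet.append(_box_average(frac, osf))
        art_weight_pet.append(_box_average(blur(frac), osf))
    truth.pet_artery_frac = art_frac_pet

    w_cath = None
    if config.catheter_activity > 0:
        ox, oy = config.artery_offsets[config.catheter_side]
        ccx = np.full(len(zs), ox + config.catheter_offset[0])
        ccy = np.full(len(zs), oy + config.catheter_offset[1])
        cath = _tube_fraction(xs, ys, zs, ccx, ccy, config.catheter_radius, edge)
        truth.catheter_frac = _box_average(cath, osf)
        w_cath = _box_average(blur(cath), osf)

    w_art = sum(art_weight_pet)
    w_tis = 1.0 - w_art - (w_cath if w_cath is not None else 0.0)

    schedule = config.schedule
    n = len(schedule)
    frames = np.empty(config.pet_shape + (n,))
    for i in range(n):
        f = w_art * truth.frame_aif[i] + w_tis * truth.frame_tissue[i]
        if w_cath is not None:
            f = f + w_cath * config.catheter_activity
        if config.pet_noise_scale > 0:
            sigma = config.pet_noise_scale * np.sqrt(
                np.maximum(f, 0.0) / schedule.durations[i])
            f = f + rng.normal(size=f.shape) * sigma
        frames[..., i] = f
    series = DynamicSeries(frames, config.pet_spacing, schedule, config.pet_origin)

    blood = _blood_samples(config, truth, rng)
    return series, blood


def _blood_samples(config: PhantomConfig, truth: GroundTruth,
                   rng: np.random.Generator) -> BloodSampleSeries:
    """Delayed, dispersed, noisy readings of the true input function."""
    t = truth.dense_times
    aif = truth.aif
    if config.blood_dispersion_tau > 0:
        k = np.exp(-t / config.blood_dispersion_tau)
        k /= k.sum()
        dispersed = np.convolve(aif, k)[: len(t)]
    else:
        dispersed = aif
    sample_times = np.concatenate([np.arange(3.0, 120.0 + 1e-9, 3.0),
                                   [150.0, 180.0, 210.0, 240.0, 300.0]])
    vals = np.interp(sample_times - config.blood_delay, t, dispersed, left=0.0)
    vals = vals * config.blood_scale
    if config.blood_noise_rel > 0:
        vals = vals * (1.0 + rng.normal(scale=config.blood_noise_rel,
                                        size=vals.shape))
    return BloodSampleSeries(sample_times, vals)


def generate_subject(config: PhantomConfig, seed: int):
    """Convenience: one phantom subject = (mra, pet series, blood, truth).

    The MRA and PET stages draw from independent streams derived from the
    same seed, so either can be regenerated alone.
    """
    mra, truth = generate_angio(config, seed)
    series, blood = generate_dynamic_pet(config, truth, seed + 10_000_019)
    return mra, series, blood, truth


# ---------------------------------------------------------------------------
# Syringe phantom (PSF calibration scene)
# ---------------------------------------------------------------------------

def generate_syringe(diameter: float = 4.7, length: float = 57.0,
                     offcenter: float = 50.0, fwhm: float = 6.86,
                     schedule: FrameSchedule | None = None, seed: int = 0,
                     activity: float = 10.0, noise_scale: float = 0.0,
                     shape: tuple[int, int, int] = (96, 96, 32),
                     spacing: tuple[float, float, float] = (1.40, 1.40, 2.03),
                     oversample: int = 4) -> DynamicSeries:
    """Constant-activity axial cylinder blurred by a Gaussian PSF.

    The cylinder (default: the 4.7 mm x 57 mm syringe at 50 mm off-center)
    is rasterized on an in-plane ``oversample``-times finer grid, blurred,
    and box-averaged to the PET grid; frames repeat the static scene with
    duration-dependent noise.  ``fwhm=0`` skips the blur (voxelized
    cylinder).
    """
    if schedule is None:
        schedule = FrameSchedule([0.0], [300.0])
    origin = _centered_origin(shape, spacing)
    osf = (oversample, oversample, 1)
    f_shape, f_spacing, f_origin = _fine_grid(shape, spacing, origin, osf)
    xs = f_origin[0] + f_spacing[0] * np.arange(f_shape[0])
    ys = f_origin[1] + f_spacing[1] * np.arange(f_shape[1])
    zs = f_origin[2] + f_spacing[2] * np.arange(f_shape[2])
    if abs(offcenter) + diameter / 2.0 > xs.max():
        raise ValueError("cylinder does not fit inside the grid")
    if length / 2.0 > zs.max() + f_spacing[2] / 2.0:
        raise ValueError("cylinder longer than the axial field of view")

    edge = float(np.mean(f_spacing[:2]))
    cx = np.full(len(zs), float(offcenter))
    cy = np.zeros(len(zs))
    frac = _tube_fraction(xs, ys, zs, cx, cy, diameter / 2.0, edge)
    frac *= np.clip(0.5 + (length / 2.0 - np.abs(zs)) / f_spacing[2], 0.0, 1.0)[None, None, :]
    if fwhm > 0:
        sigma_vox = [fwhm_to_sigma(fwhm) / s for s in f_spacing]
        frac = ndimage.gaussian_filter(frac, sigma=sigma_vox, mode="constant",
                                       cval=0.0, truncate=6.0)
    scene = activity * _box_average(frac, osf)

    rng = np.random.default_rng(seed)
    frames = np.empty(shape + (len(schedule),))
    for i, dur in enumerate(schedule.durations):
        f = scene
        if noise_scale > 0:
            sigma = noise_scale * np.sqrt(np.maximum(f, 0.0) / dur)
            f = f + rng.normal(size=f.shape) * sigma
        frames[..., i] = f
    return DynamicSeries(frames, spacing, schedule, origin)


# ---------------------------------------------------------------------------
# Simple geometric test scenes
# ---------------------------------------------------------------------------

def cylinder_volume(shape, spacing, direction, radius: float,
                    intensity: float = 1.0, background: float = 0.0) -> Volume3D:
    """Straight cylinder through the grid center along an arbitrary direction.

    Used for rotation-tolerance checks of the vessel filter; the edge is
    anti-aliased over one voxel so sampled volumes vary smoothly with the
    rotation angle.
    """
    direction = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = direction / norm
    origin = _centered_origin(shape, spacing)
    coords = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    proj = X * d[0] + Y * d[1] + Z * d[2]
    dist = np.sqrt(np.maximum((X - proj * d[0]) ** 2 + (Y - proj * d[1]) ** 2
                              + (Z - proj * d[2]) ** 2, 0.0))
    edge = float(min(spacing))
    frac = np.clip(0.5 + (radius - dist) / edge, 0.0, 1.0)
    return Volume3D(background + (intensity - background) * frac, spacing, origin)
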