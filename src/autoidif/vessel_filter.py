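"""Multiscale inertia-tensor "prolateness" filter for tubular-structure enhancement.

For every voxel, the voxel intensities inside a sphere of radius ``r`` (mm,
world distance) are interpreted as discrete masses and the inertia tensor

    I_ab = sum_m m * (|x|^2 delta_ab - x_a x_b) / sum_m m

is formed about the intensity-weighted centroid of the sphere.  With sorted
eigenvalues ``l1 <= l2 <= l3``, the scale-invariant prolateness

    p = (l2 - l1) / (l1 + l2 + l3)

is close to 0.5 for cigar-shaped (vessel-like) mass distributions, 0 for
spheres, and is combined over a set of sphere radii by the root sum of
squares, ``P = sqrt(sum_i p(r_i)^2)``.  Multiplying the angiography volume
voxel-wise by ``P`` enhances vessels against background.

The whole-volume map is computed from ten moment images (mass, first and
second moments) obtained by FFT correlation with spherical kernels; spheres
are truncated at the volume border, which is exact zero-padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .core_io import Volume3D

__all__ = [
    "InertiaEigenvalues",
    "ScaleSet",
    "ProlatenessMap",
    "default_scales",
    "inertia_eigenvalues",
    "inertia_eigenvalue_map",
    "prolateness",
    "prolateness_map",
    "multiscale_prolateness",
    "enhance",
]


@dataclass
class InertiaEigenvalues:
    """Sorted eigenvalues (mm^2) of the mass-normalized inertia tensor."""

    lambda1: float
    lambda2: float
    lambda3: float
    degenerate: bool = False  # zero total mass inside the sphere

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])


@dataclass
class ScaleSet:
    """Strictly increasing sphere radii (mm) for the multiscale combination."""

    radii: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=np.float64))
        if len(self.radii) == 0:
            raise ValueError("scale set must contain at least one radius")
        if np.any(self.radii <= 0):
            raise ValueError("sphere radii must be positive")
        if len(self.radii) > 1 and np.any(np.diff(self.radii) <= 0):
            raise ValueError("sphere radii must be strictly increasing")

    def __len__(self) -> int:
        return len(self.radii)


@dataclass
class ProlatenessMap:
    """Combined prolateness P per voxel; per-scale maps optionally retained."""

    P: Volume3D
    per_scale: dict = field(default_factory=dict)  # radius (mm) -> np.ndarray


def default_scales(spacing, r_max: float = 8.0, r_step: float = 1.0) -> ScaleSet:
    """Radii from twice the smallest voxel dimension up to ``r_max`` in
    ``r_step`` (mm) increments.

    The lower end is the smallest sphere that still contains off-center
    voxels in every direction; the upper end stays on the scale of an
    arterial diameter so larger tubular anatomy is not amplified.
    """
    r_min = 2.0 * min(spacing)
    if r_min > r_max:
        raise ValueError(f"2x smallest voxel dimension ({r_min}) exceeds r_max ({r_max})")
    radii = np.arange(r_min, r_max + 1e-9, r_step)
    return ScaleSet(radii)


# ---------------------------------------------------------------------------
# Single-voxel computation (reference path)
# ---------------------------------------------------------------------------

def _sphere_offsets(spacing, radius):
    """Voxel index offsets and world offsets (mm) inside a sphere."""
    half = [int(np.floor(radius / s)) for s in spacing]
    ox, oy, oz = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    OX, OY, OZ = np.meshgrid(ox, oy, oz, indexing="ij")
    inside = OX**2 + OY**2 + OZ**2 <= radius**2 + 1e-12
    return half, OX, OY, OZ, inside


def inertia_eigenvalues(volume: Volume3D, center, radius: float) -> InertiaEigenvalues:
    """Inertia eigenvalues of the intensity distribution inside one sphere.

    ``center`` is a voxel index triple; sphere membership is evaluated in
    world (mm) coordinates, so anisotropic voxels are handled correctly.
    Spheres are truncated at the grid edge (exact zero padding).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ci, cj, ck = (int(c) for c in center)
    shape = volume.shape
    if not (0 <= ci < shape[0] and 0 <= cj < shape[1] and 0 <= ck < shape[2]):
        raise ValueError(f"center {center} outside grid {shape}")

    half, OX, OY, OZ, inside = _sphere_offsets(volume.spacing, radius)
    # clip the offset block to the grid
    lo = [max(0, c - h) for c, h in zip((ci, cj, ck), half)]
    hi = [min(n, c + h + 1) for c, h, n in zip((ci, cj, ck), half, shape)]
    blo = [l - (c - h) for l, c, h in zip(lo, (ci, cj, ck), half)]
    bhi = [b + (h_ - l_) for b, h_, l_ in zip(blo, hi, lo)]
    sl_vol = tuple(slice(l, h) for l, h in zip(lo, hi))
    sl_blk = tuple(slice(l, h) for l, h in zip(blo, bhi))

    m = np.zeros(inside.shape)
    m[sl_blk] = volume.values[sl_vol]
    m = np.where(inside, m, 0.0)

    M = m.sum()
    if M <= 0:
        return InertiaEigenvalues(0.0, 0.0, 0.0, degenerate=True)

    cx, cy, cz = (float((m * O).sum() / M) for O in (OX, OY, OZ))
    X, Y, Z = OX - cx, OY - cy, OZ - cz
    r2 = X**2 + Y**2 + Z**2
    I = np.empty((3, 3))
    I[0, 0] = (m * (r2 - X * X)).sum()
    I[1, 1] = (m * (r2 - Y * Y)).sum()
    I[2, 2] = (m * (r2 - Z * Z)).sum()
    I[0, 1] = I[1, 0] = -(m * X * Y).sum()
    I[0, 2] = I[2, 0] = -(m * X * Z).sum()
    I[1, 2] = I[2, 1] = -(m * Y * Z).sum()
    I /= M
    lam = np.linalg.eigvalsh(I)
    lam = np.clip(lam, 0.0, None)
    # a point mass carries no orientation information either
    degenerate = bool(lam.sum() <= 0.0)
    return InertiaEigenvalues(float(lam[0]), float(lam[1]), float(lam[2]),
                              degenerate=degenerate)


def prolateness(eigs: InertiaEigenvalues) -> float:
    """p = (l2 - l1) / (l1 + l2 + l3); 0 for a degenerate (massless) sphere."""
    l1, l2, l3 = eigs.lambda1, eigs.lambda2, eigs.lambda3
    if min(l1, l2, l3) < 0:
        raise ValueError("eigenvalues must be non-negative")
    if not (l1 <= l2 <= l3):
        raise ValueError("eigenvalues must be sorted ascending")
    total = l1 + l2 + l3
    if eigs.degenerate or total == 0.0:
        return 0.0
    return (l2 - l1) / total


# ---------------------------------------------------------------------------
# Whole-volume map via FFT moment correlation
# ---------------------------------------------------------------------------

def _sym3_eigvals(xx, yy, zz, xy, xz, yz):
    """Closed-form eigenvalues of symmetric 3x3 matrices, vectorized.

    Returns (e1, e2, e3) sorted ascending.  Uses the trigonometric solution
    of the characteristic cubic; degenerate (near-isotropic) matrices fall
    back to the triple (q, q, q).
    """
    q = (xx + yy + zz) / 3.0
    dxx, dyy, dzz = xx - q, yy - q, zz - q
    p2 = dxx**2 + dyy**2 + dzz**2 + 2.0 * (xy**2 + xz**2 + yz**2)
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe = p > 0
    pinv = np.where(safe, 1.0 / np.where(safe, p, 1.0), 0.0)
    bxx, byy, bzz = dxx * pinv, dyy * pinv, dzz * pinv
    bxy, bxz, byz = xy * pinv, xz * pinv, yz * pinv
    detb = (
        bxx * (byy * bzz - byz**2)
        - bxy * (bxy * bzz - byz * bxz)
        + bxz * (bxy * byz - byy * bxz)
    )
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e3 = q + 2.0 * p * np.cos(phi)
    e1 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return e1, e2, e3


def _sphere_kernels(spacing, radius):
    """The ten moment kernels (1, x, y, z, xx, yy, zz, xy, xz, yz) on a sphere."""
    _, OX, OY, OZ, inside = _sphere_offsets(spacing, radius)
    w = inside.astype(np.float64)
    return [
        w,
        w * OX, w * OY, w * OZ,
        w * OX * OX, w * OY * OY, w * OZ * OZ,
        w * OX * OY, w * OX * OZ, w * OY * OZ,
    ]


def _correlate_many(volume: np.ndarray, kernels: list[np.ndarray]) -> list[np.ndarray]:
    """FFT correlation of one volume with several kernels, sharing the
    forward transform of the volume (zero-padded 'same' output)."""
    kshape = kernels[0].shape
    full = [n + k - 1 for n, k in zip(volume.shape, kshape)]
    fshape = [sp_fft.next_fast_len(n, real=True) for n in full]
    Vf = sp_fft.rfftn(volume, fshape)
    start = [(k - 1) // 2 for k in kshape]
    crop = tuple(slice(s, s + n) for s, n in zip(start, volume.shape))
    out = []
    for K in kernels:
        # correlation = convolution with the flipped kernel
        Kf = sp_fft.rfftn(K[::-1, ::-1, ::-1], fshape)
        full_out = sp_fft.irfftn(Vf * Kf, fshape)[tuple(slice(0, n) for n in full)]
        out.append(np.ascontiguousarray(full_out[crop]))
    return out


def inertia_eigenvalue_map(volume: Volume3D, radius: float) -> np.ndarray:
    """Inertia eigenvalues at every voxel via the FFT moment route.

    Returns an array of shape ``volume.shape + (3,)`` with eigenvalues
    sorted ascending (mm^2); degenerate (massless) spheres yield zeros.
    Same mathematics as :func:`inertia_eigenvalues`, vectorized.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    kernels = _sphere_kernels(volume.spacing, radius)
    S0, Sx, Sy, Sz, Sxx, Syy, Szz, Sxy, Sxz, Syz = _correlate_many(volume.values, kernels)
    tiny = 1e-12 * max(1.0, float(np.abs(volume.values).max())) * kernels[0].sum()
    ok = S0 > tiny
    Minv = np.where(ok, 1.0 / np.where(ok, S0, 1.0), 0.0)
    Txx = Sxx - Sx * Sx * Minv
    Tyy = Syy - Sy * Sy * Minv
    Tzz = Szz - Sz * Sz * Minv
    Txy = Sxy - Sx * Sy * Minv
    Txz = Sxz - Sx * Sz * Minv
    Tyz = Syz - Sy * Sz * Minv
    t1, t2, t3 = _sym3_eigvals(Txx, Tyy, Tzz, Txy, Txz, Tyz)
    tr = Txx + Tyy + Tzz
    lam = np.stack([tr - t3, tr - t2, tr - t1], axis=-1) * Minv[..., None]
    return np.clip(np.where(ok[..., None], lam, 0.0), 0.0, None)


def prolateness_map(volume: Volume3D, radius: float) -> np.ndarray:
    """Single-scale prolateness p at every voxel (dimensionless, in [0, 0.5]).

    Equivalent to calling :func:`inertia_eigenvalues` + :func:`prolateness`
    per voxel, but computed via ten FFT moment correlations.  Writing the
    second-moment matrix about the local centroid as T with eigenvalues
    t1 <= t2 <= t3, the inertia eigenvalues are (tr T - t_i)/M and

        p = (t3 - t2) / (2 tr T),

    so only T's eigenvalues are needed.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    kernels = _sphere_kernels(volume.spacing, radius)
    S0, Sx, Sy, Sz, Sxx, Syy, Szz, Sxy, Sxz, Syz = _correlate_many(volume.values, kernels)

    # mass below this is indistinguishable from FFT round-off: degenerate
    tiny = 1e-12 * max(1.0, float(np.abs(volume.values).max())) * kernels[0].sum()
    ok = S0 > tiny
    Minv = np.where(ok, 1.0 / np.where(ok, S0, 1.0), 0.0)

    # second moments about the intensity-weighted centroid
    Txx = Sxx - Sx * Sx * Minv
    Tyy = Syy - Sy * Sy * Minv
    Tzz = Szz - Sz * Sz * Minv
    Txy = Sxy - Sx * Sy * Minv
    Txz = Sxz - Sx * Sz * Minv
    Tyz = Syz - Sy * Sz * Minv

    t1, t2, t3 = _sym3_eigvals(Txx, Tyy, Tzz, Txy, Txz, Tyz)
    tr = Txx + Tyy + Tzz
    good = ok & (tr > tiny)
    p = np.where(good, (t3 - t2) / np.where(good, 2.0 * tr, 1.0), 0.0)
    return np.clip(p, 0.0, 0.5)


def multiscale_prolateness(volume: Volume3D, scales: ScaleSet,
                           keep_per_scale: bool = False) -> ProlatenessMap:
    """Combine single-scale prolateness maps by the root sum of squares."""
    if len(scales) == 0:
        raise ValueError("empty scale set")
    acc = np.zeros(volume.shape)
    per_scale = {}
    for r in scales.radii:
        p = prolateness_map(volume, float(r))
        acc += p * p
        if keep_per_scale:
            per_scale[float(r)] = p
    P = np.sqrt(acc)
    return ProlatenessMap(volume.with_values(P), per_scale)


def enhance(volume: Volume3D, pmap: ProlatenessMap) -> Volume3D:
    """Voxel-wise product of the angiography volume with the prolateness map."""
    if not volume.same_grid(pmap.P):
        raise ValueError("volume and prolateness map are on different grids")
    return volume.with_values(volume.values * pmap.P.values)
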