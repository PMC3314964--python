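"""Fourier-slice operators linking 2D particle transforms to the 3D model.

Geometry conventions:

* Euler angles (rot, tilt, psi) in degrees, ZYZ intrinsic:
  ``A = Rz(psi) @ Ry(tilt) @ Rz(rot)``.  A 2D Fourier grid point
  ``q = (h, k, 0)`` samples the 3D transform at ``p = Aᵀ q`` (projection-slice
  theorem).  In 2D class-averaging mode only ``psi`` is used.
* The model transform is oversampled by an integer factor ``m`` (default 3):
  the real-space map is zero-padded to ``(mD)³`` before transforming, and a
  2D frequency ``q`` lands at the oversampled voxel nearest to ``m·Aᵀq``
  (nearest-neighbour interpolation, as used for both projection and
  back-projection).  Frequencies beyond the Nyquist rate of the original
  sampling (|q| > D/2) are excluded from extraction and insertion; rotated
  points that fall outside the grid are set to zero.
* ``shift_x`` / ``shift_y`` are real-space offsets in pixels along array axes
  0 and 1; they act as pure phase ramps in Fourier space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fourier import (FourierImage, FourierVolume, RealImage, RealVolume,
                      enforce_friedel, fftc, ifftc)

__all__ = [
    "Orientation",
    "OrientationGrid",
    "Accumulator",
    "rotation_matrix",
    "oversampled_transform",
    "volume_from_fourier",
    "image_from_fourier",
    "image_grid",
    "extract_slice",
    "insert_slice",
    "apply_shift",
    "shift_phase",
    "build_orientation_grid",
    "symmetry_matrices",
    "symmetrize",
    "symmetrize_array",
    "project_real_space",
]


@dataclass
class Orientation:
    """One hypothesis for the hidden variable: 3 Euler angles + 2D origin shift."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rot", "tilt", "psi", "shift_x", "shift_y"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"Orientation.{name} must be finite")
        self.rot = float(self.rot) % 360.0
        self.psi = float(self.psi) % 360.0
        self.tilt = float(self.tilt) % 360.0

    @property
    def angles(self) -> tuple:
        return (self.rot, self.tilt, self.psi)


def _rz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic rotation A = Rz(psi) · Ry(tilt) · Rz(rot)."""
    return _rz(psi) @ _ry(tilt) @ _rz(rot)


# ---------------------------------------------------------------------------
# Model-grid plumbing: oversampled transforms and their inverses
# ---------------------------------------------------------------------------

def _pad_centered(a: np.ndarray, factor: int) -> np.ndarray:
    d = a.shape[0]
    n = factor * d
    out = np.zeros((n,) * a.ndim, dtype=a.dtype)
    lo = (n - d) // 2
    sl = tuple(slice(lo, lo + d) for _ in range(a.ndim))
    out[sl] = a
    return out


def oversampled_transform(x: RealVolume | RealImage, factor: int = 3):
    """Zero-pad a map by ``factor`` and transform.

    The result is scaled by ``factor**(ndim/2)`` so that stride-``factor``
    lattice points carry the unitary transform values of the un-padded map;
    off-lattice voxels interpolate the continuous transform.
    """
    if isinstance(x, RealVolume):
        comp = fftc(_pad_centered(x.voxels, factor)) * factor ** 1.5
        return FourierVolume(comp, x.voxel_size, oversampling=factor)
    if isinstance(x, RealImage):
        comp = fftc(_pad_centered(x.pixels, factor)) * float(factor)
        f = FourierImage(comp, x.pixel_size)
        f.oversampling = factor
        return f
    raise TypeError(f"oversampled_transform: unsupported input {type(x)!r}")


def volume_from_fourier(fv: FourierVolume) -> RealVolume:
    """Invert an (oversampled) model transform and crop to the original box."""
    m = fv.oversampling
    real = ifftc(fv.components / m ** 1.5).real
    d = fv.original_size
    lo = (fv.size - d) // 2
    return RealVolume(real[lo:lo + d, lo:lo + d, lo:lo + d], fv.voxel_size)


def image_from_fourier(fi: FourierImage) -> RealImage:
    m = getattr(fi, "oversampling", 1)
    real = ifftc(fi.components / float(m)).real
    d = fi.size // m
    lo = (fi.size - d) // 2
    return RealImage(real[lo:lo + d, lo:lo + d], fi.pixel_size)


# ---------------------------------------------------------------------------
# Image-grid geometry (shared by expectation/maximization)
# ---------------------------------------------------------------------------

class ImageGrid:
    """Masked centered 2D Fourier grid of an image of side D.

    Holds the integer frequencies inside the Nyquist disc |q| <= D/2, their
    ring indices, and flattened positions into the full D×D grid.
    """

    def __init__(self, size: int):
        self.size = size
        h = np.arange(size) - size // 2
        hh, kk = np.meshgrid(h, h, indexing="ij")
        r = np.sqrt(hh.astype(float) ** 2 + kk.astype(float) ** 2)
        self.mask = r <= size / 2
        self.h = hh[self.mask]
        self.k = kk[self.mask]
        self.ring = np.rint(r[self.mask]).astype(np.int64)
        self.n_rings = size // 2 + 1
        self.flat_index = np.flatnonzero(self.mask.ravel())
        self.n_components = self.h.size


_IMAGE_GRIDS: dict = {}


def image_grid(size: int) -> ImageGrid:
    if size not in _IMAGE_GRIDS:
        _IMAGE_GRIDS[size] = ImageGrid(size)
    return _IMAGE_GRIDS[size]


_SLICE_MAPS: dict = {}


def slice_map(angles: tuple, image_size: int, model_size: int, oversampling: int,
              model_ndim: int = 3):
    """Nearest-neighbour index map of one slice into the model grid.

    Returns (valid mask over the image grid's masked components, flat voxel
    indices for the valid components).  Cached per (angles, sizes).
    """
    key = (tuple(np.round(angles, 6)), image_size, model_size, oversampling, model_ndim)
    if key in _SLICE_MAPS:
        return _SLICE_MAPS[key]
    g = image_grid(image_size)
    a = rotation_matrix(*angles)
    q = np.stack([g.h, g.k, np.zeros_like(g.h)], axis=0).astype(np.float64)
    p = (a.T @ q) * oversampling
    if model_ndim == 2:
        p = p[:2]
    idx = np.rint(p).astype(np.int64) + model_size // 2
    valid = np.all((idx >= 0) & (idx < model_size), axis=0)
    strides = [model_size ** (model_ndim - 1 - i) for i in range(model_ndim)]
    flat = np.zeros(g.n_components, dtype=np.int64)
    for i, s in enumerate(strides):
        flat += idx[i] * s
    flat = flat[valid]
    out = (valid, flat)
    if len(_SLICE_MAPS) < 100_000:
        _SLICE_MAPS[key] = out
    return out


def shift_phase(size: int, shift_x: float, shift_y: float) -> np.ndarray:
    """Phase ramp over the masked image grid for a real-space shift (sx, sy)."""
    g = image_grid(size)
    return np.exp(-2j * np.pi * (g.h * shift_x + g.k * shift_y) / size)


def apply_shift(image: FourierImage, shift_x: float, shift_y: float) -> FourierImage:
    """Translate the underlying real image by (sx, sy) pixels via a phase ramp.

    Magnitudes are untouched; an integer shift equals a circular pixel roll.
    """
    d = image.size
    h = np.arange(d) - d // 2
    hh, kk = np.meshgrid(h, h, indexing="ij")
    phase = np.exp(-2j * np.pi * (hh * shift_x + kk * shift_y) / d)
    return FourierImage(image.components * phase, image.pixel_size)


def extract_slice(volume: FourierVolume | FourierImage, orientation: Orientation) -> FourierImage:
    """P^φ: extract a central slice at the given orientation (NN interpolation).

    Components outside the Nyquist disc, or whose rotated position falls
    outside the oversampled grid, are zero.  A nonzero shift in the
    orientation is applied as a phase ramp after extraction.
    """
    is_vol = isinstance(volume, FourierVolume)
    m = volume.oversampling if is_vol else getattr(volume, "oversampling", 1)
    model_ndim = 3 if is_vol else 2
    d = volume.size // m if is_vol else volume.size // m
    g = image_grid(d)
    valid, flat = slice_map(orientation.angles, d, volume.size, m, model_ndim)
    vals = np.zeros(g.n_components, dtype=np.complex128)
    vals[valid] = volume.components.ravel()[flat]
    out = np.zeros((d, d), dtype=np.complex128)
    out.ravel()[g.flat_index] = vals
    pixel = volume.voxel_size if is_vol else volume.pixel_size
    img = FourierImage(out, pixel)
    if orientation.shift_x or orientation.shift_y:
        img = apply_shift(img, orientation.shift_x, orientation.shift_y)
    return img


@dataclass
class Accumulator:
    """The two running sums of the reconstruction update.

    ``numerator``  accumulates Γ·CTF·X/σ² (data term),
    ``denominator`` accumulates Γ·CTF²/σ²  (weight term),
    both on the oversampled model grid.
    """

    numerator: np.ndarray
    denominator: np.ndarray
    oversampling: int
    voxel_size: float

    @classmethod
    def zeros(cls, model_size: int, oversampling: int, voxel_size: float,
              model_ndim: int = 3) -> "Accumulator":
        n = model_size * oversampling
        shape = (n,) * model_ndim
        return cls(np.zeros(shape, dtype=np.complex128),
                   np.zeros(shape, dtype=np.float64), oversampling, voxel_size)

    @property
    def model_ndim(self) -> int:
        return self.numerator.ndim

    @property
    def original_size(self) -> int:
        return self.numerator.shape[0] // self.oversampling

    def add_slice_values(self, angles: tuple, data_vals: np.ndarray,
                         weight_vals: np.ndarray) -> None:
        """Scatter per-component contributions (already on the masked image grid)."""
        d = self.original_size
        valid, flat = slice_map(angles, d, self.numerator.shape[0],
                                self.oversampling, self.model_ndim)
        np.add.at(self.numerator.ravel(), flat, data_vals[valid])
        np.add.at(self.denominator.ravel(), flat, weight_vals[valid])


def insert_slice(image: FourierImage, ctf: np.ndarray, weight: float,
                 sigma2, orientation: Orientation, acc: Accumulator) -> Accumulator:
    """P^φᵀ: back-project one image into the accumulator.

    Adds ``weight·CTF·X/σ²`` to the numerator and ``weight·CTF²/σ²`` to the
    denominator at the nearest-neighbour target voxels.  ``sigma2`` may be a
    scalar or a full-grid per-component array.  The orientation's shift is
    removed from the image (phase conjugate) before insertion, making this
    the adjoint of :func:`extract_slice`.
    """
    if weight < 0:
        raise ValueError("insert weight must be >= 0")
    if weight == 0:
        return acc
    d = image.size
    if ctf.shape != image.components.shape:
        raise ValueError("insert_slice: CTF grid does not match image grid")
    g = image_grid(d)
    x = image.components.ravel()[g.flat_index]
    if orientation.shift_x or orientation.shift_y:
        x = x * np.conj(shift_phase(d, orientation.shift_x, orientation.shift_y))
    c = ctf.ravel()[g.flat_index]
    s2 = np.broadcast_to(np.asarray(sigma2, dtype=np.float64), ctf.shape).ravel()[g.flat_index]
    acc.add_slice_values(orientation.angles, weight * c * x / s2, weight * c * c / s2)
    return acc


# ---------------------------------------------------------------------------
# Orientation sampling
# ---------------------------------------------------------------------------

@dataclass
class OrientationGrid:
    """Discretized hidden-variable domain: rotations × shift lattice.

    Rotations carry a uniform prior; shifts are uniform or centered Gaussian.
    The flattened enumeration is rotation-major then shift (tie-breaks and
    Γ array layouts follow this order).
    """

    angles: np.ndarray        # (R, 3) degrees
    shifts: np.ndarray        # (S, 2) pixels
    rot_prior: np.ndarray     # (R,)
    shift_prior: np.ndarray   # (S,)
    angular_step: float
    mode: str = "3d"

    @property
    def n_rotations(self) -> int:
        return self.angles.shape[0]

    @property
    def n_shifts(self) -> int:
        return self.shifts.shape[0]

    def __len__(self) -> int:
        return self.n_rotations * self.n_shifts

    @property
    def prior_prob(self) -> np.ndarray:
        return np.outer(self.rot_prior, self.shift_prior).ravel()

    def orientation(self, index: int) -> Orientation:
        r, s = divmod(int(index), self.n_shifts)
        return Orientation(rot=self.angles[r, 0], tilt=self.angles[r, 1],
                           psi=self.angles[r, 2],
                           shift_x=self.shifts[s, 0], shift_y=self.shifts[s, 1])

    @property
    def orientations(self) -> list:
        return [self.orientation(i) for i in range(len(self))]

    def nearest_rotation(self, rot: float, tilt: float, psi: float) -> int:
        """Index of the grid rotation closest to the given Euler triple.

        Distance is measured between the rotation matrices (Frobenius), which
        is insensitive to the Euler-angle gimbal ambiguity at tilt ≈ 0/180.
        """
        target = rotation_matrix(rot, tilt, psi)
        best, best_d = 0, np.inf
        for i, a in enumerate(self.angles):
            d = np.linalg.norm(rotation_matrix(*a) - target)
            if d < best_d:
                best, best_d = i, d
        return best


def build_orientation_grid(angular_step: float, shift_range: float = 0.0,
                           shift_step: float = 1.0, mode: str = "3d",
                           shift_sigma: float | None = None) -> OrientationGrid:
    """Quasi-uniform orientation grid at the requested angular spacing.

    3D mode tiles the sphere in latitude bands of height ``angular_step`` with
    ``round(360·sin(tilt)/step)`` azimuthal points per band (approximately
    equal-area coverage), crossed with in-plane psi and the shift lattice.
    2D mode samples psi × shifts only.
    """
    if angular_step <= 0 or shift_step <= 0:
        raise ValueError("angular_step and shift_step must be > 0")
    psis = np.arange(0.0, 360.0, angular_step)
    if mode == "2d":
        angles = np.stack([np.zeros_like(psis), np.zeros_like(psis), psis], axis=1)
    elif mode == "3d":
        rows = []
        n_tilt = max(1, int(round(180.0 / angular_step)))
        for it in range(n_tilt):
            tilt = (it + 0.5) * 180.0 / n_tilt
            n_rot = max(1, int(round(360.0 * np.sin(np.deg2rad(tilt)) / angular_step)))
            for rot in np.arange(n_rot) * 360.0 / n_rot:
                for psi in psis:
                    rows.append((rot, tilt, psi))
        angles = np.array(rows)
    else:
        raise ValueError(f"unknown grid mode {mode!r}")
    if angles.shape[0] == 0:
        raise ValueError("empty orientation grid")
    if shift_range > 0:
        vals = np.arange(-shift_range, shift_range + 1e-9, shift_step)
        sx, sy = np.meshgrid(vals, vals, indexing="ij")
        shifts = np.stack([sx.ravel(), sy.ravel()], axis=1)
    else:
        shifts = np.zeros((1, 2))
    if shift_sigma is not None and shifts.shape[0] > 1:
        w = np.exp(-(shifts[:, 0] ** 2 + shifts[:, 1] ** 2) / (2 * shift_sigma ** 2))
        shift_prior = w / w.sum()
    else:
        shift_prior = np.full(shifts.shape[0], 1.0 / shifts.shape[0])
    rot_prior = np.full(angles.shape[0], 1.0 / angles.shape[0])
    return OrientationGrid(angles=angles, shifts=shifts, rot_prior=rot_prior,
                           shift_prior=shift_prior, angular_step=angular_step, mode=mode)


# ---------------------------------------------------------------------------
# Point-group symmetry
# ---------------------------------------------------------------------------

def symmetry_matrices(group: str) -> list:
    """Rotation matrices of a Cn or Dn point group ('C1', 'C8', 'D7', ...)."""
    group = group.strip().upper()
    if len(group) < 2 or group[0] not in "CD" or not group[1:].isdigit():
        raise ValueError(f"unsupported symmetry group {group!r} (expected Cn or Dn)")
    n = int(group[1:])
    if n < 1:
        raise ValueError("group order must be >= 1")
    mats = [_rz(360.0 * i / n) for i in range(n)]
    if group[0] == "D":
        flip = np.diag([1.0, -1.0, -1.0])  # two-fold about x
        mats += [flip @ m for m in mats[:n]]
    return mats


def symmetrize_array(arr: np.ndarray, group: str, order: int = 1) -> np.ndarray:
    """Average an array (real or complex, 2D/3D) over the group rotations."""
    mats = symmetry_matrices(group)
    if len(mats) == 1:
        return arr
    c = np.array(arr.shape) // 2

    def _rot(a, m):
        mm = m if a.ndim == 3 else m[:2, :2]
        offset = c[:a.ndim] - mm @ c[:a.ndim]
        return ndimage.affine_transform(a, mm, offset=offset, order=order,
                                        mode="constant", cval=0.0)

    if np.iscomplexobj(arr):
        out = sum(_rot(arr.real, m) + 1j * _rot(arr.imag, m) for m in mats)
    else:
        out = sum(_rot(arr, m) for m in mats)
    return out / len(mats)


def symmetrize(volume: FourierVolume, group: str) -> FourierVolume:
    """Impose Cn/Dn symmetry by averaging over the group rotations."""
    if group.strip().upper() == "C1":
        return volume
    out = symmetrize_array(volume.components, group)
    return enforce_friedel(FourierVolume(out, volume.voxel_size, volume.oversampling))


def symmetrize_accumulator(acc: Accumulator, group: str) -> Accumulator:
    """Average numerator and denominator over the group before solving.

    Done at the accumulator level (not on the final map) so the per-voxel
    SNR bookkeeping reflects the number of averaged asymmetric units.
    """
    if group.strip().upper() == "C1":
        return acc
    return Accumulator(symmetrize_array(acc.numerator, group),
                       np.maximum(symmetrize_array(acc.denominator, group), 0.0),
                       acc.oversampling, acc.voxel_size)


def project_real_space(vol: RealVolume, orientation: Orientation, order: int = 3) -> RealImage:
    """High-accuracy real-space line-integral projection (inverse-crime control).

    Rotates the map with spline interpolation and integrates along the beam
    axis; used by the simulator's honest mode and by oracle tests.
    """
    a = rotation_matrix(*orientation.angles)
    c = np.array(vol.voxels.shape) // 2
    # voxel at output position p came from input position Aᵀ p (passive rotation
    # matching the Fourier-slice convention p3 = Aᵀ q).
    rotated = ndimage.affine_transform(vol.voxels, a.T, offset=c - a.T @ c,
                                       order=order, mode="constant", cval=0.0)
    img = RealImage(rotated.sum(axis=2), vol.voxel_size)
    if orientation.shift_x or orientation.shift_y:
        f = apply_shift(FourierImage(fftc(img.pixels), vol.voxel_size),
                        orientation.shift_x, orientation.shift_y)
        img = RealImage(ifftc(f.components).real, vol.voxel_size)
    return img
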