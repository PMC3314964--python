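"""Centered discrete Fourier grids shared by every other module.

Conventions (used everywhere in the package):

* Transforms are **unitary** (``norm="ortho"``), so Parseval's identity
  ``sum|x|² == sum|X|²`` holds with no extra factors and noise/signal power
  estimates are comparable across grid sizes.
* Grids are **centered**: the zero-frequency component sits at index
  ``n // 2`` along every axis (explicit fftshift).  All rotation/slice
  geometry is defined on the centered grid.
* Fourier volumes are stored on the **full complex grid** (no half-grid
  trick); Friedel symmetry ``F(-k) == conj(F(k))`` is an enforceable,
  checkable invariant rather than a storage convention.
* Frequency indexing is zero based; shells/rings have width one Fourier
  pixel at the original (un-oversampled) sampling rate, even on a grid that
  is oversampled by an integer factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RealImage",
    "FourierImage",
    "RealVolume",
    "FourierVolume",
    "ShellIndex",
    "fftc",
    "ifftc",
    "forward_transform",
    "inverse_transform",
    "shell_of",
    "enforce_friedel",
    "conjugate_reflect",
    "nyquist_mask",
]


def _check_square(a: np.ndarray, ndim: int, what: str) -> None:
    if a.ndim != ndim:
        raise ValueError(f"{what}: expected {ndim}-dimensional array, got {a.ndim}")
    if len(set(a.shape)) != 1:
        raise ValueError(f"{what}: expected equal sides, got shape {a.shape}")
    if a.shape[0] % 2 != 0:
        raise ValueError(f"{what}: side must be even, got {a.shape[0]}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{what}: non-finite values present")


@dataclass
class RealImage:
    """A square real-space particle image with its pixel size in Å/pixel."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        _check_square(self.pixels, 2, "RealImage")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class FourierImage:
    """Centered 2D Fourier transform of a particle image."""

    components: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.complex128)

    @property
    def size(self) -> int:
        return self.components.shape[0]


@dataclass
class RealVolume:
    """A cubic real-space density map with voxel size in Å/voxel."""

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        _check_square(self.voxels, 3, "RealVolume")

    @property
    def size(self) -> int:
        return self.voxels.shape[0]


@dataclass
class FourierVolume:
    """Centered 3D Fourier transform of a map, possibly on an oversampled grid.

    With ``oversampling == m``, the grid holds ``(m*D)³`` complex values and
    the stride-``m`` lattice points coincide with the Fourier components of
    the un-padded ``D³`` map (scale included, see :func:`oversampled_transform`).
    """

    components: np.ndarray
    voxel_size: float
    oversampling: int = 1

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.complex128)

    @property
    def size(self) -> int:
        """Grid side of the stored (possibly oversampled) transform."""
        return self.components.shape[0]

    @property
    def original_size(self) -> int:
        """Side of the un-oversampled map this transform represents."""
        return self.components.shape[0] // self.oversampling


@dataclass
class ShellIndex:
    """Per-component resolution shell (3D) / ring (2D) assignment.

    ``shell[idx] = round(|k| / oversampling)`` on the centered grid, so shell 0
    contains exactly the origin and shells have width one Fourier pixel at the
    un-oversampled rate.  Shells are computed for the *full* grid; downstream
    code masks to ``shell <= nyquist_shell`` where only physical frequencies
    are meaningful.
    """

    shell: np.ndarray
    oversampling: int
    shape: tuple
    n_shells: int = field(init=False)
    counts: np.ndarray = field(init=False)
    nyquist_shell: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_shells = int(self.shell.max()) + 1
        self.counts = np.bincount(self.shell.ravel(), minlength=self.n_shells)
        self.nyquist_shell = (self.shape[0] // self.oversampling) // 2

    def frequencies(self, pixel_size: float) -> np.ndarray:
        """Center frequency of each shell in Å⁻¹ (shell s → s / (D·pixel))."""
        d = self.shape[0] // self.oversampling
        return np.arange(self.n_shells) / (d * pixel_size)

    def shell_mean(self, values: np.ndarray) -> np.ndarray:
        """Mean of ``values`` over each shell (full-grid counts)."""
        sums = np.bincount(self.shell.ravel(), weights=np.asarray(values, dtype=np.float64).ravel(),
                           minlength=self.n_shells)
        return sums / self.counts

    def shell_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.shell.ravel(), weights=np.asarray(values, dtype=np.float64).ravel(),
                           minlength=self.n_shells)


def fftc(a: np.ndarray) -> np.ndarray:
    """Unitary centered forward FFT (any dimensionality)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a), norm="ortho"))


def ifftc(a: np.ndarray) -> np.ndarray:
    """Unitary centered inverse FFT."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a), norm="ortho"))


def forward_transform(x: RealImage | RealVolume) -> FourierImage | FourierVolume:
    if isinstance(x, RealImage):
        return FourierImage(fftc(x.pixels), x.pixel_size)
    if isinstance(x, RealVolume):
        return FourierVolume(fftc(x.voxels), x.voxel_size, oversampling=1)
    raise TypeError(f"forward_transform: unsupported input {type(x)!r}")


def inverse_transform(f: FourierImage | FourierVolume) -> RealImage | RealVolume:
    if isinstance(f, FourierImage):
        return RealImage(ifftc(f.components).real, f.pixel_size)
    if isinstance(f, FourierVolume):
        if f.oversampling != 1:
            raise ValueError("inverse_transform expects an un-oversampled transform; "
                             "use volume_from_fourier for oversampled model grids")
        return RealVolume(ifftc(f.components).real, f.voxel_size)
    raise TypeError(f"inverse_transform: unsupported input {type(f)!r}")


def _radius_grid(shape: tuple) -> np.ndarray:
    axes = [np.arange(n) - n // 2 for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(m.astype(np.float64) ** 2 for m in mesh))


def shell_of(grid_shape: tuple, oversampling: int = 1) -> ShellIndex:
    """Assign every component of a centered grid to a resolution shell/ring."""
    r = _radius_grid(tuple(grid_shape))
    shell = np.rint(r / oversampling).astype(np.int64)
    return ShellIndex(shell=shell, oversampling=oversampling, shape=tuple(grid_shape))


def nyquist_mask(grid_shape: tuple, oversampling: int = 1) -> np.ndarray:
    """Boolean mask of components at or below the un-oversampled Nyquist rate."""
    r = _radius_grid(tuple(grid_shape))
    d = grid_shape[0] // oversampling
    return r / oversampling <= d / 2


def conjugate_reflect(a: np.ndarray) -> np.ndarray:
    """conj(F(-k)) on a centered grid (index i → (n - i) mod n per axis)."""
    out = np.conj(np.flip(a))
    for ax in range(a.ndim):
        out = np.roll(out, 1, axis=ax)
    return out


def enforce_friedel(v: FourierVolume | FourierImage | np.ndarray):
    """Project onto the Friedel-symmetric subspace: (F(k) + conj(F(-k)))/2.

    Idempotent; leaves an already-Hermitian transform unchanged.
    """
    if isinstance(v, FourierVolume):
        return FourierVolume(enforce_friedel(v.components), v.voxel_size, v.oversampling)
    if isinstance(v, FourierImage):
        return FourierImage(enforce_friedel(v.components), v.pixel_size)
    return 0.5 * (v + conjugate_reflect(v))
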