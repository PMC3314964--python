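"""Ground-truth synthetic data: blob phantoms and CTF-corrupted noisy
projections with known orientations and classes.

The generator realizes the linear image formation model exactly: each
particle transform is CTF(ν) × (central slice of the 3D transform at the
true orientation) × (shift phase) + complex Gaussian noise whose variance
per real/imaginary component is σ²(ν) — the same convention the likelihood
and the noise update use, so recovery tests are self-consistent.

By default projections are generated through the same Fourier-slice operator
used in refinement; ``projection="real"`` instead integrates the rotated map
in real space with spline interpolation, exposing the nearest-neighbour
interpolation bias (inverse-crime control).

Scenario presets emulate three study regimes at desk scale: refinement of
very noisy data prone to overfitting, a typical-quality refinement, and
heterogeneous data with an equal split or a small minority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctf import CTFParams, ctf_image
from .fourier import RealVolume, fftc, shell_of
from .particles import ParticleSet
from .projector import (Orientation, extract_slice, image_grid,
                        oversampled_transform, project_real_space, shift_phase,
                        symmetrize_array)

__all__ = [
    "PhantomSpec",
    "SimConfig",
    "make_phantom",
    "simulate_particles",
    "scenario_preset",
    "expected_reconstruction_ssnr",
]


@dataclass
class PhantomSpec:
    """A sum-of-Gaussian-blobs phantom.

    ``blobs`` is a list of (center xyz in voxels relative to the box center,
    amplitude, width in voxels); if empty, ``n_random_blobs`` blobs are drawn
    inside 0.35×size of the center (deterministically from the seed).
    """

    size: int = 32
    voxel_size: float = 3.0
    blobs: list = field(default_factory=list)
    n_random_blobs: int = 12
    blob_width: tuple = (0.8, 1.8)       # voxels; sharp enough to carry power to mid shells
    blob_amplitude: tuple = (2.0, 5.0)   # sets the signal scale relative to unit-ish noise
    symmetry: str | None = None

    def __post_init__(self) -> None:
        if self.size % 2:
            raise ValueError("phantom size must be even")
        for center, _amp, width in self.blobs:
            if np.linalg.norm(center) + width > self.size / 2:
                raise ValueError(f"blob at {center} (width {width}) extends outside the box")


def make_phantom(spec: PhantomSpec, seed: int = 0) -> RealVolume:
    """Render the phantom map; deterministic given (spec, seed)."""
    blobs = list(spec.blobs)
    if not blobs:
        rng = np.random.default_rng(seed)
        for _ in range(spec.n_random_blobs):
            center = rng.uniform(-0.3 * spec.size, 0.3 * spec.size, size=3)
            amp = rng.uniform(*spec.blob_amplitude)
            width = rng.uniform(*spec.blob_width)
            blobs.append((center, amp, width))
    ax = np.arange(spec.size) - spec.size // 2
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((spec.size,) * 3)
    for center, amp, width in blobs:
        r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
        vol += amp * np.exp(-r2 / (2.0 * width ** 2))
    if spec.symmetry and spec.symmetry.upper() != "C1":
        vol = symmetrize_array(vol, spec.symmetry)
    return RealVolume(vol, spec.voxel_size)


@dataclass
class SimConfig:
    """Data-generation conditions (all latent variables are drawn from seed)."""

    n_particles: int = 200
    orientation_dist: str = "uniform"    # uniform | clustered
    shift_sigma: float = 0.0             # Gaussian σ of origin offsets, pixels
    defocus_range: tuple = (8000.0, 25000.0)
    voltage: float = 200.0
    spherical_aberration: float = 2.0
    amplitude_contrast: float = 0.1
    noise_sigma2: float | np.ndarray = 1.0   # per real/imag component; scalar or per-ring
    class_fractions: tuple = (1.0,)
    n_groups: int = 4
    seed: int = 0
    projection: str = "fourier"          # fourier | real (inverse-crime control)

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if abs(sum(self.class_fractions) - 1.0) > 1e-8:
            raise ValueError("class fractions must sum to 1")

    def sigma2_per_ring(self, size: int) -> np.ndarray:
        n_rings = size // 2 + 1
        s2 = np.asarray(self.noise_sigma2, dtype=np.float64)
        if s2.ndim == 0:
            return np.full(n_rings, float(s2))
        if s2.shape[0] != n_rings:
            raise ValueError(f"noise profile must have {n_rings} rings")
        return s2


def _draw_orientations(rng: np.random.Generator, n: int, dist: str) -> np.ndarray:
    rot = rng.uniform(0, 360, n)
    psi = rng.uniform(0, 360, n)
    if dist == "uniform":
        tilt = np.rad2deg(np.arccos(rng.uniform(-1, 1, n)))
    elif dist == "clustered":
        tilt = np.clip(rng.normal(60.0, 15.0, n), 0.0, 180.0)
    elif dist == "inplane":
        # 2D class-averaging scenario: a single view rotated in the plane
        return np.stack([np.zeros(n), np.zeros(n), psi], axis=1)
    else:
        raise ValueError(f"unknown orientation distribution {dist!r}")
    return np.stack([rot, tilt, psi], axis=1)


def simulate_particles(volumes: list, config: SimConfig) -> ParticleSet:
    """Generate a particle stack with full ground-truth metadata.

    ``volumes`` is one RealVolume per class on identical grids.  Returned
    metadata records every latent variable in ``true_*`` columns plus the
    generator seed.
    """
    sizes = {v.size for v in volumes}
    if len(sizes) != 1:
        raise ValueError("all class volumes must share one grid")
    d = volumes[0].size
    pixel = volumes[0].voxel_size
    rng = np.random.default_rng(config.seed)
    k_n = len(config.class_fractions)
    if k_n != len(volumes):
        raise ValueError("one volume per class fraction required")
    fvols = [oversampled_transform(v, 3) for v in volumes]
    classes = rng.choice(k_n, size=config.n_particles, p=np.asarray(config.class_fractions))
    angles = _draw_orientations(rng, config.n_particles, config.orientation_dist)
    if config.shift_sigma > 0:
        shifts = rng.normal(0.0, config.shift_sigma, size=(config.n_particles, 2))
    else:
        shifts = np.zeros((config.n_particles, 2))
    lo, hi = config.defocus_range
    group_defocus = rng.uniform(lo, hi, size=config.n_groups)
    group_index = np.arange(config.n_particles) % config.n_groups
    group_ctf = [CTFParams(defocus=df, voltage=config.voltage,
                           spherical_aberration=config.spherical_aberration,
                           amplitude_contrast=config.amplitude_contrast,
                           pixel_size=pixel) for df in group_defocus]
    s2_ring = config.sigma2_per_ring(d)
    rings_full = shell_of((d, d)).shell
    noise_amp = np.sqrt(2.0 * s2_ring[np.minimum(rings_full, d // 2)])
    four = np.empty((config.n_particles, d, d), dtype=np.complex128)
    hgrid = np.arange(d) - d // 2
    hh, kk = np.meshgrid(hgrid, hgrid, indexing="ij")
    for i in range(config.n_particles):
        ori = Orientation(rot=angles[i, 0], tilt=angles[i, 1], psi=angles[i, 2])
        if config.projection == "real":
            vol = volumes[classes[i]]
            proj = project_real_space(vol, ori)
            sl = fftc(proj.pixels) / np.sqrt(d)
        elif config.projection == "fourier":
            sl = extract_slice(fvols[classes[i]], ori).components
        else:
            raise ValueError(f"unknown projection mode {config.projection!r}")
        x = ctf_image(group_ctf[group_index[i]], (d, d)) * sl
        if shifts[i, 0] or shifts[i, 1]:
            x = x * np.exp(-2j * np.pi * (hh * shifts[i, 0] + kk * shifts[i, 1]) / d)
        if np.any(s2_ring > 0):
            noise = fftc(rng.normal(size=(d, d))) * noise_amp
            x = x + noise
        four[i] = x
    meta = pd.DataFrame({
        "particle": np.arange(config.n_particles),
        "group": group_index,
        "defocus": group_defocus[group_index],
        "true_class": classes,
        "true_rot": angles[:, 0],
        "true_tilt": angles[:, 1],
        "true_psi": angles[:, 2],
        "true_shift_x": shifts[:, 0],
        "true_shift_y": shifts[:, 1],
        "seed": config.seed,
    })
    return ParticleSet(four, pixel, group_index, group_ctf, meta)


# ---------------------------------------------------------------------------
# Scenario presets (the study conditions, fixed at desk scale)
# ---------------------------------------------------------------------------

def scenario_preset(name: str, seed: int = 0):
    """Fully specified desk-scale study conditions.

    Returns ``(phantom_specs, sim_config)``; render the phantoms with
    :func:`make_phantom` (class index added to the seed) and feed both to
    :func:`simulate_particles`.

    * ``low_snr_overfit``   — one structure, heavy white noise: the true
      data-side SSNR of a reconstruction falls below 1 beyond a low shell,
      the regime where unregularized refinement overfits.
    * ``typical_refine``    — one structure, moderate noise supporting
      refinement to intermediate shells.
    * ``hetero_equal``      — two structures at 50/50, moderate noise.
    * ``hetero_minority``   — three structures with a 6% minority class.
    """
    presets = {
        "low_snr_overfit": dict(k=1, n=240, sigma2=1.5),
        "typical_refine": dict(k=1, n=600, sigma2=0.6),
        "hetero_equal": dict(k=2, n=500, sigma2=0.35, fractions=(0.5, 0.5)),
        "hetero_minority": dict(k=3, n=1000, sigma2=0.35, fractions=(0.47, 0.47, 0.06)),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario preset {name!r} (choose from {sorted(presets)})")
    p = presets[name]
    if name == "hetero_minority":
        # complex-dissociation scenario: two distinct majority conformations
        # of the full complex and a minority state that is a dissociated
        # subcomplex (fewer blobs, lower total scattering mass) — the kind of
        # compositional heterogeneity where a small class is detectable
        specs = [PhantomSpec(size=32, voxel_size=3.0, n_random_blobs=12),
                 PhantomSpec(size=32, voxel_size=3.0, n_random_blobs=12),
                 PhantomSpec(size=32, voxel_size=3.0, n_random_blobs=5)]
    else:
        specs = [PhantomSpec(size=32, voxel_size=3.0) for _ in range(p["k"])]
    # a wide defocus spread over several groups keeps the joint CTF² coverage
    # free of shared zeros in the informative shells
    config = SimConfig(
        n_particles=p["n"],
        noise_sigma2=p["sigma2"],
        class_fractions=p.get("fractions", (1.0,)),
        defocus_range=(5000.0, 30000.0),
        n_groups=8,
        shift_sigma=0.0,
        seed=seed,
    )
    return specs, config


def expected_reconstruction_ssnr(volumes: list, config: SimConfig,
                                 half: bool = False) -> np.ndarray:
    """True per-shell SSNR a reconstruction from this data set would have.

    Computed from the configured spectra: per shell s,
    SSNR(s) = τ²_true(s) × N·(2D ring count)·⟨CTF²⟩(s) / (σ²(s) × 3D shell
    voxel count on the oversampled grid) — the expected accumulated CTF²/σ²
    per voxel times the true signal power.  ``half=True`` uses N/2.
    """
    d = volumes[0].size
    n = config.n_particles // 2 if half else config.n_particles
    f = fftc(np.mean([v.voxels for v in volumes], axis=0))
    sh = shell_of(f.shape)
    nshell = sh.nyquist_shell + 1
    tau2 = 0.5 * sh.shell_mean(np.abs(f) ** 2)[:nshell]
    g = image_grid(d)
    ring_counts = np.bincount(g.ring, minlength=nshell)[:nshell].astype(float)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.defocus_range
    group_defocus = rng.uniform(lo, hi, size=config.n_groups)
    ctf2 = np.zeros(nshell)
    for df in group_defocus:
        params = CTFParams(defocus=df, voltage=config.voltage,
                           spherical_aberration=config.spherical_aberration,
                           amplitude_contrast=config.amplitude_contrast,
                           pixel_size=volumes[0].voxel_size)
        c = ctf_image(params, (d, d)).ravel()[g.flat_index]
        ctf2 += np.bincount(g.ring, weights=c * c, minlength=nshell)[:nshell] / ring_counts
    ctf2 /= config.n_groups
    sh3 = shell_of((3 * d,) * 3, oversampling=3)
    from .fourier import nyquist_mask
    nyq = nyquist_mask((3 * d,) * 3, 3)
    vox_counts = np.bincount(sh3.shell[nyq].ravel(), minlength=nshell)[:nshell].astype(float)
    s2 = config.sigma2_per_ring(d)[:nshell]
    with np.errstate(divide="ignore", invalid="ignore"):
        ssnr = tau2 * n * ring_counts * ctf2 / (s2 * vox_counts)
    ssnr[~np.isfinite(ssnr)] = np.inf
    return ssnr
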