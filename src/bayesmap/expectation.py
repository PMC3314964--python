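"""The expectation step: Gaussian likelihoods over the orientation grid,
posterior weights Γ and the marginal log-likelihood.

The noise is modelled as independent zero-mean complex Gaussian per Fourier
component, with variance σ² *per real/imaginary part* (so E|N|² = 2σ²), σ²
shared within a resolution ring and a micrograph group.  The likelihood of
an image given an orientation φ and class k is a product of such Gaussians
over all components inside the Nyquist disc (full-grid convention: both
members of a Friedel pair are counted).  Posterior weights over the discrete
(class, orientation) grid are computed with max-subtracted exponentiation,
since the raw products underflow double precision for realistic component
counts.

Origin shifts are handled by phase ramps applied to the conjugated image
term, mathematically identical to shifting the reference slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import FourierImage, FourierVolume
from .particles import ParticleSet
from .projector import (Orientation, OrientationGrid, extract_slice, image_grid,
                        shift_phase, slice_map)

__all__ = [
    "NoiseModel",
    "ModelState",
    "PosteriorWeights",
    "squared_residual",
    "log_likelihood",
    "posterior_weights",
    "dataset_expectation",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class NoiseModel:
    """Per-group, per-ring noise power σ² (variance per real/imag component)."""

    sigma2: np.ndarray          # (n_groups, n_rings)
    group_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigma2 = np.atleast_2d(np.asarray(self.sigma2, dtype=np.float64))
        if np.any(self.sigma2 <= 0):
            raise ValueError("NoiseModel requires strictly positive sigma2 on all rings")

    @property
    def n_groups(self) -> int:
        return self.sigma2.shape[0]

    def per_component(self, group: int, size: int) -> np.ndarray:
        """σ² looked up per masked image-grid component of the given group."""
        return self.sigma2[group][image_grid(size).ring]

    @classmethod
    def from_images(cls, particles: ParticleSet) -> "NoiseModel":
        """Initial estimate: half the mean per-ring image power per group.

        Includes the signal power, so it over-estimates the noise at low
        frequency; the Eq.-10-style update corrects this within a few
        iterations.
        """
        g = image_grid(particles.size)
        counts = np.bincount(g.ring, minlength=g.n_rings).astype(float)
        sig = np.zeros((particles.n_groups, g.n_rings))
        for gi in range(particles.n_groups):
            idx = np.flatnonzero(particles.group_index == gi)
            if idx.size == 0:
                raise ValueError(f"group {gi} has no particles")
            power = np.abs(particles.fourier[idx][:, g.mask]) ** 2
            sig[gi] = 0.5 * np.bincount(
                np.tile(g.ring, idx.size), weights=power.ravel(),
                minlength=g.n_rings) / (counts * idx.size)
        return cls(np.maximum(sig, 1e-30), list(particles.group_names))


@dataclass
class ModelState:
    """Everything the EM updates read and write: K model transforms, the
    per-shell signal power τ² (raw, i.e. before the T multiplication), the
    noise model, and the class fractions."""

    volumes: list                      # K FourierVolume (3D) or FourierImage (2D refs)
    tau2: np.ndarray                   # (K, n_shells) raw per-shell signal power
    noise: NoiseModel
    class_fraction: np.ndarray         # (K,)
    T: float = 4.0
    iteration: int = 0

    def __post_init__(self) -> None:
        self.tau2 = np.atleast_2d(np.asarray(self.tau2, dtype=np.float64))
        self.class_fraction = np.asarray(self.class_fraction, dtype=np.float64)
        if self.tau2.shape[0] != len(self.volumes):
            raise ValueError("tau2 must have one row per class")
        if abs(self.class_fraction.sum() - 1.0) > 1e-8:
            raise ValueError("class fractions must sum to 1")
        if np.any(self.tau2 < 0):
            raise ValueError("tau2 must be >= 0")

    @property
    def n_classes(self) -> int:
        return len(self.volumes)


@dataclass
class PosteriorWeights:
    """Γ: per-particle posterior over (class, rotation, shift), normalized to 1,
    together with the per-particle marginal log-likelihood."""

    gamma: np.ndarray          # (N, K, R, S)
    log_marginal: np.ndarray   # (N,)
    grid: OrientationGrid | None = None

    @property
    def n_particles(self) -> int:
        return self.gamma.shape[0]

    @property
    def total_log_likelihood(self) -> float:
        return float(self.log_marginal.sum())

    def class_mass(self) -> np.ndarray:
        """(N, K) posterior mass per class."""
        return self.gamma.sum(axis=(2, 3))

    def map_assignment(self, i: int) -> tuple:
        """(class, rotation index, shift index) of the Γ maximum for particle i."""
        return np.unravel_index(int(np.argmax(self.gamma[i])), self.gamma.shape[1:])

    def entropy(self) -> np.ndarray:
        g = self.gamma.reshape(self.n_particles, -1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(g > 0, g * np.log(g), 0.0)
        return -t.sum(axis=1)


# ---------------------------------------------------------------------------
# Scalar reference operations (also the oracles the vectorized engine must match)
# ---------------------------------------------------------------------------

def _shift_of(shift) -> tuple:
    if shift is None:
        return (0.0, 0.0)
    if isinstance(shift, Orientation):
        return (shift.shift_x, shift.shift_y)
    return (float(shift[0]), float(shift[1]))


def squared_residual(image: FourierImage, ctf: np.ndarray, slice_: FourierImage,
                     shift=None) -> np.ndarray:
    """Elementwise |X - CTF·(shifted reference slice)|² over the full grid."""
    if image.components.shape != slice_.components.shape or ctf.shape != image.components.shape:
        raise ValueError("squared_residual: grids do not match")
    sx, sy = _shift_of(shift)
    ref = slice_.components
    if sx or sy:
        d = image.size
        h = np.arange(d) - d // 2
        hh, kk = np.meshgrid(h, h, indexing="ij")
        ref = ref * np.exp(-2j * np.pi * (hh * sx + kk * sy) / d)
    return np.abs(image.components - ctf * ref) ** 2


def log_likelihood(image: FourierImage, ctf: np.ndarray, slice_: FourierImage,
                   shift=None, noise: NoiseModel | None = None, group: int = 0,
                   sigma2=None) -> float:
    """Eq.-6-style Gaussian log-likelihood summed over the Nyquist-disc components.

    ``sigma2`` may be given directly (scalar or per-component over the masked
    grid); otherwise it is looked up per ring from ``noise``/``group``.
    """
    g = image_grid(image.size)
    if sigma2 is None:
        if noise is None:
            raise ValueError("provide either a NoiseModel or sigma2")
        s2 = noise.per_component(group, image.size)
    else:
        s2 = np.broadcast_to(np.asarray(sigma2, dtype=np.float64), g.ring.shape)
    if np.any(s2 <= 0):
        raise ValueError("sigma2 must be strictly positive")
    res = squared_residual(image, ctf, slice_, shift).ravel()[g.flat_index]
    return float(np.sum(-_LOG2PI - np.log(s2) - res / (2.0 * s2)))


# ---------------------------------------------------------------------------
# Vectorized engine
# ---------------------------------------------------------------------------

def reference_slices(model_volumes: list, grid: OrientationGrid, image_size: int) -> np.ndarray:
    """(K, R, J) reference slices over the masked image grid for all rotations."""
    g = image_grid(image_size)
    k_n = len(model_volumes)
    out = np.empty((k_n, grid.n_rotations, g.n_components), dtype=np.complex128)
    for ki, vol in enumerate(model_volumes):
        comps = vol.components.ravel()
        m = vol.oversampling if isinstance(vol, FourierVolume) else getattr(vol, "oversampling", 1)
        ndim = 3 if isinstance(vol, FourierVolume) else 2
        for ri, ang in enumerate(grid.angles):
            valid, flat = slice_map(tuple(ang), image_size, vol.components.shape[0], m, ndim)
            row = np.zeros(g.n_components, dtype=np.complex128)
            row[valid] = comps[flat]
            out[ki, ri] = row
    return out


def _shift_phases(grid: OrientationGrid, image_size: int) -> np.ndarray:
    """(S, J) phase ramps of the grid shifts over the masked image grid."""
    return np.stack([shift_phase(image_size, sx, sy) for sx, sy in grid.shifts])


def loglik_table(x: np.ndarray, ctf_m: np.ndarray, w: np.ndarray,
                 slices: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Gaussian log-likelihood for a batch of images against all references.

    x: (B, J) masked image transforms; ctf_m: (J,); w = 1/(2σ²) per component;
    slices: (K, R, J); phases: (S, J).  Returns (B, K, R, S) *without* the
    σ²-normalization constant (add it separately, it is shared per group).
    """
    b, j = x.shape
    k_n, r_n, _ = slices.shape
    s_n = phases.shape[0]
    flat = slices.reshape(k_n * r_n, j)
    a_term = (np.abs(x) ** 2) @ w                               # (B,)
    c_term = (np.abs(flat) ** 2) @ (ctf_m * ctf_m * w)          # (KR,)
    out = np.empty((b, k_n * r_n, s_n))
    cw = ctf_m * w
    xc = np.conj(x)
    for si in range(s_n):
        # hypothesis: X = φ_s·CTF·S, so the cross term is Re⟨X, φ_s CTF S⟩
        z = xc * (phases[si] * cw)                              # (B, J)
        cross = (z @ flat.T).real                               # (B, KR)
        out[:, :, si] = 2.0 * cross - c_term[None, :]
    out -= a_term[:, None, None]
    return out.reshape(b, k_n, r_n, s_n)


def dataset_expectation(particles: ParticleSet, model: ModelState,
                        grid: OrientationGrid, batch_size: int = 128,
                        slices: np.ndarray | None = None) -> PosteriorWeights:
    """Run the E-step over the whole data set.

    Returns Γ for every particle plus per-particle marginal log-likelihoods
    (their sum is the Eq.-7 total).  ``slices`` may be passed in to reuse
    precomputed reference slices across E/M steps of one iteration.
    """
    if particles.n_particles < 1:
        raise ValueError("dataset_expectation needs at least one particle")
    d = particles.size
    g = image_grid(d)
    if slices is None:
        slices = reference_slices(model.volumes, grid, d)
    phases = _shift_phases(grid, d)
    log_prior = (np.log(model.class_fraction)[:, None, None]
                 + np.log(grid.rot_prior)[None, :, None]
                 + np.log(grid.shift_prior)[None, None, :])
    n = particles.n_particles
    gamma = np.empty((n, model.n_classes, grid.n_rotations, grid.n_shifts))
    log_marginal = np.empty(n)
    for gi in range(particles.n_groups):
        idx = np.flatnonzero(particles.group_index == gi)
        if idx.size == 0:
            continue
        ctf_m = particles.ctf(gi).ravel()[g.flat_index]
        s2 = model.noise.per_component(gi, d)
        w = 1.0 / (2.0 * s2)
        const = float(np.sum(-_LOG2PI - np.log(s2)))
        for lo in range(0, idx.size, batch_size):
            sel = idx[lo:lo + batch_size]
            x = particles.fourier[sel][:, g.mask]
            ll = loglik_table(x, ctf_m, w, slices, phases)
            lp = ll + log_prior[None]
            flat = lp.reshape(sel.size, -1)
            mx = flat.max(axis=1)
            if not np.all(np.isfinite(mx)):
                bad = sel[~np.isfinite(mx)]
                raise FloatingPointError(
                    f"all-(-inf) log-likelihoods for particle(s) {bad.tolist()}")
            p = np.exp(flat - mx[:, None])
            z = p.sum(axis=1)
            gamma[sel] = (p / z[:, None]).reshape(lp.shape)
            log_marginal[sel] = const + mx + np.log(z)
    return PosteriorWeights(gamma=gamma, log_marginal=log_marginal, grid=grid)


def posterior_weights(image: FourierImage, model: ModelState, grid: OrientationGrid,
                      ctf: np.ndarray | None = None, group: int = 0) -> PosteriorWeights:
    """E-step for a single particle (Eq.-12 weights + marginal log-likelihood)."""
    if len(grid) == 0:
        raise ValueError("empty orientation grid")
    from .ctf import CTFParams  # local import to avoid cycle at module load
    d = image.size
    if ctf is None:
        ctf = np.ones((d, d))
    g = image_grid(d)
    slices = reference_slices(model.volumes, grid, d)
    phases = _shift_phases(grid, d)
    s2 = model.noise.per_component(group, d)
    w = 1.0 / (2.0 * s2)
    const = float(np.sum(-_LOG2PI - np.log(s2)))
    x = image.components.ravel()[None, g.flat_index]
    ll = loglik_table(x, ctf.ravel()[g.flat_index], w, slices, phases)
    lp = ll[0] + (np.log(model.class_fraction)[:, None, None]
                  + np.log(grid.rot_prior)[None, :, None]
                  + np.log(grid.shift_prior)[None, None, :])
    mx = lp.max()
    if not np.isfinite(mx):
        raise FloatingPointError("all-(-inf) log-likelihoods for particle")
    p = np.exp(lp - mx)
    z = p.sum()
    return PosteriorWeights(gamma=(p / z)[None], log_marginal=np.array([const + mx + np.log(z)]),
                            grid=grid)
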