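"""The maximization step: regularized reconstruction of each class, noise and
signal power updates, and class fractions.

The reconstruction update divides, per voxel of the oversampled model grid,
the Γ-weighted data sum by the Γ-weighted CTF²/σ² sum plus the prior term
1/(T·τ²) of the voxel's shell.  τ² is the raw per-shell signal power
(half the mean squared modulus); the heuristic constant T (default 4)
compensates the under-estimation of signal power caused by assuming
independent Fourier components, and multiplies τ² wherever it enters the
reconstruction denominator or the SNR.  Values of T much larger than 4 risk
overfitting and trigger a warning.

Nearest-neighbour gridding leaves some oversampled voxels unsampled; an
iterative normalized-convolution fill (the "iterative gridding" correction)
interpolates those from their sampled neighbours with the NN sampling
footprint, inside the Nyquist sphere only.  Per-voxel division by the
accumulated weights already compensates the sampling density exactly at the
sampled voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .expectation import ModelState, NoiseModel, PosteriorWeights, reference_slices, _shift_phases
from .fourier import FourierImage, FourierVolume, ShellIndex, enforce_friedel, shell_of, nyquist_mask
from .particles import ParticleSet
from .projector import Accumulator, OrientationGrid, image_grid, slice_map

__all__ = [
    "SignalPrior",
    "accumulate_mstep",
    "solve_map",
    "update_noise",
    "update_signal",
    "update_class_fractions",
    "fill_unsampled",
]


@dataclass
class SignalPrior:
    """Raw per-shell signal power τ² and the regularization constant T."""

    tau2: np.ndarray
    T: float = 4.0

    def __post_init__(self) -> None:
        self.tau2 = np.asarray(self.tau2, dtype=np.float64)
        if np.any(self.tau2 < 0):
            raise ValueError("tau2 must be >= 0")
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.T > 4:
            warnings.warn(f"T = {self.T} > 4: values much larger than 4 risk overfitting",
                          stacklevel=2)

    @property
    def effective_tau2(self) -> np.ndarray:
        """T-scaled τ², the value entering the reconstruction and the SNR."""
        return self.T * self.tau2


def accumulate_mstep(particles: ParticleSet, weights: PosteriorWeights,
                     model: ModelState, grid: OrientationGrid,
                     slices: np.ndarray | None = None,
                     prune: float = 1e-8, batch_size: int = 128):
    """Γ-weighted back-projection sums and residual sums for the updates.

    Returns ``(accumulators, residual_sums, residual_counts)`` where
    ``accumulators`` is one :class:`Accumulator` per class on the oversampled
    grid, and ``residual_sums``/``residual_counts`` are (n_groups, n_rings)
    arrays feeding the noise update (counts are the number of Γ-weighted
    component observations per ring: n_particles_in_group × ring size).

    Rotations whose total Γ mass across the data set falls below ``prune``
    are skipped during scattering (cost control; the dropped mass is
    negligible by construction).
    """
    d = particles.size
    g = image_grid(d)
    vol0 = model.volumes[0]
    is3d = isinstance(vol0, FourierVolume)
    m = vol0.oversampling if is3d else getattr(vol0, "oversampling", 1)
    ndim = 3 if is3d else 2
    pixel = vol0.voxel_size if is3d else vol0.pixel_size
    if slices is None:
        slices = reference_slices(model.volumes, grid, d)
    phases = _shift_phases(grid, d)
    k_n, r_n = model.n_classes, grid.n_rotations
    s_n = grid.n_shifts
    num_slices = np.zeros((k_n, r_n, g.n_components), dtype=np.complex128)
    den_slices = np.zeros((k_n, r_n, g.n_components), dtype=np.float64)
    residual_sums = np.zeros((particles.n_groups, g.n_rings))
    residual_counts = np.zeros((particles.n_groups, g.n_rings))
    ring_counts = np.bincount(g.ring, minlength=g.n_rings).astype(float)
    for gi in range(particles.n_groups):
        idx = np.flatnonzero(particles.group_index == gi)
        if idx.size == 0:
            continue
        ctf_m = particles.ctf(gi).ravel()[g.flat_index]
        s2 = model.noise.per_component(gi, d)
        w2 = 1.0 / s2
        c2w = ctf_m * ctf_m * w2
        res_j = np.zeros(g.n_components)
        for lo in range(0, idx.size, batch_size):
            sel = idx[lo:lo + batch_size]
            x = particles.fourier[sel][:, g.mask]
            y = x * (ctf_m * w2)[None, :]
            gam = weights.gamma[sel]                         # (B, K, R, S)
            res_j += (np.abs(x) ** 2).sum(axis=0)            # E1 (Γ sums to 1)
            for ki in range(k_n):
                gk = gam[:, ki]                              # (B, R, S)
                rot_mass = gk.sum(axis=(0, 2))               # (R,)
                den_slices[ki] += np.outer(rot_mass, c2w)
                e3 = rot_mass @ (np.abs(slices[ki]) ** 2)    # (J,)
                res_j += (ctf_m * ctf_m) * e3                # CTF²·Σ Γ|S|²
                for si in range(s_n):
                    gs = gk[:, :, si]                        # (B, R)
                    cross = gs.T @ y                         # (R, J) Γ-weighted data
                    num_slices[ki] += np.conj(phases[si])[None, :] * cross
                    pred = gs @ slices[ki]                   # (B, J) Σ_r Γ S
                    e2 = (np.conj(x) * phases[si] * ctf_m * pred).real.sum(axis=0)
                    res_j -= 2.0 * e2
        residual_sums[gi] = np.bincount(g.ring, weights=res_j, minlength=g.n_rings)
        residual_counts[gi] = idx.size * ring_counts
    accs = []
    total_mass = weights.gamma.sum(axis=(0, 3))              # (K, R)
    for ki in range(k_n):
        acc = Accumulator.zeros(d, m, pixel, model_ndim=ndim)
        for ri in range(r_n):
            if total_mass[ki, ri] <= prune:
                continue
            acc.add_slice_values(tuple(grid.angles[ri]), num_slices[ki, ri],
                                 den_slices[ki, ri])
        accs.append(acc)
    return accs, residual_sums, residual_counts


def fill_unsampled(values: np.ndarray, hit: np.ndarray, within: np.ndarray,
                   width: int = 3, max_iter: int = 10, tol: float = 1e-4) -> np.ndarray:
    """Iterative normalized-convolution interpolation of unsampled voxels.

    Each pass replaces still-unfilled voxels inside ``within`` by the mean of
    their already-filled neighbours under a box footprint of the given width
    (the NN sampling footprint, i.e. the oversampling factor).  Stops when no
    voxel changes by more than ``tol`` relative (i.e. no new fills) or after
    ``max_iter`` passes; voxels never reached (genuinely unmeasured regions)
    stay zero.
    """
    out = values.copy()
    filled = hit.copy()
    scale = float(width ** values.ndim)
    for _ in range(max_iter):
        todo = within & ~filled
        if not np.any(todo):
            break
        wsum = ndimage.uniform_filter(filled.astype(np.float64), size=width) * scale
        vr = ndimage.uniform_filter(np.where(filled, out.real, 0.0), size=width) * scale
        vi = ndimage.uniform_filter(np.where(filled, out.imag, 0.0), size=width) * scale
        # counts are integers in exact arithmetic; > 0.5 guards against the
        # separable filter's floating-point dust posing as a neighbour
        new = todo & (wsum > 0.5)
        if not np.any(new):
            break
        out[new] = (vr[new] + 1j * vi[new]) / wsum[new]
        filled = filled | new
    return out


def solve_map(acc: Accumulator, prior: SignalPrior, shells: ShellIndex | None = None,
              gridding_iters: int = 10, eps: float = 1e-300,
              on_empty: str = "zero"):
    """Solve the regularized reconstruction from the accumulated sums.

    Per voxel: V = numerator / (denominator + 1/(T·τ²(shell))).  Shells with
    τ² = 0 are fully damped to zero (the prior dominates); with τ² = ∞ the
    update reduces to the unregularized direct-Fourier ratio, in which case
    voxels with zero denominator are set to 0 (``on_empty="zero"``) or, if
    ``on_empty="raise"``, a singularity error names the affected shells.
    Friedel symmetry is enforced on the result.
    """
    nd = acc.model_ndim
    if shells is None:
        shells = shell_of(acc.numerator.shape, acc.oversampling)
    tau2_eff = prior.effective_tau2
    shell_idx = np.minimum(shells.shell, len(tau2_eff) - 1)
    with np.errstate(divide="ignore", over="ignore"):
        reg = np.where(tau2_eff > 0, 1.0 / np.where(tau2_eff > 0, tau2_eff, 1.0), np.inf)
    reg_vox = reg[shell_idx]
    reg_vox = np.where(shells.shell >= len(tau2_eff), np.inf, reg_vox)
    nyq = nyquist_mask(acc.numerator.shape, acc.oversampling)
    denom = acc.denominator + np.where(np.isinf(reg_vox), 0.0, reg_vox)
    ok = nyq & np.isfinite(reg_vox) & (denom > eps)
    unconstrained = nyq & (acc.denominator <= 0) & (reg_vox == 0)
    if on_empty == "raise" and np.any(unconstrained):
        bad = np.unique(shells.shell[unconstrained])
        raise ZeroDivisionError(
            f"unconstrained voxels (zero denominator, infinite tau2) on shells {bad.tolist()}")
    v = np.zeros_like(acc.numerator)
    v[ok] = acc.numerator[ok] / denom[ok]
    if gridding_iters > 0:
        hit = (acc.denominator > 0) & ok
        v = fill_unsampled(v, hit, nyq & np.isfinite(reg_vox),
                           width=acc.oversampling, max_iter=gridding_iters)
    v = enforce_friedel(v)
    if nd == 3:
        return FourierVolume(v, acc.voxel_size, acc.oversampling)
    out = FourierImage(v, acc.voxel_size)
    out.oversampling = acc.oversampling
    return out


def update_noise(residual_sums: np.ndarray, counts: np.ndarray,
                 floor: float = 1e-30, group_names: list | None = None) -> NoiseModel:
    """Per-(group, ring) noise power: σ² = Γ-weighted residual / (2 × count).

    The ½ converts squared complex residual to variance per real/imaginary
    component.  A strictly positive floor guards against noiseless synthetic
    data (callers typically pass 1e-12 × the mean image power).
    """
    residual_sums = np.atleast_2d(residual_sums)
    counts = np.atleast_2d(counts)
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("a group has no component observations")
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(counts > 0, residual_sums / (2.0 * counts), floor)
    return NoiseModel(np.maximum(s2, floor), group_names or [])


def update_signal(volume: FourierVolume | FourierImage, shells: ShellIndex | None = None,
                  T: float = 4.0) -> SignalPrior:
    """Per-shell raw signal power: τ²(s) = ½ · mean |V_l|² over shell s.

    The mean runs over the full shell population of the (oversampled) grid,
    zeros included; only shells up to Nyquist are retained.
    """
    comps = volume.components
    m = volume.oversampling if isinstance(volume, FourierVolume) else getattr(volume, "oversampling", 1)
    if shells is None:
        shells = shell_of(comps.shape, m)
    power = shells.shell_mean(np.abs(comps) ** 2)
    return SignalPrior(tau2=0.5 * power[: shells.nyquist_shell + 1], T=T)


def update_class_fractions(weights: PosteriorWeights) -> np.ndarray:
    """Mean over particles of the Γ mass per class (sums to 1)."""
    return weights.class_mass().mean(axis=0)
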