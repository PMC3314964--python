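"""The conventional comparator: hard-assignment projection matching with
direct Fourier inversion, 2D Wiener averaging, and Wiener-constant 3D
reconstruction.

The goodness-of-fit for hard assignment is the same Gaussian residual used
by the probabilistic branch (maximum-likelihood hard assignment), so the two
approaches differ only in marginalization vs. argmax and in regularization.
No low-pass filter is applied between iterations by default — this is the
deliberately non-expert conventional protocol whose overfitting behaviour
the statistical approach is compared against; an optional cosine-edge
low-pass flag exists for experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expectation import NoiseModel, _shift_phases, loglik_table
from .fourier import FourierImage, FourierVolume, fftc, nyquist_mask, shell_of
from .maximization import SignalPrior, solve_map
from .particles import ParticleSet
from .projector import (Accumulator, Orientation, OrientationGrid, image_grid,
                        insert_slice, symmetrize_accumulator)

__all__ = [
    "WienerConfig",
    "best_orientation",
    "assign_orientations",
    "direct_fourier_reconstruct",
    "wiener_average_2d",
    "wiener_constant_reconstruct",
    "projection_matching_refine",
    "half_split_maps",
]


@dataclass
class WienerConfig:
    """Wiener-constant configuration: SNR assumed equal to 1/C everywhere."""

    C: float = 1.0
    snr_profile: np.ndarray | None = None  # optional per-ring τ²/σ² curve

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("Wiener constant C must be > 0")


def _slices_for(volume, grid: OrientationGrid, image_size: int) -> np.ndarray:
    from .expectation import reference_slices
    return reference_slices([volume], grid, image_size)


def assign_orientations(particles: ParticleSet, volume, grid: OrientationGrid,
                        noise: NoiseModel | None = None,
                        batch_size: int = 128) -> list:
    """Hard assignment: the grid orientation maximizing the Gaussian
    log-likelihood for each particle (ties broken by lowest grid index)."""
    d = particles.size
    g = image_grid(d)
    slices = _slices_for(volume, grid, d)
    phases = _shift_phases(grid, d)
    out = [None] * particles.n_particles
    for gi in range(particles.n_groups):
        idx = np.flatnonzero(particles.group_index == gi)
        if idx.size == 0:
            continue
        ctf_m = particles.ctf(gi).ravel()[g.flat_index]
        if noise is None:
            w = np.full(g.n_components, 0.5)
        else:
            w = 1.0 / (2.0 * noise.per_component(gi, d))
        for lo in range(0, idx.size, batch_size):
            sel = idx[lo:lo + batch_size]
            x = particles.fourier[sel][:, g.mask]
            ll = loglik_table(x, ctf_m, w, slices, phases)[:, 0]  # (B, R, S)
            flat = ll.reshape(sel.size, -1)
            best = np.argmax(flat, axis=1)  # first max = lowest grid index
            for b, i in enumerate(sel):
                out[i] = grid.orientation(int(best[b]))
    return out


def best_orientation(image: FourierImage, volume, grid: OrientationGrid,
                     ctf: np.ndarray | None = None,
                     noise: NoiseModel | None = None) -> Orientation:
    """Single-image hard assignment (see :func:`assign_orientations`)."""
    if len(grid) == 0:
        raise ValueError("empty orientation grid")
    d = image.size
    from .ctf import CTFParams
    params = CTFParams(defocus=0.0, amplitude_contrast=1.0, pixel_size=image.pixel_size)
    ps = ParticleSet(image.components[None], image.pixel_size, np.zeros(1, dtype=int),
                     [params], group_ctf_images=[np.ones((d, d)) if ctf is None else ctf])
    return assign_orientations(ps, volume, grid, noise)[0]


def _accumulate_assigned(particles: ParticleSet, assignments: list,
                         oversampling: int, model_ndim: int = 3) -> Accumulator:
    acc = Accumulator.zeros(particles.size, oversampling, particles.pixel_size,
                            model_ndim=model_ndim)
    for i in range(particles.n_particles):
        gi = int(particles.group_index[i])
        insert_slice(FourierImage(particles.fourier[i], particles.pixel_size),
                     particles.ctf(gi), 1.0, 1.0, assignments[i], acc)
    return acc


def direct_fourier_reconstruct(particles: ParticleSet, assignments: list,
                               oversampling: int = 3, symmetry: str = "C1",
                               gridding_iters: int = 10, model_ndim: int = 3):
    """Unregularized direct Fourier inversion from hard assignments.

    Returns ``(volume, n_empty)`` where ``n_empty`` counts in-Nyquist voxels
    with zero accumulated weight (set to 0 in the output).
    """
    if len(assignments) != particles.n_particles:
        raise ValueError("one orientation required per particle")
    acc = _accumulate_assigned(particles, assignments, oversampling, model_ndim)
    acc = symmetrize_accumulator(acc, symmetry)
    n_empty = int(np.sum((acc.denominator <= 0)
                         & nyquist_mask(acc.denominator.shape, oversampling)))
    prior = SignalPrior(tau2=np.full(particles.size // 2 + 1, np.inf), T=1.0)
    vol = solve_map(acc, prior, gridding_iters=gridding_iters)
    return vol, n_empty


def wiener_constant_reconstruct(particles: ParticleSet, assignments: list,
                                C: float, oversampling: int = 3,
                                symmetry: str = "C1", gridding_iters: int = 10):
    """Direct Fourier inversion with the constant C added to the denominator
    (constant-SNR Wiener filtering)."""
    if C <= 0:
        raise ValueError("Wiener constant C must be > 0")
    acc = _accumulate_assigned(particles, assignments, oversampling)
    acc = symmetrize_accumulator(acc, symmetry)
    prior = SignalPrior(tau2=np.full(particles.size // 2 + 1, 1.0 / C), T=1.0)
    return solve_map(acc, prior, gridding_iters=gridding_iters)


def wiener_average_2d(images: list, ctfs: list, snr) -> FourierImage:
    """Wiener-filtered 2D average of an aligned image group.

    ``snr`` may be a scalar, a per-ring curve, or a full per-component array
    of the assumed signal-to-noise ratio τ²/σ².  Componentwise:
    A = Σ SNR·CTF·X / (Σ SNR·CTF² + 1).
    """
    if not images:
        raise ValueError("empty image group")
    d = images[0].size
    snr_arr = np.asarray(snr, dtype=np.float64)
    if snr_arr.ndim == 1:  # per-ring curve
        g = image_grid(d)
        full = np.zeros((d, d))
        full.ravel()[g.flat_index] = snr_arr[g.ring]
        snr_arr = full
    num = np.zeros((d, d), dtype=np.complex128)
    den = np.zeros((d, d))
    for im, c in zip(images, ctfs):
        num += snr_arr * c * im.components
        den += snr_arr * c * c
    return FourierImage(num / (den + 1.0), images[0].pixel_size)


def cosine_lowpass(volume: FourierVolume, shell_cut: float, width: float = 2.0) -> FourierVolume:
    """Cosine-edged low-pass: unity below ``shell_cut - width``, zero above
    ``shell_cut`` (shells at the un-oversampled rate)."""
    from .fourier import shell_of
    sh = shell_of(volume.components.shape, volume.oversampling)
    t = np.clip((shell_cut - sh.shell) / max(width, 1e-9), 0.0, 1.0)
    filt = 0.5 * (1.0 - np.cos(np.pi * t))
    return FourierVolume(volume.components * filt, volume.voxel_size, volume.oversampling)


def projection_matching_refine(particles: ParticleSet, initial: FourierVolume,
                               grid: OrientationGrid, n_iterations: int = 5,
                               wiener: WienerConfig | None = None,
                               lowpass_shell: float | None = None,
                               symmetry: str = "C1", noise: NoiseModel | None = None,
                               gridding_iters: int = 10):
    """Conventional iterative refinement: assign best orientations, rebuild by
    direct Fourier inversion (optionally with a Wiener constant), repeat.

    ``lowpass_shell`` applies the optional ad hoc cosine-edge low-pass to the
    model between iterations (off by default).  The noise model used for the
    σ²-weighted matching is estimated once from the images and held fixed.
    Returns (final volume, final assignments, per-iteration history).
    """
    if noise is None:
        noise = NoiseModel.from_images(particles)
    vol = initial
    history = []
    assignments = None
    for it in range(n_iterations):
        assignments = assign_orientations(particles, vol, grid, noise)
        if wiener is None:
            vol, n_empty = direct_fourier_reconstruct(
                particles, assignments, oversampling=initial.oversampling,
                symmetry=symmetry, gridding_iters=gridding_iters)
        else:
            vol = wiener_constant_reconstruct(
                particles, assignments, wiener.C, oversampling=initial.oversampling,
                symmetry=symmetry, gridding_iters=gridding_iters)
            n_empty = 0
        if lowpass_shell is not None:
            vol = cosine_lowpass(vol, lowpass_shell)
        history.append({"iteration": it + 1, "n_empty": n_empty})
    return vol, assignments, history


def half_split_maps(particles: ParticleSet, assignments: list, seed: int,
                    oversampling: int = 3, symmetry: str = "C1",
                    wiener: WienerConfig | None = None,
                    lowpass_shell: float | None = None,
                    gridding_iters: int = 10):
    """Within-run half split: reconstruct two maps from a random split of the
    data using the *shared* final assignments of one refinement, with the
    same reconstruction recipe (Wiener constant / low-pass) as the run.

    This is the optimistic internal resolution estimate of conventional
    pipelines; comparing its FSC crossing against fully independent half
    refinements exposes overfitting.
    """
    perm = np.random.default_rng(seed).permutation(particles.n_particles)
    half = (particles.n_particles + 1) // 2
    maps = []
    for sel in (np.sort(perm[:half]), np.sort(perm[half:])):
        sub = particles.subset(sel)
        asg = [assignments[i] for i in sel]
        if wiener is None:
            vol, _ = direct_fourier_reconstruct(sub, asg, oversampling=oversampling,
                                                symmetry=symmetry,
                                                gridding_iters=gridding_iters)
        else:
            vol = wiener_constant_reconstruct(sub, asg, wiener.C,
                                              oversampling=oversampling,
                                              symmetry=symmetry,
                                              gridding_iters=gridding_iters)
        if lowpass_shell is not None:
            vol = cosine_lowpass(vol, lowpass_shell)
        maps.append(vol)
    return maps[0], maps[1]
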