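"""Iterative refinement drivers: alternate the expectation step (posterior
orientation/class weights) with the maximization step (regularized
reconstruction plus noise/signal/fraction updates) until the configured
iteration count, or until the maps stop changing.

Works identically for 3D refinement/classification and for 2D class
averaging: in 2D mode the references are oversampled 2D transforms, the
orientation grid covers in-plane rotation × shifts only, and all update
formulas are dimension-agnostic.

Multi-class runs seeded from a single map divide the data set into K random
subsets during the first iteration: orientations are assigned against the
common initial model, then each subset reconstructs one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .expectation import (ModelState, NoiseModel, PosteriorWeights,
                          dataset_expectation, reference_slices)
from .fourier import (FourierImage, FourierVolume, RealImage, RealVolume,
                      shell_of)
from .maximization import (SignalPrior, accumulate_mstep, solve_map,
                           update_class_fractions, update_noise, update_signal)
from .particles import ParticleSet
from .projector import (OrientationGrid, build_orientation_grid, image_grid,
                        oversampled_transform, symmetrize_accumulator,
                        volume_from_fourier, image_from_fourier)
from .resolution import snr_map, ssnr_curve

__all__ = ["RefineConfig", "refine", "refine2d", "refine_to_map", "HalfSetJob",
           "soft_circular_mask"]


@dataclass
class RefineConfig:
    """Everything one refinement run needs besides data and a starting model.

    The angular/shift schedules are coarse-to-fine: the finer values take
    over from ``fine_from_iteration`` onward (both optional).  ``T``
    multiplies the per-shell signal power wherever it enters the
    reconstruction denominator or the SNR.  ``freeze_spectra`` keeps τ² and
    σ² at their initial values (pure likelihood ascent in V);
    ``freeze_fractions`` keeps class fractions uniform.
    """

    n_classes: int = 1
    n_iterations: int = 10
    angular_step: float = 15.0
    angular_step_fine: float | None = None
    shift_range: float = 0.0
    shift_step: float = 1.0
    shift_range_fine: float | None = None
    fine_from_iteration: int = 11
    mode: str = "3d"                    # 3d | 2d
    T: float = 4.0
    symmetry: str = "C1"
    oversampling: int = 3
    gridding_iters: int = 10
    prune: float = 1e-8
    seed: int = 0
    mask_radius: float | None = None    # soft circular image mask (pixels), optional
    freeze_spectra: bool = False
    freeze_fractions: bool = False
    update_noise_model: bool = True
    convergence_tol: float | None = None
    shift_prior_sigma: float | None = None
    batch_size: int = 128

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.angular_step_fine is not None and self.angular_step_fine > self.angular_step:
            raise ValueError("angular schedule must be non-increasing")
        if self.shift_range_fine is not None and self.shift_range_fine > self.shift_range:
            raise ValueError("shift schedule must be non-increasing")
        if self.mode not in ("3d", "2d"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def grid_for(self, iteration: int) -> OrientationGrid:
        fine = iteration >= self.fine_from_iteration
        step = self.angular_step_fine if (fine and self.angular_step_fine) else self.angular_step
        srange = self.shift_range_fine if (fine and self.shift_range_fine is not None) \
            else self.shift_range
        return build_orientation_grid(step, shift_range=srange, shift_step=self.shift_step,
                                      mode=self.mode, shift_sigma=self.shift_prior_sigma)


def soft_circular_mask(size: int, radius: float, edge: float = 3.0) -> np.ndarray:
    """Cosine-edged circular mask used for the optional masked-noise mode."""
    ax = np.arange(size) - size // 2
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    r = np.sqrt(xx ** 2 + yy ** 2)
    m = 0.5 * (1 + np.cos(np.pi * np.clip((r - radius) / edge, 0, 1)))
    m[r <= radius] = 1.0
    return m


def _as_model_transforms(initial, config: RefineConfig, pixel_size: float) -> list:
    """Normalize the starting model(s) to oversampled Fourier transforms."""
    items = initial if isinstance(initial, (list, tuple)) else [initial]
    out = []
    for it in items:
        if isinstance(it, (RealVolume, RealImage)):
            out.append(oversampled_transform(it, config.oversampling))
        elif isinstance(it, (FourierVolume, FourierImage)):
            out.append(it)
        else:
            raise TypeError(f"unsupported initial model {type(it)!r}")
    return out


def _masked_particles(particles: ParticleSet, config: RefineConfig) -> ParticleSet:
    if config.mask_radius is None:
        return particles
    from .fourier import fftc, ifftc
    m = soft_circular_mask(particles.size, config.mask_radius)
    four = np.stack([fftc(ifftc(f).real * m) for f in particles.fourier])
    return ParticleSet(four, particles.pixel_size, particles.group_index,
                       particles.group_ctf, particles.metadata, particles.group_names,
                       particles.group_ctf_images)


def _seed_classes(particles: ParticleSet, model: ModelState, grid: OrientationGrid,
                  config: RefineConfig, shells) -> ModelState:
    """K random-subset seeding from a single starting model."""
    k = config.n_classes
    weights = dataset_expectation(particles, model, grid, batch_size=config.batch_size)
    rng = np.random.default_rng(config.seed)
    assign = rng.integers(0, k, size=particles.n_particles)
    gamma = np.zeros((particles.n_particles, k) + weights.gamma.shape[2:])
    for i in range(particles.n_particles):
        gamma[i, assign[i]] = weights.gamma[i, 0]
    seeded = PosteriorWeights(gamma=gamma, log_marginal=weights.log_marginal, grid=grid)
    wide = ModelState(volumes=[model.volumes[0]] * k,
                      tau2=np.repeat(model.tau2, k, axis=0),
                      noise=model.noise,
                      class_fraction=np.full(k, 1.0 / k), T=config.T)
    accs, _, _ = accumulate_mstep(particles, seeded, wide, grid,
                                  prune=config.prune, batch_size=config.batch_size)
    volumes = []
    for ki in range(k):
        acc = symmetrize_accumulator(accs[ki], config.symmetry)
        volumes.append(solve_map(acc, SignalPrior(wide.tau2[ki], config.T), shells,
                                 gridding_iters=config.gridding_iters))
    return ModelState(volumes=volumes, tau2=wide.tau2, noise=model.noise,
                      class_fraction=np.full(k, 1.0 / k), T=config.T)


def refine(particles: ParticleSet, initial, config: RefineConfig):
    """Run the full iterative refinement.

    ``initial`` is a starting map (RealVolume / RealImage for 2D mode), a
    list of K of them, or already-oversampled transform(s).  Returns
    ``(model, history, accumulators)`` — the final model state, one history
    record per iteration (log-likelihood, class fractions, estimated
    resolution, map change), and the final per-class accumulators (whose
    denominators feed the SNR estimate).
    """
    particles = _masked_particles(particles, config)
    volumes = _as_model_transforms(initial, config, particles.pixel_size)
    model_grid_shape = volumes[0].components.shape
    m = getattr(volumes[0], "oversampling", 1)
    shells = shell_of(model_grid_shape, m)
    noise = NoiseModel.from_images(particles)
    tau2 = np.stack([update_signal(v, shells, config.T).tau2 for v in volumes])
    if len(volumes) == 1 and config.n_classes > 1:
        base = ModelState(volumes=volumes, tau2=tau2, noise=noise,
                          class_fraction=np.array([1.0]), T=config.T)
        model = _seed_classes(particles, base, config.grid_for(1), config, shells)
    else:
        if len(volumes) != config.n_classes:
            raise ValueError(f"got {len(volumes)} initial maps for K={config.n_classes}")
        model = ModelState(volumes=volumes, tau2=tau2, noise=noise,
                           class_fraction=np.full(config.n_classes, 1.0 / config.n_classes),
                           T=config.T)
    g = image_grid(particles.size)
    mean_power = float(np.mean(np.abs(particles.fourier[:, g.mask]) ** 2))
    noise_floor = 1e-12 * mean_power
    history = []
    accs = None
    prev = None
    for it in range(1, config.n_iterations + 1):
        grid = config.grid_for(it)
        slices = reference_slices(model.volumes, grid, particles.size)
        weights = dataset_expectation(particles, model, grid, slices=slices,
                                      batch_size=config.batch_size)
        accs, res_sums, res_counts = accumulate_mstep(
            particles, weights, model, grid, slices=slices,
            prune=config.prune, batch_size=config.batch_size)
        new_volumes, new_tau2, resolutions = [], [], []
        for ki in range(model.n_classes):
            acc = symmetrize_accumulator(accs[ki], config.symmetry)
            accs[ki] = acc
            prior = SignalPrior(model.tau2[ki], config.T)
            vol = solve_map(acc, prior, shells, gridding_iters=config.gridding_iters)
            if not np.all(np.isfinite(vol.components)):
                raise RuntimeError(
                    f"divergence: non-finite model for class {ki} at iteration {it}")
            new_volumes.append(vol)
            new_tau2.append(model.tau2[ki] if config.freeze_spectra
                            else update_signal(vol, shells, config.T).tau2)
            curve = ssnr_curve(snr_map(acc.denominator, SignalPrior(new_tau2[-1], config.T),
                                       shells, m), shells, particles.pixel_size)
            resolutions.append(curve.resolution)
        if config.update_noise_model and not config.freeze_spectra:
            noise = update_noise(res_sums, res_counts, floor=max(noise_floor, 1e-300),
                                 group_names=list(particles.group_names))
        fractions = (model.class_fraction if (config.freeze_fractions or model.n_classes == 1)
                     else update_class_fractions(weights))
        change = np.nan
        if prev is not None:
            num = sum(np.linalg.norm(a.components - b.components)
                      for a, b in zip(new_volumes, prev))
            den = sum(np.linalg.norm(b.components) for b in prev)
            change = num / den if den > 0 else np.inf
        prev = new_volumes
        model = ModelState(volumes=new_volumes, tau2=np.stack(new_tau2), noise=noise,
                           class_fraction=fractions, T=config.T, iteration=it)
        history.append({
            "iteration": it,
            "log_likelihood": weights.total_log_likelihood,
            "class_fraction": fractions.copy(),
            "resolution": resolutions,
            "map_change": change,
            "n_orientations": len(grid),
            "gamma_entropy_mean": float(weights.entropy().mean()),
        })
        if (config.convergence_tol is not None and np.isfinite(change)
                and change < config.convergence_tol):
            break
    return model, history, accs


def refine2d(particles: ParticleSet, initial, config: RefineConfig):
    """2D class averaging: same algorithm with in-plane references.

    ``initial`` may be RealImage(s) or the string ``"random"``, which seeds K
    references from averages of random particle subsets.
    """
    config = replace(config, mode="2d")
    if isinstance(initial, str) and initial == "random":
        rng = np.random.default_rng(config.seed)
        assign = rng.integers(0, config.n_classes, size=particles.n_particles)
        refs = []
        from .fourier import ifftc
        for ki in range(config.n_classes):
            sel = np.flatnonzero(assign == ki)
            if sel.size == 0:
                sel = np.array([ki % particles.n_particles])
            avg = np.mean([ifftc(particles.fourier[i]).real for i in sel], axis=0)
            refs.append(RealImage(avg, particles.pixel_size))
        initial = refs
        cfg = replace(config, n_classes=config.n_classes)
        return refine(particles, initial, cfg)
    return refine(particles, initial, config)


def classify(particles: ParticleSet, initial, config: RefineConfig,
             n_attempts: int = 3):
    """Multi-reference classification with repeated random initializations.

    Random-subset seeding from a single map makes the K-class EM land in a
    seed-dependent optimum; rerunning with different random subsets and
    keeping the run with the highest final marginal log-likelihood (the EM
    objective itself) selects among them.  Returns the best
    ``(model, history, accumulators)``.
    """
    best = None
    for attempt in range(max(1, n_attempts)):
        cfg = replace(config, seed=config.seed + 1000 * attempt)
        out = refine(particles, initial, cfg)
        ll = out[1][-1]["log_likelihood"]
        if best is None or ll > best[0]:
            best = (ll, out)
    return best[1]


@dataclass
class HalfSetJob:
    """Bundle handed to half-set validation: a starting map + run settings."""

    initial: object
    config: RefineConfig


def refine_to_map(particles: ParticleSet, job: HalfSetJob, seed: int) -> RealVolume:
    """Refine one half-set and return the final real-space map (class 0)."""
    cfg = replace(job.config, seed=seed)
    model, _, _ = refine(particles, job.initial, cfg)
    vol = model.volumes[0]
    if isinstance(vol, FourierVolume):
        return volume_from_fourier(vol)
    return image_from_fourier(vol)
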