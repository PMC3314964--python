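"""Gaussian likelihoods, posterior weights and the marginal likelihood."""

import numpy as np
import pytest

from bayesmap.expectation import (ModelState, NoiseModel, PosteriorWeights,
                                  dataset_expectation, log_likelihood,
                                  posterior_weights, squared_residual,
                                  _LOG2PI)
from bayesmap.fourier import FourierImage, FourierVolume, fftc
from bayesmap.particles import ParticleSet
from bayesmap.projector import (Orientation, build_orientation_grid,
                                extract_slice, image_grid, oversampled_transform)
from bayesmap.ctf import CTFParams
from bayesmap.simulate import PhantomSpec, SimConfig, make_phantom, simulate_particles


def _img(rng, d=8):
    return FourierImage(rng.normal(size=(d, d)) + 1j * rng.normal(size=(d, d)), 2.0)


def test_squared_residual_trivial_cases(rng):
    sl = _img(rng)
    ctf = rng.uniform(-1, 1, (8, 8))
    perfect = FourierImage(ctf * sl.components, 2.0)
    assert np.abs(squared_residual(perfect, ctf, sl)).max() < 1e-20
    zero = FourierImage(np.zeros((8, 8), complex), 2.0)
    x = _img(rng)
    assert np.allclose(squared_residual(x, ctf, zero), np.abs(x.components) ** 2)


def test_squared_residual_matches_scalar_loop(rng):
    x, sl = _img(rng), _img(rng)
    ctf = rng.uniform(-1, 1, (8, 8))
    res = squared_residual(x, ctf, sl, shift=(1.0, -2.0))
    h = np.arange(8) - 4
    for i in range(8):
        for j in range(8):
            phase = np.exp(-2j * np.pi * (h[i] * 1.0 + h[j] * (-2.0)) / 8)
            expect = abs(x.components[i, j] - ctf[i, j] * phase * sl.components[i, j]) ** 2
            assert res[i, j] == pytest.approx(expect, rel=1e-12)


def test_log_likelihood_perfect_match_is_normalizer_only(rng):
    sl = _img(rng, 16)
    ctf = rng.uniform(-1, 1, (16, 16))
    noise = NoiseModel(np.full((1, 9), 0.5))
    perfect = FourierImage(ctf * sl.components, 2.0)
    ll = log_likelihood(perfect, ctf, sl, noise=noise, group=0)
    g = image_grid(16)
    expect = np.sum(-_LOG2PI - np.log(noise.per_component(0, 16)))
    assert ll == pytest.approx(expect)


def test_log_likelihood_quadratic_scaling(rng):
    sl = _img(rng, 16)
    ctf = rng.uniform(-1, 1, (16, 16))
    noise = NoiseModel(np.full((1, 9), 0.7))
    zero = FourierImage(np.zeros((16, 16), complex), 2.0)
    base = log_likelihood(zero, ctf, sl, noise=noise)
    # doubling all residual amplitudes scales the quadratic term by 4
    double = FourierImage(-sl.components * ctf, 2.0)  # residual 2·CTF·S
    norm = np.sum(-_LOG2PI - np.log(noise.per_component(0, 16)))
    assert (log_likelihood(double, ctf, sl, noise=noise) - norm) == \
        pytest.approx(4 * (base - norm), rel=1e-10)


def test_log_likelihood_matches_bruteforce_sum(rng):
    x, sl = _img(rng, 16), _img(rng, 16)
    ctf = rng.uniform(-1, 1, (16, 16))
    s2 = rng.uniform(0.3, 2.0, 9)
    noise = NoiseModel(s2[None])
    ll = log_likelihood(x, ctf, sl, shift=(2, 1), noise=noise, group=0)
    g = image_grid(16)
    res = squared_residual(x, ctf, sl, shift=(2, 1)).ravel()[g.flat_index]
    manual = np.sum(-np.log(2 * np.pi * s2[g.ring]) - res / (2 * s2[g.ring]))
    assert ll == pytest.approx(manual, rel=1e-12)


def test_nonpositive_sigma_rejected(rng):
    with pytest.raises(ValueError):
        NoiseModel(np.zeros((1, 9)))
    x, sl = _img(rng, 16), _img(rng, 16)
    with pytest.raises(ValueError):
        log_likelihood(x, np.ones((16, 16)), sl, sigma2=-1.0)


@pytest.fixture(scope="module")
def toy_model(phantom16):
    fv = oversampled_transform(phantom16, 3)
    noise = NoiseModel(np.full((1, 9), 0.5))
    return ModelState(volumes=[fv], tau2=np.ones((1, 9)), noise=noise,
                      class_fraction=np.array([1.0]), T=4.0)


def test_posterior_single_entry_grid_is_certain(rng, toy_model):
    grid = build_orientation_grid(360.0, mode="2d")
    assert len(grid) == 1
    w = posterior_weights(_img(rng, 16), toy_model, grid)
    assert w.gamma[0, 0, 0, 0] == pytest.approx(1.0)


def test_posterior_symmetric_orientations_split_evenly(rng):
    """Two orientations with identical reference slices get Γ = 0.5 each."""
    const = FourierVolume(np.zeros((48, 48, 48), complex), 2.0, oversampling=3)
    const.components[24, 24, 24] = 5.0  # spherically symmetric transform
    noise = NoiseModel(np.full((1, 9), 0.5))
    model = ModelState(volumes=[const], tau2=np.ones((1, 9)), noise=noise,
                       class_fraction=np.array([1.0]), T=4.0)
    grid = build_orientation_grid(180.0, mode="2d")
    w = posterior_weights(_img(rng, 16), model, grid)
    assert np.allclose(w.gamma.sum(), 1.0)
    assert w.gamma[0, 0, 0, 0] == pytest.approx(0.5, abs=1e-10)
    assert w.gamma[0, 0, 1, 0] == pytest.approx(0.5, abs=1e-10)


def test_posterior_matches_bruteforce_product(rng, phantom16):
    """Engine Γ equals direct normalized products of likelihood × prior."""
    fva = oversampled_transform(phantom16, 3)
    vb = make_phantom(PhantomSpec(size=16, voxel_size=2.0, n_random_blobs=4), seed=8)
    fvb = oversampled_transform(vb, 3)
    noise = NoiseModel(np.full((1, 9), 0.8))
    model = ModelState(volumes=[fva, fvb], tau2=np.ones((2, 9)), noise=noise,
                       class_fraction=np.array([0.3, 0.7]), T=4.0)
    grid = build_orientation_grid(120.0, mode="2d", shift_range=1, shift_step=1)
    x = _img(rng, 16)
    ctf = np.ones((16, 16))
    w = posterior_weights(x, model, grid, ctf=ctf)
    # brute force via the scalar ops
    lp = np.zeros((2, grid.n_rotations, grid.n_shifts))
    for k, fv in enumerate((fva, fvb)):
        for r in range(grid.n_rotations):
            sl = extract_slice(fv, Orientation(psi=grid.angles[r, 2]))
            for s in range(grid.n_shifts):
                ll = log_likelihood(x, ctf, sl, shift=tuple(grid.shifts[s]), noise=noise)
                lp[k, r, s] = ll + np.log(model.class_fraction[k]) + \
                    np.log(grid.rot_prior[r]) + np.log(grid.shift_prior[s])
    p = np.exp(lp - lp.max())
    expect = p / p.sum()
    assert np.abs(w.gamma[0] - expect).max() < 1e-8
    assert w.log_marginal[0] == pytest.approx(
        lp.max() + np.log(np.exp(lp - lp.max()).sum()), rel=1e-10)


@pytest.fixture(scope="module")
def small_set(phantom16):
    cfg = SimConfig(n_particles=6, noise_sigma2=0.4, seed=5, n_groups=2,
                    defocus_range=(8000, 20000))
    return simulate_particles([phantom16], cfg)


def test_dataset_expectation_additivity_and_permutation(small_set, phantom16):
    fv = oversampled_transform(phantom16, 3)
    noise = NoiseModel(np.full((2, 9), 0.4))
    model = ModelState(volumes=[fv], tau2=np.ones((1, 9)), noise=noise,
                       class_fraction=np.array([1.0]), T=4.0)
    grid = build_orientation_grid(40.0, mode="3d")
    w = dataset_expectation(small_set, model, grid)
    # Γ normalization
    sums = w.gamma.reshape(6, -1).sum(axis=1)
    assert np.abs(sums - 1).max() < 1e-10
    # duplication doubles the total
    dup = small_set.subset(np.repeat(np.arange(6), 2))
    w2 = dataset_expectation(dup, model, grid)
    assert w2.total_log_likelihood == pytest.approx(2 * w.total_log_likelihood, rel=1e-12)
    # permutation leaves the total unchanged
    perm = small_set.subset(np.array([3, 1, 5, 0, 4, 2]))
    w3 = dataset_expectation(perm, model, grid)
    assert w3.total_log_likelihood == pytest.approx(w.total_log_likelihood, rel=1e-12)
    # total equals the sum of per-particle marginals computed one by one
    singles = sum(dataset_expectation(small_set.subset(np.array([i])), model, grid)
                  .total_log_likelihood for i in range(6))
    assert singles == pytest.approx(w.total_log_likelihood, rel=1e-12)


def test_sharpening_noise_reduces_entropy(small_set, phantom16):
    fv = oversampled_transform(phantom16, 3)
    grid = build_orientation_grid(40.0, mode="3d")
    ents = []
    for s2 in (0.8, 0.4, 0.2):
        noise = NoiseModel(np.full((2, 9), s2))
        model = ModelState(volumes=[fv], tau2=np.ones((1, 9)), noise=noise,
                          class_fraction=np.array([1.0]), T=4.0)
        ents.append(dataset_expectation(small_set, model, grid).entropy())
    for a, b in zip(ents[:-1], ents[1:]):
        assert np.all(b <= a + 1e-9)


def test_empty_inputs_rejected(small_set, toy_model):
    with pytest.raises(ValueError):
        dataset_expectation(small_set.subset(np.array([], dtype=int)), toy_model,
                            build_orientation_grid(90.0, mode="2d"))
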