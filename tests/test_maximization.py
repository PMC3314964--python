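"""M-step: accumulation, regularized solve, noise/signal/fraction updates."""

import warnings

import numpy as np
import pytest

from bayesmap.expectation import ModelState, NoiseModel, PosteriorWeights
from bayesmap.fourier import FourierImage, FourierVolume, fftc, shell_of
from bayesmap.maximization import (SignalPrior, accumulate_mstep, solve_map,
                                   update_class_fractions, update_noise,
                                   update_signal)
from bayesmap.particles import ParticleSet
from bayesmap.projector import (Accumulator, Orientation, OrientationGrid,
                                build_orientation_grid, extract_slice,
                                image_grid, insert_slice, oversampled_transform,
                                shift_phase)
from bayesmap.ctf import CTFParams
from bayesmap.simulate import PhantomSpec, SimConfig, make_phantom, simulate_particles
from bayesmap.expectation import squared_residual


@pytest.fixture(scope="module")
def toy(phantom16):
    cfg = SimConfig(n_particles=3, noise_sigma2=0.5, seed=2, n_groups=2,
                    defocus_range=(8000, 20000))
    ps = simulate_particles([phantom16], cfg)
    fv = oversampled_transform(phantom16, 3)
    noise = NoiseModel(np.array([[0.4] * 9, [0.7] * 9]))
    model = ModelState(volumes=[fv], tau2=np.ones((1, 9)), noise=noise,
                       class_fraction=np.array([1.0]), T=4.0)
    grid = build_orientation_grid(90.0, mode="2d", shift_range=1, shift_step=1)
    return ps, model, grid


def test_accumulate_delta_gamma_equals_single_insert(toy):
    ps, model, grid = toy
    gamma = np.zeros((3, 1, grid.n_rotations, grid.n_shifts))
    gamma[:, 0, 2, 4] = 1.0  # everyone on one (rotation, zero-shift) cell
    w = PosteriorWeights(gamma=gamma, log_marginal=np.zeros(3), grid=grid)
    accs, _, _ = accumulate_mstep(ps, w, model, grid, prune=0.0)
    expect = Accumulator.zeros(16, 3, 2.0, model_ndim=3)
    for i in range(3):
        gi = int(ps.group_index[i])
        o = grid.orientation(2 * grid.n_shifts + 4)
        insert_slice(FourierImage(ps.fourier[i], 2.0), ps.ctf(gi), 1.0,
                     _sigma_full(model.noise, gi), o, expect)
    assert np.abs(accs[0].numerator - expect.numerator).max() < 1e-9
    assert np.abs(accs[0].denominator - expect.denominator).max() < 1e-9


def _sigma_full(noise, gi, size=16):
    full = np.zeros((size, size))
    g = image_grid(size)
    full.ravel()[g.flat_index] = noise.sigma2[gi][g.ring]
    full[full == 0] = 1.0  # outside the disc, never read
    return full


def test_accumulate_uniform_gamma_is_half_weighted_sum(toy):
    ps, model, grid = toy
    one = ps.subset(np.array([0]))
    gamma = np.zeros((1, 1, grid.n_rotations, grid.n_shifts))
    gamma[0, 0, 0, 4] = 0.5
    gamma[0, 0, 3, 4] = 0.5
    w = PosteriorWeights(gamma=gamma, log_marginal=np.zeros(1), grid=grid)
    accs, _, _ = accumulate_mstep(one, w, model, grid, prune=0.0)
    expect = Accumulator.zeros(16, 3, 2.0, model_ndim=3)
    gi = int(ps.group_index[0])
    s2 = _sigma_full(model.noise, gi)
    for r in (0, 3):
        insert_slice(FourierImage(ps.fourier[0], 2.0), ps.ctf(gi), 0.5, s2,
                     grid.orientation(r * grid.n_shifts + 4), expect)
    assert np.abs(accs[0].numerator - expect.numerator).max() < 1e-9
    assert np.abs(accs[0].denominator - expect.denominator).max() < 1e-9


def test_accumulate_matches_loop_oracle(toy):
    """Random Γ over a 2D grid with shifts: sums equal a pure-python loop."""
    ps, model, grid = toy
    rng = np.random.default_rng(7)
    gamma = rng.uniform(size=(3, 1, grid.n_rotations, grid.n_shifts))
    gamma /= gamma.reshape(3, -1).sum(axis=1)[:, None, None, None]
    w = PosteriorWeights(gamma=gamma, log_marginal=np.zeros(3), grid=grid)
    accs, res_sums, res_counts = accumulate_mstep(ps, w, model, grid, prune=0.0)
    expect = Accumulator.zeros(16, 3, 2.0, model_ndim=3)
    g = image_grid(16)
    res_oracle = np.zeros((2, 9))
    for i in range(3):
        gi = int(ps.group_index[i])
        s2full = _sigma_full(model.noise, gi)
        img = FourierImage(ps.fourier[i], 2.0)
        for r in range(grid.n_rotations):
            sl = extract_slice(model.volumes[0], Orientation(psi=grid.angles[r, 2]))
            for s in range(grid.n_shifts):
                o = grid.orientation(r * grid.n_shifts + s)
                insert_slice(img, ps.ctf(gi), gamma[i, 0, r, s], s2full, o, expect)
                res = squared_residual(img, ps.ctf(gi), sl,
                                       shift=tuple(grid.shifts[s])).ravel()[g.flat_index]
                res_oracle[gi] += gamma[i, 0, r, s] * np.bincount(
                    g.ring, weights=res, minlength=9)
    assert np.abs(accs[0].numerator - expect.numerator).max() < 1e-8
    assert np.abs(accs[0].denominator - expect.denominator).max() < 1e-8
    assert np.abs(res_sums - res_oracle).max() < 1e-6 * np.abs(res_oracle).max()
    counts = np.bincount(g.ring, minlength=9).astype(float)
    assert np.allclose(res_counts[0], counts * 2)  # two particles in group 0
    assert np.allclose(res_counts[1], counts * 1)


def test_solve_single_image_wiener_shrinkage(phantom16):
    """One image at identity, CTF ≡ 1, σ² ≡ 1: V = X/(1 + 1/(T·τ²))."""
    fv = oversampled_transform(phantom16, 3)
    x = extract_slice(fv, Orientation())
    acc = Accumulator.zeros(16, 3, 2.0)
    insert_slice(x, np.ones((16, 16)), 1.0, 1.0, Orientation(), acc)
    tau2 = np.full(9, 0.7)
    v = solve_map(acc, SignalPrior(tau2, T=4.0), gridding_iters=0)
    shrink = 1.0 / (1.0 + 1.0 / (4.0 * 0.7))
    # every sampled voxel is shrunk toward zero by the same factor
    g = image_grid(16)
    from bayesmap.projector import slice_map
    valid, flat = slice_map((0.0, 0.0, 0.0), 16, 48, 3, 3)
    xm = x.components.ravel()[g.flat_index]
    got = v.components.ravel()[flat]
    assert np.abs(got - shrink * xm[valid]).max() < 1e-9


def test_solve_fully_damped_shell_is_zero(phantom16):
    fv = oversampled_transform(phantom16, 3)
    acc = Accumulator.zeros(16, 3, 2.0)
    insert_slice(extract_slice(fv, Orientation()), np.ones((16, 16)), 1.0, 1.0,
                 Orientation(), acc)
    tau2 = np.full(9, 1.0)
    tau2[3] = 0.0
    v = solve_map(acc, SignalPrior(tau2, T=1.0))
    sh = shell_of(v.components.shape, 3)
    assert np.abs(v.components[sh.shell == 3]).max() == 0.0


def test_solve_monotone_damping(phantom16):
    fv = oversampled_transform(phantom16, 3)
    acc = Accumulator.zeros(16, 3, 2.0)
    insert_slice(extract_slice(fv, Orientation()), np.ones((16, 16)), 1.0, 1.0,
                 Orientation(), acc)
    strong = solve_map(acc, SignalPrior(np.full(9, 0.1), T=1.0), gridding_iters=0)
    weak = solve_map(acc, SignalPrior(np.full(9, 10.0), T=1.0), gridding_iters=0)
    assert np.all(np.abs(strong.components) <= np.abs(weak.components) + 1e-15)


def test_solve_unconstrained_shell_raises(phantom16):
    acc = Accumulator.zeros(16, 3, 2.0)  # nothing inserted
    with pytest.raises(ZeroDivisionError):
        solve_map(acc, SignalPrior(np.full(9, np.inf), T=1.0), on_empty="raise")


def test_update_noise_floor_and_scaling():
    counts = np.full((1, 9), 100.0)
    floor = 1e-6
    nm = update_noise(np.zeros((1, 9)), counts, floor=floor)
    assert np.all(nm.sigma2 == floor)
    base = update_noise(np.full((1, 9), 50.0), counts, floor=floor)
    quad = update_noise(np.full((1, 9), 200.0), counts, floor=floor)
    assert np.allclose(quad.sigma2, 4 * base.sigma2)
    assert np.allclose(base.sigma2, 50.0 / (2 * 100.0))
    with pytest.raises(ValueError):
        update_noise(np.zeros((1, 9)), np.zeros((1, 9)))


def test_update_signal_definition_and_loop_oracle(rng):
    v = FourierVolume(np.zeros((16, 16, 16), complex), 2.0, oversampling=1)
    sp = update_signal(v, T=4.0)
    assert np.all(sp.tau2 == 0)
    # single nonzero component of modulus m in its shell
    v.components[8, 8 + 3, 8] = 3.0 - 4.0j  # modulus 5, shell 3
    sh = shell_of((16, 16, 16))
    sp = update_signal(v, sh, T=4.0)
    assert sp.tau2[3] == pytest.approx(25.0 / (2 * sh.counts[3]))
    # random volume: loop-based shell averaging
    w = FourierVolume(rng.normal(size=(16, 16, 16))
                      + 1j * rng.normal(size=(16, 16, 16)), 2.0)
    sp = update_signal(w, sh, T=4.0)
    for s in range(9):
        manual = 0.5 * np.mean(np.abs(w.components[sh.shell == s]) ** 2)
        assert sp.tau2[s] == pytest.approx(manual, rel=1e-12)


def test_effective_tau2_is_t_scaled_and_large_t_warns():
    sp = SignalPrior(np.array([1.0, 2.0]), T=4.0)
    assert np.allclose(sp.effective_tau2, [4.0, 8.0])
    with pytest.warns(UserWarning):
        SignalPrior(np.array([1.0]), T=8.0)
    with pytest.raises(ValueError):
        SignalPrior(np.array([-1.0]))


def test_update_class_fractions(rng):
    grid = build_orientation_grid(90.0, mode="2d")
    g1 = np.zeros((2, 2, 4, 1))
    g1[0, 0, 0, 0] = 1.0
    g1[1, 1, 2, 0] = 1.0
    w = PosteriorWeights(gamma=g1, log_marginal=np.zeros(2), grid=grid)
    assert np.allclose(update_class_fractions(w), [0.5, 0.5])
    gr = rng.uniform(size=(5, 3, 4, 1))
    gr /= gr.reshape(5, -1).sum(axis=1)[:, None, None, None]
    w = PosteriorWeights(gamma=gr, log_marginal=np.zeros(5), grid=grid)
    assert np.allclose(update_class_fractions(w), gr.sum(axis=(2, 3)).mean(axis=0))
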