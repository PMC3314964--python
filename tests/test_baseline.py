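"""Conventional comparator: hard assignment, direct Fourier inversion, Wiener."""

import numpy as np
import pytest

from bayesmap.baseline import (WienerConfig, assign_orientations,
                               best_orientation, cosine_lowpass,
                               direct_fourier_reconstruct,
                               wiener_average_2d, wiener_constant_reconstruct)
from bayesmap.expectation import (ModelState, NoiseModel, PosteriorWeights,
                                  log_likelihood)
from bayesmap.fourier import FourierImage, FourierVolume, shell_of
from bayesmap.maximization import SignalPrior, accumulate_mstep, solve_map
from bayesmap.projector import (Orientation, OrientationGrid,
                                build_orientation_grid, extract_slice,
                                oversampled_transform, volume_from_fourier)
from bayesmap.simulate import PhantomSpec, SimConfig, make_phantom, simulate_particles


@pytest.fixture(scope="module")
def fvol16(phantom16):
    return oversampled_transform(phantom16, 3)


@pytest.fixture(scope="module")
def grid2d():
    return build_orientation_grid(45.0, mode="2d")


def test_best_orientation_selfmatch(phantom16, fvol16, grid2d):
    sl = extract_slice(fvol16, grid2d.orientation(3))
    got = best_orientation(sl, fvol16, grid2d)
    assert got.psi == pytest.approx(grid2d.orientation(3).psi)


def test_best_orientation_tiebreak_lowest_index(grid2d):
    """All orientations exactly tied (spherically symmetric reference, zero
    image) → the lowest grid index wins."""
    const = FourierVolume(np.zeros((48, 48, 48), complex), 2.0, oversampling=3)
    const.components[24, 24, 24] = 5.0
    zero = FourierImage(np.zeros((16, 16), complex), 2.0)
    got = best_orientation(zero, const, grid2d)
    first = grid2d.orientation(0)
    assert (got.rot, got.tilt, got.psi) == (first.rot, first.tilt, first.psi)


def test_assignments_match_exhaustive_scalar_oracle(phantom16, fvol16):
    """20 noiseless images: vectorized assignment == exhaustive residual scan."""
    cfg = SimConfig(n_particles=20, noise_sigma2=0.0, seed=6, n_groups=2,
                    defocus_range=(8000, 20000))
    ps = simulate_particles([phantom16], cfg)
    grid = build_orientation_grid(40.0, mode="3d")
    noise = NoiseModel(np.full((2, 9), 0.5))
    got = assign_orientations(ps, fvol16, grid, noise)
    for i in range(20):
        gi = int(ps.group_index[i])
        best, best_ll = None, -np.inf
        img = FourierImage(ps.fourier[i], 2.0)
        for r in range(grid.n_rotations):
            sl = extract_slice(fvol16, grid.orientation(r))
            ll = log_likelihood(img, ps.ctf(gi), sl, noise=noise, group=gi)
            if ll > best_ll:
                best, best_ll = grid.orientation(r), ll
        assert (got[i].rot, got[i].tilt, got[i].psi) == \
            (best.rot, best.tilt, best.psi)


def test_direct_fourier_single_image_ratio(fvol16):
    """One image at identity with CTF ≡ 1: sampled plane equals X exactly."""
    sl = extract_slice(fvol16, Orientation())
    from bayesmap.particles import ParticleSet
    from bayesmap.ctf import CTFParams
    full = np.zeros((16, 16), complex)
    full[:] = sl.components
    ps = ParticleSet(full[None], 2.0, np.zeros(1, dtype=int),
                     [CTFParams(defocus=0.0, amplitude_contrast=1.0, pixel_size=2.0)],
                     group_ctf_images=[np.ones((16, 16))])
    vol, n_empty = direct_fourier_reconstruct(ps, [Orientation()], gridding_iters=0)
    back = extract_slice(vol, Orientation())
    from bayesmap.projector import image_grid
    g = image_grid(16)
    assert np.abs(back.components[g.mask] - sl.components[g.mask]).max() < 1e-9
    # duplicating the image leaves the ratio unchanged
    ps2 = ParticleSet(np.repeat(full[None], 2, axis=0), 2.0, np.zeros(2, dtype=int),
                      ps.group_ctf, group_ctf_images=[np.ones((16, 16))])
    vol2, _ = direct_fourier_reconstruct(ps2, [Orientation()] * 2, gridding_iters=0)
    assert np.abs(vol2.components - vol.components).max() < 1e-9


def test_direct_fourier_full_coverage_recovers_phantom(phantom16):
    """Noiseless 16³ toy with 200 known projections and CTF ≡ 1."""
    cfg = SimConfig(n_particles=200, noise_sigma2=0.0, seed=4,
                    amplitude_contrast=1.0, defocus_range=(0.0, 1e-6), n_groups=1)
    ps = simulate_particles([phantom16], cfg)
    truth = [Orientation(rot=r, tilt=t, psi=p) for r, t, p in
             ps.metadata[["true_rot", "true_tilt", "true_psi"]].to_numpy()]
    vol, _ = direct_fourier_reconstruct(ps, truth)
    real = volume_from_fourier(vol)
    cc = np.corrcoef(real.voxels.ravel(), phantom16.voxels.ravel())[0, 1]
    assert cc > 0.99


def test_wiener_average_limits_and_scalar_oracle(rng):
    d = 16
    imgs = [FourierImage(rng.normal(size=(d, d)) + 1j * rng.normal(size=(d, d)), 2.0)
            for _ in range(3)]
    ctfs = [rng.uniform(-1, 1, (d, d)) for _ in range(3)]
    # huge SNR, single image, CTF ≡ 1 → output ≈ input
    out = wiener_average_2d([imgs[0]], [np.ones((d, d))], snr=1e6)
    assert np.abs(out.components - imgs[0].components).max() < 1e-5
    # SNR → 0 → output → 0
    out = wiener_average_2d(imgs, ctfs, snr=1e-12)
    assert np.abs(out.components).max() < 1e-9
    # tabulated scalar formula
    snr = 2.5
    out = wiener_average_2d(imgs, ctfs, snr=snr)
    num = sum(snr * c * im.components for im, c in zip(imgs, ctfs))
    den = sum(snr * c * c for c in ctfs) + 1.0
    assert np.abs(out.components - num / den).max() < 1e-12


def test_wiener_constant_limits(phantom16):
    cfg = SimConfig(n_particles=30, noise_sigma2=0.0, seed=9, n_groups=2,
                    defocus_range=(8000, 20000))
    ps = simulate_particles([phantom16], cfg)
    truth = [Orientation(rot=r, tilt=t, psi=p) for r, t, p in
             ps.metadata[["true_rot", "true_tilt", "true_psi"]].to_numpy()]
    direct, _ = direct_fourier_reconstruct(ps, truth, gridding_iters=0)
    tiny = wiener_constant_reconstruct(ps, truth, C=1e-12, gridding_iters=0)
    hit = np.abs(direct.components) > 0
    rel = np.abs(tiny.components - direct.components)[hit].max() / \
        np.abs(direct.components[hit]).max()
    assert rel < 1e-6
    huge = wiener_constant_reconstruct(ps, truth, C=1e9, gridding_iters=0)
    assert np.sum(np.abs(huge.components) ** 2) < 1e-9 * np.sum(np.abs(direct.components) ** 2)
    with pytest.raises(ValueError):
        wiener_constant_reconstruct(ps, truth, C=0.0)


def test_regularized_solve_reduces_to_wiener_constant(phantom16):
    """Delta-Γ, uniform σ², shell-constant T·τ² = σ²/C reproduces the
    Wiener-constant reconstruction exactly (two independent accumulation
    paths)."""
    cfg = SimConfig(n_particles=12, noise_sigma2=0.0, seed=11, n_groups=2,
                    defocus_range=(8000, 20000))
    ps = simulate_particles([phantom16], cfg)
    truth = [Orientation(rot=r, tilt=t, psi=p) for r, t, p in
             ps.metadata[["true_rot", "true_tilt", "true_psi"]].to_numpy()]
    c_const = 0.3
    wien = wiener_constant_reconstruct(ps, truth, C=c_const, gridding_iters=0)
    # probabilistic route: Γ concentrated on the true orientations
    ang = ps.metadata[["true_rot", "true_tilt", "true_psi"]].to_numpy()
    grid = OrientationGrid(angles=ang, shifts=np.zeros((1, 2)),
                           rot_prior=np.full(12, 1 / 12), shift_prior=np.array([1.0]),
                           angular_step=0.0, mode="3d")
    gamma = np.zeros((12, 1, 12, 1))
    gamma[np.arange(12), 0, np.arange(12), 0] = 1.0
    w = PosteriorWeights(gamma=gamma, log_marginal=np.zeros(12), grid=grid)
    fv = oversampled_transform(phantom16, 3)
    model = ModelState(volumes=[fv], tau2=np.ones((1, 9)),
                       noise=NoiseModel(np.ones((2, 9))),
                       class_fraction=np.array([1.0]), T=4.0)
    accs, _, _ = accumulate_mstep(ps, w, model, grid, prune=0.0)
    v = solve_map(accs[0], SignalPrior(np.full(9, 1.0 / (4.0 * c_const)), T=4.0),
                  gridding_iters=0)
    assert np.abs(v.components - wien.components).max() < 1e-8


def test_cosine_lowpass_passband_and_stopband(fvol16):
    filtered = cosine_lowpass(fvol16, shell_cut=5.0, width=2.0)
    sh = shell_of(fvol16.components.shape, 3)
    low = sh.shell <= 2
    assert np.abs(filtered.components[low] - fvol16.components[low]).max() < 1e-12
    assert np.abs(filtered.components[sh.shell >= 5]).max() == 0.0


def test_wiener_config_validation():
    with pytest.raises(ValueError):
        WienerConfig(C=0.0)
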