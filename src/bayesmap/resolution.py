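"""Resolution estimation: the per-voxel SNR of the regularized reconstruction,
its spherical average (SSNR) with the >= 1 criterion, Fourier shell
correlation between maps, half-set validation, and Guinier/B-factor
sharpening against a reference map.

Threshold-crossing convention: curves are reported per shell (shell width =
one Fourier pixel at the original sampling rate) and the crossing is the
frequency of the *last shell at or above* the threshold, with no sub-shell
interpolation — shell-width precision is what small grids honestly support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import RealVolume, ShellIndex, fftc, shell_of
from .maximization import SignalPrior
from .projector import Accumulator

__all__ = [
    "ResolutionCurve",
    "snr_map",
    "ssnr_curve",
    "fsc",
    "half_set_validate",
    "guinier_bfactor",
]


@dataclass
class ResolutionCurve:
    """Per-shell frequency/value pairs plus the crossing for a stated threshold.

    ``crossing_frequency`` is in Å⁻¹ (None if the curve never falls below the
    threshold up to Nyquist); ``crossing_shell`` is the corresponding shell
    number.  ``resolution`` converts to Å.
    """

    frequency: np.ndarray
    values: np.ndarray
    threshold: float
    crossing_shell: int | None
    crossing_frequency: float | None

    @property
    def resolution(self) -> float | None:
        if not self.crossing_frequency:
            return None
        return 1.0 / self.crossing_frequency

    def crossing_at(self, threshold: float) -> tuple:
        """(shell, frequency) of the last shell with value >= threshold."""
        below = np.flatnonzero(self.values < threshold)
        if below.size == 0:
            s = len(self.values) - 1
        elif below[0] == 0:
            return 0, float(self.frequency[0])
        else:
            s = int(below[0]) - 1
        return s, float(self.frequency[s])


def _make_curve(freq: np.ndarray, vals: np.ndarray, threshold: float) -> ResolutionCurve:
    c = ResolutionCurve(frequency=np.asarray(freq), values=np.asarray(vals),
                        threshold=threshold, crossing_shell=None, crossing_frequency=None)
    s, f = c.crossing_at(threshold)
    c.crossing_shell, c.crossing_frequency = s, f
    return c


def snr_map(denominator: np.ndarray | Accumulator, prior: SignalPrior,
            shells: ShellIndex | None = None, oversampling: int = 3) -> np.ndarray:
    """Per-voxel SNR of the reconstruction: T·τ²(shell) × accumulated CTF²/σ².

    The weight term comes from the final-iteration accumulator, so the SNR
    reflects the actual Γ-weighted orientation coverage (it varies within a
    shell when the orientation distribution is uneven).
    """
    if isinstance(denominator, Accumulator):
        oversampling = denominator.oversampling
        denominator = denominator.denominator
    if shells is None:
        shells = shell_of(denominator.shape, oversampling)
    tau2_eff = prior.effective_tau2
    idx = np.minimum(shells.shell, len(tau2_eff) - 1)
    vox = tau2_eff[idx] * denominator
    vox[shells.shell >= len(tau2_eff)] = 0.0
    return vox


def ssnr_curve(snr: np.ndarray, shells: ShellIndex, pixel_size: float) -> ResolutionCurve:
    """Spherical average of the per-voxel SNR; resolution = last shell >= 1."""
    means = shells.shell_mean(snr)[: shells.nyquist_shell + 1]
    freq = shells.frequencies(pixel_size)[: shells.nyquist_shell + 1]
    return _make_curve(freq, means, threshold=1.0)


def fsc(map_a: RealVolume, map_b: RealVolume, threshold: float = 0.5) -> ResolutionCurve:
    """Fourier shell correlation between two maps on identical grids.

    Per shell: Re⟨A, conj(B)⟩ / sqrt(⟨|A|²⟩·⟨|B|²⟩) ∈ [-1, 1]; symmetric in
    its arguments.  Crossing reported at ``threshold`` (0.5 by default).
    """
    if map_a.voxels.shape != map_b.voxels.shape or map_a.voxel_size != map_b.voxel_size:
        raise ValueError("fsc: maps must share grid and voxel size")
    fa = fftc(map_a.voxels)
    fb = fftc(map_b.voxels)
    shells = shell_of(fa.shape)
    nshell = shells.nyquist_shell + 1
    cross = shells.shell_sum((fa * np.conj(fb)).real)[:nshell]
    pa = shells.shell_sum(np.abs(fa) ** 2)[:nshell]
    pb = shells.shell_sum(np.abs(fb) ** 2)[:nshell]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(pa * pb > 0, cross / np.sqrt(pa * pb), 0.0)
    freq = shells.frequencies(map_a.voxel_size)[:nshell]
    return _make_curve(freq, vals, threshold)


def half_set_validate(particles, config, seed: int, refine_fn=None):
    """Two completely independent refinements of random halves of the data.

    Both halves start from the same initial model (inside ``config``) but
    share no statistics.  Returns (map_a, map_b, fsc_curve, crossings) with
    crossings reported at FSC = 0.5 and 0.143.

    ``refine_fn(particles, config, seed)`` must return a final real-space
    map; by default the package's own MAP refinement driver is used.
    """
    if particles.n_particles < 2:
        raise ValueError("need at least two particles to split")
    if refine_fn is None:
        from .refine import refine_to_map
        refine_fn = refine_to_map
    half_a, half_b = particles.random_split(seed)
    map_a = refine_fn(half_a, config, seed)
    map_b = refine_fn(half_b, config, seed + 1)
    curve = fsc(map_a, map_b, threshold=0.5)
    crossings = {0.5: curve.crossing_at(0.5), 0.143: curve.crossing_at(0.143)}
    return map_a, map_b, curve, crossings


def _soft_spherical_mask(size: int, radius_frac: float = 0.45, edge: float = 3.0) -> np.ndarray:
    ax = np.arange(size) - size // 2
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    r0 = radius_frac * size
    mask = 0.5 * (1 + np.cos(np.pi * np.clip((r - r0) / edge, 0, 1)))
    mask[r <= r0] = 1.0
    return mask


def guinier_bfactor(map_: RealVolume, reference: RealVolume,
                    fit_range: tuple, mask: bool = True):
    """Relative B-factor of a map against a reference, plus the sharpened map.

    A straight line is fitted to ln(spherically averaged |F|) against ν² over
    ``fit_range = (d_low, d_high)`` in Å (d_low > d_high); the relative
    B-factor is four times the slope difference and the sharpened map applies
    exp(+B·ν²/4) to the amplitudes.  Both maps are masked identically with a
    soft spherical mask before fitting.
    """
    if map_.voxels.shape != reference.voxels.shape:
        raise ValueError("guinier_bfactor: maps must share grids")
    d_low, d_high = fit_range
    if d_low <= d_high:
        raise ValueError("fit_range must be (d_low, d_high) in Å with d_low > d_high")
    w = _soft_spherical_mask(map_.size) if mask else 1.0
    fm = fftc(map_.voxels * w)
    fr = fftc(reference.voxels * w)
    shells = shell_of(fm.shape)
    nshell = shells.nyquist_shell + 1
    freq = shells.frequencies(map_.voxel_size)[:nshell]
    amp_m = shells.shell_mean(np.abs(fm))[:nshell]
    amp_r = shells.shell_mean(np.abs(fr))[:nshell]
    sel = (freq >= 1.0 / d_low) & (freq <= 1.0 / d_high) & (amp_m > 0) & (amp_r > 0)
    if np.count_nonzero(sel) < 2:
        raise ValueError("empty Guinier fit range")
    nu2 = freq[sel] ** 2
    slope_m = np.polyfit(nu2, np.log(amp_m[sel]), 1)[0]
    slope_r = np.polyfit(nu2, np.log(amp_r[sel]), 1)[0]
    b = 4.0 * (slope_r - slope_m)
    # sharpen the (unmasked) map
    fm_full = fftc(map_.voxels)
    nu2_vox = (shells.shell / (map_.size * map_.voxel_size)) ** 2
    sharpened = RealVolume(
        np.real(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(
            fm_full * np.exp(b * nu2_vox / 4.0)), norm="ortho"))),
        map_.voxel_size)
    return float(b), sharpened
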