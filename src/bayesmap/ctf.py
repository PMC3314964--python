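"""Contrast transfer function of the microscope, isotropic and envelope-free.

The weak-phase-object CTF used throughout the package is

    CTF(ν) = -[ sqrt(1 - A²)·sin χ(ν) + A·cos χ(ν) ]
    χ(ν)   = π λ Δf ν²  -  (π/2) Cs λ³ ν⁴

with Δf the defocus in Å (underfocus positive), Cs the spherical aberration,
A the amplitude contrast fraction and λ the relativistic electron
wavelength.  The sign convention makes protein density positive in restored
maps; at ν = 0 the CTF equals -A.  No envelope decay and no astigmatism are
applied (astigmatism is a documented extension point).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["CTFParams", "electron_wavelength", "evaluate_ctf", "ctf_image"]


@dataclass(frozen=True)
class CTFParams:
    """Per-particle (per-micrograph) CTF parameters.

    defocus: Å, underfocus positive.  voltage: kV.  spherical_aberration: mm.
    amplitude_contrast: fraction in [0, 1].  pixel_size: Å/pixel.
    """

    defocus: float
    voltage: float = 200.0
    spherical_aberration: float = 2.0
    amplitude_contrast: float = 0.1
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError(f"voltage must be > 0 kV, got {self.voltage}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0 Å, got {self.pixel_size}")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError(
                f"amplitude_contrast must be in [0, 1], got {self.amplitude_contrast}")
        if self.spherical_aberration < 0:
            raise ValueError("spherical_aberration must be >= 0 mm")


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å for an accelerating voltage in kV.

    λ = 12.2639 / sqrt(V + 0.97845e-6 V²) with V in volts (h/sqrt(2 m e V)
    with the relativistic correction folded into the quadratic term).
    """
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


def evaluate_ctf(params: CTFParams, frequency: float | np.ndarray) -> float | np.ndarray:
    """CTF value at a (radial) spatial frequency in Å⁻¹.

    Vectorized over ``frequency``; values lie in [-1, 1].
    """
    nu = np.asarray(frequency, dtype=np.float64)
    if np.any(nu < 0):
        raise ValueError("frequency must be >= 0")
    lam = electron_wavelength(params.voltage)
    cs = params.spherical_aberration * 1e7  # mm -> Å
    chi = np.pi * lam * params.defocus * nu**2 - 0.5 * np.pi * cs * lam**3 * nu**4
    a = params.amplitude_contrast
    out = -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))
    if np.isscalar(frequency):
        return float(out)
    return out


@lru_cache(maxsize=256)
def _ctf_image_cached(params: CTFParams, shape: tuple) -> np.ndarray:
    axes = [np.arange(n) - n // 2 for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    d = shape[0]
    nu = np.sqrt(sum(m.astype(np.float64) ** 2 for m in mesh)) / (d * params.pixel_size)
    out = evaluate_ctf(params, nu)
    out.setflags(write=False)
    return out

def ctf_image(params: CTFParams, shape: tuple) -> np.ndarray:
    """CTF evaluated on a centered 2D Fourier grid (Friedel-symmetric by isotropy).

    Results are cached per unique (parameters, shape), i.e. per micrograph group.
    """
    return _ctf_image_cached(params, tuple(shape))
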