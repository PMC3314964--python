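"""In-memory particle stack: Fourier transforms, CTF groups, metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctf import CTFParams, ctf_image
from .fourier import RealImage, fftc, ifftc

__all__ = ["ParticleSet"]


@dataclass
class ParticleSet:
    """A stack of particle images held as centered 2D Fourier transforms.

    CTF parameters are shared within a micrograph group (all images picked
    from one micrograph); ``group_index[i]`` selects the group of particle i.
    ``metadata`` carries the tabular per-particle record (orientations,
    truth columns from the simulator, ...) and is never consulted by the
    refinement itself.
    """

    fourier: np.ndarray                 # (N, D, D) complex128
    pixel_size: float
    group_index: np.ndarray             # (N,) int
    group_ctf: list                     # [CTFParams] per group
    metadata: pd.DataFrame | None = None
    group_names: list = field(default_factory=list)
    group_ctf_images: list | None = None  # optional explicit per-group CTF arrays

    def __post_init__(self) -> None:
        self.fourier = np.asarray(self.fourier, dtype=np.complex128)
        self.group_index = np.asarray(self.group_index, dtype=np.int64)
        if not self.group_names:
            self.group_names = [f"group{i}" for i in range(len(self.group_ctf))]

    @property
    def n_particles(self) -> int:
        return self.fourier.shape[0]

    @property
    def size(self) -> int:
        return self.fourier.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_ctf)

    def ctf(self, group: int) -> np.ndarray:
        if self.group_ctf_images is not None:
            return self.group_ctf_images[group]
        return ctf_image(self.group_ctf[group], (self.size, self.size))

    def real_image(self, i: int) -> RealImage:
        return RealImage(ifftc(self.fourier[i]).real, self.pixel_size)

    @classmethod
    def from_real_images(cls, images: np.ndarray, pixel_size: float,
                         group_index: np.ndarray, group_ctf: list,
                         metadata: pd.DataFrame | None = None) -> "ParticleSet":
        four = np.stack([fftc(im) for im in np.asarray(images, dtype=np.float64)])
        return cls(four, pixel_size, group_index, group_ctf, metadata)

    def subset(self, idx: np.ndarray) -> "ParticleSet":
        idx = np.asarray(idx)
        meta = self.metadata.iloc[idx].reset_index(drop=True) if self.metadata is not None else None
        return ParticleSet(self.fourier[idx], self.pixel_size, self.group_index[idx],
                           self.group_ctf, meta, self.group_names, self.group_ctf_images)

    def random_split(self, seed: int) -> tuple["ParticleSet", "ParticleSet"]:
        """Deterministic disjoint half split (sizes ⌈N/2⌉ and ⌊N/2⌋)."""
        perm = np.random.default_rng(seed).permutation(self.n_particles)
        half = (self.n_particles + 1) // 2
        return self.subset(np.sort(perm[:half])), self.subset(np.sort(perm[half:]))
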