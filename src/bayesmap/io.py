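"""Standard-format I/O: MRC2014 maps/stacks (float32 mode 2) and the
named-column plain-text particle table.

The particle table is whitespace-free TSV with a header row; required CTF
columns are ``defocus`` (Å, underfocus positive), ``voltage`` (kV), ``cs``
(mm), ``amplitude_contrast`` and ``pixel_size`` (Å).  Optional columns:
``stack``/``slice`` (image reference, 0-based), ``group`` (micrograph
label), ``rot``/``tilt``/``psi`` (degrees), ``shift_x``/``shift_y``
(pixels), ``class``.  Unknown columns pass through unchanged; the
simulator's ground-truth columns are prefixed ``true_`` and are never read
by refinement.

MRC axis order: array axis 0 maps to MRC sections (NZ), i.e. a stack is
(n_images, ny, nx).  Volumes are written with ISPG = 1, stacks with 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctf import CTFParams
from .fourier import RealImage, RealVolume
from .particles import ParticleSet

__all__ = [
    "read_mrc",
    "write_mrc",
    "MrcStack",
    "read_table",
    "write_table",
    "particles_from_files",
    "particles_to_files",
    "write_manifest",
    "REQUIRED_CTF_COLUMNS",
]

REQUIRED_CTF_COLUMNS = ["defocus", "voltage", "cs", "amplitude_contrast", "pixel_size"]

_MAP_MAGIC = b"MAP "


@dataclass
class MrcStack:
    """A stack of 2D images read from / written to one MRC file."""

    images: np.ndarray  # (n, d, d) float
    pixel_size: float

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


def _build_header(shape: tuple, pixel_size: float, data: np.ndarray, ispg: int) -> bytes:
    nz, ny, nx = shape
    hi = np.zeros(256, dtype="<i4")
    hf = hi.view("<f4")
    hi[0:3] = (nx, ny, nz)
    hi[3] = 2  # mode 2: float32
    hi[7:10] = (nx, ny, nz)
    hf[10:13] = (nx * pixel_size, ny * pixel_size, nz * pixel_size)
    hf[13:16] = 90.0
    hi[16:19] = (1, 2, 3)
    hf[19:22] = (float(data.min()), float(data.max()), float(data.mean()))
    hi[22] = ispg
    hi[23] = 0  # nsymbt
    hi[52] = int.from_bytes(_MAP_MAGIC, "little")
    hi[53] = 0x00004144  # little-endian machine stamp
    hf[54] = float(data.std())
    hi[55] = 0
    return hi.tobytes()


def write_mrc(obj, path) -> None:
    """Write a RealVolume, RealImage, stack array (n, d, d) or MrcStack."""
    if isinstance(obj, RealVolume):
        data, pixel, ispg = obj.voxels, obj.voxel_size, 1
    elif isinstance(obj, RealImage):
        data, pixel, ispg = obj.pixels[None], obj.pixel_size, 0
    elif isinstance(obj, MrcStack):
        data, pixel, ispg = obj.images, obj.pixel_size, 0
    else:
        raise TypeError(f"write_mrc: unsupported object {type(obj)!r}")
    data = np.ascontiguousarray(data, dtype="<f4")
    if data.ndim != 3:
        raise ValueError("write_mrc expects 3D data (volume or image stack)")
    with open(path, "wb") as fh:
        fh.write(_build_header(data.shape, pixel, data, ispg))
        fh.write(data.tobytes())


def read_mrc(path):
    """Read a float32 MRC2014 file -> RealVolume (ISPG >= 1) or MrcStack."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 1024:
        raise ValueError(f"{path}: truncated MRC header ({len(raw)} bytes, need 1024)")
    hi = np.frombuffer(raw[:1024], dtype="<i4")
    hf = hi.view("<f4")
    if hi[52].tobytes() != _MAP_MAGIC:
        raise ValueError(f"{path}: bad MAP magic at byte offset 208")
    nx, ny, nz, mode = int(hi[0]), int(hi[1]), int(hi[2]), int(hi[3])
    if mode != 2:
        raise ValueError(f"{path}: unsupported MRC mode {mode} at byte offset 12 "
                         "(only float32 mode 2)")
    nsymbt = int(hi[23])
    mx = int(hi[7]) or nx
    pixel = float(hf[10]) / mx if hf[10] > 0 else 1.0
    n_vox = nx * ny * nz
    start = 1024 + nsymbt
    data = np.frombuffer(raw[start:start + 4 * n_vox], dtype="<f4")
    if data.size != n_vox:
        raise ValueError(f"{path}: truncated data block at byte offset {start}")
    data = data.reshape(nz, ny, nx).astype(np.float64)
    if int(hi[22]) >= 1:
        return RealVolume(data, pixel)
    return MrcStack(images=data, pixel_size=pixel)


# ---------------------------------------------------------------------------
# Particle metadata table
# ---------------------------------------------------------------------------

def read_table(path, require_ctf: bool = True) -> pd.DataFrame:
    """Read the named-column particle table; validates required CTF columns."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table: {err}") from err
    if require_ctf:
        missing = [c for c in REQUIRED_CTF_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required CTF columns: {', '.join(missing)}")
    for row, ok in enumerate(df.notna().all(axis=1)):
        if not ok:
            raise ValueError(f"{path}: malformed row {row} (missing values)")
    return df


def write_table(table: pd.DataFrame, path) -> None:
    """Write the table back out; unknown columns are preserved."""
    table.to_csv(path, sep="\t", index=False)


def particles_from_files(table_path, stack_path) -> ParticleSet:
    """Assemble a ParticleSet from a metadata table plus an MRC stack."""
    df = read_table(table_path)
    stack = read_mrc(stack_path)
    if isinstance(stack, RealVolume):
        raise ValueError(f"{stack_path}: expected an image stack, got a volume")
    if "slice" in df.columns:
        order = df["slice"].to_numpy(dtype=int)
    else:
        order = np.arange(len(df))
    if order.max() >= stack.n_images:
        raise ValueError(f"table references slice {order.max()} but stack has "
                         f"{stack.n_images} images")
    if "group" in df.columns:
        names, group_index = np.unique(df["group"].to_numpy(), return_inverse=True)
    else:
        names, group_index = np.array(["group0"]), np.zeros(len(df), dtype=int)
    group_ctf = []
    for gi in range(len(names)):
        row = df.iloc[int(np.flatnonzero(group_index == gi)[0])]
        group_ctf.append(CTFParams(defocus=float(row["defocus"]),
                                   voltage=float(row["voltage"]),
                                   spherical_aberration=float(row["cs"]),
                                   amplitude_contrast=float(row["amplitude_contrast"]),
                                   pixel_size=float(row["pixel_size"])))
    return ParticleSet.from_real_images(stack.images[order], stack.pixel_size,
                                        group_index, group_ctf, metadata=df)


def particles_to_files(particles: ParticleSet, table_path, stack_path) -> None:
    """Write a ParticleSet as an MRC stack plus metadata table."""
    from .fourier import ifftc
    images = np.stack([ifftc(f).real for f in particles.fourier])
    write_mrc(MrcStack(images, particles.pixel_size), stack_path)
    if particles.metadata is not None:
        df = particles.metadata.copy()
    else:
        df = pd.DataFrame({"particle": np.arange(particles.n_particles)})
    df["slice"] = np.arange(particles.n_particles)
    df["group"] = [particles.group_names[g] for g in particles.group_index]
    for name, getter in [("defocus", lambda p: p.defocus), ("voltage", lambda p: p.voltage),
                         ("cs", lambda p: p.spherical_aberration),
                         ("amplitude_contrast", lambda p: p.amplitude_contrast),
                         ("pixel_size", lambda p: p.pixel_size)]:
        df[name] = [getter(particles.group_ctf[g]) for g in particles.group_index]
    write_table(df, table_path)


def write_manifest(path, config, seed: int, outputs: dict) -> None:
    """Machine-readable run manifest: configuration + seed + outputs."""
    from dataclasses import asdict, is_dataclass

    def _clean(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: _clean(v) for k, v in asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump({"config": _clean(config), "seed": seed, "outputs": _clean(outputs)},
                  fh, indent=2, default=str)
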