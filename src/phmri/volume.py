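"""Core image containers and deterministic NIfTI-1 I/O.

A :class:`Volume4D` is a 4D BOLD series on a voxel grid with a world affine
and a repetition time; a :class:`StatMap` is a single 3D voxelwise statistic
(amplitude, t, z, r, Fisher-z). Both round-trip through NIfTI-1. Gzipped
output is written with the gzip member mtime fixed to zero so that repeated
runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume4D", "StatMap", "save_nifti", "ras_affine", "voxel_sizes_mm"]


def ras_affine(voxel_mm: tuple[float, float, float], grid_dims: tuple[int, int, int]) -> np.ndarray:
    """RAS+ affine with the world origin at the grid isocenter."""
    vx = np.asarray(voxel_mm, dtype=float)
    dims = np.asarray(grid_dims, dtype=float)
    aff = np.diag([vx[0], vx[1], vx[2], 1.0])
    aff[:3, 3] = -vx * (dims - 1) / 2.0
    return aff


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths (mm) from the affine's column norms."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def save_nifti(img: nib.Nifti1Image, path: str | Path) -> Path:
    """Write a NIfTI image; ``.gz`` paths are compressed with mtime=0.

    nibabel's own gzip writer embeds the wall-clock time in the gzip header,
    which breaks byte-level reproducibility; this helper does not.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raw = img.to_bytes()
    if path.name.endswith(".gz"):
        path.write_bytes(gzip.compress(raw, compresslevel=6, mtime=0))
    else:
        path.write_bytes(raw)
    return path


@dataclass
class Volume4D:
    """A 4D BOLD image: data indexed (x, y, z, t), world affine, and TR.

    ``time_origin_s`` is the acquisition time of frame 0 relative to the
    start of the infusion scan; dropping initial frames advances it.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    time_origin_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("Volume4D requires at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume4D data must be finite")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_mm(self) -> np.ndarray:
        return voxel_sizes_mm(self.affine)

    def frame_times(self) -> np.ndarray:
        """Acquisition time (s) of each retained frame."""
        return self.time_origin_s + self.tr_seconds * np.arange(self.n_volumes)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_xyzt_units("mm", "sec")
        zooms = list(img.header.get_zooms()[:3]) + [self.tr_seconds]
        img.header.set_zooms(zooms)
        img.header["toffset"] = self.time_origin_s
        return img

    def save(self, path: str | Path) -> Path:
        return save_nifti(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str | Path) -> "Volume4D":
        img = nib.load(str(path))
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"{path}: header does not carry a positive TR")
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            affine=img.affine,
            tr_seconds=tr,
            time_origin_s=float(img.header["toffset"]),
        )


@dataclass
class StatMap:
    """A 3D voxelwise-statistic map with provenance metadata."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"StatMap requires 3D data, got shape {self.data.shape}")

    @property
    def voxel_mm(self) -> np.ndarray:
        return voxel_sizes_mm(self.affine)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_xyzt_units("mm")
        if self.name:
            img.header["descrip"] = self.name.encode()[:79]
        return img

    def save(self, path: str | Path) -> Path:
        return save_nifti(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str | Path, name: str = "") -> "StatMap":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.dataobj, dtype=float), affine=img.affine, name=name)
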