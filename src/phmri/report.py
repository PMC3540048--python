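"""Cluster tables: connected components of suprathreshold maps.

Turns a detection mask plus its z map into the tabular form standard in
neuroimaging reports: one row per connected component with laterality
(from the world x of the peak: right/left/bilateral-midline), peak z,
peak coordinates in mm, and cluster volume in cm³.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from skimage import measure

from .volume import StatMap, voxel_sizes_mm

__all__ = ["ClusterRecord", "label_clusters", "cluster_volume", "write_cluster_table", "read_cluster_table"]

#: Peaks within ±2 mm of the midline are reported as bilateral ("B").
MIDLINE_BAND_MM = 2.0

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterRecord:
    cluster_id: int
    laterality: Literal["L", "R", "B"]
    peak_z: float
    peak_xyz_mm: tuple[float, float, float]
    n_voxels: int
    volume_cm3: float
    sign: Literal["increased", "decreased"]
    region: str = ""


def cluster_volume(n_voxels: int, voxel_mm: tuple[float, float, float]) -> float:
    """Cluster volume in cm³: n_voxels × voxel volume (mm³) / 1000, exactly."""
    if n_voxels < 0:
        raise ValueError("n_voxels must be nonnegative")
    return n_voxels * float(np.prod(voxel_mm)) / 1000.0


def _laterality(x_mm: float) -> str:
    if x_mm > MIDLINE_BAND_MM:
        return "R"
    if x_mm < -MIDLINE_BAND_MM:
        return "L"
    return "B"


def label_clusters(
    mask: np.ndarray,
    zmap: StatMap,
    connectivity: int = 26,
    label_volume: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
) -> list[ClusterRecord]:
    """Connected components of the mask, each summarized at its |z| peak.

    Components use the requested voxel adjacency (6 faces / 18 +edges /
    26 +corners; default 26, the usual reporting convention). The peak is
    the in-cluster voxel with maximal |z|, ties broken by lowest linear
    (C-raster) index; its world coordinates come from the z map's affine
    and set the laterality. An optional integer label volume plus name map
    fills the region column from the peak voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != zmap.data.shape:
        raise ValueError("mask and z map grids differ")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    if not mask.any():
        return []
    labeled = measure.label(mask, connectivity=_CONNECTIVITY_RANK[connectivity])
    voxel_mm = tuple(voxel_sizes_mm(zmap.affine))
    records: list[ClusterRecord] = []
    flat_z = zmap.data.reshape(-1)
    for cid in range(1, labeled.max() + 1):
        lin_idx = np.flatnonzero((labeled == cid).reshape(-1))  # ascending linear index
        absz = np.abs(flat_z[lin_idx])
        peak_lin = lin_idx[int(np.argmax(absz))]  # first max -> lowest linear index
        peak_ijk = np.unravel_index(peak_lin, mask.shape)
        peak_z = float(flat_z[peak_lin])
        world = zmap.affine @ np.array([*peak_ijk, 1.0])
        region = ""
        if label_volume is not None:
            code = int(np.asarray(label_volume)[peak_ijk])
            region = (label_names or {}).get(code, str(code) if code else "")
        records.append(
            ClusterRecord(
                cluster_id=cid,
                laterality=_laterality(float(world[0])),
                peak_z=peak_z,
                peak_xyz_mm=(float(world[0]), float(world[1]), float(world[2])),
                n_voxels=int(lin_idx.size),
                volume_cm3=cluster_volume(int(lin_idx.size), voxel_mm),
                sign="increased" if peak_z >= 0 else "decreased",
                region=region,
            )
        )
    return records


_COLUMNS = ["Region", "Lat", "Z_stat", "x_mm", "y_mm", "z_mm", "n_voxels", "Volume_cm3", "sign"]


def write_cluster_table(records: list[ClusterRecord], path: str | Path) -> Path:
    """Write records as a TSV, increased rows first, then by peak y descending."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "Region": r.region,
            "Lat": r.laterality,
            "Z_stat": r.peak_z,
            "x_mm": r.peak_xyz_mm[0],
            "y_mm": r.peak_xyz_mm[1],
            "z_mm": r.peak_xyz_mm[2],
            "n_voxels": r.n_voxels,
            "Volume_cm3": r.volume_cm3,
            "sign": r.sign,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if len(df):
        df["_sign_rank"] = (df["sign"] == "decreased").astype(int)
        df = df.sort_values(["_sign_rank", "y_mm"], ascending=[True, False], kind="mergesort")
        df = df.drop(columns="_sign_rank")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
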