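"""Paired group-level contrast between the two drug conditions.

Each subject contributes one amplitude (or Fisher-z connectivity) map per
condition of the crossover; inference is a voxelwise paired t test on the
within-subject differences, reported as z maps for both contrast
directions (A>B and B>A). This is the classical random-effects paired
design; the two directional maps are exact negatives of one another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .infusion_glm import Z_CLIP, t_to_z
from .volume import StatMap

__all__ = ["PairedGroupResult", "paired_contrast"]


@dataclass
class PairedGroupResult:
    mean_diff: StatMap
    zstat_AgtB: StatMap
    zstat_BgtA: StatMap
    n_pairs: int
    dof: int


def _as_stack(maps: Sequence[StatMap | np.ndarray]) -> tuple[np.ndarray, np.ndarray | None]:
    arrays, affine = [], None
    for m in maps:
        if isinstance(m, StatMap):
            arrays.append(m.data)
            if affine is None:
                affine = m.affine
            elif not np.allclose(affine, m.affine):
                raise ValueError("maps are not on aligned grids")
        else:
            arrays.append(np.asarray(m, dtype=float))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched grids: {sorted(shapes)}")
    return np.stack(arrays, axis=0), affine


def paired_contrast(
    amps_A: Sequence[StatMap | np.ndarray],
    amps_B: Sequence[StatMap | np.ndarray],
    mask: np.ndarray,
) -> PairedGroupResult:
    """Voxelwise paired t test of condition A versus condition B.

    Per voxel the paired differences ``d_i = A_i - B_i`` give
    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``n - 1`` degrees of freedom,
    mapped to z. Voxels where sd(d) = 0 get z = ±8 (0 if the mean difference
    is also 0) with a warning.
    """
    if len(amps_A) != len(amps_B):
        raise ValueError("condition lists must have equal length (paired design)")
    n = len(amps_A)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    A, affine = _as_stack(amps_A)
    B, affine_b = _as_stack(amps_B)
    if affine is None:
        affine = affine_b if affine_b is not None else np.eye(4)
    if A.shape != B.shape:
        raise ValueError("condition stacks have mismatched grids")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != A.shape[1:]:
        raise ValueError("mask grid does not match maps")

    d = A[:, mask] - B[:, mask]
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    dof = n - 1

    z = np.empty_like(mean_d)
    ok = sd_d > 0
    z[ok] = t_to_z(mean_d[ok] / (sd_d[ok] / np.sqrt(n)), dof)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} voxels had zero paired-difference variance; z set to ±{Z_CLIP:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        z[~ok] = np.sign(mean_d[~ok]) * Z_CLIP

    def _full(values: np.ndarray, name: str) -> StatMap:
        out = np.zeros(mask.shape)
        out[mask] = values
        return StatMap(out, affine, name=name, meta={"n_pairs": n, "dof": dof})

    zmap = _full(z, "paired z A>B")
    return PairedGroupResult(
        mean_diff=_full(mean_d, "paired mean difference A-B"),
        zstat_AgtB=zmap,
        zstat_BgtA=StatMap(-zmap.data, affine, name="paired z B>A", meta={"n_pairs": n, "dof": dof}),
        n_pairs=n,
        dof=dof,
    )
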