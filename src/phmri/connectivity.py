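"""Seed-based partial-correlation functional connectivity.

Connectivity is computed on the final steady-state window of the infusion
scan (default 5 minutes), when the drug effect has plateaued: each voxel's
partial correlation with the seed-region mean timecourse, given linear
drift and the mean WM and CSF timecourses as nuisance covariates. The
correlation maps are variance-stabilized with the Fisher z-transform
(atanh) before paired group inference, which reuses the paired t contrast
and the MRF-regularized mixture engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .group_contrast import PairedGroupResult, paired_contrast
from .mrf_ppm import MixtureFit, icm_fit, threshold_ppm
from .preprocess import mean_timecourse
from .volume import StatMap, Volume4D

__all__ = [
    "SeedROI",
    "FcMap",
    "FcGroupResult",
    "last_window",
    "seed_timecourse",
    "build_fc_nuisance",
    "partial_correlation_map",
    "group_fc_contrast",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class SeedROI:
    """A named seed region supplied as a boolean mask on the analysis grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"seed ROI {self.name!r} is empty")


@dataclass
class FcMap:
    """Voxelwise seed connectivity: raw r and Fisher z, with fit metadata."""

    r: StatMap
    fisher_z: StatMap
    n_timepoints: int
    n_nuisance: int
    flagged: np.ndarray | None = None


@dataclass
class FcGroupResult:
    paired: PairedGroupResult
    fit: MixtureFit | None
    mask_AgtB: np.ndarray
    mask_BgtA: np.ndarray


def last_window(vol: Volume4D, minutes: float = 5.0) -> Volume4D:
    """Keep the final ``floor(minutes*60/TR)`` frames of the scan."""
    n_frames = int(np.floor(minutes * 60.0 / vol.tr_seconds))
    if n_frames < 2:
        raise ValueError("window must contain at least 2 frames")
    if n_frames > vol.n_volumes:
        raise ValueError(
            f"window of {n_frames} frames exceeds scan length {vol.n_volumes}"
        )
    start = vol.n_volumes - n_frames
    return Volume4D(
        data=vol.data[..., start:].copy(),
        affine=vol.affine,
        tr_seconds=vol.tr_seconds,
        time_origin_s=vol.time_origin_s + start * vol.tr_seconds,
    )


def seed_timecourse(vol: Volume4D, roi: SeedROI) -> np.ndarray:
    """Mean timecourse over the seed ROI voxels."""
    return mean_timecourse(vol, roi.mask)


def build_fc_nuisance(n_frames: int, wm_tc: np.ndarray, csf_tc: np.ndarray) -> np.ndarray:
    """Intercept + mean-centered linear drift + mean-centered WM/CSF covariates.

    The drift is recomputed on the analysis window — the window is the
    analysis unit, so nuisance centering happens within it.
    """
    wm_tc = np.asarray(wm_tc, dtype=float)
    csf_tc = np.asarray(csf_tc, dtype=float)
    if wm_tc.shape != (n_frames,) or csf_tc.shape != (n_frames,):
        raise ValueError("nuisance timecourse length mismatch")
    drift = np.arange(n_frames, dtype=float)
    return np.column_stack(
        [np.ones(n_frames), drift - drift.mean(), wm_tc - wm_tc.mean(), csf_tc - csf_tc.mean()]
    )


def _has_intercept(nuisance: np.ndarray) -> bool:
    ones = np.ones(nuisance.shape[0])
    coef, *_ = np.linalg.lstsq(nuisance, ones, rcond=None)
    return bool(np.linalg.norm(ones - nuisance @ coef) < 1e-8 * np.sqrt(nuisance.shape[0]))


def partial_correlation_map(
    vol: Volume4D, seed_tc: np.ndarray, nuisance: np.ndarray, mask: np.ndarray
) -> FcMap:
    """Partial correlation of every in-mask voxel with the seed timecourse.

    Both the voxel series and the seed series are residualized against the
    nuisance matrix (which must span the intercept) by least squares; r is
    the Pearson correlation of the residuals, clipped to |r| <= 1 - 1e-7
    before the Fisher transform. Voxels with zero residual variance are
    flagged and set to r = 0.
    """
    seed_tc = np.asarray(seed_tc, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = vol.n_volumes
    if seed_tc.shape != (n,):
        raise ValueError("seed timecourse length mismatch")
    if nuisance.shape[0] != n:
        raise ValueError("nuisance rows do not match the number of frames")
    if not _has_intercept(nuisance):
        raise ValueError("nuisance matrix must include an intercept")

    Q, _ = np.linalg.qr(nuisance)
    seed_res = seed_tc - Q @ (Q.T @ seed_tc)
    Y = vol.data[mask].T  # n x V
    Y_res = Y - Q @ (Q.T @ Y)

    seed_norm = np.linalg.norm(seed_res)
    vox_norm = np.linalg.norm(Y_res, axis=0)
    degenerate_seed = seed_norm == 0
    flagged = (vox_norm == 0) | degenerate_seed
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Y_res.T @ seed_res) / (vox_norm * seed_norm)
    r[flagged] = 0.0
    clipped = np.abs(r) > R_CLIP
    r_c = np.clip(r, -R_CLIP, R_CLIP)
    flagged = flagged | clipped
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} voxels had degenerate or |r|=1 residual correlations",
            RuntimeWarning,
            stacklevel=2,
        )

    def _full(values: np.ndarray, name: str) -> StatMap:
        out = np.zeros(mask.shape)
        out[mask] = values
        return StatMap(out, vol.affine, name=name)

    flag_map = np.zeros(mask.shape, dtype=bool)
    flag_map[mask] = flagged
    return FcMap(
        r=_full(r_c, "seed partial correlation"),
        fisher_z=_full(np.arctanh(r_c), "seed partial correlation (Fisher z)"),
        n_timepoints=n,
        n_nuisance=nuisance.shape[1] - 1,  # conditioned regressors, intercept excluded
        flagged=flag_map,
    )


def group_fc_contrast(
    fc_A: Sequence[FcMap],
    fc_B: Sequence[FcMap],
    mask: np.ndarray,
    ppm_threshold: float = 0.5,
    max_sweeps: int = 50,
) -> FcGroupResult:
    """Paired contrast of Fisher-z connectivity maps plus MRF-PPM inference.

    The per-subject Fisher-z maps enter the paired t contrast; the resulting
    A>B z map is fed to the mixture/MRF engine, and the activation and
    deactivation PPMs (the two contrast directions) are thresholded at the
    strict PPM > 0.5 rule.
    """
    z_A = [m.fisher_z for m in fc_A]
    z_B = [m.fisher_z for m in fc_B]
    paired = paired_contrast(z_A, z_B, mask)
    mask = np.asarray(mask, dtype=bool)
    if np.ptp(paired.zstat_AgtB.data[mask]) == 0:
        # degenerate contrast (e.g. identical conditions): nothing to detect
        empty = np.zeros(mask.shape, dtype=bool)
        return FcGroupResult(paired=paired, fit=None, mask_AgtB=empty, mask_BgtA=empty.copy())
    fit = icm_fit(paired.zstat_AgtB, mask, max_sweeps=max_sweeps)
    return FcGroupResult(
        paired=paired,
        fit=fit,
        mask_AgtB=threshold_ppm(fit.ppm_act, ppm_threshold),
        mask_BgtA=threshold_ppm(fit.ppm_deact, ppm_threshold),
    )
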