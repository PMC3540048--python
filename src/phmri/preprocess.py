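"""Non-registration preprocessing for infusion BOLD series.

Implements the steps that act on an already-aligned 4D dataset: removal of
initial dummy volumes, isotropic Gaussian spatial smoothing, grand-mean
intensity normalization by a single multiplicative factor, and mean
timecourse extraction over tissue masks. There is deliberately no temporal
(high-pass) filter anywhere in this module: the infusion response of
interest is itself a low-frequency signal and would be destroyed by one.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Volume4D

__all__ = [
    "drop_initial_volumes",
    "smooth_gaussian",
    "grand_mean_normalize",
    "mean_timecourse",
    "fwhm_to_sigma",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel.
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian full-width-at-half-maximum to its standard deviation."""
    return fwhm_mm / _FWHM_FACTOR


def drop_initial_volumes(vol: Volume4D, n: int = 2) -> Volume4D:
    """Remove the first `n` frames (MR signal stabilization dummies).

    The time origin advances by ``n * tr_seconds`` so that downstream
    regressors are sampled at the true acquisition times.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= vol.n_volumes:
        raise ValueError(f"cannot drop {n} of {vol.n_volumes} volumes")
    return Volume4D(
        data=vol.data[..., n:].copy(),
        affine=vol.affine,
        tr_seconds=vol.tr_seconds,
        time_origin_s=vol.time_origin_s + n * vol.tr_seconds,
    )


def smooth_gaussian(vol: Volume4D, fwhm_mm: float = 5.0) -> Volume4D:
    """Spatially smooth each frame with an isotropic Gaussian of given FWHM.

    The kernel sd is ``fwhm / (2*sqrt(2 ln 2))`` millimetres, converted to
    voxel units per axis from the affine, so anisotropic voxels get the
    correct per-axis sigma. Reflecting (half-sample symmetric) boundaries
    preserve the spatial mean of each frame. ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return Volume4D(vol.data.copy(), vol.affine, vol.tr_seconds, vol.time_origin_s)
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigma_vox = sigma_mm / vol.voxel_mm
    smoothed = ndimage.gaussian_filter(vol.data, sigma=(*sigma_vox, 0.0), mode="reflect")
    return Volume4D(smoothed, vol.affine, vol.tr_seconds, vol.time_origin_s)


def grand_mean_normalize(
    vol: Volume4D, target: float = 10000.0, mask: np.ndarray | None = None
) -> Volume4D:
    """Scale the entire 4D dataset by one multiplicative factor.

    The factor brings the grand mean — the mean over all in-mask voxels and
    all timepoints — to `target`. The mask should be a brain mask: including
    background zeros would distort the multiplier.
    """
    if mask is None:
        sel = vol.data
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.data.shape[:3]:
            raise ValueError("mask grid does not match volume grid")
        if not mask.any():
            raise ValueError("mask is empty")
        sel = vol.data[mask]
    grand_mean = float(sel.mean())
    if grand_mean <= 0:
        raise ValueError(f"grand mean must be positive, got {grand_mean}")
    factor = target / grand_mean
    return Volume4D(vol.data * factor, vol.affine, vol.tr_seconds, vol.time_origin_s)


def mean_timecourse(vol: Volume4D, mask: np.ndarray) -> np.ndarray:
    """Per-frame arithmetic mean over the mask voxels (e.g. WM or CSF average)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.data.shape[:3]:
        raise ValueError("mask grid does not match volume grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return vol.data[mask].mean(axis=0)
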