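"""Single-subject infusion-response GLM.

The expected drug response ("infusion EV") is a ramped unit step: zero
during the 5-minute pretreatment baseline, a linear ramp from 5 to 13
minutes while the drug is delivered in divided boluses, and a plateau
thereafter. It is deliberately not convolved with a hemodynamic response
function — the infusion response evolves over minutes, far slower than the
HRF. The voxelwise statistic of interest is the fitted EV coefficient
("amplitude").

Because the true ramp onset varies with local pharmacodynamics, the design
includes data-independent onset-uncertainty regressors: the top left
singular vectors of a family of onset-shifted ramps residualized against
the nominal EV and the intercept. They absorb onset mismatch without biasing
the amplitude estimate. Linear drift and the subject's mean WM and CSF
timecourses enter as covariates of no interest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import StatMap, Volume4D

__all__ = [
    "InfusionDesign",
    "DesignMatrix",
    "SubjectGLMResult",
    "build_infusion_ev",
    "build_svd_onset_regressors",
    "assemble_design",
    "fit_voxelwise_glm",
    "t_to_z",
    "DEFAULT_ONSET_SHIFTS_S",
]

logger = logging.getLogger(__name__)

BASELINE_END_S = 300.0
RAMP_END_S = 780.0

#: Onset-shift family for the uncertainty regressors: ±60 s in 15 s steps.
DEFAULT_ONSET_SHIFTS_S: tuple[float, ...] = tuple(float(s) for s in range(-60, 75, 15))

Z_CLIP = 8.0


@dataclass(frozen=True)
class InfusionDesign:
    """The sampled infusion EV and its breakpoints."""

    sampled_ev: np.ndarray
    times_s: np.ndarray
    baseline_end_s: float = BASELINE_END_S
    ramp_end_s: float = RAMP_END_S

    def __post_init__(self) -> None:
        ev = np.asarray(self.sampled_ev)
        if ev.min() < 0 or ev.max() > 1 or np.any(np.diff(ev) < 0):
            raise ValueError("infusion EV must be nondecreasing within [0, 1]")


def _ramp_at(times_s: np.ndarray, baseline_end_s: float, ramp_end_s: float) -> np.ndarray:
    return np.clip((np.asarray(times_s, dtype=float) - baseline_end_s) / (ramp_end_s - baseline_end_s), 0.0, 1.0)


def build_infusion_ev(
    n_frames: int,
    tr_seconds: float,
    time_origin_s: float = 0.0,
    baseline_end_s: float = BASELINE_END_S,
    ramp_end_s: float = RAMP_END_S,
) -> InfusionDesign:
    """Sample the ramp/plateau EV at frame times ``time_origin + i*TR``.

    Value is 0 for t <= baseline end, (t - 300)/480 on the ramp, 1 from the
    ramp end onward. ``time_origin_s`` accounts for dropped initial frames.
    """
    times = time_origin_s + tr_seconds * np.arange(n_frames)
    if times[-1] < baseline_end_s:
        raise ValueError("scan ends before the infusion ramp starts")
    ev = _ramp_at(times, baseline_end_s, ramp_end_s)
    return InfusionDesign(sampled_ev=ev, times_s=times, baseline_end_s=baseline_end_s, ramp_end_s=ramp_end_s)


def build_svd_onset_regressors(
    n_frames: int,
    tr_seconds: float,
    time_origin_s: float = 0.0,
    onset_shifts_s: tuple[float, ...] = DEFAULT_ONSET_SHIFTS_S,
    k: int = 3,
) -> np.ndarray:
    """Top-k singular directions of the onset-shifted ramp family.

    Each shifted ramp is residualized against span{nominal EV, intercept};
    the returned ``n_frames x k`` columns are orthonormal and orthogonal to
    both by construction, so adding them never changes the amplitude fitted
    to data generated with the nominal onset.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k >= len(onset_shifts_s):
        raise ValueError("k must be smaller than the number of onset shifts")
    times = time_origin_s + tr_seconds * np.arange(n_frames)
    nominal = _ramp_at(times, BASELINE_END_S, RAMP_END_S)
    if k == 0:
        return np.empty((n_frames, 0))
    family = np.column_stack([_ramp_at(times, BASELINE_END_S + s, RAMP_END_S + s) for s in onset_shifts_s])
    basis, _ = np.linalg.qr(np.column_stack([np.ones(n_frames), nominal]))
    resid = family - basis @ (basis.T @ family)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    if s[k - 1] <= 1e-10 * max(s[0], 1e-300):
        raise ValueError(f"k={k} exceeds the numerical rank of the residual onset family")
    return u[:, :k]


@dataclass
class DesignMatrix:
    """Named GLM regressors, one row per retained frame."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns lying (numerically) in the span of the others."""
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        col = X[:, j]
        scale = np.linalg.norm(col)
        if scale == 0:
            bad.append(names[j])
            continue
        coef, *_ = np.linalg.lstsq(others, col, rcond=None)
        if np.linalg.norm(col - others @ coef) < 1e-8 * scale:
            bad.append(names[j])
    return bad


def assemble_design(
    ev: InfusionDesign,
    svd: np.ndarray | None = None,
    wm_tc: np.ndarray | None = None,
    csf_tc: np.ndarray | None = None,
) -> DesignMatrix:
    """Stack infusion EV, onset regressors, drift, WM/CSF covariates, intercept.

    Drift is a mean-centered linear trend; WM/CSF covariates are mean
    centered so the intercept keeps its interpretation. Raises on a rank
    deficient design, naming the collinear columns.
    """
    n = len(ev.sampled_ev)
    cols = [ev.sampled_ev]
    names = ["infusion_ev"]
    if svd is not None and svd.size:
        if svd.shape[0] != n:
            raise ValueError("svd regressor length mismatch")
        for j in range(svd.shape[1]):
            cols.append(svd[:, j])
            names.append(f"svd_{j + 1}")
    drift = np.arange(n, dtype=float)
    cols.append(drift - drift.mean())
    names.append("drift")
    for name, tc in (("wm", wm_tc), ("csf", csf_tc)):
        if tc is not None:
            tc = np.asarray(tc, dtype=float)
            if tc.shape != (n,):
                raise ValueError(f"{name} timecourse length mismatch")
            cols.append(tc - tc.mean())
            names.append(name)
    cols.append(np.ones(n))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    cond = np.linalg.cond(X)
    logger.info("design matrix: %d rows, %d columns, condition number %.3g", n, X.shape[1], cond)
    return DesignMatrix(matrix=X, names=names)


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to z scores by matching tail quantiles.

    Symmetric (odd) and monotone; computed through the survival function so
    large statistics do not saturate prematurely. Clipped at |z| = 8, beyond
    any plausible inference boundary.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), dof))
    z = np.where(np.isnan(z) & np.isnan(t), np.nan, z)
    return np.clip(z, -Z_CLIP, Z_CLIP)


@dataclass
class SubjectGLMResult:
    """Voxelwise infusion-EV amplitude, its standard error, and z statistic."""

    amplitude: StatMap
    se: StatMap
    zstat: StatMap
    dof: int


def fit_voxelwise_glm(vol: Volume4D, design: DesignMatrix, mask: np.ndarray) -> SubjectGLMResult:
    """Ordinary least squares per in-mask voxel; Gaussian-noise inference.

    The amplitude map holds the infusion-EV coefficient; its standard error
    comes from the residual variance with ``dof = n - rank(X)``; z maps are
    the t statistics pushed through the quantile-matching t-to-z transform.
    Voxels with zero residual variance get se = 0 and z = ±8 with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if design.n_rows != vol.n_volumes:
        raise ValueError("design rows do not match the number of frames")
    if mask.shape != vol.data.shape[:3]:
        raise ValueError("mask grid does not match volume grid")
    X = design.matrix
    n, p = X.shape
    dof = n - np.linalg.matrix_rank(X)
    Y = vol.data[mask].T  # n x V
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    i_ev = design.names.index("infusion_ev")
    amp = beta[i_ev]
    se = np.sqrt(sigma2 * xtx_inv[i_ev, i_ev])

    z = np.empty_like(amp)
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z[ok] = t_to_z(amp[ok] / se[ok], dof)
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} voxels had zero residual variance; z set to ±{Z_CLIP:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        z[~ok] = np.sign(amp[~ok]) * Z_CLIP

    def _full(values: np.ndarray, name: str) -> StatMap:
        out = np.zeros(mask.shape)
        out[mask] = values
        return StatMap(out, vol.affine, name=name, meta={"dof": dof})

    return SubjectGLMResult(
        amplitude=_full(amp, "infusion amplitude"),
        se=_full(se, "amplitude se"),
        zstat=_full(z, "infusion zstat"),
        dof=dof,
    )
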