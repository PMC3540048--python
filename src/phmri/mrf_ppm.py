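"""Spatially regularized Gaussian-mixture inference on z maps.

Instead of null-hypothesis thresholding, a z-statistic map is modelled as a
K = 3 class Gaussian mixture (deactivated / null / activated) whose class
labels carry a Markov-random-field soft-max prior: a voxel's prior class
probability is

    p_k(v) ∝ pi_k * exp(beta * m_k(v)),

where m_k(v) counts the voxel's 6-connected in-mask neighbors currently
labelled k and beta >= 0 is the spatial coupling strength. Labels and
parameters are estimated by iterated conditional modes (ICM): greedy
per-voxel label updates in raster order, maximum-likelihood parameter
updates from the hard labels, and a Besag pseudo-likelihood update of beta
by bounded 1-D search. The result is a posterior probability map (PPM) of
activation per voxel, conditioned on the neighboring labels and the data,
thresholded at the strict rule PPM > 0.5.

Three classes are used because infusion contrasts show both signal
increases and decreases; a two-class model cannot represent that output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import minimize_scalar

from .volume import StatMap

__all__ = [
    "MixtureFit",
    "init_mixture",
    "neighbor_prior",
    "icm_fit",
    "compute_ppm",
    "threshold_ppm",
]

#: Class indices, ordered by mean.
DEACT, NULL, ACT = 0, 1, 2
SIGMA_FLOOR = 0.05
BETA_MAX = 5.0

_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]



@dataclass
class MixtureFit:
    """State of the 3-class mixture + MRF model on one z map.

    ``labels`` holds class indices (0 deactivated, 1 null, 2 activated)
    inside the mask and -1 outside. ``active`` flags classes that still own
    voxels; a collapsed class keeps its slot with weight 0 so indices stay
    stable.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    mrf_beta: float
    labels: np.ndarray
    mask: np.ndarray
    active: np.ndarray
    ppm_act: np.ndarray | None = None
    ppm_deact: np.ndarray | None = None
    n_icm_sweeps: int = 0
    converged: bool = False
    objective_history: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return int(self.active.sum())

    def params_dict(self) -> dict:
        return {
            "class_names": ["deactivated", "null", "activated"],
            "means": [float(x) for x in self.means],
            "sds": [float(x) for x in self.sds],
            "weights": [float(x) for x in self.weights],
            "active": [bool(x) for x in self.active],
            "mrf_beta": float(self.mrf_beta),
            "n_icm_sweeps": int(self.n_icm_sweeps),
            "converged": bool(self.converged),
        }

    def save_params(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.params_dict(), fh, sort_keys=True)


def _robust_stats(z: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based sd: robust to heavy activation tails."""
    med = float(np.median(z))
    mad = float(np.median(np.abs(z - med)))
    return med, max(1.4826 * mad, SIGMA_FLOOR)


def init_mixture(zmap: StatMap | np.ndarray, mask: np.ndarray) -> MixtureFit:
    """Moment-based initialization of the 3-class mixture.

    The null class starts at the median and MAD-derived sd of the in-mask z
    values (robust to activation tails); the activated and deactivated classes sit
    at ±(2 + null sd) around the null mean with sd 1 and mixing 0.05 each.
    Labels start at the nearest class mean; spatial coupling starts at 0.
    """
    data = zmap.data if isinstance(zmap, StatMap) else np.asarray(zmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    z = data[mask]
    if z.size < 50:
        raise ValueError(f"need at least 50 in-mask voxels, got {z.size}")
    if np.ptp(z) == 0:
        raise ValueError("z map is constant within the mask; mixture fit is degenerate")
    m0, s0 = _robust_stats(z)
    means = np.array([m0 - (2.0 + s0), m0, m0 + (2.0 + s0)])
    sds = np.array([1.0, s0, 1.0])
    weights = np.array([0.05, 0.90, 0.05])
    labels = np.full(mask.shape, -1, dtype=np.int8)
    labels[mask] = np.argmin(np.abs(z[:, None] - means[None, :]), axis=1)
    return MixtureFit(
        means=means,
        sds=sds,
        weights=weights,
        mrf_beta=0.0,
        labels=labels,
        mask=mask,
        active=np.ones(3, dtype=bool),
    )


def _neighbor_counts(labels: np.ndarray, mask: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """m_k(v): per-voxel count of 6-connected in-mask neighbors with label k."""
    counts = np.zeros((n_classes,) + labels.shape)
    for k in range(n_classes):
        is_k = ((labels == k) & mask).astype(float)
        acc = np.zeros(labels.shape)
        for dx, dy, dz in _OFFSETS:
            shifted = np.zeros_like(is_k)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            for ax, d in enumerate((dx, dy, dz)):
                if d == 1:
                    src[ax], dst[ax] = slice(0, -1), slice(1, None)
                elif d == -1:
                    src[ax], dst[ax] = slice(1, None), slice(0, -1)
            shifted[tuple(dst)] = is_k[tuple(src)]
            acc += shifted
        counts[k] = acc
    return counts


def neighbor_prior(fit: MixtureFit, labels: np.ndarray | None = None) -> np.ndarray:
    """Soft-max label prior p_k ∝ pi_k · exp(beta · m_k), per voxel.

    Returns a (3, X, Y, Z) array normalized over the active classes inside
    the mask; with beta = 0 it reduces to the global mixing proportions.
    """
    labels = fit.labels if labels is None else labels
    m = _neighbor_counts(labels, fit.mask)
    logp = np.where(fit.active[:, None, None, None], np.log(np.maximum(fit.weights, 1e-300))[:, None, None, None], -np.inf)
    logp = logp + fit.mrf_beta * m
    logp -= logp.max(axis=0, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=0, keepdims=True)
    p[:, ~fit.mask] = 0.0
    return p


def _log_likelihoods(z: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """(V, 3) Gaussian log-likelihoods of in-mask z values; -inf for collapsed classes."""
    ll = np.full((z.size, 3), -np.inf)
    for k in range(3):
        if fit.active[k]:
            ll[:, k] = stats.norm.logpdf(z, fit.means[k], fit.sds[k])
    return ll


def _joint_objective(
    z: np.ndarray,
    labels_flat: np.ndarray,
    fit: MixtureFit,
    neighbor_idx: np.ndarray,
) -> float:
    """Joint pseudo-posterior: Σ log pi + beta·(# same-label edges) + Σ log N."""
    ll = _log_likelihoods(z, fit)
    v = np.arange(z.size)
    obj = float(np.log(np.maximum(fit.weights, 1e-300))[labels_flat].sum() + ll[v, labels_flat].sum())
    same = 0
    for j in range(neighbor_idx.shape[1]):
        nb = neighbor_idx[:, j]
        valid = nb >= 0
        same += int((labels_flat[valid] == labels_flat[nb[valid]]).sum())
    obj += fit.mrf_beta * same / 2.0  # each edge counted twice
    return obj


def _build_neighbor_index(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raster-ordered in-mask voxel list and their 6-neighbor positions.

    Returns (coords (V,3), neighbor_idx (V,6)) where neighbor_idx holds the
    position of each neighbor in the voxel list, or -1 if absent/out of mask.
    """
    coords = np.argwhere(mask)  # argwhere is C-raster (row-major) ordered
    pos = np.full(mask.shape, -1, dtype=np.int64)
    pos[tuple(coords.T)] = np.arange(coords.shape[0])
    nbr = np.full((coords.shape[0], 6), -1, dtype=np.int64)
    dims = mask.shape
    for j, (dx, dy, dz) in enumerate(_OFFSETS):
        shifted = coords + np.array([dx, dy, dz])
        ok = np.all((shifted >= 0) & (shifted < np.array(dims)), axis=1)
        nbr[ok, j] = pos[tuple(shifted[ok].T)]
    return coords, nbr


def _update_parameters(z: np.ndarray, labels_flat: np.ndarray, fit: MixtureFit) -> None:
    """ML update of means/sds/weights from the hard labels; collapse guard."""
    total = z.size
    for k in range(3):
        if not fit.active[k]:
            continue
        members = z[labels_flat == k]
        if members.size == 0:
            fit.active[k] = False
            fit.weights[k] = 0.0
            warnings.warn(
                f"mixture class {k} lost all members and was removed", RuntimeWarning, stacklevel=3
            )
            continue
        fit.means[k] = members.mean()
        fit.sds[k] = max(members.std(), SIGMA_FLOOR)
        fit.weights[k] = members.size / total
    wsum = fit.weights[fit.active].sum()
    fit.weights[fit.active] /= wsum
    fit.weights[~fit.active] = 0.0


def _update_beta(fit: MixtureFit, labels_flat: np.ndarray, neighbor_idx: np.ndarray) -> float:
    """Maximize the Besag pseudo-likelihood of the label field over beta ∈ [0, 5]."""
    V = labels_flat.size
    m = np.zeros((V, 3))
    for j in range(neighbor_idx.shape[1]):
        nb = neighbor_idx[:, j]
        valid = nb >= 0
        nl = labels_flat[nb[valid]]
        for k in range(3):
            m[valid, k] += nl == k
    logw = np.where(fit.active, np.log(np.maximum(fit.weights, 1e-300)), -np.inf)
    m_own = m[np.arange(V), labels_flat]
    logw_own = logw[labels_flat]

    def neg_pl(beta: float) -> float:
        scores = logw[None, :] + beta * m  # (V, 3)
        mx = scores.max(axis=1)
        logZ = mx + np.log(np.exp(scores - mx[:, None]).sum(axis=1))
        return -float((logw_own + beta * m_own - logZ).sum())

    res = minimize_scalar(neg_pl, bounds=(0.0, BETA_MAX), method="bounded", options={"xatol": 1e-3})
    return float(res.x)


def icm_fit(
    zmap: StatMap | np.ndarray,
    mask: np.ndarray,
    max_sweeps: int = 50,
    tol: float = 1e-4,
    init: MixtureFit | None = None,
    mrf_beta: float | None = None,
) -> MixtureFit:
    """Fit the mixture + MRF by iterated conditional modes.

    Each sweep (a) updates labels greedily in raster order — every voxel
    takes the class maximizing ``neighbor_prior × Gaussian likelihood`` —
    then (b) re-estimates class parameters from the hard labels and (c)
    re-estimates beta by pseudo-likelihood unless ``mrf_beta`` pins it.
    Stops when a sweep changes no label (and beta has stabilized to `tol`)
    or after ``max_sweeps``. The joint pseudo-posterior is recorded before
    and after every label sweep; at fixed parameters a sweep can only
    increase it, which is asserted.
    """
    data = zmap.data if isinstance(zmap, StatMap) else np.asarray(zmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    fit = init if init is not None else init_mixture(data, mask)
    if mrf_beta is not None:
        fit.mrf_beta = float(mrf_beta)

    coords, neighbor_idx = _build_neighbor_index(mask)
    z = data[mask]  # argwhere raster order matches boolean indexing order
    labels_flat = fit.labels[mask].astype(np.int64)

    # M-step from the initial assignment before the first sweep: sweeping
    # with the crude init parameters would destroy the init labels (a broad
    # null component outcompetes a tight activated one in the far tail).
    _update_parameters(z, labels_flat, fit)
    if mrf_beta is None:
        fit.mrf_beta = _update_beta(fit, labels_flat, neighbor_idx)

    for sweep in range(1, max_sweeps + 1):
        ll = _log_likelihoods(z, fit)
        logw = np.where(fit.active, np.log(np.maximum(fit.weights, 1e-300)), -np.inf)
        obj_pre = _joint_objective(z, labels_flat, fit, neighbor_idx)

        n_changes = 0
        beta = fit.mrf_beta
        for v in range(z.size):
            nb = neighbor_idx[v]
            nb = nb[nb >= 0]
            score = logw + ll[v]
            if beta != 0.0 and nb.size:
                nl = labels_flat[nb]
                for k in range(3):
                    score[k] += beta * (nl == k).sum()
            new = int(np.argmax(score))
            if new != labels_flat[v]:
                labels_flat[v] = new
                n_changes += 1

        obj_post = _joint_objective(z, labels_flat, fit, neighbor_idx)
        if obj_post < obj_pre - 1e-9 * max(1.0, abs(obj_pre)):
            raise AssertionError(
                f"ICM label sweep decreased the joint pseudo-posterior: {obj_pre} -> {obj_post}"
            )
        fit.objective_history.append(
            {"sweep": sweep, "pre_labels": obj_pre, "post_labels": obj_post, "n_changes": n_changes}
        )

        _update_parameters(z, labels_flat, fit)
        beta_change = 0.0
        if mrf_beta is None:
            new_beta = _update_beta(fit, labels_flat, neighbor_idx)
            beta_change = abs(new_beta - fit.mrf_beta)
            fit.mrf_beta = new_beta

        fit.n_icm_sweeps = sweep
        if n_changes == 0 and beta_change <= tol:
            fit.converged = True
            break

    _absorb_unseparated_classes(z, labels_flat, fit)

    fit.labels = np.full(mask.shape, -1, dtype=np.int8)
    fit.labels[mask] = labels_flat
    fit.ppm_act, fit.ppm_deact = compute_ppm(data, fit)
    return fit


def _absorb_unseparated_classes(z: np.ndarray, labels_flat: np.ndarray, fit: MixtureFit) -> None:
    """Fold alternative classes that never left the null bulk back into null.

    A hard-assignment mixture on a signal-free field tends to park a small
    class on the extreme tail of the null distribution rather than lose all
    its members. On V null draws those extremes reach about sqrt(2 ln V)
    null sd (the universal threshold), so a class whose fitted mean is
    closer to the null mean than that is indistinguishable from the null
    tail and is merged back into the null class (labels reassigned, null
    moments refitted). A genuinely activated cluster sits far outside.
    """
    if not fit.active[NULL]:
        return
    separation = np.sqrt(2.0 * np.log(z.size)) * fit.sds[NULL]
    merged = False
    for k in (DEACT, ACT):
        if not fit.active[k]:
            continue
        if abs(fit.means[k] - fit.means[NULL]) < separation:
            labels_flat[labels_flat == k] = NULL
            fit.active[k] = False
            fit.weights[k] = 0.0
            merged = True
            warnings.warn(
                f"mixture class {k} not separated from the null bulk; absorbed",
                RuntimeWarning,
                stacklevel=3,
            )
    if merged:
        members = z[labels_flat == NULL]
        fit.means[NULL] = members.mean()
        fit.sds[NULL] = max(members.std(), SIGMA_FLOOR)
        fit.weights[NULL] = members.size / z.size
        fit.weights[fit.active] /= fit.weights[fit.active].sum()


def compute_ppm(zmap: StatMap | np.ndarray, fit: MixtureFit) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probability maps given the converged labels and the data.

    ``ppm_k(v) = prior_k(v)·N(z_v; mu_k, sd_k²) / Σ_j prior_j(v)·N(...)``
    with the prior taken from :func:`neighbor_prior` at the converged hard
    labels. Returns (activation PPM, deactivation PPM); a collapsed class
    contributes zero probability.
    """
    data = zmap.data if isinstance(zmap, StatMap) else np.asarray(zmap, dtype=float)
    prior = neighbor_prior(fit)
    mask = fit.mask
    z = data[mask]
    ll = _log_likelihoods(z, fit)
    log_prior = np.log(np.maximum(prior[:, mask].T, 1e-300))
    log_prior[:, ~fit.active] = -np.inf
    score = log_prior + ll
    mx = score.max(axis=1, keepdims=True)
    resp = np.exp(score - mx)
    resp /= resp.sum(axis=1, keepdims=True)
    ppm_act = np.zeros(mask.shape)
    ppm_deact = np.zeros(mask.shape)
    ppm_act[mask] = resp[:, ACT] if fit.active[ACT] else 0.0
    ppm_deact[mask] = resp[:, DEACT] if fit.active[DEACT] else 0.0
    return ppm_act, ppm_deact


def threshold_ppm(ppm: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Detection mask under the strict rule PPM > threshold (0.5 excluded)."""
    return np.asarray(ppm) > threshold
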