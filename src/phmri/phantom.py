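"""Synthetic paired-crossover phMRI cohorts with known ground truth.

The generator emulates the signal structure of a drug-infusion BOLD study:
a two-condition within-subject crossover (default 13 subjects), a
low-frequency ramp/plateau infusion response with optionally jittered onset,
additive activation in condition-specific voxel clusters, AR(1) white-matter
and CSF compartment nuisance signals, per-session linear drift, Gaussian
noise, and a seed-coupled network present in only one condition during the
steady-state window at the end of the scan.

Baseline BOLD level is fixed at 1000 arbitrary units and planted amplitudes
are absolute additive units on that scale, so GLM estimates are directly
comparable to the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml

from .volume import Volume4D, ras_affine

__all__ = [
    "AcquisitionSpec",
    "PlantedEffect",
    "NuisanceSpec",
    "SeedNetworkSpec",
    "CohortSpec",
    "TissueMasks",
    "GroundTruth",
    "Cohort",
    "make_tissue_masks",
    "infusion_truth_timecourse",
    "generate_cohort",
    "ball_mask",
    "ellipsoid_mask",
    "BASELINE_LEVEL",
]

#: Baseline BOLD level of the phantom, arbitrary units.
BASELINE_LEVEL = 1000.0

#: Infusion timing: pretreatment baseline ends at 5 min, ramp ends at 13 min.
RAMP_START_S = 300.0
RAMP_END_S = 780.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """EPI acquisition geometry and timing.

    Defaults mirror a 3T gradient-echo EPI infusion protocol: TR 2.5 s,
    600 volumes (25 min), 3.5 mm isotropic voxels.
    """

    tr_seconds: float = 2.5
    n_volumes: int = 600
    voxel_mm: tuple[float, float, float] = (3.5, 3.5, 3.5)
    grid_dims: tuple[int, int, int] = (20, 20, 10)

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be positive")
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")

    @property
    def duration_seconds(self) -> float:
        return self.tr_seconds * self.n_volumes

    def affine(self) -> np.ndarray:
        return ras_affine(self.voxel_mm, self.grid_dims)

    def frame_times(self) -> np.ndarray:
        return self.tr_seconds * np.arange(self.n_volumes)


@dataclass
class PlantedEffect:
    """A ground-truth activation: where, how strong, in which condition."""

    mask: np.ndarray
    amplitude: float
    condition: Literal["A", "B", "both"] = "A"
    onset_jitter_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("PlantedEffect mask must be nonempty")
        if not np.isfinite(self.amplitude):
            raise ValueError("PlantedEffect amplitude must be finite")
        if self.condition not in ("A", "B", "both"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.onset_jitter_seconds < 0:
            raise ValueError("onset_jitter_seconds must be nonnegative")


@dataclass(frozen=True)
class NuisanceSpec:
    """AR(1) compartment nuisance signal: sd `amplitude`, lag-1 coefficient `ar1`."""

    amplitude: float = 2.0
    ar1: float = 0.95

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("nuisance amplitude must be nonnegative")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass
class SeedNetworkSpec:
    """Seed↔target coupling injected in one condition during the final window."""

    seed_mask: np.ndarray
    target_mask: np.ndarray
    coupling: float = 1.5
    condition: Literal["A", "B"] = "A"
    window_seconds: float = 300.0

    def __post_init__(self) -> None:
        self.seed_mask = np.asarray(self.seed_mask, dtype=bool)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if not self.seed_mask.any() or not self.target_mask.any():
            raise ValueError("seed and target masks must be nonempty")


@dataclass
class TissueMasks:
    """Mutually exclusive GM/WM/CSF compartments on one grid."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gm", "wm", "csf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if (self.gm & self.wm).any() or (self.gm & self.csf).any() or (self.wm & self.csf).any():
            raise ValueError("tissue masks must be pairwise disjoint")

    @property
    def brain(self) -> np.ndarray:
        return self.gm | self.wm | self.csf


@dataclass
class GroundTruth:
    """True per-condition amplitude maps and the seed-coupling map."""

    amplitude: dict[str, np.ndarray]
    seed_coupling: np.ndarray


@dataclass
class CohortSpec:
    """Everything needed to simulate one paired crossover cohort."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    n_subjects: int = 13
    effects: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    drift_slope_sd: float = 2.0
    wm_signal: NuisanceSpec = field(default_factory=NuisanceSpec)
    csf_signal: NuisanceSpec = field(default_factory=NuisanceSpec)
    seed_network: Optional[SeedNetworkSpec] = None
    baseline: float = BASELINE_LEVEL
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.drift_slope_sd < 0:
            raise ValueError("drift_slope_sd must be nonnegative")


@dataclass
class SubjectData:
    subject_id: str
    sessions: dict[str, Volume4D]
    condition_order: tuple[str, str]


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectData]
    tissue: TissueMasks
    truth: GroundTruth

    def amplitude_truth(self, condition: str) -> np.ndarray:
        return self.truth.amplitude[condition]


def ball_mask(grid_dims: tuple[int, int, int], center: tuple[float, float, float], radius: float) -> np.ndarray:
    """Boolean ball of the given voxel radius — convenience for planting effects."""
    grids = np.ogrid[tuple(slice(0, d) for d in grid_dims)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


def ellipsoid_mask(
    grid_dims: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    """Boolean axis-aligned ellipsoid in voxel units.

    Useful for regions that must be large relative to the smoothing kernel
    while still fitting the flattened phantom brain.
    """
    grids = np.ogrid[tuple(slice(0, d) for d in grid_dims)]
    rho2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi_axes))
    return rho2 <= 1.0


def make_tissue_masks(grid_dims: tuple[int, int, int]) -> TissueMasks:
    """Concentric ellipsoidal brain: WM core, GM shell, CSF rim.

    The normalized elliptical radius rho (semi-axes 0.45 of each grid size)
    partitions the brain ellipsoid rho<1 into WM (rho<0.45), GM
    (0.45<=rho<0.8) and CSF (0.8<=rho<1).
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if len(grid_dims) != 3 or any(d < 8 for d in grid_dims):
        raise ValueError(f"grid too small to host three tissue compartments: {grid_dims}")
    center = [(d - 1) / 2.0 for d in grid_dims]
    semi = [0.45 * d for d in grid_dims]
    grids = np.ogrid[tuple(slice(0, d) for d in grid_dims)]
    rho = np.sqrt(sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi)))
    wm = rho < 0.45
    gm = (rho >= 0.45) & (rho < 0.8)
    csf = (rho >= 0.8) & (rho < 1.0)
    masks = TissueMasks(gm=gm, wm=wm, csf=csf)
    if not (gm.any() and wm.any() and csf.any()):
        raise ValueError(f"grid {grid_dims} leaves an empty tissue compartment")
    return masks


def _ramp(times: np.ndarray, onset_shift_s: float) -> np.ndarray:
    start = RAMP_START_S + onset_shift_s
    end = RAMP_END_S + onset_shift_s
    return np.clip((times - start) / (end - start), 0.0, 1.0)


def infusion_truth_timecourse(
    acq: AcquisitionSpec, amplitude: float, onset_shift_seconds: float = 0.0
) -> np.ndarray:
    """The planted infusion response: amplitude × (shifted ramp/plateau).

    Zero through (300 + shift) s, linear ramp to (780 + shift) s, constant
    at `amplitude` thereafter, sampled at the acquisition frame times.
    """
    if abs(onset_shift_seconds) >= RAMP_START_S:
        raise ValueError("onset shift must be smaller than the 300 s baseline")
    return amplitude * _ramp(acq.frame_times(), onset_shift_seconds)


def _ar1_series(rng: np.random.Generator, n: int, spec: NuisanceSpec) -> np.ndarray:
    """Stationary AR(1) with marginal sd spec.amplitude."""
    if spec.amplitude == 0:
        return np.zeros(n)
    innov_sd = spec.amplitude * np.sqrt(1 - spec.ar1**2)
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, spec.amplitude)
    for t in range(1, n):
        x[t] = spec.ar1 * x[t - 1] + e[t]
    return x


def _simulate_session(
    spec: CohortSpec,
    tissue: TissueMasks,
    condition: str,
    jitters: dict[int, float],
    rng: np.random.Generator,
) -> Volume4D:
    acq = spec.acquisition
    n = acq.n_volumes
    brain = tissue.brain
    data = np.zeros(acq.grid_dims + (n,))
    data[brain] = spec.baseline

    times = acq.frame_times()
    for i, eff in enumerate(spec.effects):
        if eff.condition not in (condition, "both"):
            continue
        data[eff.mask] += eff.amplitude * _ramp(times, jitters[i])

    # per-session linear drift across the whole brain
    slope = rng.normal(0.0, spec.drift_slope_sd)
    drift = slope * (np.arange(n) / (n - 1) - 0.5)
    data[brain] += drift

    # compartment nuisances: full amplitude in the compartment, 0.3x bleed into GM
    wm_tc = _ar1_series(rng, n, spec.wm_signal)
    csf_tc = _ar1_series(rng, n, spec.csf_signal)
    data[tissue.wm] += wm_tc
    data[tissue.csf] += csf_tc
    data[tissue.gm] += 0.3 * wm_tc + 0.3 * csf_tc

    # The seed fluctuates intrinsically in every session; only the target's
    # coupling to it is condition-specific. Injecting the latent into the
    # seed in one condition only would change the seed's variance between
    # conditions and bias its correlation with the whole brain.
    net = spec.seed_network
    if net is not None:
        n_win = int(np.floor(net.window_seconds / acq.tr_seconds))
        latent = rng.normal(0.0, 1.0, size=n_win)
        data[net.seed_mask, -n_win:] += net.coupling * latent
        if net.condition == condition:
            data[net.target_mask, -n_win:] += net.coupling * latent

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=data.shape)
        data[brain] += noise[brain]

    return Volume4D(data=data, affine=acq.affine(), tr_seconds=acq.tr_seconds)


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Simulate the paired crossover cohort; optionally write NIfTI + manifest.

    Deterministic for a given ``spec.rng_seed``: one root seed sequence is
    split per subject by counter, and each subject's stream is split per
    condition, so outputs are bit-identical across runs and independent of
    generation order.
    """
    acq = spec.acquisition
    tissue = make_tissue_masks(acq.grid_dims)
    brain = tissue.brain
    for eff in spec.effects:
        if eff.mask.shape != brain.shape:
            raise ValueError("effect mask grid does not match acquisition grid")
        if (eff.mask & ~brain).any():
            raise ValueError("planted effect mask extends outside the brain")
    if spec.seed_network is not None:
        for m in (spec.seed_network.seed_mask, spec.seed_network.target_mask):
            if (m & ~brain).any():
                raise ValueError("seed-network mask extends outside the brain")

    root = np.random.SeedSequence(spec.rng_seed)
    subject_seeds = root.spawn(spec.n_subjects)

    truth_amp = {c: np.zeros(acq.grid_dims) for c in ("A", "B")}
    for eff in spec.effects:
        for c in ("A", "B"):
            if eff.condition in (c, "both"):
                truth_amp[c][eff.mask] += eff.amplitude
    coupling_map = np.zeros(acq.grid_dims)
    if spec.seed_network is not None:
        coupling_map[spec.seed_network.target_mask] = spec.seed_network.coupling
    truth = GroundTruth(amplitude=truth_amp, seed_coupling=coupling_map)

    subjects: list[SubjectData] = []
    for s in range(spec.n_subjects):
        jitter_rng = np.random.default_rng(subject_seeds[s])
        cond_seeds = subject_seeds[s].spawn(2)
        # onset jitter is a subject-level pharmacodynamic trait, shared by sessions
        jitters = {
            i: (jitter_rng.uniform(-e.onset_jitter_seconds, e.onset_jitter_seconds) if e.onset_jitter_seconds else 0.0)
            for i, e in enumerate(spec.effects)
        }
        sessions = {}
        for ci, cond in enumerate(("A", "B")):
            rng = np.random.default_rng(cond_seeds[ci])
            sessions[cond] = _simulate_session(spec, tissue, cond, jitters, rng)
        order = ("A", "B") if s % 2 == 0 else ("B", "A")
        subjects.append(SubjectData(subject_id=f"sub-{s + 1:02d}", sessions=sessions, condition_order=order))

    cohort = Cohort(spec=spec, subjects=subjects, tissue=tissue, truth=truth)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-session NIfTI, tissue masks, truth maps and a YAML manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    acq = cohort.spec.acquisition
    affine = acq.affine()

    def _save_mask(arr: np.ndarray, name: str) -> str:
        from .volume import save_nifti
        import nibabel as nib

        img = nib.Nifti1Image(arr.astype(np.uint8), affine)
        save_nifti(img, out_dir / name)
        return name

    mask_files = {
        "gm": _save_mask(cohort.tissue.gm, "mask_gm.nii.gz"),
        "wm": _save_mask(cohort.tissue.wm, "mask_wm.nii.gz"),
        "csf": _save_mask(cohort.tissue.csf, "mask_csf.nii.gz"),
        "brain": _save_mask(cohort.tissue.brain, "mask_brain.nii.gz"),
    }
    truth_files = {}
    for cond, amp in cohort.truth.amplitude.items():
        from .volume import StatMap

        name = f"truth_amplitude_{cond}.nii.gz"
        StatMap(amp, affine, name=f"true amplitude {cond}").save(out_dir / name)
        truth_files[cond] = name
    from .volume import StatMap

    StatMap(cohort.truth.seed_coupling, affine, name="true seed coupling").save(out_dir / "truth_seed_coupling.nii.gz")

    manifest: dict = {
        "rng_seed": cohort.spec.rng_seed,
        "baseline_units": cohort.spec.baseline,
        "amplitude_units": "absolute additive units on the baseline scale",
        "acquisition": {
            "tr_seconds": acq.tr_seconds,
            "n_volumes": acq.n_volumes,
            "voxel_mm": list(acq.voxel_mm),
            "grid_dims": list(acq.grid_dims),
        },
        "masks": mask_files,
        "truth": {"amplitude": truth_files, "seed_coupling": "truth_seed_coupling.nii.gz"},
        "subjects": [],
    }
    for sub in cohort.subjects:
        files = {}
        for cond, vol in sub.sessions.items():
            fname = f"{sub.subject_id}_cond-{cond}_bold.nii.gz"
            vol.save(out_dir / fname)
            files[cond] = fname
        manifest["subjects"].append(
            {
                "id": sub.subject_id,
                "condition_order": list(sub.condition_order),
                "bold": files,
            }
        )
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def load_cohort_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "subjects" not in manifest:
        raise ValueError(f"{path} is not a cohort manifest")
    return manifest
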