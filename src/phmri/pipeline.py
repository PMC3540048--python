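"""Pipeline configuration and stage orchestration.

Stages (simulate → preprocess → glm → group → ppm → fc → report) read and
write files under one output directory, so each stage can also be run on
its own against previously produced artifacts. Every output carries a
provenance sidecar (JSON: stage, config hash, input hashes, package
version); reruns with an unchanged config and seed are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .connectivity import (
    SeedROI,
    build_fc_nuisance,
    group_fc_contrast,
    last_window,
    partial_correlation_map,
    seed_timecourse,
)
from .group_contrast import paired_contrast
from .infusion_glm import (
    assemble_design,
    build_infusion_ev,
    build_svd_onset_regressors,
    fit_voxelwise_glm,
)
from .mrf_ppm import icm_fit, threshold_ppm
from .phantom import (
    AcquisitionSpec,
    CohortSpec,
    NuisanceSpec,
    PlantedEffect,
    SeedNetworkSpec,
    ball_mask,
    ellipsoid_mask,
    generate_cohort,
    load_cohort_manifest,
    make_tissue_masks,
    write_cohort,
)
from .preprocess import drop_initial_volumes, grand_mean_normalize, mean_timecourse, smooth_gaussian
from .report import label_clusters, write_cluster_table
from .volume import StatMap, Volume4D, save_nifti

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "default_config", "load_config", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "preprocess", "glm", "group", "ppm", "fc", "report")

#: Allowed configuration keys, by section (None = scalar leaf).
_SCHEMA: dict = {
    "rng_seed": None,
    "acquisition": {"tr_seconds": None, "n_volumes": None, "voxel_mm": None, "grid_dims": None},
    "cohort": {
        "n_subjects": None,
        "noise_sd": None,
        "baseline": None,
        "drift_slope_sd": None,
        "wm_signal": {"amplitude": None, "ar1": None},
        "csf_signal": {"amplitude": None, "ar1": None},
        "effects": None,
        "seed_network": None,
    },
    "preprocessing": {"fwhm_mm": None, "n_drop": None, "grand_mean_target": None},
    "glm": {"onset_shifts_s": None, "svd_k": None},
    "ppm": {"threshold": None, "max_sweeps": None},
    "connectivity": {"window_minutes": None, "seed_name": None},
    "report": {"connectivity": None},
}

_EFFECT_KEYS = {"center", "radius", "semi_axes", "amplitude", "condition", "onset_jitter_seconds"}
_NETWORK_KEYS = {
    "seed_center",
    "seed_radius",
    "target_center",
    "target_radius",
    "target_semi_axes",
    "coupling",
    "condition",
}


def default_config() -> dict:
    """The desk-scale demo: one condition-A activation plus a condition-A
    seed-coupled network, 13 subjects, unit noise."""
    return {
        "rng_seed": 0,
        "acquisition": {
            "tr_seconds": 2.5,
            "n_volumes": 600,
            "voxel_mm": [3.5, 3.5, 3.5],
            "grid_dims": [20, 20, 10],
        },
        "cohort": {
            "n_subjects": 13,
            "noise_sd": 1.0,
            "baseline": 1000.0,
            "drift_slope_sd": 2.0,
            "wm_signal": {"amplitude": 2.0, "ar1": 0.95},
            "csf_signal": {"amplitude": 2.0, "ar1": 0.95},
            "effects": [
                {
                    "center": [4, 10, 5],
                    "semi_axes": [3.0, 4.0, 2.5],
                    "amplitude": 1.5,
                    "condition": "A",
                    "onset_jitter_seconds": 0.0,
                }
            ],
            "seed_network": {
                "seed_center": [9, 5, 5],
                "seed_radius": 2.2,
                "target_center": [10, 14, 5],
                "target_semi_axes": [4.5, 4.0, 2.8],
                "coupling": 1.5,
                "condition": "A",
            },
        },
        "preprocessing": {"fwhm_mm": 5.0, "n_drop": 2, "grand_mean_target": 10000.0},
        "glm": {"onset_shifts_s": [-60, -45, -30, -15, 0, 15, 30, 45, 60], "svd_k": 3},
        "ppm": {"threshold": 0.5, "max_sweeps": 50},
        "connectivity": {"window_minutes": 5.0, "seed_name": "caudate_like_seed"},
        "report": {"connectivity": 26},
    }


def _validate(node: dict, schema: dict, path: str = "") -> None:
    for key, value in node.items():
        if key not in schema:
            raise ValueError(f"unknown config key: {path}{key}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            _validate(value, sub, f"{path}{key}.")
    if path == "cohort.":
        for eff in node.get("effects") or []:
            extra = set(eff) - _EFFECT_KEYS
            if extra:
                raise ValueError(f"unknown effect keys: {sorted(extra)}")
        net = node.get("seed_network")
        if net:
            extra = set(net) - _NETWORK_KEYS
            if extra:
                raise ValueError(f"unknown seed_network keys: {sorted(extra)}")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class PipelineConfig:
    """Validated configuration; thin dict wrapper with typed accessors."""

    raw: dict

    def __post_init__(self) -> None:
        _validate(self.raw, _SCHEMA)
        self.raw = _merge(default_config(), self.raw)

    @property
    def rng_seed(self) -> int:
        return int(self.raw["rng_seed"])

    def acquisition(self) -> AcquisitionSpec:
        a = self.raw["acquisition"]
        return AcquisitionSpec(
            tr_seconds=float(a["tr_seconds"]),
            n_volumes=int(a["n_volumes"]),
            voxel_mm=tuple(float(v) for v in a["voxel_mm"]),
            grid_dims=tuple(int(v) for v in a["grid_dims"]),
        )

    def seed_network_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Seed and target masks, restricted to gray matter (where real seed
        ROIs live; planting into WM/CSF would leak the network signal into
        the nuisance regressors)."""
        net = self.raw["cohort"].get("seed_network")
        if not net:
            raise ValueError("config has no cohort.seed_network")
        dims = self.acquisition().grid_dims
        gm = make_tissue_masks(dims).gm
        seed = ball_mask(dims, tuple(net["seed_center"]), float(net["seed_radius"])) & gm
        if "target_semi_axes" in net:
            target = ellipsoid_mask(dims, tuple(net["target_center"]), tuple(net["target_semi_axes"]))
        else:
            target = ball_mask(dims, tuple(net["target_center"]), float(net["target_radius"]))
        return seed, target & gm

    def cohort_spec(self) -> CohortSpec:
        acq = self.acquisition()
        c = self.raw["cohort"]
        dims = acq.grid_dims
        gm = make_tissue_masks(dims).gm
        effects = []
        for e in c.get("effects") or []:
            if "semi_axes" in e:
                shape = ellipsoid_mask(dims, tuple(e["center"]), tuple(e["semi_axes"]))
            else:
                shape = ball_mask(dims, tuple(e["center"]), float(e["radius"]))
            effects.append(
                PlantedEffect(
                    mask=shape & gm,
                    amplitude=float(e["amplitude"]),
                    condition=e.get("condition", "A"),
                    onset_jitter_seconds=float(e.get("onset_jitter_seconds", 0.0)),
                )
            )
        net = c.get("seed_network")
        seed_network = None
        if net:
            seed_mask, target_mask = self.seed_network_masks()
            seed_network = SeedNetworkSpec(
                seed_mask=seed_mask,
                target_mask=target_mask,
                coupling=float(net["coupling"]),
                condition=net.get("condition", "A"),
                window_seconds=float(self.raw["connectivity"]["window_minutes"]) * 60.0,
            )
        return CohortSpec(
            acquisition=acq,
            n_subjects=int(c["n_subjects"]),
            effects=effects,
            noise_sd=float(c["noise_sd"]),
            drift_slope_sd=float(c["drift_slope_sd"]),
            wm_signal=NuisanceSpec(**c["wm_signal"]),
            csf_signal=NuisanceSpec(**c["csf_signal"]),
            seed_network=seed_network,
            baseline=float(c["baseline"]),
            rng_seed=self.rng_seed,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(raw)
    if seed is not None:
        cfg.raw["rng_seed"] = int(seed)
    return cfg


# ---------------------------------------------------------------- provenance


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_provenance(stage_dir: Path, cfg: PipelineConfig, inputs: list[Path]) -> None:
    record = {
        "stage": stage_dir.name,
        "config_hash": cfg.config_hash(),
        "inputs": {p.name: _hash_file(p) for p in sorted(inputs)},
        "version": __version__,
    }
    (stage_dir / "provenance.json").write_text(json.dumps(record, sort_keys=True, indent=1))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing prerequisite artifact {path}; run the '{producer}' stage first"
        )
    return path


def _load_mask(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


# ------------------------------------------------------------------- stages


def _stage_simulate(cfg: PipelineConfig, out_dir: Path) -> None:
    stage = out_dir / "simulate"
    cohort = generate_cohort(cfg.cohort_spec())
    write_cohort(cohort, stage)
    _write_provenance(stage, cfg, [stage / "manifest.yaml"])


def _stage_preprocess(cfg: PipelineConfig, out_dir: Path) -> None:
    sim = out_dir / "simulate"
    manifest = load_cohort_manifest(_require(sim / "manifest.yaml", "simulate"))
    stage = out_dir / "preprocess"
    stage.mkdir(parents=True, exist_ok=True)
    p = cfg.raw["preprocessing"]
    brain = _load_mask(_require(sim / manifest["masks"]["brain"], "simulate"))
    wm = _load_mask(sim / manifest["masks"]["wm"])
    csf = _load_mask(sim / manifest["masks"]["csf"])
    outputs = []
    for sub in manifest["subjects"]:
        for cond, fname in sub["bold"].items():
            vol = Volume4D.load(_require(sim / fname, "simulate"))
            vol = drop_initial_volumes(vol, int(p["n_drop"]))
            vol = smooth_gaussian(vol, float(p["fwhm_mm"]))
            vol = grand_mean_normalize(vol, float(p["grand_mean_target"]), brain)
            out = stage / f"{sub['id']}_cond-{cond}_preproc.nii.gz"
            vol.save(out)
            outputs.append(out)
            tc = np.column_stack([mean_timecourse(vol, wm), mean_timecourse(vol, csf)])
            np.savetxt(
                stage / f"{sub['id']}_cond-{cond}_nuisance.tsv",
                tc,
                delimiter="\t",
                header="wm\tcsf",
                comments="",
            )
    _write_provenance(stage, cfg, outputs)


def _stage_glm(cfg: PipelineConfig, out_dir: Path) -> None:
    sim = out_dir / "simulate"
    pre = out_dir / "preprocess"
    manifest = load_cohort_manifest(_require(sim / "manifest.yaml", "simulate"))
    stage = out_dir / "glm"
    stage.mkdir(parents=True, exist_ok=True)
    g = cfg.raw["glm"]
    brain = _load_mask(sim / manifest["masks"]["brain"])
    outputs = []
    for sub in manifest["subjects"]:
        for cond in sub["bold"]:
            vol = Volume4D.load(_require(pre / f"{sub['id']}_cond-{cond}_preproc.nii.gz", "preprocess"))
            nuis = np.loadtxt(pre / f"{sub['id']}_cond-{cond}_nuisance.tsv", delimiter="\t", skiprows=1)
            ev = build_infusion_ev(vol.n_volumes, vol.tr_seconds, vol.time_origin_s)
            svd = build_svd_onset_regressors(
                vol.n_volumes,
                vol.tr_seconds,
                vol.time_origin_s,
                onset_shifts_s=tuple(float(s) for s in g["onset_shifts_s"]),
                k=int(g["svd_k"]),
            )
            design = assemble_design(ev, svd, wm_tc=nuis[:, 0], csf_tc=nuis[:, 1])
            design.save_tsv(stage / f"{sub['id']}_cond-{cond}_design.tsv")
            result = fit_voxelwise_glm(vol, design, brain)
            for name, sm in (("amplitude", result.amplitude), ("zstat", result.zstat)):
                out = stage / f"{sub['id']}_cond-{cond}_{name}.nii.gz"
                sm.save(out)
                outputs.append(out)
    _write_provenance(stage, cfg, outputs)


def _stage_group(cfg: PipelineConfig, out_dir: Path) -> None:
    sim = out_dir / "simulate"
    glm = out_dir / "glm"
    manifest = load_cohort_manifest(_require(sim / "manifest.yaml", "simulate"))
    stage = out_dir / "group"
    stage.mkdir(parents=True, exist_ok=True)
    # group inference is restricted to gray matter, where the BOLD
    # activations of interest (and the phantom's planted responses) live
    gm = _load_mask(sim / manifest["masks"]["gm"])
    amps = {"A": [], "B": []}
    for sub in manifest["subjects"]:
        for cond in ("A", "B"):
            amps[cond].append(
                StatMap.load(_require(glm / f"{sub['id']}_cond-{cond}_amplitude.nii.gz", "glm"))
            )
    result = paired_contrast(amps["A"], amps["B"], gm)
    outputs = []
    for name, sm in (
        ("mean_diff", result.mean_diff),
        ("zstat_AgtB", result.zstat_AgtB),
        ("zstat_BgtA", result.zstat_BgtA),
    ):
        out = stage / f"contrast_{name}.nii.gz"
        sm.save(out)
        outputs.append(out)
    _write_provenance(stage, cfg, outputs)


def _stage_ppm(cfg: PipelineConfig, out_dir: Path) -> None:
    sim = out_dir / "simulate"
    group = out_dir / "group"
    manifest = load_cohort_manifest(_require(sim / "manifest.yaml", "simulate"))
    stage = out_dir / "ppm"
    stage.mkdir(parents=True, exist_ok=True)
    gm = _load_mask(sim / manifest["masks"]["gm"])
    zmap = StatMap.load(_require(group / "contrast_zstat_AgtB.nii.gz", "group"))
    p = cfg.raw["ppm"]
    fit = icm_fit(zmap, gm, max_sweeps=int(p["max_sweeps"]))
    fit.save_params(stage / "mixture_params.yaml")
    save_nifti(nib.Nifti1Image(fit.labels.astype(np.int8), zmap.affine), stage / "labels.nii.gz")
    outputs = [stage / "labels.nii.gz"]
    thr = float(p["threshold"])
    for name, ppm, det in (
        ("act", fit.ppm_act, threshold_ppm(fit.ppm_act, thr)),
        ("deact", fit.ppm_deact, threshold_ppm(fit.ppm_deact, thr)),
    ):
        StatMap(ppm, zmap.affine, name=f"ppm {name}").save(stage / f"ppm_{name}.nii.gz")
        save_nifti(nib.Nifti1Image(det.astype(np.uint8), zmap.affine), stage / f"mask_{name}.nii.gz")
        outputs += [stage / f"ppm_{name}.nii.gz", stage / f"mask_{name}.nii.gz"]
    _write_provenance(stage, cfg, outputs)


def _stage_fc(cfg: PipelineConfig, out_dir: Path) -> None:
    sim = out_dir / "simulate"
    pre = out_dir / "preprocess"
    manifest = load_cohort_manifest(_require(sim / "manifest.yaml", "simulate"))
    stage = out_dir / "fc"
    stage.mkdir(parents=True, exist_ok=True)
    gm = _load_mask(sim / manifest["masks"]["gm"])
    wm = _load_mask(sim / manifest["masks"]["wm"])
    csf = _load_mask(sim / manifest["masks"]["csf"])
    conn = cfg.raw["connectivity"]
    net = cfg.raw["cohort"].get("seed_network")
    if not net:
        raise ValueError("connectivity stage requires cohort.seed_network in the config")
    seed_mask, _ = cfg.seed_network_masks()
    roi = SeedROI(name=str(conn["seed_name"]), mask=seed_mask)
    # seed-based connectivity is a gray-matter analysis
    fc = {"A": [], "B": []}
    outputs = []
    for sub in manifest["subjects"]:
        for cond in ("A", "B"):
            vol = Volume4D.load(_require(pre / f"{sub['id']}_cond-{cond}_preproc.nii.gz", "preprocess"))
            win = last_window(vol, float(conn["window_minutes"]))
            nuisance = build_fc_nuisance(
                win.n_volumes, mean_timecourse(win, wm), mean_timecourse(win, csf)
            )
            fc_map = partial_correlation_map(win, seed_timecourse(win, roi), nuisance, gm)
            out = stage / f"{sub['id']}_cond-{cond}_fisherz.nii.gz"
            fc_map.fisher_z.save(out)
            outputs.append(out)
            fc[cond].append(fc_map)
    result = group_fc_contrast(
        fc["A"], fc["B"], gm, ppm_threshold=float(cfg.raw["ppm"]["threshold"]),
        max_sweeps=int(cfg.raw["ppm"]["max_sweeps"]),
    )
    result.paired.zstat_AgtB.save(stage / "fc_zstat_AgtB.nii.gz")
    result.fit.save_params(stage / "fc_mixture_params.yaml")
    affine = result.paired.zstat_AgtB.affine
    for name, det in (("AgtB", result.mask_AgtB), ("BgtA", result.mask_BgtA)):
        save_nifti(nib.Nifti1Image(det.astype(np.uint8), affine), stage / f"fc_mask_{name}.nii.gz")
        outputs.append(stage / f"fc_mask_{name}.nii.gz")
    _write_provenance(stage, cfg, outputs)


def _stage_report(cfg: PipelineConfig, out_dir: Path) -> None:
    group = out_dir / "group"
    ppm = out_dir / "ppm"
    fc = out_dir / "fc"
    stage = out_dir / "report"
    stage.mkdir(parents=True, exist_ok=True)
    conn_rule = int(cfg.raw["report"]["connectivity"])
    zmap = StatMap.load(_require(group / "contrast_zstat_AgtB.nii.gz", "group"))
    records = []
    for name in ("act", "deact"):
        mask = _load_mask(_require(ppm / f"mask_{name}.nii.gz", "ppm"))
        records.extend(label_clusters(mask, zmap, connectivity=conn_rule))
    outputs = [write_cluster_table(records, stage / "contrast_clusters.tsv")]
    if (fc / "fc_zstat_AgtB.nii.gz").exists():
        fz = StatMap.load(fc / "fc_zstat_AgtB.nii.gz")
        fc_records = []
        for name in ("AgtB", "BgtA"):
            mask = _load_mask(fc / f"fc_mask_{name}.nii.gz")
            fc_records.extend(label_clusters(mask, fz, connectivity=conn_rule))
        outputs.append(write_cluster_table(fc_records, stage / "fc_clusters.tsv"))
    _write_provenance(stage, cfg, outputs)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "glm": _stage_glm,
    "group": _stage_group,
    "ppm": _stage_ppm,
    "fc": _stage_fc,
    "report": _stage_report,
}


def run_stage(name: str, cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run one stage against previously produced artifacts in ``out_dir``."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("running stage %s -> %s", name, out_dir / name)
    _STAGE_FUNCS[name](cfg, out_dir)
    return out_dir / name


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full demo: simulate → … → report."""
    out_dir = Path(out_dir)
    for name in STAGES:
        run_stage(name, cfg, out_dir)
    return out_dir
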