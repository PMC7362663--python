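"""End-to-end pipeline: simulate -> DTI -> perfusion -> label -> features
-> train -> evaluate, with file-based intermediates and a provenance
manifest so each stage is independently inspectable and a run can resume
from what already exists on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .dti import compute_metrics, smooth_and_normalize
from .evaluate import EvalReport, run_loocv
from .features import FeatureConfig, assemble_feature_matrix, relative_metrics
from .labeling import LabelingConfig, derive_pdm_labels, threshold_ic, threshold_perfusion
from .perfusion import fit_cbf_map
from .phantom import PhantomSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("penumbra")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run bit-for-bit."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    backend: str = "svm"
    seed: int = 0
    smoothing_sigma: float = 1.0
    label_on_smoothed: bool = True
    outdir: str = "penumbra_run"
    resume: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            for key in ("grid", "gamma_params"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = PhantomSpec(**ph)
        if "labeling" in kwargs:
            kwargs["labeling"] = LabelingConfig(**kwargs["labeling"])
        if "features" in kwargs:
            fc = dict(kwargs["features"])
            for key in ("coronal_window", "axial_window", "bin_range"):
                if key in fc:
                    fc[key] = tuple(fc[key])
            kwargs["features"] = FeatureConfig(**fc)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute all stages in order, writing every intermediate artifact.

    With ``resume`` enabled, a stage whose output files already exist is
    loaded from disk instead of recomputed, so deleting one intermediate
    regenerates only the downstream stages.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.phantom
    v, s_mm = spec.voxel_size_mm, spec.slice_thickness_mm
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(), "stages": {}}

    # ---- stage 1: simulate -------------------------------------------------
    cohort_dir = out / "cohort"
    if config.resume and (cohort_dir / "spec.json").exists():
        log.info("resume: loading cohort from %s", cohort_dir)
        _, phantoms = pio.load_cohort(cohort_dir)
    else:
        log.info("simulating cohort: %d rats, %d slices, grid %s", spec.n_rats, spec.n_slices, spec.grid)
        phantoms = generate_cohort(spec)
        pio.write_cohort(phantoms, spec, cohort_dir)
    manifest["stages"]["simulate"] = {"n_rats": len(phantoms)}

    features_by_rat: dict[str, pd.DataFrame] = {}
    for p in phantoms:
        rat_dir = out / "derived" / p.rat_id
        rat_dir.mkdir(parents=True, exist_ok=True)

        # ---- stage 2: DTI metrics ------------------------------------------
        metrics = compute_metrics(p.eigen)
        smooth_and_normalize(metrics, sigma_vox=config.smoothing_sigma)
        for name in ("MD", "FA"):
            pio.save_nifti(np.nan_to_num(metrics.smoothed[name], nan=-1.0), rat_dir / f"{name}_smoothed.nii.gz", v, s_mm)

        # ---- stage 3: perfusion --------------------------------------------
        cbf_path = rat_dir / "rcbf.nii.gz"
        if config.resume and cbf_path.exists():
            rcbf = pio.load_nifti(cbf_path).astype(float)
            rcbf[rcbf < 0] = np.nan
        else:
            cbf = fit_cbf_map(p.dsc, p.brain_mask)
            rcbf = cbf.rcbf
            pio.save_nifti(np.nan_to_num(rcbf, nan=-1.0), cbf_path, v, s_mm)

        # ---- stage 4: PDM labels -------------------------------------------
        md_for_labels = metrics.smoothed["MD"] if config.label_on_smoothed else metrics.raw["MD"]
        ic_mask = threshold_ic(md_for_labels, config.labeling, p.brain_mask, p.ventricle_mask)
        deficit = threshold_perfusion(rcbf, config.labeling, p.brain_mask, p.ventricle_mask)
        labels = derive_pdm_labels(ic_mask, deficit, config.labeling, p.brain_mask, p.ventricle_mask)
        pio.save_nifti(labels.label, rat_dir / "labels.nii.gz", v, s_mm)
        with open(rat_dir / "labels_qc.json", "w") as fh:
            json.dump({**labels.qc, **labels.counts()}, fh, indent=2)

        # ---- stage 5: features ---------------------------------------------
        rel, _ = relative_metrics(metrics, config.features)
        df = assemble_feature_matrix(rel, labels, p.rat_id, config.features)
        df.to_csv(rat_dir / "features.csv", index=False)
        features_by_rat[p.rat_id] = df
        log.info("rat %s: %d eligible voxels, label counts %s", p.rat_id, len(df), labels.counts())

    manifest["stages"]["features"] = {"n_rows": int(sum(len(d) for d in features_by_rat.values()))}

    # ---- stage 6+7: train & evaluate (LOOCV) -------------------------------
    report = run_loocv(
        features_by_rat,
        backend=config.backend,
        seed=config.seed,
        voxel_volume_mm3=v * v * s_mm,
    )
    report.to_json(out / "report.json")
    if report.slice_volumes is not None:
        report.slice_volumes.to_csv(out / "slice_volumes.csv", index=False)
    manifest["stages"]["evaluate"] = {
        "hemisphere_accuracy_pct": report.pooled["hemisphere_accuracy_pct"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete: hemisphere accuracy %.1f%%", report.pooled["hemisphere_accuracy_pct"])
    return report
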