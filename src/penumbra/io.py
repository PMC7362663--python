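"""NIfTI and sidecar I/O for cohort artifacts.

Volumes are stored with nibabel in (slice, row, col[, channel/time]) axis
order and the in-plane voxel size / slice thickness recorded in the
affine.  A cohort directory holds one subdirectory per animal plus a
``spec.json`` sidecar from which the generating spec can be rebuilt.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dti import EigenMaps
from .perfusion import DscSeries
from .phantom import PhantomSpec, RatPhantom

__all__ = ["save_nifti", "load_nifti", "write_cohort", "load_cohort"]


def _affine(voxel_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([slice_mm, voxel_mm, voxel_mm, 1.0])


def save_nifti(arr: np.ndarray, path: Path, voxel_mm: float = 0.16, slice_mm: float = 1.0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(arr)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(voxel_mm, slice_mm)), str(path))


def load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_cohort(phantoms: list[RatPhantom], spec: PhantomSpec, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "spec.json", "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)
    for p in phantoms:
        d = outdir / p.rat_id
        v, s = spec.voxel_size_mm, spec.slice_thickness_mm
        save_nifti(p.eigen.stack(), d / "eigen.nii.gz", v, s)
        save_nifti(p.dsc.signal, d / "dsc.nii.gz", v, s)
        save_nifti(p.brain_mask, d / "brain_mask.nii.gz", v, s)
        save_nifti(p.ventricle_mask, d / "ventricle_mask.nii.gz", v, s)
        save_nifti(p.truth_labels.astype(np.int16), d / "truth_labels.nii.gz", v, s)
        save_nifti(np.nan_to_num(p.cbf_drop_map, nan=-1.0), d / "cbf_drop.nii.gz", v, s)


def load_cohort(outdir: Path) -> tuple[PhantomSpec, list[RatPhantom]]:
    outdir = Path(outdir)
    with open(outdir / "spec.json") as fh:
        raw = json.load(fh)
    for key in ("grid", "gamma_params"):
        raw[key] = tuple(raw[key])
    spec = PhantomSpec(**raw)
    phantoms = []
    for d in sorted(p for p in outdir.iterdir() if p.is_dir()):
        brain = load_nifti(d / "brain_mask.nii.gz").astype(bool)
        eig = EigenMaps.from_stack(load_nifti(d / "eigen.nii.gz"), brain)
        t0 = spec.gamma_params[3]
        baseline_len = max(int(t0 / spec.tr_s) - 5, 2)
        dsc = DscSeries(
            signal=np.asarray(load_nifti(d / "dsc.nii.gz"), dtype=float),
            tr_s=spec.tr_s,
            te_s=spec.te_s,
            baseline_window=(0, baseline_len),
        )
        drop = load_nifti(d / "cbf_drop.nii.gz").astype(float)
        drop[drop < 0] = np.nan
        phantoms.append(
            RatPhantom(
                rat_id=d.name,
                eigen=eig,
                dsc=dsc,
                truth_labels=load_nifti(d / "truth_labels.nii.gz").astype(np.int16),
                ventricle_mask=load_nifti(d / "ventricle_mask.nii.gz").astype(bool),
                brain_mask=brain,
                cbf_drop_map=drop,
            )
        )
    return spec, phantoms
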