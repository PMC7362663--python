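"""Perfusion-diffusion-mismatch (PDM) tissue labeling.

Supervision labels for the classifiers are defined from two thresholded
maps on the stroke-side (ipsilateral) hemisphere:

- infarct core (IC): mean diffusivity reduced by more than 30% of the
  contralateral-hemisphere mean, ventricles excluded;
- perfusion deficit: rCBF reduced by more than 46% of the contralateral-
  hemisphere mean;
- ischemic penumbra (IP): the mismatch, deficit voxels that are not IC;
- normal tissue (NT): ipsilateral voxels without perfusion deficit.

Both thresholds use strict inequality: a voxel exactly at threshold is not
lesion.  A final contiguity correction reassigns voxels whose within-slice
8-neighbourhood is dominated by a single different class, removing isolated
misclassified pixels.  Hemispheres are split at the image midline; the
contralateral reference is the hemisphere mean for thresholds and the
column-mirrored voxel for voxel-wise relative features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .dti import ConfigurationError

__all__ = [
    "LabelingConfig",
    "LabelMap",
    "LABEL_EXCLUDED",
    "LABEL_IC",
    "LABEL_IP",
    "LABEL_NT",
    "hemisphere_mask",
    "mirror_columns",
    "contralateral_reference",
    "threshold_ic",
    "threshold_perfusion",
    "derive_pdm_labels",
    "contiguity_correction",
]

LABEL_EXCLUDED, LABEL_IC, LABEL_IP, LABEL_NT = 0, 1, 2, 3
LABEL_NAMES = {LABEL_EXCLUDED: "EXCLUDED", LABEL_IC: "IC", LABEL_IP: "IP", LABEL_NT: "NT"}

_NEIGH8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class LabelingConfig:
    md_reduction_threshold: float = 0.30
    cbf_reduction_threshold: float = 0.46
    contiguity_min_neighbors: int = 6
    contiguity_passes: int = 1
    ipsilateral_side: str = "left"

    def __post_init__(self) -> None:
        for name in ("md_reduction_threshold", "cbf_reduction_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name}={v} must lie in (0, 1)")
        if not 1 <= self.contiguity_min_neighbors <= 8:
            raise ConfigurationError("contiguity_min_neighbors must be in [1, 8]")
        if self.ipsilateral_side not in ("left", "right"):
            raise ConfigurationError(f"ipsilateral_side must be 'left' or 'right', got {self.ipsilateral_side!r}")


@dataclass
class LabelMap:
    """Per-voxel tissue classes with bookkeeping about which rule fired."""

    label: np.ndarray  # int: 0 excluded, 1 IC, 2 IP, 3 NT
    qc: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {name: int((self.label == code).sum()) for code, name in LABEL_NAMES.items()}


def hemisphere_mask(shape: tuple[int, ...], side: str) -> np.ndarray:
    """Boolean mask of the requested hemisphere; columns split at midline."""
    cols = shape[-1]
    if cols % 2 != 0:
        raise ConfigurationError(f"column count {cols} must be even for a defined midline")
    half = cols // 2
    col_sel = np.arange(cols) < half if side == "left" else np.arange(cols) >= half
    out = np.zeros(shape, dtype=bool)
    out[..., col_sel] = True
    return out


def mirror_columns(map_: np.ndarray) -> np.ndarray:
    """Reflect the column axis about the image midline (c -> C-1-c)."""
    return map_[..., ::-1]


def contralateral_reference(
    map_: np.ndarray,
    side: str,
    mask: np.ndarray,
    exclude: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Contralateral hemisphere mean and per-voxel mirror values.

    The scalar mean (over in-mask contralateral voxels, minus any
    ``exclude`` region such as ventricles) anchors the reduction
    thresholds; the mirrored map supplies each voxel's homologous value
    for relative metrics.
    """
    contra = ~hemisphere_mask(map_.shape, side)
    sel = contra & mask.astype(bool)
    if exclude is not None:
        sel &= ~exclude.astype(bool)
    if not sel.any():
        raise ValueError("empty contralateral mask")
    mean = float(np.nanmean(map_[sel]))
    return mean, mirror_columns(map_)


def threshold_ic(
    md: np.ndarray,
    cfg: LabelingConfig,
    brain_mask: np.ndarray,
    ventricle_mask: np.ndarray,
) -> np.ndarray:
    """IC candidates: ipsilateral, non-ventricle, MD < (1-thr) x contralateral mean."""
    ipsi = hemisphere_mask(md.shape, cfg.ipsilateral_side) & brain_mask.astype(bool)
    ref, _ = contralateral_reference(md, cfg.ipsilateral_side, brain_mask, exclude=ventricle_mask)
    cut = (1.0 - cfg.md_reduction_threshold) * ref
    with np.errstate(invalid="ignore"):
        below = md < cut
    return below & ipsi & ~ventricle_mask.astype(bool)


def threshold_perfusion(
    rcbf: np.ndarray,
    cfg: LabelingConfig,
    brain_mask: np.ndarray,
    ventricle_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Perfusion deficit: ipsilateral, rCBF < (1-thr) x contralateral mean."""
    vent = ventricle_mask if ventricle_mask is not None else np.zeros(rcbf.shape, dtype=bool)
    ipsi = hemisphere_mask(rcbf.shape, cfg.ipsilateral_side) & brain_mask.astype(bool)
    ref, _ = contralateral_reference(rcbf, cfg.ipsilateral_side, brain_mask, exclude=vent)
    cut = (1.0 - cfg.cbf_reduction_threshold) * ref
    with np.errstate(invalid="ignore"):
        below = rcbf < cut
    return below & ipsi & ~vent.astype(bool)


def derive_pdm_labels(
    ic_mask: np.ndarray,
    deficit_mask: np.ndarray,
    cfg: LabelingConfig,
    brain_mask: np.ndarray,
    ventricle_mask: np.ndarray,
) -> LabelMap:
    """Combine the diffusion and perfusion masks into IC / IP / NT labels.

    IP is the mismatch (deficit minus IC); NT is the ipsilateral remainder.
    IC voxels outside the perfusion deficit keep their IC label (the
    diffusion lesion takes precedence) and are counted in QC.  Contiguity
    correction is applied last.
    """
    if ic_mask.shape != deficit_mask.shape:
        raise ValueError("masks must share a grid")
    ipsi = hemisphere_mask(ic_mask.shape, cfg.ipsilateral_side) & brain_mask.astype(bool)
    eligible = ipsi & ~ventricle_mask.astype(bool)

    label = np.zeros(ic_mask.shape, dtype=np.int16)
    label[eligible] = LABEL_NT
    label[deficit_mask & eligible] = LABEL_IP
    label[ic_mask & eligible] = LABEL_IC

    ic_outside_deficit = int((ic_mask & ~deficit_mask & eligible).sum())
    lm = LabelMap(label=label, qc={"ic_outside_deficit": ic_outside_deficit})
    return contiguity_correction(lm, cfg)


def contiguity_correction(labels: LabelMap | np.ndarray, cfg: LabelingConfig) -> LabelMap:
    """Reassign voxels dominated by a single different class in-plane.

    A labeled voxel whose within-slice 8-neighbourhood contains at least
    ``cfg.contiguity_min_neighbors`` voxels of one *other* class is
    reassigned to that class (ties broken toward the lower class code).
    Updates are synchronous within a pass; ``cfg.contiguity_passes`` passes
    are applied.  Excluded voxels never change and never count as
    neighbours of any tissue class.
    """
    if isinstance(labels, LabelMap):
        lab = labels.label.copy()
        qc = dict(labels.qc)
    else:
        lab = np.asarray(labels).copy()
        qc = {}
    classes = (LABEL_IC, LABEL_IP, LABEL_NT)
    n_reassigned = 0
    for _ in range(cfg.contiguity_passes):
        counts = np.zeros((len(classes),) + lab.shape)
        for k, cls in enumerate(classes):
            is_cls = (lab == cls).astype(float)
            for s in range(lab.shape[0]):
                counts[k, s] = convolve(is_cls[s], _NEIGH8, mode="constant", cval=0.0)
        new = lab.copy()
        for k, cls in enumerate(classes):
            others = [j for j in range(len(classes)) if j != k]
            other_counts = counts[others][:, lab == cls]  # (n_other, n_vox)
            vox_idx = np.argwhere(lab == cls)
            best = np.argmax(other_counts, axis=0)  # ties -> lower class code
            best_count = other_counts[best, np.arange(other_counts.shape[1])]
            move = best_count >= cfg.contiguity_min_neighbors
            tgt = np.array([classes[others[b]] for b in best])
            sel = vox_idx[move]
            new[tuple(sel.T)] = tgt[move]
            n_reassigned += int(move.sum())
        lab = new
    qc["contiguity_reassigned"] = qc.get("contiguity_reassigned", 0) + n_reassigned
    return LabelMap(label=lab, qc=qc)
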