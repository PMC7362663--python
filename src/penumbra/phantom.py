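"""Synthetic rat-brain phantom cohorts for the stroke-segmentation pipeline.

Real acquisitions for this analysis are multi-slice coronal volumes per
animal: three diffusion-tensor eigenvalue maps and a DSC-MRI bolus-passage
time-series per voxel, with one hemisphere carrying a permanent-occlusion
stroke lesion.  The generator emulates that structure on a (slice, row,
col) grid:

- an elliptical brain mask, mirror-symmetric about the image midline;
- small periventricular CSF regions with elevated diffusivity (2.5x the
  normal-tissue MD), recorded in a ventricle mask;
- one random ellipsoidal infarct core (IC) per animal spanning contiguous
  slices, surrounded by a 1-3 voxel penumbra (IP) rim, confined to one
  hemisphere; lesion position and size vary across animals;
- eigenvalue maps: normal tissue has lam = (1.2, 0.9, 0.6)e-3 mm^2/s with
  a smooth, mirror-symmetric anisotropy modulation that preserves the
  trace (so MD is spatially flat and FA stays left-right symmetric, as
  observed hyperacutely); lesions scale all three eigenvalues by a common
  factor (default 40% drop in the IC, 10% in the IP rim);
- DSC signal: a gamma-variate concentration bolus through the exponential
  signal model S = S0 exp(-TE*C), with per-voxel amplitude scaled by
  (1 - cbf_drop); CBF deficits are graded IC > IP > ipsilateral NT >
  contralateral (default drops 0.80 / 0.60 / 0.10 / 0).

Additive Gaussian noise (clipped at zero, eigenvalues re-sorted) models
measurement noise on both channels.  All randomness derives from the spec
seed, so a spec is a complete, reproducible description of a cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dti import ConfigurationError, EigenMaps
from .labeling import (
    LABEL_IC,
    LABEL_IP,
    LABEL_NT,
    LabelingConfig,
    contiguity_correction,
)
from .perfusion import DscSeries, gamma_variate

__all__ = ["PhantomSpec", "RatPhantom", "generate_cohort", "make_dsc_series"]

#: Normal-tissue eigenvalue baseline (mm^2/s), sorted descending.
NT_EIGENVALUES = (1.2e-3, 0.9e-3, 0.6e-3)
#: Ventricle MD as a multiple of normal-tissue MD.
VENTRICLE_MD_FACTOR = 2.5
#: DSC baseline signal level (arbitrary units).
BASELINE_SIGNAL = 100.0


@dataclass(frozen=True)
class PhantomSpec:
    """Complete, seeded description of a synthetic cohort.

    Drop fractions are reductions relative to the contralateral value:
    a diffusivity drop of 0.40 means the lesion retains 60% of normal
    diffusivity.  CBF drops must straddle the 46% viability threshold
    (IP above it, ipsilateral NT below it) so that the generated geometry
    is recoverable by perfusion-diffusion-mismatch labeling.
    """

    n_rats: int = 14
    n_slices: int = 5
    grid: tuple[int, int] = (128, 128)
    voxel_size_mm: float = 0.16
    slice_thickness_mm: float = 1.0
    ic_diffusivity_drop: float = 0.40
    ip_diffusivity_drop: float = 0.10
    ic_cbf_drop: float = 0.80
    ip_cbf_drop: float = 0.60
    nt_cbf_drop: float = 0.10
    noise_sd_eigen: float = 5e-6
    noise_sd_signal: float = 1.0
    gamma_params: tuple[float, float, float, float] = (0.3, 3.0, 4.0, 30.0)  # K, alpha, beta (s), t0 (s)
    ip_rim_voxels: tuple[int, int] = (1, 3)  # min/max penumbra rim thickness
    n_timepoints: int = 300
    tr_s: float = 1.0
    te_s: float = 0.020
    ipsilateral_side: str = "left"
    kspace_zerofill: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        drops = {
            "ic_diffusivity_drop": self.ic_diffusivity_drop,
            "ip_diffusivity_drop": self.ip_diffusivity_drop,
            "ic_cbf_drop": self.ic_cbf_drop,
            "ip_cbf_drop": self.ip_cbf_drop,
            "nt_cbf_drop": self.nt_cbf_drop,
        }
        for name, v in drops.items():
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name}={v} violates 0 <= drop < 1")
        if not self.ic_cbf_drop > self.ip_cbf_drop > self.nt_cbf_drop:
            raise ConfigurationError(
                "CBF drops must be graded ic_cbf_drop > ip_cbf_drop > nt_cbf_drop, got "
                f"{self.ic_cbf_drop} / {self.ip_cbf_drop} / {self.nt_cbf_drop}"
            )
        if self.ip_cbf_drop <= 0.46:
            raise ConfigurationError(
                f"ip_cbf_drop={self.ip_cbf_drop} must exceed 0.46 so the penumbra is a perfusion deficit"
            )
        if self.nt_cbf_drop >= 0.46:
            raise ConfigurationError(
                f"nt_cbf_drop={self.nt_cbf_drop} must be below 0.46 so normal tissue is not a deficit"
            )
        if self.grid[1] % 2 != 0:
            raise ConfigurationError(f"grid columns must be even for a defined midline, got {self.grid[1]}")
        if self.ipsilateral_side not in ("left", "right"):
            raise ConfigurationError(f"ipsilateral_side must be 'left' or 'right', got {self.ipsilateral_side!r}")
        if self.n_rats < 1 or self.n_slices < 1:
            raise ConfigurationError("n_rats and n_slices must be positive")
        if not 1 <= self.ip_rim_voxels[0] <= self.ip_rim_voxels[1]:
            raise ConfigurationError(f"ip_rim_voxels={self.ip_rim_voxels} must satisfy 1 <= min <= max")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RatPhantom:
    """One synthetic animal: images, masks and geometric ground truth."""

    rat_id: str
    eigen: EigenMaps
    dsc: DscSeries
    truth_labels: np.ndarray  # 0 excluded, 1 IC, 2 IP, 3 NT
    ventricle_mask: np.ndarray
    brain_mask: np.ndarray
    cbf_drop_map: np.ndarray


def _brain_mask(n_slices: int, rows: int, cols: int) -> np.ndarray:
    """Elliptical brain cross-section, identical per slice, mirror-symmetric."""
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    ell = ((rr - r0) / (0.40 * rows)) ** 2 + ((cc - c0) / (0.42 * cols)) ** 2 <= 1.0
    return np.broadcast_to(ell, (n_slices, rows, cols)).copy()


def _ventricle_mask(brain: np.ndarray) -> np.ndarray:
    """Two small symmetric periventricular blobs near the midline."""
    n_slices, rows, cols = brain.shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr, dc = max(2, rows // 20), max(1, cols // 28)
    off = max(3, cols // 14)
    blob_l = ((rr - r0) / dr) ** 2 + ((cc - (c0 - off)) / dc) ** 2 <= 1.0
    blob_r = ((rr - r0) / dr) ** 2 + ((cc - (c0 + off)) / dc) ** 2 <= 1.0
    vent = np.broadcast_to(blob_l | blob_r, brain.shape).copy()
    return vent & brain


def _lesion_masks(
    spec: PhantomSpec, brain: np.ndarray, vent: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random ellipsoidal IC with an IP rim, confined to the lesioned hemisphere."""
    n_slices, rows, cols = brain.shape
    half = cols // 2
    ipsi_cols = np.arange(cols) < half if spec.ipsilateral_side == "left" else np.arange(cols) >= half
    ipsi = np.zeros(brain.shape, dtype=bool)
    ipsi[:, :, ipsi_cols] = True

    # lesion centre in hemisphere cortex; size scales with the grid
    if spec.ipsilateral_side == "left":
        c_lo, c_hi = 0.16 * cols, 0.34 * cols
    else:
        c_lo, c_hi = 0.66 * cols, 0.84 * cols
    cen_s = rng.uniform(0.35, 0.65) * (n_slices - 1)
    cen_r = rng.uniform(0.35, 0.65) * (rows - 1)
    cen_c = rng.uniform(c_lo, c_hi)
    rad_s = rng.uniform(0.45, 0.75) * max(n_slices / 2.0, 1.0)
    rad_r = rng.uniform(0.14, 0.22) * rows
    rad_c = rng.uniform(0.10, 0.16) * cols
    lo, hi = spec.ip_rim_voxels
    rim = int(rng.integers(lo, hi + 1))  # IP rim thickness, voxels

    ss, rr, cc = np.mgrid[0:n_slices, 0:rows, 0:cols]
    dist = np.sqrt(
        ((ss - cen_s) / max(rad_s, 0.5)) ** 2
        + ((rr - cen_r) / rad_r) ** 2
        + ((cc - cen_c) / rad_c) ** 2
    )
    ic = (dist <= 1.0) & brain & ipsi & ~vent
    # rim: scale the ellipsoid so its in-plane half-axes grow by `rim` voxels
    grow = 1.0 + rim / min(rad_r, rad_c)
    ip = (dist <= grow) & ~(dist <= 1.0) & brain & ipsi & ~vent
    return ic, ip


def _anisotropy_field(shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth mirror-symmetric deviatoric modulation in [0.5, 1.5].

    Varies anisotropy (white- vs grey-matter-like) across the slab while
    leaving the eigenvalue trace — hence MD — untouched.
    """
    n_slices, rows, cols = shape
    s = np.arange(n_slices)[:, None, None] / max(n_slices - 1, 1)
    r = np.arange(rows)[None, :, None] / max(rows - 1, 1)
    c_half = np.abs(np.arange(cols) - (cols - 1) / 2.0)[None, None, :] / (cols / 2.0)
    return 1.0 + 0.5 * np.sin(2 * np.pi * r) * np.cos(np.pi * c_half) * np.cos(np.pi * s / 2.0)


def _zerofill_smooth(vol: np.ndarray) -> np.ndarray:
    """Emulate acquisition at half matrix size zero-filled back up.

    Each slice is low-pass filtered by cropping its 2-D spatial-frequency
    representation to the central half in each dimension and zero-padding
    back — the smoothing (sinc interpolation) that k-space zero-filling
    imparts to real acquisitions.
    """
    out = np.empty_like(vol, dtype=float)
    rows, cols = vol.shape[-2:]
    r4, c4 = rows // 4, cols // 4
    for s in range(vol.shape[0]):
        f = np.fft.fftshift(np.fft.fft2(vol[s]))
        keep = np.zeros_like(f)
        keep[r4 : rows - r4, c4 : cols - c4] = f[r4 : rows - r4, c4 : cols - c4]
        out[s] = np.real(np.fft.ifft2(np.fft.ifftshift(keep)))
    return out


def make_dsc_series(
    spec: PhantomSpec, cbf_drop_map: np.ndarray, rng: np.random.Generator | None = None
) -> DscSeries:
    """Forward-model a DSC signal series from a per-voxel CBF-drop map.

    The underlying concentration curve is the spec's gamma-variate with its
    amplitude scaled by (1 - drop); rCBF recovered by the perfusion module
    is then proportional to (1 - drop) exactly.  NaN drops mark voxels with
    no bolus (outside the brain): they stay at baseline.
    """
    drops = np.asarray(cbf_drop_map, dtype=float)
    if np.nanmin(drops) < 0 or np.nanmax(drops) >= 1:
        raise ConfigurationError("cbf_drop_map values must lie in [0, 1)")
    K, alpha, beta, t0 = spec.gamma_params
    t = np.arange(spec.n_timepoints) * spec.tr_s
    bolus = gamma_variate(t, K, alpha, beta, t0)  # (T,)
    amp = np.where(np.isnan(drops), 0.0, 1.0 - drops)
    conc = amp[..., None] * bolus
    signal = BASELINE_SIGNAL * np.exp(-spec.te_s * conc)
    if spec.noise_sd_signal > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd_signal, signal.shape)
        signal = np.clip(signal, 1e-6, None)
    baseline_len = max(int(t0 / spec.tr_s) - 5, 2)
    return DscSeries(signal=signal, tr_s=spec.tr_s, te_s=spec.te_s, baseline_window=(0, baseline_len))


def generate_cohort(spec: PhantomSpec) -> list[RatPhantom]:
    """Generate ``spec.n_rats`` seeded phantoms; bit-identical for a given spec."""
    rng = np.random.default_rng(spec.seed)
    n_slices, (rows, cols) = spec.n_slices, spec.grid
    phantoms: list[RatPhantom] = []
    md_nt = float(np.mean(NT_EIGENVALUES))
    dev_base = np.array(NT_EIGENVALUES) - md_nt  # trace-free deviatoric part

    for i in range(spec.n_rats):
        brain = _brain_mask(n_slices, rows, cols)
        vent = _ventricle_mask(brain)
        ic, ip = _lesion_masks(spec, brain, vent, rng)

        labels = np.zeros(brain.shape, dtype=np.int16)
        half = cols // 2
        ipsi_cols = np.arange(cols) < half if spec.ipsilateral_side == "left" else np.arange(cols) >= half
        ipsi = np.zeros(brain.shape, dtype=bool)
        ipsi[:, :, ipsi_cols] = True
        labels[ic] = LABEL_IC
        labels[ip] = LABEL_IP
        labels[brain & ipsi & ~vent & ~ic & ~ip] = LABEL_NT
        # store contiguity-corrected geometry so the ground truth is
        # self-consistent with the labeling stage's final cleanup step
        labels = contiguity_correction(
            labels, LabelingConfig(ipsilateral_side=spec.ipsilateral_side)
        ).label

        aniso = _anisotropy_field(brain.shape)
        lam = md_nt + aniso[..., None] * dev_base  # (S, R, C, 3), MD flat
        scale = np.ones(brain.shape)
        scale[ic] = 1.0 - spec.ic_diffusivity_drop
        scale[ip] = 1.0 - spec.ip_diffusivity_drop
        lam = lam * scale[..., None]
        lam[vent] = VENTRICLE_MD_FACTOR * md_nt  # isotropic CSF-like
        lam[~brain] = 0.0
        if spec.kspace_zerofill:
            lam = np.stack([_zerofill_smooth(lam[..., k]) for k in range(3)], axis=-1)
        if spec.noise_sd_eigen > 0:
            lam = lam + rng.normal(0.0, spec.noise_sd_eigen, lam.shape)
        lam = np.clip(lam, 0.0, None)
        eigen = EigenMaps.from_stack(lam, brain)

        drops = np.full(brain.shape, np.nan)
        drops[brain] = 0.0
        drops[brain & ipsi] = spec.nt_cbf_drop
        drops[ip] = spec.ip_cbf_drop
        drops[ic] = spec.ic_cbf_drop
        drops[vent] = 0.0
        dsc = make_dsc_series(spec, drops, rng)

        phantoms.append(
            RatPhantom(
                rat_id=f"rat{i:02d}",
                eigen=eigen,
                dsc=dsc,
                truth_labels=labels,
                ventricle_mask=vent,
                brain_mask=brain,
                cbf_drop_map=drops,
            )
        )
    return phantoms
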