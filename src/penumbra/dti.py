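"""Diffusion-tensor metrics from eigenvalue maps.

The diffusion tensor at each voxel is summarised by its sorted eigenvalues
``lam1 >= lam2 >= lam3`` (units mm^2/s).  From these we derive the six
scalar metrics used throughout the pipeline:

- MD  mean diffusivity, (l1+l2+l3)/3
- AD  axial diffusivity, l1
- RD  radial diffusivity, (l2+l3)/2
- q   pure (deviatoric) anisotropy, sqrt(sum_i (l_i - MD)^2)
- L   total tensor magnitude, sqrt(sum_i l_i^2)
- FA  fractional anisotropy, sqrt(3/2) * q / L, dimensionless in [0, 1]

Maps are defined on a (slice, row, col) grid with a boolean brain mask;
voxels outside the mask carry NaN.  Smoothing is a within-slice normalised
Gaussian convolution that renormalises over in-mask voxels, and map
normalisation is a linear rescale of in-mask values to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ConfigurationError",
    "EigenMaps",
    "MetricMaps",
    "METRIC_NAMES",
    "compute_metrics",
    "gaussian_smooth",
    "normalize01",
    "smooth_and_normalize",
]

#: Canonical metric order used for map dictionaries and feature blocks.
METRIC_NAMES = ("MD", "AD", "RD", "FA", "L", "q")


class ConfigurationError(ValueError):
    """Raised when a configuration value violates a documented invariant."""


@dataclass
class EigenMaps:
    """Sorted diffusion-tensor eigenvalue maps on a (slice, row, col) grid."""

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.lam1.shape, self.lam2.shape, self.lam3.shape, self.brain_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"eigenvalue maps and mask must share one shape, got {shapes}")
        self.brain_mask = self.brain_mask.astype(bool)

    @classmethod
    def from_stack(cls, eigvals: np.ndarray, brain_mask: np.ndarray) -> "EigenMaps":
        """Build from a (..., 3) stack, sorting each voxel's triple descending."""
        lam = np.sort(np.asarray(eigvals, dtype=float), axis=-1)[..., ::-1]
        return cls(lam[..., 0].copy(), lam[..., 1].copy(), lam[..., 2].copy(), brain_mask)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.lam1.shape

    def stack(self) -> np.ndarray:
        return np.stack([self.lam1, self.lam2, self.lam3], axis=-1)


@dataclass
class MetricMaps:
    """The six DTI metric maps plus smoothed and [0,1]-normalised variants.

    ``raw`` always holds all six metrics; ``smoothed`` and ``normalized``
    are filled by :func:`smooth_and_normalize`.  ``normalization_bounds``
    records the (min, max) used for each normalised map so values can be
    mapped back to physical units.
    """

    raw: dict[str, np.ndarray]
    brain_mask: np.ndarray
    smoothed: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    normalization_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    qc: dict[str, int] = field(default_factory=dict)


def compute_metrics(eigen: EigenMaps) -> MetricMaps:
    """Compute MD, AD, RD, FA, q and L from sorted eigenvalue maps.

    Voxels outside the brain mask are NaN.  An all-zero tensor (L == 0)
    has FA defined as 0 and is counted in ``qc['zero_tensor']``.
    """
    mask = eigen.brain_mask
    l1, l2, l3 = eigen.lam1, eigen.lam2, eigen.lam3

    md = (l1 + l2 + l3) / 3.0
    ad = l1.astype(float).copy()
    rd = (l2 + l3) / 2.0
    q = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    big_l = np.sqrt(l1**2 + l2**2 + l3**2)

    zero_tensor = (big_l == 0) & mask
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * q / big_l
    fa = np.where(big_l > 0, fa, 0.0)

    maps = {"MD": md, "AD": ad, "RD": rd, "FA": fa, "L": big_l, "q": q}
    for name, m in maps.items():
        m = m.astype(float)
        m[~mask] = np.nan
        maps[name] = m
    return MetricMaps(raw=maps, brain_mask=mask, qc={"zero_tensor": int(zero_tensor.sum())})


def gaussian_smooth(
    map_: np.ndarray,
    mask: np.ndarray,
    sigma_vox: float,
    truncate: float = 2.0,
) -> np.ndarray:
    """Within-slice normalised Gaussian smoothing restricted to the mask.

    Kernel weights are renormalised over in-mask voxels so that masked-out
    neighbours contribute nothing; a constant in-mask map is therefore
    returned unchanged.  Out-of-mask voxels stay NaN.
    """
    if sigma_vox <= 0:
        raise ConfigurationError(f"smoothing sigma must be > 0, got {sigma_vox}")
    mask = mask.astype(bool)
    out = np.full(map_.shape, np.nan, dtype=float)
    filled = np.where(mask, map_, 0.0)
    for s in range(map_.shape[0]):
        num = gaussian_filter(filled[s], sigma=sigma_vox, truncate=truncate, mode="constant")
        den = gaussian_filter(mask[s].astype(float), sigma=sigma_vox, truncate=truncate, mode="constant")
        with np.errstate(divide="ignore", invalid="ignore"):
            sm = num / den
        out[s][mask[s]] = sm[mask[s]]
    return out


def normalize01(map_: np.ndarray, mask: np.ndarray, name: str = "map") -> tuple[np.ndarray, tuple[float, float]]:
    """Linearly rescale in-mask values to [0, 1]; returns (map, (min, max))."""
    mask = mask.astype(bool)
    vals = map_[mask]
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if hi == lo:
        raise ConfigurationError(f"cannot normalise constant map {name!r} (all values {lo})")
    out = np.full(map_.shape, np.nan, dtype=float)
    out[mask] = (map_[mask] - lo) / (hi - lo)
    return out, (lo, hi)


def smooth_and_normalize(metrics: MetricMaps, sigma_vox: float = 1.0, truncate: float = 2.0) -> MetricMaps:
    """Fill the smoothed and normalised variants of all six metric maps.

    Smoothing is applied to the derived metric maps (not the eigenvalues),
    then each smoothed map is normalised per-rat over the whole brain mask.
    """
    for name in METRIC_NAMES:
        sm = gaussian_smooth(metrics.raw[name], metrics.brain_mask, sigma_vox, truncate)
        metrics.smoothed[name] = sm
        metrics.normalized[name], metrics.normalization_bounds[name] = normalize01(
            sm, metrics.brain_mask, name
        )
    return metrics
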