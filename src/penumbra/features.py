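"""Voxel-wise feature engineering: 110 features per hemisphere voxel.

Each eligible voxel (ipsilateral, in-brain, non-ventricle) is described by
three blocks, 110 features in total:

- 18 relative DTI features: the six relative metrics
  rX = (X_ipsilateral - X_contralateral) / X_contralateral, where the
  contralateral value is the column-mirrored homologous voxel, taken at
  the voxel itself and at the vertically adjacent voxels in the slices
  below and above (edge slices replicate the nearest slice);
- 90 windowed-histogram features: per metric, an 11-bin normalised
  histogram over the in-plane (coronal) 7x7 window plus its skewness and
  kurtosis, and skewness and kurtosis over a 3x3 window in the axial
  projection reconstructed from the coronal stack (6 x 15 = 90);
- 2 Mahalanobis distances from the voxel's relative-DTI features to the
  Gaussian distribution of infarct-core voxels seen in training, one in
  the 6-dim same-slice space and one in the full 18-dim space.

Histogram bins are equal-width on [-1, 1] with out-of-range values clipped
into the end bins; skewness and kurtosis use population moments (kurtosis
is excess, i.e. 0 for a Gaussian) with a zero-variance convention of 0.
Windows are centred with edge replication, and voxels where a relative
metric is undefined (mirror value ~ 0, or outside the brain) contribute a
relative change of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .dti import ConfigurationError, METRIC_NAMES, MetricMaps
from .labeling import LabelMap, mirror_columns

__all__ = [
    "FeatureConfig",
    "IcDistribution",
    "META_COLUMNS",
    "feature_names",
    "dti_block_names",
    "relative_metrics",
    "fit_ic_distribution",
    "mahalanobis_block",
    "assemble_feature_matrix",
]

META_COLUMNS = ("rat_id", "slice", "row", "col", "label")


@dataclass(frozen=True)
class FeatureConfig:
    coronal_window: tuple[int, int] = (7, 7)
    axial_window: tuple[int, int] = (3, 3)
    n_bins: int = 11
    bin_range: tuple[float, float] = (-1.0, 1.0)
    mirror_eps: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("coronal_window", "axial_window"):
            w = getattr(self, name)
            if w[0] % 2 == 0 or w[1] % 2 == 0:
                raise ConfigurationError(f"{name}={w} must be odd-sized")
        if self.n_bins < 2:
            raise ConfigurationError(f"n_bins={self.n_bins} must be >= 2")
        if not self.bin_range[1] > self.bin_range[0]:
            raise ConfigurationError(f"empty bin range {self.bin_range}")


def dti_block_names() -> list[str]:
    """The 18 relative-DTI column names: 6 own-slice, 6 below, 6 above."""
    own = [f"r{m}" for m in METRIC_NAMES]
    below = [f"r{m}_below" for m in METRIC_NAMES]
    above = [f"r{m}_above" for m in METRIC_NAMES]
    return own + below + above


def feature_names(cfg: FeatureConfig | None = None) -> list[str]:
    """All 110 feature column names in their fixed order [dti | hist | mahal]."""
    cfg = cfg or FeatureConfig()
    names = dti_block_names()
    for m in METRIC_NAMES:
        names += [f"r{m}_cor_bin{i:02d}" for i in range(cfg.n_bins)]
        names += [f"r{m}_cor_skew", f"r{m}_cor_kurt", f"r{m}_ax_skew", f"r{m}_ax_kurt"]
    names += ["mahal6", "mahal18"]
    return names


def relative_metrics(
    metrics: MetricMaps, cfg: FeatureConfig | None = None
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Per-voxel relative change of each smoothed metric vs its mirror voxel.

    rX = (X - X_mirror) / X_mirror with the mirror obtained by reflecting
    the column index about the midline.  Where the mirror value is
    non-finite or smaller than ``mirror_eps`` in magnitude the feature is
    set to 0 and counted in QC; out-of-mask voxels are 0 as well.
    """
    cfg = cfg or FeatureConfig()
    source = metrics.smoothed if metrics.smoothed else metrics.raw
    rel: dict[str, np.ndarray] = {}
    qc = {"undefined_mirror": 0}
    for name in METRIC_NAMES:
        x = source[name]
        mir = mirror_columns(x)
        ok = np.isfinite(x) & np.isfinite(mir) & (np.abs(mir) > cfg.mirror_eps)
        out = np.zeros(x.shape, dtype=float)
        out[ok] = (x[ok] - mir[ok]) / mir[ok]
        qc["undefined_mirror"] += int((np.isfinite(x) & ~ok).sum())
        rel[name] = out
    return rel, qc


def _moments(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population skewness and excess kurtosis along the last axis."""
    mu = windows.mean(axis=-1, keepdims=True)
    d = windows - mu
    m2 = (d**2).mean(axis=-1)
    m3 = (d**3).mean(axis=-1)
    m4 = (d**4).mean(axis=-1)
    ok = m2 > 1e-30
    skew = np.zeros(m2.shape)
    kurt = np.zeros(m2.shape)
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    kurt[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    return skew, kurt


def _bin_counts(windows: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Normalised histogram counts along the last axis; clips into end bins."""
    lo, hi = cfg.bin_range
    width = (hi - lo) / cfg.n_bins
    idx = np.floor((windows - lo) / width).astype(int)
    idx = np.clip(idx, 0, cfg.n_bins - 1)
    n, w = windows.shape
    counts = np.zeros((n, cfg.n_bins))
    np.add.at(counts, (np.repeat(np.arange(n), w), idx.ravel()), 1.0)
    return counts / w


def _coronal_windows(vol: np.ndarray, sl: np.ndarray, rr: np.ndarray, cc: np.ndarray, win: tuple[int, int]) -> np.ndarray:
    """In-plane windows (edge-replicated) around the given voxels, flattened."""
    hr, hc = win[0] // 2, win[1] // 2
    out = np.empty((sl.size, win[0] * win[1]))
    for s in np.unique(sl):
        pad = np.pad(vol[s], ((hr, hr), (hc, hc)), mode="edge")
        swv = np.lib.stride_tricks.sliding_window_view(pad, win)
        here = sl == s
        out[here] = swv[rr[here], cc[here]].reshape(here.sum(), -1)
    return out


def _axial_windows(vol: np.ndarray, sl: np.ndarray, rr: np.ndarray, cc: np.ndarray, win: tuple[int, int]) -> np.ndarray:
    """Windows in the axial projection (slice x column planes at fixed row)."""
    hs, hc = win[0] // 2, win[1] // 2
    out = np.empty((sl.size, win[0] * win[1]))
    for r in np.unique(rr):
        plane = vol[:, r, :]  # (S, C)
        pad = np.pad(plane, ((hs, hs), (hc, hc)), mode="edge")
        swv = np.lib.stride_tricks.sliding_window_view(pad, win)
        here = rr == r
        out[here] = swv[sl[here], cc[here]].reshape(here.sum(), -1)
    return out


@dataclass
class IcDistribution:
    """Gaussian summary of infarct-core relative-DTI features from training.

    Holds mean and ridge-regularised covariance in the 6-dim same-slice
    space and the 18-dim three-slice space; frozen into the trained model
    so test-time Mahalanobis features never see test-set statistics.
    """

    mean6: np.ndarray
    cov6: np.ndarray
    mean18: np.ndarray
    cov18: np.ndarray
    ridge6: float
    ridge18: float
    n_voxels: int
    _cho6: tuple | None = field(default=None, repr=False, compare=False)
    _cho18: tuple | None = field(default=None, repr=False, compare=False)


def _fit_gaussian(x: np.ndarray, ridge_scale: float = 1e-6) -> tuple[np.ndarray, np.ndarray, float]:
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    # absolute floor keeps a degenerate (near-identical) cloud well posed
    ridge = max(ridge_scale * float(np.mean(np.diag(cov))), 1e-12)
    return mean, cov + ridge * np.eye(cov.shape[0]), ridge


def fit_ic_distribution(features18: np.ndarray, ridge_scale: float = 1e-6) -> IcDistribution:
    """Fit the IC feature distribution on training IC voxels' 18-dim block.

    The 6-dim variant uses the own-slice columns (the first six).  Requires
    at least d+1 voxels for the d-dim covariance to be meaningful.
    """
    x = np.asarray(features18, dtype=float)
    if x.ndim != 2 or x.shape[1] != 18:
        raise ValueError(f"expected (n, 18) IC feature block, got {x.shape}")
    if x.shape[0] < 19:
        raise ValueError(
            f"need at least 19 IC voxels to fit the 18-dim covariance, got {x.shape[0]}; "
            "enlarge the training set"
        )
    mean6, cov6, ridge6 = _fit_gaussian(x[:, :6], ridge_scale)
    mean18, cov18, ridge18 = _fit_gaussian(x, ridge_scale)
    return IcDistribution(mean6, cov6, mean18, cov18, ridge6, ridge18, x.shape[0])


def _cho(dist: IcDistribution, which: str):
    attr = "_cho6" if which == "6" else "_cho18"
    if getattr(dist, attr) is None:
        cov = dist.cov6 if which == "6" else dist.cov18
        ridge = dist.ridge6 if which == "6" else dist.ridge18
        for _ in range(8):
            try:
                object.__setattr__(dist, attr, cho_factor(cov, lower=True))
                break
            except np.linalg.LinAlgError:
                ridge *= 10.0
                cov = cov + ridge * np.eye(cov.shape[0])
        else:
            raise np.linalg.LinAlgError("covariance not positive definite after ridge escalation")
    return getattr(dist, attr)


def mahalanobis_block(features18: np.ndarray, dist: IcDistribution) -> np.ndarray:
    """Mahalanobis distances to the IC distribution: (n, 2) = [6-dim, 18-dim]."""
    x = np.atleast_2d(np.asarray(features18, dtype=float))
    if x.shape[1] != 18:
        raise ValueError(f"expected 18 columns, got {x.shape[1]}")
    out = np.empty((x.shape[0], 2))
    for j, (which, mean, sub) in enumerate(
        [("6", dist.mean6, x[:, :6]), ("18", dist.mean18, x)]
    ):
        d = sub - mean
        sol = cho_solve(_cho(dist, which), d.T)
        out[:, j] = np.sqrt(np.maximum(np.einsum("ij,ji->i", d, sol), 0.0))
    return out


def assemble_feature_matrix(
    rel: dict[str, np.ndarray],
    labels: LabelMap | np.ndarray,
    rat_id: str,
    cfg: FeatureConfig | None = None,
    dist: IcDistribution | None = None,
) -> pd.DataFrame:
    """One row per eligible voxel with the 110 features in fixed column order.

    ``rel`` maps metric names to full-grid relative-metric volumes.  The
    Mahalanobis block is filled with a sentinel 0 when no IC distribution
    is supplied (level-1 use) and with real distances otherwise.
    """
    cfg = cfg or FeatureConfig()
    lab = labels.label if isinstance(labels, LabelMap) else np.asarray(labels)
    sl, rr, cc = np.nonzero(lab > 0)
    n = sl.size
    if n == 0:
        raise ValueError("no eligible voxels to featurise")
    arr6 = np.stack([rel[m] for m in METRIC_NAMES])  # (6, S, R, C)
    n_slices = arr6.shape[1]

    below = np.clip(sl - 1, 0, n_slices - 1)
    above = np.clip(sl + 1, 0, n_slices - 1)
    own_f = arr6[:, sl, rr, cc].T
    below_f = arr6[:, below, rr, cc].T
    above_f = arr6[:, above, rr, cc].T
    dti18 = np.concatenate([own_f, below_f, above_f], axis=1)

    hist_parts = []
    for k in range(len(METRIC_NAMES)):
        cor = _coronal_windows(arr6[k], sl, rr, cc, cfg.coronal_window)
        counts = _bin_counts(cor, cfg)
        cs, ck = _moments(cor)
        ax = _axial_windows(arr6[k], sl, rr, cc, cfg.axial_window)
        as_, ak = _moments(ax)
        hist_parts.append(np.column_stack([counts, cs, ck, as_, ak]))
    hist90 = np.concatenate(hist_parts, axis=1)

    mahal = mahalanobis_block(dti18, dist) if dist is not None else np.zeros((n, 2))

    data = np.concatenate([dti18, hist90, mahal], axis=1)
    cols = feature_names(cfg)
    if data.shape[1] != len(cols):
        raise ValueError(f"feature block mismatch: {data.shape[1]} columns vs {len(cols)} names")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in assembled feature matrix")
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "rat_id", rat_id)
    df.insert(1, "slice", sl)
    df.insert(2, "row", rr)
    df.insert(3, "col", cc)
    df.insert(4, "label", lab[sl, rr, cc].astype(int))
    return df
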