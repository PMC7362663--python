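"""Feature engineering: relative metrics, windowed histograms, Mahalanobis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kurtosis, skew

from penumbra import (
    FeatureConfig,
    METRIC_NAMES,
    assemble_feature_matrix,
    compute_metrics,
    dti_block_names,
    feature_names,
    fit_ic_distribution,
    mahalanobis_block,
    relative_metrics,
    smooth_and_normalize,
)
from penumbra.features import IcDistribution
from penumbra.labeling import LABEL_IC, LABEL_NT

CFG = FeatureConfig()


def _rel_maps(shape, value=0.0):
    return {m: np.full(shape, float(value)) for m in METRIC_NAMES}


def _labels(shape, where=None):
    lab = np.zeros(shape, dtype=np.int16)
    if where is None:
        lab[:, :, : shape[2] // 2] = LABEL_NT
    else:
        lab[where] = LABEL_NT
    return lab


class TestRelativeMetrics:
    def test_symmetric_maps_give_zero(self, noiseless_cohort):
        p = noiseless_cohort[0]
        metrics = compute_metrics(p.eigen)
        # wipe the lesion: make the volume perfectly symmetric
        sym = {m: np.where(np.isfinite(v), np.nanmean(v), np.nan) for m, v in metrics.raw.items()}
        metrics.raw.update(sym)
        rel, _ = relative_metrics(metrics, CFG)
        for m in METRIC_NAMES:
            assert np.allclose(rel[m], 0.0)

    def test_forty_percent_reduction_gives_minus_point_four(self):
        md = np.full((1, 4, 8), 1.0)
        md[0, :, :4] = 0.6  # ipsilateral at 60% of mirror
        from penumbra.dti import MetricMaps

        maps = MetricMaps(raw={m: md.copy() for m in METRIC_NAMES}, brain_mask=np.ones(md.shape, bool))
        rel, _ = relative_metrics(maps, CFG)
        assert np.allclose(rel["MD"][0, :, :4], -0.4)
        assert np.allclose(rel["MD"][0, :, 4:], 1 / 0.6 - 1)

    def test_matches_explicit_mirror_indexing(self):
        rng = np.random.default_rng(4)
        vol = rng.uniform(0.5, 2.0, (2, 6, 10))
        from penumbra.dti import MetricMaps

        maps = MetricMaps(raw={m: vol.copy() for m in METRIC_NAMES}, brain_mask=np.ones(vol.shape, bool))
        rel, _ = relative_metrics(maps, CFG)
        C = vol.shape[2]
        for s in range(2):
            for r in range(6):
                for c in range(C):
                    mir = vol[s, r, C - 1 - c]
                    assert rel["MD"][s, r, c] == pytest.approx((vol[s, r, c] - mir) / mir, rel=1e-12)

    def test_tiny_mirror_value_zeroed_with_qc(self):
        vol = np.ones((1, 2, 4))
        vol[0, 0, 3] = 0.0  # mirror of (0,0,0)
        from penumbra.dti import MetricMaps

        maps = MetricMaps(raw={m: vol.copy() for m in METRIC_NAMES}, brain_mask=np.ones(vol.shape, bool))
        rel, qc = relative_metrics(maps, CFG)
        assert rel["MD"][0, 0, 0] == 0.0
        assert qc["undefined_mirror"] >= 1


class TestDtiBlock:
    def _slice_coded_matrix(self):
        """Relative maps whose value equals the slice index."""
        shape = (3, 4, 8)
        rel = {m: np.broadcast_to(np.arange(3, dtype=float)[:, None, None], shape).copy() for m in METRIC_NAMES}
        lab = _labels(shape)
        return assemble_feature_matrix(rel, lab, "r", CFG)

    def test_block_order_own_below_above(self):
        df = self._slice_coded_matrix()
        mid = df[df["slice"] == 1].iloc[0]
        names = dti_block_names()
        assert [mid[n] for n in names[:6]] == [1.0] * 6  # own
        assert [mid[n] for n in names[6:12]] == [0.0] * 6  # below = slice-1
        assert [mid[n] for n in names[12:]] == [2.0] * 6  # above = slice+1

    def test_edge_slice_replication(self):
        df = self._slice_coded_matrix()
        first = df[df["slice"] == 0].iloc[0]
        assert first["rMD_below"] == first["rMD"]
        last = df[df["slice"] == 2].iloc[0]
        assert last["rMD_above"] == last["rMD"]

    def test_block_length_is_18(self):
        assert len(dti_block_names()) == 18


class TestHistogramBlock:
    def test_constant_zero_window_middle_bin(self):
        shape = (1, 9, 10)
        df = assemble_feature_matrix(_rel_maps(shape, 0.0), _labels(shape), "r", CFG)
        row = df.iloc[0]
        assert row["rMD_cor_bin05"] == 1.0
        for i in [j for j in range(11) if j != 5]:
            assert row[f"rMD_cor_bin{i:02d}"] == 0.0
        assert row["rMD_cor_skew"] == 0.0 and row["rMD_cor_kurt"] == 0.0
        assert row["rMD_ax_skew"] == 0.0 and row["rMD_ax_kurt"] == 0.0

    def test_window_against_brute_force_counts_and_moments(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(-1.2, 1.2, 49)  # includes out-of-range values
        shape = (1, 7, 14)
        rel = _rel_maps(shape, 0.0)
        rel["MD"][0, :, :7] = vals.reshape(7, 7)
        lab = np.zeros(shape, dtype=np.int16)
        lab[0, 3, 3] = LABEL_NT  # centred: window == the 7x7 block exactly
        df = assemble_feature_matrix(rel, lab, "r", CFG)
        row = df.iloc[0]

        edges = np.linspace(-1, 1, 12)
        clipped = np.clip(vals, -1, 1 - 1e-12)
        counts, _ = np.histogram(clipped, bins=edges)
        for i in range(11):
            assert row[f"rMD_cor_bin{i:02d}"] == pytest.approx(counts[i] / 49, abs=1e-12)
        assert row["rMD_cor_skew"] == pytest.approx(skew(vals, bias=True), abs=1e-12)
        assert row["rMD_cor_kurt"] == pytest.approx(kurtosis(vals, fisher=True, bias=True), abs=1e-12)

    def test_axial_moments_against_brute_force(self):
        rng = np.random.default_rng(12)
        shape = (3, 6, 10)
        rel = _rel_maps(shape, 0.0)
        rel["MD"] = rng.uniform(-0.5, 0.5, shape)
        lab = np.zeros(shape, dtype=np.int16)
        lab[1, 3, 2] = LABEL_NT
        df = assemble_feature_matrix(rel, lab, "r", CFG)
        window = rel["MD"][0:3, 3, 1:4].ravel()  # slices 0..2, cols 1..3 at row 3
        assert df.iloc[0]["rMD_ax_skew"] == pytest.approx(skew(window, bias=True), abs=1e-12)
        assert df.iloc[0]["rMD_ax_kurt"] == pytest.approx(kurtosis(window, fisher=True, bias=True), abs=1e-12)

    def test_histograms_sum_to_one(self, noiseless_cohort):
        p = noiseless_cohort[0]
        metrics = smooth_and_normalize(compute_metrics(p.eigen))
        rel, _ = relative_metrics(metrics, CFG)
        df = assemble_feature_matrix(rel, p.truth_labels, p.rat_id, CFG)
        for m in METRIC_NAMES:
            bins = df[[f"r{m}_cor_bin{i:02d}" for i in range(11)]].sum(axis=1)
            np.testing.assert_allclose(bins, 1.0, atol=1e-12)


class TestMahalanobis:
    def _dist(self, rng, n=200):
        x = rng.normal(size=(n, 18)) @ np.diag(rng.uniform(0.5, 2.0, 18))
        return x, fit_ic_distribution(x)

    def test_distance_zero_at_mean(self):
        rng = np.random.default_rng(13)
        x, dist = self._dist(rng)
        d = mahalanobis_block(dist.mean18[None, :], dist)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_identity_covariance_reduces_to_euclidean(self):
        mean = np.zeros(18)
        dist = IcDistribution(
            mean6=mean[:6], cov6=np.eye(6), mean18=mean, cov18=np.eye(18), ridge6=0.0, ridge18=0.0, n_voxels=100
        )
        rng = np.random.default_rng(14)
        x = rng.normal(size=(5, 18))
        d = mahalanobis_block(x, dist)
        np.testing.assert_allclose(d[:, 1], np.linalg.norm(x, axis=1), atol=1e-10)
        np.testing.assert_allclose(d[:, 0], np.linalg.norm(x[:, :6], axis=1), atol=1e-10)

    def test_matches_explicit_inverse(self):
        rng = np.random.default_rng(15)
        x, dist = self._dist(rng)
        pts = rng.normal(size=(10, 18))
        d = mahalanobis_block(pts, dist)
        inv18 = np.linalg.inv(dist.cov18)
        inv6 = np.linalg.inv(dist.cov6)
        for i in range(10):
            dx = pts[i] - dist.mean18
            assert d[i, 1] == pytest.approx(np.sqrt(dx @ inv18 @ dx), abs=1e-10)
            dx6 = pts[i, :6] - dist.mean6
            assert d[i, 0] == pytest.approx(np.sqrt(dx6 @ inv6 @ dx6), abs=1e-10)

    def test_sample_covariance_formula(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(40, 18))
        dist = fit_ic_distribution(x)
        manual = (x - x.mean(0)).T @ (x - x.mean(0)) / (x.shape[0] - 1)
        np.testing.assert_allclose(dist.cov18 - dist.ridge18 * np.eye(18), manual, atol=1e-12)

    def test_degenerate_identical_cloud(self):
        x = np.tile(np.linspace(0, 1, 18), (25, 1))
        dist = fit_ic_distribution(x)
        d = mahalanobis_block(x[:1], dist)
        assert np.allclose(d, 0.0, atol=1e-6)

    def test_too_few_ic_voxels_raises(self):
        with pytest.raises(ValueError, match="at least 19"):
            fit_ic_distribution(np.zeros((5, 18)))

    def test_refit_with_extra_rows_changes_distribution(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(50, 18))
        extra = rng.normal(loc=3.0, size=(10, 18))
        d1 = fit_ic_distribution(x)
        d2 = fit_ic_distribution(np.vstack([x, extra]))
        assert not np.allclose(d1.mean18, d2.mean18)


class TestMatrixSchema:
    def test_110_columns_in_blocks(self):
        names = feature_names()
        assert len(names) == 110
        assert names[:18] == dti_block_names()
        assert names[-2:] == ["mahal6", "mahal18"]
        assert len(names[18:-2]) == 90

    def test_row_count_and_stable_order(self):
        shape = (2, 6, 8)
        rel = _rel_maps(shape, 0.1)
        lab = _labels(shape)
        df1 = assemble_feature_matrix(rel, lab, "a", CFG)
        df2 = assemble_feature_matrix(rel, lab, "b", CFG)
        assert len(df1) == int((lab > 0).sum())
        assert list(df1.columns) == list(df2.columns)
        assert list(df1.columns[5:]) == feature_names()

    def test_sentinel_vs_real_mahalanobis(self):
        rng = np.random.default_rng(18)
        shape = (1, 8, 10)
        rel = {m: rng.uniform(-0.2, 0.2, shape) for m in METRIC_NAMES}
        lab = _labels(shape)
        df0 = assemble_feature_matrix(rel, lab, "r", CFG)
        assert (df0["mahal18"] == 0).all()
        x = rng.normal(size=(30, 18))
        dist = fit_ic_distribution(x)
        df1 = assemble_feature_matrix(rel, lab, "r", CFG, dist=dist)
        assert (df1["mahal18"] > 0).all()

    def test_no_nan_inf_on_phantom(self, noiseless_cohort):
        p = noiseless_cohort[1]
        metrics = smooth_and_normalize(compute_metrics(p.eigen))
        rel, _ = relative_metrics(metrics, CFG)
        df = assemble_feature_matrix(rel, p.truth_labels, p.rat_id, CFG)
        assert np.isfinite(df[feature_names()].to_numpy()).all()

    def test_translation_consistency(self):
        rng = np.random.default_rng(19)
        shape = (1, 16, 20)
        base = {m: rng.uniform(-0.3, 0.3, shape) for m in METRIC_NAMES}
        shifted = {m: np.roll(v, 1, axis=2) for m, v in base.items()}
        lab = np.zeros(shape, dtype=np.int16)
        lab[0, 8, 5] = LABEL_NT
        lab_s = np.roll(lab, 1, axis=2)
        f0 = assemble_feature_matrix(base, lab, "r", CFG)[feature_names()].to_numpy()
        f1 = assemble_feature_matrix(shifted, lab_s, "r", CFG)[feature_names()].to_numpy()
        np.testing.assert_allclose(f0, f1, atol=1e-12)
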