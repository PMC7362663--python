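"""PDM labeling: thresholds, mismatch algebra, contiguity correction."""

import numpy as np
import pytest

from penumbra import (
    LabelMap,
    LabelingConfig,
    compute_metrics,
    contiguity_correction,
    contralateral_reference,
    derive_pdm_labels,
    fit_cbf_map,
    threshold_ic,
    threshold_perfusion,
)
from penumbra.labeling import LABEL_EXCLUDED, LABEL_IC, LABEL_IP, LABEL_NT, hemisphere_mask, mirror_columns

CFG = LabelingConfig()


def _grid(cols=8, rows=4, fill=1.0):
    """Full-mask single-slice grid with a constant contralateral side."""
    m = np.full((1, rows, cols), fill)
    mask = np.ones((1, rows, cols), bool)
    vent = np.zeros((1, rows, cols), bool)
    return m, mask, vent


class TestContralateralReference:
    def test_symmetric_map_mirrors_to_itself(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(size=(2, 6, 5))
        sym = np.concatenate([half, half[..., ::-1]], axis=-1)
        _, mirror = contralateral_reference(sym, "left", np.ones(sym.shape, bool))
        np.testing.assert_array_equal(mirror, sym)

    def test_column_reflection_index(self):
        m = np.zeros((1, 1, 128))
        m[0, 0, 117] = 42.0
        _, mirror = contralateral_reference(m, "left", np.ones(m.shape, bool))
        assert mirror[0, 0, 10] == 42.0

    def test_constant_contralateral_mean(self):
        m, mask, _ = _grid()
        m[0, :, 4:] = 7.0
        mean, _ = contralateral_reference(m, "left", mask)
        assert mean == 7.0

    def test_empty_contralateral_raises(self):
        m, mask, _ = _grid()
        mask[..., 4:] = False
        with pytest.raises(ValueError, match="contralateral"):
            contralateral_reference(m, "left", mask)


class TestThresholds:
    @pytest.mark.parametrize(
        "factor, is_ic", [(0.69, True), (0.70, False), (0.71, False)]
    )
    def test_md_threshold_strict_boundary(self, factor, is_ic):
        md, mask, vent = _grid(fill=1.0)
        md[0, 1, 1] = factor
        out = threshold_ic(md, CFG, mask, vent)
        assert out[0, 1, 1] == is_ic
        assert out.sum() == int(is_ic)

    def test_ventricle_voxel_never_ic(self):
        md, mask, vent = _grid(fill=1.0)
        md[0, 1, 1] = 0.5
        vent[0, 1, 1] = True
        assert threshold_ic(md, CFG, mask, vent).sum() == 0

    @pytest.mark.parametrize(
        "factor, deficit", [(0.50, True), (0.54, False), (0.60, False)]
    )
    def test_cbf_threshold_strict_boundary(self, factor, deficit):
        rcbf, mask, vent = _grid(fill=1.0)
        rcbf[0, 2, 0] = factor
        out = threshold_perfusion(rcbf, CFG, mask, vent)
        assert out[0, 2, 0] == deficit
        assert out.sum() == int(deficit)

    def test_whole_hemisphere_deficit(self):
        rcbf, mask, vent = _grid(fill=1.0)
        rcbf[..., :4] = 0.20
        out = threshold_perfusion(rcbf, CFG, mask, vent)
        assert np.array_equal(out, hemisphere_mask(rcbf.shape, "left"))


class TestPdmAlgebra:
    def _blocks(self, rows=12, cols=16):
        mask = np.ones((1, rows, cols), bool)
        vent = np.zeros_like(mask)
        ic = np.zeros_like(mask)
        deficit = np.zeros_like(mask)
        ic[0, 3:9, 2:5] = True
        deficit[0, 2:10, 1:6] = True  # strictly contains ic
        return mask, vent, ic, deficit

    def test_mismatch_rim_and_partition(self):
        mask, vent, ic, deficit = self._blocks()
        lm = derive_pdm_labels(ic, deficit, CFG, mask, vent)
        assert np.array_equal(lm.label == LABEL_IC, ic)
        assert np.array_equal(lm.label == LABEL_IP, deficit & ~ic)
        ipsi = hemisphere_mask(mask.shape, "left") & mask
        counts = lm.counts()
        assert counts["IC"] + counts["IP"] + counts["NT"] == int(ipsi.sum())

    def test_deficit_equal_ic_gives_empty_ip(self):
        mask, vent, ic, _ = self._blocks()
        lm = derive_pdm_labels(ic, ic.copy(), CFG, mask, vent)
        assert lm.counts()["IP"] == 0

    def test_ic_outside_deficit_kept_with_qc(self):
        mask, vent, ic, deficit = self._blocks()
        deficit[0, 3, :] = False  # carve deficit away from one IC row
        lm = derive_pdm_labels(ic, deficit, CFG, mask, vent)
        assert lm.qc["ic_outside_deficit"] == int((ic & ~deficit).sum())
        assert np.all(lm.label[ic] == LABEL_IC)


class TestContiguity:
    def test_isolated_voxel_reassigned(self):
        lab = np.full((1, 5, 5), LABEL_NT, dtype=np.int16)
        lab[0, 2, 2] = LABEL_IC
        out = contiguity_correction(LabelMap(label=lab), CFG)
        assert out.label[0, 2, 2] == LABEL_NT

    def test_interior_of_uniform_block_unchanged(self):
        lab = np.full((1, 9, 9), LABEL_NT, dtype=np.int16)
        lab[0, 2:7, 2:7] = LABEL_IC
        out = contiguity_correction(LabelMap(label=lab), CFG)
        assert out.label[0, 4, 4] == LABEL_IC
        assert np.array_equal(out.label[0, 3:6, 3:6], lab[0, 3:6, 3:6])

    def test_matches_brute_force_neighborhood_scan(self):
        rng = np.random.default_rng(7)
        lab = rng.choice([LABEL_EXCLUDED, LABEL_IC, LABEL_IP, LABEL_NT], size=(2, 12, 12), p=[0.2, 0.2, 0.2, 0.4]).astype(np.int16)
        out = contiguity_correction(LabelMap(label=lab.copy()), CFG)

        expected = lab.copy()
        n_moved = 0
        for s in range(lab.shape[0]):
            for r in range(lab.shape[1]):
                for c in range(lab.shape[2]):
                    cls = lab[s, r, c]
                    if cls == LABEL_EXCLUDED:
                        continue
                    counts = {k: 0 for k in (LABEL_IC, LABEL_IP, LABEL_NT)}
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if dr == dc == 0:
                                continue
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < lab.shape[1] and 0 <= cc < lab.shape[2]:
                                v = lab[s, rr, cc]
                                if v != LABEL_EXCLUDED:
                                    counts[v] += 1
                    others = {k: v for k, v in counts.items() if k != cls}
                    best = min([k for k, v in others.items() if v == max(others.values())])
                    if others[best] >= CFG.contiguity_min_neighbors:
                        expected[s, r, c] = best
                        n_moved += 1
        np.testing.assert_array_equal(out.label, expected)
        assert out.qc["contiguity_reassigned"] == n_moved

    def test_excluded_voxels_never_change(self):
        lab = np.full((1, 5, 5), LABEL_IC, dtype=np.int16)
        lab[0, 2, 2] = LABEL_EXCLUDED
        out = contiguity_correction(LabelMap(label=lab), CFG)
        assert out.label[0, 2, 2] == LABEL_EXCLUDED


class TestRoundTripAndProperties:
    def test_noiseless_round_trip_voxel_exact(self, noiseless_cohort):
        """Thresholding the generated raw maps reproduces the stored truth."""
        for p in noiseless_cohort:
            md = compute_metrics(p.eigen).raw["MD"]
            rcbf = fit_cbf_map(p.dsc, p.brain_mask).rcbf
            ic = threshold_ic(md, CFG, p.brain_mask, p.ventricle_mask)
            deficit = threshold_perfusion(rcbf, CFG, p.brain_mask, p.ventricle_mask)
            lm = derive_pdm_labels(ic, deficit, CFG, p.brain_mask, p.ventricle_mask)
            np.testing.assert_array_equal(lm.label, p.truth_labels)

    def test_partition_invariant_on_phantom(self, rat0, rat0_metrics, rat0_cbf):
        ic = threshold_ic(rat0_metrics.raw["MD"], CFG, rat0.brain_mask, rat0.ventricle_mask)
        deficit = threshold_perfusion(rat0_cbf.rcbf, CFG, rat0.brain_mask, rat0.ventricle_mask)
        lm = derive_pdm_labels(ic, deficit, CFG, rat0.brain_mask, rat0.ventricle_mask)
        eligible = hemisphere_mask(lm.label.shape, "left") & rat0.brain_mask & ~rat0.ventricle_mask
        c = lm.counts()
        assert c["IC"] + c["IP"] + c["NT"] == int(eligible.sum())

    def test_raising_md_threshold_shrinks_ic(self, rat0, rat0_metrics):
        sizes = []
        for thr in (0.2, 0.3, 0.4, 0.5):
            cfg = LabelingConfig(md_reduction_threshold=thr)
            sizes.append(int(threshold_ic(rat0_metrics.raw["MD"], cfg, rat0.brain_mask, rat0.ventricle_mask).sum()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
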