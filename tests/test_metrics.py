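"""Seven-metric suite vs brute-force oracles, identities, aggregation."""

import math

import numpy as np
import pytest

from msaunet.metrics import (
    METRIC_NAMES,
    compute_case_metrics,
    evaluate_model,
    hausdorff_distance,
    overlap_metrics,
    volume_metrics,
)

from .oracles import hausdorff_oracle, overlap_oracle, volume_oracle


def square_mask(size, r0, c0, side):
    m = np.zeros((size, size), dtype=np.uint8)
    m[r0:r0 + side, c0:c0 + side] = 1
    return m


class TestOverlap:
    def test_identical_masks(self):
        m = square_mask(16, 4, 4, 6)
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a = square_mask(16, 0, 0, 4)
        b = square_mask(16, 10, 10, 4)
        assert overlap_metrics(a, b) == (0.0, 0.0, 0.0, 0.0)

    def test_half_covered_square(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[2:4, 2:4] = 1  # 4 pixels
        pred = np.zeros((8, 8), dtype=np.uint8)
        pred[2, 2:4] = 1  # 2 of those 4
        dsc, jsc, ppv, se = overlap_metrics(gt, pred)
        assert dsc == pytest.approx(2 * 2 / (4 + 2))
        assert jsc == pytest.approx(0.5)
        assert ppv == 1.0
        assert se == 0.5

    def test_empty_gt_se_nan(self):
        dsc, jsc, ppv, se = overlap_metrics(np.zeros((4, 4)), square_mask(4, 0, 0, 2))
        assert math.isnan(se)

    def test_empty_pred_ppv_nan(self):
        dsc, jsc, ppv, se = overlap_metrics(square_mask(4, 0, 0, 2), np.zeros((4, 4)))
        assert math.isnan(ppv)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            overlap_metrics(np.zeros((4, 4)), np.zeros((5, 5)))


class TestHausdorff:
    def test_identical_zero(self):
        m = square_mask(16, 3, 3, 5)
        assert hausdorff_distance(m, m) == 0.0

    def test_single_pixels_3_4_5(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff_distance(a, b) == pytest.approx(5.0)

    def test_shifted_squares(self):
        a = square_mask(16, 4, 4, 5)
        b = square_mask(16, 4, 5, 5)
        assert hausdorff_distance(a, b) == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hausdorff_distance(np.zeros((8, 8)), square_mask(8, 1, 1, 2))

    def test_symmetry(self, rng):
        a = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        b = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        if a.any() and b.any():
            assert hausdorff_distance(a, b) == hausdorff_distance(b, a)

    def test_percentile_leq_max(self, rng):
        a = (rng.random((24, 24)) > 0.7).astype(np.uint8)
        b = (rng.random((24, 24)) > 0.7).astype(np.uint8)
        assert hausdorff_distance(a, b, percentile=95) <= hausdorff_distance(a, b)


class TestVolume:
    def test_identical(self):
        m = square_mask(16, 2, 2, 6)
        assert volume_metrics(m, m) == (0.0, 0.0)

    def test_superset_20pct(self):
        gt = np.zeros((20, 20), dtype=np.uint8)
        gt.flat[:100] = 1
        pred = np.zeros((20, 20), dtype=np.uint8)
        pred.flat[:120] = 1
        rvd, voe = volume_metrics(gt, pred)
        assert rvd == pytest.approx(0.2)
        assert voe == pytest.approx(1 - 100 / 120)

    def test_disjoint_voe_one(self):
        a = square_mask(16, 0, 0, 4)
        b = square_mask(16, 10, 10, 4)
        _, voe = volume_metrics(a, b)
        assert voe == 1.0

    def test_empty_gt_raises(self):
        with pytest.raises(ValueError):
            volume_metrics(np.zeros((4, 4)), square_mask(4, 0, 0, 2))


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self, random_mask_pairs):
        for gt, pred in random_mask_pairs[:40]:  # full 200 run in acceptance
            dsc, jsc, ppv, se = overlap_metrics(gt, pred)
            o_dsc, o_jsc, o_ppv, o_se = overlap_oracle(gt, pred)
            assert dsc == pytest.approx(o_dsc, abs=1e-9)
            assert jsc == pytest.approx(o_jsc, abs=1e-9)
            assert ppv == pytest.approx(o_ppv, abs=1e-9)
            assert se == pytest.approx(o_se, abs=1e-9)
            assert hausdorff_distance(gt, pred) == pytest.approx(
                hausdorff_oracle(gt, pred), abs=1e-9
            )
            rvd, voe = volume_metrics(gt, pred)
            o_rvd, o_voe = volume_oracle(gt, pred)
            assert rvd == pytest.approx(o_rvd, abs=1e-9)
            assert voe == pytest.approx(o_voe, abs=1e-9)

    def test_ppv_se_duality(self, random_mask_pairs):
        for gt, pred in random_mask_pairs[:20]:
            _, _, ppv_ab, _ = overlap_metrics(gt, pred)
            _, _, _, se_ba = overlap_metrics(pred, gt)
            assert ppv_ab == pytest.approx(se_ba, abs=1e-12)


class TestCoupledIdentities:
    def test_voe_and_dsc_identities(self, random_mask_pairs):
        for gt, pred in random_mask_pairs[:30]:
            dsc, jsc, _, _ = overlap_metrics(gt, pred)
            _, voe = volume_metrics(gt, pred)
            assert voe == pytest.approx(1 - jsc, abs=1e-12)
            assert dsc == pytest.approx(2 * jsc / (1 + jsc), abs=1e-12)


class TestCaseMetricsPolicy:
    def test_empty_pred_policy(self):
        gt = square_mask(16, 4, 4, 4)
        cm = compute_case_metrics(gt, np.zeros((16, 16)), case_id="c")
        assert cm.dsc == 0.0 and cm.jsc == 0.0
        assert math.isnan(cm.ppv)
        assert cm.hd == pytest.approx(math.hypot(16, 16))
        assert "empty_pred" in cm.flags and "hd_fallback_diagonal" in cm.flags

    def test_clean_case_no_flags(self):
        m = square_mask(16, 4, 4, 5)
        cm = compute_case_metrics(m, m)
        assert cm.flags == []
        assert (cm.dsc, cm.jsc, cm.ppv, cm.se, cm.hd, cm.rvd, cm.voe) == (
            1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0)


class TestEvaluateModel:
    def test_identical_pairs_aggregate(self):
        m = square_mask(16, 4, 4, 5)
        report = evaluate_model([(m, m)] * 4, label="perfect")
        agg = report.aggregate
        assert agg["dsc"] == (1.0, 0.0)
        assert agg["hd"] == (0.0, 0.0)
        assert agg["voe"] == (0.0, 0.0)

    def test_mean_sd_hand_computed(self):
        # two cases with DSC 0.6 and 0.8 -> mean 0.7, sample SD ~0.141421
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[0, :4] = 1
        pred_06 = np.zeros_like(gt)
        pred_06[0, :2] = 1
        pred_06[1, :1] = 1  # TP=2, |gt|=4, |pred|=3 -> dsc=4/7... construct directly
        # simpler: craft dsc exactly 0.6 and 0.8
        gt1 = np.zeros((10, 10), dtype=np.uint8); gt1[0, :5] = 1
        p1 = np.zeros_like(gt1); p1[0, :3] = 1; p1[1, :2] = 1   # TP=3, dsc=6/10=0.6
        gt2 = np.zeros((10, 10), dtype=np.uint8); gt2[0, :5] = 1
        p2 = np.zeros_like(gt2); p2[0, :4] = 1; p2[1, :1] = 1   # TP=4, dsc=8/10=0.8
        report = evaluate_model([(gt1, p1), (gt2, p2)])
        mean, sd = report.aggregate["dsc"]
        assert mean == pytest.approx(0.7, abs=1e-12)
        assert sd == pytest.approx(np.std([0.6, 0.8], ddof=1), abs=1e-12)
        assert sd == pytest.approx(0.1414213562, abs=1e-9)

    def test_aggregate_recomputable_from_per_case(self, random_mask_pairs):
        report = evaluate_model(random_mask_pairs[:10])
        frame = report.to_frame()
        for m in METRIC_NAMES:
            vals = frame[m].dropna()
            mean, sd = report.aggregate[m]
            assert mean == pytest.approx(vals.mean())
            assert sd == pytest.approx(vals.std(ddof=1))

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_model([])

    def test_row_count(self, random_mask_pairs):
        report = evaluate_model(random_mask_pairs[:7])
        assert len(report.to_frame()) == 7

    def test_save_roundtrip(self, tmp_path, random_mask_pairs):
        report = evaluate_model(random_mask_pairs[:5], label="m")
        report.save(tmp_path)
        assert (tmp_path / "m_cases.csv").exists()
        assert (tmp_path / "m_aggregate.json").exists()


class TestBounds:
    def test_bounds_hold_on_random_pairs(self, random_mask_pairs):
        for gt, pred in random_mask_pairs[:50]:
            cm = compute_case_metrics(gt, pred)
            for m in ("dsc", "jsc", "ppv", "se", "voe"):
                v = getattr(cm, m)
                if not math.isnan(v):
                    assert 0.0 <= v <= 1.0
            assert cm.hd >= 0.0
            assert cm.rvd >= 0.0
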