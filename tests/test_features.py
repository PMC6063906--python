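import numpy as np
import pytest

from ceus_radiomics.features import (DIRECTIONS, FEATURE_CLASSES, FEATURE_NAMES,
                                     ExtractionParams, QuantizationParams,
                                     extract_all, feature_class,
                                     first_order_features, glcm_features,
                                     glcm_matrix, glrlm_features,
                                     quantize, swt_subbands, vascular_features,
                                     wavelet_features)
from ceus_radiomics.phantom import ROIMask
from ceus_radiomics.segmentation import ReplenishmentFit, VesselMask

import _oracles as oracles


def full_roi(shape):
    return ROIMask(np.ones(shape, bool))


DUMMY_FIT = ReplenishmentFit(A=1.0, beta=0.5, velocity=0.5, fit_rmse=0.0)


class TestFeatureCatalogue:
    def test_partition_counts(self):
        counts = {}
        for name in FEATURE_NAMES:
            counts[feature_class(name)] = counts.get(feature_class(name), 0) + 1
        assert counts == {"first_order": 14, "textural": 30,
                          "vascular": 15, "wavelet": 176}

    def test_signature_candidates_exist(self):
        # the features reported as a typical CEUS radiomic signature must
        # all be present under their canonical names
        for name in ("fo_median", "vasc_network_length", "glcm_energy",
                     "wavD_glrlm_RLN", "glrlm_RLN"):
            assert name in FEATURE_CLASSES


class TestFirstOrder:
    def test_constant_roi(self):
        img = np.full((6, 6), 3.0)
        f = first_order_features(img, full_roi((6, 6)))
        assert f["fo_median"] == 3.0
        assert f["fo_range"] == 0.0
        assert f["fo_variance"] == 0.0
        assert f["fo_uniformity"] == 1.0

    def test_hand_computed_example(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        f = first_order_features(img, full_roi((2, 2)))
        assert f["fo_mean"] == 2.5
        assert f["fo_median"] == 2.5
        assert f["fo_range"] == 3.0

    def test_returns_exactly_14(self, rng):
        f = first_order_features(rng.uniform(0, 1, (8, 8)), full_roi((8, 8)))
        assert len(f) == 14

    def test_matches_oracle_on_random_grids(self, rng):
        for _ in range(5):
            img = rng.integers(0, 9, size=(6, 6)).astype(float)
            roi = rng.uniform(0, 1, size=(6, 6)) > 0.2
            roi[0, 0] = True
            roi[0, 1] = True
            got = first_order_features(img, ROIMask(roi))
            want = oracles.first_order_oracle(img, roi)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, abs=1e-10), k

    def test_empty_roi_rejected(self):
        roi = np.zeros((4, 4), bool)
        roi[0, 0] = True
        with pytest.raises(ValueError):
            first_order_features(np.ones((4, 4)), ROIMask(roi))


class TestGLCM:
    def test_constant_roi_degenerate_matrix(self):
        img = np.full((5, 5), 2.0)
        f = glcm_features(img, full_roi((5, 5)))
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_contrast"] == pytest.approx(0.0)

    def test_checkerboard_horizontal_energy(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        f = glcm_features(img.astype(float), full_roi((6, 6)),
                          QuantizationParams(n_levels=2), directions=((0, 1),))
        # all mass sits equally on the two off-diagonal cells
        assert f["glcm_energy"] == pytest.approx(0.5)
        assert f["glcm_max_probability"] == pytest.approx(0.5)

    def test_matrix_normalized_per_direction(self, rng):
        img = rng.integers(0, 5, size=(7, 7)).astype(float)
        roi = np.ones((7, 7), bool)
        qimg = np.zeros((7, 7), dtype=np.int64)
        qimg[roi] = quantize(img[roi], 8)
        for d in DIRECTIONS:
            mat = glcm_matrix(qimg, 8, directions=(d,))
            assert mat.sum() == pytest.approx(1.0)

    def test_matches_oracle_on_random_grids(self, rng):
        for _ in range(5):
            img = rng.integers(0, 7, size=(6, 6)).astype(float)
            roi = rng.uniform(0, 1, size=(6, 6)) > 0.25
            roi[2:4, 2:4] = True
            q = QuantizationParams(n_levels=6)
            got = glcm_features(img, ROIMask(roi), q)
            qimg = np.zeros((6, 6), dtype=int)
            qimg[roi] = quantize(img[roi], 6)
            want = oracles.glcm_features_oracle(qimg.tolist(), 6, DIRECTIONS)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, abs=1e-10), k

    def test_single_pixel_roi_rejected(self):
        roi = np.zeros((4, 4), bool)
        roi[1, 1] = True
        with pytest.raises(ValueError):
            glcm_features(np.ones((4, 4)), ROIMask(roi))


class TestGLRLM:
    def test_single_row_hand_enumeration(self):
        # runs {(a,2),(b,3)} -> RLN = (1^2 + 1^2) / 2 = 1
        img = np.array([[1.0, 1.0, 2.0, 2.0, 2.0]])
        f = glrlm_features(img, full_roi((1, 5)), QuantizationParams(n_levels=2),
                           directions=((0, 1),))
        assert f["glrlm_RLN"] == pytest.approx(1.0)
        assert f["glrlm_GLN"] == pytest.approx(1.0)

    def test_constant_row_single_run(self):
        img = np.zeros((1, 8))
        f = glrlm_features(img, full_roi((1, 8)), directions=((0, 1),))
        assert f["glrlm_RLN"] == pytest.approx(1.0)
        assert f["glrlm_RP"] == pytest.approx(1.0 / 8.0)

    def test_matches_oracle_on_random_grids(self, rng):
        for _ in range(5):
            img = rng.integers(0, 5, size=(6, 6)).astype(float)
            roi = rng.uniform(0, 1, size=(6, 6)) > 0.25
            roi[2:4, 2:4] = True
            q = QuantizationParams(n_levels=4)
            got = glrlm_features(img, ROIMask(roi), q)
            qimg = np.zeros((6, 6), dtype=int)
            qimg[roi] = quantize(img[roi], 4)
            want = oracles.glrlm_features_oracle(qimg.tolist(), 4, DIRECTIONS,
                                                 int(roi.sum()))
            for k, v in want.items():
                assert got[k] == pytest.approx(v, abs=1e-10), k

    def test_textural_total_is_30(self, rng):
        img = rng.uniform(0, 1, size=(8, 8))
        roi = full_roi((8, 8))
        assert len(glcm_features(img, roi)) + len(glrlm_features(img, roi)) == 30


class TestVascular:
    def test_straight_line_vessel(self):
        roi = full_roi((100, 100))
        v = np.zeros((100, 100), bool)
        v[50, 40:60] = True  # 1-px line of length 20
        f = vascular_features(VesselMask(v), roi, DUMMY_FIT)
        assert f["vasc_n_vessels"] == 1
        assert abs(f["vasc_network_length"] - 20) <= 2
        assert f["vasc_n_branch_points"] == 0
        assert f["vasc_vascular_area"] == 20

    def test_vessel_mask_equals_roi(self):
        roi = full_roi((20, 20))
        f = vascular_features(VesselMask(np.ones((20, 20), bool)), roi, DUMMY_FIT)
        assert f["vasc_rbv"] == pytest.approx(1.0)
        assert f["vasc_dist_mean"] == pytest.approx(0.0)

    def test_empty_vessel_mask_is_finite(self):
        roi = full_roi((20, 20))
        f = vascular_features(VesselMask(np.zeros((20, 20), bool)), roi, DUMMY_FIT)
        assert f["vasc_n_vessels"] == 0
        assert f["vasc_rbv"] == 0.0
        assert np.isfinite(list(f.values())).all()
        assert f["vasc_dist_max"] > 0  # distance to ROI boundary fallback

    def test_rbv_recovery_on_phantom(self, default_phantom):
        from ceus_radiomics.segmentation import segment_vessels

        _, roi, seq, truth = default_phantom
        vm = segment_vessels(seq, roi)
        f = vascular_features(vm, roi, DUMMY_FIT)
        assert f["vasc_rbv"] == pytest.approx(truth.true_rbv, rel=0.10)

    def test_area_and_length_monotone_under_disjoint_growth(self):
        roi = full_roi((60, 60))
        v = np.zeros((60, 60), bool)
        v[30, 10:30] = True
        grown = v.copy()
        grown[10, 40:55] = True  # add a disjoint vessel
        f1 = vascular_features(VesselMask(v), roi, DUMMY_FIT)
        f2 = vascular_features(VesselMask(grown), roi, DUMMY_FIT)
        assert f2["vasc_vascular_area"] > f1["vasc_vascular_area"]
        assert f2["vasc_network_length"] > f1["vasc_network_length"]

    def test_flow_velocity_passthrough(self):
        roi = full_roi((10, 10))
        fit = ReplenishmentFit(A=1.0, beta=0.7, velocity=0.35, fit_rmse=0.0)
        f = vascular_features(VesselMask(np.zeros((10, 10), bool)), roi, fit)
        assert f["vasc_flow_velocity"] == 0.35


class TestWavelet:
    def test_returns_exactly_176(self, rng):
        img = rng.uniform(0, 1, size=(16, 16))
        f = wavelet_features(img, full_roi((16, 16)))
        assert len(f) == 176

    def test_subband_shapes_match_input(self, rng):
        img = rng.uniform(0, 1, size=(17, 23))  # odd extents exercise padding
        bands = swt_subbands(img)
        assert set(bands) == {"A", "H", "V", "D"}
        for b in bands.values():
            assert b.shape == img.shape

    def test_constant_image_details_vanish(self):
        img = np.full((16, 16), 5.0)
        bands = swt_subbands(img)
        for k in ("H", "V", "D"):
            assert np.abs(bands[k]).max() < 1e-10
        assert bands["A"].std() < 1e-10


class TestExtractAll:
    def test_full_vector_counts_and_determinism(self, small_study):
        rec = small_study.scans[0]
        fv1 = extract_all(rec.seq, rec.rois[0], user_id="user1", dataset_id=1)
        fv2 = extract_all(rec.seq, rec.rois[0], user_id="user1", dataset_id=1)
        assert list(fv1.values) == FEATURE_NAMES
        assert len(fv1.values) == 235
        assert fv1.values == fv2.values
        counts = {}
        for name in fv1.values:
            counts[feature_class(name)] = counts.get(feature_class(name), 0) + 1
        assert counts == {"first_order": 14, "textural": 30,
                          "vascular": 15, "wavelet": 176}

    def test_rbv_test_retest_concordance(self, default_study_features):
        # rBV is locked to phantom geometry, so it must be highly
        # concordant between the two acquisitions of each position
        from ceus_radiomics.selection import concordance_cc

        df = default_study_features
        wide = df[df["user_id"] == "user1"].pivot_table(
            index=["mouse_id", "position_id"], columns="dataset",
            values="vasc_rbv")
        assert concordance_cc(wide[1].to_numpy(), wide[2].to_numpy()) > 0.8
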