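import numpy as np
import pytest

import ranklomics as rk
from ranklomics.core import FeatureVector, GrayImage, RoiMask, CaseRecord
from ranklomics.errors import DegenerateMatrixError, SchemaError, TooSmallRoiError
from ranklomics.texture import (
    ANGLES,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    average_over_angles,
    compute_glcm,
    compute_glrlm,
    extract_case_features,
    glcm_features,
    glcm_stats,
    glrlm_features,
    quantize_gray,
)
from ranklomics.synthetic import PerturbationSpec, generate_texture_image, perturb_intensity

from _oracles import glcm_enumerate, run_length_enumerate


def _img(values, levels):
    return GrayImage(np.asarray(values, dtype=int), bit_depth=levels - 1)


FULL = np.ones


class TestComputeGLCM:
    def test_two_by_two_alternating_columns(self):
        P = compute_glcm(_img([[0, 1], [0, 1]], 2), FULL((2, 2)), d=1, theta=0)
        assert P.p[0, 1] == 0.5 and P.p[1, 0] == 0.5
        assert P.p[0, 0] == 0.0 and P.p[1, 1] == 0.0

    def test_constant_image_single_entry(self):
        P = compute_glcm(_img(np.full((3, 3), 1), 4), FULL((3, 3)), theta=45)
        assert P.p[1, 1] == 1.0 and P.p.sum() == 1.0

    def test_single_pixel_mask_degenerate(self):
        mask = np.zeros((3, 3))
        mask[1, 1] = 1
        with pytest.raises(DegenerateMatrixError):
            compute_glcm(_img(np.zeros((3, 3)), 2), mask, theta=0)

    def test_matches_pair_enumeration_oracle(self):
        """Masked accumulation must agree exactly with exhaustive per-pixel
        enumeration on 200 random 8x8 images, all four angles."""
        rng = np.random.default_rng(7)
        for trial in range(200):
            img = rng.integers(0, 4, size=(8, 8))
            mask = rng.random((8, 8)) < 0.8
            symmetric = bool(trial % 2)
            for theta in ANGLES:
                expected = glcm_enumerate(img, mask, 1, theta, 4, symmetric)
                if expected.sum() == 0:
                    continue
                P = compute_glcm(_img(img, 4), mask, d=1, theta=theta, symmetric=symmetric)
                np.testing.assert_allclose(P.p, expected, atol=1e-14)

    def test_symmetric_matrix_is_symmetric(self):
        rng = np.random.default_rng(8)
        P = compute_glcm(_img(rng.integers(0, 5, (10, 10)), 5), FULL((10, 10)), theta=135)
        np.testing.assert_allclose(P.p, P.p.T)

    def test_matches_skimage_on_full_mask(self):
        """Cross-check against scikit-image's graycomatrix (which cannot mask,
        so full-frame only).  skimage's pi/4 walks down-right, i.e. our 135
        degrees under symmetric closure."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(9)
        img = rng.integers(0, 6, size=(12, 12))
        sk = graycomatrix(
            img.astype(np.uint8), [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=6, symmetric=True, normed=True,
        )
        pairing = {0: 0, 45: 3, 90: 2, 135: 1}  # ours -> skimage angle index
        for theta, k in pairing.items():
            P = compute_glcm(_img(img, 6), FULL((12, 12)), d=1, theta=theta)
            np.testing.assert_allclose(P.p, sk[:, :, 0, k], atol=1e-12)


class TestGLCMStats:
    def test_symmetric_marginals_coincide(self):
        rng = np.random.default_rng(10)
        P = compute_glcm(_img(rng.integers(0, 4, (8, 8)), 4), FULL((8, 8)), theta=0)
        s = glcm_stats(P)
        assert s.mu_x == pytest.approx(s.mu_y)
        assert s.sigma_x == pytest.approx(s.sigma_y)
        assert s.px.sum() == pytest.approx(1.0)
        assert s.p_diff.sum() == pytest.approx(1.0)

    def test_diagonal_matrix(self):
        P = rk.compute_glcm(_img([[0, 0], [1, 1]], 2), FULL((2, 2)), theta=0)
        # rows are constant -> pairs (0,0) and (1,1) only
        s = glcm_stats(P)
        assert s.p_diff.tolist() == [1.0, 0.0]
        assert s.mu_x == pytest.approx(0.5)

    def test_independent_table_has_hxy_equal_hxy1(self):
        from ranklomics.texture import GLCMatrix

        px = np.array([0.2, 0.3, 0.5])
        P = GLCMatrix(np.outer(px, px), 3, 1, 0, True)
        s = glcm_stats(P)
        assert s.hxy == pytest.approx(s.hxy1, abs=1e-12)


class TestGLCMFeatures:
    def test_constant_image_closed_forms(self):
        P = compute_glcm(_img(np.full((4, 4), 2), 8), FULL((4, 4)), theta=0)
        f = glcm_features(P)
        assert f["contrast"] == 0.0
        assert f["dissimilarity"] == 0.0
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["homogeneity"] == 1.0

    def test_alternating_image_closed_forms(self):
        P = compute_glcm(_img([[0, 1], [0, 1]], 2), FULL((2, 2)), theta=0)
        f = glcm_features(P)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(0.5)
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(np.log(2))

    def test_uniform_table(self):
        from ranklomics.texture import GLCMatrix

        g = 4
        P = GLCMatrix(np.full((g, g), 1 / g**2), g, 1, 0, True)
        f = glcm_features(P)
        assert f["energy"] == pytest.approx(1 / g**2)
        assert f["information_measure_of_correlation"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_skimage_graycoprops(self):
        """contrast/dissimilarity/energy/correlation against the independent
        scikit-image implementations on a random full-mask image (skimage's
        'homogeneity' is the squared-denominator form, not ours, so it is
        excluded)."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(11)
        img = rng.integers(0, 8, size=(16, 16))
        sk = graycomatrix(img.astype(np.uint8), [1], [0], levels=8, symmetric=True, normed=True)
        P = compute_glcm(_img(img, 8), FULL((16, 16)), theta=0)
        f = glcm_features(P)
        assert f["contrast"] == pytest.approx(graycoprops(sk, "contrast")[0, 0])
        assert f["dissimilarity"] == pytest.approx(graycoprops(sk, "dissimilarity")[0, 0])
        assert f["energy"] == pytest.approx(graycoprops(sk, "ASM")[0, 0])
        assert f["correlation"] == pytest.approx(graycoprops(sk, "correlation")[0, 0])

    def test_entropy_and_energy_ranges(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            img = rng.integers(0, 8, size=(10, 10))
            f = glcm_features(compute_glcm(_img(img, 8), FULL((10, 10)), theta=0))
            assert 0 < f["energy"] <= 1
            assert 0 <= f["entropy"] <= 2 * np.log(8)
            assert 0 < f["homogeneity"] <= 1


class TestAverageOverAngles:
    def test_identical_vectors_unchanged(self):
        v = FeatureVector(("a", "b"), np.array([1.0, 2.0]))
        out = average_over_angles([v, v, v, v])
        assert out.values.tolist() == [1.0, 2.0]

    def test_arithmetic_mean(self):
        vectors = [FeatureVector(("contrast",), np.array([float(x)])) for x in (1, 2, 3, 4)]
        assert average_over_angles(vectors).values[0] == pytest.approx(2.5)

    def test_name_mismatch_rejected(self):
        v1 = FeatureVector(("a",), np.array([1.0]))
        v2 = FeatureVector(("b",), np.array([1.0]))
        with pytest.raises(SchemaError):
            average_over_angles([v1, v2])


class TestGLRLM:
    def test_row_runs(self):
        R = compute_glrlm(_img([[0, 0, 0, 1, 1]], 2), FULL((1, 5)), theta=0)
        assert R.r[0, 2] == 1 and R.r[1, 1] == 1 and R.r.sum() == 2

    def test_constant_row_closed_form(self):
        n = 6
        R = compute_glrlm(_img(np.zeros((1, n)), 2), FULL((1, n)), theta=0)
        f = glrlm_features(R)
        assert f["sre"] == pytest.approx(1 / n**2)
        assert f["lre"] == pytest.approx(n**2)

    def test_checkerboard_all_unit_runs(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        R = compute_glrlm(_img(img, 2), FULL((6, 6)), theta=0)
        f = glrlm_features(R)
        assert f["rp"] == pytest.approx(1.0)
        assert R.r[:, 1:].sum() == 0

    def test_runs_truncated_at_mask_boundaries(self):
        mask = np.array([[1, 1, 0, 1, 1]])
        R = compute_glrlm(_img(np.zeros((1, 5)), 2), mask, theta=0)
        assert R.r[0, 1] == 2  # two runs of length 2, not one of length 5

    def test_matches_line_scanner_oracle_all_angles(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            img = rng.integers(0, 3, size=(7, 9))
            mask = rng.random((7, 9)) < 0.85
            if not mask.any():
                continue
            for theta in ANGLES:
                R = compute_glrlm(_img(img, 3), mask, theta=theta)
                np.testing.assert_array_equal(R.r, run_length_enumerate(img, mask, theta, 3))


class TestDisorderMonotonicity:
    def test_shuffling_smooth_texture_lowers_homogeneity_raises_entropy(self):
        """Replacing a growing fraction of a smooth ramp's pixels by a random
        shuffle must, on average over seeds, decrease GLCM homogeneity and
        increase entropy."""
        base = np.repeat(np.arange(8), 32).reshape(16, 16)
        fractions = [0.0, 0.25, 0.6, 1.0]
        hom, ent = [], []
        for frac in fractions:
            h_vals, e_vals = [], []
            for seed in range(10):
                rng = np.random.default_rng(100 + seed)
                img = base.copy().ravel()
                k = int(frac * img.size)
                idx = rng.choice(img.size, size=k, replace=False)
                img[idx] = rng.permutation(img[idx])
                f = glcm_features(
                    compute_glcm(_img(img.reshape(16, 16), 8), FULL((16, 16)), theta=0)
                )
                h_vals.append(f["homogeneity"])
                e_vals.append(f["entropy"])
            hom.append(np.mean(h_vals))
            ent.append(np.mean(e_vals))
        assert all(a > b for a, b in zip(hom, hom[1:]))
        assert all(a < b for a, b in zip(ent, ent[1:]))


class TestExtractCaseFeatures:
    def test_panel_structure(self):
        case = generate_texture_image(rk.TextureParams(), seed=21)
        row = extract_case_features(case)
        assert len(row.features) == 4 * 14 + 4 * 11
        for source in ("raw", "ranklet_vertical", "ranklet_horizontal", "ranklet_diagonal"):
            for name in GLCM_FEATURE_NAMES:
                assert f"{source}_{name}" in row.features
            for name in GLRLM_FEATURE_NAMES:
                assert f"{source}_{name}" in row.features

    def test_too_small_roi_propagates(self):
        pix = np.arange(64).reshape(8, 8)
        mask = np.zeros((8, 8))
        mask[2:5, 2:5] = 1
        case = CaseRecord("tiny", GrayImage(pix), RoiMask(mask))
        with pytest.raises(TooSmallRoiError):
            extract_case_features(case)

    def test_gamma_perturbation_preserves_ranklet_panels_only(self):
        rng = np.random.default_rng(22)
        pix = rng.uniform(5, 240, size=(48, 48))
        mask = np.zeros((48, 48))
        mask[8:40, 8:40] = 1
        case = CaseRecord("a", GrayImage(pix), RoiMask(mask))
        warped = CaseRecord(
            "a'",
            perturb_intensity(case.image, PerturbationSpec("gamma", 0.8), rounding=False),
            case.mask,
        )
        row = extract_case_features(case, normalize=False)
        row_w = extract_case_features(warped, normalize=False)
        ranklet_cols = [c for c in row.features if c.startswith("ranklet_")]
        raw_glcm_cols = [f"raw_{n}" for n in GLCM_FEATURE_NAMES]
        for c in ranklet_cols:
            assert row.features[c] == row_w.features[c], c
        assert any(row.features[c] != row_w.features[c] for c in raw_glcm_cols)


class TestQuantizeGray:
    def test_equal_width_binning(self):
        img = GrayImage(np.array([[0, 127, 128, 255]]))
        out = quantize_gray(img, 32)
        assert out.pixels.tolist() == [[0, 15, 16, 31]]

    def test_levels_bound(self):
        rng = np.random.default_rng(23)
        out = quantize_gray(GrayImage(rng.integers(0, 256, (8, 8))), 8)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 7
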