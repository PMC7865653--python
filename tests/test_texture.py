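"""Texture matrices and features against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from lesionrad.texture import (
    DIRECTIONS_3D,
    aggregate_patient,
    build_matrices,
    first_order,
    texture_features,
)
from lesionrad.types import DegenerateLesionError, LesionVolume

from conftest import make_discretized, random_small_lesion
from oracles import (
    glcm_brute,
    glcm_features_brute,
    glrlm_brute,
    glszm_brute,
    ngtdm_brute,
    ngtdm_features_brute,
    rl_features_brute,
)

IN_PLANE = ((1, 0, 0), (0, 1, 0))


def checkerboard_441():
    levels = (np.indices((4, 4, 1)).sum(axis=0) % 2 + 1).astype(np.int32)
    return make_discretized(levels, ng=2)


class TestGLCM:
    def test_checkerboard_in_plane_offsets(self):
        """Alternating two-level plane: every axis-aligned neighbor pair
        differs, so all co-occurrence mass is off-diagonal and contrast is
        exactly 1."""
        m = build_matrices(checkerboard_441(), directions=IN_PLANE)
        off_diag = m.glcm.sum() - np.trace(m.glcm)
        assert off_diag == pytest.approx(1.0, abs=1e-12)
        f = texture_features(m)
        assert f["glcm_contrast"] == pytest.approx(1.0, abs=1e-12)
        assert f["glcm_dissimilarity"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_lesion_single_diagonal_entry(self):
        levels = np.zeros((4, 4, 4), dtype=np.int32)
        levels[1:3, 1:3, 1:3] = 2
        m = build_matrices(make_discretized(levels, ng=3))
        expected = np.zeros((3, 3))
        expected[1, 1] = 1.0
        np.testing.assert_allclose(m.glcm, expected)
        f = texture_features(m)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["glcm_dissimilarity"] == 0.0

    def test_normalized_and_symmetric(self, rng):
        for _ in range(10):
            m = build_matrices(random_small_lesion(rng))
            assert m.glcm.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(m.glcm, m.glcm.T, atol=1e-15)
            assert (m.glcm >= 0).all()

    def test_single_voxel_rejected(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[1, 1, 1] = 1
        with pytest.raises(DegenerateLesionError):
            build_matrices(make_discretized(levels, ng=2))


class TestMatrixOracles:
    """Vectorized construction vs independent enumeration, 1e-10."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_all_matrices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(4):
            les = random_small_lesion(rng, ng=4, max_side=9)
            m = build_matrices(les)
            np.testing.assert_allclose(
                m.glcm, glcm_brute(les.levels, 4, DIRECTIONS_3D), atol=1e-10
            )
            np.testing.assert_allclose(
                m.glrlm, glrlm_brute(les.levels, 4, DIRECTIONS_3D), atol=0
            )
            np.testing.assert_allclose(m.glszm, glszm_brute(les.levels, 4), atol=0)
            s, n = ngtdm_brute(les.levels, 4)
            np.testing.assert_allclose(m.ngtdm_s, s, atol=1e-10)
            np.testing.assert_allclose(m.ngtdm_n, n, atol=0)

    def test_features_match_brute_force(self, rng):
        for _ in range(8):
            les = random_small_lesion(rng, ng=3, max_side=8)
            m = build_matrices(les)
            f = texture_features(m)
            assert all(np.isfinite(v) for v in f.values())
            for name, val in glcm_features_brute(m.glcm).items():
                assert f[name] == pytest.approx(val, abs=1e-10), name
            for name, val in rl_features_brute(
                m.glrlm, m.n_voxels, m.n_directions, "glrlm"
            ).items():
                assert f[name] == pytest.approx(val, abs=1e-10, rel=1e-10), name
            for name, val in rl_features_brute(m.glszm, m.n_voxels, 1, "glszm").items():
                assert f[name] == pytest.approx(val, abs=1e-10, rel=1e-10), name
            for name, val in ngtdm_features_brute(m.ngtdm_s, m.ngtdm_n).items():
                assert f[name] == pytest.approx(val, abs=1e-10, rel=1e-10), name


class TestMatrixInvariants:
    def test_run_and_zone_voxel_conservation(self, rng):
        """Summed run lengths equal the voxel count per direction (x13 when
        merged); zone sizes sum to the voxel count."""
        for _ in range(5):
            les = random_small_lesion(rng)
            m = build_matrices(les)
            lengths = np.arange(1, m.glrlm.shape[1] + 1)
            assert (m.glrlm * lengths).sum() == 13 * les.n_voxels
            sizes = np.arange(1, m.glszm.shape[1] + 1)
            assert (m.glszm * sizes).sum() == les.n_voxels

    def test_ngtdm_absent_levels_have_zero_s(self, rng):
        les = random_small_lesion(rng, ng=6)
        m = build_matrices(les)
        present = np.zeros(6, bool)
        present[np.unique(les.levels[les.mask]) - 1] = True
        assert np.all(m.ngtdm_s[~present] == 0)
        assert np.all(m.ngtdm_n[~present] == 0)

    @pytest.mark.parametrize("axes", [(0, 1), (0, 2), (1, 2)])
    def test_rotation_invariance_90deg(self, rng, axes):
        """Direction merging makes features exact under axis-aligned
        rotations."""
        les = random_small_lesion(rng)
        rot = np.rot90(les.levels, k=1, axes=axes)
        f0 = texture_features(build_matrices(les))
        f1 = texture_features(build_matrices(make_discretized(rot, les.n_levels)))
        for name in f0:
            assert f0[name] == pytest.approx(f1[name], rel=1e-12, abs=1e-12), name


class TestFirstOrder:
    def test_hand_example(self):
        vol = LesionVolume(
            np.array([[[1.0, 2, 3, 4, 5]]]), np.ones((1, 1, 5), bool), (1, 1, 1)
        )
        f = first_order(vol)
        assert f["fo_mean"] == 3
        assert f["fo_median"] == 3
        assert f["fo_range"] == 4
        assert f["fo_iqr"] == 2  # linear-interpolation quantiles: 4 - 2
        assert f["fo_mad"] == 1

    def test_constant_lesion_flags(self):
        vol = LesionVolume(np.full((2, 2, 2), 7.0), np.ones((2, 2, 2), bool), (1, 1, 1))
        f = first_order(vol)
        assert f["fo_std"] == 0 and f["fo_mad"] == 0 and f["fo_range"] == 0
        assert np.isnan(f["fo_skewness"]) and np.isnan(f["fo_kurtosis"])

    def test_mode_most_frequent(self):
        vol = LesionVolume(
            np.array([[[1.0, 1, 2]]]), np.ones((1, 1, 3), bool), (1, 1, 1)
        )
        assert first_order(vol)["fo_mode"] == 1


class TestAggregation:
    def test_single_lesion_single_phase_identity(self):
        df = pd.DataFrame({"lesion_id": [0], "phase": [0], "f": [3.7]})
        assert aggregate_patient(df)["f"] == 3.7

    def test_median_across_phases(self):
        df = pd.DataFrame(
            {"lesion_id": [0, 0, 0], "phase": [0, 1, 2], "f": [1.0, 2.0, 9.0]}
        )
        assert aggregate_patient(df)["f"] == 2.0

    def test_nested_median_two_lesions_three_phases(self):
        # lesion 0 phases -> median 2; lesion 1 phases -> median 7; result 4.5
        df = pd.DataFrame(
            {
                "lesion_id": [0, 0, 0, 1, 1, 1],
                "phase": [0, 1, 2, 0, 1, 2],
                "f": [1.0, 2.0, 9.0, 6.0, 7.0, 8.0],
            }
        )
        assert aggregate_patient(df)["f"] == 4.5


def test_shift_invariance_after_fixed_bin_quantization(rng):
    """Adding a constant to the image leaves bin assignment, hence every
    matrix feature, unchanged under fixed-bin-number quantization."""
    from lesionrad.preprocess import quantize

    img = rng.normal(50, 10, (8, 8, 8))
    mask = np.ones((8, 8, 8), bool)
    a = quantize(LesionVolume(img, mask, (1, 1, 1)), n_levels=8)
    b = quantize(LesionVolume(img + 123.4, mask, (1, 1, 1)), n_levels=8)
    fa = texture_features(build_matrices(a))
    fb = texture_features(build_matrices(b))
    for name in fa:
        assert fa[name] == pytest.approx(fb[name], rel=1e-12), name
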