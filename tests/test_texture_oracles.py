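"""Texture families vs independent brute-force enumeration oracles.

Each family's vectorized implementation is checked against a plain-loop
oracle (tests/oracles.py) on many random small volumes with random masks,
plus the hand-computable strip examples.
"""

import numpy as np
import pytest

from oracles import (
    gldm_matrix_oracle,
    glcm_features_oracle,
    glcm_matrices_oracle,
    glrlm_matrices_oracle,
    glszm_matrix_oracle,
    ngtdm_features_oracle,
    rlm_features_oracle,
)
from plnm_radiomics.features.texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    _GLDM_MAP,
    _GLRLM_MAP,
    _GLSZM_MAP,
    glcm_features,
    glcm_matrices,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrices,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
)
from plnm_radiomics.imaging import DegenerateInputError, DiscretizedVolume, ImageVolume, Mask, discretize

from conftest import random_discretized


def n_random_volumes(rng, n):
    return [random_discretized(rng) for _ in range(n)]


def disc_from(levels, mask=None, ng=None):
    lvl = np.asarray(levels, dtype=np.int32)
    if lvl.ndim == 1:
        lvl = lvl.reshape(-1, 1, 1)
    m = np.ones(lvl.shape, bool) if mask is None else np.asarray(mask, bool).reshape(lvl.shape)
    lvl = lvl * m
    return DiscretizedVolume(
        levels=lvl, n_levels=ng or int(lvl.max()), bin_width=1.0, mask=m
    )


class TestGLCM:
    def test_constant_region(self):
        d = disc_from(np.ones((3, 3, 3), int).ravel().reshape(3, 3, 3))
        f = glcm_features(d)
        assert f["MaximumProbability"] == 1.0
        assert f["JointEntropy"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0 and f["MCC"] == 1.0

    def test_strip_pair_counting(self):
        # 1x4 strip [1,1,2,2]: x-direction pairs {(1,1),(1,2),(2,2)},
        # symmetric counts -> Contrast 1/3, MaxProb 1/3
        d = disc_from([1, 1, 2, 2])
        mats = glcm_matrices(d)
        assert len(mats) == 1  # only the x direction has pairs
        expected = np.array([[2, 1], [1, 2]]) / 6.0
        np.testing.assert_allclose(mats[0], expected)
        f = glcm_features(d)
        np.testing.assert_allclose(f["Contrast"], 1 / 3)
        np.testing.assert_allclose(f["MaximumProbability"], 1 / 3)

    def test_matrices_equal_oracle(self, rng):
        for d in n_random_volumes(rng, 30):
            ours = glcm_matrices(d)
            theirs = glcm_matrices_oracle(d.levels, d.mask, d.n_levels)
            assert len(ours) == len(theirs)
            for a, b in zip(ours, theirs):
                np.testing.assert_allclose(a, b, atol=1e-12)

    def test_features_equal_oracle(self, rng):
        for d in n_random_volumes(rng, 25):
            ours = glcm_features(d)
            theirs = glcm_features_oracle(d.levels, d.mask, d.n_levels)
            assert sorted(ours) == sorted(GLCM_FEATURES)
            for k in GLCM_FEATURES:
                np.testing.assert_allclose(ours[k], theirs[k], atol=1e-9, err_msg=k)


class TestGLRLM:
    def test_constant_strip_single_run(self):
        d = disc_from([1] * 5)
        mats = glrlm_matrices(d)
        # a single level-1 run of length 5 must appear in exactly one direction
        run5 = [m for m in mats if m[0, 4] == 1]
        assert len(run5) == 1
        f = glrlm_features(d)
        assert sorted(f) == sorted(GLRLM_FEATURES)

    def test_strip_run_enumeration(self):
        # [1,1,2] along x: runs {(1,len2),(2,len1)} -> SRE = (1*(1/4)+1*1)/2
        d = disc_from([1, 1, 2])
        x_dir_matrices = [m for m in glrlm_matrices(d) if m[0, 1] == 1]
        assert len(x_dir_matrices) == 1
        f_x = rlm_features_oracle(x_dir_matrices[0], 3)
        np.testing.assert_allclose(f_x["Short"], 5 / 8)

    def test_matrices_equal_oracle(self, rng):
        for d in n_random_volumes(rng, 30):
            ours = glrlm_matrices(d)
            theirs = glrlm_matrices_oracle(d.levels, d.mask, d.n_levels)
            for a, b in zip(ours, theirs):
                np.testing.assert_allclose(a, b, atol=1e-12)

    def test_features_equal_oracle(self, rng):
        n_vox = None
        for d in n_random_volumes(rng, 25):
            n_vox = int(d.mask.sum())
            ours = glrlm_features(d)
            oracle_dirs = [
                rlm_features_oracle(r, n_vox)
                for r in glrlm_matrices_oracle(d.levels, d.mask, d.n_levels)
            ]
            for name, key in _GLRLM_MAP.items():
                expect = np.mean([f[key] for f in oracle_dirs])
                np.testing.assert_allclose(ours[name], expect, atol=1e-9, err_msg=name)


class TestGLSZM:
    def test_constant_cube_single_zone(self):
        d = disc_from(np.ones((2, 2, 2), int))
        z = glszm_matrix(d)
        assert z[0, 7] == 1 and z.sum() == 1
        f = glszm_features(d)
        assert f["ZoneEntropy"] == 0.0
        assert sorted(f) == sorted(GLSZM_FEATURES)

    def test_two_singleton_zones_one_bit(self):
        # two isolated voxels of different levels -> ZoneEntropy = 1 bit
        lvl = np.zeros((5, 1, 1), int)
        mask = np.zeros((5, 1, 1), bool)
        lvl[0], mask[0] = 1, True
        lvl[4], mask[4] = 2, True
        d = DiscretizedVolume(levels=lvl, n_levels=2, bin_width=1.0, mask=mask)
        f = glszm_features(d)
        np.testing.assert_allclose(f["ZoneEntropy"], 1.0)

    def test_matrix_equals_flood_fill_oracle(self, rng):
        for d in n_random_volumes(rng, 40):
            np.testing.assert_allclose(
                glszm_matrix(d), glszm_matrix_oracle(d.levels, d.mask, d.n_levels),
                atol=1e-12,
            )

    def test_features_equal_oracle(self, rng):
        for d in n_random_volumes(rng, 20):
            ours = glszm_features(d)
            oracle = rlm_features_oracle(
                glszm_matrix_oracle(d.levels, d.mask, d.n_levels), int(d.mask.sum())
            )
            for name, key in _GLSZM_MAP.items():
                np.testing.assert_allclose(ours[name], oracle[key], atol=1e-9, err_msg=name)


class TestNGTDM:
    def test_constant_region(self):
        d = disc_from(np.ones((3, 3, 3), int))
        f = ngtdm_features(d)
        assert f["Contrast"] == 0.0 and f["Complexity"] == 0.0
        assert f["Coarseness"] == 1e6  # uniform-region sentinel
        assert sorted(f) == sorted(NGTDM_FEATURES)

    def test_strip_hand_enumeration(self):
        # 1x3 strip [1,2,1]:
        #   voxel0: nb mean 2, |1-2| = 1 ; voxel1: nb mean 1, |2-1| = 1
        #   voxel2: nb mean 2, |1-2| = 1  => s = [2, 1], n = [2, 1]
        d = disc_from([1, 2, 1])
        f = ngtdm_features(d)
        n, s = np.array([2, 1]), np.array([2.0, 1.0])
        p = n / 3
        ps = float((p * s).sum())
        np.testing.assert_allclose(f["Coarseness"], 1 / ps)
        contrast = (2 * p[0] * p[1] * 1) / (2 * 1) * (3 / 3)
        np.testing.assert_allclose(f["Contrast"], contrast)
        # |i p_i - j p_j| = |2/3 - 2/3| = 0 here: Busyness hits its 0 sentinel
        assert f["Busyness"] == 0.0

    def test_features_equal_oracle(self, rng):
        for d in n_random_volumes(rng, 40):
            try:
                ours = ngtdm_features(d)
            except DegenerateInputError:
                continue  # all voxels isolated: oracle would divide by zero too
            theirs = ngtdm_features_oracle(d.levels, d.mask, d.n_levels)
            for k in NGTDM_FEATURES:
                np.testing.assert_allclose(ours[k], theirs[k], atol=1e-9, err_msg=k)


class TestGLDM:
    def test_constant_cube_center_dependence(self):
        d = disc_from(np.ones((3, 3, 3), int))
        m = gldm_matrix(d, alpha=0)
        # center voxel has all 26 neighbours equal
        assert m[0, 26] == 1
        f = gldm_features(d)
        assert sorted(f) == sorted(GLDM_FEATURES)

    def test_strip_hand_count(self):
        # [1,2,1] with alpha 0: no equal-level neighbours -> single column
        d = disc_from([1, 2, 1])
        m = gldm_matrix(d, alpha=0)
        assert m.shape[1] == 1
        np.testing.assert_allclose(m[:, 0], [2, 1])

    def test_matrix_equals_neighbor_count_oracle(self, rng):
        for d in n_random_volumes(rng, 40):
            alpha = float(rng.integers(0, 2))
            np.testing.assert_allclose(
                gldm_matrix(d, alpha),
                gldm_matrix_oracle(d.levels, d.mask, d.n_levels, alpha),
                atol=1e-12,
            )

    def test_features_equal_oracle(self, rng):
        for d in n_random_volumes(rng, 20):
            ours = gldm_features(d)
            oracle = rlm_features_oracle(
                gldm_matrix_oracle(d.levels, d.mask, d.n_levels, 0.0), int(d.mask.sum())
            )
            for name, key in _GLDM_MAP.items():
                np.testing.assert_allclose(ours[name], oracle[key], atol=1e-9, err_msg=name)


class TestJointInvariances:
    """Properties that hold across all texture families."""

    def _families(self, d):
        return {
            "glcm": glcm_features(d),
            "glrlm": glrlm_features(d),
            "glszm": glszm_features(d),
            "gldm": gldm_features(d),
        }

    def test_translation_invariance(self, rng):
        lvl = rng.integers(1, 5, size=(4, 4, 4)).astype(np.int32)
        mask = rng.random((4, 4, 4)) > 0.3
        d1 = DiscretizedVolume(lvl * mask, 4, 1.0, mask)
        big_lvl = np.zeros((8, 8, 8), np.int32)
        big_mask = np.zeros((8, 8, 8), bool)
        big_lvl[2:6, 1:5, 3:7] = lvl * mask
        big_mask[2:6, 1:5, 3:7] = mask
        d2 = DiscretizedVolume(big_lvl, 4, 1.0, big_mask)
        f1, f2 = self._families(d1), self._families(d2)
        for fam in f1:
            for k in f1[fam]:
                np.testing.assert_allclose(f1[fam][k], f2[fam][k], atol=1e-9,
                                           err_msg=f"{fam}.{k}")

    def test_intensity_shift_invariance_via_discretization(self, rng):
        x = rng.uniform(0, 150, size=(5, 5, 5))
        mask = Mask(rng.random((5, 5, 5)) > 0.3)
        d1 = discretize(ImageVolume(x), mask, 25)
        d2 = discretize(ImageVolume(x + 77.7), mask, 25)
        f1, f2 = self._families(d1), self._families(d2)
        for fam in f1:
            for k in f1[fam]:
                np.testing.assert_allclose(f1[fam][k], f2[fam][k], atol=1e-9)

    def test_empty_mask_raises_everywhere(self):
        lvl = np.zeros((3, 3, 3), np.int32)
        d = DiscretizedVolume(lvl, 1, 1.0, np.zeros((3, 3, 3), bool))
        for fn in (glcm_features, glrlm_features, glszm_features, ngtdm_features, gldm_features):
            with pytest.raises(DegenerateInputError):
                fn(d)
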