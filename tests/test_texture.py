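"""Texture features: worked examples, oracle agreement, invariances."""

import numpy as np
import pytest

import oracles
from bladder_radiomics import texture
from bladder_radiomics.discretize import DiscretizationSpec
from bladder_radiomics.errors import DegenerateVoiError, EmptyMaskError
from bladder_radiomics.volume_io import Voi
from conftest import random_masked_subgrid

HORIZONTAL = ((0, 1, 0),)

# the canonical single-slice example grid used throughout
GRID_3X3 = np.array([[1, 1, 2], [2, 2, 3], [3, 3, 3]])[..., None]
FULL = np.ones_like(GRID_3X3, dtype=bool)


class TestHistogram:
    def test_constant_voi_conventions(self):
        f = texture.histogram_features([5] * 20)
        assert f["HISTO_Entropy_log2"] == 0.0
        assert f["HISTO_Energy"] == 1.0
        assert f["HISTO_Skewness"] == 0.0
        assert f["HISTO_Kurtosis"] == 0.0

    def test_two_equiprobable_levels(self):
        f = texture.histogram_features([1, 2] * 8)
        assert f["HISTO_Entropy_log2"] == pytest.approx(1.0)
        assert f["HISTO_Energy"] == pytest.approx(0.5)
        assert f["HISTO_AUC_CSH"] == pytest.approx(0.5)

    def test_entropy_bases_consistent(self):
        f = texture.histogram_features([1, 1, 2, 3])
        assert f["HISTO_Entropy_log10"] == pytest.approx(
            f["HISTO_Entropy_log2"] * np.log10(2)
        )

    def test_kurtosis_of_normal_sample(self):
        rng = np.random.default_rng(5)
        # raw (non-excess) standardized fourth moment: ~3 for a normal sample
        f = texture.histogram_features(rng.standard_normal(200_000))
        assert f["HISTO_Kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(1, 9, 500)
        shuffled = rng.permutation(levels)
        a = texture.histogram_features(levels)
        b = texture.histogram_features(shuffled)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12), key


class TestGlcm:
    def test_constant_voi(self):
        f = texture.glcm_features(np.full((3, 3, 2), 4), np.ones((3, 3, 2), bool), 8)
        assert f["GLCM_Homogeneity"] == pytest.approx(1.0)
        assert f["GLCM_Contrast"] == 0.0
        assert f["GLCM_Dissimilarity"] == 0.0
        assert f["GLCM_Energy"] == pytest.approx(1.0)
        assert f["GLCM_Correlation"] == 0.0  # zero-variance convention

    def test_worked_example_contrast(self):
        f = texture.glcm_features(GRID_3X3, FULL, 3, directions=HORIZONTAL)
        assert f["GLCM_Contrast"] == pytest.approx(1.0 / 3.0)

    def test_checkerboard_contrast(self):
        x, y, z = np.indices((4, 4, 2))
        levels = 1 + (x + y + z) % 2
        f = texture.glcm_features(levels, np.ones_like(levels, bool), 2,
                                  directions=((1, 0, 0), (0, 1, 0), (0, 0, 1)))
        assert f["GLCM_Contrast"] == pytest.approx(1.0)

    def test_matrix_normalized_and_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            levels, mask = random_masked_subgrid(rng)
            try:
                p = texture.glcm_matrix(levels, mask, 8)
            except DegenerateVoiError:
                continue
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(p, p.T, atol=1e-15)

    def test_single_voxel_raises(self):
        mask = np.zeros((3, 3, 1), bool)
        mask[1, 1, 0] = True
        with pytest.raises(DegenerateVoiError):
            texture.glcm_matrix(GRID_3X3, mask, 3)

    def test_mirror_doubling_bound(self):
        # mirroring along axis 0 duplicates all pairs and adds only pairs
        # crossing the mirror plane; the normalized matrices may differ by at
        # most twice that boundary fraction in L1
        rng = np.random.default_rng(21)
        levels = rng.integers(1, 5, (6, 6, 3))
        mask = np.ones_like(levels, bool)
        mirrored = np.concatenate([levels, levels[::-1]], axis=0)
        mmask = np.ones_like(mirrored, bool)
        p1 = texture.glcm_matrix(levels, mask, 4)
        p2 = texture.glcm_matrix(mirrored, mmask, 4)
        c1 = oracles.glcm_counts(levels, mask, 4, texture.DIRECTIONS_3D)
        c2 = oracles.glcm_counts(mirrored, mmask, 4, texture.DIRECTIONS_3D)
        boundary = c2.sum() - 2 * c1.sum()
        assert boundary >= 0
        l1 = np.abs(p1 - p2).sum()
        assert l1 <= 2 * boundary / c2.sum() + 1e-12


class TestGlrlm:
    def test_worked_example_runs(self):
        m = texture.glrlm_matrix(GRID_3X3, FULL, 3, directions=HORIZONTAL)
        # runs: (1,2), (2,1), (2,2), (3,1), (3,3)
        assert m.sum() == 5
        assert m[0, 1] == 1 and m[1, 0] == 1 and m[1, 1] == 1
        assert m[2, 0] == 1 and m[2, 2] == 1
        f = texture.glrlm_features(m, 9, n_directions=1)
        assert f["GLRLM_SRE"] == pytest.approx(2.6111111111 / 5, rel=1e-9)
        assert f["GLRLM_LRLGE"] == pytest.approx(
            (4 / 1 + 1 / 4 + 4 / 4 + 1 / 9 + 9 / 9) / 5, rel=1e-12
        )

    def test_constant_rows_single_direction(self):
        # constant VOI, rows of length L along the scan direction
        levels = np.ones((4, 6, 2), dtype=int)
        mask = np.ones_like(levels, bool)
        m = texture.glrlm_matrix(levels, mask, 1, directions=HORIZONTAL)
        f = texture.glrlm_features(m, levels.size, n_directions=1)
        assert f["GLRLM_LRE"] == pytest.approx(36.0)  # L = 6
        assert f["GLRLM_RP"] == pytest.approx(1.0 / 6.0)

    def test_mask_breaks_runs(self):
        levels = np.ones((1, 5, 1), dtype=int)
        mask = np.ones_like(levels, bool)
        mask[0, 2, 0] = False  # hole splits the row into 2 + 2
        m = texture.glrlm_matrix(levels, mask, 1, directions=HORIZONTAL)
        assert m[0, 1] == 2 and m.sum() == 2

    def test_conservation_law(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            levels, mask = random_masked_subgrid(rng)
            m = texture.glrlm_matrix(levels, mask, 8)
            lengths = np.arange(1, m.shape[1] + 1)
            assert (m * lengths).sum() == 13 * mask.sum()


class TestGlzlm:
    def test_worked_example_zones(self):
        m = texture.glzlm_matrix(GRID_3X3, FULL, 3)
        # zones: level 1 size 2, level 2 size 3, level 3 size 4
        assert m.sum() == 3
        assert m[0, 1] == 1 and m[1, 2] == 1 and m[2, 3] == 1
        f = texture.glzlm_features(m, 9)
        assert f["GLZLM_SZE"] == pytest.approx((1 / 4 + 1 / 9 + 1 / 16) / 3, rel=1e-12)
        assert f["GLZLM_ZP"] == pytest.approx(1.0 / 3.0)

    def test_constant_voi_single_zone(self):
        levels = np.full((3, 4, 2), 2)
        mask = np.ones_like(levels, bool)
        nv = levels.size
        f = texture.glzlm_features(texture.glzlm_matrix(levels, mask, 4), nv)
        assert f["GLZLM_SZE"] == pytest.approx(1 / nv**2)
        assert f["GLZLM_LZE"] == pytest.approx(nv**2)
        assert f["GLZLM_ZP"] == pytest.approx(1 / nv)

    def test_conservation_law(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            levels, mask = random_masked_subgrid(rng)
            m = texture.glzlm_matrix(levels, mask, 8)
            sizes = np.arange(1, m.shape[1] + 1)
            assert (m * sizes).sum() == mask.sum()


class TestNgldm:
    def test_constant_voi(self):
        f = texture.ngldm_features(np.full((3, 3, 2), 3), np.ones((3, 3, 2), bool), 4)
        assert f["NGLDM_Coarseness"] == pytest.approx(1.0 / texture.NGLDM_EPS)
        assert f["NGLDM_Contrast"] == 0.0
        assert f["NGLDM_Busyness"] == 0.0

    def test_two_level_strip_against_oracle(self):
        levels = np.tile(np.array([1, 2]), (4, 3))[..., None]
        mask = np.ones_like(levels, dtype=bool)
        got = texture.ngldm_features(levels, mask, 2)
        want = oracles.ngldm_features(levels, mask, 2)
        for key in got:
            assert got[key] == pytest.approx(want[key], rel=1e-10)

    def test_coarseness_decreases_with_noise(self):
        # busier fields have larger neighborhood differences, so coarseness drops
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(29)
        mask = np.ones((8, 8, 3), bool)

        def quantize(x):
            lo, hi = x.min(), x.max()
            return np.minimum((8 * (x - lo) / (hi - lo)).astype(int) + 1, 8)

        wins = 0
        for _ in range(15):
            base = gaussian_filter(rng.normal(size=mask.shape), sigma=1.5)
            extra = rng.normal(size=mask.shape)
            c_s = texture.ngldm_features(
                quantize(base + 0.02 * extra), mask, 8
            )["NGLDM_Coarseness"]
            c_n = texture.ngldm_features(
                quantize(base + 0.50 * extra), mask, 8
            )["NGLDM_Coarseness"]
            wins += c_s > c_n
        assert wins >= 12

    def test_isolated_voxels_raise(self):
        mask = np.zeros((5, 5, 1), bool)
        mask[0, 0, 0] = mask[4, 4, 0] = True
        with pytest.raises(DegenerateVoiError):
            texture.ngldm_features(np.ones((5, 5, 1), int), mask, 2)


class TestOracleAgreement:
    """Every matrix family vs brute-force enumeration on random subgrids."""

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_all_families_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        checked = 0
        while checked < 12:
            levels, mask = random_masked_subgrid(rng)
            nv = int(mask.sum())
            try:
                got_glcm = texture.glcm_features(levels, mask, 8)
            except DegenerateVoiError:
                continue
            checked += 1
            want_glcm = oracles.glcm_features(levels, mask, 8, texture.DIRECTIONS_3D)
            for k, v in want_glcm.items():
                assert got_glcm[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

            got = texture.glrlm_features(
                texture.glrlm_matrix(levels, mask, 8), nv
            )
            want = oracles.rl_features(
                oracles.glrlm_counts(levels, mask, 8, texture.DIRECTIONS_3D), nv, 13
            )
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

            got = texture.glzlm_features(texture.glzlm_matrix(levels, mask, 8), nv)
            want = oracles.zone_features(oracles.glzlm_counts(levels, mask, 8), nv)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

            try:
                got = texture.ngldm_features(levels, mask, 8)
            except DegenerateVoiError:
                continue
            want = oracles.ngldm_features(levels, mask, 8)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k


class TestExtraction:
    def test_feature_panel_names(self, strong_cohort):
        _, records, _ = strong_cohort
        from bladder_radiomics import default_specs, extract_features

        per_seq = extract_features(records[0], default_specs())
        assert set(per_seq) == {"T2", "DWI", "ADC"}
        for feats in per_seq.values():
            assert set(feats) == set(texture.ALL_FEATURES) | set(texture.EXTRA_FEATURES)
            assert len(texture.ALL_FEATURES) == 37
            assert all(np.isfinite(v) for v in feats.values())

    def test_translation_invariance(self):
        rng = np.random.default_rng(31)
        levels, mask = random_masked_subgrid(rng, max_shape=(5, 5, 3))
        spec = DiscretizationSpec(0.0, 9.0, n_levels=8)
        voi_a = Voi(values=levels[mask].astype(float), subgrid=levels.astype(float),
                    submask=mask)
        pad = np.pad(levels, ((2, 1), (0, 3), (1, 0)))
        pmask = np.pad(mask, ((2, 1), (0, 3), (1, 0)))
        voi_b = Voi(values=pad[pmask].astype(float), subgrid=pad.astype(float),
                    submask=pmask)
        fa = texture.compute_features(voi_a, spec)
        fb = texture.compute_features(voi_b, spec)
        for key in fa:
            assert fa[key] == pytest.approx(fb[key], rel=1e-12), key

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            texture.glcm_matrix(np.ones((2, 2, 2), int), np.zeros((2, 2, 2), bool), 2)
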