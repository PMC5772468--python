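"""Group statistics, permutation FWE, masking and peak reporting."""

import numpy as np
import pytest
from scipy import stats

from circabold.bold import make_affine, make_atlas, region_mask
from circabold.inference import (covariate_slope_t, exclusive_mask,
                                 one_sample_t, peak_table, permutation_fwe,
                                 roi_small_volume, uncorrected_p)


def _maps(rng, n=8, shape=(6, 6, 6)):
    return [rng.normal(size=shape) for _ in range(n)]


class TestOneSampleT:
    def test_hand_computed_example(self):
        maps = [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0)]
        sm = one_sample_t(maps)
        assert sm.t[0, 0, 0] == pytest.approx(3.4641016)
        assert sm.dof == 2

    def test_zero_variance_becomes_nan(self):
        maps = [np.zeros((2, 2, 2)) for _ in range(5)]
        sm = one_sample_t(maps)
        assert np.isnan(sm.t).all()

    def test_sign_flip_negates(self, rng):
        maps = _maps(rng)
        t1 = one_sample_t(maps).t
        t2 = one_sample_t([-m for m in maps]).t
        assert np.allclose(t1, -t2)

    def test_minimum_subjects(self, rng):
        with pytest.raises(ValueError):
            one_sample_t(_maps(rng, n=2))


class TestCovariateSlope:
    def test_exact_linear_fit_flagged_and_capped(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        maps = [np.full((2, 2, 2), 0.7 * c + 1.0) for c in cov]
        sm = covariate_slope_t(maps, cov)
        assert sm.info["perfect_fit_voxels"] == 8
        assert np.all(sm.t == 1e6)

    def test_null_covariate_gives_small_slopes(self, rng):
        maps = _maps(rng, n=20)
        cov = rng.normal(size=20)
        sm = covariate_slope_t(maps, cov)
        # slope t is t-distributed with df 18 under the null
        assert abs(np.mean(sm.t)) < 0.2
        assert 0.8 < np.std(sm.t) < 1.3

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            covariate_slope_t(_maps(rng, n=5), np.ones(5))

    def test_recovers_planted_negative_slope_region(self):
        """Subjects with larger covariate values decline more in one region:
        the slope test localises the association over repeated runs."""
        shape = (8, 8, 8)
        region = np.zeros(shape, bool)
        region[2:5, 2:5, 2:5] = True
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cov = rng.normal(size=16)
            maps = []
            for c in cov:
                m = rng.normal(0, 1, size=shape)
                m[region] += -1.2 * c
                maps.append(m)
            base = covariate_slope_t(maps, cov)
            sm = permutation_fwe(maps, base, n_perm=500, seed=seed,
                                 covariate=cov, two_sided=True)
            sig = (np.nan_to_num(sm.fwe_p, nan=1.0) <= 0.05)
            hits += int((sig & region & (sm.t < 0)).any()
                        and not (sig & ~region).any())
        assert hits >= 9


class TestPermutationFWE:
    def test_small_n_enumerates_exhaustively(self, rng):
        maps = _maps(rng, n=4)
        base = one_sample_t(maps)
        with pytest.warns(UserWarning, match="16 distinct sign patterns"):
            sm = permutation_fwe(maps, base, n_perm=500, seed=0)
        # exhaustive p-values are multiples of 1/16
        vals = sm.fwe_p[np.isfinite(sm.fwe_p)]
        assert np.allclose(vals * 16, np.round(vals * 16))

    def test_strong_voxel_attains_minimum_p(self, rng):
        maps = []
        for _ in range(12):
            m = rng.normal(size=(5, 5, 5))
            m[2, 2, 2] += 50.0
            maps.append(m)
        base = one_sample_t(maps)
        sm = permutation_fwe(maps, base, n_perm=500, seed=1, two_sided=False)
        assert sm.fwe_p[2, 2, 2] == pytest.approx(1.0 / 501.0)

    def test_null_data_rarely_significant(self, rng):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            maps = _maps(r, n=8)
            base = one_sample_t(maps)
            sm = permutation_fwe(maps, base, n_perm=256, seed=seed)
            hits += int((np.nan_to_num(sm.fwe_p, nan=1.0) <= 0.05).any())
        assert hits <= 7      # ~5% nominal


class TestROISmallVolume:
    def test_whole_volume_mask_equals_whole_brain(self, rng):
        maps = _maps(rng, n=8)
        base = one_sample_t(maps)
        sm1 = permutation_fwe(maps, base, n_perm=256, seed=3)
        sm2 = roi_small_volume(maps, base, np.ones((6, 6, 6), bool),
                               n_perm=256, seed=3)
        assert np.allclose(sm1.fwe_p, sm2.fwe_p, equal_nan=True)

    def test_restriction_never_hurts_with_exhaustive_null(self, rng):
        maps = _maps(rng, n=6)
        for m in maps:
            m[1, 1, 1] += 2.0
        base = one_sample_t(maps)
        roi = np.zeros((6, 6, 6), bool)
        roi[:3, :3, :3] = True
        with pytest.warns(UserWarning):
            whole = permutation_fwe(maps, base, n_perm=200, seed=0)
            small = roi_small_volume(maps, base, roi, n_perm=200, seed=0)
        assert small.fwe_p[1, 1, 1] <= whole.fwe_p[1, 1, 1]

    def test_empty_mask_rejected(self, rng):
        maps = _maps(rng, n=6)
        base = one_sample_t(maps)
        with pytest.raises(ValueError):
            roi_small_volume(maps, base, np.zeros((6, 6, 6), bool))


class TestExclusiveMask:
    def _sm(self, rng, boost=0.0):
        maps = _maps(rng, n=10)
        if boost:
            for m in maps:
                m += boost
        base = one_sample_t(maps)
        return maps, permutation_fwe(maps, base, n_perm=256, seed=5)

    def test_masking_by_itself_empties_significant_voxels(self, rng):
        maps, sm = self._sm(rng, boost=3.0)
        masked = exclusive_mask(sm, sm, p_thresh=0.05)
        # every voxel uncorrected-significant in itself is removed
        assert not masked.mask[uncorrected_p(sm) < 0.05].any()

    def test_null_other_leaves_primary_untouched(self, rng):
        maps, sm = self._sm(rng, boost=3.0)
        null_t = np.zeros_like(sm.t)
        other = type(sm)(t=null_t, dof=sm.dof, mask=sm.mask, fwe_p=None,
                         n_subjects=sm.n_subjects)
        masked = exclusive_mask(sm, other)
        assert np.array_equal(masked.mask, sm.mask)
        assert np.allclose(masked.t[masked.mask], sm.t[sm.mask])

    def test_geometry_mismatch(self, rng):
        _, sm = self._sm(rng)
        other = one_sample_t(_maps(rng, n=6, shape=(5, 5, 5)))
        with pytest.raises(ValueError):
            exclusive_mask(sm, other)


class TestPeakTable:
    def _fwe(self, maps, seed=0):
        base = one_sample_t(maps)
        return permutation_fwe(maps, base, n_perm=500, seed=seed)

    def test_no_significant_voxels_gives_empty_table(self, rng):
        atlas = make_atlas((12, 14, 12))
        maps = [rng.normal(size=(12, 14, 12)) for _ in range(10)]
        sm = self._fwe(maps)
        pt = peak_table(sm, atlas, make_affine((12, 14, 12)))
        assert pt.rows.empty

    def test_single_blob_labelled_by_region(self, rng):
        atlas = make_atlas((12, 14, 12))
        thal = region_mask(atlas, "thalamus")
        maps = []
        for _ in range(10):
            m = rng.normal(size=(12, 14, 12))
            m[thal] += 8.0
            maps.append(m)
        sm = self._fwe(maps)
        pt = peak_table(sm, atlas, make_affine((12, 14, 12)))
        assert not pt.rows.empty
        assert (pt.rows["region"] == "thalamus").any()
        assert pt.rows["p_fwe"].is_monotonic_increasing

    def test_two_blobs_two_rows_sorted(self, rng):
        atlas = make_atlas((12, 14, 12))
        m1 = region_mask(atlas, "lingual")
        m2 = region_mask(atlas, "frontal")
        maps = []
        for _ in range(10):
            m = rng.normal(size=(12, 14, 12))
            m[m1] += 9.0
            m[m2] -= 6.0
            maps.append(m)
        sm = self._fwe(maps)
        pt = peak_table(sm, atlas, make_affine((12, 14, 12)))
        regions = set(pt.rows["region"])
        assert {"lingual", "frontal"} <= regions
        assert pt.rows["p_fwe"].is_monotonic_increasing

    def test_z_equivalent_matches_t_tail(self):
        t, dof = 4.0, 20
        z = stats.norm.isf(stats.t.sf(t, dof))
        assert 0 < z < t     # z equivalent is smaller than t at modest df

    def test_requires_fwe(self, rng):
        sm = one_sample_t(_maps(rng, n=5))
        with pytest.raises(ValueError):
            peak_table(sm, make_atlas((6, 6, 6)), make_affine((6, 6, 6)))
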