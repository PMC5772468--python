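"""Canonical HRF, design construction and OLS estimation."""

import logging

import numpy as np
import pandas as pd
import pytest

from circabold.bold import simulate_motion
from circabold.glm import (DesignMatrix, build_design, canonical_hrf, fit_glm,
                           session_contrast, smooth_volume)
from circabold.pvt import PVTSession, simulate_pvt_session
from circabold.behavior import partition_rts


@pytest.fixture(scope="module")
def pvt():
    return simulate_pvt_session(6.0, None, seed=11)


@pytest.fixture(scope="module")
def design(pvt, ):
    motion = simulate_motion(273, np.random.default_rng(0))
    return build_design(pvt, partition_rts(pvt.rts), motion)


class TestHRF:
    def test_peak_near_five_seconds(self):
        h = canonical_hrf(0.01)
        assert np.argmax(h) * 0.01 == pytest.approx(5.0, abs=0.05)

    def test_zero_at_onset_and_unit_peak(self):
        h = canonical_hrf(0.1)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_positive_net_response(self):
        h = canonical_hrf(0.1)
        assert h.sum() * 0.1 > 0

    def test_matches_reference_double_gamma(self):
        """Cross-check the kernel shape against nilearn's SPM HRF."""
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = canonical_hrf(0.1)
        ref = nilearn_hrf.spm_hrf(2.2, oversampling=22, time_length=32.1)
        n = min(len(ours), len(ref))
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestDesign:
    def test_column_structure(self, design):
        # 4 event mains + 4 tmods + 6 motion + 9 drift + intercept
        n_events = sum(1 for c in design.columns
                       if c in ("fast", "intermediate", "slow", "lapse"))
        n_tmod = sum(1 for c in design.columns if c.endswith("_tmod"))
        n_drift = sum(1 for c in design.columns if c.startswith("drift"))
        assert n_events == 4 and n_tmod == 4
        assert n_drift == int(np.floor(2 * 273 * 2.2 / 128))
        assert design.columns[-1] == "intercept"
        assert design.matrix.shape == (273, len(design.columns))

    def test_single_event_column_is_sampled_hrf(self):
        trials = pd.DataFrame({"onset_s": [0.0], "trial_type": ["clock"],
                               "response_time_ms": [300.0]})
        pvt1 = PVTSession("s", "SD", 0, trials)
        part = partition_rts(np.full(8, 300.0))   # thresholds degenerate
        from circabold.behavior import RTPartition
        part = RTPartition(labels=np.array(["fast"]), p25=400, p75=450)
        motion = np.zeros((273, 6))
        d = build_design(pvt1, part, motion)
        hrf = canonical_hrf(0.1)
        col = d.matrix[:, d.columns.index("fast")]
        expect = np.interp(d.frame_times, np.arange(hrf.size) * 0.1,
                           hrf, right=0.0)
        assert np.allclose(col[:15], expect[:15], atol=1e-6)

    def test_absent_event_type_dropped_with_log(self, caplog):
        trials = pd.DataFrame({"onset_s": [10.0, 30.0, 50.0],
                               "trial_type": ["clock"] * 3,
                               "response_time_ms": [300.0, 310.0, 320.0]})
        pvt3 = PVTSession("s", "SD", 0, trials)
        from circabold.behavior import RTPartition
        part = RTPartition(labels=np.array(["fast", "slow", "slow"]),
                           p25=305, p75=308)
        with caplog.at_level(logging.INFO, logger="circabold.glm"):
            d = build_design(pvt3, part, np.zeros((273, 6)))
        assert "lapse" in d.dropped and "intermediate" in d.dropped
        assert "lapse" not in d.columns

    def test_determinism(self, pvt):
        m = simulate_motion(273, np.random.default_rng(3))
        d1 = build_design(pvt, partition_rts(pvt.rts), m)
        d2 = build_design(pvt, partition_rts(pvt.rts), m)
        assert np.array_equal(d1.matrix, d2.matrix)


class TestFit:
    def _toy(self, rng, n_scans=10, n_reg=3, n_vox=3):
        X = rng.normal(size=(n_scans, n_reg))
        d = DesignMatrix(matrix=X, columns=[f"c{i}" for i in range(n_reg)],
                         tr=2.2, frame_times=np.arange(n_scans) * 2.2)
        Y = rng.normal(size=(1, 1, n_vox, n_scans))
        return X, d, Y

    def test_matches_normal_equation_oracle(self, rng):
        X, d, Y = self._toy(rng)
        res = fit_glm(Y, d)
        # independent oracle: solve the normal equations voxel by voxel
        flat = Y.reshape(-1, 10).T
        oracle = np.linalg.inv(X.T @ X) @ X.T @ flat
        ours = np.stack([res.betas[c].ravel() for c in d.columns])
        assert np.allclose(ours, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        X, d, Y = self._toy(rng)
        res = fit_glm(Y, d)
        beta = np.stack([res.betas[c].ravel() for c in d.columns])
        resid = Y.reshape(-1, 10).T - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-6

    def test_scaling_equivariance(self, rng):
        X, d, Y = self._toy(rng)
        r1 = fit_glm(Y, d)
        r2 = fit_glm(3.5 * Y, d)
        for c in d.columns:
            assert np.allclose(3.5 * r1.betas[c], r2.betas[c])

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.normal(size=(10, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        d = DesignMatrix(matrix=X, columns=["a", "b", "a_copy"], tr=2.2,
                         frame_times=np.arange(10) * 2.2)
        with pytest.raises(np.linalg.LinAlgError, match="a_copy"):
            fit_glm(np.zeros((1, 1, 1, 10)), d)

    def test_dof(self, rng):
        X, d, Y = self._toy(rng)
        assert fit_glm(Y, d).dof == 7

    def test_requested_contrast_must_exist(self, rng):
        X, d, Y = self._toy(rng)
        res = fit_glm(Y, d)
        with pytest.raises(ValueError):
            session_contrast(res, "fast")


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        v = rng.normal(size=(8, 8, 8))
        assert np.array_equal(smooth_volume(v, 0.0), v)

    def test_constant_preserved(self):
        v = np.full((8, 8, 8), 3.7)
        assert np.allclose(smooth_volume(v, 8.0, 3.0), v)

    def test_delta_becomes_gaussian_with_correct_sigma(self):
        v = np.zeros((21, 21, 21))
        v[10, 10, 10] = 1.0
        out = smooth_volume(v, 8.0, 3.0)
        sigma_vox = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        x = np.arange(21) - 10.0
        g = np.exp(-x ** 2 / (2 * sigma_vox ** 2))
        g /= g.sum()
        expect = g[:, None, None] * g[None, :, None] * g[None, None, :]
        assert np.allclose(out, expect, atol=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), -1.0)
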