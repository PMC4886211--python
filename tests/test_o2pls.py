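import warnings

import numpy as np
import pytest

from fermlink.o2pls import (
    O2PLSModel, O2PLSError,
    fit_o2pls, predict_y, cross_validate, select_components, vip_pred,
)
from fermlink.synthetic import LatentSpec, assemble_dataset
from fermlink.tables import clr_transform, min_max_normalize
from conftest import principal_angles_deg


def _align_signs(A, B):
    """Flip columns of A to match B's signs (subspace comparisons)."""
    A = A.copy()
    for a in range(A.shape[1]):
        if A[:, a] @ B[:, a] < 0:
            A[:, a] *= -1
    return A


class TestFit:
    def test_rank_one_noise_free_recovery(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 1, 30)
        w = rng.normal(0, 1, 6); w /= np.linalg.norm(w)
        c = rng.normal(0, 1, 4); c /= np.linalg.norm(c)
        X = np.outer(t, w)
        Y = np.outer(t, c)
        m = fit_o2pls(X, Y, 1, scale="center")
        assert min(np.linalg.norm(m.W[:, 0] - w), np.linalg.norm(m.W[:, 0] + w)) < 1e-8
        assert min(np.linalg.norm(m.C[:, 0] - c), np.linalg.norm(m.C[:, 0] + c)) < 1e-8
        assert m.r2y_cum > 1 - 1e-10

    def test_weights_match_dense_svd_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(0, 1, (20, 8))
        Y = rng.normal(0, 1, (20, 5))
        m = fit_o2pls(X, Y, 2, scale="center")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc.T @ Yc)
        W_oracle = _align_signs(U[:, :2], m.W)
        C_oracle = _align_signs(Vt[:2].T, m.C)
        assert np.abs(m.W - W_oracle).max() < 1e-8
        assert np.abs(m.C - C_oracle).max() < 1e-8

    def test_zero_cross_covariance_raises(self):
        t = np.array([1.0, 1.0, -1.0, -1.0])
        u = np.array([1.0, -1.0, 1.0, -1.0])       # exactly orthogonal to t
        X = np.outer(t, [1.0, 0.5, 0.0])
        Y = np.outer(u, [0.3, 1.0])
        with pytest.raises(O2PLSError, match="no joint variation"):
            fit_o2pls(X, Y, 1, scale="center")

    def test_model_invariants(self, fitted_model):
        m = fitted_model
        K = m.n_components
        assert np.abs(m.W.T @ m.W - np.eye(K)).max() < 1e-8
        assert np.abs(m.C.T @ m.C - np.eye(K)).max() < 1e-8
        if m.T_orth_x.size:
            assert np.abs(m.T.T @ m.T_orth_x).max() < 1e-6 * np.linalg.norm(m.T)
        assert 0.0 <= m.r2y_cum <= 1.0
        assert abs((m.vip_pred ** 2).mean() - 1.0) < 1e-10

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (25, 7))
        Y = rng.normal(0, 1, (25, 4)) + X[:, :4]
        m1 = fit_o2pls(X, Y, 2, scale="uv")
        m2 = fit_o2pls(X, 3.7 * Y, 2, scale="uv")
        assert np.allclose(m1.W, m2.W, atol=1e-10)
        assert np.allclose(m1.C, m2.C, atol=1e-10)
        assert np.allclose(m1.vip_pred, m2.vip_pred, atol=1e-10)
        cv1 = cross_validate(X, Y, 2, folds=5)
        cv2 = cross_validate(X, 3.7 * Y, 2, folds=5)
        assert abs(cv1.q2_cum - cv2.q2_cum) < 1e-10


class TestVip:
    def test_hand_computed_two_component_toy(self):
        """p=3, SSY=(3,1), w1=(1,0,0), w2=(0,1,0) -> VIP=(1.5, sqrt(3)/2, 0)."""
        m = O2PLSModel(
            W=np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
            C=np.eye(2), T=np.eye(2), U=np.eye(2), B=np.eye(2),
            W_orth_x=np.empty((3, 0)), P_orth_x=np.empty((3, 0)),
            T_orth_x=np.empty((2, 0)), C_orth_y=np.empty((2, 0)),
            P_orth_y=np.empty((2, 0)), U_orth_y=np.empty((2, 0)),
            x_center=np.zeros(3), x_scale=np.ones(3),
            y_center=np.zeros(2), y_scale=np.ones(2), scaling="center",
            r2x_cum=1.0, r2y_cum=1.0, vip_pred=np.empty(0),
            ssy_per_component=np.array([3.0, 1.0]),
        )
        vip = vip_pred(m)
        assert np.allclose(vip, [1.5, np.sqrt(3) / 2, 0.0], atol=1e-12)

    def test_equal_weights_give_unit_vip(self):
        w = np.full((4, 1), 0.5)
        m = O2PLSModel(
            W=w, C=np.ones((1, 1)), T=np.ones((2, 1)), U=np.ones((2, 1)),
            B=np.ones((1, 1)),
            W_orth_x=np.empty((4, 0)), P_orth_x=np.empty((4, 0)),
            T_orth_x=np.empty((2, 0)), C_orth_y=np.empty((1, 0)),
            P_orth_y=np.empty((1, 0)), U_orth_y=np.empty((2, 0)),
            x_center=np.zeros(4), x_scale=np.ones(4),
            y_center=np.zeros(1), y_scale=np.ones(1), scaling="center",
            r2x_cum=1.0, r2y_cum=1.0, vip_pred=np.empty(0),
            ssy_per_component=np.array([2.0]),
        )
        assert np.allclose(vip_pred(m), 1.0, atol=1e-12)

    def test_mean_square_is_one_for_random_fits(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.normal(0, 1, (15, 6))
            Y = rng.normal(0, 1, (15, 4)) + 0.5 * X[:, :4]
            m = fit_o2pls(X, Y, 2)
            assert abs((m.vip_pred ** 2).mean() - 1.0) < 1e-10


class TestPredict:
    def test_training_predictions_consistent(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 6))
        Y = rng.normal(0, 1, (20, 5)) + X[:, :5]
        m = fit_o2pls(X, Y, 2, nx=1, ny=1, scale="uv")
        pred = predict_y(m, X)
        fit_recon = (m.T @ m.B @ m.C.T) * m.y_scale + m.y_center
        assert np.abs(pred - fit_recon).max() < 1e-10

    def test_mean_row_predicts_mean_y(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (20, 6))
        Y = rng.normal(0, 1, (20, 5)) + X[:, :5]
        m = fit_o2pls(X, Y, 2)
        pred = predict_y(m, X.mean(axis=0))
        assert np.abs(pred - Y.mean(axis=0)).max() < 1e-10

    def test_column_mismatch_raises(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (12, 6))
        Y = rng.normal(0, 1, (12, 3)) + X[:, :3]
        m = fit_o2pls(X, Y, 1)
        with pytest.raises(O2PLSError, match="columns"):
            predict_y(m, np.zeros((2, 5)))

    def test_noise_free_synthetic_holdout(self):
        """High holdout Q2 on generator output without orthogonal structure."""
        spec = LatentSpec(seed=13, nx_orth=0, ny_orth=0,
                          noise_sd_x=0.0, noise_sd_y=0.0)
        ds = assemble_dataset(spec)
        X = clr_transform(ds.abundance).T.to_numpy()
        Y = min_max_normalize(ds.flavours).values.T.to_numpy()
        train = np.arange(len(X)) % 3 != 0
        m = fit_o2pls(X[train], Y[train], 2, scale="center")
        pred = predict_y(m, X[~train])
        ss = ((Y[~train] - Y[train].mean(axis=0)) ** 2).sum()
        q2 = 1 - ((Y[~train] - pred) ** 2).sum() / ss
        assert q2 > 0.99


class TestCrossValidation:
    def test_exact_linear_map_gives_high_q2(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (70, 2)) @ rng.normal(0, 1, (2, 8))  # rank-2 block
        Y = X @ rng.normal(0, 1, (8, 5))
        cv = cross_validate(X, Y, 2, folds=7)
        assert cv.q2_cum > 0.99

    def test_leave_one_out_runs(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (12, 5))
        Y = X[:, :3] + 0.01 * rng.normal(0, 1, (12, 3))
        cv = cross_validate(X, Y, 1, folds=12)
        assert np.isfinite(cv.q2_cum)

    def test_too_many_folds_raises(self):
        X = np.random.default_rng(0).normal(0, 1, (5, 3))
        with pytest.raises(O2PLSError, match="folds"):
            cross_validate(X, X[:, :2], 1, folds=6)

    def test_per_component_q2_sums_to_cumulative(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (30, 6))
        Y = X[:, :4] + 0.1 * rng.normal(0, 1, (30, 4))
        cv = cross_validate(X, Y, 3, folds=5)
        assert abs(cv.q2_per_component.sum() - cv.q2_cum) < 1e-12

    def test_q2_below_r2(self, prepared, fitted_model):
        cv = cross_validate(prepared["X"], prepared["Y"], 2, nx=1, ny=1,
                            folds=7, scale="center")
        assert cv.q2_cum <= fitted_model.r2y_cum + 1e-9


class TestSelectComponents:
    def test_pure_noise_returns_k1_with_warning(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (30, 6))
        Y = rng.normal(0, 1, (30, 4))
        with pytest.warns(UserWarning, match="K=1"):
            K, nx, ny = select_components(X, Y, max_components=3, max_orth=1)
        assert K == 1

    def test_negative_infinity_limit_gives_max_k(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (40, 8))
        Y = X[:, :5] + 0.05 * rng.normal(0, 1, (40, 5))
        K, _, _ = select_components(X, Y, max_components=3, max_orth=0,
                                    limit=-np.inf)
        assert K == 3
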