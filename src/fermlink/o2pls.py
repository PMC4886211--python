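"""Two-way orthogonal projections to latent structures (O2PLS).

O2PLS decomposes a paired pair of blocks ``X`` (n x p) and ``Y`` (n x q)
into joint components shared by both blocks, block-specific orthogonal
components, and residual noise:

    X = T W' + T_ox P_ox' + E,      Y = U C' + U_oy P_oy' + F,
    U ~ T B   (inner regression)

Joint weights ``W`` and ``C`` are the leading left/right singular vectors
of the cross-covariance ``X'Y``; orthogonal components are then extracted
from each block's residual against its joint scores and deflated, and the
joint scores and inner regression are re-estimated on the filtered
blocks.  Model quality is summarized by the explained-variance fractions
R2X/R2Y and the cross-validated predictive fraction Q2 = 1 - PRESS/SS
(seven-fold by default), and per-predictor importance by the VIP score of
the predictive (joint) components.

Both blocks are column-centered and, by default, scaled to unit variance
("uv"); centering-only is available via ``scale="center"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class O2PLSError(ValueError):
    """Raised for invalid fits or predictions."""


def _as_array(M) -> np.ndarray:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float)
    return np.asarray(M, dtype=float)


def _preprocess(M: np.ndarray, scale: str):
    center = M.mean(axis=0)
    if scale == "uv":
        sd = M.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
    elif scale == "center":
        sd = np.ones(M.shape[1])
    else:
        raise O2PLSError(f"unknown scaling {scale!r}; use 'uv' or 'center'")
    return (M - center) / sd, center, sd


@dataclass
class O2PLSModel:
    """A fitted O2PLS model.

    Attributes follow the standard two-block notation: joint weights
    ``W`` (p x K) and ``C`` (q x K) with unit-norm columns, joint scores
    ``T``/``U`` on the orthogonal-filtered blocks, the K x K inner
    regression ``B``, orthogonal weights/loadings/scores for each block,
    centering/scaling records, and the diagnostics ``r2x_cum``,
    ``r2y_cum`` and ``vip_pred``.
    """

    W: np.ndarray
    C: np.ndarray
    T: np.ndarray
    U: np.ndarray
    B: np.ndarray
    W_orth_x: np.ndarray
    P_orth_x: np.ndarray
    T_orth_x: np.ndarray
    C_orth_y: np.ndarray
    P_orth_y: np.ndarray
    U_orth_y: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    scaling: str
    r2x_cum: float
    r2y_cum: float
    vip_pred: np.ndarray
    ssy_per_component: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


@dataclass
class CVResult:
    """Cross-validation summary for an O2PLS configuration."""

    folds: int
    q2_per_component: np.ndarray   # incremental Q2 of joint components 1..K
    q2_cum: float
    limit: float = 0.05
    chosen: tuple[int, int, int] | None = None   # (K, nx, ny) when selected


def _dominant_left_vector(M: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    v = u[:, 0]
    j = np.argmax(np.abs(v))
    return v if v[j] >= 0 else -v


def fit_o2pls(X, Y, n_components: int, nx: int = 0, ny: int = 0,
              scale: str = "uv") -> O2PLSModel:
    """Fit an O2PLS model with ``n_components`` joint and nx/ny orthogonal parts.

    Estimation: (1) SVD of the cross-covariance X'Y gives W and C;
    (2) nx rounds of X-orthogonal extraction: the dominant left singular
    vector of (X - T W')' T defines an orthogonal weight whose score and
    loading are deflated from X; (3) symmetric procedure on Y;
    (4) joint scores, inner regression B and the diagnostics are
    recomputed on the filtered blocks.  Column signs follow the
    convention that each W column's largest-magnitude entry is positive
    (C flips jointly so predictions are invariant).

    Raises on rank-deficient joint scores (reduce K) and on an (all but)
    zero cross-covariance ("no joint variation").
    """
    X = _as_array(X)
    Y = _as_array(Y)
    n, p = X.shape
    n2, q = Y.shape
    if n != n2:
        raise O2PLSError(f"X has {n} rows but Y has {n2}")
    if n < 3:
        raise O2PLSError("need at least 3 samples")
    K = int(n_components)
    if K < 1:
        raise O2PLSError("n_components must be >= 1")
    if K + max(nx, ny) >= min(n, p, q):
        raise O2PLSError(
            f"K={K} with nx={nx}, ny={ny} exceeds the usable rank of an "
            f"{n}x{p} / {n}x{q} problem"
        )

    Xs, x_center, x_scale = _preprocess(X, scale)
    Ys, y_center, y_scale = _preprocess(Y, scale)
    X0, Y0 = Xs.copy(), Ys.copy()

    cov = Xs.T @ Ys
    Uc, sv, Vt = np.linalg.svd(cov, full_matrices=False)
    if sv[0] <= 1e-12 * max(n, p, q):
        raise O2PLSError("no joint variation: X'Y is numerically zero")
    if len(sv) < K:
        raise O2PLSError(f"cross-covariance supports at most {len(sv)} components")
    W = Uc[:, :K].copy()
    C = Vt[:K].T.copy()
    # deterministic sign convention
    for a in range(K):
        j = np.argmax(np.abs(W[:, a]))
        if W[j, a] < 0:
            W[:, a] *= -1.0
            C[:, a] *= -1.0

    W_ox = np.empty((p, 0)); P_ox = np.empty((p, 0)); T_ox = np.empty((n, 0))
    for _ in range(nx):
        T = Xs @ W
        E = Xs - T @ W.T
        w_o = _dominant_left_vector(E.T @ T)
        t_o = Xs @ w_o
        denom = t_o @ t_o
        if denom <= 1e-300:
            raise O2PLSError("degenerate X-orthogonal score; reduce nx")
        p_o = Xs.T @ t_o / denom
        Xs = Xs - np.outer(t_o, p_o)
        W_ox = np.column_stack([W_ox, w_o])
        P_ox = np.column_stack([P_ox, p_o])
        T_ox = np.column_stack([T_ox, t_o])

    C_oy = np.empty((q, 0)); P_oy = np.empty((q, 0)); U_oy = np.empty((n, 0))
    for _ in range(ny):
        U = Ys @ C
        F = Ys - U @ C.T
        c_o = _dominant_left_vector(F.T @ U)
        u_o = Ys @ c_o
        denom = u_o @ u_o
        if denom <= 1e-300:
            raise O2PLSError("degenerate Y-orthogonal score; reduce ny")
        p_o = Ys.T @ u_o / denom
        Ys = Ys - np.outer(u_o, p_o)
        C_oy = np.column_stack([C_oy, c_o])
        P_oy = np.column_stack([P_oy, p_o])
        U_oy = np.column_stack([U_oy, u_o])

    T = Xs @ W
    U = Ys @ C
    gram = T.T @ T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise O2PLSError(
            "joint score matrix is rank deficient; reduce the number of components"
        )
    B = np.linalg.solve(gram, T.T @ U)
    Y_hat = T @ B @ C.T

    ss_y = (Y0 ** 2).sum()
    r2y = 1.0 - ((Y0 - Y_hat) ** 2).sum() / ss_y if ss_y > 0 else 0.0
    X_hat = T @ W.T
    if T_ox.size:
        X_hat = X_hat + T_ox @ P_ox.T
    ss_x = (X0 ** 2).sum()
    r2x = 1.0 - ((X0 - X_hat) ** 2).sum() / ss_x if ss_x > 0 else 0.0

    ssy_comp = np.array([
        (T[:, a] ** 2).sum() * ((B[a] @ C.T) ** 2).sum() for a in range(K)
    ])
    model = O2PLSModel(
        W=W, C=C, T=T, U=U, B=B,
        W_orth_x=W_ox, P_orth_x=P_ox, T_orth_x=T_ox,
        C_orth_y=C_oy, P_orth_y=P_oy, U_orth_y=U_oy,
        x_center=x_center, x_scale=x_scale,
        y_center=y_center, y_scale=y_scale, scaling=scale,
        r2x_cum=float(r2x), r2y_cum=float(r2y),
        vip_pred=np.empty(0), ssy_per_component=ssy_comp,
    )
    model.vip_pred = vip_pred(model)
    return model


def vip_pred(model: O2PLSModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) where
    SSY_a is the Y sum of squares captured by the rank-one contribution of
    joint component a.  The mean of VIP^2 equals 1 by construction, so
    values above 1 flag predictors that matter more than average.
    """
    ssy = model.ssy_per_component
    total = ssy.sum()
    if total <= 0:
        raise O2PLSError("zero explained Y variance: VIP undefined")
    p = model.W.shape[0]
    wn = model.W / np.linalg.norm(model.W, axis=0)
    return np.sqrt(p * (wn ** 2 @ ssy) / total)


def predict_y(model: O2PLSModel, X_new) -> np.ndarray:
    """Predict the Y block for new X rows, in Y's original units.

    New rows are centered/scaled with the training parameters, the
    X-orthogonal variation is removed with the fitted orthogonal weights
    and loadings, and the joint regression is applied and un-scaled.
    """
    X_new = _as_array(X_new)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.W.shape[0]:
        raise O2PLSError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.W.shape[0]}"
        )
    Xs = (X_new - model.x_center) / model.x_scale
    for a in range(model.W_orth_x.shape[1]):
        t_o = Xs @ model.W_orth_x[:, a]
        Xs = Xs - np.outer(t_o, model.P_orth_x[:, a])
    Ys = Xs @ model.W @ model.B @ model.C.T
    return Ys * model.y_scale + model.y_center


def _interleaved_folds(n: int, folds: int) -> np.ndarray:
    return np.arange(n) % folds


def cross_validate(X, Y, n_components: int, nx: int = 0, ny: int = 0,
                   folds: int = 7, scale: str = "uv",
                   limit: float = 0.05) -> CVResult:
    """Q2 by deterministic interleaved k-fold cross-validation.

    Sample i joins fold ``i mod folds`` in the given row order (the
    pipeline orders rows by batch then day, so folds interleave the time
    series).  Q2(cum) = 1 - PRESS/SS with SS the total centered sum of
    squares of Y; the per-component Q2 of component a is
    Q2(1..a) - Q2(1..a-1), evaluated on nested sub-models sharing the
    fold fits.
    """
    X = _as_array(X)
    Y = _as_array(Y)
    n = X.shape[0]
    if folds < 2:
        raise O2PLSError("folds must be >= 2")
    if folds > n:
        raise O2PLSError(f"folds={folds} exceeds n={n}")
    K = int(n_components)
    assign = _interleaved_folds(n, folds)
    press = np.zeros(K)
    for f in range(folds):
        test = assign == f
        train = ~test
        if train.sum() < max(3, K + max(nx, ny) + 1):
            raise O2PLSError(f"training split too small in fold {f}")
        m = fit_o2pls(X[train], Y[train], K, nx=nx, ny=ny, scale=scale)
        Xs = (X[test] - m.x_center) / m.x_scale
        for a in range(m.W_orth_x.shape[1]):
            t_o = Xs @ m.W_orth_x[:, a]
            Xs = Xs - np.outer(t_o, m.P_orth_x[:, a])
        for a in range(1, K + 1):
            Ta = m.T[:, :a]
            Ba = np.linalg.solve(Ta.T @ Ta, Ta.T @ m.U[:, :a])
            Ys = Xs @ m.W[:, :a] @ Ba @ m.C[:, :a].T
            pred = Ys * m.y_scale + m.y_center
            press[a - 1] += ((Y[test] - pred) ** 2).sum()
    ss = ((Y - Y.mean(axis=0)) ** 2).sum()
    q2_cum = 1.0 - press / ss
    q2_inc = np.diff(np.concatenate([[0.0], q2_cum]))
    return CVResult(folds=folds, q2_per_component=q2_inc,
                    q2_cum=float(q2_cum[-1]), limit=limit)


def select_components(X, Y, max_components: int = 5, max_orth: int = 3,
                      folds: int = 7, scale: str = "uv",
                      limit: float = 0.05) -> tuple[int, int, int]:
    """Greedy forward selection of (K, nx, ny) by cross-validated Q2.

    K grows while the incremental per-component Q2 exceeds ``limit``;
    then nx and ny grow while Q2(cum) improves by more than ``limit``.
    If even the first joint component fails the limit, K = 1 is returned
    with a warning.
    """
    if max_components < 1:
        raise O2PLSError("max_components must be >= 1")
    K = 1
    base = cross_validate(X, Y, 1, folds=folds, scale=scale, limit=limit)
    if base.q2_per_component[0] <= limit:
        warnings.warn(
            "first joint component fails the cross-validation limit; "
            "returning K=1", stacklevel=2,
        )
        best_q2 = base.q2_cum
    else:
        best_q2 = base.q2_cum
        while K < max_components:
            res = cross_validate(X, Y, K + 1, folds=folds, scale=scale, limit=limit)
            if res.q2_per_component[K] > limit:
                K += 1
                best_q2 = res.q2_cum
            else:
                break
    nx = 0
    while nx < max_orth:
        try:
            res = cross_validate(X, Y, K, nx=nx + 1, folds=folds,
                                 scale=scale, limit=limit)
        except O2PLSError:
            break
        if res.q2_cum > best_q2 + limit:
            nx += 1
            best_q2 = res.q2_cum
        else:
            break
    ny = 0
    while ny < max_orth:
        try:
            res = cross_validate(X, Y, K, nx=nx, ny=ny + 1, folds=folds,
                                 scale=scale, limit=limit)
        except O2PLSError:
            break
        if res.q2_cum > best_q2 + limit:
            ny += 1
            best_q2 = res.q2_cum
        else:
            break
    return K, nx, ny
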