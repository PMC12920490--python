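"""Compiled PLS1 kernels.

Hot loops of the nested leave-one-out machinery (one PLS1 decomposition per
inner fold, thousands per model, hundreds of thousands under permutation) are
JIT-compiled with numba.  All kernels use plain loops so no BLAS layout
assumptions are involved; the algebra is identical to the reference NIPALS
formulation in :mod:`interobattery.plsr`.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def pls1_path(Xs, yc, k_max):  # pragma: no cover - exercised via plsr tests
    """NIPALS PLS1 on standardised X / centred y; returns (W, P, q, k_eff)."""
    n, p = Xs.shape
    Xd = Xs.copy()
    W = np.zeros((p, k_max))
    P = np.zeros((p, k_max))
    q = np.zeros(k_max)
    ynorm = np.sqrt(np.sum(yc * yc))
    xnorm = np.sqrt(np.sum(Xs * Xs))
    tol = 1e-12 * (ynorm * xnorm + 1e-300)
    k_eff = 0
    for k in range(k_max):
        w = np.zeros(p)
        for i in range(n):
            yi = yc[i]
            for j in range(p):
                w[j] += Xd[i, j] * yi
        nw = np.sqrt(np.sum(w * w))
        if nw <= tol:
            break
        for j in range(p):
            w[j] /= nw
        t = np.zeros(n)
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += Xd[i, j] * w[j]
            t[i] = s
        tt = np.sum(t * t)
        if tt <= 1e-30:
            break
        pk = np.zeros(p)
        qk = 0.0
        for i in range(n):
            ti = t[i]
            qk += yc[i] * ti
            for j in range(p):
                pk[j] += Xd[i, j] * ti
        for j in range(p):
            pk[j] /= tt
        qk /= tt
        for i in range(n):
            ti = t[i]
            for j in range(p):
                Xd[i, j] -= ti * pk[j]
        for j in range(p):
            W[j, k] = w[j]
            P[j, k] = pk[j]
        q[k] = qk
        k_eff += 1
    return W, P, q, k_eff


@nb.njit(cache=True)
def coef_path(W, P, q, k_eff):  # pragma: no cover
    """Standardised coefficients for K = 1..k_eff (columns of B).

    B_K = W_K (P_K^T W_K)^{-1} q_K; R = P^T W is unit upper triangular for
    PLS1, so each solve is a back-substitution.
    """
    p = W.shape[0]
    B = np.zeros((p, k_eff))
    if k_eff == 0:
        return B
    R = np.zeros((k_eff, k_eff))
    for a in range(k_eff):
        for b in range(k_eff):
            s = 0.0
            for j in range(p):
                s += P[j, a] * W[j, b]
            R[a, b] = s
    for K in range(1, k_eff + 1):
        z = np.zeros(K)
        for i in range(K - 1, -1, -1):
            s = q[i]
            for j in range(i + 1, K):
                s -= R[i, j] * z[j]
            z[i] = s / R[i, i]
        for j in range(p):
            acc = 0.0
            for a in range(K):
                acc += W[j, a] * z[a]
            B[j, K - 1] = acc
    return B


@nb.njit(cache=True)
def _fit_predict_row(Xtr, ytr, xrow, k):  # pragma: no cover
    """Standardise on Xtr/ytr, fit PLS1 at (up to) k components, predict xrow.

    Returns (prediction, ok); ok=False when a training column is constant.
    """
    m, p = Xtr.shape
    mu = np.zeros(p)
    sd = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(m):
            s += Xtr[i, j]
        mu[j] = s / m
    for j in range(p):
        s = 0.0
        for i in range(m):
            d = Xtr[i, j] - mu[j]
            s += d * d
        v = s / m
        if v <= 0.0:
            return 0.0, False
        sd[j] = np.sqrt(v)
    ym = np.mean(ytr)
    Xs = np.empty((m, p))
    for i in range(m):
        for j in range(p):
            Xs[i, j] = (Xtr[i, j] - mu[j]) / sd[j]
    yc = ytr - ym
    W, P, q, k_eff = pls1_path(Xs, yc, k)
    if k_eff == 0:
        return ym, True
    B = coef_path(W, P, q, k_eff)
    pred = ym
    for j in range(p):
        pred += (xrow[j] - mu[j]) / sd[j] * B[j, k_eff - 1]
    return pred, True


@nb.njit(cache=True)
def inner_select_k(Xtr, ytr, k_max):  # pragma: no cover
    """Inner LOO over the training rows; returns the K with smallest MSE
    (first/smallest K on ties), or -1 when every inner fold is degenerate."""
    m, p = Xtr.shape
    sse = np.zeros(k_max)
    n_ok = 0
    Xj = np.empty((m - 1, p))
    yj = np.empty(m - 1)
    for j in range(m):
        idx = 0
        for i in range(m):
            if i != j:
                for c in range(p):
                    Xj[idx, c] = Xtr[i, c]
                yj[idx] = ytr[i]
                idx += 1
        # standardise on the m-1 rows
        mu = np.zeros(p)
        sd = np.zeros(p)
        degenerate = False
        for c in range(p):
            s = 0.0
            for i in range(m - 1):
                s += Xj[i, c]
            mu[c] = s / (m - 1)
        for c in range(p):
            s = 0.0
            for i in range(m - 1):
                d = Xj[i, c] - mu[c]
                s += d * d
            v = s / (m - 1)
            if v <= 0.0:
                degenerate = True
                break
            sd[c] = np.sqrt(v)
        if degenerate:
            continue
        ym = np.mean(yj)
        Xs = np.empty((m - 1, p))
        for i in range(m - 1):
            for c in range(p):
                Xs[i, c] = (Xj[i, c] - mu[c]) / sd[c]
        W, P, q, k_eff = pls1_path(Xs, yj - ym, k_max)
        if k_eff == 0:
            continue
        B = coef_path(W, P, q, k_eff)
        last = 0.0
        for K in range(k_max):
            if K < k_eff:
                pred = ym
                for c in range(p):
                    pred += (Xtr[j, c] - mu[c]) / sd[c] * B[c, K]
                e = (pred - ytr[j]) ** 2
                last = e
            else:
                e = last  # K beyond the effective rank predicts like K=k_eff
            sse[K] += e
        n_ok += 1
    if n_ok == 0:
        return -1
    best = 0
    for K in range(1, k_max):
        if sse[K] < sse[best]:
            best = K
    return best + 1


@nb.njit(cache=True)
def nested_loo(X, y, k_max):  # pragma: no cover
    """Outer LOO with inner-LOO K selection; returns (predictions, chosen_k)."""
    n, p = X.shape
    preds = np.empty(n)
    chosen = np.empty(n, dtype=np.int64)
    Xtr = np.empty((n - 1, p))
    ytr = np.empty(n - 1)
    for i in range(n):
        idx = 0
        for r in range(n):
            if r != i:
                for c in range(p):
                    Xtr[idx, c] = X[r, c]
                ytr[idx] = y[r]
                idx += 1
        k_i = inner_select_k(Xtr, ytr, k_max)
        if k_i < 1:
            k_i = 1
        pred, ok = _fit_predict_row(Xtr, ytr, X[i], k_i)
        preds[i] = pred if ok else np.mean(ytr)
        chosen[i] = k_i
    return preds, chosen


@nb.njit(cache=True)
def loo_predictions_fixed_k(X, y, chosen_k):  # pragma: no cover
    """Outer-LOO predictions with the per-fold K held fixed."""
    n, p = X.shape
    preds = np.empty(n)
    Xtr = np.empty((n - 1, p))
    ytr = np.empty(n - 1)
    for i in range(n):
        idx = 0
        for r in range(n):
            if r != i:
                for c in range(p):
                    Xtr[idx, c] = X[r, c]
                ytr[idx] = y[r]
                idx += 1
        pred, ok = _fit_predict_row(Xtr, ytr, X[i], int(chosen_k[i]))
        preds[i] = pred if ok else np.mean(ytr)
    return preds


@nb.njit(cache=True)
def full_weights(Xs, yc, k):  # pragma: no cover
    """Coefficient vector of a fit at K=k on pre-standardised X, centred y."""
    W, P, q, k_eff = pls1_path(Xs, yc, k)
    if k_eff == 0:
        return np.zeros(Xs.shape[1])
    B = coef_path(W, P, q, k_eff)
    return B[:, k_eff - 1].copy()
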