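"""Partial least squares regression (PLS1) with nested leave-one-out
cross-validation and permutation inference.

The engine fits a single-outcome PLSR by NIPALS with a cumulative coefficient
path: one decomposition at ``k_max`` yields the regression coefficients for
every K = 1..k_max, which makes the inner leave-one-out component search cheap
enough to nest inside an outer leave-one-out loop and to rerun hundreds of
times under permutation.

Conventions
-----------
* Predictor columns are z-scored and the outcome centred inside every training
  fold; the held-out row never contributes to standardisation, component
  selection, or fitting.
* Inner ties in mean squared prediction error break toward the smallest K
  (parsimony).
* The model-level test statistic is the Pearson correlation r between the
  outcome and its out-of-sample predictions; its permutation p-value uses the
  add-one convention p = (1 + #{r_null >= r_obs}) / (1 + n_perm).
* Reported weights are the standardised regression coefficients of a
  refit on all rows at the modal outer K; a weight is flagged significant when
  it falls outside the [2.5%, 97.5%] quantiles of its permutation null.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from . import _engine

__all__ = [
    "PlsrFit",
    "PlsrCvResult",
    "plsr_fit",
    "plsr_predict",
    "nested_loo_cv",
    "permutation_inference",
    "final_weights",
]


# --------------------------------------------------------------------------- #
# Core PLS1 decomposition
# --------------------------------------------------------------------------- #

def _check_columns(X: np.ndarray, names=None) -> None:
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ValueError(f"constant predictor column: {label}")


def _pls1_path(Xs: np.ndarray, yc: np.ndarray, k_max: int):
    """NIPALS PLS1 on standardised X / centred y.

    Returns ``(W, P, q)`` truncated to the effective number of components
    (deflation can exhaust the covariance early on degenerate data).
    """
    n, p = Xs.shape
    Xd = Xs.copy()
    W = np.empty((p, k_max))
    P = np.empty((p, k_max))
    q = np.empty(k_max)
    scale = max(float(np.abs(Xs).max()), 1.0) * max(float(np.abs(yc).max()), 1.0)
    k_eff = 0
    for k in range(k_max):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale * n:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-12:
            break
        pk = (Xd.T @ t) / tt
        q[k] = float(yc @ t) / tt
        Xd -= t[:, None] * pk[None, :]
        W[:, k] = w
        P[:, k] = pk
        k_eff += 1
    return W[:, :k_eff], P[:, :k_eff], q[:k_eff]


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Standardised coefficient vectors for K = 1..k_eff, as columns.

    Uses B_K = W_K (P_K^T W_K)^{-1} q_K; P^T W is unit upper triangular for
    PLS1, so each solve is a cheap back-substitution.
    """
    k = q.size
    B = np.empty((W.shape[0], k))
    if k == 0:
        return B
    R = P.T @ W
    for K in range(1, k + 1):
        z = solve_triangular(R[:K, :K], q[:K], lower=False)
        B[:, K - 1] = W[:, :K] @ z
    return B


# --------------------------------------------------------------------------- #
# Public fit object
# --------------------------------------------------------------------------- #

@dataclass
class PlsrFit:
    n_components: int
    weights: np.ndarray  # standardised regression coefficients, one per predictor
    x_weights: np.ndarray  # W (p x K)
    x_loadings: np.ndarray  # P (p x K)
    y_loadings: np.ndarray  # q (K,)
    x_scores: np.ndarray  # T (n x K)
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    predictor_names: list | None = None


@dataclass
class PlsrCvResult:
    predictions: np.ndarray  # out-of-sample prediction per subject
    chosen_k: np.ndarray  # K selected by the inner loop, per outer fold
    modal_k: int
    r: float  # Pearson r(actual, out-of-sample predicted)
    weights: np.ndarray | None = None  # full-data refit at modal K
    p_perm: float = float("nan")
    null_lo: np.ndarray | None = None  # per-weight 2.5% null quantile
    null_hi: np.ndarray | None = None  # per-weight 97.5% null quantile
    significant: np.ndarray | None = None
    r_null: np.ndarray | None = None
    predictor_names: list | None = None

    def significant_predictors(self) -> list:
        if self.significant is None:
            return []
        names = self.predictor_names or list(range(len(self.significant)))
        return [n for n, s in zip(names, self.significant) if s]


def plsr_fit(X: np.ndarray, y: np.ndarray, k: int, predictor_names=None) -> PlsrFit:
    """Fit PLS1 with *k* components on all rows.

    X columns are z-scored and y centred internally; the stored parameters
    make predictions reproducible on new raw rows via :func:`plsr_predict`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_columns(X, predictor_names)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    rank = np.linalg.matrix_rank(Xs)
    if k > rank:
        raise ValueError(f"k={k} exceeds predictor rank {rank}")
    ym = float(y.mean())
    W, P, q = _pls1_path(Xs, y - ym, k)
    if q.size < k:
        raise ValueError(f"decomposition exhausted after {q.size} components (asked {k})")
    B = _coef_path(W, P, q)
    T = _scores(Xs, W, P)  # deflation-sequence scores, mutually orthogonal
    return PlsrFit(
        n_components=k,
        weights=B[:, -1],
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        x_mean=mu,
        x_std=sd,
        y_mean=ym,
        predictor_names=list(predictor_names) if predictor_names is not None else None,
    )


def _scores(Xs: np.ndarray, W: np.ndarray, P: np.ndarray) -> np.ndarray:
    Xd = Xs.copy()
    T = np.empty((Xs.shape[0], W.shape[1]))
    for k in range(W.shape[1]):
        t = Xd @ W[:, k]
        T[:, k] = t
        Xd -= t[:, None] * P[:, k][None, :]
    return T


def plsr_predict(fit: PlsrFit, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    return fit.y_mean + ((X_new - fit.x_mean) / fit.x_std) @ fit.weights


def final_weights(X: np.ndarray, y: np.ndarray, k: int, predictor_names=None) -> np.ndarray:
    """Standardised coefficients of a refit on all rows at K=*k*."""
    return plsr_fit(X, y, k, predictor_names).weights


# --------------------------------------------------------------------------- #
# Nested leave-one-out cross-validation
# --------------------------------------------------------------------------- #

def nested_loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    k_max: int = 10,
    predictor_names=None,
) -> PlsrCvResult:
    """Outer LOO predictions with per-fold inner-LOO component selection.

    The left-out row takes no part in standardisation, K selection, or
    fitting.  Returns out-of-sample predictions, the per-fold K, and the
    Pearson correlation r between actual and predicted values.  Inner ties in
    mean squared error break toward the smallest K; inner folds with a
    degenerate (constant) column are skipped.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("nested LOO CV requires n >= 10")
    if p < 2:
        raise ValueError("need at least 2 predictor variables")
    k_max = int(min(k_max, n - 2, p))
    _check_columns(X, predictor_names)

    preds, chosen = _engine.nested_loo(X, y, k_max)
    r = _pearson(y, preds)
    return PlsrCvResult(
        predictions=preds,
        chosen_k=chosen,
        modal_k=_modal_k(chosen),
        r=r,
        predictor_names=list(predictor_names) if predictor_names is not None else None,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _modal_k(chosen: np.ndarray) -> int:
    counts = Counter(chosen.tolist())
    top = max(counts.values())
    modes = sorted(k for k, c in counts.items() if c == top)
    if top == 1:  # no modal K: fall back to the smallest median K
        return int(np.floor(np.median(chosen)))
    return int(modes[0])


def _loo_r_fixed_k(X: np.ndarray, y: np.ndarray, chosen_k: np.ndarray) -> float:
    """Outer-LOO r with the per-fold K held fixed (permutation-null workhorse)."""
    preds = _engine.loo_predictions_fixed_k(X, y, chosen_k)
    return _pearson(y, preds)


def _full_weights_fast(Xs: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Weights of the full-data refit on pre-standardised X (null refits)."""
    return _engine.full_weights(Xs, y - y.mean(), k)


# --------------------------------------------------------------------------- #
# Permutation inference
# --------------------------------------------------------------------------- #

def permutation_inference(
    X: np.ndarray,
    y: np.ndarray,
    k_max: int = 10,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
    predictor_names=None,
    reselect_k: bool = False,
) -> PlsrCvResult:
    """Nested-CV fit plus permutation p-value for r and per-weight null CIs.

    For each of ``n_perm`` row permutations of y the out-of-sample r is
    recomputed with the observed per-fold K held fixed (set ``reselect_k=True``
    to rerun the full inner selection per permutation), and the full-data
    weights are refit at the observed modal K.  A weight is significant when it
    falls outside its null [alpha/2, 1-alpha/2] quantiles.
    """
    if n_perm < 200:
        raise ValueError("n_perm must be >= 200 for stable 95% null quantiles")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    base = nested_loo_cv(X, y, k_max, predictor_names)
    obs_w = final_weights(X, y, base.modal_k, predictor_names)

    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = np.ascontiguousarray((X - mu) / sd)
    rng = np.random.default_rng(seed)
    r_null = np.empty(n_perm)
    w_null = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        yp = rng.permutation(y)
        if reselect_k:
            r_null[b] = nested_loo_cv(X, yp, k_max).r
        else:
            r_null[b] = _loo_r_fixed_k(X, yp, base.chosen_k)
        w_null[b] = _full_weights_fast(Xs, yp, base.modal_k)

    p_perm = (1 + int(np.sum(r_null >= base.r))) / (1 + n_perm)
    lo = np.quantile(w_null, alpha / 2, axis=0)
    hi = np.quantile(w_null, 1 - alpha / 2, axis=0)
    sig = (obs_w < lo) | (obs_w > hi)
    return PlsrCvResult(
        predictions=base.predictions,
        chosen_k=base.chosen_k,
        modal_k=base.modal_k,
        r=base.r,
        weights=obs_w,
        p_perm=p_perm,
        null_lo=lo,
        null_hi=hi,
        significant=sig,
        r_null=r_null,
        predictor_names=base.predictor_names,
    )
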