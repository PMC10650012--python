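"""Vectorized/JIT evaluation backend for large feature-subset searches.

The exhaustive search evaluates ~3000 feature subsets x 5 classifiers x
5 folds for every subject-day-side cell; per-fit overhead of generic
estimator objects dominates at that scale.  This module re-implements the
five classifiers with the same mathematical definitions on small dense
problems:

* LDA / QDA: closed-form Gaussian discriminants, batched over subsets
  (covariance sub-matrices are sliced from one full-catalog covariance).
* 1-NN: per-dimension squared-difference tensors shared across subsets.
* SVC (RBF, C=1): SMO on precomputed kernels, JIT-compiled.
* Random forest: JIT-compiled CART with bootstrap + random feature
  sub-sampling (Gini for classification, variance for regression).

Fold assignment and training-fold z-scoring are identical to the sklearn
backend (:mod:`sipemg.evaluation`); agreement between the two backends is
covered by tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

_SMO_TOL = 1e-3
_SMO_MAX_ITER = 20000


# ---------------------------------------------------------------- SMO SVC

@njit(cache=True)
def _smo_fit(K, y, C):
    """SMO for C-SVC on a precomputed kernel; returns (alpha, b)."""
    n = K.shape[0]
    alpha = np.zeros(n)
    u = np.zeros(n)  # decision values without intercept
    m_val = 0.0
    M_val = 0.0
    for _ in range(_SMO_MAX_ITER):
        m_val = -1e300
        M_val = 1e300
        i = -1
        j = -1
        for t in range(n):
            g = y[t] - u[t]
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                if g > m_val:
                    m_val = g
                    i = t
            if (y[t] < 0 and alpha[t] < C) or (y[t] > 0 and alpha[t] > 0):
                if g < M_val:
                    M_val = g
                    j = t
        if i < 0 or j < 0 or m_val - M_val < _SMO_TOL:
            break
        Ei = u[i] - y[i]
        Ej = u[j] - y[j]
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta < 1e-12:
            eta = 1e-12
        aj = alpha[j] + y[j] * (Ei - Ej) / eta
        if y[i] == y[j]:
            L = max(0.0, alpha[i] + alpha[j] - C)
            H = min(C, alpha[i] + alpha[j])
        else:
            L = max(0.0, alpha[j] - alpha[i])
            H = min(C, C + alpha[j] - alpha[i])
        if aj < L:
            aj = L
        elif aj > H:
            aj = H
        dj = aj - alpha[j]
        if abs(dj) < 1e-14:
            break
        ai = alpha[i] + y[i] * y[j] * (alpha[j] - aj)
        di = ai - alpha[i]
        for t in range(n):
            u[t] += di * y[i] * K[t, i] + dj * y[j] * K[t, j]
        alpha[i] = ai
        alpha[j] = aj
    # intercept: mean over free SVs, midpoint fallback
    b_sum = 0.0
    n_free = 0
    for t in range(n):
        if 1e-12 < alpha[t] < C - 1e-12:
            b_sum += y[t] - u[t]
            n_free += 1
    b = b_sum / n_free if n_free > 0 else 0.5 * (m_val + M_val)
    return alpha, b


@njit(cache=True)
def _svc_subset_preds(Dtr, Dte, S, y_pm, C, gammas):
    """Predictions for every subset; D* are (n, n_tr, p) per-dim sq diffs."""
    m, k = S.shape
    n_tr = Dtr.shape[0]
    n_te = Dte.shape[0]
    preds = np.zeros((m, n_te), dtype=np.bool_)
    Ktr = np.zeros((n_tr, n_tr))
    Kte = np.zeros((n_te, n_tr))
    for s in range(m):
        g = gammas[s]
        for a in range(n_tr):
            for bq in range(n_tr):
                d2 = 0.0
                for q in range(k):
                    d2 += Dtr[a, bq, S[s, q]]
                Ktr[a, bq] = np.exp(-g * d2)
        alpha, b = _smo_fit(Ktr, y_pm, C)
        for a in range(n_te):
            acc = b
            for bq in range(n_tr):
                if alpha[bq] > 0.0:
                    d2 = 0.0
                    for q in range(k):
                        d2 += Dte[a, bq, S[s, q]]
                    acc += alpha[bq] * y_pm[bq] * np.exp(-g * d2)
            preds[s, a] = acc > 0.0
    return preds


# ------------------------------------------------------------ random forest

@njit(cache=True)
def _build_tree(Xb, yb, classification, max_features,
                feat, thr, left, right, value):
    """CART on a bootstrap sample; arrays are preallocated outputs."""
    n, k = Xb.shape
    idx = np.arange(n)
    # stack of (node, start, end)
    stack = np.zeros((2 * n + 2, 3), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        cnt = end - start
        s_sum = 0.0
        for t in range(start, end):
            s_sum += yb[idx[t]]
        mean = s_sum / cnt
        value[node] = mean
        if cnt < 2 or (classification and (mean <= 0.0 or mean >= 1.0)):
            feat[node] = -1
            continue
        # random feature order; try max_features, extend if no valid split
        order = np.arange(k)
        for a in range(k - 1, 0, -1):
            bq = np.random.randint(0, a + 1)
            tmp = order[a]
            order[a] = order[bq]
            order[bq] = tmp
        best_gain = -1.0
        best_f = -1
        best_t = 0.0
        tried = 0
        for fi in range(k):
            f = order[fi]
            if tried >= max_features and best_f >= 0:
                break
            tried += 1
            vals = np.empty(cnt)
            for t in range(cnt):
                vals[t] = Xb[idx[start + t], f]
            srt = np.argsort(vals)
            nl = 0
            sl = 0.0
            for q in range(cnt - 1):
                pos = srt[q]
                nl += 1
                sl += yb[idx[start + pos]]
                if vals[srt[q + 1]] <= vals[pos]:
                    continue
                nr = cnt - nl
                sr = s_sum - sl
                # classification: Gini proxy; regression: SSE proxy
                if classification:
                    gain = (sl * sl + (nl - sl) * (nl - sl)) / nl \
                        + (sr * sr + (nr - sr) * (nr - sr)) / nr
                else:
                    gain = sl * sl / nl + sr * sr / nr
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_t = 0.5 * (vals[pos] + vals[srt[q + 1]])
        if best_f < 0:
            feat[node] = -1
            continue
        # partition idx[start:end] by the split
        buf = np.empty(cnt, dtype=np.int64)
        nl = 0
        nr = 0
        for t in range(start, end):
            if Xb[idx[t], best_f] <= best_t:
                buf[nl] = idx[t]
                nl += 1
        for t in range(start, end):
            if Xb[idx[t], best_f] > best_t:
                buf[nl + nr] = idx[t]
                nr += 1
        for t in range(cnt):
            idx[start + t] = buf[t]
        feat[node] = best_f
        thr[node] = best_t
        left[node] = n_nodes
        right[node] = n_nodes + 1
        stack[top, 0] = n_nodes
        stack[top, 1] = start
        stack[top, 2] = start + nl
        top += 1
        stack[top, 0] = n_nodes + 1
        stack[top, 1] = start + nl
        stack[top, 2] = end
        top += 1
        n_nodes += 2
    return n_nodes


@njit(cache=True)
def _forest_predict(Xtr, ytr, Xte, n_trees, max_features, classification,
                    seed):
    """Bootstrap forest; returns mean leaf value per test point."""
    n, k = Xtr.shape
    n_te = Xte.shape[0]
    np.random.seed(seed)
    out = np.zeros(n_te)
    max_nodes = 2 * n + 2
    feat = np.empty(max_nodes, dtype=np.int64)
    thr = np.empty(max_nodes)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    value = np.empty(max_nodes)
    Xb = np.empty((n, k))
    yb = np.empty(n)
    for _ in range(n_trees):
        for t in range(n):
            bidx = np.random.randint(0, n)
            for q in range(k):
                Xb[t, q] = Xtr[bidx, q]
            yb[t] = ytr[bidx]
        _build_tree(Xb, yb, classification, max_features,
                    feat, thr, left, right, value)
        for t in range(n_te):
            node = 0
            while feat[node] >= 0:
                if Xte[t, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            out[t] += value[node]
    return out / n_trees


@njit(cache=True)
def _rf_subset_preds(Xtr, ytr, Xte, S, n_trees, seed):
    m, k = S.shape
    n_te = Xte.shape[0]
    preds = np.zeros((m, n_te), dtype=np.bool_)
    mf = max(1, int(np.sqrt(k)))
    for s in range(m):
        Xtr_s = Xtr[:, S[s]].copy()
        Xte_s = Xte[:, S[s]].copy()
        proba = _forest_predict(Xtr_s, ytr, Xte_s, n_trees, mf, True, seed)
        for t in range(n_te):
            preds[s, t] = proba[t] > 0.5
    return preds


# --------------------------------------------------------- batched LDA/QDA

def _class_stats(Xtr: np.ndarray, ytr: np.ndarray):
    n = len(ytr)
    stats = {}
    for c in (0, 1):
        Xc = Xtr[ytr == c]
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        stats[c] = (len(Xc) / n, mu, dev.T @ dev, len(Xc))
    return stats


def _lda_preds(Xtr, ytr, Xte, S):
    stats = _class_stats(Xtr, ytr)
    pi0, mu0, sc0, n0 = stats[0]
    pi1, mu1, sc1, n1 = stats[1]
    # weighted average of per-class ML covariances
    cov = pi0 * (sc0 / n0) + pi1 * (sc1 / n1)
    m, k = S.shape
    cov_s = cov[S[:, :, None], S[:, None, :]]
    cov_s = cov_s + 1e-9 * np.eye(k)[None]
    d = (mu1 - mu0)[S]
    w = np.linalg.solve(cov_s, d[..., None])[..., 0]       # (m, k)
    mid = 0.5 * (mu0 + mu1)[S]
    b = -np.einsum("mk,mk->m", mid, w) + np.log(pi1 / pi0)
    scores = np.einsum("tmk,mk->mt", Xte[:, S], w) + b[:, None]
    return scores > 0.0


def _qda_preds(Xtr, ytr, Xte, S, reg=1e-3):
    # reg mirrors sklearn QDA reg_param: (1-r) Sigma + r I per class
    stats = _class_stats(Xtr, ytr)
    m, k = S.shape
    disc = []
    for c in (0, 1):
        pi, mu, sc, nc = stats[c]
        cov = sc / max(nc - 1, 1)
        cov_s = ((1.0 - reg) * cov[S[:, :, None], S[:, None, :]]
                 + reg * np.eye(k)[None])
        inv = np.linalg.inv(cov_s)
        _, logdet = np.linalg.slogdet(cov_s)
        diff = Xte[:, S] - mu[S][None]                      # (te, m, k)
        quad = np.einsum("tmk,mkl,tml->tm", diff, inv, diff)
        disc.append(-0.5 * logdet[None, :] - 0.5 * quad + np.log(pi))
    return (disc[1] > disc[0]).T


def _knn_preds(Dte, ytr, S):
    te, tr, p = Dte.shape
    m, k = S.shape
    onehot = np.zeros((p, m))
    for s in range(m):
        onehot[S[s], s] = 1.0
    dist = Dte.reshape(te * tr, p) @ onehot
    nearest = dist.reshape(te, tr, m).argmin(axis=1)        # (te, m)
    return ytr[nearest].T.astype(bool)


def _f1_batch(preds: np.ndarray, yte: np.ndarray) -> np.ndarray:
    """F1 of the positive class per subset; 0 when undefined."""
    pos = yte.astype(bool)[None, :]
    tp = (preds & pos).sum(axis=1).astype(float)
    fp = (preds & ~pos).sum(axis=1)
    fn = (~preds & pos).sum(axis=1)
    denom = 2 * tp + fp + fn
    return np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)


# --------------------------------------------------------------- front end

def evaluate_subsets(sub_fm: pd.DataFrame,
                     subset_list: Sequence[tuple[str, ...]], model: str,
                     protocol, rf_trees: int = 25) -> np.ndarray:
    """Mean cross-fold F-score for every subset on one cell's rows."""
    from .evaluation import classification_folds

    if protocol.task != "classify":
        raise ValueError("fast engine handles classification only")
    names = sorted({n for s in subset_list for n in s})
    ks = {len(s) for s in subset_list}
    if len(ks) != 1:
        raise ValueError("subsets passed together must share one size")
    col = {n: i for i, n in enumerate(names)}
    S = np.array([[col[n] for n in s] for s in subset_list], dtype=np.int64)
    X = sub_fm[names].to_numpy(dtype=float)
    y = (sub_fm["label"].to_numpy() == protocol.positive_class).astype(int)
    folds = classification_folds(y, protocol)
    acc = np.zeros(len(subset_list))
    for tr, te in folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        preds = _fold_preds(Xtr, y[tr], Xte, S, model, protocol.seed, rf_trees)
        acc += _f1_batch(preds, y[te])
    return acc / len(folds)


def _fold_preds(Xtr, ytr, Xte, S, model, seed, rf_trees):
    if model == "LDA":
        return _lda_preds(Xtr, ytr, Xte, S)
    if model == "QDA":
        return _qda_preds(Xtr, ytr, Xte, S)
    if model == "KNN1":
        Dte = (Xte[:, None, :] - Xtr[None, :, :])**2
        return _knn_preds(Dte, ytr, S)
    if model == "SVC":
        Dtr = (Xtr[:, None, :] - Xtr[None, :, :])**2
        Dte = (Xte[:, None, :] - Xtr[None, :, :])**2
        k = S.shape[1]
        # sklearn gamma='scale': 1 / (k * flattened-variance of the slice)
        col_mean = Xtr.mean(axis=0)
        col_sq = (Xtr**2).mean(axis=0)
        e2 = col_sq[S].mean(axis=1)
        e1 = col_mean[S].mean(axis=1)
        var = np.maximum(e2 - e1**2, 1e-12)
        gammas = 1.0 / (k * var)
        y_pm = np.where(ytr > 0, 1.0, -1.0)
        return _svc_subset_preds(Dtr, Dte, S, y_pm, 1.0, gammas)
    if model == "RF":
        return _rf_subset_preds(Xtr, ytr.astype(np.float64), Xte, S,
                                rf_trees, seed)
    raise ValueError(f"unknown classifier {model!r}")


def fast_rf_regression_scores(sub_fm: pd.DataFrame,
                              subset_list: Sequence[tuple[str, ...]],
                              protocol, n_trees: int = 100) -> np.ndarray:
    """Mean cross-fold RMSE (mL) per subset for the JIT random forest.

    Same folds and scaling as :func:`sipemg.evaluation.cv_regress`; used
    where the generic estimator is too slow for a full search.
    """
    from .evaluation import regression_folds

    drink = sub_fm[sub_fm["label"] == protocol.positive_class] \
        if "label" in sub_fm.columns else sub_fm
    names = sorted({n for s in subset_list for n in s})
    col = {n: i for i, n in enumerate(names)}
    X = drink[names].to_numpy(dtype=float)
    y = drink["volume_ml"].to_numpy(dtype=float)
    folds = regression_folds(len(y), protocol)
    acc = np.zeros(len(subset_list))
    for tr, te in folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        for s, subset in enumerate(subset_list):
            cols = np.array([col[n] for n in subset], dtype=np.int64)
            pred = _forest_predict(np.ascontiguousarray(Xtr[:, cols]), y[tr],
                                   np.ascontiguousarray(Xte[:, cols]),
                                   n_trees, len(cols), False, protocol.seed)
            acc[s] += np.sqrt(np.mean((pred - y[te])**2))
    return acc / len(folds)
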