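"""Numba kernels: linear epsilon-SVR (SMO on the dual) and the
leave-one-out / feature-fraction / permutation grids built on it.

The dual in the single-coefficient form (beta_i = alpha_i - alpha_i*):

    maximize  y'beta - 0.5 beta'K beta - eps ||beta||_1
    subject to sum(beta) = 0,  -C <= beta_i <= C

solved by pairwise coordinate ascent: for a pair (i, j) the update
beta_i += d, beta_j -= d preserves the equality constraint; the optimal d
on each linear segment of the L1 term has a closed form and the best
candidate is taken.  The bias is recovered from the KKT interval.  These
kernels exist because the permutation-based family-wise-error analysis
needs on the order of 10^5-10^6 SVR fits on one CPU; correctness is pinned
to libsvm (sklearn.svm.SVR) in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def svr_dual_solve(k_mat, y, c_reg, eps, beta, tol, max_iter):  # pragma: no cover
    """SMO with maximal-violating-pair selection on the epsilon-SVR dual.
    ``beta`` is modified in place (pass zeros or a warm start); returns
    the bias term.  ``max_iter`` scales the pair-update budget."""
    n = y.shape[0]
    # gradient cache: G_i = y_i - (K beta)_i
    g = y - k_mat @ beta
    for _ in range(max_iter * n):
        # directional derivatives of the dual at the current point:
        # up_i for increasing beta_i, down_j for decreasing beta_j
        i_best = -1
        j_best = -1
        up_max = -1e300
        down_min = 1e300
        for t in range(n):
            bt = beta[t]
            if bt < c_reg:
                up = g[t] - eps if bt >= 0.0 else g[t] + eps
                if up > up_max:
                    up_max = up
                    i_best = t
            if bt > -c_reg:
                down = g[t] - eps if bt > 0.0 else g[t] + eps
                if down < down_min:
                    down_min = down
                    j_best = t
        if i_best < 0 or j_best < 0 or i_best == j_best:
            break
        if up_max - down_min < tol:
            break
        i, j = i_best, j_best
        eta = k_mat[i, i] + k_mat[j, j] - 2.0 * k_mat[i, j]
        if eta < 1e-12:
            eta = 1e-12
        bi, bj = beta[i], beta[j]
        lo = max(-c_reg - bi, bj - c_reg)
        hi = min(c_reg - bi, bj + c_reg)
        if hi <= lo:
            break
        gd = g[i] - g[j]
        # candidate steps: unconstrained optima on the four sign segments,
        # plus the kinks and the box edges; take the best exact gain
        best_d = 0.0
        best_gain = 0.0
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                d = (gd - eps * si + eps * sj) / eta
                if d < lo:
                    d = lo
                elif d > hi:
                    d = hi
                gain = (d * gd - 0.5 * eta * d * d
                        - eps * (abs(bi + d) - abs(bi))
                        - eps * (abs(bj - d) - abs(bj)))
                if gain > best_gain:
                    best_gain = gain
                    best_d = d
        for d in (-bi, bj, lo, hi):
            if lo <= d <= hi:
                gain = (d * gd - 0.5 * eta * d * d
                        - eps * (abs(bi + d) - abs(bi))
                        - eps * (abs(bj - d) - abs(bj)))
                if gain > best_gain:
                    best_gain = gain
                    best_d = d
        if best_gain <= 1e-14:
            break
        d = best_d
        beta[i] += d
        beta[j] -= d
        for t in range(n):
            g[t] -= d * (k_mat[t, i] - k_mat[t, j])
    # bias from the KKT interval: for every i,
    #   beta_i = C        -> b <= G_i - eps
    #   0 < beta_i < C    -> b  = G_i - eps
    #   beta_i = 0        -> G_i - eps <= b <= G_i + eps
    #   -C < beta_i < 0   -> b  = G_i + eps
    #   beta_i = -C       -> b >= G_i + eps
    edge = 1e-9 * c_reg
    ub = np.inf
    lb = -np.inf
    for i in range(n):
        if beta[i] >= c_reg - edge:
            v = g[i] - eps
            if v < ub:
                ub = v
        elif beta[i] <= -c_reg + edge:
            v = g[i] + eps
            if v > lb:
                lb = v
        elif beta[i] > edge:
            v = g[i] - eps
            if v < ub:
                ub = v
            if v > lb:
                lb = v
        elif beta[i] < -edge:
            v = g[i] + eps
            if v < ub:
                ub = v
            if v > lb:
                lb = v
        else:
            v1 = g[i] - eps
            v2 = g[i] + eps
            if v2 < ub:
                ub = v2
            if v1 > lb:
                lb = v1
    if lb == -np.inf and ub == np.inf:
        return 0.0
    if lb == -np.inf:
        return ub
    if ub == np.inf:
        return lb
    return 0.5 * (lb + ub)


@njit(cache=False)
def _rank_by_abs(w):  # pragma: no cover
    """Indices sorted by decreasing |w|, ties broken by lower index
    (stable insertion sort; the feature count is small)."""
    p = w.shape[0]
    order = np.arange(p)
    for i in range(1, p):
        key = order[i]
        key_val = abs(w[key])
        j = i - 1
        while j >= 0 and abs(w[order[j]]) < key_val:
            order[j + 1] = order[j]
            j -= 1
        order[j + 1] = key
    return order


@njit(cache=False)
def loocv_grid_core(x, y, ks, c_reg, eps, tol, max_sweeps,
                    store_weights):  # pragma: no cover
    """LOOCV predictions for every feature-count in ``ks``.

    For each left-out subject: z-score the training features, fit the
    full-feature SVR (which is also the 100% model and supplies the
    |weight| ranking, ties to lower index), then walk the feature count
    downward; dropping one ranked feature at a time is a rank-one kernel
    downdate, so each smaller model is re-solved warm from the previous
    one.  Returns the (n_fracs, n) prediction matrix and, optionally, the
    per-fold signed weights embedded in full feature space.
    """
    n, p = x.shape
    nf = ks.shape[0]
    preds = np.zeros((nf, n))
    weights = np.zeros((nf, n, p)) if store_weights else np.zeros((1, 1, 1))
    xt = np.empty((n - 1, p))
    yt = np.empty(n - 1)
    for fold in range(n):
        m = 0
        for i in range(n):
            if i != fold:
                xt[m] = x[i]
                yt[m] = y[i]
                m += 1
        mu = np.zeros(p)
        sd = np.zeros(p)
        for j in range(p):
            mu[j] = xt[:, j].mean()
            s = xt[:, j].std()
            sd[j] = s if s > 1e-12 else 1.0
        xs = (xt - mu) / sd
        xtest = (x[fold] - mu) / sd
        k_mat = xs @ xs.T
        beta = np.zeros(n - 1)
        b = svr_dual_solve(k_mat, yt, c_reg, eps, beta, tol, max_sweeps)
        w_full = xs.T @ beta
        order = _rank_by_abs(w_full)
        # record all fractions that keep every feature
        for f in range(nf):
            if ks[f] == p:
                pred = b
                for j in range(p):
                    pred += w_full[j] * xtest[j]
                preds[f, fold] = pred
                if store_weights:
                    for j in range(p):
                        weights[f, fold, j] = w_full[j]
        for k in range(p - 1, 0, -1):
            # drop the (k+1)-th ranked feature: rank-one kernel downdate
            drop = order[k]
            col = xs[:, drop]
            for a in range(n - 1):
                for bidx in range(n - 1):
                    k_mat[a, bidx] -= col[a] * col[bidx]
            needed = False
            for f in range(nf):
                if ks[f] == k:
                    needed = True
            b = svr_dual_solve(k_mat, yt, c_reg, eps, beta, tol, max_sweeps)
            if not needed:
                continue
            pred = b
            for t in range(k):
                j = order[t]
                wj = 0.0
                for a in range(n - 1):
                    wj += xs[a, j] * beta[a]
                pred += wj * xtest[j]
                if store_weights:
                    for f in range(nf):
                        if ks[f] == k:
                            weights[f, fold, j] = wj
            for f in range(nf):
                if ks[f] == k:
                    preds[f, fold] = pred
    return preds, weights


@njit(cache=False)
def _pearson(a, b):  # pragma: no cover
    n = a.shape[0]
    ma = a.mean()
    mb = b.mean()
    num = 0.0
    va = 0.0
    vb = 0.0
    for i in range(n):
        da = a[i] - ma
        db = b[i] - mb
        num += da * db
        va += da * da
        vb += db * db
    if va <= 0.0 or vb <= 0.0:
        return 0.0
    return num / np.sqrt(va * vb)


@njit(cache=False)
def grid_correlations(x, y, ks, c_reg, eps, tol, max_sweeps):  # pragma: no cover
    """Pearson r(predicted, observed) per feature fraction."""
    preds, _ = loocv_grid_core(x, y, ks, c_reg, eps, tol, max_sweeps, False)
    nf = ks.shape[0]
    rs = np.empty(nf)
    for f in range(nf):
        rs[f] = _pearson(preds[f], y)
    return rs


@njit(cache=False)
def permutation_max_null(x, y_perms, ks, c_reg, eps, tol, max_sweeps):  # pragma: no cover
    """Max-over-fractions |r| for each pre-shuffled label vector."""
    n_perm = y_perms.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        rs = grid_correlations(x, y_perms[b], ks, c_reg, eps, tol, max_sweeps)
        m = 0.0
        for f in range(rs.shape[0]):
            if abs(rs[f]) > m:
                m = abs(rs[f])
        null[b] = m
    return null
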