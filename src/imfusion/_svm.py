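"""Minimal linear C-SVC solver for very small, very numerous problems.

Time-resolved pairwise decoding at the default design sizes needs on the
order of 5e7 classifier fits per run (66 stimulus pairs x ~800 timepoints
x 8 leave-one-pseudotrial-out folds x 10-50 chunk randomisations x 12
subjects), each on ~14 training samples.  That is far beyond what per-fit
calls into a general-purpose library can do, so the inner loop is a small
SMO (maximal-violating-pair) solver for the C-SVC dual, compiled with
numba and operating on precomputed Gram matrices.  The test-suite checks
its decision values against libsvm (``sklearn.svm.SVC``) on randomised
problems.

The dual is parameterised by ``beta_i = y_i * alpha_i``:

    min_beta  0.5 beta' K beta - y' beta
    s.t.      sum(beta) = 0,  beta_i in [0, C] (y_i=+1) or [-C, 0] (y_i=-1)

and the decision value of a test point is ``k_test' beta + b``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 10_000


@njit(cache=True)
def smo_train(K, y, C, tol, max_iter):
    """Solve the C-SVC dual on kernel matrix ``K`` (n x n), labels +-1.

    Returns ``(beta, b)`` with ``beta = y * alpha``.
    """
    n = K.shape[0]
    beta = np.zeros(n)
    F = -y.astype(np.float64)  # F_i = (K beta)_i - y_i
    up = np.empty(n)
    lo = np.empty(n)
    for i in range(n):
        if y[i] > 0:
            up[i] = C
            lo[i] = 0.0
        else:
            up[i] = 0.0
            lo[i] = -C
    for _ in range(max_iter):
        imin = -1
        jmax = -1
        Fmin = 1e300
        Fmax = -1e300
        for k in range(n):
            if beta[k] < up[k] - 1e-12 and F[k] < Fmin:
                Fmin = F[k]
                imin = k
            if beta[k] > lo[k] + 1e-12 and F[k] > Fmax:
                Fmax = F[k]
                jmax = k
        if imin < 0 or jmax < 0 or Fmax - Fmin < tol:
            break
        i = imin
        j = jmax
        curv = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if curv < 1e-12:
            curv = 1e-12
        d = (Fmax - Fmin) / curv
        if d > up[i] - beta[i]:
            d = up[i] - beta[i]
        if d > beta[j] - lo[j]:
            d = beta[j] - lo[j]
        beta[i] += d
        beta[j] -= d
        for k in range(n):
            F[k] += d * (K[k, i] - K[k, j])
    # intercept from the KKT conditions: -F_i for free points, midpoint of
    # the violating bounds otherwise
    s = 0.0
    nf = 0
    Fmin = 1e300
    Fmax = -1e300
    for k in range(n):
        free = beta[k] > lo[k] + 1e-8 and beta[k] < up[k] - 1e-8
        if free:
            s += F[k]
            nf += 1
        if beta[k] < up[k] - 1e-12 and F[k] < Fmin:
            Fmin = F[k]
        if beta[k] > lo[k] + 1e-12 and F[k] > Fmax:
            Fmax = F[k]
    if nf > 0:
        b = -s / nf
    else:
        b = -0.5 * (Fmin + Fmax)
    return beta, b


@njit(cache=True)
def decision_values(K_test, beta, b):
    """Decision values for test rows of kernel against training points."""
    nt = K_test.shape[0]
    out = np.empty(nt)
    for i in range(nt):
        acc = b
        for j in range(K_test.shape[1]):
            acc += K_test[i, j] * beta[j]
        out[i] = acc
    return out


@njit(cache=True)
def pair_loso_accuracy(G, pairs_a, pairs_b, n_pseudo, C, tol, max_iter):
    """Leave-one-pseudotrial-out pairwise accuracy from per-time Grams.

    Parameters
    ----------
    G:
        ``(n_time, n_cond * n_pseudo, n_cond * n_pseudo)`` Gram matrices of
        the windowed pseudotrial features at each timepoint; pseudotrials of
        condition ``c`` occupy rows ``c*n_pseudo .. (c+1)*n_pseudo - 1``.
    pairs_a, pairs_b:
        Condition indices (0-based) of each binary problem.
    Returns
    -------
    ``(n_pairs, n_time)`` fraction-correct array.  Features are mean-centred
    per fold using the training mean (applied in Gram space).
    """
    n_time = G.shape[0]
    n_pairs = pairs_a.shape[0]
    m = 2 * n_pseudo
    ntr = m - 2
    acc = np.zeros((n_pairs, n_time))
    P = np.empty((m, m))
    idx = np.empty(m, np.int64)
    tr = np.empty(ntr, np.int64)
    te = np.empty(2, np.int64)
    Ktr = np.empty((ntr, ntr))
    Kte = np.empty((2, ntr))
    y = np.empty(ntr)
    rowmean = np.empty(m)
    for t in range(n_time):
        Gt = G[t]
        for p in range(n_pairs):
            a = pairs_a[p]
            b = pairs_b[p]
            for u in range(n_pseudo):
                idx[u] = a * n_pseudo + u
                idx[n_pseudo + u] = b * n_pseudo + u
            for r in range(m):
                ir = idx[r]
                for c in range(m):
                    P[r, c] = Gt[ir, idx[c]]
            total = 0.0
            for f in range(n_pseudo):
                # training set: all pseudotrials except number f of each class
                k = 0
                for u in range(n_pseudo):
                    if u != f:
                        tr[k] = u
                        y[k] = 1.0
                        k += 1
                for u in range(n_pseudo):
                    if u != f:
                        tr[k] = n_pseudo + u
                        y[k] = -1.0
                        k += 1
                te[0] = f
                te[1] = n_pseudo + f
                # centre in Gram space with the training mean
                mm = 0.0
                for r in range(m):
                    s = 0.0
                    for c in range(ntr):
                        s += P[r, tr[c]]
                    rowmean[r] = s / ntr
                for c in range(ntr):
                    mm += rowmean[tr[c]]
                mm /= ntr
                for r in range(ntr):
                    for c in range(ntr):
                        Ktr[r, c] = P[tr[r], tr[c]] - rowmean[tr[r]] - rowmean[tr[c]] + mm
                for r in range(2):
                    for c in range(ntr):
                        Kte[r, c] = P[te[r], tr[c]] - rowmean[te[r]] - rowmean[tr[c]] + mm
                beta, bias = smo_train(Ktr, y, C, tol, max_iter)
                dv = decision_values(Kte, beta, bias)
                for r in range(2):
                    truth_sign = 1.0 if r == 0 else -1.0
                    if dv[r] * truth_sign > 0.0:
                        total += 1.0
                    elif dv[r] == 0.0:
                        total += 0.5
            acc[p, t] = total / (2.0 * n_pseudo)
    return acc


def fit_linear_gram(X_train: np.ndarray, y: np.ndarray, C: float = 1.0,
                    tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER):
    """Fit on raw features and return ``(w, b)`` of the primal hyperplane.

    Convenience wrapper used by time-generalization, where one training fit
    is evaluated at every test timepoint: with a linear kernel the test
    decision value is ``x @ w + b``.
    """
    X_train = np.ascontiguousarray(X_train, dtype=np.float64)
    K = X_train @ X_train.T
    beta, b = smo_train(K, np.asarray(y, dtype=np.float64), C, tol, max_iter)
    w = X_train.T @ beta
    return w, b
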