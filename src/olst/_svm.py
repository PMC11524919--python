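"""Numba-compiled linear soft-margin SVM engine.

Solves  min_{w,b}  0.5*(||w||^2 + b^2) + C * sum_i hinge(y_i (w.x_i + b))
via dual coordinate descent (L1-loss dual), treating the intercept as an
extra all-ones feature.  The primal is strictly convex, so the solution
is unique; the epoch-level shuffling uses a seeded xorshift generator,
making every fit fully deterministic.

This in-package solver exists because model search multiplies leave-one-
out cross-validation by thousands of candidate (subset, cost) pairs; the
per-fit overhead of a general-purpose library dominates that workload.
The test suite cross-checks the solver against an independent reference
implementation on the same objective.
"""
from __future__ import annotations

import numpy as np
from numba import njit

TOL = 1e-4
MAX_EPOCHS = 300


@njit(cache=True)
def dual_cd_warm(X: np.ndarray, y: np.ndarray, C: float, alpha: np.ndarray,
                 tol: float, max_epochs: int, seed: int) -> np.ndarray:
    """Weights (last entry = intercept feature) for augmented X, starting
    from (and updating in place) the dual variables ``alpha``."""
    n, p = X.shape
    w = np.zeros(p)
    for i in range(n):
        if alpha[i] > C:
            alpha[i] = C
        if alpha[i] != 0.0:
            for j in range(p):
                w[j] += alpha[i] * y[i] * X[i, j]
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += X[i, j] * X[i, j]
        qii[i] = s
    idx = np.arange(n)
    state = np.uint64(seed * 2654435761 + 88172645463325252)
    for _ in range(max_epochs):
        for k in range(n - 1, 0, -1):
            state ^= state << np.uint64(13)
            state ^= state >> np.uint64(7)
            state ^= state << np.uint64(17)
            r = int(state % np.uint64(k + 1))
            idx[k], idx[r] = idx[r], idx[k]
        max_pg = 0.0
        for k in range(n):
            i = idx[k]
            if qii[i] <= 0.0:
                continue
            g = 0.0
            for j in range(p):
                g += w[j] * X[i, j]
            G = y[i] * g - 1.0
            a = alpha[i]
            if a <= 0.0:
                pg = G if G < 0.0 else 0.0
            elif a >= C:
                pg = G if G > 0.0 else 0.0
            else:
                pg = G
            if abs(pg) > max_pg:
                max_pg = abs(pg)
            if pg != 0.0:
                na = a - G / qii[i]
                if na < 0.0:
                    na = 0.0
                elif na > C:
                    na = C
                d = (na - a) * y[i]
                if d != 0.0:
                    for j in range(p):
                        w[j] += d * X[i, j]
                    alpha[i] = na
        if max_pg < tol:
            break
    return w


@njit(cache=True)
def dual_cd(X: np.ndarray, y: np.ndarray, C: float,
            tol: float, max_epochs: int, seed: int) -> np.ndarray:
    """Cold-start fit: weights (last entry = intercept) for augmented X."""
    alpha = np.zeros(X.shape[0])
    return dual_cd_warm(X, y, C, alpha, tol, max_epochs, seed)


@njit(cache=True)
def loocv_decisions(X: np.ndarray, y: np.ndarray, C: float,
                    standardize: bool, tol: float, max_epochs: int,
                    seed: int) -> np.ndarray:
    """Out-of-fold decision values for n-fold leave-one-out CV.

    Each fold re-standardizes with its own training statistics when
    ``standardize`` is set.
    """
    n, p = X.shape
    dec = np.empty(n)
    Xtr = np.empty((n - 1, p + 1))
    ytr = np.empty(n - 1)
    S = np.zeros(p)
    SS = np.zeros(p)
    for i in range(n):
        for j in range(p):
            S[j] += X[i, j]
            SS[j] += X[i, j] * X[i, j]
    # warm start: fit once on the full data (full-data standardization);
    # each fold then starts from these dual variables minus its test row.
    mu = np.empty(p)
    sd = np.empty(p)
    for j in range(p):
        if standardize:
            m = S[j] / n
            v = SS[j] / n - m * m
            mu[j] = m
            sd[j] = np.sqrt(v) if v > 1e-24 else 1.0
        else:
            mu[j] = 0.0
            sd[j] = 1.0
    Xfull = np.empty((n, p + 1))
    for i in range(n):
        for j in range(p):
            Xfull[i, j] = (X[i, j] - mu[j]) / sd[j]
        Xfull[i, p] = 1.0
    alpha_full = np.zeros(n)
    dual_cd_warm(Xfull, y, C, alpha_full, tol, max_epochs, seed)
    alpha_tr = np.empty(n - 1)
    for i in range(n):
        for j in range(p):
            if standardize:
                m = (S[j] - X[i, j]) / (n - 1)
                v = (SS[j] - X[i, j] * X[i, j]) / (n - 1) - m * m
                mu[j] = m
                sd[j] = np.sqrt(v) if v > 1e-24 else 1.0
            else:
                mu[j] = 0.0
                sd[j] = 1.0
        k = 0
        for t in range(n):
            if t == i:
                continue
            for j in range(p):
                Xtr[k, j] = (X[t, j] - mu[j]) / sd[j]
            Xtr[k, p] = 1.0
            ytr[k] = y[t]
            alpha_tr[k] = alpha_full[t]
            k += 1
        w = dual_cd_warm(Xtr, ytr, C, alpha_tr, tol, max_epochs, seed + i)
        d = w[p]
        for j in range(p):
            d += w[j] * (X[i, j] - mu[j]) / sd[j]
        dec[i] = d
    return dec


@njit(cache=True)
def kfold_decisions(X: np.ndarray, y: np.ndarray, C: float, folds: np.ndarray,
                    n_folds: int, standardize: bool, tol: float,
                    max_epochs: int, seed: int) -> np.ndarray:
    """Out-of-fold decision values for a fixed fold assignment."""
    n, p = X.shape
    dec = np.empty(n)
    for f in range(n_folds):
        ntr = 0
        for i in range(n):
            if folds[i] != f:
                ntr += 1
        Xtr = np.empty((ntr, p + 1))
        ytr = np.empty(ntr)
        mu = np.zeros(p)
        sd = np.ones(p)
        if standardize:
            for j in range(p):
                s = 0.0
                ss = 0.0
                for i in range(n):
                    if folds[i] != f:
                        s += X[i, j]
                        ss += X[i, j] * X[i, j]
                m = s / ntr
                v = ss / ntr - m * m
                mu[j] = m
                sd[j] = np.sqrt(v) if v > 1e-24 else 1.0
        k = 0
        for i in range(n):
            if folds[i] != f:
                for j in range(p):
                    Xtr[k, j] = (X[i, j] - mu[j]) / sd[j]
                Xtr[k, p] = 1.0
                ytr[k] = y[i]
                k += 1
        w = dual_cd(Xtr, ytr, C, tol, max_epochs, seed + f)
        for i in range(n):
            if folds[i] == f:
                d = w[p]
                for j in range(p):
                    d += w[j] * (X[i, j] - mu[j]) / sd[j]
                dec[i] = d
    return dec
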