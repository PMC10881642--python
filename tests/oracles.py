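"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the varimax
oracle is Kaiser's original pairwise planar-rotation sweep with the
closed-form angle; the AUC oracle counts every (positive, negative) pair;
the OLS oracle solves the normal equations directly.
"""

import numpy as np


def varimax_pairwise_oracle(loadings, kaiser=True, sweeps=200, tol=1e-12):
    """Kaiser's pairwise planar-rotation varimax."""
    A = np.array(loadings, dtype=float)
    p, k = A.shape
    if kaiser:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    for _ in range(sweeps):
        total = 0.0
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = A[:, a], A[:, b]
                u = x**2 - y**2
                v = 2 * x * y
                num = 2 * (u * v).sum() - 2 * u.sum() * v.sum() / p
                den = (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                total += abs(phi)
                c, s = np.cos(phi), np.sin(phi)
                A[:, a], A[:, b] = c * x + s * y, -s * x + c * y
        if total < tol:
            break
    if kaiser:
        A = A * h[:, None]
    return A


def auc_pair_count(pos, neg):
    """AUC by exhaustive comparison of every (positive, negative) pair."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (pos.size * neg.size)


def ols_normal_equations(X, y):
    """OLS coefficients via the normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
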