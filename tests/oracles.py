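"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementation paths: subset
enumeration instead of greedy search, explicit matrix algebra instead of
vectorized shortcuts, closed forms instead of Monte Carlo.
"""

import numpy as np


def build_adjacency(voxels, connectivity="3d"):
    """26-connectivity adjacency lists over an explicit voxel list."""
    vox = [tuple(int(x) for x in v) for v in voxels]
    adj = [[] for _ in vox]
    for a in range(len(vox)):
        for b in range(a + 1, len(vox)):
            d = [abs(vox[a][i] - vox[b][i]) for i in range(3)]
            if max(d) == 1 and (connectivity == "3d" or d[2] == 0):
                adj[a].append(b)
                adj[b].append(a)
    return vox, adj


def connected_ksubsets(voxels, k, connectivity="3d"):
    """All connected k-subsets of a voxel set, by breadth-first growth."""
    vox, adj = build_adjacency(voxels, connectivity)
    frontier = {frozenset([i]) for i in range(len(vox))}
    for _ in range(k - 1):
        nxt = set()
        for s in frontier:
            nb = set()
            for v in s:
                nb.update(adj[v])
            for u in nb - s:
                nxt.add(s | {u})
        frontier = nxt
    return [frozenset(vox[i] for i in s) for s in frontier]


def best_quintet_mean(values, voxels, k=5, connectivity="3d"):
    """Exhaustive maximum mean over all connected k-subsets; None if none."""
    subsets = connected_ksubsets(voxels, k, connectivity)
    if not subsets:
        return None
    best = -np.inf
    for s in subsets:
        m = float(np.mean([values[v] for v in s]))
        if m > best:
            best = m
    return best


def ols_full(y, X):
    """Textbook OLS: beta, se, t, df via explicit matrix algebra."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se, beta / se, df


def simple_slope_t(y, x, m, cov, M, alpha=0.05):
    """|t| of the simple slope of x at moderator value M, by re-centered
    regression y ~ x + (m-M) + x*(m-M) [+ cov]."""
    mm = m - M
    cols = [np.ones_like(x), x, mm, x * mm]
    if cov is not None:
        cols.extend(np.atleast_2d(cov.T))
    X = np.column_stack(cols)
    _, se, t, df = ols_full(y, X)
    return abs(t[1]), df


def clopper_pearson_by_inversion(x, n, alpha=0.05, tol=1e-11):
    """CI by direct bisection on the binomial tail probabilities."""
    from scipy.stats import binom

    def search(f, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    if x == 0:
        low = 0.0
    else:
        # largest p with P(X >= x | p) <= alpha/2
        low = search(lambda p: binom.sf(x - 1, n, p) <= alpha / 2, 0.0, 1.0)
    if x == n:
        high = 1.0
    else:
        # smallest p with P(X <= x | p) <= alpha/2 -> search from above
        high = 1.0 - search(
            lambda q: binom.cdf(x, n, 1.0 - q) <= alpha / 2, 0.0, 1.0)
    return low, high


def partial_spearman_matrix_oracle(x, y, cov):
    """Rank, project onto the orthogonal complement of [1, cov], correlate."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    Z = np.column_stack([np.ones(n)] +
                        ([] if cov is None else [np.asarray(cov, float)]))
    P = np.eye(n) - Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    ex, ey = P @ rx, P @ ry
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


def welch_oracle(a, b, alpha=0.05):
    """Textbook Welch statistic, Satterthwaite df and CI."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    diff = a.mean() - b.mean()
    se = np.sqrt(va + vb)
    t_stat = diff / se
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    half = tdist.ppf(1 - alpha / 2, df) * se
    return t_stat, df, (diff - half, diff + half)
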