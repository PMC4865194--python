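"""Independent reference implementations used only to verify the package.

Everything here is deliberately written the slow, obvious way (nested
loops, explicit normal equations, exhaustive enumeration) and shares no
code path with the package.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_morans_i(values, W) -> float:
    """Moran's I by the textbook double sum."""
    x = np.asarray(values, dtype=float)
    W = np.asarray(W, dtype=float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += W[i, j]
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / s0) * num / den


def prim_mst_max_edge(coords) -> float:
    """Longest edge of the Euclidean MST via Prim's algorithm."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    in_tree = [0]
    out = set(range(1, n))
    max_edge = 0.0
    while out:
        best = None
        for i in in_tree:
            for j in out:
                d = float(np.hypot(*(coords[i] - coords[j])))
                if best is None or d < best[0]:
                    best = (d, j)
        max_edge = max(max_edge, best[0])
        in_tree.append(best[1])
        out.remove(best[1])
    return max_edge


def brute_edge_filter(points, simplices) -> tuple[float, list]:
    """Re-run the mean-edge filter: unique edges, inclusive comparison."""
    pts = np.asarray(points, dtype=float)
    edges = set()
    for a, b, c in simplices:
        for i, j in ((a, b), (b, c), (a, c)):
            edges.add((min(i, j), max(i, j)))
    mean_len = np.mean([np.hypot(*(pts[i] - pts[j])) for i, j in edges])
    kept = []
    for a, b, c in simplices:
        ls = [np.hypot(*(pts[i] - pts[j])) for i, j in ((a, b), (b, c), (a, c))]
        if max(ls) <= mean_len:
            kept.append((a, b, c))
    return float(mean_len), kept


def point_in_triangle(p, a, b, c, eps=1e-12) -> bool:
    """Barycentric point-in-triangle test, boundary inclusive."""
    v0 = np.asarray(c, float) - a
    v1 = np.asarray(b, float) - a
    v2 = np.asarray(p, float) - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    den = d00 * d11 - d01 * d01
    if abs(den) < eps:
        return False
    u = (d11 * d20 - d01 * d21) / den
    v = (d00 * d21 - d01 * d20) / den
    return u >= -eps and v >= -eps and u + v <= 1 + eps


def normal_equations_residuals(Y, design) -> np.ndarray:
    """Least-squares residuals via explicitly solved normal equations."""
    X = np.asarray(design, float)
    Y = np.asarray(Y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    return Y - X @ beta


def power_iteration_pca(X, n_iter=20000, tol=1e-14):
    """Eigenpairs of the correlation matrix by power iteration + deflation."""
    X = np.asarray(X, float)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    C = (Z.T @ Z) / (len(Z) - 1)
    p = C.shape[0]
    vals, vecs = [], []
    A = C.copy()
    rng = np.random.default_rng(0)
    for _ in range(p):
        v = rng.standard_normal(p)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            w = A @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            if np.abs(np.abs(w @ v) - 1) < tol:
                v = w
                break
            v = w
        lam = float(v @ C @ v)
        vals.append(lam)
        vecs.append(v.copy())
        A = A - lam * np.outer(v, v)
    order = np.argsort(vals)[::-1]
    return np.array(vals)[order], np.column_stack([vecs[i] for i in order])


def hat_matrix_fit(Y, X) -> np.ndarray:
    """Fitted values via the explicit hat matrix on centred data."""
    Yc = np.asarray(Y, float) - np.asarray(Y, float).mean(0)
    Xc = np.asarray(X, float) - np.asarray(X, float).mean(0)
    H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
    return H @ Yc


def sequential_forward_selection(Y, vectors, alpha, n_perm, seed):
    """Independent re-run of double-criterion forward selection.

    Uses explicit least-squares fits throughout (no orthonormal
    shortcuts) and the same permutation protocol (one stream: global
    test first, then one test per admitted step).
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    V = np.asarray(vectors, float)
    n, m = V.shape
    Yc = Y - Y.mean(0)
    ss_tot = (Yc ** 2).sum()

    def rss(cols):
        if not cols:
            return ss_tot
        X = np.column_stack([np.ones(n)] + [V[:, j] for j in cols])
        res = Yc - X @ np.linalg.lstsq(X, Yc, rcond=None)[0]
        return float((res ** 2).sum())

    def adj(r2, k):
        return 1 - (1 - r2) * (n - 1) / (n - k - 1)

    # global gate
    rss_all = rss(list(range(m)))
    f_obs = ((ss_tot - rss_all) / m) / (rss_all / (n - m - 1))
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        Yp = Yc[p]
        X = np.column_stack([np.ones(n), V])
        res = Yp - X @ np.linalg.lstsq(X, Yp, rcond=None)[0]
        r = float((res ** 2).sum())
        f = ((ss_tot - r) / m) / (r / (n - m - 1))
        if f >= f_obs:
            count += 1
    if (1 + count) / (1 + n_perm) > alpha:
        return []
    adj_global = adj(1 - rss_all / ss_tot, m)

    selected: list[int] = []
    remaining = list(range(m))
    while remaining:
        rss_sel = rss(selected)
        gains = {j: rss_sel - rss(selected + [j]) for j in remaining}
        best = min(remaining, key=lambda j: (-gains[j], j))
        # permutation test of the best candidate against reduced-model residuals
        Xsel = np.column_stack([np.ones(n)] + [V[:, j] for j in selected])
        resid = Yc - Xsel @ np.linalg.lstsq(Xsel, Yc, rcond=None)[0]
        df = n - len(selected) - 2
        ss_res = float((resid ** 2).sum())
        g_obs = gains[best]
        f_obs = g_obs / ((ss_res - g_obs) / df)
        count = 0
        v = V[:, best]
        for _ in range(n_perm):
            p = rng.permutation(n)
            Rp = resid[p]
            X1 = np.column_stack([np.ones(n), v])
            res1 = Rp - X1 @ np.linalg.lstsq(X1, Rp, rcond=None)[0]
            g = float((Rp ** 2).sum() - (res1 ** 2).sum())
            f = g / ((ss_res - g) / df)
            if f >= f_obs:
                count += 1
        if (1 + count) / (1 + n_perm) > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        r2_cum = 1 - rss(selected) / ss_tot
        if adj(r2_cum, len(selected)) > adj_global:
            break
    return selected


def nested_loop_manhattan(profiles) -> np.ndarray:
    """Pairwise Manhattan distances by explicit loops."""
    P = np.asarray(profiles, float)
    ns = len(P)
    M = np.zeros((ns, ns))
    for a in range(ns):
        for b in range(ns):
            M[a, b] = sum(abs(P[a, k] - P[b, k]) for k in range(P.shape[1]))
    return M


def exhaustive_mantel_p(M, R, tail="greater"):
    """Exhaustive Mantel p-value over all relabelings of R."""
    M = np.asarray(M, float)
    R = np.asarray(R, float)
    ns = M.shape[0]
    iu = np.triu_indices(ns, 1)

    def corr(x, y):
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(M[iu], R[iu])
    count = total = 0
    for perm in permutations(range(ns)):
        p = list(perm)
        Rp = R[np.ix_(p, p)]
        r = corr(M[iu], Rp[iu])
        total += 1
        if tail == "greater" and r >= r_obs:
            count += 1
        elif tail == "less" and r <= r_obs:
            count += 1
        elif tail == "two-sided" and abs(r) >= abs(r_obs):
            count += 1
    return r_obs, count / total
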