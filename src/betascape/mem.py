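"""Moran Eigenvector Maps (dbMEM): construction, selection and classification.

A spatial weighting matrix W is the binary adjacency of a
distance-band graph (sites are neighbours iff their distance is at most
d_max).  MEMs are the eigenvectors of the doubly centred matrix
Omega = C W C with C = I - 11'/n; the eigenvalue of each vector is
proportional to its Moran's I under W (I_k = (n / 1'W1) * lambda_k),
so positive-eigenvalue vectors model positive spatial autocorrelation
at nested scales, from one long wave down to neighbour-to-neighbour
oscillation.

The neighbourhood distance is chosen by AICc over a ladder of candidate
thresholds spanning the minimum-spanning-tree connectivity distance up
to the maximum pairwise distance.  MEMs entering the model are chosen
by forward selection under the double stopping criterion (permutation
alpha and the global model's adjusted R^2), then split into broad- and
fine-scale submodels and pruned of vectors collinear with the
geomorphological dummies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .community import CommunityMatrix
from .rda import adjusted_r2
from .transforms import PredictorSet

__all__ = [
    "SpatialWeightMatrix",
    "MEMBasis",
    "distance_band_weights",
    "candidate_thresholds",
    "mem_basis",
    "select_weight_matrix",
    "forward_select",
    "classify_scales",
    "prune_vs_geo",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeightMatrix:
    """Binary distance-band connectivity: links iff distance <= d_max_km."""

    links: np.ndarray
    d_max_km: float
    connected: bool = True

    def __post_init__(self) -> None:
        W = np.asarray(self.links, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("links must be square")
        if not np.allclose(W, W.T):
            raise ValueError("links must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("links must have a zero diagonal")
        self.links = W

    @property
    def n(self) -> int:
        return self.links.shape[0]

    @property
    def total_weight(self) -> float:
        """1'W1, the normalising constant of Moran's I."""
        return float(self.links.sum())


@dataclass
class MEMBasis:
    """Orthonormal positive-eigenvalue eigenvectors of the centred W.

    ``morans_i`` holds each vector's Moran's I, which equals
    ``(n / total_weight) * eigenvalue`` by construction.  ``scale_class``
    starts ``unassigned`` and is filled by :func:`classify_scales`.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    morans_i: np.ndarray
    d_max_km: float
    total_weight: float
    scale_class: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        m = self.vectors.shape[1]
        if self.scale_class is None:
            self.scale_class = np.array(["unassigned"] * m, dtype=object)

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    def names(self) -> list[str]:
        return [f"MEM{k + 1}" for k in range(self.n_vectors)]


def distance_band_weights(coords: np.ndarray, d_max_km: float) -> SpatialWeightMatrix:
    """Build the binary adjacency of the distance-band graph at d_max_km."""
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    W = ((d <= d_max_km) & (d > 0)).astype(float)
    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        logger.warning("distance band %.3f km leaves the graph in %d components",
                       d_max_km, n_comp)
    return SpatialWeightMatrix(W, float(d_max_km), connected=n_comp == 1)


def candidate_thresholds(coords: np.ndarray, n_candidates: int = 50) -> np.ndarray:
    """Evenly spaced neighbourhood distances from d_mst to d_full.

    The lower end is the longest edge of the Euclidean minimum spanning
    tree — the smallest threshold that keeps the graph connected — and
    the upper end is the maximum pairwise distance.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 sites")
    if n_candidates < 1:
        raise ValueError("n_candidates must be positive")
    d = squareform(pdist(coords))
    if np.any(d[np.triu_indices_from(d, 1)] == 0):
        raise ValueError("coincident sites collapse the threshold range")
    mst = minimum_spanning_tree(d)
    d_mst = float(mst.data.max())
    d_full = float(d.max())
    if n_candidates == 1:
        return np.array([d_mst])
    return np.linspace(d_mst, d_full, n_candidates)


def mem_basis(W: SpatialWeightMatrix, tol_factor: float = 1e-9) -> MEMBasis:
    """Eigendecompose Omega = C W C and keep positive-eigenvalue vectors.

    Eigenvalues come back in descending order; vectors are orthonormal
    and orthogonal to the constant vector.  Raises when no eigenvalue is
    positive (no positive spatial structure — e.g. the complete graph).
    """
    n = W.n
    if W.total_weight == 0:
        raise ValueError("weight matrix has zero total weight")
    ones = np.ones((n, n)) / n
    C = np.eye(n) - ones
    omega = C @ W.links @ C
    omega = (omega + omega.T) / 2.0  # symmetrise fp noise for eigh
    evals, evecs = np.linalg.eigh(omega)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = tol_factor * max(np.abs(evals).max(), 1.0)
    pos = evals > tol
    if not pos.any():
        raise ValueError("no positive spatial structure: all eigenvalues <= tolerance")
    evals, evecs = evals[pos], evecs[:, pos]
    morans = (n / W.total_weight) * evals
    return MEMBasis(evecs, evals, morans, W.d_max_km, W.total_weight)


def _centred(Y) -> np.ndarray:
    vals = Y.values if isinstance(Y, CommunityMatrix) else np.asarray(Y, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    return vals - vals.mean(axis=0)


def aicc(n: int, rss: float, k: int) -> float:
    """Corrected Akaike criterion for a least-squares model with k regressors.

    AICc = n ln(RSS/n) + 2(k+1) + 2(k+1)(k+2)/(n-k-2); for a
    multivariate response RSS is pooled over columns (single-dispersion
    approximation).
    """
    if n - k - 2 <= 0:
        raise ValueError("AICc undefined: n - k - 2 <= 0")
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * np.log(rss / n) + 2 * (k + 1) + 2 * (k + 1) * (k + 2) / (n - k - 2)


def select_weight_matrix(
    Y,
    candidates: np.ndarray,
    coords: np.ndarray,
) -> tuple[SpatialWeightMatrix, pd.DataFrame]:
    """Choose the neighbourhood distance by AICc over candidate thresholds.

    For each candidate the MEM basis is built, vectors are ordered by
    the sum of squares of Y they individually explain, and AICc is
    evaluated for the nested models on the first k vectors; the
    candidate's score is the minimum over k.  Returns the winning
    weight matrix and the per-candidate table
    (d_max_km, n_mem, best_k, aicc).
    """
    Yc = _centred(Y)
    n = Yc.shape[0]
    ss_tot = float((Yc ** 2).sum())
    rows = []
    best: tuple[float, float] | None = None
    for d_max in np.asarray(candidates, dtype=float):
        W = distance_band_weights(coords, d_max)
        try:
            basis = mem_basis(W)
        except ValueError as e:
            logger.warning("candidate %.3f km skipped: %s", d_max, e)
            rows.append((d_max, 0, np.nan, np.nan))
            continue
        # orthonormal basis => explained SS of vector v is ||v'Yc||^2 and
        # nested-model RSS is ss_tot minus the cumulative sum
        proj = basis.vectors.T @ Yc
        gains = (proj ** 2).sum(axis=1)
        order = np.argsort(gains)[::-1]
        cum = np.cumsum(gains[order])
        scores = []
        for k in range(1, len(cum) + 1):
            if n - k - 2 <= 0:
                break
            scores.append(aicc(n, ss_tot - cum[k - 1], k))
        if not scores:
            logger.warning("candidate %.3f km skipped: AICc undefined for every k", d_max)
            rows.append((d_max, basis.n_vectors, np.nan, np.nan))
            continue
        k_best = int(np.argmin(scores)) + 1
        score = float(np.min(scores))
        rows.append((d_max, basis.n_vectors, k_best, score))
        if best is None or score < best[1]:
            best = (d_max, score)
    table = pd.DataFrame(rows, columns=["d_max_km", "n_mem", "best_k", "aicc"])
    if best is None:
        raise ValueError("no candidate threshold yielded a scorable MEM basis")
    return distance_band_weights(coords, best[0]), table


def _perm_pvalue_partial(v: np.ndarray, resid: np.ndarray, n_sel: int,
                         n_perm: int, rng: np.random.Generator) -> float:
    """Permutation p for adding orthonormal vector v to a model with n_sel terms.

    The reduced-model residual matrix is row-permuted; residual total SS
    is permutation-invariant, so only the candidate's explained SS
    varies and the pseudo-F comparison reduces to comparing those.
    """
    n = resid.shape[0]
    ss_res = float((resid ** 2).sum())
    gain_obs = float(((v @ resid) ** 2).sum())
    df_res = n - n_sel - 2  # constant + selected + candidate
    if df_res <= 0:
        return 1.0
    f_obs = gain_obs / ((ss_res - gain_obs) / df_res)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        gain = float(((v @ resid[p]) ** 2).sum())
        f = gain / ((ss_res - gain) / df_res)
        if f >= f_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def forward_select(
    Y,
    basis: MEMBasis,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[int]:
    """Forward selection of MEMs with the double stopping criterion.

    The global model (all MEMs) is first tested by permutation; a
    non-significant global model returns an empty selection.  Vectors
    then enter in order of explained sum of squares; selection stops
    when the best remaining candidate's permutation p-value exceeds
    ``alpha``, or — after admitting a candidate — when the cumulative
    adjusted R^2 exceeds the global model's adjusted R^2.

    Returns basis column indices in order of entry.
    """
    if n_perm < 99:
        logger.warning("n_perm=%d gives coarse p-value resolution; 99+ recommended", n_perm)
    rng = np.random.default_rng(seed)
    Yc = _centred(Y)
    n, m = Yc.shape[0], basis.n_vectors
    ss_tot = float((Yc ** 2).sum())
    if ss_tot == 0:
        return []
    proj = basis.vectors.T @ Yc
    gains = (proj ** 2).sum(axis=1)  # per-vector explained SS, order-free (orthonormal)

    # global significance gate
    r2_global = float(gains.sum()) / ss_tot
    adj_global = adjusted_r2(r2_global, n, m)
    f_obs = (gains.sum() / m) / ((ss_tot - gains.sum()) / (n - m - 1)) if n - m - 1 > 0 else np.inf
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        g = float(((basis.vectors.T @ Yc[p]) ** 2).sum())
        f = (g / m) / ((ss_tot - g) / (n - m - 1)) if n - m - 1 > 0 else np.inf
        if f >= f_obs:
            count += 1
    p_global = (1 + count) / (1 + n_perm)
    if p_global > alpha:
        logger.info("global MEM model not significant (p=%.4f > %.2f); empty selection",
                    p_global, alpha)
        return []

    selected: list[int] = []
    remaining = list(range(m))
    resid = Yc.copy()
    cum_ss = 0.0
    while remaining:
        # orthonormality: candidate gain is independent of what's selected;
        # ties break to the lowest index for determinism
        best_j = min(remaining, key=lambda j: (-gains[j], j))
        pval = _perm_pvalue_partial(basis.vectors[:, best_j], resid,
                                    len(selected), n_perm, rng)
        if pval > alpha:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        v = basis.vectors[:, best_j]
        resid = resid - np.outer(v, v @ resid)
        cum_ss += gains[best_j]
        adj_cum = adjusted_r2(cum_ss / ss_tot, n, len(selected))
        if adj_cum > adj_global:
            break
    return selected


def _sign_run_length(v: np.ndarray, axis_coord: np.ndarray) -> float:
    """Mean run length of the sign sequence of v along a coordinate ordering."""
    order = np.argsort(axis_coord, kind="stable")
    signs = np.sign(v[order])
    signs[signs == 0] = 1
    runs = 1 + int((np.diff(signs) != 0).sum())
    return len(v) / runs


def classify_scales(
    basis: MEMBasis,
    selected: list[int],
    rule: str = "eigenvalue_split",
    param=None,
    coords: np.ndarray | None = None,
) -> MEMBasis:
    """Assign selected MEMs to broad/fine submodels.

    Rules:

    - ``eigenvalue_split``: the ``param`` (q) selected vectors with the
      highest eigenvalue ranks are broad, the rest fine.  ``param=None``
      takes the top half (rounded up).
    - ``period_threshold``: broad iff the mean sign-run length of the
      vector along the dominant geographic axis is >= ``param``
      (requires ``coords``).
    - ``explicit``: ``param = (broad_indices, fine_indices)`` encodes a
      judgment-based split (the field practice of classifying by map
      inspection and periodicity cannot be automated).
    """
    if not selected:
        raise ValueError("no selected MEMs to classify")
    classes = np.array(["unassigned"] * basis.n_vectors, dtype=object)
    if rule == "eigenvalue_split":
        q = int(np.ceil(len(selected) / 2)) if param is None else int(param)
        by_eig = sorted(selected, key=lambda j: -basis.eigenvalues[j])
        for r, j in enumerate(by_eig):
            classes[j] = "broad" if r < q else "fine"
    elif rule == "period_threshold":
        if coords is None:
            raise ValueError("period_threshold rule needs coords")
        if param is None:
            raise ValueError("period_threshold rule needs a run-length param")
        coords = np.asarray(coords, dtype=float)
        axis = int(np.argmax(coords.var(axis=0)))
        for j in selected:
            rl = _sign_run_length(basis.vectors[:, j], coords[:, axis])
            classes[j] = "broad" if rl >= param else "fine"
    elif rule == "explicit":
        broad, fine = param
        leftovers = set(selected) - set(broad) - set(fine)
        if leftovers:
            raise ValueError(f"explicit rule leaves MEM indices unassigned: {sorted(leftovers)}")
        for j in broad:
            classes[j] = "broad"
        for j in fine:
            classes[j] = "fine"
    else:
        raise ValueError(f"unknown classification rule {rule!r}")
    return replace(basis, scale_class=classes)


def prune_vs_geo(
    basis: MEMBasis,
    selected: list[int],
    geo: PredictorSet,
    r_threshold: float = 0.3,
) -> tuple[list[int], pd.DataFrame]:
    """Drop selected MEMs collinear with any geomorphology dummy column.

    A MEM leaves the model when |Pearson r| with any Geo column exceeds
    ``r_threshold`` — such vectors are mathematical images of the unit
    layout and would blur the historical vs purely-spatial attribution.
    Returns the retained indices (entry order kept) and a report of all
    (MEM, geo column, r) pairs inspected.
    """
    if geo.n_sites != basis.vectors.shape[0]:
        raise ValueError("geo rows must align with basis rows")
    G = geo.columns - geo.columns.mean(axis=0)
    g_norm = np.sqrt((G ** 2).sum(axis=0))
    if np.any(g_norm == 0):
        raise ValueError("constant geo column")
    rows = []
    retained = []
    for j in selected:
        v = basis.vectors[:, j]
        vc = v - v.mean()
        r = (vc @ G) / (np.sqrt((vc ** 2).sum()) * g_norm)
        worst = int(np.argmax(np.abs(r)))
        drop = bool(np.abs(r[worst]) > r_threshold)
        rows.append((f"MEM{j + 1}", geo.labels[worst], float(r[worst]), drop))
        if not drop:
            retained.append(j)
        else:
            logger.info("prune_vs_geo: dropping MEM%d (r=%.3f with %s)",
                        j + 1, r[worst], geo.labels[worst])
    report = pd.DataFrame(rows, columns=["mem", "geo_column", "r", "dropped"])
    return retained, report
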