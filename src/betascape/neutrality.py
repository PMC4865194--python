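"""Correlogram-based diagnostic of neutral spatial dynamics.

Neutral community dynamics (ecological equivalence plus dispersal
limitation) predict that species incidences are mutually independent
while sharing similar spatial autocorrelation profiles.  The
diagnostic, following the population-genetics protocol of Diniz-Filho
and colleagues, computes per-species Moran's I correlograms on the
spatially predicted incidence matrix, the matrix **M** of pairwise
Manhattan distances between species correlograms, the matrix **R** of
pairwise Pearson correlations between species profiles, and the Mantel
correlation between M and R.  Under neutrality M and R are unrelated;
shared (non-neutral) drivers make species with similar correlograms
also covary, pushing the M-R relationship negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .mem import SpatialWeightMatrix

__all__ = [
    "Correlogram",
    "MantelResult",
    "morans_i",
    "distance_classes",
    "correlogram",
    "correlogram_distance_matrix",
    "species_correlation_matrix",
    "mantel",
    "neutrality_diagnostic",
]

logger = logging.getLogger(__name__)

_EXHAUSTIVE_MAX = 7


def _nonconstant_mask(Y: np.ndarray) -> np.ndarray:
    """Columns with variation beyond fp noise about their mean."""
    sd = Y.std(axis=0)
    scale = np.abs(Y).max() if Y.size else 1.0
    return sd > 1e-12 * max(scale, 1.0)


@dataclass
class Correlogram:
    """Moran's I of one species across ordered distance classes."""

    species: str
    class_edges: np.ndarray          # n_classes + 1 boundaries (km)
    morans_i: np.ndarray             # NaN where a class has no pairs
    class_counts: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.class_counts > 0


@dataclass
class MantelResult:
    r: float
    p_value: float
    tail: str
    n_perm: int
    exhaustive: bool
    m_mean: float
    m_sd: float
    r_mean: float
    r_sd: float


def morans_i(values: np.ndarray, W) -> float:
    """Moran's I: (n / 1'W1) * (z'Wz / z'z), z the centred values."""
    x = np.asarray(values, dtype=float)
    Wm = W.links if isinstance(W, SpatialWeightMatrix) else np.asarray(W, dtype=float)
    n = len(x)
    if Wm.shape != (n, n):
        raise ValueError("weight matrix shape must match values")
    s0 = Wm.sum()
    if s0 == 0:
        raise ValueError("distance class has no pairs")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined")
    return float((n / s0) * (z @ Wm @ z) / denom)


def distance_classes(coords: np.ndarray, n_classes: int | None = None,
                     method: str = "quantile") -> np.ndarray:
    """Distance-class boundaries over all pairwise distances.

    ``quantile`` (default) gives classes of (near-)equal pair counts;
    ``linear`` gives equal-width classes.  ``n_classes=None`` applies
    Sturges' rule to the pair count.
    """
    coords = np.asarray(coords, dtype=float)
    d = pdist(coords)
    if len(d) == 0:
        raise ValueError("need at least 2 sites")
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(len(d)) + 1))
    max_classes = len(np.unique(d))
    if n_classes > max_classes:
        raise ValueError(
            f"n_classes={n_classes} exceeds pair support; at most {max_classes} possible")
    if method == "quantile":
        edges = np.quantile(d, np.linspace(0, 1, n_classes + 1))
        edges = np.unique(edges)
        if len(edges) < n_classes + 1:
            logger.warning("tied distances reduce %d requested classes to %d",
                           n_classes, len(edges) - 1)
    elif method == "linear":
        edges = np.linspace(d.min(), d.max(), n_classes + 1)
    else:
        raise ValueError("method must be 'quantile' or 'linear'")
    edges[0] = np.nextafter(edges[0], -np.inf)  # include the smallest pair
    return edges


def _class_weights(coords: np.ndarray, edges: np.ndarray) -> list[np.ndarray]:
    d = squareform(pdist(np.asarray(coords, dtype=float)))
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        W = ((d > lo) & (d <= hi)).astype(float)
        np.fill_diagonal(W, 0.0)
        out.append(W)
    return out


def correlogram(
    predicted_Y: np.ndarray,
    coords: np.ndarray,
    n_classes: int | None = None,
    species: list[str] | None = None,
    method: str = "quantile",
) -> list[Correlogram]:
    """Per-species Moran's I correlograms of a site x species matrix.

    Constant columns have no defined correlogram; they are excluded with
    a warning (``species_correlation_matrix`` applies the same
    exclusion so M and R stay index-consistent).
    """
    Y = np.atleast_2d(np.asarray(predicted_Y, dtype=float))
    if species is None:
        species = [f"sp{j}" for j in range(Y.shape[1])]
    edges = distance_classes(coords, n_classes, method=method)
    weights = _class_weights(coords, edges)
    counts = np.array([W.sum() / 2 for W in weights])
    n = Y.shape[0]
    Z = Y - Y.mean(axis=0)
    var = (Z ** 2).sum(axis=0)
    ok = _nonconstant_mask(Y)
    out: list[Correlogram] = []
    for j, name in enumerate(species):
        if not ok[j]:
            logger.warning("correlogram: species %s is constant, excluded", name)
            continue
        vals = np.full(len(weights), np.nan)
        for c, W in enumerate(weights):
            s0 = W.sum()
            if s0 == 0:
                continue
            vals[c] = (n / s0) * (Z[:, j] @ W @ Z[:, j]) / var[j]
        out.append(Correlogram(name, edges, vals, counts.copy()))
    return out


def correlogram_distance_matrix(correlograms: list[Correlogram]) -> np.ndarray:
    """Manhattan distances between species correlograms (matrix M).

    Only classes valid (pair-supported, finite) in *all* correlograms
    contribute, so entries are comparable.
    """
    if len(correlograms) < 2:
        raise ValueError("need at least 2 correlograms")
    e0 = correlograms[0].class_edges
    for c in correlograms:
        if not np.array_equal(c.class_edges, e0):
            raise ValueError("correlograms must share class edges")
    I = np.vstack([c.morans_i for c in correlograms])
    valid = np.all(np.isfinite(I), axis=0)
    if not valid.any():
        raise ValueError("no distance class is valid across all correlograms")
    I = I[:, valid]
    diff = np.abs(I[:, None, :] - I[None, :, :]).sum(axis=2)
    return diff


def species_correlation_matrix(predicted_Y: np.ndarray,
                               species: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Pearson correlations among species profiles (matrix R).

    Constant columns are excluded (warned), mirroring the correlogram
    exclusion; returns the matrix and the retained species names.
    """
    Y = np.atleast_2d(np.asarray(predicted_Y, dtype=float))
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    if species is None:
        species = [f"sp{j}" for j in range(Y.shape[1])]
    keep = _nonconstant_mask(Y)
    if not keep.all():
        dropped = [s for s, k in zip(species, keep) if not k]
        logger.warning("species_correlation_matrix: constant columns excluded: %s", dropped)
    Yk = Y[:, keep]
    R = np.corrcoef(Yk, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return R, [s for s, k in zip(species, keep) if k]


def _triangle(M: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(M.shape[0], -1)
    return M[i, j]


def mantel(
    M: np.ndarray,
    R: np.ndarray,
    n_perm: int = 9999,
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Mantel test between two symmetric species x species matrices.

    The statistic is the Pearson correlation of the lower triangles;
    permutations relabel the rows and columns of the second matrix
    simultaneously.  With 7 or fewer species all relabelings are
    enumerated exactly.  For ``tail='greater'``,
    ``p = (1 + #{r* >= r}) / (1 + n_perm)``; ``'less'`` mirrors it and
    ``'two-sided'`` uses ``|r*| >= |r|``.
    """
    M = np.asarray(M, dtype=float)
    R = np.asarray(R, dtype=float)
    if M.shape != R.shape or M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M and R must be square matrices of the same size")
    if not (np.allclose(M, M.T) and np.allclose(R, R.T)):
        raise ValueError("M and R must be symmetric")
    ns = M.shape[0]
    if ns < 4:
        raise ValueError("need at least 4 species (too few triangle entries)")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be greater, less or two-sided")

    tm = _triangle(M)
    tr = _triangle(R)
    if tm.std() == 0 or tr.std() == 0:
        raise ValueError("degenerate matrix: zero variance in the lower triangle")

    def corr(a, b):
        az, bz = a - a.mean(), b - b.mean()
        return float((az @ bz) / np.sqrt((az @ az) * (bz @ bz)))

    r_obs = corr(tm, tr)

    def exceed(r_perm: float) -> bool:
        if tail == "greater":
            return r_perm >= r_obs
        if tail == "less":
            return r_perm <= r_obs
        return abs(r_perm) >= abs(r_obs)

    exhaustive = ns <= _EXHAUSTIVE_MAX
    if exhaustive:
        total = 0
        count = 0
        for perm in _permutations(range(ns)):
            p = np.array(perm)
            r_p = corr(tm, _triangle(R[np.ix_(p, p)]))
            total += 1
            if exceed(r_p):
                count += 1
        p_value = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            p = rng.permutation(ns)
            r_p = corr(tm, _triangle(R[np.ix_(p, p)]))
            if exceed(r_p):
                count += 1
        p_value = (1 + count) / (1 + n_perm)
        n_used = n_perm

    return MantelResult(
        r=r_obs, p_value=p_value, tail=tail, n_perm=n_used, exhaustive=exhaustive,
        m_mean=float(tm.mean()), m_sd=float(tm.std(ddof=1)),
        r_mean=float(tr.mean()), r_sd=float(tr.std(ddof=1)),
    )


def neutrality_diagnostic(
    predicted_Y: np.ndarray,
    coords: np.ndarray,
    n_classes: int | None = None,
    n_perm: int = 9999,
    tail: str = "greater",
    seed: int | None = None,
    species: list[str] | None = None,
) -> tuple[MantelResult, np.ndarray, np.ndarray, list[str]]:
    """Full diagnostic: correlograms -> M, profile correlations -> R, Mantel.

    Returns (MantelResult, M, R, retained species).  Constant species
    columns are excluded consistently from both matrices.
    """
    Y = np.atleast_2d(np.asarray(predicted_Y, dtype=float))
    if species is None:
        species = [f"sp{j}" for j in range(Y.shape[1])]
    keep = _nonconstant_mask(Y)
    Yk = Y[:, keep]
    kept = [s for s, k in zip(species, keep) if k]
    if len(kept) < 4:
        raise ValueError("fewer than 4 non-constant species; diagnostic undefined")
    cgs = correlogram(Yk, coords, n_classes, species=kept)
    M = correlogram_distance_matrix(cgs)
    R, _ = species_correlation_matrix(Yk, species=kept)
    res = mantel(M, R, n_perm=n_perm, tail=tail, seed=seed)
    return res, M, R, kept
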