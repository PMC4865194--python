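"""Redundancy analysis, adjusted R², multi-set variation partitioning,
and permutation tests.

RDA is the least-squares projection of a (column-centred) multivariate
response onto the column space of centred predictors, followed by an
eigendecomposition of the fitted values; R² is the fitted sum of
squares over the total, and the Ezekiel adjustment
``1 - (1 - R²)(n - 1)/(n - m - 1)`` (with m the *rank* of the
predictor block) makes fractions comparable across predictor sets of
different sizes.  Variation partitioning decomposes the adjusted R² of
up to four predictor sets into all unique and shared fractions by
inverting the subset-union system exactly, so the fractions sum to the
full-model adjusted R² by construction; negative fractions are an
honest property of the adjustment and are reported as-is.

Significance of models and of unique fractions uses permutation
pseudo-F tests: free row permutation of the response for simple RDA,
reduced-model residual permutation for partial RDA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .community import CommunityMatrix
from .transforms import PredictorSet

__all__ = [
    "RdaFit",
    "VarpartResult",
    "adjusted_r2",
    "rda",
    "partial_rda",
    "varpart",
    "anova_permutation",
    "predict_fitted",
]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class RdaFit:
    """Result of a (partial) redundancy analysis."""

    r2: float
    r2_adj: float
    rank_x: int
    rank_z: int
    fitted: np.ndarray
    residuals: np.ndarray
    explained_axes: np.ndarray        # site scores on constrained axes
    axis_variance_fraction: np.ndarray
    pseudo_f: float
    n: int

    @property
    def n_axes(self) -> int:
        return self.explained_axes.shape[1]


@dataclass
class VarpartResult:
    """Adjusted-R² fractions over every non-empty subset of predictor sets.

    ``fraction_table`` maps ``"&"``-joined sorted set names (e.g.
    ``"Clim&Geo"``) to the variance fraction shared by exactly those
    sets and no others; ``residual`` is 1 minus the full-model adjusted
    R².  ``testable_pvalues`` holds permutation p-values for each
    unique fraction (keyed by set name) and the full model
    (``"full_model"``).
    """

    sets: list[str]
    fraction_table: dict[str, float]
    residual: float
    full_model_r2_adj: float
    testable_pvalues: dict[str, float] = field(default_factory=dict)

    def unique_fractions(self) -> dict[str, float]:
        return {s: self.fraction_table[s] for s in self.sets}

    def to_json(self, **kwargs) -> str:
        payload = {
            "sets": self.sets,
            "fractions": self.fraction_table,
            "residual": self.residual,
            "full_model_r2_adj": self.full_model_r2_adj,
            "p_values": self.testable_pvalues,
        }
        return json.dumps(payload, sort_keys=True, **kwargs)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment; m is the model rank (may exceed n-2 → undefined)."""
    if m <= 0:
        return 0.0
    if n - m - 1 <= 0:
        raise ValueError(f"adjusted R² undefined for n={n}, rank={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _values(obj) -> np.ndarray:
    if isinstance(obj, CommunityMatrix):
        v = obj.values
    elif isinstance(obj, PredictorSet):
        v = obj.columns
    else:
        v = np.asarray(obj, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    return v


def _orthobasis(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the column space of centred X, with its rank."""
    Xc = X - X.mean(axis=0)
    if Xc.size == 0:
        return np.zeros((X.shape[0], 0)), 0
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > _RANK_TOL * max(s[0], 1.0)).sum()) if len(s) else 0
    return U[:, :rank], rank


def _stack(sets) -> np.ndarray:
    blocks = [_values(s) for s in sets if s is not None]
    if not blocks:
        raise ValueError("no predictor columns supplied")
    return np.hstack(blocks)


def rda(Y, X) -> RdaFit:
    """Redundancy analysis of Y on X (both centred internally).

    X may be a PredictorSet, an array, or a sequence of those (stacked).
    Rank-deficient X is handled by projecting on an orthonormal basis of
    its column space; the reported rank is the effective model df.
    """
    Yv = _values(Y)
    Xv = _stack(X if isinstance(X, (list, tuple)) else [X])
    n = Yv.shape[0]
    if Xv.shape[0] != n:
        raise ValueError("X rows must align with Y rows")
    Yc = Yv - Yv.mean(axis=0)
    Q, rank = _orthobasis(Xv)
    if n <= rank + 1:
        raise ValueError(f"too few sites (n={n}) for predictor rank {rank}")
    fitted = Q @ (Q.T @ Yc)
    residuals = Yc - fitted
    ss_tot = float((Yc ** 2).sum())
    ss_fit = float((fitted ** 2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    r2a = adjusted_r2(r2, n, rank)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > _RANK_TOL * max(s[0] if len(s) else 0.0, 1.0)
    scores = U[:, keep] * s[keep]
    axis_frac = (s[keep] ** 2) / ss_tot if ss_tot > 0 else s[keep] * 0.0
    df_res = n - rank - 1
    f = (ss_fit / rank) / ((ss_tot - ss_fit) / df_res) if rank > 0 and ss_tot > ss_fit else np.inf
    return RdaFit(r2, r2a, rank, 0, fitted, residuals, scores, axis_frac, f, n)


def partial_rda(Y, X, Z) -> RdaFit:
    """Partial RDA of Y on X given covariables Z.

    Y and X are residualised on (centred) Z, then RDA is run on the
    residuals.  The reported ``r2`` is the *semipartial* fraction — the
    conditional fitted sum of squares over the **total** SS of Y — so
    it plugs directly into variation-partitioning arithmetic.  The
    adjusted value follows the same convention (difference of adjusted
    R² of union and covariable models).
    """
    if Z is None or (isinstance(Z, (list, tuple)) and not any(s is not None for s in Z)):
        return rda(Y, X)
    Yv = _values(Y)
    Yc = Yv - Yv.mean(axis=0)
    Xv = _stack(X if isinstance(X, (list, tuple)) else [X])
    Zv = _stack(Z if isinstance(Z, (list, tuple)) else [Z])
    n = Yv.shape[0]
    Qz, rank_z = _orthobasis(Zv)
    Yr = Yc - Qz @ (Qz.T @ Yc)
    Xr = (Xv - Xv.mean(axis=0)) - Qz @ (Qz.T @ (Xv - Xv.mean(axis=0)))
    Qx, rank_x = _orthobasis(Xr)
    if rank_x == 0:
        logger.info("partial_rda: X lies in span(Z); conditional R² is 0")
    if n <= rank_x + rank_z + 1:
        raise ValueError("combined rank of X and Z too large for n")
    fitted = Qx @ (Qx.T @ Yr)
    residuals = Yr - fitted
    ss_tot = float((Yc ** 2).sum())
    ss_fit = float((fitted ** 2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    # semipartial adjusted fraction: adjR2(X u Z) - adjR2(Z)
    ss_z = float(((Qz @ (Qz.T @ Yc)) ** 2).sum())
    r2_union = (ss_z + ss_fit) / ss_tot if ss_tot > 0 else 0.0
    r2a = adjusted_r2(r2_union, n, rank_x + rank_z) - adjusted_r2(ss_z / ss_tot, n, rank_z)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > _RANK_TOL * max(s[0] if len(s) else 0.0, 1.0)
    scores = U[:, keep] * s[keep]
    axis_frac = (s[keep] ** 2) / ss_tot if ss_tot > 0 else s[keep] * 0.0
    df_res = n - rank_x - rank_z - 1
    ss_res = float((residuals ** 2).sum())
    f = (ss_fit / rank_x) / (ss_res / df_res) if rank_x > 0 and ss_res > 0 else np.inf
    return RdaFit(r2, r2a, rank_x, rank_z, fitted, residuals, scores, axis_frac, f, n)


def anova_permutation(Y, X, Z=None, n_perm: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Permutation pseudo-F test of (partial) RDA significance.

    Simple RDA permutes rows of Y freely; partial RDA permutes the
    residuals of Y on Z and re-adds the Z fit (reduced-model scheme).
    Returns (observed F, p) with p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    Yv = _values(Y)
    Yc = Yv - Yv.mean(axis=0)
    n = Yc.shape[0]
    if Z is None:
        fit = rda(Y, X)
        if not np.isfinite(fit.pseudo_f):
            raise ValueError("degenerate residual df for the permutation test")
        Q, rank = _orthobasis(_stack(X if isinstance(X, (list, tuple)) else [X]))
        df_res = n - rank - 1
        count = 0
        for _ in range(n_perm):
            Yp = Yc[rng.permutation(n)]
            ssf = float(((Q.T @ Yp) ** 2).sum())
            sst = float((Yp ** 2).sum())
            f = (ssf / rank) / ((sst - ssf) / df_res)
            if f >= fit.pseudo_f:
                count += 1
        return fit.pseudo_f, (1 + count) / (1 + n_perm)

    fit = partial_rda(Y, X, Z)
    if fit.rank_x == 0 or not np.isfinite(fit.pseudo_f):
        raise ValueError("degenerate partial model for the permutation test")
    Zv = _stack(Z if isinstance(Z, (list, tuple)) else [Z])
    Xv = _stack(X if isinstance(X, (list, tuple)) else [X])
    Qz, rank_z = _orthobasis(Zv)
    Xr = (Xv - Xv.mean(axis=0)) - Qz @ (Qz.T @ (Xv - Xv.mean(axis=0)))
    Qx, rank_x = _orthobasis(Xr)
    fit_z = Qz @ (Qz.T @ Yc)
    resid_z = Yc - fit_z
    df_res = n - rank_x - rank_z - 1
    count = 0
    for _ in range(n_perm):
        Rp = resid_z[rng.permutation(n)]
        Rp = Rp - Qz @ (Qz.T @ Rp)   # re-residualise the permuted residuals
        ssf = float(((Qx.T @ Rp) ** 2).sum())
        ssr = float((Rp ** 2).sum()) - ssf
        f = (ssf / rank_x) / (ssr / df_res)
        if f >= fit.pseudo_f:
            count += 1
    return fit.pseudo_f, (1 + count) / (1 + n_perm)


def _subset_key(names: tuple[str, ...]) -> str:
    return "&".join(sorted(names))


def varpart(
    Y,
    predictor_sets: dict[str, object],
    n_perm: int = 999,
    seed: int | None = None,
    test_fractions: bool = True,
) -> VarpartResult:
    """Variation partitioning of Y over up to four named predictor sets.

    Computes the adjusted R² of every non-empty union of sets, then
    solves the linear system relating union-R² values to the
    ``2^k - 1`` disjoint fractions, which is exact and guarantees the
    fractions sum to the full-model adjusted R².  Unique fractions and
    the full model get reduced-model permutation p-values.

    ``predictor_sets`` maps set name -> PredictorSet/array (a ``None``
    value degrades gracefully to a partition over the remaining sets).
    """
    sets = {k: v for k, v in predictor_sets.items() if v is not None}
    names = sorted(sets.keys())
    k = len(names)
    if k == 0:
        raise ValueError("no predictor sets supplied")
    if k > 4:
        raise ValueError("at most 4 predictor sets are supported")
    Yv = _values(Y)
    n = Yv.shape[0]

    subsets = [tuple(c) for r in range(1, k + 1) for c in combinations(names, r)]
    f_union: dict[tuple[str, ...], float] = {}
    for sub in subsets:
        fit = rda(Y, [sets[s] for s in sub])
        f_union[sub] = fit.r2_adj

    # atoms: fraction shared by exactly the sets in S; f(U) counts every atom
    # whose index set intersects U, giving an invertible 0/1 system
    A = np.zeros((len(subsets), len(subsets)))
    for i, U in enumerate(subsets):
        for j, S in enumerate(subsets):
            if set(U) & set(S):
                A[i, j] = 1.0
    b = np.array([f_union[U] for U in subsets])
    atoms = np.linalg.solve(A, b)

    full = tuple(names)
    fraction_table = {_subset_key(S): float(a) for S, a in zip(subsets, atoms)}
    full_adj = f_union[full]
    # enforce the sum identity to the last bit
    drift = full_adj - sum(fraction_table.values())
    fraction_table[_subset_key(full)] += drift
    residual = 1.0 - full_adj

    pvalues: dict[str, float] = {}
    if test_fractions:
        ss = np.random.SeedSequence(seed).spawn(k + 1)
        _, p_full = anova_permutation(Y, [sets[s] for s in names], None,
                                      n_perm=n_perm, seed=ss[0])
        pvalues["full_model"] = p_full
        for i, name in enumerate(names):
            others = [sets[s] for s in names if s != name]
            try:
                _, p = anova_permutation(Y, sets[name], others if others else None,
                                         n_perm=n_perm, seed=ss[i + 1])
            except ValueError as e:
                logger.warning("unique fraction of %s untestable: %s", name, e)
                p = float("nan")
            pvalues[name] = p

    return VarpartResult(names, fraction_table, residual, full_adj, pvalues)


def predict_fitted(Y, X) -> np.ndarray:
    """Fitted values of the RDA of Y on X (the spatially predicted matrix).

    This is the input to the neutrality diagnostic: the component of the
    (transformed) incidence matrix explained by the chosen predictor
    set, typically the union of broad- and fine-scale MEMs.
    """
    return rda(Y, X).fitted
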