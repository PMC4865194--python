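"""Community transforms and predictor construction.

Hellinger transformation of the incidence matrix, linear detrending on
geographic coordinates, greedy correlation pruning of climate
variables, correlation-matrix PCA for the climatic predictor set, and
dummy coding of categorical units for the geomorphological set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .community import CommunityMatrix

__all__ = [
    "PredictorSet",
    "PcaSummary",
    "hellinger",
    "detrend",
    "prune_correlated",
    "climate_pca",
    "dummy_code",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictorSet:
    """A named site x p predictor block aligned with the community matrix."""

    name: str
    columns: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("label count must match predictor columns")

    @property
    def n_sites(self) -> int:
        return self.columns.shape[0]

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        idx = pd.Index(cell_ids, name="cell_id") if cell_ids is not None else None
        return pd.DataFrame(self.columns, index=idx, columns=self.labels)


@dataclass
class PcaSummary:
    """Loadings and per-axis variance fractions of a correlation-matrix PCA."""

    loadings: pd.DataFrame  # variable x axis
    variance_fraction: np.ndarray
    n_axes_kept: int


def hellinger(cm: CommunityMatrix) -> CommunityMatrix:
    """Hellinger-transform: y'_ij = sqrt(y_ij / row_sum_i).

    Rows acquire unit Euclidean norm, which makes Euclidean-based
    ordination (RDA) appropriate for composition data.  A zero row is an
    error naming the offending cell.
    """
    Y = cm.values
    if np.any(Y < 0):
        raise ValueError("hellinger requires non-negative values")
    rs = Y.sum(axis=1)
    if np.any(rs <= 0):
        bad = cm.cell_ids[rs <= 0]
        raise ValueError(f"zero-sum rows (no species): cells {list(bad)}")
    return cm.with_values(np.sqrt(Y / rs[:, None]), "hellinger")


def detrend(cm: CommunityMatrix, coords: np.ndarray) -> CommunityMatrix:
    """Remove linear spatial trends: residuals of each column on centred (x, y).

    Returned columns are orthogonal to x, y and the constant.  Collinear
    coordinates (all sites on a line) are permitted — the regression is
    rank-deficient but well-posed via least squares; fully coincident
    sites are not.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (cm.n_sites, 2):
        raise ValueError("coords must be n_sites x 2 aligned with the matrix")
    Xc = coords - coords.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("all sites coincide; cannot detrend")
    design = np.column_stack([np.ones(cm.n_sites), Xc])
    beta, *_ = np.linalg.lstsq(design, cm.values, rcond=None)
    resid = cm.values - design @ beta
    return cm.with_values(resid, "detrended")


def prune_correlated(
    X: pd.DataFrame,
    threshold: float = 0.85,
    keep: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedily drop variables until no pair exceeds |Pearson r| > threshold.

    While any pair exceeds the threshold, the worst pair's lower-priority
    member is dropped.  Priority: variables named earlier in ``keep``
    outrank later ones; any listed variable outranks an unlisted one;
    otherwise column order decides (the later column goes).  Returns the
    retained table and the list of ``(dropped, kept, r)`` decisions.
    """
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    if (X.std(axis=0, ddof=1) == 0).any():
        const = X.columns[X.std(axis=0, ddof=1) == 0].tolist()
        raise ValueError(f"constant columns cannot be correlation-pruned: {const}")

    def priority(name: str) -> tuple:
        cols = list(X.columns)
        if keep and name in keep:
            return (0, keep.index(name))
        return (1, cols.index(name))

    retained = list(X.columns)
    dropped: list[tuple[str, str, float]] = []
    while len(retained) >= 2:
        corr = X[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r = corr[i, j]
        if abs(r) <= threshold:
            break
        a, b = retained[i], retained[j]
        loser = b if priority(a) < priority(b) else a
        winner = a if loser == b else b
        retained.remove(loser)
        dropped.append((loser, winner, float(r)))
        logger.info("prune_correlated: dropped %s (|r|=%.3f with %s)", loser, abs(r), winner)
    return X[retained], dropped


def climate_pca(X: pd.DataFrame, n_axes: int = 2) -> tuple[PredictorSet, PcaSummary]:
    """Correlation-matrix PCA of climate variables; scores become `Clim`.

    Variables are standardised to zero mean and unit variance, so the
    eigendecomposition is of the correlation matrix.  Loadings are the
    unit-norm eigenvectors, signed so each axis' largest-magnitude
    loading is positive; scores are the standardised data projected on
    them.
    """
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 sites")
    if n_axes > X.shape[1]:
        raise ValueError(f"n_axes={n_axes} exceeds {X.shape[1]} variables")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(n_components=X.shape[1])
    scores_all = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T  # variable x axis, unit-norm rows of components_
    # deterministic sign: largest-|loading| entry positive per axis
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores_all = scores_all * flip
    frac = pca.explained_variance_ratio_
    labels = [f"PC{k + 1}" for k in range(n_axes)]
    summary = PcaSummary(
        loadings=pd.DataFrame(loadings, index=X.columns,
                              columns=[f"PC{k + 1}" for k in range(loadings.shape[1])]),
        variance_fraction=frac,
        n_axes_kept=n_axes,
    )
    return PredictorSet("Clim", scores_all[:, :n_axes], labels), summary


def dummy_code(units: np.ndarray, name: str = "Geo") -> PredictorSet:
    """Dummy-code a categorical unit label: k levels -> k-1 indicators.

    The first level in sorted order is the reference; the design matrix
    has rank k-1 after centring, which is the degrees of freedom the
    adjusted-R² correction uses.
    """
    units = np.asarray(units)
    levels = sorted(np.unique(units).tolist())
    if len(levels) < 2:
        raise ValueError("dummy coding needs at least 2 levels (no variance otherwise)")
    cols = np.column_stack([(units == lv).astype(float) for lv in levels[1:]])
    labels = [f"unit_{lv}" for lv in levels[1:]]
    return PredictorSet(name, cols, labels)
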