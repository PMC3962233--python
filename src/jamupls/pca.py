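"""Covariance PCA of the plant-by-efficacy frequency matrix and biplots.

The frequency matrix counts, for each plant and efficacy class, how many
formulas of that class use the plant.  PCA is done on the column-centered
covariance matrix (divisor n-1, no variance scaling); biplot coordinates
place plants as points and efficacy classes as vectors so that projections
of points onto vectors approximate the centered counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, ScalingError, ShapeError
from .formulary import EfficacyLabels, PlantUsageMatrix, to_dummy

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "BiplotCoords",
    "build_frequency_matrix",
    "fit_pca",
    "variance_explained",
    "biplot_coords",
]


@dataclass(frozen=True)
class PCAModel:
    """Full eigendecomposition of the sample covariance of a data matrix.

    ``eigenvalues`` descend; ``eigenvectors`` has orthonormal columns with a
    deterministic sign (largest-absolute entry of each column positive);
    ``scores`` are the centered data projected on the eigenvectors.
    """

    column_means: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray

    @property
    def n_variables(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass(frozen=True)
class BiplotCoords:
    """2-D biplot: observation points G, variable vectors H, G @ H.T = rank-2 fit."""

    points: np.ndarray
    vectors: np.ndarray
    alpha: int


def build_frequency_matrix(
    usage: PlantUsageMatrix,
    labels: EfficacyLabels,
    class_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Plant x efficacy count matrix: cell (j, l) = formulas of class l using plant j."""
    if usage.formula_ids != labels.formula_ids:
        raise ShapeError("usage matrix and labels have different formula ids")
    if class_names is None:
        class_names = sorted(set(labels.labels))
    dummy = to_dummy(labels, class_names)
    counts = usage.X.T.astype(np.int64) @ dummy.Y.astype(np.int64)
    return pd.DataFrame(counts, index=list(usage.plant_ids), columns=list(dummy.class_names))


def fit_pca(A) -> PCAModel:
    """Eigendecompose the covariance of ``A`` (observations x variables)."""
    M = np.asarray(A, dtype=float)
    if isinstance(A, pd.DataFrame):
        M = A.to_numpy(dtype=float)
    if M.ndim != 2:
        raise ShapeError(f"expected a 2-D matrix, got {M.ndim}-D")
    n, p = M.shape
    if n < 2:
        raise FitError("PCA needs at least 2 observations")
    means = M.mean(axis=0)
    Mc = M - means
    V = (Mc.T @ Mc) / (n - 1)
    lam, C = np.linalg.eigh(V)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    C = C[:, order]
    # Sign convention: make each eigenvector's largest-|entry| positive.
    for j in range(p):
        k = int(np.argmax(np.abs(C[:, j])))
        if C[k, j] < 0:
            C[:, j] = -C[:, j]
    if lam.sum() == 0:
        logger.warning("constant input matrix: all eigenvalues are zero")
    Z = Mc @ C
    return PCAModel(column_means=means, eigenvalues=lam, eigenvectors=C, scores=Z)


def variance_explained(model: PCAModel, n_components: int) -> float:
    """Cumulative proportion of total variance captured by the leading components."""
    p = model.eigenvalues.size
    if not 1 <= n_components <= p:
        raise ShapeError(f"n_components must be in [1, {p}], got {n_components}")
    total = model.eigenvalues.sum()
    if total == 0:
        raise FitError("variance explained is undefined for an all-zero spectrum")
    return float(model.eigenvalues[:n_components].sum() / total)


def biplot_coords(model: PCAModel, dims: int = 2, alpha: int = 0) -> BiplotCoords:
    """Joint observation/variable coordinates in the leading ``dims`` components.

    ``alpha=0``: points are raw scores, vectors are eigenvector columns.
    ``alpha=1``: points are standardized scores, vectors are covariance-scaled
    loadings (vector length then tracks each variable's spread).  Both give
    the same rank-``dims`` reconstruction ``G @ H.T``.
    """
    p = model.n_variables
    if p < dims:
        raise ShapeError(f"cannot draw {dims}-D biplot with only {p} variables")
    if alpha not in (0, 1):
        raise ValueError(f"alpha must be 0 or 1, got {alpha}")
    Z = model.scores[:, :dims]
    C = model.eigenvectors[:, :dims]
    if alpha == 0:
        return BiplotCoords(points=Z.copy(), vectors=C.copy(), alpha=0)
    lam = model.eigenvalues[:dims]
    if np.any(lam <= 0):
        raise ScalingError("alpha=1 biplot requires positive eigenvalues in plotted dims")
    s = np.sqrt(lam)
    return BiplotCoords(points=Z / s, vectors=C * s, alpha=1)
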