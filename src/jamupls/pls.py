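"""Two-block PLS regression (NIPALS) and its discriminant-analysis wrapper.

``fit_pls`` implements NIPALS PLS2 on column-centered blocks.  Scores are
``T = X W~`` for the deflation-corrected weights; coefficients use the
corrected path ``B = W (P^T W)^{-1} Q^T`` so that ``Yhat = Xc B + y_means``
holds exactly.  ``deflation="weight"`` switches X-deflation from ``t p^T``
to ``t w^T``, the convention of the trilinear model, and is provided so the
two routes can be cross-checked against each other.

Classification assigns each observation to the class with the largest
predicted indicator value; ties break toward the lower class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ComponentError, FitError, LabelError, ShapeError

__all__ = [
    "PLSModel",
    "ConfusionMatrix",
    "fit_pls",
    "predict",
    "classify",
    "confusion",
    "cross_validate",
    "choose_components",
]


@dataclass(frozen=True)
class PLSModel:
    n_components: int
    weights: np.ndarray          # W, m x c (unit-norm columns)
    corrected_weights: np.ndarray  # W~, m x c; T = Xc @ W~
    x_loadings: np.ndarray       # P, m x c
    y_loadings: np.ndarray       # Q, p x c
    scores: np.ndarray           # T, n x c
    coefficients: np.ndarray     # B, m x p
    x_means: np.ndarray
    y_means: np.ndarray
    deflation: str = "loading"
    x_residuals: np.ndarray | None = None  # E
    y_residuals: np.ndarray | None = None  # F

    @property
    def n_predictors(self) -> int:
        return self.weights.shape[0]


def _nipals(Xc, Yc, n_components, deflation, tol, max_iter):
    n, m = Xc.shape
    p = Yc.shape[1]
    Xres = Xc.copy()
    W = np.empty((m, n_components))
    P = np.empty((m, n_components))
    Q = np.empty((p, n_components))
    T = np.empty((n, n_components))
    Yres = Yc.copy()
    B_inner = None
    for c in range(n_components):
        u = Yres[:, int(np.argmax(Yres.var(axis=0)))]
        if not np.any(u):
            u = Yres[:, 0]
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xres.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ComponentError(
                    f"X residual exhausted while extracting component {c + 1}"
                )
            w /= nw
            t_new = Xres @ w
            tt = t_new @ t_new
            if tt == 0:
                raise ComponentError(
                    f"zero score while extracting component {c + 1}"
                )
            q = Yres.T @ t_new / tt
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
            qq = q @ q
            u = Yres @ q / qq if qq > 0 else Yres[:, 0]
        tt = t @ t
        p_vec = Xres.T @ t / tt
        W[:, c], P[:, c], Q[:, c], T[:, c] = w, p_vec, q, t
        if deflation == "loading":
            Xres -= np.outer(t, p_vec)
        else:
            Xres -= np.outer(t, w)
        Tc = T[:, : c + 1]
        B_inner = np.linalg.solve(Tc.T @ Tc, Tc.T @ Yc)
        Yres = Yc - Tc @ B_inner
    return W, P, Q, T, Xres, Yres, B_inner


def _corrected_weights_projector(W: np.ndarray) -> np.ndarray:
    """W~_c = prod_{q<c} (I - w_q w_q^T) w_c, matching t w^T deflation."""
    m, C = W.shape
    Wt = np.empty_like(W)
    for c in range(C):
        v = W[:, c].copy()
        for q in range(c - 1, -1, -1):
            v -= W[:, q] * (W[:, q] @ v)
        Wt[:, c] = v
    return Wt


def fit_pls(
    X,
    Y,
    n_components: int,
    deflation: str = "loading",
    tol: float = 1e-12,
    max_iter: int = 500,
    keep_residuals: bool = False,
) -> PLSModel:
    """NIPALS PLS2 with both blocks column-centered.

    ``deflation="loading"`` (default) is the classical algorithm with
    orthogonal scores; ``"weight"`` deflates X by ``t w^T`` and corrects the
    weights with successive projectors, matching the trilinear module.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ShapeError("X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise ShapeError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    if deflation not in ("loading", "weight"):
        raise ValueError(f"unknown deflation {deflation!r}")
    n, m = X.shape
    if not 1 <= n_components <= min(n - 1, m):
        raise ComponentError(
            f"n_components must be in [1, {min(n - 1, m)}], got {n_components}"
        )
    if np.allclose(Y.var(axis=0), 0):
        raise FitError("Y has no variance; nothing to fit")
    x_means = X.mean(axis=0)
    y_means = Y.mean(axis=0)
    Xc = X - x_means
    Yc = Y - y_means
    W, P, Q, T, E, F, B_inner = _nipals(Xc, Yc, n_components, deflation, tol, max_iter)
    if deflation == "loading":
        Wt = W @ np.linalg.inv(P.T @ W)
        B = Wt @ Q.T
    else:
        Wt = _corrected_weights_projector(W)
        B = Wt @ B_inner
    return PLSModel(
        n_components=n_components,
        weights=W,
        corrected_weights=Wt,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coefficients=B,
        x_means=x_means,
        y_means=y_means,
        deflation=deflation,
        x_residuals=E if keep_residuals else None,
        y_residuals=F if keep_residuals else None,
    )


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Yhat = (X_new - x_means) @ B + y_means."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_predictors:
        raise ShapeError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_predictors}"
        )
    return (X_new - model.x_means) @ model.coefficients + model.y_means


def classify(Y_hat, class_names: Sequence[str]) -> tuple[str, ...]:
    """Row-wise argmax decision; ties break toward the lower class index."""
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y_hat.ndim == 1:
        Y_hat = Y_hat[None, :]
    if Y_hat.shape[1] != len(class_names):
        raise ShapeError(
            f"Y_hat has {Y_hat.shape[1]} columns for {len(class_names)} classes"
        )
    idx = np.argmax(Y_hat, axis=1)  # np.argmax returns the first (lowest) maximizer
    return tuple(class_names[i] for i in idx)


@dataclass(frozen=True)
class ConfusionMatrix:
    """L x L counts (rows = observed, columns = predicted) with percent summaries."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __init__(self, counts, class_names: Sequence[str]) -> None:
        arr = np.asarray(counts, dtype=np.int64)
        names = tuple(str(c) for c in class_names)
        if arr.shape != (len(names), len(names)):
            raise ShapeError(
                f"counts shape {arr.shape} does not match {len(names)} classes"
            )
        if (arr < 0).any():
            raise ValueError("confusion counts must be non-negative")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "class_names", names)

    @classmethod
    def from_counts(cls, counts, class_names: Sequence[str]) -> "ConfusionMatrix":
        return cls(counts, class_names)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def per_class_percent_correct(self) -> np.ndarray:
        """100 * diagonal / row total, rounded to 1 decimal (NaN for empty rows)."""
        rows = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * np.diag(self.counts) / rows
        return np.round(pct, 1)

    @property
    def overall_percent_correct(self) -> float:
        """100 * trace / grand total, rounded to 1 decimal."""
        if self.grand_total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.round(100.0 * self.trace / self.grand_total, 1))

    def to_table(self) -> pd.DataFrame:
        """Layout with observed rows, predicted columns, Total row/column and % Correct."""
        names = list(self.class_names)
        df = pd.DataFrame(self.counts, index=names, columns=names)
        df["Total"] = self.row_totals
        df["% Correct"] = self.per_class_percent_correct
        total_row = pd.Series(
            list(self.column_totals) + [self.grand_total, self.overall_percent_correct],
            index=df.columns,
            name="Total",
        )
        return pd.concat([df, total_row.to_frame().T])


def confusion(
    observed: Sequence[str],
    predicted: Sequence[str],
    class_names: Sequence[str],
) -> ConfusionMatrix:
    """Tally observed vs predicted labels over a fixed ordered class set."""
    if len(observed) != len(predicted):
        raise ShapeError(
            f"{len(observed)} observed labels vs {len(predicted)} predicted"
        )
    index = {c: l for l, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for o, p in zip(observed, predicted):
        if o not in index:
            raise LabelError(f"unseen observed label {o!r}")
        if p not in index:
            raise LabelError(f"unseen predicted label {p!r}")
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(counts, class_names)


def cross_validate(
    X,
    labels: Sequence[str],
    class_names: Sequence[str],
    n_components: int,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """K-fold cross-validated classification accuracy of the PLS-DA model."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = X.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must be in [2, {n}]")
    index = {c: l for l, c in enumerate(class_names)}
    Y = np.zeros((n, len(class_names)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    correct = 0
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        model = fit_pls(X[mask], Y[mask], n_components)
        pred = classify(predict(model, X[held]), class_names)
        correct += sum(pred[i] == labels[j] for i, j in enumerate(held))
    return correct / n


def choose_components(
    X,
    labels: Sequence[str],
    class_names: Sequence[str],
    max_components: int = 15,
    n_folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick the component count maximizing CV accuracy over 1..min(max, rank)."""
    X = np.asarray(X, dtype=float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    upper = max(1, min(max_components, rank, X.shape[0] - 1))
    best_c, best_acc = 1, -1.0
    for c in range(1, upper + 1):
        acc = cross_validate(X, labels, class_names, c, n_folds=n_folds, seed=seed)
        if acc > best_acc:
            best_c, best_acc = c, acc
    return best_c
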