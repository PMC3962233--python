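"""Trilinear PLS regression on an observations x plants x activities tensor.

Each component factorizes the unfolded predictor block into an observation
score and a pair of unit-norm mode weights (plants, activities) chosen to
maximize covariance with the response score: the J x K reshape of
``X_unfolded^T y_u`` is decomposed by SVD and its leading singular vectors
are the mode weights.  The unfolded weight of a component is the Kronecker
product ``w_K (x) w_J``, matching the activity-major column order of the
unfolding.  X is deflated by ``t w^T``, so scores can be recovered from the
original unfolded block through successive-projector corrected weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ComponentError, ConvergenceError, FitError, ShapeError
from .formulary import DummyResponse, UsageTensor, fold, matricize
from .pls import classify

__all__ = [
    "NPLSModel",
    "SignificanceMatrix",
    "fit_npls",
    "build_corrected_weights",
    "predict_npls",
    "activity_significance",
]

#: Weight-magnitude cutoff for calling an activity significant; the rule of
#: thumb it is borrowed from is stated for sample sizes of 350 or more.
WEIGHT_THRESHOLD = 0.3
MIN_SAMPLE_FOR_THRESHOLD = 350


@dataclass(frozen=True)
class NPLSModel:
    n_components: int
    shape: tuple[int, int, int]          # (I, J, K) of the training tensor
    plant_weights: np.ndarray            # W^J, J x C, unit-norm columns
    activity_weights: np.ndarray         # W^K, K x C, unit-norm columns
    combined_weights: np.ndarray         # JK x C, columns w_c = w^K_c (x) w^J_c
    corrected_weights: np.ndarray        # JK x C; T = Xc_unfolded @ this
    scores: np.ndarray                   # T, I x C
    y_scores: np.ndarray                 # V, I x C
    y_weights: np.ndarray                # U, L x C (unit-norm columns)
    inner_coefficients: np.ndarray       # C x L, regression of Y on T
    coefficients: np.ndarray             # B_NPLS, JK x L
    x_means: np.ndarray                  # JK
    y_means: np.ndarray                  # L
    x_residuals: np.ndarray | None = None  # I x J x K tensor
    y_residuals: np.ndarray | None = None  # I x L

    @property
    def n_plants(self) -> int:
        return self.plant_weights.shape[0]

    @property
    def n_activities(self) -> int:
        return self.activity_weights.shape[0]

    def coefficients_tensor(self) -> np.ndarray:
        """B_NPLS reshaped to J x K x L."""
        J, K = self.n_plants, self.n_activities
        L = self.coefficients.shape[1]
        return self.coefficients.reshape(K, J, L).transpose(1, 0, 2)


def build_corrected_weights(W_combined: np.ndarray) -> np.ndarray:
    """Deflation correction: W~_c = (I - w_1 w_1^T)...(I - w_{c-1} w_{c-1}^T) w_c."""
    W = np.asarray(W_combined, dtype=float)
    Wt = np.empty_like(W)
    for c in range(W.shape[1]):
        v = W[:, c].copy()
        for q in range(c - 1, -1, -1):
            v -= W[:, q] * (W[:, q] @ v)
        Wt[:, c] = v
    return Wt


def _as_unfolded(X3) -> tuple[np.ndarray, int, int]:
    if isinstance(X3, UsageTensor):
        arr = X3.X3.astype(float)
    else:
        arr = np.asarray(X3, dtype=float)
    if arr.ndim != 3:
        raise ShapeError(f"expected a 3-D tensor, got {arr.ndim}-D")
    _, J, K = arr.shape
    return matricize(arr), J, K


def _as_response(Y) -> np.ndarray:
    if isinstance(Y, DummyResponse):
        return Y.Y.astype(float)
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ShapeError(f"response must be 1-D or 2-D, got {arr.ndim}-D")
    return arr


def fit_npls(
    X3,
    Y,
    n_components: int,
    tol: float = 1e-12,
    max_iter: int = 2000,
    keep_residuals: bool = False,
) -> NPLSModel:
    """Fit a trilinear PLS model with ``n_components`` latent components.

    ``X3`` is an I x J x K array (or :class:`UsageTensor`); ``Y`` an I x L
    matrix, :class:`DummyResponse`, or a single response vector.  The
    unfolded X is column-centered; Y is column-centered.
    """
    Xu, J, K = _as_unfolded(X3)
    Yf = _as_response(Y)
    I = Xu.shape[0]
    if Yf.shape[0] != I:
        raise ShapeError(f"X has {I} observations but Y has {Yf.shape[0]}")
    if not 1 <= n_components <= min(I - 1, J * K):
        raise ComponentError(
            f"n_components must be in [1, {min(I - 1, J * K)}], got {n_components}"
        )
    if np.allclose(Yf.var(axis=0), 0):
        raise FitError("Y has no variance; nothing to fit")
    x_means = Xu.mean(axis=0)
    y_means = Yf.mean(axis=0)
    Xc = Xu - x_means
    Yc = Yf - y_means
    L = Yc.shape[1]

    Xres = Xc.copy()
    Yres = Yc.copy()
    WJ = np.empty((J, n_components))
    WK = np.empty((K, n_components))
    Wcomb = np.empty((J * K, n_components))
    T = np.empty((I, n_components))
    V = np.empty((I, n_components))
    U = np.empty((L, n_components))
    B_inner = None

    for c in range(n_components):
        col = int(np.argmax(Yres.var(axis=0)))
        u = Yres[:, col]
        if not np.any(u):
            raise ComponentError(
                f"Y residual exhausted while extracting component {c + 1}"
            )
        t = np.zeros(I)
        q = np.zeros(L)
        converged = False
        for _ in range(max_iter):
            z = Xres.T @ u
            if not np.any(z):
                raise ComponentError(
                    f"X residual exhausted while extracting component {c + 1}"
                )
            Z = z.reshape(K, J).T  # J x K, Z[j, k] = sum_i X_ijk u_i
            Um, _, Vm = np.linalg.svd(Z, full_matrices=False)
            wJ = Um[:, 0]
            wK = Vm[0]
            # sign convention: largest-|entry| of wJ positive; flip wK along
            # with wJ so the combined weight (and hence t) is unchanged
            k = int(np.argmax(np.abs(wJ)))
            if wJ[k] < 0:
                wJ, wK = -wJ, -wK
            w = np.kron(wK, wJ)
            t_new = Xres @ w
            nq = Yres.T @ t_new
            nqn = np.linalg.norm(nq)
            q = nq / nqn if nqn > 0 else nq
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                converged = True
                break
            t = t_new
            u = Yres @ q
        if not converged:
            raise ConvergenceError(
                f"component {c + 1} did not converge in {max_iter} iterations"
            )
        WJ[:, c], WK[:, c], Wcomb[:, c], T[:, c] = wJ, wK, w, t
        U[:, c] = q
        V[:, c] = Yres @ q
        Xres -= np.outer(t, w)
        Tc = T[:, : c + 1]
        B_inner = np.linalg.solve(Tc.T @ Tc, Tc.T @ Yc)
        Yres = Yc - Tc @ B_inner

    Wt = build_corrected_weights(Wcomb)
    B_npls = Wt @ B_inner
    return NPLSModel(
        n_components=n_components,
        shape=(I, J, K),
        plant_weights=WJ,
        activity_weights=WK,
        combined_weights=Wcomb,
        corrected_weights=Wt,
        scores=T,
        y_scores=V,
        y_weights=U,
        inner_coefficients=B_inner,
        coefficients=B_npls,
        x_means=x_means,
        y_means=y_means,
        x_residuals=fold(Xres, J, K) if keep_residuals else None,
        y_residuals=Yres if keep_residuals else None,
    )


def predict_npls(model: NPLSModel, X3_new) -> np.ndarray:
    """Yhat = (matricize(X3_new) - x_means) @ B_NPLS + y_means."""
    Xu, J, K = _as_unfolded(X3_new)
    if (J, K) != (model.n_plants, model.n_activities):
        raise ShapeError(
            f"tensor modes (J={J}, K={K}) do not match model "
            f"(J={model.n_plants}, K={model.n_activities})"
        )
    return (Xu - model.x_means) @ model.coefficients + model.y_means


def classify_npls(model: NPLSModel, X3_new, class_names: Sequence[str]) -> tuple[str, ...]:
    return classify(predict_npls(model, X3_new), class_names)


@dataclass(frozen=True)
class SignificanceMatrix:
    """Binary K x L activity-by-efficacy significance calls with evidence values."""

    S: np.ndarray
    evidence: np.ndarray
    threshold: float
    activity_ids: tuple[str, ...]
    class_names: tuple[str, ...]


def activity_significance(
    X3,
    Y,
    n_components: int = 2,
    threshold: float = WEIGHT_THRESHOLD,
    mode: str = "one-vs-rest",
    activity_ids: Sequence[str] | None = None,
    class_names: Sequence[str] | None = None,
) -> SignificanceMatrix:
    """Flag activities whose absolute activity-mode weight reaches ``threshold``.

    ``mode="one-vs-rest"`` (default) fits one binary-response trilinear model
    per efficacy class; the evidence for activity k against class l is the
    maximum of ``|w^K_kc|`` over that model's components, and the call is
    inclusive (evidence == threshold is significant).  ``mode="joint"`` fits
    a single multi-response model and attributes each component to the class
    with the largest |Y-weight|.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    Yf = _as_response(Y)
    I = Yf.shape[0]
    L = Yf.shape[1]
    if isinstance(X3, UsageTensor):
        K = len(X3.activity_ids)
        if activity_ids is None:
            activity_ids = X3.activity_ids
    else:
        K = np.asarray(X3).shape[2]
    if activity_ids is None:
        activity_ids = tuple(f"A{k + 1}" for k in range(K))
    if class_names is None:
        if isinstance(Y, DummyResponse):
            class_names = Y.class_names
        else:
            class_names = tuple(f"C{l + 1}" for l in range(L))
    if I < MIN_SAMPLE_FOR_THRESHOLD:
        warnings.warn(
            f"|w^K| >= {threshold} significance rule is stated for sample sizes "
            f">= {MIN_SAMPLE_FOR_THRESHOLD}; got {I}",
            stacklevel=2,
        )

    evidence = np.zeros((K, L))
    if mode == "one-vs-rest":
        for l in range(L):
            model = fit_npls(X3, Yf[:, l], n_components)
            evidence[:, l] = np.abs(model.activity_weights).max(axis=1)
    elif mode == "joint":
        model = fit_npls(X3, Yf, n_components)
        owner = np.argmax(np.abs(model.y_weights), axis=0)  # class per component
        for c in range(n_components):
            l = int(owner[c])
            evidence[:, l] = np.maximum(evidence[:, l], np.abs(model.activity_weights[:, c]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    S = (evidence >= threshold).astype(np.int8)
    return SignificanceMatrix(
        S=S,
        evidence=evidence,
        threshold=float(threshold),
        activity_ids=tuple(str(a) for a in activity_ids),
        class_names=tuple(str(c) for c in class_names),
    )
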