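"""Permutation test on PLS-DA coefficients to find main-ingredient plants.

The null distribution is built by permuting whole response rows (each
formula keeps its one-hot dummy row, rows are shuffled against the fixed
predictor block) and refitting the model with identical settings.  P-values
are two-sided on |b| with the add-one convention, so p >= 1/(B+1) > 0 and
the test is exact under exchangeability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, ShapeError
from .pls import fit_pls

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "permutation_null",
    "coef_pvalues",
    "permutation_test",
    "significant_plants",
    "significance_histogram",
    "histogram_percentages",
    "benjamini_hochberg",
    "summary_table",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_B: np.ndarray       # m x L coefficients of the unpermuted fit
    p_values: np.ndarray         # m x L in (0, 1]
    n_permutations: int
    alpha: float
    seed: int
    significant: np.ndarray      # m x L binary, p <= alpha (after optional FDR)
    plant_ids: tuple[str, ...]
    class_names: tuple[str, ...]
    fdr: bool = False


def permutation_null(
    X,
    Y,
    n_components: int,
    n_permutations: int,
    seed: int = 0,
    max_resample: int = 100,
) -> np.ndarray:
    """Null coefficient samples of shape (n_permutations, m, L).

    Each replicate permutes Y's rows uniformly at random and refits PLS-DA
    with identical settings.  A degenerate permuted fit is resampled (and
    logged); this cannot happen from row permutation alone but guards
    against pathological inputs.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ShapeError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    out = np.empty((n_permutations, X.shape[1], Y.shape[1]))
    for b in range(n_permutations):
        for attempt in range(max_resample):
            perm = rng.permutation(n)
            try:
                model = fit_pls(X, Y[perm], n_components)
            except FitError:
                logger.warning("degenerate permuted fit at replicate %d; resampling", b)
                continue
            out[b] = model.coefficients
            break
        else:
            raise FitError(f"replicate {b} degenerate after {max_resample} resamples")
    return out


def coef_pvalues(observed_B, null_samples) -> np.ndarray:
    """p_jl = (1 + #{|b*_jl| >= |b_jl|}) / (B + 1), two-sided via absolute values."""
    observed_B = np.asarray(observed_B, dtype=float)
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.shape[1:] != observed_B.shape:
        raise ShapeError(
            f"null sample shape {null_samples.shape[1:]} does not match "
            f"observed {observed_B.shape}"
        )
    B = null_samples.shape[0]
    exceed = (np.abs(null_samples) >= np.abs(observed_B)[None]).sum(axis=0)
    return (1.0 + exceed) / (B + 1.0)


def benjamini_hochberg(p_values: np.ndarray, alpha: float) -> np.ndarray:
    """Binary rejection matrix under BH step-up control at level ``alpha``."""
    flat = np.asarray(p_values, dtype=float).ravel()
    m = flat.size
    order = np.argsort(flat)
    ranked = flat[order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    passing = np.flatnonzero(ranked <= thresh)
    reject = np.zeros(m, dtype=np.int8)
    if passing.size:
        reject[order[: passing[-1] + 1]] = 1
    return reject.reshape(np.asarray(p_values).shape)


def permutation_test(
    X,
    Y,
    n_components: int,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    fdr: bool = False,
    plant_ids: Sequence[str] | None = None,
    class_names: Sequence[str] | None = None,
) -> PermutationResult:
    """Observed fit + permutation null + p-values + significance calls."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    observed = fit_pls(X, Y, n_components).coefficients
    null = permutation_null(X, Y, n_components, n_permutations, seed=seed)
    p = coef_pvalues(observed, null)
    if fdr:
        sig = benjamini_hochberg(p, alpha)
    else:
        sig = (p <= alpha).astype(np.int8)
    if plant_ids is None:
        plant_ids = tuple(f"P{j + 1}" for j in range(X.shape[1]))
    if class_names is None:
        class_names = tuple(f"C{l + 1}" for l in range(Y.shape[1]))
    return PermutationResult(
        observed_B=observed,
        p_values=p,
        n_permutations=n_permutations,
        alpha=alpha,
        seed=seed,
        significant=sig,
        plant_ids=tuple(str(x) for x in plant_ids),
        class_names=tuple(str(x) for x in class_names),
        fdr=fdr,
    )


def significant_plants(
    result: PermutationResult,
) -> tuple[dict[str, list[str]], np.ndarray]:
    """Per-efficacy significant plant lists and the per-plant count histogram.

    The histogram entry h[g] counts plants significant for exactly g
    efficacies, g = 0..L; it partitions the plant set (sums to m).
    """
    sig = result.significant
    per_class = {
        cls: [result.plant_ids[j] for j in np.flatnonzero(sig[:, l])]
        for l, cls in enumerate(result.class_names)
    }
    counts_per_plant = sig.sum(axis=1)
    L = sig.shape[1]
    hist = np.bincount(counts_per_plant, minlength=L + 1)
    return per_class, hist


def significance_histogram(significant: np.ndarray) -> np.ndarray:
    """Histogram of per-row significance counts from a binary m x L matrix."""
    sig = np.asarray(significant)
    return np.bincount(sig.sum(axis=1), minlength=sig.shape[1] + 1)


def histogram_percentages(hist: Sequence[int]) -> np.ndarray:
    """Share of plants at each significance count, as percentages to 1 decimal."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total == 0:
        raise ValueError("empty histogram")
    return np.round(100.0 * hist / total, 1)


def summary_table(result: PermutationResult) -> pd.DataFrame:
    """Per-efficacy count of significant plants (layout of the printed summary)."""
    per_class, _ = significant_plants(result)
    return pd.DataFrame(
        {"Efficacy": list(result.class_names),
         "Total": [len(per_class[c]) for c in result.class_names]}
    )
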