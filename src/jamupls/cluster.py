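"""Ward-linkage hierarchical clustering and the activity-efficacy clustergram.

``ward_cluster`` is an explicit Lance-Williams implementation on Euclidean
input.  Merge heights use the Ward-objective (variance) convention: the
height of a merge is the increase in total within-cluster sum of squares it
causes, which for singletons i, j equals ||x_i - x_j||^2 / 2.  Ties break
toward the lowest cluster-index pair, so output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, ShapeError

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageTree",
    "ClustergramResult",
    "ward_cluster",
    "leaf_order",
    "to_newick",
    "cophenetic_matrix",
    "clustergram",
]


@dataclass(frozen=True)
class LinkageTree:
    """Agglomeration record: (cluster_a, cluster_b, height, size) per merge.

    Leaves are clusters 0..n-1; the merge at step s creates cluster n+s
    (scipy-style ids).  Heights are Ward-objective increases and are
    monotone non-decreasing.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def ward_cluster(rows, labels: Sequence[str] | None = None) -> LinkageTree:
    """Agglomerative Ward linkage on the Euclidean geometry of ``rows``."""
    M = np.asarray(rows, dtype=float)
    if isinstance(rows, pd.DataFrame):
        M = rows.to_numpy(dtype=float)
        if labels is None:
            labels = [str(i) for i in rows.index]
    if M.ndim != 2:
        raise ShapeError(f"expected a 2-D matrix of row vectors, got {M.ndim}-D")
    n = M.shape[0]
    if n < 2:
        raise FitError("need at least 2 rows to cluster")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ShapeError(f"{len(labels)} labels for {n} rows")

    # D[a, b] = Ward merge cost of active clusters a, b (ids 0..2n-2).
    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    diff = M[:, None, :] - M[None, :, :]
    D0 = 0.5 * np.einsum("ijk,ijk->ij", diff, diff)
    D[:n, :n] = D0
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    merges = []
    for step in range(n - 1):
        # lowest-index pair among exact ties
        best = (np.inf, None)
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                if D[a, b] < best[0]:
                    best = (D[a, b], (a, b))
        height, (a, b) = best
        new = n + step
        sizes[new] = sizes[a] + sizes[b]
        for k in active:
            if k in (a, b):
                continue
            # Lance-Williams update in the Ward-objective form
            D[new, k] = D[k, new] = (
                (sizes[a] + sizes[k]) * D[a, k]
                + (sizes[b] + sizes[k]) * D[b, k]
                - sizes[k] * D[a, b]
            ) / (sizes[a] + sizes[b] + sizes[k])
        active = [k for k in active if k not in (a, b)] + [new]
        merges.append((int(a), int(b), float(height), int(sizes[new])))
    return LinkageTree(merges=tuple(merges), labels=labels)


def _children(tree: LinkageTree) -> dict[int, tuple[int, int]]:
    n = tree.n_leaves
    return {n + s: (m[0], m[1]) for s, m in enumerate(tree.merges)}


def _heights(tree: LinkageTree) -> dict[int, float]:
    n = tree.n_leaves
    h = {i: 0.0 for i in range(n)}
    for s, m in enumerate(tree.merges):
        h[n + s] = m[2]
    return h


def leaf_order(tree: LinkageTree) -> list[int]:
    """Left-to-right leaf indices of the dendrogram."""
    children = _children(tree)
    root = tree.n_leaves + len(tree.merges) - 1
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node in children:
            a, b = children[node]
            stack.append(b)
            stack.append(a)
        else:
            order.append(node)
    return order


def to_newick(tree: LinkageTree, precision: int = 10) -> str:
    """Newick serialization; branch length = parent height - child height."""
    children = _children(tree)
    heights = _heights(tree)
    fmt = f"%.{precision}g"

    def render(node: int, parent_height: float) -> str:
        length = fmt % (parent_height - heights[node])
        if node in children:
            a, b = children[node]
            inner = f"({render(a, heights[node])},{render(b, heights[node])})"
            return f"{inner}:{length}"
        return f"{tree.labels[node]}:{length}"

    root = tree.n_leaves + len(tree.merges) - 1
    if root in children:
        a, b = children[root]
        return f"({render(a, heights[root])},{render(b, heights[root])});"
    return f"{tree.labels[root]};"


def cophenetic_matrix(tree: LinkageTree) -> np.ndarray:
    """n x n matrix of the merge height at which each leaf pair first joins."""
    n = tree.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    for s, (a, b, h, _) in enumerate(tree.merges):
        for i in members[a]:
            for j in members[b]:
                C[i, j] = C[j, i] = h
        members[n + s] = members.pop(a) + members.pop(b)
    return C


@dataclass(frozen=True)
class ClustergramResult:
    row_tree: LinkageTree
    col_tree: LinkageTree
    matrix: pd.DataFrame          # reordered by dendrogram leaf orders
    dropped_rows: tuple[str, ...]


def clustergram(S, row_ids: Sequence[str] | None = None,
                col_ids: Sequence[str] | None = None) -> ClustergramResult:
    """Cluster rows and columns of a binary significance matrix independently.

    Rows with no significant cell are dropped (and logged) before
    clustering; the returned matrix is reordered by both dendrograms.
    """
    from .npls import SignificanceMatrix

    if isinstance(S, SignificanceMatrix):
        df = pd.DataFrame(S.S, index=list(S.activity_ids), columns=list(S.class_names))
    elif isinstance(S, pd.DataFrame):
        df = S.copy()
    else:
        M = np.asarray(S)
        if row_ids is None:
            row_ids = [f"R{i + 1}" for i in range(M.shape[0])]
        if col_ids is None:
            col_ids = [f"C{j + 1}" for j in range(M.shape[1])]
        df = pd.DataFrame(M, index=list(row_ids), columns=list(col_ids))
    if not np.isin(df.to_numpy(), (0, 1)).all():
        raise ShapeError("clustergram expects a binary significance matrix")

    keep = df.sum(axis=1) > 0
    dropped = tuple(df.index[~keep])
    if dropped:
        logger.info("dropping %d all-zero rows: %s", len(dropped), ", ".join(dropped[:10]))
    df = df.loc[keep]
    if df.shape[0] == 0:
        raise FitError("no rows left after dropping all-zero rows")
    row_tree = ward_cluster(df.to_numpy(dtype=float), labels=list(df.index))
    col_tree = ward_cluster(df.to_numpy(dtype=float).T, labels=list(df.columns))
    rorder = [df.index[i] for i in leaf_order(row_tree)]
    corder = [df.columns[j] for j in leaf_order(col_tree)]
    return ClustergramResult(
        row_tree=row_tree,
        col_tree=col_tree,
        matrix=df.loc[rorder, corder],
        dropped_rows=dropped,
    )
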