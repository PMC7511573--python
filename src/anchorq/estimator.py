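"""Semi-supervised q-vector estimation by exhaustive Boolean subset search.

The estimation problem: a test contains K *anchor* items whose q-vectors
are the columns of an expert-specified reachability matrix R, plus items
with unknown q-vectors.  Given the observed N x K anchor response block X
and an unknown item's response column Y, the q-vector estimate is built in
two steps:

1. search all 2^K - 1 non-empty subsets S of anchor columns for the one
   whose combined response — entrywise AND of ``X[:, S]`` under the
   conjunctive (DINA) gate, entrywise OR under the disjunctive (DINO)
   gate — is closest to Y in Hamming distance;
2. expand the winning subset into a q-vector by entrywise OR of the
   corresponding reachability columns.

The Hamming distance here equals the squared Euclidean distance between
binary vectors, so the integer count is the exact loss; no floating point
enters the argmin.  Subsets are enumerated by cardinality and then
lexicographically, and the first minimum wins, so ties resolve to the
smallest, lexicographically earliest subset (parsimony + determinism).

With noise-free data over a rich enough profile set, the minimizer
recovers the true q-vector exactly for both gates — the executable content
of the identifiability theory for independent attributes: AND/OR
combinations of anchor ideal-response columns are in bijection with OR
combinations of reachability columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import MODELS, gate_for_model
from .structures import as_binary_array, expand_subset

__all__ = [
    "ENUMERATION_CAP",
    "SubsetSolution",
    "nonempty_subsets",
    "combine_anchor_columns",
    "subset_loss",
    "estimate_qvector",
    "estimate_qmatrix",
]

#: refuse to enumerate more than 2^ENUMERATION_CAP subsets without an override
ENUMERATION_CAP = 20


@dataclass(frozen=True)
class SubsetSolution:
    """Estimate for one unknown item.

    Attributes
    ----------
    item : int
        Position of the item within the unknown block (0-based).
    subset : tuple of int
        Winning subset of anchor-column indices, 0-based, sorted.
    loss : int
        Hamming distance between the item's responses and the combined
        anchor responses of ``subset``; 0 <= loss <= N.
    q_hat : numpy.ndarray
        OR-expansion of ``subset`` over the reachability columns.
    runner_up : tuple of int | None
        Second-best subset in enumeration order (diagnostic only).
    runner_up_loss : int | None
    """

    item: int
    subset: tuple[int, ...]
    loss: int
    q_hat: np.ndarray = field(repr=False)
    runner_up: tuple[int, ...] | None = None
    runner_up_loss: int | None = None

    @property
    def loss_gap(self) -> int | None:
        """Margin between the runner-up loss and the winning loss."""
        if self.runner_up_loss is None:
            return None
        return self.runner_up_loss - self.loss

    @property
    def subset_1based(self) -> tuple[int, ...]:
        """The winning subset with attribute labels counted from 1 (A1..AK)."""
        return tuple(i + 1 for i in self.subset)


def nonempty_subsets(K: int, cap: int = ENUMERATION_CAP) -> list[tuple[int, ...]]:
    """All non-empty subsets of {0..K-1}, ordered by cardinality then lexicographically."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > cap:
        raise ValueError(
            f"K={K} would enumerate 2^{K} subsets; raise `cap` explicitly to override"
        )
    return [
        subset
        for size in range(1, K + 1)
        for subset in itertools.combinations(range(K), size)
    ]


def combine_anchor_columns(X, subset: Sequence[int], model: str) -> np.ndarray:
    """Entrywise AND (DINA) or OR (DINO) of the selected anchor response columns."""
    gate = gate_for_model(model)
    X = as_binary_array(X, "anchor block", ndim=2)
    idx = sorted(set(int(i) for i in subset))
    if not idx:
        raise ValueError("subset must be non-empty")
    if idx[0] < 0 or idx[-1] >= X.shape[1]:
        raise ValueError(f"subset indices must lie in [0, {X.shape[1] - 1}], got {idx}")
    cols = X[:, idx]
    return cols.min(axis=1) if gate == "conjunctive" else cols.max(axis=1)


def subset_loss(X, y, subset: Sequence[int], model: str) -> int:
    """Hamming distance between *y* and the combined anchor columns of *subset*.

    Equals the binary quadratic form (y - c)^T (y - c) with c the AND/OR
    combination, evaluated as an exact integer count.
    """
    y = as_binary_array(y, "response column", ndim=1)
    combined = combine_anchor_columns(X, subset, model)
    if combined.shape != y.shape:
        raise ValueError(f"column length {y.shape[0]} != anchor block rows {combined.shape[0]}")
    return int(np.count_nonzero(combined != y))


def _prediction_matrix(X: np.ndarray, subsets: list[tuple[int, ...]], model: str) -> np.ndarray:
    gate = gate_for_model(model)
    op = np.min if gate == "conjunctive" else np.max
    return np.stack([op(X[:, list(sub)], axis=1) for sub in subsets], axis=1)


def _solve_columns(
    X: np.ndarray, Y: np.ndarray, R: np.ndarray, model: str, cap: int
) -> list[SubsetSolution]:
    """Exhaustive search for every column of Y at once."""
    K = R.shape[1]
    subsets = nonempty_subsets(K, cap=cap)
    preds = _prediction_matrix(X, subsets, model)  # (N, n_subsets)
    # losses[s, j] = Hamming(prediction of subset s, item j)
    losses = (preds[:, :, None] != Y[:, None, :]).sum(axis=0)
    solutions = []
    for j in range(Y.shape[1]):
        order = np.argsort(losses[:, j], kind="stable")  # first minimum wins
        best = int(order[0])
        runner = int(order[1]) if len(order) > 1 else None
        solutions.append(
            SubsetSolution(
                item=j,
                subset=subsets[best],
                loss=int(losses[best, j]),
                q_hat=expand_subset(R, subsets[best]),
                runner_up=subsets[runner] if runner is not None else None,
                runner_up_loss=int(losses[runner, j]) if runner is not None else None,
            )
        )
    return solutions


def estimate_qvector(X, y, R, model: str, cap: int = ENUMERATION_CAP) -> SubsetSolution:
    """Estimate one unknown item's q-vector from anchor responses.

    Parameters
    ----------
    X : array-like of shape (N, K)
        Observed responses to the K anchor items, aligned with R's columns.
    y : array-like of shape (N,)
        Observed responses to the unknown item.
    R : array-like of shape (K, K)
        Reachability matrix whose columns are the anchor q-vectors.
    model : {"dina", "dino"}
    cap : int
        Enumeration cap on K (the search is O(2^K)).

    Returns
    -------
    SubsetSolution
        Global minimizer over all non-empty subsets; ties broken toward
        the smallest, lexicographically earliest subset.
    """
    if model.lower() not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    X = as_binary_array(X, "anchor block", ndim=2)
    y = as_binary_array(y, "response column", ndim=1)
    R = as_binary_array(R, "reachability matrix", ndim=2)
    if X.shape[1] != R.shape[1]:
        raise ValueError(
            f"anchor block has {X.shape[1]} columns but R has {R.shape[1]}"
        )
    if y.shape[0] != X.shape[0]:
        raise ValueError("response column length must match the anchor block rows")
    return _solve_columns(X, y[:, None], R, model.lower(), cap)[0]


def estimate_qmatrix(
    U,
    R,
    model: str,
    anchor_cols: Sequence[int] | None = None,
    cap: int = ENUMERATION_CAP,
) -> tuple[np.ndarray, list[SubsetSolution]]:
    """Estimate the q-vectors of every non-anchor column of a response matrix.

    Each unknown column is estimated independently by
    :func:`estimate_qvector`; nothing is shared across items beyond the
    anchor block itself.

    Parameters
    ----------
    U : array-like of shape (N, K + M)
        Observed response matrix; anchor columns identified by *anchor_cols*
        (default: the first K columns, K taken from R).
    R : array-like of shape (K, K)
        Reachability matrix.
    model : {"dina", "dino"}
    anchor_cols : sequence of int, optional
        0-based positions of the anchor columns within U.

    Returns
    -------
    Q_hat : numpy.ndarray of shape (K, M)
        Estimated q-vectors of the unknown items, in U's column order.
    solutions : list of SubsetSolution
        Per-item diagnostics (winning subset, loss, runner-up, loss gap).
    """
    if model.lower() not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    U = as_binary_array(U, "response matrix", ndim=2)
    R = as_binary_array(R, "reachability matrix", ndim=2)
    K = R.shape[1]
    if anchor_cols is None:
        anchor_cols = range(K)
    anchor_cols = [int(i) for i in anchor_cols]
    if len(anchor_cols) != K:
        raise ValueError(
            f"anchor block must have exactly K={K} columns, got {len(anchor_cols)}"
        )
    unknown_cols = [j for j in range(U.shape[1]) if j not in set(anchor_cols)]
    if not unknown_cols:
        raise ValueError("response matrix has no non-anchor columns to estimate")
    X = U[:, anchor_cols]
    Y = U[:, unknown_cols]
    solutions = _solve_columns(X, Y, R, model.lower(), cap)
    Q_hat = np.stack([sol.q_hat for sol in solutions], axis=1)
    return Q_hat, solutions
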