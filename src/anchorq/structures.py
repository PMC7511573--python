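"""Boolean algebra of attribute hierarchies, Q-matrices and ideal responses.

Cognitive diagnosis models describe test items in terms of K binary latent
skills ("attributes").  A Q-matrix is a K x J binary incidence matrix whose
entry ``q[k, j] = 1`` says item *j* requires attribute *k*; a column of the
Q-matrix is an item's *q-vector*.  This module follows Tatsuoka's
orientation throughout: Q-matrices are stored attributes x items, and
mastery profiles are the rows of an ``(n, K)`` array.

The structural objects of the theory are all built here:

* the reachability matrix ``R = (A + I)^K`` (Boolean powers of the
  prerequisite adjacency matrix ``A``), whose columns serve as the
  q-vectors of the expert-specified anchor items;
* the student matrix (all 2^K admissible mastery profiles under an
  independent structure) and the reduced Q-matrix (all 2^K - 1 non-zero
  q-vectors);
* the "augment" operation: expanding a subset of reachability columns
  into a q-vector by entrywise logical OR;
* deterministic ("ideal") item responses under the conjunctive gate
  (correct iff *every* required attribute is mastered) and the disjunctive
  gate (correct iff *at least one* required attribute is mastered).

The canonical column order of the student and reduced matrices is binary
counting with attribute 1 as the least significant bit, i.e. attribute 1
toggles fastest: for K=2 the student columns are (0,0), (1,0), (0,1),
(1,1).  This matches the order in which the worked examples of the
literature print these matrices and makes file outputs deterministic.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GATES",
    "as_binary_array",
    "boolean_matmul",
    "reachability_from_adjacency",
    "is_reachability_matrix",
    "student_matrix",
    "reduced_qmatrix",
    "expand_subset",
    "ideal_responses",
]

GATES = ("conjunctive", "disjunctive")

#: enumerating 2^K columns above this K is almost certainly a mistake
ENUMERATION_WARN_K = 20


def as_binary_array(a, name: str = "array", ndim: int | None = None) -> np.ndarray:
    """Validate that *a* contains only 0/1 entries and return it as int8."""
    arr = np.asarray(a)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))].ravel()[0]
        raise ValueError(f"{name} must contain only 0/1 entries (found {bad!r})")
    if ndim is not None and arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr.astype(np.int8)


def boolean_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix product over the Boolean semiring (OR of ANDs)."""
    return ((a.astype(np.int64) @ b.astype(np.int64)) > 0).astype(np.int8)


def reachability_from_adjacency(A) -> np.ndarray:
    """Boolean closure ``R = (A + I)^K`` of a prerequisite adjacency matrix.

    ``A[k1, k2] = 1`` encodes a direct prerequisite relation from attribute
    *k1* to attribute *k2*.  The result is reflexive (unit diagonal) and
    transitively closed; its columns are the q-vectors of anchor items that
    probe each attribute together with everything reachable from it.  For
    independent attributes (``A = 0``) the reachability matrix is the
    identity.

    Parameters
    ----------
    A : array-like of shape (K, K)
        Binary adjacency matrix with zero diagonal.

    Returns
    -------
    numpy.ndarray of shape (K, K), int8
    """
    A = as_binary_array(A, "adjacency matrix", ndim=2)
    K = A.shape[0]
    if A.shape[1] != K:
        raise ValueError(f"adjacency matrix must be square, got shape {A.shape}")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency matrix must have a zero diagonal")
    base = (A | np.eye(K, dtype=np.int8)).astype(np.int8)
    R = np.eye(K, dtype=np.int8)
    for _ in range(K):
        R = boolean_matmul(R, base)
    return R


def is_reachability_matrix(R) -> bool:
    """True iff *R* is binary, square, reflexive and Boolean-transitively closed."""
    try:
        R = as_binary_array(R, "matrix", ndim=2)
    except ValueError:
        return False
    if R.shape[0] != R.shape[1]:
        return False
    if np.any(np.diag(R) != 1):
        return False
    return bool(np.array_equal(boolean_matmul(R, R), R))


def _check_k(K) -> int:
    if not isinstance(K, (int, np.integer)) or isinstance(K, bool):
        raise ValueError(f"K must be a positive integer, got {K!r}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > ENUMERATION_WARN_K:
        warnings.warn(
            f"enumerating 2^{K} attribute patterns; this is exponential in K",
            RuntimeWarning,
            stacklevel=3,
        )
    return int(K)


def student_matrix(K: int) -> np.ndarray:
    """All 2^K mastery profiles as columns of a K x 2^K binary matrix.

    Columns are in binary-counting order with attribute 1 (row 0) as the
    least significant bit, so the zero profile comes first and attribute 1
    toggles fastest: for K=2 the columns read (0,0), (1,0), (0,1), (1,1).
    """
    K = _check_k(K)
    codes = np.arange(2**K, dtype=np.int64)
    return ((codes[None, :] >> np.arange(K)[:, None]) & 1).astype(np.int8)


def reduced_qmatrix(K: int) -> np.ndarray:
    """The 2^K - 1 non-zero q-vectors, i.e. the student matrix minus its zero column.

    Under an independent attribute structure this is the full reduced
    Q-matrix: every q-vector consistent with the (trivial) hierarchy.
    Column order is inherited from :func:`student_matrix`.
    """
    return student_matrix(K)[:, 1:]


def _check_subset(subset: Iterable[int], K: int) -> tuple[int, ...]:
    idx = tuple(sorted(set(int(i) for i in subset)))
    if not idx:
        raise ValueError("subset must be non-empty (the empty set is excluded from the search)")
    if idx[0] < 0 or idx[-1] >= K:
        raise ValueError(f"subset indices must lie in [0, {K - 1}], got {idx}")
    return idx


def expand_subset(R, subset: Sequence[int]) -> np.ndarray:
    """Entrywise OR of the selected columns of a reachability matrix.

    This is the augment operation: any reduced-Q column can be written as
    the disjunction of some reachability columns.  Indices are 0-based.
    """
    R = as_binary_array(R, "reachability matrix", ndim=2)
    idx = _check_subset(subset, R.shape[1])
    return R[:, list(idx)].max(axis=1)


def ideal_responses(Q, profiles, gate: str = "conjunctive") -> np.ndarray:
    """Deterministic latent responses of mastery profiles to Q-matrix items.

    Under the conjunctive gate the latent response eta is 1 iff the profile
    masters every attribute the item requires; under the disjunctive gate
    the latent response w is 1 iff it masters at least one required
    attribute.  An item requiring no attributes has eta = 1 and w = 0 for
    every profile (empty-product convention of the two gate definitions).

    Parameters
    ----------
    Q : array-like of shape (K, J)
        Q-matrix, attributes x items.
    profiles : array-like of shape (n, K)
        Mastery profiles as rows.
    gate : {"conjunctive", "disjunctive"}

    Returns
    -------
    numpy.ndarray of shape (n, J), int8
        Row i, column j holds the latent response of profile i to item j.
    """
    if gate not in GATES:
        raise ValueError(f"gate must be one of {GATES}, got {gate!r}")
    Q = as_binary_array(Q, "Q-matrix", ndim=2)
    P = np.asarray(profiles)
    if P.ndim == 1:
        P = P[None, :]
    P = as_binary_array(P, "profiles", ndim=2)
    if P.shape[1] != Q.shape[0]:
        raise ValueError(
            f"profiles have {P.shape[1]} attributes but the Q-matrix has {Q.shape[0]} rows"
        )
    counts = P.astype(np.int64) @ Q.astype(np.int64)  # mastered-and-required per item
    if gate == "conjunctive":
        L = counts == Q.sum(axis=0, dtype=np.int64)[None, :]
    else:
        L = counts > 0
    return L.astype(np.int8)
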