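"""Small worked-example bundles used throughout the tests and docs.

Three classical worked examples of the Boolean Q-matrix theory plus one
seeded noisy bundle.  The matrices are stored as literals (not recomputed
through the library) so they can serve as independent expected values.

Note on ``example2``: the disjunctive-gate latent response matrix computed
directly from the gate definition differs from the version sometimes
printed alongside this example, which coincides with the conjunctive B of
``example1`` (a profile mastering either attribute answers the q=(1,1)
item correctly under the OR gate).  Both are returned: ``W`` is the
recomputed matrix, ``W_printed`` the (likely typographical) variant.
"""

from __future__ import annotations

import numpy as np

from .models import simulate_responses
from .structures import student_matrix

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("example1", "example2", "example3", "toy_noisy")


def _example1() -> dict:
    R = np.array([[1, 0], [0, 1]], dtype=np.int8)
    Q_r = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
    Q_s = np.array([[0, 1, 0, 1], [0, 0, 1, 1]], dtype=np.int8)
    B = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]], dtype=np.int8
    )  # rows = profiles of Q_s, columns = items of Q_r, conjunctive gate
    return {"K": 2, "R": R, "Q_r": Q_r, "Q_s": Q_s, "B": B}


def _example2() -> dict:
    bundle = _example1()
    # disjunctive gate on the same matrices, evaluated from the definition
    W = np.array([[0, 0, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int8)
    W_printed = bundle.pop("B")
    bundle.update({"W": W, "W_printed": W_printed})
    return bundle


def _example3() -> dict:
    # K = 3 unstructured hierarchy: attribute 1 is prerequisite to 2 and 3
    A = np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=np.int8)
    R = np.array([[1, 1, 1], [0, 1, 0], [0, 0, 1]], dtype=np.int8)
    Q_r = np.array([[1, 1, 1, 1], [0, 1, 0, 1], [0, 0, 1, 1]], dtype=np.int8)
    Q_s = np.array(
        [[0, 1, 1, 1, 1], [0, 0, 1, 0, 1], [0, 0, 0, 1, 1]], dtype=np.int8
    )
    B = np.array(
        [
            [0, 0, 0, 0],
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    return {"K": 3, "A": A, "R": R, "Q_r": Q_r, "Q_s": Q_s, "B": B}


def _toy_noisy(seed: int = 7) -> dict:
    """Seeded K=2 noisy bundle for estimator smoke tests (synthetic)."""
    K = 2
    R = np.eye(K, dtype=np.int8)
    Q_r = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
    Q_t = np.concatenate([R, Q_r], axis=1)
    rng = np.random.default_rng(seed)
    profiles = student_matrix(K).T[rng.integers(0, 4, size=50)]
    U = simulate_responses(Q_t, profiles, 0.1, 0.1, "dina", rng)
    return {
        "K": K,
        "R": R,
        "Q_r": Q_r,
        "Q_t": Q_t,
        "profiles": profiles,
        "U": U,
        "seed": seed,
        "model": "dina",
    }


def make_fixture(name: str) -> dict:
    """Return one of the named bundles as a dict of numpy arrays."""
    builders = {
        "example1": _example1,
        "example2": _example2,
        "example3": _example3,
        "toy_noisy": _toy_noisy,
    }
    try:
        return builders[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
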