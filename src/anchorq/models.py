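"""Stochastic layer: DINA/DINO response probabilities, sampling designs, simulation.

The DINA ("deterministic inputs, noisy AND") and DINO ("deterministic
inputs, noisy OR") models wrap a deterministic latent response in
item-level noise.  With latent response L (eta for DINA, w for DINO),

    P(X = 1 | alpha) = (1 - s)   if L = 1,
                       g         if L = 0,

where s is the slip probability (wrong answer despite having the skills)
and g the guess probability (right answer without them).

Two examinee sampling designs are provided:

* ``random`` — profiles drawn i.i.d. uniformly from all 2^K patterns;
* ``optimal`` — profiles drawn with replacement from the K patterns that
  maximally discriminate candidate q-vectors: ``1 - e_k`` (all skills but
  one) for DINA, ``e_k`` (exactly one skill) for DINO.  These are the
  profiles used in the identifiability arguments for the two gates.
"""

from __future__ import annotations

import warnings

import numpy as np

from .structures import as_binary_array, ideal_responses, student_matrix

__all__ = [
    "MODELS",
    "DESIGNS",
    "gate_for_model",
    "validate_item_params",
    "design_support",
    "sample_profiles",
    "response_probability",
    "simulate_responses",
]

MODELS = ("dina", "dino")
DESIGNS = ("random", "optimal")

_GATE = {"dina": "conjunctive", "dino": "disjunctive"}


def gate_for_model(model: str) -> str:
    """Map a model name to its deterministic gate (DINA->AND, DINO->OR)."""
    try:
        return _GATE[model.lower()]
    except KeyError:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}") from None


def validate_item_params(s, g, n_items: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Validate slip/guess parameters; broadcast scalars to per-item arrays.

    Requires 0 <= s, g < 1.  Items with s + g >= 1 respond anti-monotonely
    (mastery lowers the success probability); this is permitted but flagged
    with a warning.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if n_items is not None:
        s = np.broadcast_to(s, (n_items,)).copy() if s.size in (1, n_items) else s
        g = np.broadcast_to(g, (n_items,)).copy() if g.size in (1, n_items) else g
        if s.shape != (n_items,) or g.shape != (n_items,):
            raise ValueError(
                f"expected {n_items} slip/guess values, got {s.size} and {g.size}"
            )
    if np.any((s < 0) | (s >= 1)) or np.any((g < 0) | (g >= 1)):
        raise ValueError("slip and guess probabilities must lie in [0, 1)")
    if np.any(s + g >= 1):
        warnings.warn(
            "some items have s + g >= 1: mastery lowers the success probability",
            UserWarning,
            stacklevel=2,
        )
    return s, g


def design_support(design: str, model: str, K: int) -> np.ndarray:
    """Profiles a design samples from, as rows of an (n_support, K) array.

    random  -> all 2^K patterns; optimal/DINA -> {1 - e_k}; optimal/DINO -> {e_k}.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")
    gate = gate_for_model(model)  # validates the model name
    if design == "random":
        return student_matrix(K).T.copy()
    if gate == "conjunctive":
        return (1 - np.eye(K, dtype=np.int8)).astype(np.int8)
    return np.eye(K, dtype=np.int8)


def sample_profiles(design: str, model: str, K: int, n: int, rng) -> np.ndarray:
    """Draw *n* profiles i.i.d. uniformly (with replacement) from the design support."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    support = design_support(design, model, K)
    idx = rng.integers(0, support.shape[0], size=n)
    return support[idx]


def response_probability(alpha, q, s: float, g: float, model: str) -> float:
    """P(correct) of one profile on one item: 1 - s if the gate fires, g otherwise."""
    gate = gate_for_model(model)
    s_arr, g_arr = validate_item_params(s, g, n_items=1)
    q = np.asarray(q)
    latent = ideal_responses(q.reshape(-1, 1), np.asarray(alpha).reshape(1, -1), gate)[0, 0]
    return float(1.0 - s_arr[0]) if latent else float(g_arr[0])


def simulate_responses(Q, profiles, s, g, model: str, rng) -> np.ndarray:
    """Simulate a binary N x J response matrix under DINA or DINO.

    Each response is an independent Bernoulli draw: a uniform u is compared
    with the item response probability and the answer is correct when
    u <= P.  With s = g = 0 the output equals the ideal response matrix
    bit for bit.

    Parameters
    ----------
    Q : array-like of shape (K, J)
        Test Q-matrix, attributes x items.
    profiles : array-like of shape (N, K)
        Examinee mastery profiles as rows.
    s, g : scalar or array-like of length J
        Per-item slip and guess probabilities.
    model : {"dina", "dino"}
    rng : int | numpy.random.Generator
        Seed or generator; fixed seeds give bit-reproducible output.
    """
    gate = gate_for_model(model)
    Q = as_binary_array(Q, "Q-matrix", ndim=2)
    J = Q.shape[1]
    s, g = validate_item_params(s, g, n_items=J)
    rng = np.random.default_rng(rng)
    L = ideal_responses(Q, profiles, gate)
    p = np.where(L == 1, 1.0 - s[None, :], g[None, :])
    u = rng.random(L.shape)
    return (u <= p).astype(np.int8)
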