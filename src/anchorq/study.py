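"""Monte-Carlo recovery study: condition grid, replication management, CRR tables.

The study design crosses five factors: sample size N (30, 60, ..., 300),
slip/guess level of the K anchor items (0, 0.05, ..., 0.45), slip/guess
level of the unknown items (same levels), model (DINA/DINO) and sampling
design (random/optimal), with K = 5 independent attributes throughout and
30 replications per condition.  A "level" x sets s_j = g_j = x for every
item in its block.  Each replication builds the test Q-matrix
``Q_t = [I_5 | Q_r]`` where Q_r is the full 31-column reduced Q-matrix,
simulates responses, estimates all 31 unknown q-vectors from the anchor
block, and scores the correct recovery rate

    CRR = (1 / (K * M)) * sum_{k,j} 1{q_hat[k, j] == q[k, j]},

the fraction of matching entries between the estimated and true reduced
Q-matrices (M = 31 for K = 5).

Reproducibility: every replication's generator is seeded with the tuple
(master seed, model, design, N, anchor level, unknown level, replication
index), so any single cell of any table can be replayed exactly,
independently of scheduling or of which other cells ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .estimator import estimate_qmatrix
from .models import DESIGNS, MODELS, sample_profiles, simulate_responses
from .structures import reduced_qmatrix

__all__ = [
    "PARAM_LEVELS",
    "SAMPLE_SIZES",
    "DEFAULT_K",
    "DEFAULT_REPLICATIONS",
    "SimulationCondition",
    "RecoveryResult",
    "crr",
    "replication_rng",
    "run_replication",
    "run_condition",
    "run_grid",
    "parameter_table",
    "sample_size_table",
]

#: slip/guess levels of the study grid
PARAM_LEVELS = tuple(round(0.05 * i, 2) for i in range(10))
#: examinee sample sizes of the study grid
SAMPLE_SIZES = tuple(range(30, 301, 30))
DEFAULT_K = 5
DEFAULT_REPLICATIONS = 30

_MODEL_CODE = {m: i for i, m in enumerate(MODELS)}
_DESIGN_CODE = {d: i for i, d in enumerate(DESIGNS)}


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the study grid."""

    model: str = "dina"
    design: str = "random"
    n: int = 300
    anchor_level: float = 0.0
    unknown_level: float = 0.0
    k: int = DEFAULT_K
    replications: int = DEFAULT_REPLICATIONS
    master_seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if self.n < 1 or self.k < 1 or self.replications < 1:
            raise ValueError("n, k and replications must all be >= 1")
        for lvl in (self.anchor_level, self.unknown_level):
            if not 0.0 <= lvl < 0.5:
                raise ValueError(f"slip/guess level must lie in [0, 0.5), got {lvl}")


@dataclass
class RecoveryResult:
    """Per-replication CRR values of one condition, with their summary."""

    condition: SimulationCondition
    crrs: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.crrs))

    @property
    def sd(self) -> float:
        """Sample SD (ddof=1) of the replication CRR values."""
        if len(self.crrs) < 2:
            return float("nan")
        return float(np.std(self.crrs, ddof=1))


def crr(Q_hat, Q_true) -> float:
    """Correct recovery rate: fraction of matching entries of two K x M matrices."""
    Q_hat = np.asarray(Q_hat)
    Q_true = np.asarray(Q_true)
    if Q_hat.shape != Q_true.shape:
        raise ValueError(f"shape mismatch: {Q_hat.shape} vs {Q_true.shape}")
    return float(np.mean(Q_hat == Q_true))


def replication_rng(cond: SimulationCondition, rep: int) -> np.random.Generator:
    """Deterministic child generator for replication *rep* of a condition."""
    seq = np.random.SeedSequence(
        [
            int(cond.master_seed),
            _MODEL_CODE[cond.model],
            _DESIGN_CODE[cond.design],
            int(cond.n),
            int(round(cond.anchor_level * 100)),
            int(round(cond.unknown_level * 100)),
            int(rep),
        ]
    )
    return np.random.default_rng(seq)


def run_replication(cond: SimulationCondition, rep: int) -> float:
    """Simulate -> estimate -> score one replication; returns its CRR."""
    K = cond.k
    R = np.eye(K, dtype=np.int8)
    Q_r = reduced_qmatrix(K)
    M = Q_r.shape[1]
    Q_t = np.concatenate([R, Q_r], axis=1)
    level = np.concatenate(
        [np.full(K, cond.anchor_level), np.full(M, cond.unknown_level)]
    )
    rng = replication_rng(cond, rep)
    profiles = sample_profiles(cond.design, cond.model, K, cond.n, rng)
    U = simulate_responses(Q_t, profiles, level, level, cond.model, rng)
    Q_hat, _ = estimate_qmatrix(U, R, cond.model)
    return crr(Q_hat, Q_r)


def run_condition(cond: SimulationCondition) -> RecoveryResult:
    """Run all replications of one condition."""
    values = np.array([run_replication(cond, r) for r in range(cond.replications)])
    return RecoveryResult(condition=cond, crrs=values)


def run_grid(
    models: Sequence[str] = ("dina",),
    designs: Sequence[str] = ("random",),
    ns: Iterable[int] = SAMPLE_SIZES,
    anchor_levels: Iterable[float] = PARAM_LEVELS,
    unknown_levels: Iterable[float] = PARAM_LEVELS,
    replications: int = DEFAULT_REPLICATIONS,
    master_seed: int = 0,
    k: int = DEFAULT_K,
    on_replication: Callable[[dict], None] | None = None,
) -> pd.DataFrame:
    """Run a (sub)grid of conditions; one row per replication in the result.

    Returns a long-format DataFrame with columns ``model, design, n,
    anchor_level, unknown_level, rep, crr``.  Cells are mutually
    independent given the master seed, so any scheduling (or any subset of
    the grid) reproduces the same values.  ``on_replication`` is called
    with each row dict as it is produced (structured logging hook).
    """
    records: list[dict] = []
    for model in models:
        for design in designs:
            for n in ns:
                for a in anchor_levels:
                    for u in unknown_levels:
                        cond = SimulationCondition(
                            model=model,
                            design=design,
                            n=int(n),
                            anchor_level=float(a),
                            unknown_level=float(u),
                            k=k,
                            replications=replications,
                            master_seed=master_seed,
                        )
                        for rep in range(replications):
                            row = {
                                "model": model,
                                "design": design,
                                "n": int(n),
                                "anchor_level": float(a),
                                "unknown_level": float(u),
                                "rep": rep,
                                "crr": run_replication(cond, rep),
                            }
                            records.append(row)
                            if on_replication is not None:
                                on_replication(row)
    return pd.DataFrame.from_records(records)


def parameter_table(df: pd.DataFrame, model: str, design: str, n: int) -> pd.DataFrame:
    """Anchor-level x unknown-level table of mean CRR, with marginal means.

    Rows are anchor (reachability-matrix) item levels, columns are
    unknown-item levels; the trailing row/column "M" hold unweighted
    marginal means of the cells (equivalently the pooled replication mean,
    as every cell has the same replication count).
    """
    sub = df[(df["model"] == model) & (df["design"] == design) & (df["n"] == n)]
    if sub.empty:
        raise ValueError(f"no rows for model={model}, design={design}, n={n}")
    table = sub.pivot_table(
        index="anchor_level", columns="unknown_level", values="crr", aggfunc="mean"
    )
    table["M"] = table.mean(axis=1)
    table.loc["M"] = table.mean(axis=0)
    table.index.name = "anchor_level"
    table.columns.name = "unknown_level"
    return table


def sample_size_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-N summary across the parameter grid, one (mean, sd) pair per model x design.

    The SD pools the raw replication CRR values of every parameter
    combination at that N (not the per-condition SDs); the trailing "Mean"
    row pools all sample sizes.
    """
    pieces = {}
    for (model, design), sub in df.groupby(["model", "design"]):
        by_n = sub.groupby("n")["crr"].agg(["mean", "std"])
        by_n.loc["Mean"] = [sub["crr"].mean(), sub["crr"].std()]
        pieces[(model, design)] = by_n
    out = pd.concat(pieces, axis=1)
    out.columns.names = ["model", "design", "stat"]
    return out
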