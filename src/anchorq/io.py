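"""CSV readers/writers and run configuration.

All matrices are stored as strict 0/1 integers in plain CSV with a header
row and a label column, so round trips are lossless.  Two Q-matrix
orientations exist in the literature: the traditional attributes x items
layout and the now-common items x attributes layout.  Files default to
rows = items, columns = attributes; pass ``attributes_in_rows=True`` to
read/write the transposed (attributes x items) layout.  In memory,
Q-matrices are always attributes x items and response matrices are always
examinees x items.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_binary_matrix",
    "write_binary_matrix",
    "read_qmatrix",
    "write_qmatrix",
    "read_responses",
    "write_responses",
    "RunConfig",
]


def read_binary_matrix(path) -> pd.DataFrame:
    """Read a labelled CSV of strict 0/1 entries.

    Raises
    ------
    ValueError
        Naming the offending row/column label if any cell is not 0 or 1,
        or if rows are ragged.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV (ragged rows?): {exc}") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = ~values.isin([0, 1]) | values.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-binary value {df.loc[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
    return df.astype(np.int8)


def write_binary_matrix(df: pd.DataFrame, path) -> None:
    """Write a labelled binary matrix as 0/1 integers."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.astype(int).to_csv(path)


def _default_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def read_qmatrix(path, attributes_in_rows: bool = False) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a Q-matrix CSV; returns (K x J array, attribute labels, item labels).

    Default file layout is rows = items, columns = attributes; with
    ``attributes_in_rows=True`` the file is already attributes x items.
    The in-memory array is attributes x items either way.
    """
    df = read_binary_matrix(path)
    if not attributes_in_rows:
        df = df.T
    return (
        df.to_numpy(dtype=np.int8),
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
    )


def write_qmatrix(
    Q,
    path,
    attributes_in_rows: bool = False,
    attribute_labels: list[str] | None = None,
    item_labels: list[str] | None = None,
) -> None:
    """Write an attributes x items Q-matrix, honouring the orientation flag."""
    Q = np.asarray(Q)
    K, J = Q.shape
    attrs = attribute_labels or _default_labels("A", K)
    items = item_labels or _default_labels("item", J)
    df = pd.DataFrame(Q, index=attrs, columns=items)
    if not attributes_in_rows:
        df = df.T
    write_binary_matrix(df, path)


def read_responses(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an examinees x items response CSV; returns (array, examinee, item labels)."""
    df = read_binary_matrix(path)
    return (
        df.to_numpy(dtype=np.int8),
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
    )


def write_responses(
    U,
    path,
    examinee_labels: list[str] | None = None,
    item_labels: list[str] | None = None,
) -> None:
    U = np.asarray(U)
    n, J = U.shape
    df = pd.DataFrame(
        U,
        index=examinee_labels or _default_labels("e", n),
        columns=item_labels or _default_labels("item", J),
    )
    write_binary_matrix(df, path)


@dataclass
class RunConfig:
    """Configuration of one study run; round-trips losslessly through YAML."""

    model: str = "dina"
    design: str = "random"
    k: int = 5
    n: int = 300
    anchor_level: float = 0.0
    unknown_level: float = 0.0
    replications: int = 30
    seed: int = 0
    responses: str | None = None
    reachability: str | None = None
    out: str | None = None
    attributes_in_rows: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
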