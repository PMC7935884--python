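"""On-disk formats and run configuration.

TSV is the canonical format (gene identifiers and condition labels may
contain commas); CSV is accepted on read by file extension. Floats are
serialized with shortest-round-trip representations, so write-then-read
returns bit-identical values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, SchemaError

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_report",
    "load_run_config",
    "config_hash",
]

EVENT_COLUMNS = ("event_id", "tof", "extinction", "green", "red", "condition", "replicate")
NUMERIC_EVENT_COLUMNS = ("tof", "extinction", "green", "red")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise DataError(f"input file is empty: {path}")
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if len(table) == 0:
        raise DataError(f"input table has a header but no rows: {path}")
    return table


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read a flow-event table, validating schema and numeric channels."""
    table = _read_table(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table {path} is missing columns: {missing}")
    for col in NUMERIC_EVENT_COLUMNS:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise SchemaError(
                f"non-numeric value {table[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row} of {path}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise SchemaError(f"missing value in column {col!r} at line {row} of {path}")
        if (numeric < 0).any():
            raise SchemaError(f"negative values in channel column {col!r} of {path}")
        table[col] = numeric
    if (table["condition"].isna() | (table["condition"] == "")).any():
        raise SchemaError(f"empty condition labels in {path}")
    if (table["replicate"].isna() | (table["replicate"] == "")).any():
        raise SchemaError(f"empty replicate labels in {path}")
    return table


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"cannot write event table lacking columns: {missing}")
    events.to_csv(path, sep=_sep_for(path), index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample matrix; first column is the gene id."""
    table = _read_table(path)
    gene_col = table.columns[0]
    if table[gene_col].duplicated().any():
        dupes = table[gene_col][table[gene_col].duplicated()].head(3).tolist()
        raise SchemaError(f"duplicate gene ids in {path}: {dupes}")
    matrix = table.set_index(gene_col)
    matrix.index.name = "gene_id"
    for col in matrix.columns:
        numeric = pd.to_numeric(matrix[col], errors="coerce")
        bad = numeric.isna() & matrix[col].notna() & (matrix[col].str.lower() != "nan")
        if bad.any():
            pos = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(
                f"non-numeric value in sample column {col!r} at line {pos} of {path}"
            )
        matrix[col] = numeric
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    out = matrix.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep=_sep_for(path), index=True)


def write_report(results: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV (or CSV by extension)."""
    path = Path(path)
    results.to_csv(path, sep=_sep_for(path), index=False)


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain mapping."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such config file: {path}")
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise DataError(f"config {path} must be a mapping, got {type(config).__name__}")
    return dict(config)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for run logs."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
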