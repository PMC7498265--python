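"""Tab-separated table I/O and provenance records.

All matrices are written as TSV with cell identifiers in the first column
and gene/exon identifiers in the header; long tables keep their column
headers.  Writers and readers round-trip byte-identically (floats use
repr-precision via pandas' default formatting with explicit float_format).
Provenance records are flat ``key: value`` text files with a config hash
sufficient to re-execute a run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_table",
    "write_provenance",
    "read_provenance",
    "config_hash",
]


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "cell_id") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(record: dict) -> str:
    payload = json.dumps(record, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(record: dict, path: str | Path) -> None:
    lines = [f"config_hash: {config_hash(record)}"]
    for key in sorted(record):
        lines.append(f"{key}: {json.dumps(record[key], default=str)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_provenance(path: str | Path) -> dict:
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(": ")
        if key == "config_hash":
            out[key] = value
            continue
        out[key] = json.loads(value)
    return out
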