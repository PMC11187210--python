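"""Delimited-table I/O for compendia, metadata and regulon databases.

All tables are plain text (TSV or CSV, dialect auto-detected from the
header line), features as rows and samples as columns, lossless to
1e-12 on round trip.  Reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compendium import METADATA_COLUMNS


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples numeric table (first column = ids)."""
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed table ({exc})") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature identifiers {dup}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate sample identifiers")
    non_numeric = [
        c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)
    ]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    return df


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    sep = _detect_sep(path)
    meta = pd.read_csv(path, sep=sep)
    missing = [c for c in ("sample_id", "condition_id", "is_reference") if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id {dup}")
    if "batch" not in meta.columns:
        meta["batch"] = "batch0"
    meta["is_reference"] = (
        meta["is_reference"].astype(str).str.lower().isin(["true", "1", "yes"])
    )
    return meta


def write_metadata(meta: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = [c for c in METADATA_COLUMNS if c in meta.columns] + [
        c for c in meta.columns if c not in METADATA_COLUMNS
    ]
    meta[cols].to_csv(path, sep=sep, index=False)


def read_regulon_db(path) -> dict:
    """Two-column regulator/gene table -> {regulator: set of genes}."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in df.columns]
    if "regulator" in cols and "gene" in cols:
        df.columns = cols
    elif df.shape[1] == 2:
        df.columns = ["regulator", "gene"]
    else:
        raise ValueError(f"{path}: expected columns regulator, gene")
    db: dict[str, set] = {}
    for _, row in df.iterrows():
        db.setdefault(str(row["regulator"]), set()).add(str(row["gene"]))
    return db


def write_regulon_db(db: dict, path, sep: str = "\t") -> None:
    rows = [(reg, gene) for reg in sorted(db) for gene in sorted(db[reg])]
    pd.DataFrame(rows, columns=["regulator", "gene"]).to_csv(
        path, sep=sep, index=False
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
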