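"""Reading and writing the pipeline's tabular formats.

One dialect throughout: tab-delimited UTF-8 with a header row and no
quoting.  Counts files carry ``gene_id`` as the first column followed by
one column per sample; metadata files carry ``sample_id``, ``tissue``,
``stage``, ``batch``, ``replicate``.  Gene ids are opaque strings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import REQUIRED_META_COLUMNS, CountMatrix, ValidationError


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV (first column gene_id) into a genes x samples frame."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValidationError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene id(s): {dups[:10]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.floor(values)):
        raise ValidationError(f"{path}: counts must be integers")
    if np.any(values < 0):
        raise ValidationError(f"{path}: counts must be non-negative")
    return df.astype(np.int64)


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample ids")
    missing = [c for c in REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: metadata missing columns {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return df


def load_count_matrix(counts_path, metadata_path) -> CountMatrix:
    counts = read_counts(counts_path)
    meta = read_metadata(metadata_path)
    uncovered = [s for s in counts.columns if s not in meta.index]
    if uncovered:
        raise ValidationError(
            f"metadata does not cover sample(s): {uncovered[:10]}"
        )
    return CountMatrix(counts=counts, sample_meta=meta)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
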