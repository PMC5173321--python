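"""Plain-text readers and writers for the pipeline's tabular and sequence formats.

All formats are TSV, FASTA or JSON so that runs are diffable and portable:
counts (first column ``cluster_id``, one column per sample), sample sheets,
truth tables, cluster maps, equivalence classes, annotation tables and DE
result tables.  Validation errors name the offending file and entry.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

SAMPLE_SHEET_COLUMNS = ["sample_id", "dataset", "condition", "timepoint_h", "gate", "replicate"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a cluster x sample count matrix; counts must be non-negative integers."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "cluster_id":
        raise SchemaError(f"{path}: first column must be 'cluster_id', got {df.columns[0]!r}")
    df = df.set_index("cluster_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate cluster id {dup!r}")
    if df.columns.duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise SchemaError(f"{path}: non-numeric counts")
    if (values < 0).any():
        raise SchemaError(f"{path}: negative counts")
    if not np.allclose(values, np.round(values)):
        raise SchemaError(f"{path}: counts must be integers")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.index.name = "cluster_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gate": str})
    _require_columns(df, SAMPLE_SHEET_COLUMNS, path)
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id", drop=False)


def check_counts_samples(counts: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Counts columns and sample-sheet rows must describe the same samples."""
    extra = set(sheet.index) - set(counts.columns)
    missing = set(counts.columns) - set(sheet.index)
    if extra:
        raise SchemaError(f"samples absent from counts: {sorted(extra)}")
    if missing:
        raise SchemaError(f"count columns absent from sample sheet: {sorted(missing)}")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["id", "kind", "label"], path)
    return df


def read_cluster_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["transcript_id", "cluster_id"], path)
    if df["transcript_id"].duplicated().any():
        raise SchemaError(f"{path}: transcript mapped twice")
    return dict(zip(df["transcript_id"], df["cluster_id"]))


def write_cluster_map(cluster_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(cluster_map.items()), columns=["transcript_id", "cluster_id"]
    ).to_csv(path, sep="\t", index=False)


def read_equivalence_classes(path: str | Path) -> list[tuple[frozenset[str], int]]:
    """Equivalence-class TSV: comma-joined transcript ids, read count."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["transcript_ids", "count"], path)
    rows = []
    for i, row in df.iterrows():
        ids = frozenset(str(row["transcript_ids"]).split(","))
        count = int(row["count"])
        if count < 1 or not ids or "" in ids:
            raise SchemaError(f"{path}: malformed row {i + 2}")
        rows.append((ids, count))
    return rows


def write_fasta(records: list[SeqRecord], path: str | Path, width: int = 80) -> None:
    """Write upper-case FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = str(rec.seq).upper()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_de_result(result, path: str | Path) -> None:
    """DE result TSV: cluster_id, contrast, log2fc, pvalue, fdr, direction."""
    table = result.table.copy()
    table.insert(0, "contrast", result.contrast)
    table.index.name = "cluster_id"
    table.to_csv(path, sep="\t")


def read_de_result(path: str | Path):
    from .de import DEResult  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["cluster_id", "contrast", "log2fc", "pvalue", "fdr", "direction"], path)
    contrasts = df["contrast"].unique()
    if len(contrasts) != 1:
        raise SchemaError(f"{path}: expected a single contrast, found {list(contrasts)}")
    table = df.set_index("cluster_id")[["log2fc", "pvalue", "fdr", "direction"]]
    return DEResult(table=table, contrast=str(contrasts[0]))
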