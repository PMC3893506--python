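"""Readers and writers for the plain-text interchange formats.

All tabular formats are TSV. Expression matrices carry features on rows
(first column ``feature_id``) and time-point labels as the remaining column
headers, holding log2 expression ratios versus the untreated control.
Gene sets use GMT, pathway topologies a four-column edge list, promoters
FASTA plus BED6 TSS records, and motifs JASPAR-style position frequency
matrices (four count rows A/C/G/T per record).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a feature x time matrix of log2 ratios.

    Raises :class:`FormatError` on duplicate feature ids or non-finite
    values, matching the ExpressionMatrix invariants.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids in {path}: {dups[:5]}")
    values = df.to_numpy(dtype=float)
    if values.size and not np.isfinite(values).all():
        raise FormatError(f"non-finite expression values in {path}")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# gene sets (GMT) and pathway edge lists


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file into ``{pathway_id: (description, gene set)}``."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f"at least one gene"
                )
            pid, desc, genes = parts[0], parts[1], parts[2:]
            if pid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            sets[pid] = (desc, {g for g in genes if g})
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in sets.items():
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


EDGE_COLUMNS = ["pathway_id", "source", "target", "edge_type"]


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing edge columns {missing}")
    return df[EDGE_COLUMNS]


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.reindex(columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read BED6 TSS records (0-based half-open, strand in column 6)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: invalid strand values {df.loc[bad, 'strand'].unique()}")
    return df


def write_bed6(records: pd.DataFrame, path: str | Path) -> None:
    records.reindex(columns=BED6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# JASPAR-style position frequency matrices

_PFM_ROW = re.compile(r"^\s*([ACGT])\s*[\[|]?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def read_pfms(path: str | Path) -> dict[str, np.ndarray]:
    """Parse JASPAR-format PFMs: ``>id`` headers and four A/C/G/T count rows.

    Returns ``{matrix_id: 4 x width count array}`` with rows in A, C, G, T
    order regardless of the order in the file.
    """
    pfms: dict[str, np.ndarray] = {}
    current_id: str | None = None
    rows: dict[str, np.ndarray] = {}

    def flush() -> None:
        nonlocal current_id, rows
        if current_id is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise FormatError(f"PFM {current_id!r}: needs exactly rows A, C, G, T")
        widths = {len(rows[b]) for b in "ACGT"}
        if len(widths) != 1:
            raise FormatError(f"PFM {current_id!r}: ragged rows")
        pfms[current_id] = np.vstack([rows[b] for b in "ACGT"])
        current_id, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
                continue
            m = _PFM_ROW.match(line)
            if m is None or current_id is None:
                raise FormatError(f"{path}:{lineno}: unparseable PFM line {line!r}")
            base, payload = m.group(1), m.group(2)
            rows[base] = np.array([float(x) for x in payload.split()], dtype=float)
    flush()
    return pfms


def write_pfms(pfms: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mid, counts in pfms.items():
            counts = np.asarray(counts)
            fh.write(f">{mid}\n")
            for base, row in zip("ACGT", counts):
                joined = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {joined} ]\n")


# ---------------------------------------------------------------------------
# generic tables


def read_table(path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
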