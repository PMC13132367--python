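"""File-format readers and writers.

Formats: gene x sample counts as gzip TSV or MatrixMarket triplet with
gene/column sidecars; per-cell tables and clinical tables as CSV; gene sets
as GMT. Every writer/reader pair is an identity on its domain. CSV dialect:
comma, UTF-8, '.' decimal, no index column; coordinates are microns.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (CELL_TABLE_COLUMNS, CellTranscriptMatrix, ClinicalTable,
                    CountMatrix, validate_cell_table)

__all__ = [
    "write_expression_tsv", "read_expression_tsv",
    "write_expression_mtx", "read_expression_mtx",
    "read_expression",
    "read_gmt", "write_gmt",
    "read_cell_table", "write_cell_table",
    "read_clinical", "write_clinical",
    "read_cell_transcript_matrix", "write_cell_transcript_matrix",
    "file_checksum",
]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: CountMatrix, path: str | Path) -> None:
    """Gzip TSV: first column 'gene', then one column per sample id."""
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        fh.write("gene\t" + "\t".join(matrix.samples) + "\n")
        for g, row in zip(matrix.genes, matrix.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_expression_tsv(path: str | Path) -> CountMatrix:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "gene":
            raise ValueError(f"malformed header in {path.name}: {header[:3]}")
        samples = header[1:]
        genes: list[str] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(samples) + 1:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {len(samples) + 1} fields, "
                    f"got {len(fields)}")
            g = fields[0]
            if g in seen:
                raise ValueError(f"duplicate gene: {g}")
            seen.add(g)
            vals = [int(v) for v in fields[1:]]
            if any(v < 0 for v in vals):
                raise ValueError(f"{path.name}:{lineno}: negative count for {g}")
            genes.append(g)
            rows.append(vals)
    return CountMatrix(genes, samples, np.array(rows, dtype=np.int64))


def write_expression_mtx(matrix: CountMatrix, prefix: str | Path) -> None:
    """MatrixMarket triplet (<prefix>.mtx) plus <prefix>.genes.txt and
    <prefix>.columns.txt sidecars."""
    prefix = Path(prefix)
    counts = matrix.counts
    nz = np.nonzero(counts)
    with open(prefix.with_suffix(".mtx"), "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{counts.shape[0]} {counts.shape[1]} {len(nz[0])}\n")
        for i, j in zip(*nz):
            fh.write(f"{i + 1} {j + 1} {int(counts[i, j])}\n")
    prefix.with_suffix(".genes.txt").write_text("\n".join(matrix.genes) + "\n")
    prefix.with_suffix(".columns.txt").write_text("\n".join(matrix.samples) + "\n")


def read_expression_mtx(prefix: str | Path) -> CountMatrix:
    """Read the MTX trio written by :func:`write_expression_mtx`.

    Validates triplet indices against the declared dimensions, reporting the
    offending line number.
    """
    prefix = Path(prefix)
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".columns.txt").read_text().splitlines()
    mtx_path = prefix.with_suffix(".mtx")
    with open(mtx_path) as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket matrix coordinate"):
            raise ValueError(f"malformed MatrixMarket header in {mtx_path.name}")
        lineno = 1
        line = fh.readline(); lineno += 1
        while line.startswith("%"):
            line = fh.readline(); lineno += 1
        nr, nc, nnz = (int(v) for v in line.split())
        if nr != len(genes) or nc != len(samples):
            raise ValueError(
                f"dimension mismatch: mtx declares {nr}x{nc}, sidecars give "
                f"{len(genes)}x{len(samples)}")
        counts = np.zeros((nr, nc), dtype=np.int64)
        for _ in range(nnz):
            line = fh.readline(); lineno += 1
            i, j, v = line.split()
            i, j, v = int(i), int(j), int(v)
            if not (1 <= i <= nr and 1 <= j <= nc):
                raise ValueError(
                    f"{mtx_path.name}:{lineno}: index ({i},{j}) out of range "
                    f"for {nr}x{nc} matrix")
            if v < 0:
                raise ValueError(f"{mtx_path.name}:{lineno}: negative count")
            counts[i - 1, j - 1] = v
    return CountMatrix(genes, samples, counts)


def read_expression(path: str | Path) -> CountMatrix:
    """Dispatch on extension: .mtx trio or (gzip) TSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        return read_expression_mtx(path.with_suffix(""))
    return read_expression_tsv(path)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT dialect: name <tab> description <tab> gene1 <tab> gene2 ...

    Set names must be unique; genes are de-duplicated preserving first
    occurrence; empty sets are rejected.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{Path(path).name}:{lineno}: GMT line needs "
                             f">= 3 fields, got {len(fields)}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name: {name}")
        seen: set[str] = set()
        genes = [g for g in fields[2:]
                 if g and not (g in seen or seen.add(g))]
        if not genes:
            raise ValueError(f"{Path(path).name}:{lineno}: empty gene set {name}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes)
             for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cell and clinical tables
# ---------------------------------------------------------------------------

def read_cell_table(path: str | Path) -> pd.DataFrame:
    """CSV with columns cell_id,x_um,y_um,BATF3,CD3,CD8[,...]; extra columns
    are preserved untouched. NA coordinates are rejected."""
    table = pd.read_csv(path, float_precision="round_trip")
    for col in CELL_TABLE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cell table missing column: {col}")
    if table[["x_um", "y_um"]].isna().any().any():
        raise ValueError("NA coordinates in cell table")
    return validate_cell_table(table)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(table)
    table.to_csv(path, index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    """CSV sample_id,response[,os_time,os_event]."""
    return ClinicalTable(pd.read_csv(path))


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cell x gene matrices with coordinates
# ---------------------------------------------------------------------------

def write_cell_transcript_matrix(matrix: CellTranscriptMatrix,
                                 prefix: str | Path) -> None:
    """Counts as an MTX trio plus a <prefix>.coords.csv coordinate table
    (and hidden-truth columns, if any, for lossless round-trips)."""
    cm = CountMatrix(list(matrix.genes), list(matrix.cell_ids), matrix.counts)
    write_expression_mtx(cm, prefix)
    coords = pd.DataFrame({"cell_id": matrix.cell_ids,
                           "x_um": matrix.x_um, "y_um": matrix.y_um})
    if matrix.meta is not None:
        coords = pd.concat([coords, matrix.meta.reset_index(drop=True)], axis=1)
    coords.to_csv(Path(prefix).with_suffix(".coords.csv"), index=False)


def read_cell_transcript_matrix(prefix: str | Path) -> CellTranscriptMatrix:
    prefix = Path(prefix)
    cm = read_expression_mtx(prefix)
    coords = pd.read_csv(prefix.with_suffix(".coords.csv"),
                         float_precision="round_trip")
    for col in ("cell_id", "x_um", "y_um"):
        if col not in coords.columns:
            raise ValueError(f"coordinate table missing column: {col}")
    if list(coords["cell_id"]) != cm.samples:
        raise ValueError("coordinate table cell ids do not match matrix columns")
    extra = [c for c in coords.columns if c not in ("cell_id", "x_um", "y_um")]
    meta = coords[extra].copy() if extra else None
    return CellTranscriptMatrix(
        cm.samples, coords["x_um"].to_numpy(), coords["y_um"].to_numpy(),
        cm.genes, cm.counts, meta)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
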