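"""Readers and writers for the on-disk formats the pipeline touches.

Formats: MatrixMarket UMI count matrices with gene/barcode sidecars
(10x-style triplet), TCR contig CSV tables (filtered_contig_annotations
dialect), BED6 gene coordinates, TSV somatic variant tables, CSV survival
tables and newick trees.  Every reader/writer pair round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_CHAINS = {"TRA", "TRB"}
#: gamma/delta chains are recognised but excluded from alpha-beta analyses
DROPPED_CHAINS = {"TRG", "TRD"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Raw UMI counts, genes x cells, with per-cell sample labels.

    ``values`` is a CSR sparse matrix of nonnegative integers.  Gene ids are
    unique; (sample, barcode) pairs are unique.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        self.values = sp.csr_matrix(self.values)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells or len(self.sample_of_cell) != n_cells:
            raise FormatError("barcode/sample labels do not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        pairs = list(zip(self.sample_of_cell, self.barcodes))
        if len(set(pairs)) != n_cells:
            raise FormatError("duplicate (sample, barcode) pair")
        if self.values.nnz:
            data = self.values.data
            if (data < 0).any():
                raise ValueError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer count entry")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "ExpressionMatrix":
        """Return a new matrix restricted to boolean/index masks."""
        v = self.values
        gi, bc, sm = self.gene_ids, self.barcodes, self.sample_of_cell
        if gene_mask is not None:
            v = v[gene_mask, :]
            gi = gi[gene_mask]
        if cell_mask is not None:
            v = v[:, cell_mask]
            bc = bc[cell_mask]
            sm = sm[cell_mask]
        return ExpressionMatrix(sp.csr_matrix(v), gi, bc, sm)


@dataclass
class ContigRecord:
    """One assembled TCR contig from one cell."""

    barcode: str
    sample: str
    chain: str
    cdr3_aa: str
    cdr3_nt: str
    productive: bool

    def __post_init__(self) -> None:
        if self.chain not in VALID_CHAINS:
            raise ValueError(f"chain must be TRA or TRB, got {self.chain!r}")
        if self.productive and (not self.cdr3_aa or not self.cdr3_nt):
            raise ValueError("productive contig with empty CDR3")


def read_counts(
    matrix_path, genes_path, barcodes_path, sample_id: str
) -> ExpressionMatrix:
    """Read a MatrixMarket counts file with gene/barcode sidecar TSVs.

    The MTX file is genes x cells with 1-based indices per the MatrixMarket
    standard; sparse zeros are preserved.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"invalid MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_single_column(genes_path)
    barcodes = _read_single_column(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars list "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    samples = np.array([sample_id] * len(barcodes), dtype=object)
    return ExpressionMatrix(mat, np.array(genes, dtype=object),
                            np.array(barcodes, dtype=object), samples)


def write_counts(matrix: ExpressionMatrix, matrix_path, genes_path, barcodes_path) -> None:
    coo = matrix.values.tocoo()
    ordered = sp.coo_matrix(
        (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
    )
    scipy.io.mmwrite(str(matrix_path), ordered, field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in matrix.barcodes))


def _read_single_column(path) -> list[str]:
    lines = [ln.split("\t")[0].strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if len(set(lines)) != len(lines):
        raise FormatError(f"duplicate entries in {path}")
    return lines


CONTIG_COLUMNS = ["barcode", "sample", "chain", "cdr3", "cdr3_nt", "productive"]


def read_contigs(csv_path) -> list[ContigRecord]:
    """Read a 10x-style contig annotation CSV into alpha/beta contig records.

    TRG/TRD rows are excluded (the pipeline analyses paired alpha-beta
    clonotypes only); the number dropped is logged.
    """
    df = pd.read_csv(csv_path, dtype=str)
    missing = {"barcode", "chain", "cdr3", "cdr3_nt", "productive"} - set(df.columns)
    if missing:
        raise FormatError(f"contig CSV missing columns: {sorted(missing)}")
    if "sample" not in df.columns:
        df["sample"] = ""
    records: list[ContigRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        chain = str(row.chain)
        if chain in DROPPED_CHAINS:
            dropped += 1
            continue
        if chain not in VALID_CHAINS:
            raise FormatError(f"unknown chain value {chain!r}")
        prod = str(row.productive).strip().lower()
        if prod not in {"true", "false"}:
            raise FormatError(f"unparseable productive flag {row.productive!r}")
        records.append(
            ContigRecord(
                barcode=str(row.barcode),
                sample=str(row.sample),
                chain=chain,
                cdr3_aa="" if pd.isna(row.cdr3) else str(row.cdr3),
                cdr3_nt="" if pd.isna(row.cdr3_nt) else str(row.cdr3_nt),
                productive=prod == "true",
            )
        )
    if dropped:
        logger.info("dropped %d TRG/TRD contig rows", dropped)
    return records


def write_contigs(records: Sequence[ContigRecord], csv_path) -> None:
    rows = [
        {
            "barcode": r.barcode,
            "sample": r.sample,
            "chain": r.chain,
            "cdr3": r.cdr3_aa,
            "cdr3_nt": r.cdr3_nt,
            "productive": "True" if r.productive else "False",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CONTIG_COLUMNS).to_csv(csv_path, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED6 gene coordinates into a frame indexed by gene id.

    Coordinates stay 0-based half-open (BED convention).  Columns:
    chrom, start, end, strand.
    """
    rows = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise FormatError(f"{path}:{i}: expected 6 BED columns, got {len(parts)}")
        chrom, start, end, name, _score, strand = parts[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-integer coordinate") from exc
        if start_i >= end_i:
            raise FormatError(f"{path}:{i}: start >= end")
        if strand not in {"+", "-"}:
            raise FormatError(f"{path}:{i}: bad strand {strand!r}")
        if not chrom:
            raise FormatError(f"{path}:{i}: empty chromosome")
        if name in rows:
            raise FormatError(f"{path}:{i}: duplicate gene {name}")
        rows[name] = (chrom, start_i, end_i, strand)
    coords = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "start", "end", "strand"]
    )
    coords.index.name = "gene_id"
    return coords


def write_bed(coords: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for gene, row in coords.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{gene}\t0\t{row.strand}\n"
            )


VARIANT_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "effect", "flank"]
VARIANT_EFFECTS = {"nonsynonymous", "synonymous", "indel"}


def read_variants(path) -> pd.DataFrame:
    """Read a TSV somatic variant table (1-based positions, VCF convention)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str,
                                            "ref": str, "alt": str,
                                            "effect": str, "flank": str})
    missing = set(VARIANT_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise FormatError(f"variant table missing columns: {sorted(missing)}")
    if "flank" not in df.columns:
        df["flank"] = ""
    df["flank"] = df["flank"].fillna("")
    df["pos"] = df["pos"].astype(int)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.pos < 1:
            raise FormatError(f"line {i}: position must be >= 1")
        if row.ref == row.alt:
            raise FormatError(f"line {i}: ref equals alt")
        if row.effect not in VARIANT_EFFECTS:
            raise FormatError(f"line {i}: unknown effect {row.effect!r}")
    return df[VARIANT_COLUMNS]


def write_variants(df: pd.DataFrame, path) -> None:
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


SURVIVAL_COLUMNS = ["patient", "time", "event", "score"]


def read_survival(path) -> pd.DataFrame:
    """Read a CSV survival table: patient, time (months), event (0/1), score."""
    df = pd.read_csv(path, dtype={"patient": str})
    missing = set(SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"survival table missing columns: {sorted(missing)}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    df["score"] = df["score"].astype(float)
    if (df["time"] <= 0).any():
        raise FormatError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise FormatError("event must be 0 or 1")
    return df[SURVIVAL_COLUMNS]


def write_survival(df: pd.DataFrame, path) -> None:
    df[SURVIVAL_COLUMNS].to_csv(path, index=False)


def write_newick(tree, path) -> None:
    """Write a tree carrying a ``newick`` attribute (or a newick string)."""
    newick = getattr(tree, "newick", tree)
    if not isinstance(newick, str) or not newick.rstrip().endswith(";"):
        raise ValueError("not a newick tree")
    Path(path).write_text(newick.rstrip() + "\n")
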