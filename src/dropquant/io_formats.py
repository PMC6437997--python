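"""Readers and writers for every on-disk format the pipeline touches.

Coordinates are 0-based, half-open throughout, including the barcode
geometry offsets.  FASTQ files may be plain text or gzip (detected from
magic bytes, not the file extension).  Count matrices are written in
MatrixMarket coordinate format with real-valued entries because the EM
step produces fractional molecule counts; the tier matrix is a dense TSV.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse


class ReadTriple(NamedTuple):
    """A demultiplexed read pair: cell barcode, UMI and the cDNA sequence."""

    cb: str
    umi: str
    cdna: str
    has_n: bool


@dataclass(frozen=True)
class BarcodeGeometry:
    """Where the cell barcode and UMI live within read 1.

    Defaults describe 10x Chromium V2 chemistry: a 16-base cell barcode
    followed by a 10-base UMI, both starting at the 5' end of read 1.
    """

    cb_length: int = 16
    umi_length: int = 10
    cb_offset: int = 0
    umi_offset: int = 16

    def __post_init__(self) -> None:
        if self.cb_length < 1 or self.umi_length < 1:
            raise ValueError("barcode and UMI lengths must be >= 1")
        if self.cb_offset < 0 or self.umi_offset < 0:
            raise ValueError("offsets must be non-negative")
        cb_span = (self.cb_offset, self.cb_offset + self.cb_length)
        umi_span = (self.umi_offset, self.umi_offset + self.umi_length)
        lo, hi = sorted([cb_span, umi_span])
        if lo[1] > hi[0]:
            raise ValueError("cell-barcode and UMI spans overlap")

    @property
    def min_read1_length(self) -> int:
        return max(self.cb_offset + self.cb_length, self.umi_offset + self.umi_length)

    def extract(self, read1: str) -> tuple[str, str]:
        cb = read1[self.cb_offset : self.cb_offset + self.cb_length]
        umi = read1[self.umi_offset : self.umi_offset + self.umi_length]
        return cb, umi


def read_fastq_pairs(
    path_r1: str | os.PathLike,
    path_r2: str | os.PathLike,
    geometry: BarcodeGeometry,
) -> Iterator[ReadTriple]:
    """Stream (cell barcode, UMI, cDNA) triples from a FASTQ pair.

    Records are yielded in file order.  Reads whose barcode or UMI contains
    an ambiguous base are flagged via ``has_n`` so the caller can discard
    them before tallying.  Mismatched record counts between the two files
    raise a ``ValueError`` naming the first unmatched record index.
    """
    with pysam.FastxFile(os.fspath(path_r1)) as f1, pysam.FastxFile(
        os.fspath(path_r2)
    ) as f2:
        for idx, (r1, r2) in enumerate(zip_longest(f1, f2)):
            if r1 is None or r2 is None:
                raise ValueError(
                    f"record count mismatch between FASTQ files at record {idx}"
                )
            seq1 = r1.sequence or ""
            if len(seq1) < geometry.min_read1_length:
                raise ValueError(
                    f"read 1 shorter than barcode geometry at record {idx}"
                )
            cb, umi = geometry.extract(seq1.upper())
            cdna = (r2.sequence or "").upper()
            yield ReadTriple(cb, umi, cdna, "N" in cb or "N" in umi)


def _open_text_write(path: str | os.PathLike):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _open_text_read(path: str | os.PathLike):
    """Open plain or gzip text, sniffing the gzip magic bytes."""
    path = os.fspath(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def write_fastq(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) records as 4-line FASTQ with constant quality."""
    with _open_text_write(path) as out:
        for name, seq in records:
            out.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    with pysam.FastxFile(os.fspath(path)) as fh:
        return [(rec.name, (rec.sequence or "").upper()) for rec in fh]


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    with _open_text_write(path) as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


def read_t2g(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column transcript-to-gene TSV into a dict."""
    t2g: dict[str, str] = {}
    with _open_text_read(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"t2g line {lineno} has fewer than 2 columns")
            tx, gene = parts[0], parts[1]
            if tx in t2g:
                raise ValueError(f"transcript {tx!r} appears twice in t2g")
            t2g[tx] = gene
    if not t2g:
        raise ValueError("empty transcript-to-gene map")
    return t2g


def write_t2g(path: str | os.PathLike, t2g: dict[str, str]) -> None:
    with _open_text_write(path) as out:
        for tx, gene in t2g.items():
            out.write(f"{tx}\t{gene}\n")


def read_whitelist(path: str | os.PathLike) -> set[str]:
    """Read one barcode per line; duplicates collapse, mixed lengths error."""
    barcodes: set[str] = set()
    with _open_text_read(path) as fh:
        for line in fh:
            bc = line.strip()
            if bc:
                barcodes.add(bc)
    if not barcodes:
        raise ValueError("empty whitelist file")
    if len({len(b) for b in barcodes}) != 1:
        raise ValueError("whitelist barcodes have mixed lengths")
    return barcodes


def write_whitelist(path: str | os.PathLike, barcodes: Iterable[str]) -> None:
    with _open_text_write(path) as out:
        for bc in sorted(barcodes):
            out.write(bc + "\n")


@dataclass
class QuantOutput:
    """Cells-by-genes molecule counts with per-entry evidence tiers."""

    barcodes: list[str]
    genes: list[str]
    counts: np.ndarray
    tiers: np.ndarray
    variance: Optional[np.ndarray] = None

    def validate(self) -> None:
        shape = (len(self.barcodes), len(self.genes))
        if self.counts.shape != shape or self.tiers.shape != shape:
            raise ValueError("count/tier matrices do not match barcode/gene labels")
        if self.variance is not None and self.variance.shape != shape:
            raise ValueError("variance matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.variance is not None and np.any(self.variance < 0):
            raise ValueError("negative variances")
        if not np.isin(self.tiers, [0, 1, 2, 3]).all():
            raise ValueError("tiers must be integers in {0,1,2,3}")
        if np.any(self.counts[self.tiers == 0] != 0):
            raise ValueError("tier-0 entries must have zero counts")


def write_quant(output_dir: str | os.PathLike, quant: QuantOutput) -> None:
    """Write the quantification result (MTX counts, TSV tiers, label files)."""
    quant.validate()
    output_dir = os.fspath(output_dir)
    os.makedirs(output_dir, exist_ok=True)
    counts = scipy.sparse.coo_matrix(np.asarray(quant.counts, dtype=float))
    scipy.io.mmwrite(os.path.join(output_dir, "quants_mat.mtx"), counts)
    with open(os.path.join(output_dir, "quants_mat_rows.txt"), "w") as out:
        out.writelines(b + "\n" for b in quant.barcodes)
    with open(os.path.join(output_dir, "quants_mat_cols.txt"), "w") as out:
        out.writelines(g + "\n" for g in quant.genes)
    tiers = pd.DataFrame(quant.tiers, index=quant.barcodes, columns=quant.genes)
    tiers.to_csv(os.path.join(output_dir, "quants_tier_mat.tsv"), sep="\t")
    if quant.variance is not None:
        var = scipy.sparse.coo_matrix(np.asarray(quant.variance, dtype=float))
        scipy.io.mmwrite(os.path.join(output_dir, "quants_var_mat.mtx"), var)


def read_quant(output_dir: str | os.PathLike) -> QuantOutput:
    output_dir = os.fspath(output_dir)
    counts = scipy.io.mmread(os.path.join(output_dir, "quants_mat.mtx")).toarray()
    with open(os.path.join(output_dir, "quants_mat_rows.txt")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    with open(os.path.join(output_dir, "quants_mat_cols.txt")) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    tiers = pd.read_csv(
        os.path.join(output_dir, "quants_tier_mat.tsv"), sep="\t", index_col=0
    ).to_numpy(dtype=int)
    var_path = os.path.join(output_dir, "quants_var_mat.mtx")
    variance = scipy.io.mmread(var_path).toarray() if os.path.exists(var_path) else None
    return QuantOutput(barcodes, genes, counts, tiers, variance)


def write_eqclasses(
    path: str | os.PathLike,
    cell_tables: dict[str, dict[tuple[str, tuple[str, ...]], int]],
) -> None:
    """Dump per-cell (UMI, equivalence class) read counts as TSV.

    Columns: barcode, UMI, comma-joined transcript ids, read count.  This
    lets the deduplication stage be driven by an external mapper.
    """
    with _open_text_write(path) as out:
        out.write("barcode\tumi\ttranscripts\tcount\n")
        for cb, table in cell_tables.items():
            for (umi, eqclass), count in table.items():
                out.write(f"{cb}\t{umi}\t{','.join(eqclass)}\t{count}\n")


def read_eqclasses(
    path: str | os.PathLike,
) -> dict[str, dict[tuple[str, tuple[str, ...]], int]]:
    tables: dict[str, dict[tuple[str, tuple[str, ...]], int]] = {}
    with _open_text_read(path) as fh:
        header = fh.readline()
        if not header.startswith("barcode\t"):
            raise ValueError("malformed equivalence-class dump (missing header)")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cb, umi, txs, count = line.split("\t")
            key = (umi, tuple(sorted(txs.split(","))))
            tables.setdefault(cb, {})[key] = tables.setdefault(cb, {}).get(key, 0) + int(count)
    return tables
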