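"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates entering the system are converted to 0-based,
half-open (BED) semantics at this boundary and stay that way everywhere
downstream.  Every reader validates strictly and raises :class:`FormatError`
naming the offending line, so later stages can assume well-formed in-memory
objects.

Supported formats: FASTA, BED3-BED6, bedGraph, JASPAR PFM text, and TSV
tables (expression matrices: gene rows x sample columns; differential
expression: columns ``gene``, ``log2fc``, ``fdr``).  Plain text and gzip
only.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file violated its format contract (message names file and line)."""


class LookupMissError(KeyError):
    """A requested identifier (gene, chromosome, ...) is absent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, the universal region currency."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset,
            self.strand, self.name, self.score,
        )


@dataclass
class SignalTrack:
    """Sorted, non-overlapping intervals with a non-negative value each.

    Used for coverage / enrichment tracks such as H3K4me1 or DNase signal.
    """

    intervals: list[GenomicInterval]
    values: list[float]
    mark: str = ""
    sample: str = ""
    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.values):
            raise ValueError("intervals and values length mismatch")
        for v in self.values:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"track value must be finite and >= 0, got {v}")
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        self.intervals = [self.intervals[i] for i in order]
        self.values = [self.values[i] for i in order]
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError(
                    f"overlapping track intervals at {iv.chrom}:{iv.start}"
                )
            prev = iv
        self._index()

    def _index(self) -> None:
        by: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            chroms.setdefault(iv.chrom, []).append(i)
        for chrom, idx in chroms.items():
            by[chrom] = (
                np.array([self.intervals[i].start for i in idx], dtype=np.int64),
                np.array([self.intervals[i].end for i in idx], dtype=np.int64),
                np.array([self.values[i] for i in idx], dtype=float),
            )
        self._by_chrom = by

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def weighted_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value * covered-length over [start, end); uncovered = 0."""
        if chrom not in self._by_chrom:
            raise LookupMissError(f"chromosome {chrom!r} absent from track")
        starts, ends, vals = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, vals[lo:hi]))


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: raw base counts per motif column.

    ``counts`` is 4 x L in fixed row order A, C, G, T.
    """

    motif_id: str
    tf_name: str
    counts: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        mat = np.asarray(self.counts, dtype=float)
        if mat.shape[0] != 4 or mat.shape[1] < 4:
            raise ValueError(
                f"PFM {self.motif_id}: expected 4 x L matrix with L >= 4, "
                f"got shape {mat.shape}"
            )
        if (mat < 0).any():
            raise ValueError(f"PFM {self.motif_id}: negative count")
        if (mat.sum(axis=0) <= 0).any():
            raise ValueError(f"PFM {self.motif_id}: all-zero column")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def length(self) -> int:
        return len(self.counts[0])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values on a CPM-like scale.

    ``is_counts`` flags a raw-counts variant (pre-normalization).
    """

    data: pd.DataFrame
    is_counts: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        arr = self.data.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class DERecord:
    """One differential-expression result: gene, log2 fold change, FDR."""

    gene: str
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr out of [0,1] for {self.gene}: {self.fdr}")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"non-finite log2fc for {self.gene}")


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------

def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _fail(path: str | Path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: uppercase sequence}``.

    Sequences are case-folded to upper case and must contain only A, C, G,
    T, N.  Duplicate ids, empty sequences and malformed headers raise
    :class:`FormatError` with the line number.
    """
    sequences: dict[str, str] = {}
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _flush(lineno: int) -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            _fail(path, header_line, f"empty sequence for id {current_id!r}")
        sequences[current_id] = seq

    with _open_text(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    _fail(path, lineno, "malformed header: missing sequence id")
                if name in sequences:
                    _fail(path, lineno, f"duplicate sequence id {name!r}")
                current_id = name
                header_line = lineno
                chunks = []
            else:
                if current_id is None:
                    _fail(path, lineno, "sequence data before any header")
                upper = line.upper()
                bad = set(upper) - VALID_BASES
                if bad:
                    _fail(
                        path, lineno,
                        "invalid nucleotide character(s): "
                        + ", ".join(sorted(repr(c) for c in bad)),
                    )
                chunks.append(upper)
        _flush(lineno + 1)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file, preserving input order.

    Coordinates are kept 0-based half-open.  start >= end or negative start
    raises :class:`FormatError` with the line number.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, f"expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, "non-integer coordinate")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    _fail(path, lineno, f"non-numeric score {fields[4]!r}")
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                _fail(path, lineno, f"invalid strand {strand!r}")
            if start < 0:
                _fail(path, lineno, f"negative start {start}")
            if start >= end:
                _fail(path, lineno, f"start {start} >= end {end}")
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, mark: str = "", sample: str = "") -> SignalTrack:
    """Read a 4-column bedGraph into a sorted, overlap-checked SignalTrack."""
    intervals: list[GenomicInterval] = []
    values: list[float] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                _fail(path, lineno, f"expected 4 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                _fail(path, lineno, "non-numeric coordinate or value")
            if start < 0 or start >= end:
                _fail(path, lineno, f"invalid interval {start}-{end}")
            if not math.isfinite(value) or value < 0:
                _fail(path, lineno, f"value must be finite and >= 0, got {value}")
            intervals.append(GenomicInterval(fields[0], start, end))
            values.append(value)
    try:
        return SignalTrack(intervals, values, mark=mark, sample=sample)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for iv, v in zip(track.intervals, track.values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:g}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: str | Path) -> list[PFM]:
    """Read a JASPAR 2016+ text motif library.

    Each record is ``>ID NAME`` followed by four count rows in A, C, G, T
    order, with or without ``A [ ... ]`` brackets.
    """
    pfms: list[PFM] = []
    with _open_text(path) as fh:
        lines = [(i, ln.rstrip("\n")) for i, ln in enumerate(fh, start=1)]
    lines = [(i, ln) for i, ln in lines if ln.strip()]
    pos = 0
    while pos < len(lines):
        lineno, header = lines[pos]
        if not header.startswith(">"):
            _fail(path, lineno, f"expected motif header, got {header!r}")
        parts = header[1:].split(None, 1)
        if not parts:
            _fail(path, lineno, "malformed motif header")
        motif_id = parts[0]
        tf_name = parts[1].strip() if len(parts) > 1 else motif_id
        if pos + 4 >= len(lines) + 0 and pos + 4 > len(lines):
            _fail(path, lineno, "truncated motif record: expected 4 count rows")
        rows: list[list[float]] = []
        for offset, base in enumerate("ACGT"):
            if pos + 1 + offset >= len(lines):
                _fail(path, lineno, "truncated motif record: expected 4 count rows")
            row_lineno, row = lines[pos + 1 + offset]
            tokens = row.replace("[", " ").replace("]", " ").split()
            if tokens and tokens[0].upper() in "ACGT":
                if tokens[0].upper() != base:
                    _fail(
                        path, row_lineno,
                        f"count rows must be in A,C,G,T order; got {tokens[0]!r}",
                    )
                tokens = tokens[1:]
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                _fail(path, row_lineno, f"non-numeric count in row {base}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            _fail(path, lineno, f"count rows of unequal length: {sorted(lengths)}")
        try:
            pfms.append(PFM(motif_id, tf_name, tuple(tuple(r) for r in rows)))
        except ValueError as exc:
            _fail(path, lineno, str(exc))
        pos += 5
    if not pfms:
        raise FormatError(f"{path}: no motifs found")
    return pfms


def write_jaspar_pfm(pfms: Iterable[PFM], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.tf_name}\n")
            for base, row in zip("ACGT", pfm.matrix):
                counts = " ".join(f"{c:g}" for c in row)
                fh.write(f"{base} [ {counts} ]\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, is_counts: bool = False) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column = gene id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(
            f"{path}: non-numeric values in column(s) {non_numeric}"
        )
    df.index = df.index.astype(str)
    try:
        return ExpressionMatrix(df.astype(float), is_counts=is_counts)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


DE_COLUMNS = ("gene", "log2fc", "fdr")


def read_de_tsv(path: str | Path) -> list[DERecord]:
    """Read a differential-expression TSV with columns gene, log2fc, fdr."""
    try:
        df = pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    for col in ("log2fc", "fdr"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene {dup!r} in DE table")
    records = []
    for row in df.itertuples(index=False):
        try:
            records.append(DERecord(str(row.gene), float(row.log2fc), float(row.fdr)))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc} (column fdr/log2fc)") from exc
    return records


def write_de_tsv(records: Sequence[DERecord], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": [r.gene for r in records],
         "log2fc": [r.log2fc for r in records],
         "fdr": [r.fdr for r in records]}
    ).to_csv(path, sep="\t", index=False)


def read_tss_tsv(path: str | Path) -> list[GenomicInterval]:
    """Read a TSS annotation TSV with columns gene, chrom, tss, strand.

    Each TSS is returned as a 1-bp interval named by its gene.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in ("gene", "chrom", "tss", "strand") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    out = []
    for row in df.itertuples(index=False):
        tss = int(row.tss)
        out.append(
            GenomicInterval(str(row.chrom), tss, tss + 1, str(row.strand),
                            name=str(row.gene))
        )
    return out


def write_tss_tsv(tss_list: Sequence[GenomicInterval], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": [t.name for t in tss_list],
         "chrom": [t.chrom for t in tss_list],
         "tss": [t.start for t in tss_list],
         "strand": [t.strand for t in tss_list]}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT-style geneset file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, "GMT line needs name, description, >=1 gene")
            if fields[0] in sets:
                _fail(path, lineno, f"duplicate geneset {fields[0]!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise FormatError(f"{path}: no genesets found")
    return sets
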