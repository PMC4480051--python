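"""Alignment matrix construction.

Reads and writes multiple sequence alignments and applies the
matrix-construction rules used for plastome phylogenomics: excision of
user-specified column blocks (one inverted-repeat copy, inversion regions)
and removal of every column containing at least one alignment gap, with full
column provenance so any derived matrix can be traced back to source
coordinates.

All coordinates are 0-based, half-open column intervals.

Character conventions: sequences are over ``{A, C, G, T, N, -}`` plus IUPAC
ambiguity codes. Ambiguity codes and ``N`` are treated as missing data for
pairwise comparison but do *not* trigger gap-column removal — only ``-``
does. ``?`` on input is normalized to ``N``; the match character ``.`` is
rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    BoundsError,
    DuplicateTaxonError,
    ParseError,
    UndefinedComparisonError,
)

GAP = b"-"
_AMBIG = "RYSWKMBDHVN"
_VALID = frozenset(b"ACGT-" + _AMBIG.encode())
_ACGT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ACGT_CODE[_b] = _i


def _normalize_row(taxon: str, row: str) -> bytes:
    s = row.upper().replace("?", "N").encode("ascii", errors="replace")
    bad = set(s) - set(_VALID)
    if bad:
        chars = ", ".join(repr(chr(c)) for c in sorted(bad))
        raise ParseError(
            f"taxon {taxon!r}: unsupported characters {chars} "
            "(match-character '.' dialects are not supported)"
        )
    return s


@dataclass(frozen=True)
class MultipleAlignment:
    """A taxa x columns character matrix.

    ``matrix`` is an (n_taxa, n_columns) byte array over the alphabet above;
    rows are addressable by taxon label via :meth:`row`.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray  # dtype 'S1', shape (len(taxa), n_columns)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            seen: set[str] = set()
            dup = next(t for t in self.taxa if t in seen or seen.add(t))
            raise DuplicateTaxonError(f"duplicate taxon label {dup!r}")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentShapeError("matrix shape does not match taxa")

    @classmethod
    def from_rows(cls, taxa: Sequence[str], rows: Sequence[str]) -> "MultipleAlignment":
        if len(taxa) != len(rows):
            raise AlignmentShapeError("taxa and rows differ in count")
        norm = [_normalize_row(t, r) for t, r in zip(taxa, rows)]
        if norm:
            width = len(norm[0])
            for t, s in zip(taxa, norm):
                if len(s) != width:
                    raise AlignmentShapeError(
                        f"taxon {t!r} has {len(s)} columns, expected {width}"
                    )
            matrix = np.frombuffer(b"".join(norm), dtype="S1").reshape(len(norm), width)
        else:
            matrix = np.empty((0, 0), dtype="S1")
        return cls(taxa=tuple(taxa), matrix=matrix)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, taxon: str) -> str:
        return self.matrix[self.taxa.index(taxon)].tobytes().decode()

    @property
    def rows(self) -> list[str]:
        return [self.matrix[i].tobytes().decode() for i in range(self.n_taxa)]

    def subset(self, taxa: Iterable[str]) -> "MultipleAlignment":
        """Row subset in the given order (labels must exist)."""
        taxa = list(taxa)
        idx = [self.taxa.index(t) for t in taxa]
        return MultipleAlignment(taxa=tuple(taxa), matrix=self.matrix[idx])

    def codes(self) -> np.ndarray:
        """uint8 matrix: A,C,G,T -> 0..3; gap/missing/ambiguity -> 4."""
        return _ACGT_CODE[self.matrix.view(np.uint8)]


@dataclass(frozen=True)
class ColumnMap:
    """Ordered source-column indices surviving a transformation."""

    kept_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        k = self.kept_columns
        if any(b <= a for a, b in zip(k, k[1:])):
            raise BoundsError("kept_columns must be strictly increasing")

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("output_column\tsource_column\n")
            for i, src in enumerate(self.kept_columns):
                fh.write(f"{i}\t{src}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ColumnMap":
        kept = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("output_column"):
                    continue
                kept.append(int(line.split("\t")[1]))
        return cls(kept_columns=tuple(kept))


@dataclass(frozen=True)
class StripReport:
    n_before: int
    n_after: int

    @property
    def fraction_removed(self) -> float:
        if self.n_before == 0:
            return 0.0
        return (self.n_before - self.n_after) / self.n_before

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("n_before\tn_after\tfraction_removed\n")
            fh.write(f"{self.n_before}\t{self.n_after}\t{self.fraction_removed:.10g}\n")


def read_alignment(path: str | Path, format: str | None = None) -> MultipleAlignment:
    """Read a FASTA or NEXUS alignment, preserving input taxon order.

    ``format`` is ``"fasta"`` or ``"nexus"``; when omitted it is inferred
    from the file extension.
    """
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".nxs"} else "fasta"
    if format not in {"fasta", "nexus"}:
        raise ParseError(f"unsupported alignment format {format!r}")
    try:
        if format == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), "nexus"))
    except (AlignmentShapeError, DuplicateTaxonError):
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ParseError(f"could not parse {path} as {format}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no sequences found")
    return MultipleAlignment.from_rows(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def write_alignment(aln: MultipleAlignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    records = [
        SeqRecord(Seq(row), id=taxon, description="", annotations={"molecule_type": "DNA"})
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.seq}\n")
    elif format == "nexus":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "nexus")
    else:
        raise ParseError(f"unsupported alignment format {format!r}")


def _union_mask(n_columns: int, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    drop = np.zeros(n_columns, dtype=bool)
    for start, end in intervals:
        if start > end:
            raise BoundsError(f"interval ({start}, {end}) is reversed")
        if start < 0 or end > n_columns:
            raise BoundsError(
                f"interval ({start}, {end}) outside [0, {n_columns})"
            )
        drop[start:end] = True
    return drop


def excise_columns(
    aln: MultipleAlignment, intervals: Sequence[tuple[int, int]]
) -> tuple[MultipleAlignment, ColumnMap]:
    """Delete the union of the given column intervals.

    Overlapping intervals are unioned; the returned :class:`ColumnMap` maps
    each surviving output column to its source index.
    """
    drop = _union_mask(aln.n_columns, intervals)
    kept = np.flatnonzero(~drop)
    out = MultipleAlignment(taxa=aln.taxa, matrix=aln.matrix[:, kept])
    return out, ColumnMap(kept_columns=tuple(int(i) for i in kept))


def strip_gap_columns(
    aln: MultipleAlignment,
) -> tuple[MultipleAlignment, ColumnMap, StripReport]:
    """Remove every column in which at least one taxon has ``-``.

    Ambiguity codes and ``N`` do not count as gaps. Returns the stripped
    alignment, the provenance map and a :class:`StripReport` with the
    fraction of columns removed.
    """
    gapped = (aln.matrix == GAP).any(axis=0) if aln.n_taxa else np.zeros(0, bool)
    kept = np.flatnonzero(~gapped)
    out = MultipleAlignment(taxa=aln.taxa, matrix=aln.matrix[:, kept])
    report = StripReport(n_before=aln.n_columns, n_after=out.n_columns)
    return out, ColumnMap(kept_columns=tuple(int(i) for i in kept)), report


@dataclass(frozen=True)
class PairwiseComparison:
    """Result of a pairwise percent difference/identity computation."""

    percent: float
    mode: str
    n_compared: int
    n_mismatch: int


def pairwise_percent_difference(
    a: str, b: str, mode: str = "difference"
) -> PairwiseComparison:
    """Percent difference or identity between two aligned sequences.

    Only columns where *both* characters are unambiguous bases (A/C/G/T)
    are compared; gaps, N and IUPAC ambiguities are skipped. ``difference``
    is 100 x mismatches / compared columns; ``identity`` is its complement.
    """
    if mode not in {"difference", "identity"}:
        raise ValueError(f"mode must be 'difference' or 'identity', got {mode!r}")
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"sequences differ in length ({len(a)} vs {len(b)})"
        )
    ca = _ACGT_CODE[np.frombuffer(a.upper().encode(), dtype=np.uint8)]
    cb = _ACGT_CODE[np.frombuffer(b.upper().encode(), dtype=np.uint8)]
    comparable = (ca < 4) & (cb < 4)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedComparisonError("no columns with unambiguous bases in both sequences")
    mismatches = int(((ca != cb) & comparable).sum())
    diff = 100.0 * mismatches / n
    pct = diff if mode == "difference" else 100.0 - diff
    return PairwiseComparison(percent=pct, mode=mode, n_compared=n, n_mismatch=mismatches)
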