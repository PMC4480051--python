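"""Indel cataloguing.

Identifies shared gap footprints in a gapped alignment and applies the four
acceptance criteria used for scoring plastome indels as single evolutionary
events:

(i)   length >= 2 bp, excluding mononucleotide repeats regardless of length;
(ii)  attributable (or not) to slipped-strand mispairing (SSM), diagnosed by
      a perfect or near-perfect copy of the indel segment in the immediately
      adjacent flank;
(iii) unambiguous — the footprint must not partially overlap a different
      indel footprint;
(iv)  shared by two or more rows (autapomorphic indels are not scored).

Terminal gap runs (touching a row's start or end) are treated as missing
data, never as indels. Rejection reasons are evaluated in a fixed order
(too_short, mononucleotide, ambiguous_overlap, autapomorphic) so reports are
deterministic: an event failing several criteria records the first.

Accepted events are optionally classified by genomic region (coding /
intron / intergenic spacer) against a GFF3 annotation on alignment
coordinates, and encoded as a binary presence/absence character matrix
(state 1 = gap present, i.e. segment absent).
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import GAP, MultipleAlignment
from .errors import ConsistencyError, ParseError

# rejection reasons, in evaluation order
TOO_SHORT = "too_short"
MONONUCLEOTIDE = "mononucleotide"
AMBIGUOUS_OVERLAP = "ambiguous_overlap"
AUTAPOMORPHIC = "autapomorphic"
TERMINAL = "terminal"

# SSM classes
SSM_PERFECT = "perfect"
SSM_NEAR_PERFECT = "near_perfect"
SSM_NONE = "none"
SSM_UNASSESSED = "unassessed"

# region classes, in tie-break precedence order
REGION_CODING = "coding"
REGION_INTRON = "intron"
REGION_IGS = "igs"
REGION_UNASSIGNED = "unassigned"
_REGION_PRECEDENCE = {REGION_CODING: 2, REGION_INTRON: 1, REGION_IGS: 0}

_MISSING_BYTES = frozenset(b"NRYSWKMBDHV")


@dataclass(frozen=True)
class GapRun:
    """One maximal run of ``-`` in one row."""

    taxon: str
    interval: tuple[int, int]
    terminal: bool


@dataclass(frozen=True)
class IndelCriteria:
    """Tunable acceptance thresholds for indel scoring."""

    min_length: int = 2
    min_shared: int = 2
    exclude_mononucleotide: bool = True
    ssm_identity_threshold: float = 0.80
    require_non_overlap: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_shared < 1:
            raise ValueError("min_length and min_shared must be >= 1")
        if not (0 < self.ssm_identity_threshold <= 1):
            raise ValueError("ssm_identity_threshold must be in (0, 1]")


@dataclass(frozen=True)
class IndelEvent:
    """A shared gap footprint: identical interval across ``gapped_taxa``."""

    interval: tuple[int, int]
    gapped_taxa: tuple[str, ...]  # alignment row order
    status: str = "candidate"  # candidate | accepted | rejected
    reject_reason: str | None = None
    ssm: str = SSM_UNASSESSED
    region: str = REGION_UNASSIGNED
    overlapping: bool = False  # partial overlap with a different footprint

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def event_id(self) -> str:
        return f"indel_{self.interval[0]}_{self.interval[1]}"


@dataclass(frozen=True)
class RegionAnnotation:
    """Region features on alignment column coordinates (0-based half-open)."""

    features: tuple[tuple[int, int, str, str], ...]  # (start, end, class, name)

    def __post_init__(self) -> None:
        for start, end, cls, _ in self.features:
            if cls not in _REGION_PRECEDENCE:
                raise ConsistencyError(f"unknown region class {cls!r}")
            if start >= end:
                raise ConsistencyError(f"empty feature interval ({start}, {end})")

    @classmethod
    def from_gff3(cls, path: str | Path, n_columns: int | None = None) -> "RegionAnnotation":
        """Read CDS and intron features from GFF3; inter-feature spans -> igs.

        GFF3 is 1-based inclusive; coordinates are converted to 0-based
        half-open. ``n_columns``, when given, bounds the trailing igs span.
        """
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        mapped = []
        for f in db.all_features():
            if f.featuretype == "CDS":
                rcls = REGION_CODING
            elif f.featuretype == "intron":
                rcls = REGION_INTRON
            else:
                continue
            mapped.append((f.start - 1, f.end, rcls, f.id or f.featuretype))
        mapped.sort(key=lambda x: (x[0], x[1]))
        feats: list[tuple[int, int, str, str]] = []
        cursor = 0
        igs_i = 0
        for start, end, rcls, name in mapped:
            if start > cursor:
                feats.append((cursor, start, REGION_IGS, f"igs_{igs_i}"))
                igs_i += 1
            feats.append((start, end, rcls, name))
            cursor = max(cursor, end)
        if n_columns is not None and cursor < n_columns:
            feats.append((cursor, n_columns, REGION_IGS, f"igs_{igs_i}"))
        return cls(features=tuple(feats))

    def to_gff3(self, path: str | Path, seqid: str = "alignment") -> None:
        """Write coding/intron features (igs spans are implicit)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for start, end, rcls, name in self.features:
                if rcls == REGION_IGS:
                    continue
                ftype = "CDS" if rcls == REGION_CODING else "intron"
                fh.write(
                    f"{seqid}\tplastgap\t{ftype}\t{start + 1}\t{end}\t.\t+\t.\tID={name}\n"
                )


def extract_gap_runs(aln: MultipleAlignment) -> list[GapRun]:
    """Every maximal gap run per row, in (row order, start) order."""
    runs: list[GapRun] = []
    is_gap = aln.matrix == GAP
    n = aln.n_columns
    for i, taxon in enumerate(aln.taxa):
        g = is_gap[i].astype(np.int8)
        bounds = np.flatnonzero(np.diff(np.concatenate(([0], g, [0]))))
        for start, end in zip(bounds[0::2], bounds[1::2]):
            runs.append(
                GapRun(
                    taxon=taxon,
                    interval=(int(start), int(end)),
                    terminal=(start == 0 or end == n),
                )
            )
    return runs


def cluster_events(runs: Sequence[GapRun]) -> list[IndelEvent]:
    """Merge identical gap footprints into candidate events.

    Terminal runs are excluded entirely (missing data). Events whose
    intervals partially overlap another event's (non-identical,
    non-disjoint — including nested) are flagged ``overlapping``; the flag
    becomes an ``ambiguous_overlap`` rejection in :func:`apply_criteria`.
    Taxon order within an event follows the order runs were supplied
    (alignment row order from :func:`extract_gap_runs`).
    """
    by_interval: dict[tuple[int, int], list[str]] = defaultdict(list)
    for run in runs:
        if run.terminal:
            continue
        by_interval[run.interval].append(run.taxon)
    intervals = sorted(by_interval)
    overlapping: set[tuple[int, int]] = set()
    for (s1, e1), (s2, e2) in itertools.combinations(intervals, 2):
        if s2 >= e1:
            continue  # sorted: disjoint with everything that starts later
        overlapping.add((s1, e1))
        overlapping.add((s2, e2))
    events = []
    for iv in intervals:
        events.append(
            IndelEvent(
                interval=iv,
                gapped_taxa=tuple(by_interval[iv]),
                overlapping=iv in overlapping,
            )
        )
    return events


def _ungapped_row_indices(aln: MultipleAlignment, interval: tuple[int, int]) -> list[int]:
    start, end = interval
    block = aln.matrix[:, start:end]
    return [i for i in range(aln.n_taxa) if not (block[i] == GAP).any()]


def _is_mononucleotide(aln: MultipleAlignment, event: IndelEvent) -> bool:
    """Segment is a single repeated base with a matching adjacent base.

    The segment is read from the first row (alignment order) that is fully
    ungapped across the event interval; if no such row exists the test is
    inapplicable and returns False.
    """
    start, end = event.interval
    rows = _ungapped_row_indices(aln, event.interval)
    if not rows:
        return False
    seg = aln.matrix[rows[0], start:end]
    base = seg[0]
    if base not in b"ACGT" or not (seg == base).all():
        return False
    row = aln.matrix[rows[0]]
    left = row[start - 1] if start > 0 else None
    right = row[end] if end < aln.n_columns else None
    return left == base or right == base


def apply_criteria(
    events: Sequence[IndelEvent],
    aln: MultipleAlignment,
    criteria: IndelCriteria = IndelCriteria(),
) -> list[IndelEvent]:
    """Assign accepted/rejected status with the first failing criterion."""
    out = []
    for ev in events:
        if ev.interval[1] > aln.n_columns or ev.interval[0] < 0:
            raise ConsistencyError(f"event interval {ev.interval} outside alignment")
        reason = None
        if ev.length < criteria.min_length:
            reason = TOO_SHORT
        elif criteria.exclude_mononucleotide and _is_mononucleotide(aln, ev):
            reason = MONONUCLEOTIDE
        elif criteria.require_non_overlap and ev.overlapping:
            reason = AMBIGUOUS_OVERLAP
        elif len(ev.gapped_taxa) < criteria.min_shared:
            reason = AUTAPOMORPHIC
        if reason is None:
            out.append(replace(ev, status="accepted", reject_reason=None))
        else:
            out.append(replace(ev, status="rejected", reject_reason=reason))
    return out


def _consensus_segment(
    aln: MultipleAlignment, rows: Sequence[int], start: int, end: int
) -> list[bytes | None]:
    """Per-column majority base over the given rows.

    Only unambiguous bases vote; ties are broken by the earliest row whose
    base is among the tied maxima; a column with no voting base yields None.
    """
    seg: list[bytes | None] = []
    block = aln.matrix[:, start:end]
    for j in range(end - start):
        counts: Counter[bytes] = Counter()
        for i in rows:
            c = block[i, j]
            if c in b"ACGT":
                counts[c] += 1
        if not counts:
            seg.append(None)
            continue
        top = max(counts.values())
        tied = {c for c, k in counts.items() if k == top}
        if len(tied) == 1:
            seg.append(next(iter(tied)))
        else:
            pick = next(block[i, j] for i in rows if block[i, j] in tied)
            seg.append(pick)
    return seg


def _identity(a: Sequence[bytes | None], b: Sequence[bytes | None]) -> float:
    matches = sum(1 for x, y in zip(a, b) if x is not None and x == y)
    return matches / len(a)


def detect_ssm(
    event: IndelEvent,
    aln: MultipleAlignment,
    criteria: IndelCriteria = IndelCriteria(),
) -> str:
    """Classify an event as SSM-derived by flank repeat comparison.

    The ungapped segment at the event interval (majority consensus across
    rows without gaps there) is compared with the equal-length windows
    immediately upstream and downstream in the same consensus. ``perfect``
    if either window matches exactly; ``near_perfect`` if the best identity
    reaches ``ssm_identity_threshold``; otherwise ``none``. Windows
    truncated by the alignment edge are skipped.
    """
    start, end = event.interval
    length = end - start
    rows = _ungapped_row_indices(aln, event.interval)
    if not rows:
        raise ConsistencyError(
            f"no taxon is fully ungapped at {event.interval}; SSM undefined"
        )
    seg = _consensus_segment(aln, rows, start, end)
    best = -1.0
    for ws, we in ((start - length, start), (end, end + length)):
        if ws < 0 or we > aln.n_columns:
            continue
        flank = _consensus_segment(aln, rows, ws, we)
        best = max(best, _identity(seg, flank))
    if best == 1.0:
        return SSM_PERFECT
    if best >= criteria.ssm_identity_threshold:
        return SSM_NEAR_PERFECT
    return SSM_NONE


def classify_region(event: IndelEvent, annotation: RegionAnnotation) -> str:
    """Region class of the feature with maximal overlap.

    Ties broken by precedence coding > intron > igs; no overlap ->
    unassigned.
    """
    start, end = event.interval
    best: tuple[int, int] | None = None
    best_cls = REGION_UNASSIGNED
    for fs, fe, cls, _name in annotation.features:
        ov = min(end, fe) - max(start, fs)
        if ov <= 0:
            continue
        key = (ov, _REGION_PRECEDENCE[cls])
        if best is None or key > best:
            best = key
            best_cls = cls
    return best_cls


def catalog_indels(
    aln: MultipleAlignment,
    criteria: IndelCriteria = IndelCriteria(),
    annotation: RegionAnnotation | None = None,
) -> list[IndelEvent]:
    """Full cataloguing pipeline: runs -> events -> criteria -> SSM -> region."""
    events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln, criteria)
    out = []
    for ev in events:
        if ev.status == "accepted":
            ev = replace(ev, ssm=detect_ssm(ev, aln, criteria))
            if annotation is not None:
                ev = replace(ev, region=classify_region(ev, annotation))
        out.append(ev)
    return out


@dataclass(frozen=True)
class BinaryCharacterMatrix:
    """Taxa x indel presence/absence characters.

    States per taxon: ``'1'`` gap present (segment absent), ``'0'`` segment
    present, ``'?'`` missing (N/ambiguity across the whole event interval).
    """

    taxa: tuple[str, ...]
    character_ids: tuple[str, ...]
    states: np.ndarray  # dtype '<U1', shape (n_taxa, n_characters)

    @property
    def n_characters(self) -> int:
        return int(self.states.shape[1])

    def column(self, char_id: str) -> dict[str, str]:
        j = self.character_ids.index(char_id)
        return {t: self.states[i, j] for i, t in enumerate(self.taxa)}

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("taxon\t" + "\t".join(self.character_ids) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(self.states[i]) + "\n")

    def to_nexus(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(
                f"    DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_characters};\n"
            )
            fh.write(
                '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n'
            )
            fh.write("    MATRIX\n")
            width = max((len(t) for t in self.taxa), default=0) + 2
            for i, t in enumerate(self.taxa):
                label = t.replace(" ", "_")
                fh.write(f"    {label:<{width}}{''.join(self.states[i])}\n")
            fh.write("    ;\nEND;\n")


def build_character_matrix(
    events: Sequence[IndelEvent], aln: MultipleAlignment
) -> BinaryCharacterMatrix:
    """Encode accepted events as binary characters against ``aln``'s taxa."""
    accepted = [ev for ev in events if ev.status == "accepted"]
    states = np.full((aln.n_taxa, len(accepted)), "0", dtype="<U1")
    missing = np.isin(aln.matrix, np.frombuffer(bytes(_MISSING_BYTES), dtype="S1"))
    for j, ev in enumerate(accepted):
        start, end = ev.interval
        for t in ev.gapped_taxa:
            if t not in aln.taxa:
                raise ConsistencyError(f"event taxon {t!r} not in alignment")
            states[aln.taxa.index(t), j] = "1"
        all_missing = missing[:, start:end].all(axis=1)
        for i in np.flatnonzero(all_missing):
            if aln.taxa[i] not in ev.gapped_taxa:
                states[i, j] = "?"
    return BinaryCharacterMatrix(
        taxa=aln.taxa,
        character_ids=tuple(ev.event_id for ev in accepted),
        states=states,
    )


def summarize_catalog(events: Sequence[IndelEvent]) -> dict[str, int]:
    """Counts mirroring the printed indel summary: totals, per-reason
    rejections, SSM classes and region classes over accepted events."""
    summary: dict[str, int] = {
        "total_candidates": len(events),
        "accepted": sum(e.status == "accepted" for e in events),
    }
    for reason in (TOO_SHORT, MONONUCLEOTIDE, AMBIGUOUS_OVERLAP, AUTAPOMORPHIC):
        summary[f"rejected_{reason}"] = sum(e.reject_reason == reason for e in events)
    for ssm in (SSM_PERFECT, SSM_NEAR_PERFECT, SSM_NONE):
        summary[f"ssm_{ssm}"] = sum(
            e.status == "accepted" and e.ssm == ssm for e in events
        )
    summary["ssm_attributed"] = summary["ssm_perfect"] + summary["ssm_near_perfect"]
    for region in (REGION_CODING, REGION_INTRON, REGION_IGS, REGION_UNASSIGNED):
        summary[f"region_{region}"] = sum(
            e.status == "accepted" and e.region == region for e in events
        )
    return summary


_CATALOG_COLUMNS = (
    "event_id\tstart\tend\tlength\tstatus\treject_reason\tssm\tregion\tgapped_taxa\tmissing_taxa"
)


def write_catalog_tsv(
    events: Sequence[IndelEvent],
    aln: MultipleAlignment,
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    missing = np.isin(aln.matrix, np.frombuffer(bytes(_MISSING_BYTES), dtype="S1"))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(_CATALOG_COLUMNS + "\n")
        for ev in events:
            start, end = ev.interval
            all_missing = missing[:, start:end].all(axis=1)
            miss = [
                aln.taxa[i]
                for i in np.flatnonzero(all_missing)
                if aln.taxa[i] not in ev.gapped_taxa
            ]
            fh.write(
                "\t".join(
                    [
                        ev.event_id,
                        str(start),
                        str(end),
                        str(ev.length),
                        ev.status,
                        ev.reject_reason or ".",
                        ev.ssm,
                        ev.region,
                        ",".join(ev.gapped_taxa),
                        ",".join(miss) or ".",
                    ]
                )
                + "\n"
            )


def read_catalog_tsv(path: str | Path) -> list[dict]:
    """Parse a catalogue TSV back into row dicts (taxa lists split)."""
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = dict(zip(header, line.split("\t")))
            vals["start"] = int(vals["start"])
            vals["end"] = int(vals["end"])
            vals["length"] = int(vals["length"])
            vals["gapped_taxa"] = (
                vals["gapped_taxa"].split(",") if vals["gapped_taxa"] != "." else []
            )
            vals["missing_taxa"] = (
                vals["missing_taxa"].split(",") if vals["missing_taxa"] != "." else []
            )
            rows.append(vals)
    if header is None:
        raise ParseError(f"{path}: empty catalogue")
    return rows
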