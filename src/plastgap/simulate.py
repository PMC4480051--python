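"""Synthetic plastome-alignment generator with indel ground truth.

Emulates the inputs the analysis modules expect, with no downloads: a
clocklike pure-birth (Yule) tree, K80-class substitution simulation along
its branches (transition/transversion ratio kappa, optional gamma rate
heterogeneity), indel events of length >= 2 injected on branches — a
configurable fraction SSM-type (a segment duplicating the immediately
adjacent motif) and a fraction mononucleotide-repeat contractions or
expansions — plus optional terminal-gap missing data. Every injected event
is recorded as ground truth (branch, final alignment interval, type,
member taxa) for recovery testing.

Construction guarantees, by design rather than by chance:

* events never overlap (rejection sampling with reserved flank windows);
* SSM events have a perfect adjacent duplicate at creation time;
* plain events are resampled until their flank identity is below the SSM
  threshold and they are not homopolymer-adjacent, so ground-truth SSM
  labels are unambiguous;
* by default events are placed only on branches whose descendant set
  excludes the designated outgroup leaf and has between 2 and n-2 members,
  so every event is shared (criterion iv), polarizable against the
  outgroup, and synapomorphic for its branch's descendants.

A stress mode (``ssm_flank_noise``) substitutes bases in SSM upstream
flanks after assembly, degrading repeat identity for negative tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import yaml

from .alignment import MultipleAlignment
from .errors import ConfigurationError, ConsistencyError, DensityError
from .indels import SSM_NONE, SSM_PERFECT, RegionAnnotation

_CODE2BYTE = np.frombuffer(b"AGCT", dtype="S1")  # purines 0,1; pyrimidines 2,3
_GAP = np.frombuffer(b"-", dtype="S1")[0]

TYPE_SSM_INSERTION = "ssm_insertion"
TYPE_SSM_DELETION = "ssm_deletion"
TYPE_PLAIN_INSERTION = "plain_insertion"
TYPE_PLAIN_DELETION = "plain_deletion"
TYPE_MONO_INSERTION = "mononucleotide_insertion"
TYPE_MONO_DELETION = "mononucleotide_deletion"
_SSM_TYPES = frozenset({TYPE_SSM_INSERTION, TYPE_SSM_DELETION})
_MONO_TYPES = frozenset({TYPE_MONO_INSERTION, TYPE_MONO_DELETION})
_INSERTION_TYPES = frozenset(
    {TYPE_SSM_INSERTION, TYPE_PLAIN_INSERTION, TYPE_MONO_INSERTION}
)


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale defaults: 20 taxa x 20 kb, plastome-like divergence.

    ``events_per_branch`` is the Poisson mean per eligible branch;
    ``ssm_fraction`` / ``mononucleotide_fraction`` partition events by
    type; indel lengths are min_indel_length + Geometric(p) - 1. Branch
    lengths are in expected substitutions per site (pure-birth waiting
    times multiplied by ``rate``).
    """

    n_taxa: int = 20
    sequence_length: int = 20_000
    birth_rate: float = 1.0
    rate: float = 0.01  # expected substitutions per site per unit time
    kappa: float = 2.0
    gamma_shape: float | None = None
    events_per_branch: float = 3.5
    ssm_fraction: float = 0.47
    mononucleotide_fraction: float = 0.10
    length_geometric_p: float = 0.35
    min_indel_length: int = 2
    ssm_identity_threshold: float = 0.80
    terminal_gap_fraction: float = 0.0
    terminal_gap_mean: int = 200
    ssm_flank_noise: int = 0
    mean_feature_length: int = 1_000
    coding_fraction: float = 0.25
    intron_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ConfigurationError("n_taxa must be >= 4")
        if self.sequence_length < 1000:
            raise ConfigurationError("sequence_length must be >= 1000")
        if not (0 <= self.ssm_fraction <= 1 and 0 <= self.mononucleotide_fraction <= 1):
            raise ConfigurationError("type fractions must lie in [0, 1]")
        if self.ssm_fraction + self.mononucleotide_fraction > 1:
            raise ConfigurationError("ssm + mononucleotide fractions exceed 1")
        for name in ("birth_rate", "rate", "events_per_branch"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class TruthEvent:
    """Ground truth for one injected indel."""

    event_id: str
    branch: frozenset[str]  # descendant leaf set of the bearing branch
    type: str
    alignment_interval: tuple[int, int]
    length: int
    member_taxa: frozenset[str]  # taxa bearing the event (== branch)
    gapped_taxa: frozenset[str]  # taxa showing the gap footprint

    @property
    def is_insertion(self) -> bool:
        return self.type in _INSERTION_TYPES

    @property
    def is_mononucleotide(self) -> bool:
        return self.type in _MONO_TYPES

    @property
    def expected_ssm(self) -> str:
        return SSM_PERFECT if self.type in _SSM_TYPES else SSM_NONE


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    alignment: MultipleAlignment
    annotation: RegionAnnotation
    truth: tuple[TruthEvent, ...]
    outgroup: str
    sequences: dict[str, str]  # per-taxon gapless sequences (post-indel)


def simulate_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Yule (pure-birth) tree with ``n_taxa`` leaves.

    The waiting time with k lineages is Exp(k * birth_rate); a final wait
    with all n lineages present is included, so the expected root height is
    (rate / birth_rate) * sum_{k=2..n} 1/k in branch-length units.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    pend: dict[int, float] = {}
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = root.new_child()
        pend[id(child)] = 0.0
        active.append(child)
    while True:
        k = len(active)
        dt = rng.exponential(1.0 / (k * config.birth_rate))
        for nd in active:
            pend[id(nd)] += dt
        if k == n:
            break
        split = active.pop(int(rng.integers(k)))
        split.edge.length = pend[id(split)] * config.rate
        for _ in range(2):
            child = split.new_child()
            pend[id(child)] = 0.0
            active.append(child)
    for nd in active:
        nd.edge.length = pend[id(nd)] * config.rate
    width = len(str(n))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"t{i + 1:0{width}d}")
    root.edge.length = None
    return tree


def evolve_sequences(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """K80 substitution simulation along branches.

    Returns uint8 code arrays (A=0, G=1, C=2, T=3) per leaf label. The
    sequences are column-homologous (substitutions only); column index is
    the residue homology map used for true-alignment construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.sequence_length
    beta = 1.0 / (config.kappa + 2.0)
    alpha = config.kappa * beta
    if config.gamma_shape:
        site_rate = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, L)
    else:
        site_rate = np.ones(L)
    seqs: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.integers(0, 4, L, dtype=np.uint8)
    }
    out: dict[str, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            seq = seqs[id(nd)]
        else:
            parent = seqs[id(nd.parent_node)]
            t = (nd.edge.length or 0.0) * site_rate
            e1 = np.exp(-4.0 * beta * t)
            e2 = np.exp(-2.0 * (alpha + beta) * t)
            p_same = 0.25 + 0.25 * e1 + 0.5 * e2
            p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
            u = rng.random(L)
            seq = parent.copy()
            ts = (u >= p_same) & (u < p_same + p_ts)
            seq[ts] ^= 1  # A<->G, C<->T
            tv = u >= p_same + p_ts
            pick = rng.random(L) < 0.5
            seq[tv] = np.where(pick, (parent + 2) % 4, ((parent ^ 1) + 2) % 4)[tv]
            seqs[id(nd)] = seq
        if nd.is_leaf():
            out[nd.taxon.label] = seqs.setdefault(id(nd), seq)
    return out


def _descendant_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _is_homopolymer(seg: np.ndarray) -> bool:
    return bool((seg == seg[0]).all())


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return float((a == b).mean())


@dataclass
class _Pending:
    anchor: int  # deletion interval start, or insertion point, in root coords
    length: int
    type: str
    members: frozenset[str]
    content: np.ndarray | None  # inserted codes; None => per-row flank copy

    @property
    def is_insertion(self) -> bool:
        return self.type in _INSERTION_TYPES


class _Placer:
    """Non-overlapping placement of reserved root-coordinate windows."""

    def __init__(self, rng: np.random.Generator, length: int, max_tries: int = 500):
        self.rng = rng
        self.L = length
        self.max_tries = max_tries
        self.reserved: list[tuple[int, int]] = []

    def free(self, start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in self.reserved)

    def reserve(self, start: int, end: int) -> None:
        self.reserved.append((start, end))


def _draw_type(config: SimulationConfig, rng: np.random.Generator) -> str:
    u = rng.random()
    insertion = rng.random() < 0.5
    if u < config.mononucleotide_fraction:
        return TYPE_MONO_INSERTION if insertion else TYPE_MONO_DELETION
    if u < config.mononucleotide_fraction + config.ssm_fraction:
        return TYPE_SSM_INSERTION if insertion else TYPE_SSM_DELETION
    return TYPE_PLAIN_INSERTION if insertion else TYPE_PLAIN_DELETION


def _position_ok(
    M: np.ndarray, ref: int, s: int, ell: int, etype: str, thr: float
) -> bool:
    """Content screen at anchor ``s`` read from reference row ``ref``."""
    seg = M[ref, s : s + ell]
    up = M[ref, s - ell : s]
    down = M[ref, s + ell : s + 2 * ell]
    if etype == TYPE_SSM_INSERTION:
        return not _is_homopolymer(up)
    if etype == TYPE_SSM_DELETION:
        return not _is_homopolymer(seg)
    if etype == TYPE_PLAIN_DELETION:
        return (
            not _is_homopolymer(seg)
            and _identity(seg, up) < thr
            and _identity(seg, down) < thr
        )
    return True  # plain insertions screen content instead; mono overwrites


def _sample_plain_content(
    M: np.ndarray, ref: int, p: int, ell: int, thr: float, rng: np.random.Generator
) -> np.ndarray:
    up = M[ref, p - ell : p]
    down = M[ref, p : p + ell]
    for _ in range(200):
        c = rng.integers(0, 4, ell, dtype=np.uint8)
        if _is_homopolymer(c):
            continue
        if _identity(c, up) < thr and _identity(c, down) < thr:
            return c
    raise DensityError("could not sample non-SSM insertion content")


def inject_indels(
    leaf_seqs: Mapping[str, np.ndarray],
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    branches: Sequence[Iterable[str]] | None = None,
) -> SyntheticDataset:
    """Inject indel events on branches and build the true alignment.

    ``branches``, when given, restricts events to the branches whose
    descendant leaf sets match the given sets (overriding the default
    eligibility rule; one Poisson draw per listed branch).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taxa = tuple(sorted(leaf_seqs))
    n = len(taxa)
    row_of = {t: i for i, t in enumerate(taxa)}
    L = config.sequence_length
    M = np.stack([np.asarray(leaf_seqs[t], dtype=np.uint8) for t in taxa])

    # designated outgroup: first leaf of the smaller root-child clade
    sides = sorted(
        (_descendant_labels(c) for c in tree.seed_node.child_nodes()),
        key=lambda s: (len(s), sorted(s)),
    )
    outgroup = min(sides[0])

    if branches is not None:
        available = {
            _descendant_labels(nd)
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        }
        candidates = []
        for b in branches:
            b = frozenset(b)
            if b not in available:
                raise ConsistencyError(f"no branch with descendant set {sorted(b)}")
            candidates.append(b)
    else:
        candidates = [
            d
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
            for d in [_descendant_labels(nd)]
            if outgroup not in d and 2 <= len(d) <= n - 2
        ]

    placer = _Placer(rng, L)
    thr = config.ssm_identity_threshold
    pending: list[_Pending] = []
    for desc in candidates:
        for _ in range(rng.poisson(config.events_per_branch)):
            etype = _draw_type(config, rng)
            ell = (
                config.min_indel_length
                + int(rng.geometric(config.length_geometric_p))
                - 1
            )
            member_rows = [row_of[t] for t in sorted(desc)]
            nonmember_rows = [i for i in range(n) if taxa[i] not in desc]
            ref = member_rows[0] if etype in _INSERTION_TYPES else nonmember_rows[0]
            lo, hi = ell + 2, L - 2 * ell - 2
            if hi <= lo:
                raise DensityError(f"sequence too short for event length {ell}")
            for _try in range(placer.max_tries):
                s = int(rng.integers(lo, hi))
                win = (s - ell - 2, s + 2 * ell + 2)
                if placer.free(*win) and _position_ok(M, ref, s, ell, etype, thr):
                    break
            else:
                raise DensityError(
                    "could not place event without overlap; lower events_per_branch"
                )
            placer.reserve(*win)
            content: np.ndarray | None = None
            if etype == TYPE_MONO_INSERTION:
                base = np.uint8(rng.integers(0, 4))
                M[:, s - 1] = base
                content = np.full(ell, base, dtype=np.uint8)
            elif etype == TYPE_MONO_DELETION:
                base = np.uint8(rng.integers(0, 4))
                M[:, s - 1 : s + ell] = base
            elif etype == TYPE_SSM_DELETION:
                M[:, s - ell : s] = M[:, s : s + ell]  # per-row tandem duplicate
            elif etype == TYPE_PLAIN_INSERTION:
                content = _sample_plain_content(M, ref, s, ell, thr, rng)
            pending.append(
                _Pending(anchor=s, length=ell, type=etype, members=desc, content=content)
            )

    return _assemble(config, tree, taxa, M, pending, outgroup, rng)


def _assemble(
    config: SimulationConfig,
    tree: dendropy.Tree,
    taxa: tuple[str, ...],
    M: np.ndarray,
    pending: list[_Pending],
    outgroup: str,
    rng: np.random.Generator,
) -> SyntheticDataset:
    n, L = M.shape
    row_of = {t: i for i, t in enumerate(taxa)}
    all_taxa = frozenset(taxa)
    B = _CODE2BYTE[M]  # (n, L) byte matrix in root coordinates

    deletions = [ev for ev in pending if not ev.is_insertion]
    insertions = sorted(
        (ev for ev in pending if ev.is_insertion), key=lambda ev: ev.anchor
    )
    for ev in deletions:
        rows = [row_of[t] for t in ev.members]
        B[rows, ev.anchor : ev.anchor + ev.length] = _GAP

    ins_pos = np.array([ev.anchor for ev in insertions], dtype=int)
    ins_len = np.array([ev.length for ev in insertions], dtype=int)

    def offset_at(root_col: int) -> int:
        return int(ins_len[ins_pos < root_col].sum())

    pieces: list[np.ndarray] = []
    ins_blocks: dict[int, np.ndarray] = {}
    cursor = 0
    for k, ev in enumerate(insertions):
        pieces.append(B[:, cursor : ev.anchor])
        block = np.full((n, ev.length), _GAP, dtype="S1")
        for t in ev.members:
            i = row_of[t]
            if ev.content is None:  # SSM: copy of the row's own upstream flank
                block[i] = _CODE2BYTE[M[i, ev.anchor - ev.length : ev.anchor]]
            else:
                block[i] = _CODE2BYTE[ev.content]
        ins_blocks[k] = block
        pieces.append(block)
        cursor = ev.anchor
    pieces.append(B[:, cursor:])
    final = np.concatenate(pieces, axis=1) if pieces else B

    truth: list[TruthEvent] = []
    eid = 0
    for ev in deletions:
        off = offset_at(ev.anchor)
        start = ev.anchor + off
        truth.append(
            TruthEvent(
                event_id=f"sim_{eid:03d}",
                branch=ev.members,
                type=ev.type,
                alignment_interval=(start, start + ev.length),
                length=ev.length,
                member_taxa=ev.members,
                gapped_taxa=ev.members,
            )
        )
        eid += 1
    for k, ev in enumerate(insertions):
        start = ev.anchor + int(ins_len[:k].sum())
        truth.append(
            TruthEvent(
                event_id=f"sim_{eid:03d}",
                branch=ev.members,
                type=ev.type,
                alignment_interval=(start, start + ev.length),
                length=ev.length,
                member_taxa=ev.members,
                gapped_taxa=all_taxa - ev.members,
            )
        )
        eid += 1
    truth.sort(key=lambda t: t.alignment_interval)

    # stress mode: degrade SSM upstream-flank identity after assembly
    if config.ssm_flank_noise:
        for tr in truth:
            if tr.expected_ssm != SSM_PERFECT:
                continue
            start, _ = tr.alignment_interval
            cols = rng.choice(
                np.arange(start - tr.length, start),
                size=min(config.ssm_flank_noise, tr.length),
                replace=False,
            )
            for c in cols:
                current = final[:, c].copy()
                shift = np.uint8(rng.integers(1, 4))
                for i in range(n):
                    if current[i] != _GAP:
                        code = int(np.flatnonzero(_CODE2BYTE == current[i])[0])
                        final[i, c] = _CODE2BYTE[(code + shift) % 4]

    # per-taxon gapless sequences via an independent splice path (exact when
    # ssm_flank_noise == 0; the stress mode mutates the assembled matrix only)
    sequences: dict[str, str] = {}
    for t in taxa:
        i = row_of[t]
        dels = sorted(
            (ev.anchor, ev.anchor + ev.length)
            for ev in deletions
            if t in ev.members
        )
        parts: list[np.ndarray] = []
        cur = 0
        for k, ev in enumerate(insertions):
            parts.append(_segment_without(M[i], cur, ev.anchor, dels))
            if t in ev.members:
                parts.append(ins_blocks[k][i])
            cur = ev.anchor
        parts.append(_segment_without(M[i], cur, L, dels))
        sequences[t] = np.concatenate(parts).tobytes().decode()

    # terminal-gap missing data (incomplete assemblies)
    if config.terminal_gap_fraction > 0:
        n_masked = int(round(config.terminal_gap_fraction * n))
        rows = rng.choice(n, size=n_masked, replace=False)
        for i in rows:
            g = int(rng.geometric(1.0 / config.terminal_gap_mean))
            g = min(g, final.shape[1] // 4)
            if rng.random() < 0.5:
                removed = int((final[i, :g] != _GAP).sum())
                final[i, :g] = _GAP
                sequences[taxa[i]] = sequences[taxa[i]][removed:]
            else:
                removed = int((final[i, final.shape[1] - g :] != _GAP).sum())
                final[i, final.shape[1] - g :] = _GAP
                if removed:
                    sequences[taxa[i]] = sequences[taxa[i]][:-removed]

    alignment = MultipleAlignment(taxa=taxa, matrix=final)
    annotation = _simulate_annotation(config, final.shape[1], rng)
    return SyntheticDataset(
        config=config,
        tree=tree,
        alignment=alignment,
        annotation=annotation,
        truth=tuple(truth),
        outgroup=outgroup,
        sequences=sequences,
    )


def _segment_without(
    row: np.ndarray, start: int, end: int, dels: list[tuple[int, int]]
) -> np.ndarray:
    """Byte codes of row[start:end] minus deleted intervals."""
    keep = np.ones(end - start, dtype=bool)
    for ds, de in dels:
        a, b = max(ds, start), min(de, end)
        if a < b:
            keep[a - start : b - start] = False
    return _CODE2BYTE[row[start:end][keep]]


def _simulate_annotation(
    config: SimulationConfig, n_columns: int, rng: np.random.Generator
) -> RegionAnnotation:
    """Alternating feature/spacer layout over the final alignment columns."""
    feats: list[tuple[int, int, str, str]] = []
    cursor = 0
    fid = 0
    igs_i = 0
    p = 1.0 / config.mean_feature_length
    while cursor < n_columns:
        block = min(int(rng.geometric(p)), n_columns - cursor)
        u = rng.random()
        if u < config.coding_fraction:
            feats.append((cursor, cursor + block, "coding", f"cds_{fid}"))
            fid += 1
        elif u < config.coding_fraction + config.intron_fraction:
            feats.append((cursor, cursor + block, "intron", f"intron_{fid}"))
            fid += 1
        else:
            feats.append((cursor, cursor + block, "igs", f"igs_{igs_i}"))
            igs_i += 1
        cursor += block
    # merge adjacent same-class blocks and renumber igs spans so that the
    # GFF3 round trip (igs = inter-feature complement) is exact
    merged: list[tuple[int, int, str, str]] = []
    for f in feats:
        if merged and merged[-1][2] == f[2] and merged[-1][1] == f[0]:
            prev = merged.pop()
            merged.append((prev[0], f[1], prev[2], prev[3]))
        else:
            merged.append(f)
    out: list[tuple[int, int, str, str]] = []
    igs_i = 0
    for start, end, cls, name in merged:
        if cls == "igs":
            out.append((start, end, cls, f"igs_{igs_i}"))
            igs_i += 1
        else:
            out.append((start, end, cls, name))
    return RegionAnnotation(features=tuple(out))


def simulate_dataset(
    config: SimulationConfig, branches: Sequence[Iterable[str]] | None = None
) -> SyntheticDataset:
    """One-shot pipeline: tree -> sequences -> indels, from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    seqs = evolve_sequences(tree, config, rng)
    return inject_indels(seqs, tree, config, rng, branches=branches)


# ---------------------------------------------------------------------------
# persistence


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Write alignment FASTA, tree Newick, annotation GFF3, truth TSV and
    the generating config; :func:`read_dataset` reproduces the dataset."""
    from .alignment import write_alignment

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_alignment(dataset.alignment, d / "alignment.fasta")
    dataset.tree.write(path=str(d / "tree.nwk"), schema="newick", unquoted_underscores=True)
    dataset.annotation.to_gff3(d / "annotation.gff3")
    dataset.config.to_yaml(d / "config.yaml")
    with open(d / "truth.tsv", "w") as fh:
        fh.write(f"# outgroup\t{dataset.outgroup}\n")
        fh.write(
            "event_id\ttype\tstart\tend\tlength\tmember_taxa\tgapped_taxa\n"
        )
        for tr in dataset.truth:
            fh.write(
                "\t".join(
                    [
                        tr.event_id,
                        tr.type,
                        str(tr.alignment_interval[0]),
                        str(tr.alignment_interval[1]),
                        str(tr.length),
                        ",".join(sorted(tr.member_taxa)),
                        ",".join(sorted(tr.gapped_taxa)),
                    ]
                )
                + "\n"
            )
    with open(d / "sequences.fasta", "w") as fh:
        for t in dataset.alignment.taxa:
            fh.write(f">{t}\n{dataset.sequences[t]}\n")


def read_dataset(directory: str | Path) -> SyntheticDataset:
    from .alignment import read_alignment
    from .treemap import read_tree

    d = Path(directory)
    config = SimulationConfig.from_yaml(d / "config.yaml")
    alignment = read_alignment(d / "alignment.fasta")
    tree = read_tree(d / "tree.nwk")
    annotation = RegionAnnotation.from_gff3(d / "annotation.gff3", alignment.n_columns)
    truth: list[TruthEvent] = []
    outgroup = ""
    with open(d / "truth.tsv") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# outgroup"):
                outgroup = line.split("\t")[1]
                continue
            if not header_seen:
                header_seen = True
                continue
            eid, etype, start, end, length, members, gapped = line.split("\t")
            truth.append(
                TruthEvent(
                    event_id=eid,
                    branch=frozenset(members.split(",")),
                    type=etype,
                    alignment_interval=(int(start), int(end)),
                    length=int(length),
                    member_taxa=frozenset(members.split(",")),
                    gapped_taxa=frozenset(gapped.split(",")),
                )
            )
    sequences = {}
    with open(d / "sequences.fasta") as fh:
        label = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                label = line[1:]
                sequences[label] = ""
            elif label:
                sequences[label] += line
    return SyntheticDataset(
        config=config,
        tree=tree,
        alignment=alignment,
        annotation=annotation,
        truth=tuple(truth),
        outgroup=outgroup,
        sequences=sequences,
    )


# ---------------------------------------------------------------------------
# recovery scoring against ground truth


@dataclass(frozen=True)
class RecoveryScore:
    n_truth: int  # recoverable (non-mononucleotide) truth events
    n_accepted: int
    interval_precision: float
    interval_recall: float
    membership_accuracy: float  # over interval-matched events
    ssm_accuracy: float  # over interval-matched events
    mononucleotide_rejected: bool  # every mono truth event rejected as such


def score_recovery(dataset: SyntheticDataset, criteria=None) -> RecoveryScore:
    """Catalogue the synthetic alignment and compare with ground truth."""
    from .indels import IndelCriteria, MONONUCLEOTIDE, catalog_indels

    criteria = criteria or IndelCriteria(
        ssm_identity_threshold=dataset.config.ssm_identity_threshold
    )
    events = catalog_indels(dataset.alignment, criteria)
    accepted = {ev.interval: ev for ev in events if ev.status == "accepted"}
    truth_rec = {
        tr.alignment_interval: tr for tr in dataset.truth if not tr.is_mononucleotide
    }
    matched = set(accepted) & set(truth_rec)
    n_acc, n_tru = len(accepted), len(truth_rec)
    membership = ssm_ok = 0
    for iv in matched:
        ev, tr = accepted[iv], truth_rec[iv]
        if frozenset(ev.gapped_taxa) == tr.gapped_taxa:
            membership += 1
        if ev.ssm == tr.expected_ssm:
            ssm_ok += 1
    mono_truth = [tr for tr in dataset.truth if tr.is_mononucleotide]
    by_interval = {ev.interval: ev for ev in events}
    mono_ok = all(
        by_interval.get(tr.alignment_interval) is not None
        and by_interval[tr.alignment_interval].reject_reason == MONONUCLEOTIDE
        for tr in mono_truth
    )
    nm = len(matched)
    return RecoveryScore(
        n_truth=n_tru,
        n_accepted=n_acc,
        interval_precision=nm / n_acc if n_acc else 1.0,
        interval_recall=nm / n_tru if n_tru else 1.0,
        membership_accuracy=membership / nm if nm else 1.0,
        ssm_accuracy=ssm_ok / nm if nm else 1.0,
        mononucleotide_rejected=mono_ok,
    )


@dataclass(frozen=True)
class TabulationScore:
    n_branches: int
    n_matching: int  # branches whose tabulated count equals injections
    homoplastic_total: int

    @property
    def all_match(self) -> bool:
        return self.n_matching == self.n_branches and self.homoplastic_total == 0


def score_tabulation(dataset: SyntheticDataset, criteria=None) -> TabulationScore:
    """Map recovered characters on the true tree and compare the per-clade
    tabulation with per-branch injection counts."""
    from collections import Counter

    from .indels import IndelCriteria, build_character_matrix, catalog_indels
    from .treemap import map_characters, tabulate_clades

    criteria = criteria or IndelCriteria(
        ssm_identity_threshold=dataset.config.ssm_identity_threshold
    )
    events = catalog_indels(dataset.alignment, criteria)
    matrix = build_character_matrix(events, dataset.alignment)
    classifications = map_characters(
        dataset.tree, matrix, outgroup=[dataset.outgroup]
    )
    tab = tabulate_clades(
        classifications,
        clade_defs={
            ",".join(sorted(b)): b
            for b in {tr.branch for tr in dataset.truth if not tr.is_mononucleotide}
        },
    )
    injected = Counter(
        tr.branch for tr in dataset.truth if not tr.is_mononucleotide
    )
    n_match = sum(
        1
        for branch, count in injected.items()
        if tab.count_for(",".join(sorted(branch))) == count
    )
    return TabulationScore(
        n_branches=len(injected),
        n_matching=n_match,
        homoplastic_total=tab.homoplastic_total,
    )
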