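"""Outgroup-randomization (jackknife) congruence experiment.

Repeatedly draws one outgroup representative per lineage pool, re-infers
the tree for ingroup + drawn outgroups, prunes the outgroups, and asks
whether the ingroup topology is stable across draws, summarizing per-node
bootstrap support variability (mean +/- sample standard deviation).

The built-in inference backend is distance-based — Jukes–Cantor distances,
neighbor joining, and nonparametric bootstrap supports from seeded column
resampling — so the experiment runs at desk scale. An external
maximum-likelihood program can be wrapped instead (its command line is
recorded verbatim); it is never reimplemented here.

Per-iteration randomness is derived from the master seed and the drawn
outgroup set (``SeedSequence([seed, crc32(selection)])``), so any single
iteration can be reproduced in isolation and identical draws yield
identical analyses — with singleton pools every iteration is exactly the
same, giving zero support variance by construction.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from skbio import DistanceMatrix
from skbio.tree import nj

from .alignment import MultipleAlignment
from .errors import BackendError, ConfigurationError, ConsistencyError, DataError
from .treemap import parse_tree

_JC_MAX = 5.0  # distance cap when p >= 3/4 (saturation)


@dataclass(frozen=True)
class OutgroupPool:
    """Named pools of candidate outgroup taxa (labels in the alignment)."""

    pools: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, members in self.pools.items():
            if not members:
                raise ConfigurationError(f"outgroup pool {name!r} is empty")

    @classmethod
    def from_config(cls, path: str | Path) -> "OutgroupPool":
        """Plain-text config: ``pool_name: taxon1, taxon2, ...`` per line."""
        pools: dict[str, tuple[str, ...]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ConfigurationError(f"bad pool line: {line!r}")
                name, rest = line.split(":", 1)
                members = tuple(t.strip() for t in rest.split(",") if t.strip())
                pools[name.strip()] = members
        return cls(pools=pools)


@dataclass(frozen=True)
class JackknifeConfig:
    n_iterations: int = 16
    seed: int = 0
    backend: str = "builtin_nj"
    bootstrap_replicates: int = 100
    with_replacement: bool = True  # pool draws independent across iterations
    external_cmd: str | None = None  # template for the external_ml backend

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.backend not in {"builtin_nj", "external_ml"}:
            raise ConfigurationError(f"unknown backend {self.backend!r}")


@dataclass
class IterationResult:
    index: int
    chosen_outgroups: dict[str, str]
    tree: dendropy.Tree  # full tree, supports on internal nodes
    ingroup_tree: dendropy.Tree  # outgroups pruned
    ingroup_supports: dict[frozenset[str], float]  # bipartition -> % support


def sample_outgroups(
    pools: OutgroupPool, config: JackknifeConfig
) -> list[dict[str, str]]:
    """One uniform draw per pool per iteration, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    names = sorted(pools.pools)
    if config.with_replacement:
        return [
            {name: str(rng.choice(pools.pools[name])) for name in names}
            for _ in range(config.n_iterations)
        ]
    orders = {}
    for name in names:
        members = pools.pools[name]
        if len(members) < config.n_iterations:
            raise ConfigurationError(
                f"pool {name!r} has {len(members)} members; "
                f"{config.n_iterations} needed without replacement"
            )
        orders[name] = [members[i] for i in rng.permutation(len(members))]
    return [
        {name: orders[name][i] for name in names}
        for i in range(config.n_iterations)
    ]


def jc_distance_matrix(aln: MultipleAlignment) -> np.ndarray:
    """Jukes–Cantor pairwise distances over shared unambiguous columns."""
    codes = aln.codes()
    valid = codes < 4
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        shared = valid[i] & valid[j]
        ns = int(shared.sum())
        if ns == 0:
            raise DataError(
                f"no shared unambiguous columns between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
            )
        p = float((shared & (codes[i] != codes[j])).sum()) / ns
        d[i, j] = d[j, i] = _jc(p)
    return d


def _jc(p: float) -> float:
    if p >= 0.75:
        return _JC_MAX
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _nj_tree(distances: np.ndarray, taxa: Sequence[str]) -> dendropy.Tree:
    dm = DistanceMatrix(distances, ids=list(taxa))
    newick = str(nj(dm))
    return parse_tree(newick)


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the side not containing the alphabetically first leaf."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def _restrict(biparts: Iterable[frozenset[str]], keep: frozenset[str]) -> set[frozenset[str]]:
    ref = min(keep)
    out = set()
    for side in biparts:
        side = frozenset(side) & keep
        if ref in side:
            side = keep - side
        if 2 <= len(side) <= len(keep) - 2:
            out.add(side)
    return out


def run_iteration(
    aln: MultipleAlignment,
    ingroup: Sequence[str],
    selection: Mapping[str, str],
    config: JackknifeConfig,
    index: int,
) -> IterationResult:
    """Infer one support-annotated tree for ingroup + selected outgroups."""
    outgroups = [selection[name] for name in sorted(selection)]
    taxa = list(ingroup) + outgroups
    missing = [t for t in taxa if t not in aln.taxa]
    if missing:
        raise ConsistencyError(f"taxa absent from alignment: {missing}")
    sub = aln.subset(taxa)
    if config.backend == "external_ml":
        tree = _external_ml_tree(sub, config)
    else:
        key = zlib.crc32(",".join(outgroups).encode())
        tree = _builtin_nj_tree(sub, config, key)
    ingroup_set = frozenset(ingroup)
    support_map = {
        bp: getattr(nd, "support", None)
        for bp, nd in _bipartition_nodes(tree).items()
    }
    ingroup_supports: dict[frozenset[str], float] = {}
    if len(ingroup_set) >= 4:
        for bp, sup in support_map.items():
            for side in _restrict([bp], ingroup_set):
                if sup is not None:
                    prev = ingroup_supports.get(side)
                    ingroup_supports[side] = max(prev, sup) if prev is not None else sup
    from .treemap import prune_taxa

    ingroup_tree = prune_taxa(tree, set(aln_taxa_of(tree)) - ingroup_set)
    return IterationResult(
        index=index,
        chosen_outgroups=dict(selection),
        tree=tree,
        ingroup_tree=ingroup_tree,
        ingroup_supports=ingroup_supports,
    )


def aln_taxa_of(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _bipartition_nodes(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out[side] = nd
    return out


def _builtin_nj_tree(
    sub: MultipleAlignment, config: JackknifeConfig, selection_key: int
) -> dendropy.Tree:
    # Seeded by (master seed, drawn outgroup set): identical draws yield
    # byte-identical analyses, so degenerate pools give sd 0 at every node,
    # and any single iteration is reproducible in isolation.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, selection_key]))
    codes = sub.codes()
    n, ncols = codes.shape
    pairs = list(combinations(range(n), 2))
    shared = np.empty((len(pairs), ncols), dtype=np.float64)
    mismatch = np.empty_like(shared)
    valid = codes < 4
    for k, (i, j) in enumerate(pairs):
        s = valid[i] & valid[j]
        shared[k] = s
        mismatch[k] = s & (codes[i] != codes[j])

    def tree_from_weights(w: np.ndarray) -> dendropy.Tree:
        ns = shared @ w
        nm = mismatch @ w
        if (ns == 0).any():
            raise DataError("a taxon pair has no shared unambiguous columns")
        d = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            p = nm[k] / ns[k]
            d[i, j] = d[j, i] = _jc(float(p))
        return _nj_tree(d, sub.taxa)

    base = tree_from_weights(np.ones(ncols))
    node_by_bp = _bipartition_nodes(base)
    counts = {bp: 0 for bp in node_by_bp}
    b = config.bootstrap_replicates
    for _ in range(b):
        w = rng.multinomial(ncols, np.full(ncols, 1.0 / ncols)).astype(np.float64)
        rep = tree_from_weights(w)
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    for bp, nd in node_by_bp.items():
        sup = 100.0 * counts[bp] / b if b else 100.0
        nd.support = sup
        nd.label = f"{sup:g}"
    return base


def _external_ml_tree(sub: MultipleAlignment, config: JackknifeConfig) -> dendropy.Tree:
    """Wrap an external ML program. ``external_cmd`` is a template with
    ``{fasta}`` and ``{out}`` placeholders; the produced Newick at ``{out}``
    is read back. The command line is attached to the tree as ``ml_command``.
    """
    if not config.external_cmd:
        raise BackendError("external_ml backend requires external_cmd")
    prog = config.external_cmd.split()[0]
    if shutil.which(prog) is None:
        raise BackendError(f"external backend executable {prog!r} not found")
    from .alignment import write_alignment

    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "iter.fasta"
        out = Path(tmp) / "iter.nwk"
        write_alignment(sub, fasta)
        cmd = config.external_cmd.format(fasta=fasta, out=out)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            raise BackendError(f"external backend failed: {proc.stderr[-500:]}")
        tree = parse_tree(out.read_text())
    tree.ml_command = cmd
    return tree


@dataclass(frozen=True)
class CongruenceReport:
    rf_distances: tuple[tuple[int, int, int], ...]  # (iter_i, iter_j, rf)
    all_identical: bool
    consensus_bipartitions: frozenset[frozenset[str]]
    consensus_newick: str

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# all_identical\t{str(self.all_identical).lower()}\n")
            fh.write(f"# strict_consensus\t{self.consensus_newick}\n")
            fh.write("iteration_a\titeration_b\trf_distance\n")
            for i, j, rf in self.rf_distances:
                fh.write(f"{i}\t{j}\t{rf}\n")


def compare_ingroup_topologies(results: Sequence[IterationResult]) -> CongruenceReport:
    """Pairwise unrooted RF distances between pruned ingroup topologies,
    an all-identical flag, and the strict consensus."""
    if len(results) < 2:
        raise ConfigurationError("need >= 2 iterations to compare")
    leafsets = {frozenset(aln_taxa_of(r.ingroup_tree)) for r in results}
    if len(leafsets) != 1:
        raise ConsistencyError("ingroup leaf sets differ between iterations")
    tns = dendropy.TaxonNamespace()
    trees = [
        dendropy.Tree.get(
            data=r.ingroup_tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=tns,
            preserve_underscores=True,
        )
        for r in results
    ]
    for t in trees:
        t.is_rooted = False
        t.encode_bipartitions()
    rf = []
    all_identical = True
    for (i, ti), (j, tj) in combinations(enumerate(trees), 2):
        d = int(treecompare.symmetric_difference(ti, tj))
        rf.append((results[i].index, results[j].index, d))
        if d != 0:
            all_identical = False
    consensus = dendropy.TreeList(trees).consensus(min_freq=1.0)
    consensus_bp = frozenset.intersection(
        *[frozenset(bipartitions(r.ingroup_tree)) for r in results]
    )
    return CongruenceReport(
        rf_distances=tuple(rf),
        all_identical=all_identical,
        consensus_bipartitions=consensus_bp,
        consensus_newick=consensus.as_string(schema="newick").strip(),
    )


@dataclass(frozen=True)
class NodeSupportSummary:
    bipartition: frozenset[str]
    mean_support: float
    sd_support: float
    n: int
    in_consensus: bool


def summarize_node_support(
    results: Sequence[IterationResult],
    consensus_bipartitions: Iterable[frozenset[str]] | None = None,
) -> list[NodeSupportSummary]:
    """Mean and sample (n-1) standard deviation of bootstrap support per
    ingroup bipartition, across the iterations containing it."""
    if len(results) < 2:
        raise ConfigurationError("need >= 2 iterations to summarize")
    if consensus_bipartitions is None:
        consensus_bipartitions = frozenset.intersection(
            *[frozenset(r.ingroup_supports) for r in results]
        ) if results else frozenset()
    consensus = set(consensus_bipartitions)
    values: dict[frozenset[str], list[float]] = {}
    for r in results:
        for bp, sup in r.ingroup_supports.items():
            values.setdefault(bp, []).append(sup)
    out = []
    for bp in sorted(values, key=lambda s: (len(s), sorted(s))):
        v = np.array(values[bp], dtype=float)
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        out.append(
            NodeSupportSummary(
                bipartition=bp,
                mean_support=float(v.mean()),
                sd_support=sd,
                n=len(v),
                in_consensus=bp in consensus,
            )
        )
    return out


def write_support_summary_tsv(
    summaries: Sequence[NodeSupportSummary],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("bipartition\tmean_support\tsd_support\tn\tin_consensus\n")
        for s in summaries:
            fh.write(
                f"{','.join(sorted(s.bipartition))}\t{s.mean_support:.4f}\t"
                f"{s.sd_support:.4f}\t{s.n}\t{str(s.in_consensus).lower()}\n"
            )


def run_jackknife(
    aln: MultipleAlignment,
    ingroup: Sequence[str],
    pools: OutgroupPool,
    config: JackknifeConfig,
) -> tuple[list[IterationResult], CongruenceReport, list[NodeSupportSummary]]:
    """Full experiment: sample, infer, prune, compare, summarize."""
    pool_taxa = {t for members in pools.pools.values() for t in members}
    if pool_taxa & set(ingroup):
        raise ConfigurationError(
            f"pool candidates overlap ingroup: {sorted(pool_taxa & set(ingroup))}"
        )
    selections = sample_outgroups(pools, config)
    results = [
        run_iteration(aln, ingroup, sel, config, i)
        for i, sel in enumerate(selections)
    ]
    report = compare_ingroup_topologies(results)
    summaries = summarize_node_support(results, report.consensus_bipartitions)
    return results, report, summaries
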