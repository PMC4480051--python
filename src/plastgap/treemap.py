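"""Mapping binary indel characters onto a reference tree.

Characters encode gap presence (1 = segment absent). Each variable
character is assigned its minimum number of state changes on the tree
(unit-cost small parsimony; exact for binary characters on arbitrary
topologies, including polytomies) and classified:

* ``synapomorphic`` — one change, derived state shared by >= 2 leaves that
  form a clade in the rooted tree;
* ``homoplastic`` — >= 2 changes required;
* ``autapomorphic`` — one change but the derived state is confined to a
  single leaf (should not arise when catalogue criteria were applied);
* ``invariant_excluded`` — no variation among scored leaves.

Polarity (which state is derived) comes from the outgroup state when known,
otherwise from the minority-state heuristic (ties resolved to state 1,
i.e. gap-as-derived). Missing states constrain nothing: such leaves carry
the full state set in the parsimony pass and are ignored by the monophyly
test.

Trees are DendroPy :class:`~dendropy.Tree` objects throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .errors import (
    ConsistencyError,
    OutgroupError,
    ParseError,
    UndefinedCharacterError,
)
from .indels import BinaryCharacterMatrix

MISSING = None
_INF = float("inf")

STATUS_SYNAPOMORPHIC = "synapomorphic"
STATUS_HOMOPLASTIC = "homoplastic"
STATUS_AUTAPOMORPHIC = "autapomorphic"
STATUS_INVARIANT = "invariant_excluded"


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; numeric internal-node labels become supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"could not parse {path} as Newick: {exc}") from exc
    _labels_to_supports(tree)
    return tree


def parse_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"could not parse Newick string: {exc}") from exc
    _labels_to_supports(tree)
    return tree


def _labels_to_supports(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.label is None:
            continue
        try:
            nd.support = float(nd.label)
        except ValueError:
            pass


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def root_with_outgroup(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root a copy of the tree on the branch separating outgroup from ingroup."""
    og = frozenset(outgroup)
    tree = tree.clone(depth=1)
    leaves = frozenset(leaf_labels(tree))
    if not og or not og <= leaves or og == leaves:
        raise OutgroupError(
            f"outgroup must be a proper nonempty subset of leaves; got {sorted(og)}"
        )
    target = None
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        ls = _leafset(nd)
        if ls == og or ls == leaves - og:
            target = nd
            break
    if target is None:
        raise OutgroupError(f"outgroup {sorted(og)} is not separable on this tree")
    edge = target.edge
    if edge.length is not None:
        tree.reroot_at_edge(edge, length1=edge.length / 2.0, length2=edge.length / 2.0)
    else:
        tree.reroot_at_edge(edge)
    tree.is_rooted = True
    return tree


def prune_taxa(tree: dendropy.Tree, drop: Iterable[str]) -> dendropy.Tree:
    """Copy of the tree without the given leaves."""
    drop = set(drop)
    tree = tree.clone(depth=1)
    keep = [t for t in tree.taxon_namespace if t.label not in drop]
    tree.retain_taxa(keep)
    return tree


def _states_for(tree: dendropy.Tree, character: Mapping[str, int | None]) -> dict:
    obs = {}
    for lf in tree.leaf_node_iter():
        obs[lf.taxon.label] = character.get(lf.taxon.label, MISSING)
    return obs


def _root_costs(
    tree: dendropy.Tree, character: Mapping[str, int | None]
) -> tuple[float, float]:
    """Minimum change counts with the root fixed at state 0 / state 1."""
    obs = _states_for(tree, character)
    if all(v is MISSING for v in obs.values()):
        raise UndefinedCharacterError("character is missing for every leaf")
    cost: dict[dendropy.Node, tuple[float, float]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            s = obs[nd.taxon.label]
            if s is MISSING:
                cost[nd] = (0.0, 0.0)
            elif s == 0:
                cost[nd] = (0.0, _INF)
            elif s == 1:
                cost[nd] = (_INF, 0.0)
            else:
                raise UndefinedCharacterError(f"state {s!r} is not binary")
        else:
            c0 = c1 = 0.0
            for ch in nd.child_nodes():
                k0, k1 = cost[ch]
                c0 += min(k0, k1 + 1)
                c1 += min(k0 + 1, k1)
            cost[nd] = (c0, c1)
    return cost[tree.seed_node]


def fitch_steps(tree: dendropy.Tree, character: Mapping[str, int | None]) -> int:
    """Minimum number of binary state changes on the tree.

    Unit-cost dynamic program over an arbitrary rooting; missing leaves
    (absent from the mapping or ``None``) carry both states at no cost, so
    they impose no constraint. The result is rooting-invariant.
    """
    return int(min(_root_costs(tree, character)))


@dataclass(frozen=True)
class IndelClassification:
    character_id: str
    fitch_steps: int
    status: str
    derived_state: int | None
    supported_clade: frozenset[str] | None  # leaf set; present iff synapomorphic


def _derived_state(
    states: Mapping[str, int | None], outgroup_state: int | None
) -> int:
    if outgroup_state in (0, 1):
        return 1 - outgroup_state
    n1 = sum(1 for v in states.values() if v == 1)
    n0 = sum(1 for v in states.values() if v == 0)
    if n1 < n0:
        return 1
    if n0 < n1:
        return 0
    return 1  # tie: gap-as-derived


def is_monophyletic(tree: dendropy.Tree, labels: Iterable[str]) -> bool:
    """Do the labels form a clade (ignoring leaves absent from the set only
    if they lie outside the MRCA)?"""
    want = frozenset(labels)
    for nd in tree.preorder_node_iter():
        if _leafset(nd) == want:
            return True
    return False


def classify_character(
    tree: dendropy.Tree,
    character_id: str,
    character: Mapping[str, int | None],
    outgroup_state: int | None = None,
) -> IndelClassification:
    """Classify one binary character on a rooted tree.

    ``character`` maps leaf labels to 0/1/None for the leaves of ``tree``
    (the ingroup); ``outgroup_state`` is the observed state in the outgroup
    when known. The monophyly test ignores missing leaves: the derived set
    is a clade when some node's non-missing descendants are exactly the
    derived leaves and no derived leaf lies outside it.
    """
    states = _states_for(tree, character)
    scored = {t: v for t, v in states.items() if v is not MISSING}
    if not scored:
        raise UndefinedCharacterError(
            f"character {character_id}: missing for all leaves"
        )
    if len(set(scored.values())) < 2:
        return IndelClassification(
            character_id=character_id,
            fitch_steps=0,
            status=STATUS_INVARIANT,
            derived_state=None,
            supported_clade=None,
        )
    derived = _derived_state(scored, outgroup_state)
    # Polarized count: the root is constrained to the ancestral state, so a
    # single change is possible iff the derived leaves form a rooted clade.
    steps = int(_root_costs(tree, character)[1 - derived])
    derived_leaves = frozenset(t for t, v in scored.items() if v == derived)
    if steps >= 2:
        status = STATUS_HOMOPLASTIC
        clade = None
    elif len(derived_leaves) == 1:
        status = STATUS_AUTAPOMORPHIC
        clade = None
    else:
        status = STATUS_SYNAPOMORPHIC
        clade = _mrca_leafset(tree, derived_leaves)
    return IndelClassification(
        character_id=character_id,
        fitch_steps=steps,
        status=status,
        derived_state=derived,
        supported_clade=clade,
    )


def _mrca_leafset(tree: dendropy.Tree, labels: frozenset[str]) -> frozenset[str]:
    """Leaf set of the smallest node containing all the labels (the seed
    node is treated as the root)."""
    best: frozenset[str] | None = None
    for nd in tree.postorder_node_iter():
        ls = _leafset(nd)
        if labels <= ls and (best is None or len(ls) < len(best)):
            best = ls
    assert best is not None
    return best


def _derived_clade(
    tree: dendropy.Tree,
    derived_leaves: frozenset[str],
    scored: Mapping[str, int],
) -> bool:
    """Derived leaves monophyletic, ignoring missing-state leaves."""
    inside = _mrca_leafset(tree, derived_leaves)
    for label in inside:
        if label in scored and label not in derived_leaves:
            return False
    return True


@dataclass(frozen=True)
class CladeTabulation:
    """Per-clade synapomorphic indel counts plus a homoplasy total."""

    rows: tuple[tuple[str, frozenset[str] | None, int], ...]  # (label, leafset, count)
    homoplastic_total: int
    autapomorphic_total: int = 0
    invariant_total: int = 0

    def count_for(self, label: str) -> int:
        for name, _ls, count in self.rows:
            if name == label:
                return count
        return 0

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("clade\tn_indels\tleaf_set\n")
            for name, ls, count in self.rows:
                leaves = ",".join(sorted(ls)) if ls else "."
                fh.write(f"{name}\t{count}\t{leaves}\n")
            fh.write(f"Homoplasious indels\t{self.homoplastic_total}\t.\n")


def tabulate_clades(
    classifications: Sequence[IndelClassification],
    clade_defs: Mapping[str, Iterable[str]] | None = None,
) -> CladeTabulation:
    """Count synapomorphic characters per named clade (exact leaf-set
    equality); unmatched synapomorphies are listed under their literal leaf
    sets; homoplastic characters are totalled separately."""
    defs = {name: frozenset(ls) for name, ls in (clade_defs or {}).items()}
    by_set: dict[frozenset[str], int] = defaultdict(int)
    n_homo = n_auta = n_invar = 0
    for cl in classifications:
        if cl.status == STATUS_SYNAPOMORPHIC:
            by_set[cl.supported_clade] += 1
        elif cl.status == STATUS_HOMOPLASTIC:
            n_homo += 1
        elif cl.status == STATUS_AUTAPOMORPHIC:
            n_auta += 1
        else:
            n_invar += 1
    rows: list[tuple[str, frozenset[str] | None, int]] = []
    named_sets = set()
    for name in sorted(defs):
        ls = defs[name]
        named_sets.add(ls)
        rows.append((name, ls, by_set.get(ls, 0)))
    for ls in sorted(set(by_set) - named_sets, key=lambda s: (len(s), sorted(s))):
        rows.append(("{" + ",".join(sorted(ls)) + "}", ls, by_set[ls]))
    return CladeTabulation(
        rows=tuple(rows),
        homoplastic_total=n_homo,
        autapomorphic_total=n_auta,
        invariant_total=n_invar,
    )


def outgroup_state_from_matrix(
    matrix: BinaryCharacterMatrix, char_id: str, outgroup: Sequence[str]
) -> int | None:
    """Outgroup state for one character: the shared state of the outgroup
    rows when they agree and are scored, else None."""
    col = matrix.column(char_id)
    vals = {col[t] for t in outgroup if t in col and col[t] != "?"}
    if len(vals) == 1:
        return int(vals.pop())
    return None


def map_characters(
    tree: dendropy.Tree,
    matrix: BinaryCharacterMatrix,
    outgroup: Sequence[str] = (),
) -> list[IndelClassification]:
    """Classify every character of the matrix on the tree.

    When outgroup labels are given the tree is rooted on them, they are
    pruned, and each character's polarity is taken from the outgroup rows.
    Taxa present in the matrix must cover the tree's leaves.
    """
    tree_leaves = set(leaf_labels(tree))
    mat_taxa = set(matrix.taxa)
    if not tree_leaves <= mat_taxa:
        missing = sorted(tree_leaves - mat_taxa)
        raise ConsistencyError(f"tree leaves absent from character matrix: {missing}")
    if outgroup:
        rooted = root_with_outgroup(tree, outgroup)
        ingroup_tree = prune_taxa(rooted, outgroup)
    else:
        ingroup_tree = tree
    out = []
    for char_id in matrix.character_ids:
        col = matrix.column(char_id)
        character = {
            t: (None if col[t] == "?" else int(col[t]))
            for t in col
            if t not in outgroup
        }
        og_state = (
            outgroup_state_from_matrix(matrix, char_id, outgroup) if outgroup else None
        )
        out.append(classify_character(ingroup_tree, char_id, character, og_state))
    return out


def write_classifications_tsv(
    classifications: Sequence[IndelClassification],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("character_id\tfitch_steps\tstatus\tderived_state\tsupported_clade\n")
        for cl in classifications:
            clade = ",".join(sorted(cl.supported_clade)) if cl.supported_clade else "."
            derived = "." if cl.derived_state is None else str(cl.derived_state)
            fh.write(
                f"{cl.character_id}\t{cl.fitch_steps}\t{cl.status}\t{derived}\t{clade}\n"
            )
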