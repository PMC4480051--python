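"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from plastgap.alignment import MultipleAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_alignment(
    rng: np.random.Generator,
    n_taxa: int = 6,
    n_columns: int = 40,
    gap_prob: float = 0.15,
) -> MultipleAlignment:
    """Random gapped matrix over A/C/G/T/- with independent per-cell gaps."""
    bases = np.array(list("ACGT-"))
    probs = [(1 - gap_prob) / 4] * 4 + [gap_prob]
    rows = [
        "".join(rng.choice(bases, size=n_columns, p=probs))
        for _ in range(n_taxa)
    ]
    taxa = [f"s{i}" for i in range(n_taxa)]
    return MultipleAlignment.from_rows(taxa, rows)


def brute_force_gap_runs(aln: MultipleAlignment) -> list[tuple[str, int, int, bool]]:
    """Per-character scan for maximal gap runs (oracle for extract_gap_runs)."""
    out = []
    for taxon, row in zip(aln.taxa, aln.rows):
        start = None
        for j, ch in enumerate(row + "X"):  # sentinel terminates a final run
            if ch == "-" and start is None:
                start = j
            elif ch != "-" and start is not None:
                out.append((taxon, start, j, start == 0 or j == len(row)))
                start = None
    return out


def brute_force_fitch(tree, states: dict, fixed_root: int | None = None) -> int:
    """Exhaustive minimum change count over all internal (and missing-leaf)
    state assignments; oracle for the parsimony DP."""
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    free: list[int] = []
    fixed: dict[int, int] = {}
    for nd in nodes:
        i = index[id(nd)]
        if nd.is_leaf():
            s = states.get(nd.taxon.label)
            if s is None:
                free.append(i)
            else:
                fixed[i] = s
        else:
            free.append(i)
    if fixed_root is not None:
        root_i = index[id(tree.seed_node)]
        free.remove(root_i)
        fixed[root_i] = fixed_root
    m = len(free)
    assign = np.zeros((2**m, len(nodes)), dtype=np.uint8)
    if m:
        bits = ((np.arange(2**m)[:, None] >> np.arange(m)) & 1).astype(np.uint8)
        assign[:, free] = bits
    for i, s in fixed.items():
        assign[:, i] = s
    changes = np.zeros(2**m, dtype=np.int64)
    for nd in nodes:
        if nd.parent_node is None:
            continue
        changes += assign[:, index[id(nd.parent_node)]] != assign[:, index[id(nd)]]
    return int(changes.min())


def scored_set_is_clade(tree, derived: frozenset, scored: dict) -> bool:
    """Independent monophyly test: some node's scored descendant set equals
    the derived set exactly."""
    for nd in tree.preorder_node_iter():
        under = {
            lf.taxon.label
            for lf in nd.leaf_iter()
            if lf.taxon.label in scored
        }
        if under == set(derived):
            return True
    return False
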