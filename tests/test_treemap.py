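"""Tree mapping: parsimony steps, synapomorphy classification, tabulation."""

import numpy as np
import pytest

from plastgap.errors import OutgroupError, UndefinedCharacterError
from plastgap.indels import BinaryCharacterMatrix
from plastgap.simulate import SimulationConfig, simulate_tree
from plastgap.treemap import (
    STATUS_AUTAPOMORPHIC,
    STATUS_HOMOPLASTIC,
    STATUS_INVARIANT,
    STATUS_SYNAPOMORPHIC,
    classify_character,
    fitch_steps,
    leaf_labels,
    map_characters,
    parse_tree,
    prune_taxa,
    read_tree,
    root_with_outgroup,
    tabulate_clades,
    write_tree,
)

from conftest import brute_force_fitch, scored_set_is_clade


def random_tree(seed, n):
    cfg = SimulationConfig(n_taxa=max(n, 4), sequence_length=1000, seed=seed)
    return simulate_tree(cfg)


class TestTreeIO:
    def test_parse_four_leaves(self):
        t = parse_tree("((A,B),(C,D));")
        assert sorted(leaf_labels(t)) == ["A", "B", "C", "D"]

    def test_support_labels_attached(self):
        t = parse_tree("((A,B)95,(C,D)87);")
        sups = sorted(
            nd.support for nd in t.preorder_node_iter() if hasattr(nd, "support")
        )
        assert sups == [87.0, 95.0]

    def test_round_trip_preserves_topology(self, tmp_path):
        from plastgap.jackknife import bipartitions

        t = random_tree(3, 20)
        p = tmp_path / "t.nwk"
        write_tree(t, p)
        back = read_tree(p)
        assert bipartitions(back) == bipartitions(t)

    def test_malformed_newick(self, tmp_path):
        from plastgap.errors import ParseError

        p = tmp_path / "bad.nwk"
        p.write_text("((A,B),(C,D);")
        with pytest.raises(ParseError):
            read_tree(p)


class TestRooting:
    def test_single_outgroup(self):
        t = parse_tree("(A,B,(C,D));")
        r = root_with_outgroup(t, {"D"})
        kids = [sorted(l.taxon.label for l in c.leaf_iter())
                for c in r.seed_node.child_nodes()]
        assert ["D"] in kids and ["A", "B", "C"] in kids

    def test_all_leaves_is_error(self):
        t = parse_tree("(A,B,(C,D));")
        with pytest.raises(OutgroupError):
            root_with_outgroup(t, {"A", "B", "C", "D"})

    def test_non_monophyletic_outgroup(self):
        t = parse_tree("((A,B),(C,D));")
        with pytest.raises(OutgroupError):
            root_with_outgroup(t, {"A", "C"})

    @pytest.mark.parametrize("seed", range(3))
    def test_reroot_preserves_unrooted_topology(self, seed):
        from plastgap.jackknife import bipartitions

        t = random_tree(seed, 10)
        leaf = sorted(leaf_labels(t))[seed]
        r = root_with_outgroup(t, {leaf})
        assert bipartitions(r) == bipartitions(t)


class TestFitchSteps:
    t4 = parse_tree("((A,B),(C,D));")

    def test_textbook_cases(self):
        assert fitch_steps(self.t4, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1
        assert fitch_steps(self.t4, {"A": 1, "C": 1, "B": 0, "D": 0}) == 2
        assert fitch_steps(self.t4, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0

    def test_missing_leaves_unconstrained(self):
        assert fitch_steps(self.t4, {"A": 1, "B": None, "C": 0, "D": 0}) == 1
        with pytest.raises(UndefinedCharacterError):
            fitch_steps(self.t4, {"A": None, "B": None, "C": None, "D": None})

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(seed, int(rng.integers(4, 9)))
        labels = leaf_labels(tree)
        for _ in range(10):
            states = {
                t: int(s) if s < 2 else None
                for t, s in zip(labels, rng.integers(0, 3, len(labels)))
            }
            if all(v is None for v in states.values()):
                continue
            assert fitch_steps(tree, states) == brute_force_fitch(tree, states)

    @pytest.mark.parametrize("seed", range(3))
    def test_rerooting_and_leaf_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(seed, 8)
        labels = leaf_labels(tree)
        states = {t: int(rng.integers(0, 2)) for t in labels}
        if len(set(states.values())) < 2:
            states[labels[0]] = 1 - states[labels[0]]
        ref = fitch_steps(tree, states)
        for leaf in labels[:4]:
            rerooted = root_with_outgroup(tree, {leaf})
            assert fitch_steps(rerooted, states) == ref


class TestClassify:
    t4 = parse_tree("((A,B),(C,D));")

    def test_textbook_synapomorphy(self):
        c = classify_character(self.t4, "x", {"A": 1, "B": 1, "C": 0, "D": 0}, 0)
        assert c.status == STATUS_SYNAPOMORPHIC
        assert c.supported_clade == frozenset({"A", "B"})

    def test_homoplasy(self):
        c = classify_character(self.t4, "x", {"A": 1, "C": 1, "B": 0, "D": 0}, 0)
        assert c.status == STATUS_HOMOPLASTIC and c.fitch_steps == 2

    def test_autapomorphy_flagged(self):
        c = classify_character(self.t4, "x", {"A": 1, "B": 0, "C": 0, "D": 0}, 0)
        assert c.status == STATUS_AUTAPOMORPHIC

    def test_invariant_excluded(self):
        c = classify_character(self.t4, "x", {"A": 1, "B": 1, "C": 1, "D": 1}, 0)
        assert c.status == STATUS_INVARIANT

    def test_conspecific_cherry_synapomorphy(self):
        t = parse_tree("(((sp1a,sp1b),C),D);")
        c = classify_character(t, "x", {"sp1a": 1, "sp1b": 1, "C": 0, "D": 0}, 0)
        assert c.status == STATUS_SYNAPOMORPHIC
        assert c.supported_clade == frozenset({"sp1a", "sp1b"})

    def test_minority_polarity_when_outgroup_unknown(self):
        c = classify_character(self.t4, "x", {"A": 1, "B": 0, "C": 0, "D": 0}, None)
        assert c.derived_state == 1
        c = classify_character(self.t4, "x", {"A": 1, "B": 1, "C": 0, "D": 0}, None)
        assert c.derived_state == 1  # tie resolved to gap-as-derived

    @pytest.mark.parametrize("seed", range(8))
    def test_synapomorphy_agrees_with_monophyly_test(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(seed, 8)
        labels = leaf_labels(tree)
        for _ in range(15):
            states = {
                t: int(s) if s < 2 else None
                for t, s in zip(labels, rng.integers(0, 3, len(labels)))
            }
            scored = {t: v for t, v in states.items() if v is not None}
            if len(set(scored.values())) < 2:
                continue
            og = int(rng.integers(0, 2))
            c = classify_character(tree, "x", states, og)
            derived = frozenset(t for t, v in scored.items() if v == 1 - og)
            expect_syn = len(derived) >= 2 and scored_set_is_clade(tree, derived, scored)
            assert (c.status == STATUS_SYNAPOMORPHIC) == expect_syn
            # polarized step count equals brute force with fixed root state
            assert c.fitch_steps == brute_force_fitch(tree, states, fixed_root=og)


class TestTabulation:
    def test_counts_and_unmatched(self):
        t = parse_tree("(((A,B),(C,D)),E);")
        chars = {
            "c1": {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0},
            "c2": {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0},
            "c3": {"C": 1, "D": 1, "A": 0, "B": 0, "E": 0},
            "c4": {"A": 1, "C": 1, "B": 0, "D": 0, "E": 0},  # homoplastic
        }
        cls = [classify_character(t, k, v, 0) for k, v in chars.items()]
        tab = tabulate_clades(cls, {"pairAB": {"A", "B"}})
        assert tab.count_for("pairAB") == 2
        assert tab.homoplastic_total == 1
        unmatched = [r for r in tab.rows if r[1] == frozenset({"C", "D"})]
        assert unmatched and unmatched[0][2] == 1

    def test_empty_classifications(self):
        tab = tabulate_clades([], {"pair": {"A", "B"}})
        assert tab.count_for("pair") == 0 and tab.homoplastic_total == 0


class TestMapCharacters:
    def test_pipeline_with_outgroup_rows(self):
        t = parse_tree("(((A,B),(C,D)),OG);")
        taxa = ("A", "B", "C", "D", "OG")
        states = np.array(
            [["1"], ["1"], ["0"], ["0"], ["0"]], dtype="<U1"
        )
        m = BinaryCharacterMatrix(taxa=taxa, character_ids=("c1",), states=states)
        cls = map_characters(t, m, outgroup=["OG"])
        assert cls[0].status == STATUS_SYNAPOMORPHIC
        assert cls[0].supported_clade == frozenset({"A", "B"})

    def test_insertion_polarity_from_outgroup(self):
        # gap present in outgroup and distant taxa: derived state is 0
        t = parse_tree("(((A,B),(C,D)),OG);")
        taxa = ("A", "B", "C", "D", "OG")
        states = np.array(
            [["0"], ["0"], ["1"], ["1"], ["1"]], dtype="<U1"
        )
        m = BinaryCharacterMatrix(taxa=taxa, character_ids=("c1",), states=states)
        cls = map_characters(t, m, outgroup=["OG"])
        assert cls[0].status == STATUS_SYNAPOMORPHIC
        assert cls[0].derived_state == 0
        assert cls[0].supported_clade == frozenset({"A", "B"})

    def test_taxa_mismatch_raises(self):
        from plastgap.errors import ConsistencyError

        t = parse_tree("((A,B),(C,D));")
        m = BinaryCharacterMatrix(
            taxa=("A", "B", "C"),
            character_ids=("c1",),
            states=np.array([["1"], ["1"], ["0"]], dtype="<U1"),
        )
        with pytest.raises(ConsistencyError):
            map_characters(t, m)
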