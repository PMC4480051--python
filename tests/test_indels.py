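"""Indel cataloguing: gap runs, clustering, criteria, SSM, regions, coding."""

import numpy as np
import pytest

from plastgap.alignment import MultipleAlignment
from plastgap.indels import (
    AMBIGUOUS_OVERLAP,
    AUTAPOMORPHIC,
    MONONUCLEOTIDE,
    SSM_NEAR_PERFECT,
    SSM_NONE,
    SSM_PERFECT,
    TOO_SHORT,
    IndelCriteria,
    IndelEvent,
    RegionAnnotation,
    apply_criteria,
    build_character_matrix,
    catalog_indels,
    classify_region,
    cluster_events,
    detect_ssm,
    extract_gap_runs,
    read_catalog_tsv,
    summarize_catalog,
    write_catalog_tsv,
)

from conftest import brute_force_gap_runs, random_alignment


def aln_of(*rows):
    return MultipleAlignment.from_rows([f"t{i}" for i in range(len(rows))], list(rows))


class TestGapRuns:
    def test_internal_and_terminal_runs(self):
        aln = aln_of("AC--GT", "--ACGT", "ACGT--")
        runs = extract_gap_runs(aln)
        assert [(r.taxon, r.interval, r.terminal) for r in runs] == [
            ("t0", (2, 4), False),
            ("t1", (0, 2), True),
            ("t2", (4, 6), True),
        ]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_character_scan(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n_taxa=6, n_columns=50, gap_prob=0.25)
        got = [(r.taxon, *r.interval, r.terminal) for r in extract_gap_runs(aln)]
        assert got == brute_force_gap_runs(aln)


class TestClustering:
    def test_identical_footprints_merge(self):
        aln = aln_of("ACGT----GG", "ACGT----GG", "ACGTACGTGG", "ACGT----GG")
        events = cluster_events(extract_gap_runs(aln))
        assert len(events) == 1
        assert events[0].interval == (4, 8)
        assert events[0].gapped_taxa == ("t0", "t1", "t3")
        assert not events[0].overlapping

    def test_partial_overlap_flags_both(self):
        aln = aln_of("ACGT----GGCA", "ACGTGG----CA", "ACGTACGTGGCA")
        events = cluster_events(extract_gap_runs(aln))
        assert [e.interval for e in events] == [(4, 8), (6, 10)]
        assert all(e.overlapping for e in events)

    def test_nested_runs_flag_both(self):
        aln = aln_of("ACGT----GGCA", "ACGTG--TGGCA", "ACGTACGTGGCA")
        events = cluster_events(extract_gap_runs(aln))
        assert all(e.overlapping for e in events)

    def test_terminal_runs_excluded(self):
        aln = aln_of("--GTACGT", "ACGTAC--", "ACGTACGT")
        assert cluster_events(extract_gap_runs(aln)) == []

    def test_every_run_covered_or_terminal(self, rng):
        aln = random_alignment(rng, n_taxa=5, n_columns=60, gap_prob=0.2)
        runs = extract_gap_runs(aln)
        events = cluster_events(runs)
        intervals = {e.interval for e in events}
        for r in runs:
            assert r.terminal or r.interval in intervals


class TestCriteria:
    def test_too_short(self):
        aln = aln_of("ACG-ACGT", "ACG-ACGT", "ACG-ACGT", "ACGTACGT")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert events[0].status == "rejected"
        assert events[0].reject_reason == TOO_SHORT

    def test_mononucleotide_with_matching_flank(self):
        # segment AAAA, adjacent base A in the reading taxon
        aln = aln_of("GA----AGCT", "GA----AGCT", "GAAAAAAGCT", "GAAAAAAGCT")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert events[0].reject_reason == MONONUCLEOTIDE

    def test_homopolymer_without_matching_flank_passes(self):
        aln = aln_of("GC----TGCT", "GC----TGCT", "GCAAAATGCT", "GCAAAATGCT")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert events[0].status == "accepted"

    def test_autapomorphic(self):
        aln = aln_of("ACG--CGTAC", "ACGTACGTAC", "ACGTACGTAC")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert events[0].reject_reason == AUTAPOMORPHIC

    def test_ambiguous_overlap(self):
        aln = aln_of("ACGT----GGCA", "ACGT----GGCA", "ACGTGG----CA",
                     "ACGTGG----CA", "ACGTACGTGGCA")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert {e.reject_reason for e in events} == {AMBIGUOUS_OVERLAP}

    def test_reason_order_too_short_before_overlap(self):
        # single-column run overlapping a longer run: too_short reported first
        aln = aln_of("ACG-TACGTA", "ACG-TACGTA", "AC---ACGTA", "AC---ACGTA",
                     "ACGTTACGTA")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        reasons = {e.interval: e.reject_reason for e in events}
        assert reasons[(3, 4)] == TOO_SHORT
        assert reasons[(2, 5)] == AMBIGUOUS_OVERLAP

    def test_summary_counts_are_conserved(self, rng):
        aln = random_alignment(rng, n_taxa=6, n_columns=80, gap_prob=0.15)
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        s = summarize_catalog(events)
        rejected = sum(v for k, v in s.items() if k.startswith("rejected_"))
        assert s["accepted"] + rejected == s["total_candidates"]


class TestSSM:
    def test_perfect_tandem_repeat(self):
        aln = aln_of("CATGATGC", "CATG---C", "CATG---C")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert detect_ssm(events[0], aln) == SSM_PERFECT

    def test_near_perfect_at_threshold_boundary(self):
        # upstream flank identity exactly 4/5 = 0.80 (>= threshold)
        aln = aln_of("ATGCCATGCAG", "ATGCC-----G", "ATGCC-----G")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert detect_ssm(events[0], aln) == SSM_NEAR_PERFECT

    def test_no_repeat(self):
        aln = aln_of("AAATTGCACCGGT", "AAATT---CCGGT", "AAATT---CCGGT")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert detect_ssm(events[0], aln) == SSM_NONE

    def test_downstream_repeat_detected(self):
        aln = aln_of("CC---ATGAA", "CCATGATGAA", "CCATGATGAA")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        assert detect_ssm(events[0], aln) == SSM_PERFECT


class TestRegions:
    ann = RegionAnnotation(
        features=(
            (0, 10, "coding", "cds1"),
            (10, 14, "intron", "i1"),
            (14, 30, "igs", "igs_0"),
        )
    )

    def test_containment_majority_and_tie(self):
        ev = lambda a, b: IndelEvent(interval=(a, b), gapped_taxa=("x", "y"))
        assert classify_region(ev(16, 20), self.ann) == "igs"
        assert classify_region(ev(7, 11), self.ann) == "coding"  # 3 vs 1
        assert classify_region(ev(8, 12), self.ann) == "coding"  # 2 vs 2 tie
        assert classify_region(ev(12, 16), self.ann) == "intron"  # 2 vs 2 tie
        assert classify_region(ev(40, 44), self.ann) == "unassigned"

    def test_gff3_round_trip(self, tmp_path):
        p = tmp_path / "ann.gff3"
        self.ann.to_gff3(p)
        back = RegionAnnotation.from_gff3(p, n_columns=30)
        assert back == self.ann


class TestCharacterMatrix:
    def test_direct_encoding(self):
        aln = aln_of("ACGT----GG", "ACGT----GG", "ACGTACGTGG", "ACGTNNNNGG")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        m = build_character_matrix(events, aln)
        assert m.n_characters == 1
        assert m.column(m.character_ids[0]) == {
            "t0": "1", "t1": "1", "t2": "0", "t3": "?"
        }

    def test_empty_catalogue(self):
        aln = aln_of("ACGT", "ACGT")
        m = build_character_matrix([], aln)
        assert m.n_characters == 0

    def test_nexus_and_tsv_export(self, tmp_path):
        aln = aln_of("ACGT----GG", "ACGT----GG", "ACGTACGTGG")
        events = apply_criteria(cluster_events(extract_gap_runs(aln)), aln)
        m = build_character_matrix(events, aln)
        m.to_nexus(tmp_path / "m.nex")
        text = (tmp_path / "m.nex").read_text()
        assert "DATATYPE=STANDARD" in text
        states = [line.split()[-1] for line in text.splitlines() if line.strip().startswith("t")]
        assert states == ["1", "1", "0"]


class TestCatalogIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        aln = random_alignment(rng, n_taxa=6, n_columns=80, gap_prob=0.15)
        events = catalog_indels(aln)
        p = tmp_path / "catalog.tsv"
        write_catalog_tsv(events, aln, p, ["hdr"])
        rows = read_catalog_tsv(p)
        assert len(rows) == len(events)
        for row, ev in zip(rows, events):
            assert (row["start"], row["end"]) == ev.interval
            assert tuple(row["gapped_taxa"]) == ev.gapped_taxa
            assert row["status"] == ev.status
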