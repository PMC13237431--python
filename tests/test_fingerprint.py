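"""Diagnostic-site discovery and profile classification."""

import numpy as np
import pytest

from hcarkit.align_io import Group, SeqRecord
from hcarkit.fingerprint import (
    Call,
    DiagnosticProfile,
    InputError,
    Verdict,
    classify_cohort,
    classify_sequence,
    count_pairwise_differences,
    discover_diagnostic_positions,
    nondiagnostic_differences,
    partition_by_pocket,
    split_by_pocket,
)
from conftest import make_alignment
from oracles import brute_force_diagnostics, random_alignment


def small_panel():
    #              12345678
    return make_alignment(
        [
            ("a1", Group.GROUP_A, "MKVLSTRG"),
            ("a2", Group.GROUP_A, "MKVLSTRG"),
            ("b1", Group.GROUP_B, "MKALSTWG"),
            ("b2", Group.GROUP_B, "MKALSTWG"),
        ],
        "a1",
    )


class TestDiscovery:
    def test_finds_group_fixed_disjoint_columns(self):
        profile = discover_diagnostic_positions(small_panel())
        assert profile.positions == (3, 7)
        assert profile.state_a == (frozenset("V"), frozenset("R"))
        assert profile.state_b == (frozenset("A"), frozenset("W"))

    def test_identical_groups_give_empty_profile(self):
        aln = make_alignment(
            [
                ("a1", Group.GROUP_A, "MKVL"),
                ("a2", Group.GROUP_A, "MKVL"),
                ("b1", Group.GROUP_B, "MKVL"),
                ("b2", Group.GROUP_B, "MKVL"),
            ]
        )
        assert len(discover_diagnostic_positions(aln)) == 0

    def test_gap_or_x_blocks_strict_but_not_relaxed_disjointness(self):
        aln = make_alignment(
            [
                ("a1", Group.GROUP_A, "MV"),
                ("a2", Group.GROUP_A, "MV"),
                ("b1", Group.GROUP_B, "MA"),
                ("b2", Group.GROUP_B, "MX"),
            ]
        )
        assert discover_diagnostic_positions(aln).positions == ()
        relaxed = discover_diagnostic_positions(aln, strict=False)
        assert relaxed.positions == (2,)
        assert relaxed.state_b == (frozenset("A"),)  # X stripped

    def test_insertion_columns_never_diagnostic(self):
        # column 2 is group-disjoint once gaps are stripped, but it is an
        # insertion column (no reference number) and must stay excluded
        aln = make_alignment(
            [
                ("r", Group.GROUP_A, "M-V"),
                ("a", Group.GROUP_A, "MQV"),
                ("b1", Group.GROUP_B, "MWV"),
                ("b2", Group.GROUP_B, "MWV"),
            ],
            "r",
        )
        assert discover_diagnostic_positions(aln, strict=False).positions == ()

    def test_missing_group_rejected(self):
        aln = make_alignment(
            [("a1", Group.GROUP_A, "MK"), ("a2", Group.GROUP_A, "MK")]
        )
        with pytest.raises(InputError):
            discover_diagnostic_positions(aln)

    @pytest.mark.parametrize("strict", [True, False])
    def test_matches_bruteforce_oracle_on_random_alignments(self, rng, strict):
        for _ in range(100):
            aln = random_alignment(rng)
            got = discover_diagnostic_positions(
                aln, strict=strict, min_group_size=1
            )
            expected = brute_force_diagnostics(aln, strict=strict)
            assert list(got.positions) == [p for p, _, _ in expected]
            assert list(got.state_a) == [a for _, a, _ in expected]
            assert list(got.state_b) == [b for _, _, b in expected]

    def test_invariant_to_record_order_and_duplication(self, rng):
        aln = small_panel()
        reordered = make_alignment(
            [(r.id, r.group, r.residues) for r in reversed(aln.records)],
            "a1",
        )
        extra = make_alignment(
            [(r.id, r.group, r.residues) for r in aln.records]
            + [("a3", Group.GROUP_A, aln["a1"].residues)],
            "a1",
        )
        base = discover_diagnostic_positions(aln)
        assert discover_diagnostic_positions(reordered).positions == base.positions
        assert discover_diagnostic_positions(extra).positions == base.positions


class TestPairwiseDifferences:
    def test_identical_zero_and_single_substitution(self):
        aln = make_alignment(
            [("x", Group.QUERY, "MKLV"), ("y", Group.QUERY, "MKIV"),
             ("z", Group.QUERY, "MKLV")]
        )
        assert count_pairwise_differences(aln, "x", "z") == 0
        assert count_pairwise_differences(aln, "x", "y") == 1

    def test_indel_columns_excluded(self):
        aln = make_alignment(
            [("x", Group.QUERY, "MK--LV"), ("y", Group.QUERY, "MKQRIV")]
        )
        assert count_pairwise_differences(aln, "x", "y") == 1  # only L/I

    def test_nondiagnostic_differences_listed_separately(self):
        aln = make_alignment(
            [
                ("a1", Group.GROUP_A, "MKVLSTRG"),
                ("a2", Group.GROUP_A, "MKVLSTRG"),
                ("b1", Group.GROUP_B, "MKALSTWC"),  # pos 8 private to b1
                ("b2", Group.GROUP_B, "MKALSTWG"),
            ],
            "a1",
        )
        profile = discover_diagnostic_positions(aln)
        assert profile.positions == (3, 7)
        assert nondiagnostic_differences(aln, "a1", "b1", profile) == [8]


class TestClassification:
    def profile(self):
        return discover_diagnostic_positions(small_panel())

    def test_group_a_consensus_classifies_a_like(self):
        aln = small_panel()
        res = classify_sequence("a1", self.profile(), aln)
        assert (res.n_a, res.n_b) == (2, 0)
        assert res.verdict is Verdict.A_LIKE

    def test_neither_and_ambiguous_are_distinct(self):
        aln = make_alignment(
            [
                ("a1", Group.GROUP_A, "MKVLSTRG"),
                ("a2", Group.GROUP_A, "MKVLSTRG"),
                ("b1", Group.GROUP_B, "MKALSTWG"),
                ("b2", Group.GROUP_B, "MKALSTWG"),
                ("q1", Group.QUERY, "MKSLSTXG"),  # pos3 S: neither; pos7 X
                ("q2", Group.QUERY, "MKVLST-G"),  # pos7 gap: ambiguous
            ],
            "a1",
        )
        profile = self.profile()
        r1 = classify_sequence("q1", profile, aln)
        assert r1.call_at(3) is Call.NEITHER
        assert r1.call_at(7) is Call.AMBIGUOUS
        assert (r1.n_neither, r1.n_ambiguous) == (1, 1)
        r2 = classify_sequence("q2", profile, aln)
        assert r2.call_at(7) is Call.AMBIGUOUS
        assert r2.verdict is Verdict.A_LIKE  # 1 vs 0 with no pocket conflict

    def test_counts_always_sum_to_profile_size(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, n_seqs=6, width=30)
            profile = discover_diagnostic_positions(aln, min_group_size=1)
            if len(profile) == 0:
                continue
            for rec in aln.records:
                res = classify_sequence(rec.id, profile, aln)
                assert (
                    res.n_a + res.n_b + res.n_neither + res.n_ambiguous
                    == len(profile)
                )

    def test_dropping_a_position_never_increases_counts(self):
        aln = small_panel()
        profile = self.profile()
        full = classify_sequence("b1", profile, aln)
        smaller = classify_sequence("b1", profile.drop_position(3), aln)
        assert smaller.n_a <= full.n_a
        assert smaller.n_b <= full.n_b

    def test_tie_gives_mixed(self):
        aln = make_alignment(
            [
                ("a1", Group.GROUP_A, "VVRR"),
                ("a2", Group.GROUP_A, "VVRR"),
                ("b1", Group.GROUP_B, "AAWW"),
                ("b2", Group.GROUP_B, "AAWW"),
                ("q", Group.QUERY, "VARW"),
            ],
            "a1",
        )
        profile = discover_diagnostic_positions(aln)
        res = classify_sequence("q", profile, aln)
        assert res.n_a == res.n_b == 2
        assert res.verdict is Verdict.MIXED

    def test_pocket_conflict_blocks_a_like(self):
        aln = make_alignment(
            [
                ("a1", Group.GROUP_A, "VVRR"),
                ("a2", Group.GROUP_A, "VVRR"),
                ("b1", Group.GROUP_B, "AAWW"),
                ("b2", Group.GROUP_B, "AAWW"),
                ("q", Group.QUERY, "VVRW"),  # one B match at position 4
            ],
            "a1",
        )
        profile = discover_diagnostic_positions(aln)
        # all proximal: the B match at 4 blocks A_LIKE
        res = classify_sequence("q", profile, aln)
        assert res.verdict is Verdict.MIXED
        # flag position 4 as distal: verdict becomes A_LIKE
        distal = partition_by_pocket(profile, [4])
        res2 = classify_sequence("q", distal, aln)
        assert res2.pocket_n_b == 0
        assert res2.verdict is Verdict.A_LIKE

    def test_cohort_of_one_equals_single_call(self):
        aln = small_panel()
        profile = self.profile()
        results, table = classify_cohort(["b1"], profile, aln)
        single = classify_sequence("b1", profile, aln)
        assert results == [single]
        assert table.loc[0, "query_id"] == "b1"
        assert table.loc[0, "verdict"] == single.verdict.value


class TestPocketPartition:
    def test_partition_splits_and_flags(self):
        profile = discover_diagnostic_positions(small_panel())
        flagged = partition_by_pocket(profile, [7])
        proximal, distal = split_by_pocket(flagged)
        assert proximal == [3] and distal == [7]

    def test_empty_and_full_distal_sets(self):
        profile = discover_diagnostic_positions(small_panel())
        assert split_by_pocket(partition_by_pocket(profile, []))[1] == []
        all_distal = partition_by_pocket(profile, profile.positions)
        assert split_by_pocket(all_distal)[0] == []

    def test_unknown_distal_position_rejected(self):
        profile = discover_diagnostic_positions(small_panel())
        with pytest.raises(InputError):
            partition_by_pocket(profile, [99])


class TestProfileSerialization:
    def test_json_roundtrip(self, tmp_path):
        profile = partition_by_pocket(
            discover_diagnostic_positions(small_panel()), [7]
        )
        path = tmp_path / "profile.json"
        profile.to_json(path)
        assert DiagnosticProfile.from_json(path) == profile
        assert DiagnosticProfile.from_json(profile.to_json()) == profile
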