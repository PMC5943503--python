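"""QC cascade: flag removal, length window, replicate consistency, background."""

from __future__ import annotations

import pytest

from plateau.filtering import (
    FilterConfig,
    FilterConfigError,
    background_remove,
    length_filter,
    remove_flagged,
    replicate_filter,
)
from plateau.io_tables import PeptideRecord
from tests.conftest import make_design


def rec(seq="ACDEFGHIKLM", runs=("r1",), decoy=False, cont=False, proteins=("P1",)):
    return PeptideRecord(
        seq, proteins, {r: 1.0 for r in runs}, is_contaminant=cont, is_decoy=decoy
    )


class TestRemoveFlagged:
    def test_counts_and_removal(self):
        records = (
            [rec() for _ in range(7)]
            + [rec(decoy=True, proteins=()) for _ in range(2)]
            + [rec(cont=True)]
        )
        out = remove_flagged(records)
        assert len(out.kept) == 7
        assert out.n_decoy == 2 and out.n_contaminant == 1

    def test_double_flag_counted_in_both_tallies(self):
        out = remove_flagged([rec(decoy=True, cont=True, proteins=())])
        assert out.kept == []
        assert out.n_decoy == 1 and out.n_contaminant == 1

    def test_no_flags_is_identity(self):
        records = [rec(), rec("CCDEFGHIKLM")]
        assert remove_flagged(records).kept == records


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept", [(10, False), (11, True), (30, True), (31, False)]
    )
    def test_inclusive_window_boundaries(self, length, kept):
        records = [rec("A" * length)]
        assert (length_filter(records) == records) is kept

    def test_cd4_12mer_kept(self):
        records = [rec("KSWITFDLKNKE")]
        assert length_filter(records) == records

    def test_empty_input(self):
        assert length_filter([]) == []

    def test_commutes_with_flag_removal(self):
        records = [rec("A" * 9, decoy=True, proteins=()), rec("A" * 12),
                   rec("A" * 40, cont=True), rec("A" * 25)]
        a = length_filter(remove_flagged(records).kept)
        b = remove_flagged(length_filter(records)).kept
        assert a == b


class TestReplicateFilter:
    def test_two_of_three_in_each_bio_rep_retained(self):
        design = make_design(conditions=("condA",))
        p = rec(runs=["condA_b1_t1", "condA_b1_t2",
                      "condA_b2_t1", "condA_b2_t2", "condA_b2_t3"])
        out = replicate_filter([p], design)
        assert out.union == [p]
        assert out.by_condition["condA"] == [p]

    def test_failing_one_bio_rep_removed(self):
        design = make_design(conditions=("condA",))
        p = rec(runs=["condA_b1_t1",
                      "condA_b2_t1", "condA_b2_t2", "condA_b2_t3"])
        out = replicate_filter([p], design)
        assert out.union == []

    def test_planted_patterns_hand_enumerated(self):
        # 3 consistent peptides (>=2 tech reps in both bio reps) survive;
        # 2 one-run-only peptides do not.
        design = make_design(conditions=("condA",))
        consistent = [
            rec("A" * 11, runs=["condA_b1_t1", "condA_b1_t2",
                                "condA_b2_t2", "condA_b2_t3"]),
            rec("C" * 11, runs=["condA_b1_t1", "condA_b1_t2", "condA_b1_t3",
                                "condA_b2_t1", "condA_b2_t2", "condA_b2_t3"]),
            rec("D" * 11, runs=["condA_b1_t2", "condA_b1_t3",
                                "condA_b2_t1", "condA_b2_t3"]),
        ]
        sporadic = [
            rec("E" * 11, runs=["condA_b1_t1"]),
            rec("F" * 11, runs=["condA_b2_t3"]),
        ]
        out = replicate_filter(consistent + sporadic, design)
        assert out.union == consistent

    def test_membership_is_per_condition(self):
        design = make_design()
        p = rec(runs=["condA_b1_t1", "condA_b1_t2",
                      "condA_b2_t1", "condA_b2_t2"])
        out = replicate_filter([p], design)
        assert out.by_condition["condA"] == [p]
        assert out.by_condition["condB"] == []
        assert out.union == [p]

    def test_any_bio_rep_mode(self):
        design = make_design(conditions=("condA",))
        p = rec(runs=["condA_b1_t1", "condA_b1_t2"])
        strict = replicate_filter([p], design)
        loose = replicate_filter(
            [p], design, FilterConfig(require_all_bio_reps=False)
        )
        assert strict.union == [] and loose.union == [p]

    def test_idempotent_and_run_order_invariant(self):
        design = make_design(conditions=("condA",))
        runs = ["condA_b1_t2", "condA_b2_t1", "condA_b1_t1", "condA_b2_t3"]
        p = rec(runs=runs)
        once = replicate_filter([p], design)
        twice = replicate_filter(once.union, design)
        assert once.union == twice.union == [p]

    def test_too_few_tech_reps_is_config_error(self):
        design = make_design(conditions=("condA",), n_tech=1)
        with pytest.raises(FilterConfigError):
            replicate_filter([rec()], design, FilterConfig(min_tech_reps=2))

    def test_config_validation(self):
        with pytest.raises(FilterConfigError):
            FilterConfig(min_tech_reps=4, tech_reps_total=3)
        with pytest.raises(FilterConfigError):
            FilterConfig(min_peptide_length=31, max_peptide_length=30)


class TestBackgroundRemove:
    def test_peptide_seen_in_control_removed(self):
        design = make_design()
        background = rec(runs=["ctrl_1", "condA_b1_t1"])
        clean = rec("C" * 11, runs=["condA_b1_t1"])
        out = background_remove([background, clean], design)
        assert out.kept == [clean] and out.removed == [background]

    def test_no_control_observation_is_identity(self):
        design = make_design()
        records = [rec(runs=["condA_b1_t1"])]
        out = background_remove(records, design)
        assert out.kept == records and out.removed == []

    def test_epitope_removed_when_any_member_in_control(self, cd74_records,
                                                        cd74_proteome):
        from plateau.epitope_core import call_epitopes, map_peptides

        design = make_design()
        tainted = PeptideRecord(
            "KPVSKMRMATPLLMQA", ("P04233",), {"ctrl_1": 5.0, "condA_b1_t1": 1.0}
        )
        records = [r for r in cd74_records if r.sequence != tainted.sequence]
        records.append(tainted)
        epitopes = call_epitopes(map_peptides(records, cd74_proteome).aligned)
        out = background_remove(epitopes, design)
        assert out.kept == [] and len(out.removed) == 1

    def test_planted_background_binders_exactly_removed(self):
        design = make_design()
        planted = [rec(seq, runs=["ctrl_1"]) for seq in
                   ("AAAAAAAAAAC", "AAAAAAAAAAD", "AAAAAAAAAAE",
                    "AAAAAAAAAAF", "AAAAAAAAAAG")]
        clean = [rec(seq, runs=["condA_b1_t1"]) for seq in
                 ("CCCCCCCCCCA", "CCCCCCCCCCD")]
        out = background_remove(planted + clean, design)
        assert out.removed == planted and out.kept == clean

    def test_missing_controls_is_config_error(self):
        design = make_design(n_controls=0)
        with pytest.raises(FilterConfigError):
            background_remove([rec()], design)


def test_cascade_is_monotone():
    design = make_design(conditions=("condA",))
    records = [
        rec("A" * 11, runs=["condA_b1_t1", "condA_b1_t2",
                            "condA_b2_t1", "condA_b2_t2"]),
        rec("C" * 10),
        rec("D" * 11, decoy=True, proteins=()),
        rec("E" * 11, runs=["condA_b1_t1"]),
    ]
    s1 = remove_flagged(records).kept
    s2 = length_filter(s1)
    s3 = replicate_filter(s2, design).union
    assert set(map(id, s3)) <= set(map(id, s2)) <= set(map(id, s1)) <= set(
        map(id, records)
    )
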