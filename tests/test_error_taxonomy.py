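"""Event extraction and the homopolymer-aware error taxonomy."""

import random

import pytest

from mitobench.aligner import AlignedPair, global_align, normalize_gaps
from mitobench.error_taxonomy import (
    EXTENSION_CATEGORIES,
    ErrorCategory,
    ErrorEvent,
    classify_event,
    classify_events,
    extract_events,
    profile,
)
from mitobench.seq_io import CircularSequence


def _lin(seq):
    return CircularSequence("r", seq, "linear")


def _aligned(ref_row, asm_row):
    return normalize_gaps(AlignedPair(ref_row, asm_row, 0.0))


class TestExtractEvents:
    def test_single_deletion_left_normalized(self):
        pair = _aligned("AACCTT", "AAC-TT")
        (event,) = extract_events(pair)
        assert (event.kind, event.bases, event.ref_pos) == ("deletion", "C", 2)

    def test_identical_rows_give_no_events(self):
        assert extract_events(_aligned("ACGT", "ACGT")) == []

    def test_maximal_insertion_run_is_one_event(self):
        pair = _aligned("AC--GT", "ACTAGT")
        (event,) = extract_events(pair)
        assert (event.kind, event.bases, event.length) == ("insertion", "TA", 2)

    def test_insertion_ref_pos_is_following_coordinate(self):
        pair = _aligned("AC-GT", "ACTGT")
        (event,) = extract_events(pair)
        assert event.ref_pos == 2

    def test_adjacent_substitutions_stay_separate(self):
        events = extract_events(_aligned("AACC", "AGTC"))
        assert [e.kind for e in events] == ["substitution"] * 2
        assert [e.ref_pos for e in events] == [1, 2]

    def test_rejects_non_normalized_alignment(self):
        pair = AlignedPair("ACCCT", "ACC-T", 0.0)
        with pytest.raises(ValueError, match="not gap-normalized"):
            extract_events(pair)

    def test_n_columns_skipped_by_default_counted_on_request(self):
        pair = _aligned("ANGT", "ACGT")
        assert extract_events(pair) == []
        (event,) = extract_events(pair, count_ambiguous=True)
        assert event.kind == "substitution"

    def test_event_totals_match_gap_runs_plus_mismatches(self):
        rng = random.Random(5)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 20)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 20)))
            pair = normalize_gaps(global_align(a, b))
            events = extract_events(pair)
            # conservation: per-kind base counts follow from row lengths
            ins = sum(e.length for e in events if e.kind == "insertion")
            dels = sum(e.length for e in events if e.kind == "deletion")
            assert ins == pair.ref_row.count("-")
            assert dels == pair.asm_row.count("-")
            # deletions never overlap on the reference
            spans = sorted(
                (e.ref_pos, e.ref_pos + e.length)
                for e in events
                if e.kind == "deletion"
            )
            assert all(s0 >= e_prev for (_, e_prev), (s0, _) in zip(spans, spans[1:]))


class TestClassifyEvent:
    def test_deletion_from_two_base_run_is_homopolymer(self):
        event = ErrorEvent("deletion", 1, 2, "C")
        out = classify_event(event, _lin("AACCTT"))
        assert out.category == ErrorCategory.HP_DEL_1
        assert (out.hp_nucleotide, out.hp_run_len) == ("C", 2)

    def test_double_insertion_next_to_run_is_homopolymer(self):
        event = ErrorEvent("insertion", 2, 2, "TT")
        out = classify_event(event, _lin("ACTTTTGA"))
        assert out.category == ErrorCategory.HP_INS_2
        assert out.hp_run_len == 4

    def test_lone_base_context_is_single_indel(self):
        deletion = ErrorEvent("deletion", 1, 2, "G")
        assert (
            classify_event(deletion, _lin("ACGTA")).category
            == ErrorCategory.DEL_1
        )
        insertion = ErrorEvent("insertion", 2, 2, "AC")
        assert (
            classify_event(insertion, _lin("TTGGC")).category
            == ErrorCategory.INS_SHORT
        )

    def test_insertion_next_to_lone_base_is_single_not_homopolymer(self):
        # reference-run criterion: the run must be >= 2 before the edit
        event = ErrorEvent("insertion", 1, 2, "A")
        assert (
            classify_event(event, _lin("GCAGC")).category == ErrorCategory.INS_1
        )

    def test_resulting_run_criterion_switch(self):
        event = ErrorEvent("insertion", 2, 2, "AA")
        ref = _lin("GCTGC")
        assert (
            classify_event(event, ref).category == ErrorCategory.INS_SHORT
        )
        assert (
            classify_event(event, ref, hp_criterion="resulting-run").category
            == ErrorCategory.HP_INS_2
        )

    def test_multiplicities_and_extension_categories(self):
        ref = _lin("A" * 12 + "CGT")
        for k, expected in [
            (1, ErrorCategory.HP_DEL_1),
            (7, ErrorCategory.HP_DEL_7),
            (8, ErrorCategory.HP_DEL_GT7),
        ]:
            event = ErrorEvent("deletion", k, 0, "A" * k)
            assert classify_event(event, ref).category == expected
        long_ins = ErrorEvent("insertion", 5, 13, "ACGTA")
        assert classify_event(long_ins, ref).category == ErrorCategory.INS_LONG
        assert ErrorCategory.INS_LONG in EXTENSION_CATEGORIES
        assert ErrorCategory.HP_DEL_7 not in EXTENSION_CATEGORIES

    def test_homopolymer_run_wraps_circular_origin(self):
        # run of A spans the origin: ...AA|AA... is a 4-run on a circle
        ref = CircularSequence("r", "AACGTAA", "circular")
        event = ErrorEvent("insertion", 1, 0, "A")
        out = classify_event(event, ref)
        assert out.category == ErrorCategory.HP_INS_1
        assert out.hp_run_len == 4
        linear = _lin("AACGTAA")
        assert classify_event(event, linear).hp_run_len == 2

    def test_substitution(self):
        event = ErrorEvent("substitution", 1, 3, "A>G")
        assert (
            classify_event(event, _lin("ACGTA")).category
            == ErrorCategory.SUBSTITUTION
        )


class TestProfile:
    def test_empty(self):
        assert profile([]).total == 0

    def test_totals_count_events_once_regardless_of_length(self):
        ref = _lin("ACTTTTGA")
        events = [
            classify_event(ErrorEvent("insertion", 2, 2, "TT"), ref),
            classify_event(ErrorEvent("insertion", 2, 2, "TT"), ref),
            classify_event(ErrorEvent("insertion", 2, 2, "TT"), ref),
            classify_event(ErrorEvent("substitution", 1, 1, "C>G"), ref),
        ]
        prof = profile(events)
        assert prof.total == 4
        assert prof[ErrorCategory.HP_INS_2] == 3
        assert prof[ErrorCategory.SUBSTITUTION] == 1

    def test_unclassified_events_rejected(self):
        with pytest.raises(ValueError):
            profile([ErrorEvent("deletion", 1, 0, "A")])

    def test_to_dict_total_consistent(self):
        ref = _lin("ACTTTTGA")
        events = classify_events(
            [ErrorEvent("insertion", 2, 2, "TT")], ref
        )
        d = profile(events).to_dict()
        assert d["total"] == sum(v for k, v in d.items() if k != "total") == 1
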