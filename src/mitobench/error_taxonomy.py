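"""Extraction and classification of assembly errors from an alignment.

Discordances between a candidate assembly and the reference are carried as
events — one per maximal gap run (indels) and one per mismatching aligned
column (substitutions) — and classified with a homopolymer-aware taxonomy:
an indel of 1-7 identical bases that lengthens or shortens a reference
homopolymer run (two or more bases long) is a homopolymer insertion or
deletion of that multiplicity; everything else falls into simple
substitution, single insertion/deletion (1 bp), or short insertion/deletion
(2-4 bp). Extension categories (non-homopolymer indels >= 5 bp, homopolymer
indels > 7 bp) make the classifier total; they are flagged as lying outside
the published taxonomy.

The homopolymer criterion examines the *reference* run as it exists before
the edit (the reference is the ground truth); inserting an A next to a lone
A is therefore a single insertion, not a homopolymer event. The alternative
reading — the run as it exists after the edit — is available behind the
``hp_criterion="resulting-run"`` switch.

Events are counted once each regardless of length; per-assembly totals are
event counts, not discordant-base counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional

from .aligner import GAP, AlignedPair, normalize_gaps
from .seq_io import CircularSequence

__all__ = [
    "ErrorCategory",
    "PAPER_CATEGORIES",
    "EXTENSION_CATEGORIES",
    "ErrorEvent",
    "ErrorProfile",
    "extract_events",
    "classify_event",
    "classify_events",
    "profile",
]

_HP_MAX = 7  # multiplicities named by the taxonomy: single .. septuple


class ErrorCategory(str, Enum):
    HP_INS_1 = "HP_INS_1"
    HP_INS_2 = "HP_INS_2"
    HP_INS_3 = "HP_INS_3"
    HP_INS_4 = "HP_INS_4"
    HP_INS_5 = "HP_INS_5"
    HP_INS_6 = "HP_INS_6"
    HP_INS_7 = "HP_INS_7"
    HP_DEL_1 = "HP_DEL_1"
    HP_DEL_2 = "HP_DEL_2"
    HP_DEL_3 = "HP_DEL_3"
    HP_DEL_4 = "HP_DEL_4"
    HP_DEL_5 = "HP_DEL_5"
    HP_DEL_6 = "HP_DEL_6"
    HP_DEL_7 = "HP_DEL_7"
    SUBSTITUTION = "SUBSTITUTION"
    INS_1 = "INS_1"
    INS_SHORT = "INS_SHORT"  # 2-4 bp, non-homopolymer
    DEL_1 = "DEL_1"
    DEL_SHORT = "DEL_SHORT"  # 2-4 bp, non-homopolymer
    INS_LONG = "INS_LONG"  # >= 5 bp, outside the published taxonomy
    DEL_LONG = "DEL_LONG"
    HP_INS_GT7 = "HP_INS_GT7"
    HP_DEL_GT7 = "HP_DEL_GT7"


#: Categories named by the published taxonomy.
PAPER_CATEGORIES = frozenset(
    c for c in ErrorCategory
    if c not in (
        ErrorCategory.INS_LONG,
        ErrorCategory.DEL_LONG,
        ErrorCategory.HP_INS_GT7,
        ErrorCategory.HP_DEL_GT7,
    )
)

#: Totality extensions, flagged in reports as outside the taxonomy.
EXTENSION_CATEGORIES = frozenset(ErrorCategory) - PAPER_CATEGORIES


@dataclass(frozen=True)
class ErrorEvent:
    """One discordance between assembly and reference.

    ``kind`` is the structural carrier ('insertion', 'deletion' or
    'substitution'); ``category`` is filled by :func:`classify_event`.
    ``ref_pos`` is the 0-based reference coordinate of the event's left
    edge — for insertions, the reference coordinate immediately following
    the gap run (the insertion sits before that base). ``bases`` holds the
    inserted/deleted bases, or "ref>asm" for a substitution.
    """

    kind: str
    length: int
    ref_pos: int
    bases: str
    category: Optional[ErrorCategory] = None
    hp_nucleotide: Optional[str] = None
    hp_run_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind == "substitution" and self.length != 1:
            raise ValueError("substitution events have length 1")
        if self.kind != "substitution" and self.length != len(self.bases):
            raise ValueError("indel length must equal len(bases)")
        hp = self.category is not None and self.category.name.startswith("HP_")
        if hp != (self.hp_nucleotide is not None) or hp != (
            self.hp_run_len is not None
        ):
            raise ValueError(
                "hp_nucleotide/hp_run_len present iff homopolymer-classified"
            )


@dataclass(frozen=True)
class ErrorProfile:
    """Per-category event counts; ``total`` is the number of events."""

    counts: Dict[ErrorCategory, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cat}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, category: ErrorCategory) -> int:
        return self.counts.get(category, 0)

    def nonzero(self) -> Dict[str, int]:
        return {c.value: n for c, n in sorted(self.counts.items()) if n}

    def to_dict(self) -> Dict[str, int]:
        d = {c.value: self.counts.get(c, 0) for c in ErrorCategory}
        d["total"] = self.total
        return d

    def __eq__(self, other) -> bool:
        if not isinstance(other, ErrorProfile):
            return NotImplemented
        cats = set(self.counts) | set(other.counts)
        return all(self[c] == other[c] for c in cats)


def extract_events(
    pair: AlignedPair, count_ambiguous: bool = False
) -> List[ErrorEvent]:
    """Pull unclassified carrier events out of a gap-normalized alignment.

    One insertion per maximal gap run in the reference row, one deletion
    per maximal gap run in the assembly row, one substitution per
    mismatching aligned column. Columns involving N are skipped unless
    ``count_ambiguous`` is set (the simulator never emits N; real input
    may carry it). Rejects alignments that are not in canonical left-
    shifted gap form.
    """
    canonical = normalize_gaps(pair)
    if canonical.ref_row != pair.ref_row or canonical.asm_row != pair.asm_row:
        raise ValueError(
            "alignment is not gap-normalized; run normalize_gaps first"
        )
    events: List[ErrorEvent] = []
    ref_pos = 0
    i = 0
    n = len(pair.ref_row)
    ref_row, asm_row = pair.ref_row, pair.asm_row
    while i < n:
        r, a = ref_row[i], asm_row[i]
        if r == GAP:  # insertion run
            j = i
            while j < n and ref_row[j] == GAP:
                j += 1
            events.append(
                ErrorEvent(
                    kind="insertion",
                    length=j - i,
                    ref_pos=ref_pos,
                    bases=asm_row[i:j],
                )
            )
            i = j
        elif a == GAP:  # deletion run
            j = i
            while j < n and asm_row[j] == GAP:
                j += 1
            events.append(
                ErrorEvent(
                    kind="deletion",
                    length=j - i,
                    ref_pos=ref_pos,
                    bases=ref_row[i:j],
                )
            )
            ref_pos += j - i
            i = j
        else:
            if r != a and ("N" not in (r, a) or count_ambiguous):
                events.append(
                    ErrorEvent(
                        kind="substitution",
                        length=1,
                        ref_pos=ref_pos,
                        bases=f"{r}>{a}",
                    )
                )
            ref_pos += 1
            i += 1
    return sorted(events, key=lambda e: (e.ref_pos, e.kind))


def _run_containing(seq: str, pos: int, circular: bool) -> int:
    """Length of the maximal identical-base run containing ``pos``."""
    n = len(seq)
    ch = seq[pos]
    left = pos
    while left > 0 and seq[left - 1] == ch:
        left -= 1
    right = pos
    while right < n - 1 and seq[right + 1] == ch:
        right += 1
    length = right - left + 1
    if circular and length < n:
        if left == 0:
            k = n - 1
            while k > right and seq[k] == ch:
                length += 1
                k -= 1
        if right == n - 1:
            k = 0
            while k < left and seq[k] == ch:
                length += 1
                k += 1
    return length


def _adjacent_run(seq: str, pos: int, ch: str, circular: bool) -> int:
    """Longest run of ``ch`` immediately flanking insertion point ``pos``.

    The insertion sits between reference bases ``pos - 1`` and ``pos``
    (circularly). If both flanks carry ``ch`` they belong to one run.
    """
    n = len(seq)
    left = (pos - 1) % n if (circular or pos > 0) else None
    right = pos % n if (circular or pos < n) else None
    if left is not None and seq[left] == ch:
        return _run_containing(seq, left, circular)
    if right is not None and seq[right] == ch:
        return _run_containing(seq, right, circular)
    return 0


def classify_event(
    event: ErrorEvent,
    reference: CircularSequence,
    hp_criterion: str = "reference-run",
) -> ErrorEvent:
    """Assign a taxonomy category to a carrier event.

    Rules, in order: substitutions are SUBSTITUTION; an indel of identical
    bases whose flanking reference run of that base is >= 2 bp long is a
    homopolymer event of multiplicity = indel length; remaining length-1
    indels are single insertions/deletions; lengths 2-4 short; >= 5 long.
    """
    if hp_criterion not in ("reference-run", "resulting-run"):
        raise ValueError(f"unknown hp_criterion {hp_criterion!r}")
    if event.kind == "substitution":
        return replace(event, category=ErrorCategory.SUBSTITUTION)

    seq = reference.seq
    circular = reference.is_circular
    mono = len(set(event.bases)) == 1
    hp_run = 0
    if mono:
        ch = event.bases[0]
        if event.kind == "deletion":
            # deleted bases are reference bases; their containing run
            hp_run = _run_containing(seq, event.ref_pos, circular)
        else:
            hp_run = _adjacent_run(seq, event.ref_pos, ch, circular)
        if hp_criterion == "resulting-run" and event.kind == "insertion":
            # judge the run as it exists in the assembly, after the edit
            hp_run += event.length

    if mono and hp_run >= 2:
        tag = "HP_INS" if event.kind == "insertion" else "HP_DEL"
        suffix = str(event.length) if event.length <= _HP_MAX else "GT7"
        ref_run = (
            _run_containing(seq, event.ref_pos, circular)
            if event.kind == "deletion"
            else _adjacent_run(seq, event.ref_pos, event.bases[0], circular)
        )
        return replace(
            event,
            category=ErrorCategory[f"{tag}_{suffix}"],
            hp_nucleotide=event.bases[0],
            hp_run_len=ref_run,
        )
    tag = "INS" if event.kind == "insertion" else "DEL"
    if event.length == 1:
        category = ErrorCategory[f"{tag}_1"]
    elif event.length <= 4:
        category = ErrorCategory[f"{tag}_SHORT"]
    else:
        category = ErrorCategory[f"{tag}_LONG"]
    return replace(event, category=category)


def classify_events(
    events: List[ErrorEvent],
    reference: CircularSequence,
    hp_criterion: str = "reference-run",
) -> List[ErrorEvent]:
    return [classify_event(e, reference, hp_criterion) for e in events]


def profile(events: List[ErrorEvent]) -> ErrorProfile:
    """Tally classified events per category (each event counts once)."""
    counts: Dict[ErrorCategory, int] = {}
    for e in events:
        if e.category is None:
            raise ValueError("profile() requires classified events")
        counts[e.category] = counts.get(e.category, 0) + 1
    return ErrorProfile(counts=counts)
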