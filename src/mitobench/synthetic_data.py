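"""Synthetic mitogenome references and error-injected assemblies.

Every pipeline stage is testable offline against ground truth: this module
builds a ~16.7 kb circular vertebrate-mitogenome-like reference (13
protein-coding genes valid under the vertebrate mitochondrial code, 22
tRNAs, 2 rRNAs, a control region, and a tunable fraction of sites inside
homopolymer runs), then derives "assemblies" from it by injecting an exact,
per-category count of errors mimicking the nanopore profile — dominated by
1-2 bp indels at homopolymer runs with a minority of substitutions and
non-homopolymer indels.

Injection is count-based (not rate-based) so that recovery can be checked
exactly: each event is recorded in a replayable :class:`TruthSet`, placed
in left-normalized form at loci spaced at least ``min_spacing`` bp apart
(preventing event merging during alignment — a deliberate idealization
relative to real nanopore data, where adjacent errors do interact).
Homopolymer events draw their run length-weighted, mirroring the empirical
concentration of miscounts at longer runs. A rate-based Poisson mode is
available for stress tests where exact recovery is not required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .circular_norm import reverse_complement
from .error_taxonomy import (
    ErrorCategory,
    ErrorEvent,
    classify_event,
)
from .seq_io import CircularSequence, GeneAnnotation

__all__ = [
    "GenomeSpec",
    "ErrorSpec",
    "TruthSet",
    "GenomePackingError",
    "PlacementError",
    "generate_reference",
    "inject_errors",
    "apply_events",
    "MODAL_ERROR_SPEC_COUNTS",
]

#: A typical per-assembly error profile for a long-read mitogenome
#: (single homopolymer insertions dominating, then single homopolymer
#: deletions and double homopolymer insertions, with a minority of
#: substitutions and non-homopolymer single indels; 78 events in all).
MODAL_ERROR_SPEC_COUNTS: Dict[ErrorCategory, int] = {
    ErrorCategory.HP_INS_1: 40,
    ErrorCategory.HP_DEL_1: 14,
    ErrorCategory.HP_INS_2: 10,
    ErrorCategory.SUBSTITUTION: 6,
    ErrorCategory.DEL_1: 4,
    ErrorCategory.INS_1: 4,
}

_BASES = "ACGT"

# Canonical vertebrate mitochondrial gene lengths (bp) used when the
# requested gene counts match the standard 13 PCG / 22 tRNA / 2 rRNA plan.
_PCG_LENGTHS = (975, 1044, 1551, 690, 168, 681, 786, 348, 297, 1377, 1836, 522, 1140)
_PCG_NAMES = ("nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
              "nad3", "nad4l", "nad4", "nad5", "nad6", "cytb")
_RRNA_LENGTHS = (950, 1600)
_RRNA_NAMES = ("rrnS", "rrnL")
_TRNA_LENGTH = 70
_CR_LENGTH = 1065
_STOPS = ("TAA", "TAG", "AGA", "AGG")
# recode table for third-position edits that kill an in-frame stop
_DESTOP = {"TAA": "TAC", "TAG": "TAC", "AGA": "AGC", "AGG": "AGC"}

#: Events are kept clear of the rotation anchor at the reference start and
#: of the sequence end, so circular normalization recovers the exact frame.
_TERMINAL_GUARD = 40


class GenomePackingError(ValueError):
    """The requested genes cannot be packed into the requested length."""


class PlacementError(ValueError):
    """No qualifying locus found for an error category."""


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic circular mitogenome-like reference.

    ``hp_fraction`` targets the fraction of sites lying inside identical-
    base runs of length >= 2; the realized value lands within about
    +/- 0.05 of the target. ``gc`` is the G+C fraction.
    """

    seed: int
    length: int = 16705
    hp_fraction: float = 0.45
    gc: float = 0.38
    n_pcg: int = 13
    n_trna: int = 22
    n_rrna: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if not 0 < self.hp_fraction < 0.9:
            raise ValueError("hp_fraction must be in (0, 0.9)")
        if self.length < 200:
            raise ValueError("length too small for a mitogenome-like sequence")


@dataclass(frozen=True)
class ErrorSpec:
    """Exact per-category error counts to inject, with placement spacing."""

    seed: int
    counts: Dict[ErrorCategory, int] = field(default_factory=dict)
    min_spacing: int = 10

    def __post_init__(self) -> None:
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        for cat, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cat}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class TruthSet:
    """The injected events, in reference coordinates, plus provenance."""

    events: Tuple[ErrorEvent, ...]
    reference_id: str
    mutated_id: str

    def profile_counts(self) -> Dict[ErrorCategory, int]:
        out: Dict[ErrorCategory, int] = {}
        for e in self.events:
            out[e.category] = out.get(e.category, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "mutated_id": self.mutated_id,
            "events": [
                {
                    "category": e.category.value,
                    "kind": e.kind,
                    "ref_pos": e.ref_pos,
                    "length": e.length,
                    "bases": e.bases,
                }
                for e in self.events
            ],
        }


def _draw_run_lengths(rng: np.random.Generator, spec: GenomeSpec) -> np.ndarray:
    """Run lengths whose expected >=2-run site fraction hits the target.

    Runs of length >= 2 are drawn with mean m = 2.3 (lengths 2/3/4 at
    0.75/0.20/0.05); the singleton probability q then solves
    hp_fraction = (1-q) m / (q + (1-q) m).
    """
    f = spec.hp_fraction
    m = 2.3
    q = m * (1 - f) / (f + m * (1 - f))
    n_draws = int(spec.length * 1.2) + 16
    singleton = rng.random(n_draws) < q
    multi = rng.choice([2, 3, 4], size=n_draws, p=[0.75, 0.20, 0.05])
    return np.where(singleton, 1, multi)


def _run_base_weights(gc: float) -> np.ndarray:
    """Run-base weights whose no-repeat Markov chain is stationary at gc.

    Consecutive runs must differ in base, so drawing run bases directly
    from the target composition would inflate the minority (G/C at low gc)
    bases. A small fixed-point iteration corrects the weights so the
    chain's stationary distribution matches the target base composition.
    """
    target = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    w = target.copy()
    for _ in range(200):
        # transition matrix of the no-repeat chain under weights w
        P = np.tile(w, (4, 1))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        pi = target.copy()
        for _ in range(200):
            pi = pi @ P
        w *= target / np.maximum(pi, 1e-12)
        w /= w.sum()
    return w


def _draw_sequence(rng: np.random.Generator, spec: GenomeSpec) -> str:
    weights = _run_base_weights(spec.gc)
    lengths = _draw_run_lengths(rng, spec)
    chars: List[str] = []
    total = 0
    prev = None
    for run_len in lengths:
        idx = [i for i, b in enumerate(_BASES) if b != prev]
        w = weights[idx]
        ch = _BASES[int(rng.choice(idx, p=w / w.sum()))]
        run_len = int(min(run_len, spec.length - total))
        chars.append(ch * run_len)
        prev = ch
        total += run_len
        if total >= spec.length:
            break
    seq = "".join(chars)
    # keep the circular junction run-free so run arithmetic never wraps
    if seq[0] == seq[-1]:
        forbidden = {seq[0], seq[-2] if len(seq) > 1 else seq[0]}
        repl = next(b for b in _BASES if b not in forbidden)
        seq = seq[:-1] + repl
    return seq


def _layout_genes(spec: GenomeSpec) -> List[GeneAnnotation]:
    """Pack rRNA / tRNA / PCG intervals plus a control region, no overlap."""
    standard = (
        spec.n_pcg == 13 and spec.n_trna == 22 and spec.n_rrna == 2
    )
    if standard:
        pcg_lengths, pcg_names = list(_PCG_LENGTHS), list(_PCG_NAMES)
        rrna_lengths, rrna_names = list(_RRNA_LENGTHS), list(_RRNA_NAMES)
    else:
        pcg_lengths = [300] * spec.n_pcg
        pcg_names = [f"pcg{i + 1}" for i in range(spec.n_pcg)]
        rrna_lengths = [900] * spec.n_rrna
        rrna_names = [f"rrn{i + 1}" for i in range(spec.n_rrna)]
    trna_names = [f"trn{i + 1}" for i in range(spec.n_trna)]

    # interleave in a mitogenome-like order: rRNAs first, tRNAs spread
    # between the protein-coding genes, control region at the end
    plan: List[Tuple[str, int, str]] = []
    trna_iter = iter(trna_names)
    for name, length in zip(rrna_names, rrna_lengths):
        plan.append((name, length, "rRNA"))
        nxt = next(trna_iter, None)
        if nxt:
            plan.append((nxt, _TRNA_LENGTH, "tRNA"))
    for i, (name, length) in enumerate(zip(pcg_names, pcg_lengths)):
        plan.append((name, length, "PCG"))
        for _ in range(2 if i % 2 == 0 else 1):
            nxt = next(trna_iter, None)
            if nxt:
                plan.append((nxt, _TRNA_LENGTH, "tRNA"))
    for name in trna_iter:
        plan.append((name, _TRNA_LENGTH, "tRNA"))

    spacer = 2
    needed = sum(length for _, length, _ in plan) + spacer * len(plan)
    cr_len = min(_CR_LENGTH, max(0, spec.length - needed - _TERMINAL_GUARD))
    if needed + _TERMINAL_GUARD > spec.length:
        raise GenomePackingError(
            f"cannot pack {len(plan)} genes ({needed} bp with spacers) "
            f"into {spec.length} bp"
        )
    annotations = []
    pos = _TERMINAL_GUARD  # keep the rotation anchor gene-free
    minus_pcg = {"nad6"} if standard else {pcg_names[-2]} if len(pcg_names) > 1 else set()
    trna_strands = {}
    for i, name in enumerate(trna_names):
        trna_strands[name] = "-" if i % 3 == 2 else "+"
    for name, length, kind in plan:
        if kind == "PCG":
            strand = "-" if name in minus_pcg else "+"
        elif kind == "tRNA":
            strand = trna_strands[name]
        else:
            strand = "+"
        annotations.append(GeneAnnotation(name, pos, pos + length, strand, kind))
        pos += length + spacer
    if cr_len >= 50:
        annotations.append(GeneAnnotation("CR", pos, pos + cr_len, "+", "CR"))
    return annotations


def _force_orf(seq: List[str], ann: GeneAnnotation) -> None:
    """Rewrite a PCG interval in place into a valid open reading frame.

    The gene starts with ATG, ends with TAA, and carries no internal stop
    under the vertebrate mitochondrial code; internal stops are removed by
    third-position recoding.
    """
    gene = "".join(seq[ann.start : ann.end])
    if ann.strand == "-":
        gene = reverse_complement(gene)
    n_codons = len(gene) // 3
    codons = [gene[3 * k : 3 * k + 3] for k in range(n_codons)]
    tail = gene[3 * n_codons :]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for k in range(1, n_codons - 1):
        if codons[k] in _DESTOP:
            codons[k] = _DESTOP[codons[k]]
    gene = "".join(codons) + tail
    if ann.strand == "-":
        gene = reverse_complement(gene)
    seq[ann.start : ann.end] = list(gene)


def generate_reference(
    spec: GenomeSpec,
) -> Tuple[CircularSequence, List[GeneAnnotation]]:
    """Deterministically build a synthetic reference and its gene track."""
    rng = np.random.default_rng(spec.seed)
    annotations = _layout_genes(spec)
    seq = list(_draw_sequence(rng, spec))
    for ann in annotations:
        if ann.kind == "PCG":
            _force_orf(seq, ann)
    reference = CircularSequence(
        id=f"synthetic_ref_seed{spec.seed}",
        seq="".join(seq),
        topology="circular",
    )
    return reference, annotations


def _reference_runs(seq: str) -> List[Tuple[int, int, str]]:
    """Maximal identical-base runs as (start, length, base)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i, seq[i]))
        i = j
    return runs


class _Footprints:
    """Interval bookkeeping enforcing the minimum event spacing."""

    def __init__(self, min_spacing: int) -> None:
        self.min_spacing = min_spacing
        self.taken: List[Tuple[int, int]] = []

    def fits(self, start: int, end: int) -> bool:
        for s, e in self.taken:
            if start < e + self.min_spacing and s < end + self.min_spacing:
                return False
        return True

    def add(self, start: int, end: int) -> None:
        self.taken.append((start, end))


_MAX_DRAWS = 2000


def _place_events(
    reference: CircularSequence, spec: ErrorSpec, rng: np.random.Generator
) -> List[ErrorEvent]:
    seq = reference.seq
    n = len(seq)
    if spec.total * spec.min_spacing >= n:
        raise PlacementError(
            f"{spec.total} events at >= {spec.min_spacing} bp spacing do "
            f"not fit in {n} bp"
        )
    lo, hi = _TERMINAL_GUARD, n - _TERMINAL_GUARD
    runs = [r for r in _reference_runs(seq) if lo <= r[0] and r[0] + r[1] <= hi]
    multi_runs = [r for r in runs if r[1] >= 2]
    run_weights = np.array([r[1] for r in multi_runs], dtype=float)
    run_weights /= run_weights.sum()
    footprints = _Footprints(spec.min_spacing)
    events: List[ErrorEvent] = []

    def propose(name: str):
        """One random candidate (carrier, footprint) for a category."""
        if name.startswith("HP_"):
            if not multi_runs:
                return None
            k = 8 + int(rng.integers(0, 3)) if name.endswith("GT7") else int(name[-1])
            idx = int(rng.choice(len(multi_runs), p=run_weights))
            start, run_len, ch = multi_runs[idx]
            if name.startswith("HP_DEL") and run_len < k:
                return None
            kind = "insertion" if "INS" in name else "deletion"
            carrier = ErrorEvent(kind=kind, length=k, ref_pos=start, bases=ch * k)
            return carrier, (start - 1, start + run_len + 1)
        pos = int(rng.integers(lo, hi))
        if name == "SUBSTITUTION":
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == seq[pos]:
                return None
            carrier = ErrorEvent(
                kind="substitution", length=1, ref_pos=pos,
                bases=f"{seq[pos]}>{alt}",
            )
            return carrier, (pos, pos + 1)
        if name == "INS_1":
            alt = _BASES[int(rng.integers(0, 4))]
            if alt in (seq[pos - 1], seq[pos]):
                return None  # would touch a run and become a homopolymer event
            carrier = ErrorEvent(kind="insertion", length=1, ref_pos=pos, bases=alt)
            return carrier, (pos - 1, pos + 1)
        if name == "DEL_1":
            if seq[pos] in (seq[pos - 1], seq[pos + 1]):
                return None  # must delete from a singleton run
            carrier = ErrorEvent(
                kind="deletion", length=1, ref_pos=pos, bases=seq[pos]
            )
            return carrier, (pos - 1, pos + 2)
        if name in ("INS_SHORT", "INS_LONG"):
            length = int(rng.integers(2, 5) if name == "INS_SHORT" else rng.integers(5, 9))
            ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=length))
            if len(set(ins)) == 1:
                return None  # all-same would be a homopolymer event
            if ins[-1] == seq[pos - 1] or ins[0] == seq[pos]:
                return None  # keep the placement left-normalized and unique
            carrier = ErrorEvent(
                kind="insertion", length=length, ref_pos=pos, bases=ins
            )
            return carrier, (pos - 1, pos + 1)
        if name in ("DEL_SHORT", "DEL_LONG"):
            length = int(rng.integers(2, 5) if name == "DEL_SHORT" else rng.integers(5, 9))
            if pos + length >= hi:
                return None
            seg = seq[pos : pos + length]
            if len(set(seg)) == 1:
                return None  # all-same would be a homopolymer event
            if seq[pos - 1] == seq[pos + length - 1]:
                return None  # deletion could left-shift; keep it canonical
            if seq[pos] == seq[pos + length]:
                return None  # or shift right equivalently
            carrier = ErrorEvent(
                kind="deletion", length=length, ref_pos=pos, bases=seg
            )
            return carrier, (pos - 1, pos + length + 1)
        raise PlacementError(f"unhandled category {name}")

    for category in sorted(spec.counts, key=lambda c: c.value):
        for _ in range(spec.counts[category]):
            for _ in range(_MAX_DRAWS):
                cand = propose(category.value)
                if cand is None:
                    continue
                carrier, (fs, fe) = cand
                if not footprints.fits(fs, fe):
                    continue
                classified = classify_event(carrier, reference)
                if classified.category != category:
                    continue  # context did not realize the requested class
                footprints.add(fs, fe)
                events.append(classified)
                break
            else:
                raise PlacementError(
                    f"no qualifying locus found for {category.value} after "
                    f"{_MAX_DRAWS} draws; the genome may lack the required "
                    "context — regenerate the reference"
                )
    events.sort(key=lambda e: e.ref_pos)
    return events


def apply_events(reference_seq: str, events: Sequence[ErrorEvent]) -> str:
    """Replay injected events (reference coordinates) onto a sequence."""
    seq = reference_seq
    for e in sorted(events, key=lambda ev: ev.ref_pos, reverse=True):
        p = e.ref_pos
        if e.kind == "substitution":
            _, alt = e.bases.split(">")
            seq = seq[:p] + alt + seq[p + 1 :]
        elif e.kind == "deletion":
            if seq[p : p + e.length] != e.bases:
                raise ValueError(f"replay mismatch at {p}")
            seq = seq[:p] + seq[p + e.length :]
        else:
            seq = seq[:p] + e.bases + seq[p:]
    return seq


def inject_errors(
    reference: CircularSequence,
    spec: ErrorSpec,
    rotate_by: int = 0,
    revcomp: bool = False,
) -> Tuple[CircularSequence, TruthSet]:
    """Derive an error-injected "assembly" from the reference.

    Events are placed at uniformly drawn loci satisfying their category's
    sequence context and the spacing constraint, recorded in reference
    coordinates, then the optional rotation and reverse-complement are
    applied last (they model the arbitrary frame and strand at which an
    assembler reports a circular contig, and leave the truth untouched).
    """
    rng = np.random.default_rng(spec.seed)
    events = _place_events(reference, spec, rng)
    mutated = apply_events(reference.seq, events)
    mutated_id = f"{reference.id}_mut_seed{spec.seed}"
    if rotate_by:
        r = rotate_by % len(mutated)
        mutated = mutated[r:] + mutated[:r]
    if revcomp:
        mutated = reverse_complement(mutated)
    assembly = CircularSequence(
        id=mutated_id, seq=mutated, topology=reference.topology
    )
    return assembly, TruthSet(
        events=tuple(events),
        reference_id=reference.id,
        mutated_id=mutated_id,
    )


def poisson_error_spec(
    mean_counts: Dict[ErrorCategory, float], seed: int, min_spacing: int = 10
) -> ErrorSpec:
    """Rate-based stress-test variant: Poisson draw per category."""
    rng = np.random.default_rng(seed)
    counts = {
        cat: int(rng.poisson(lam)) for cat, lam in mean_counts.items()
    }
    return ErrorSpec(seed=seed, counts=counts, min_spacing=min_spacing)
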