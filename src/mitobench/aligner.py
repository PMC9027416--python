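"""Optimal global alignment with affine gaps, plus canonical gap placement.

The benchmark compares exactly two sequences at a time (one candidate
assembly against the reference), so a full Needleman-Wunsch/Gotoh dynamic
program is both tractable and preferable to multiple-alignment heuristics:
it is deterministic and its optimality can be checked against brute-force
oracles.

A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the opening
column carries the open penalty, each further column the extension). The
default scoring (+2 / -3 / -5 / -2) favors contiguous indels over scattered
mismatches, matching the indel-dominated discordance profile of nanopore
assemblies at ~99.9% identity.

The position of an indel inside a homopolymer run is alignment-arbitrary;
:func:`normalize_gaps` shifts every gap run to its leftmost score-equivalent
placement so that downstream error classification is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .seq_io import CircularSequence

__all__ = [
    "ScoringScheme",
    "AlignedPair",
    "AlignmentGuardError",
    "global_align",
    "normalize_gaps",
    "write_alignment_fasta",
]

_NEG = -1e18

GAP = "-"


class AlignmentGuardError(ValueError):
    """The DP matrix would exceed the configured cell guard."""


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters (match > 0; penalties < 0)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > 0:
            raise ValueError("match score must be positive")
        if not (self.mismatch < 0 and self.gap_open < 0 and self.gap_extend < 0):
            raise ValueError("mismatch/gap penalties must be negative")


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped rows (reference on top) and the score."""

    ref_row: str
    asm_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.asm_row):
            raise ValueError("aligned rows must have equal length")
        for r, a in zip(self.ref_row, self.asm_row):
            if r == GAP and a == GAP:
                raise ValueError("column with gaps in both rows")

    @property
    def reference_seq(self) -> str:
        return self.ref_row.replace(GAP, "")

    @property
    def assembly_seq(self) -> str:
        return self.asm_row.replace(GAP, "")


# Traceback byte layout: bits 0-1 = predecessor state of M, bits 2-3 of X
# (gap in the assembly row), bits 4-5 of Y (gap in the reference row);
# state codes 0=M, 1=X, 2=Y. Ties break M > X > Y, giving a deterministic
# (later canonicalized) path.
@njit(cache=True)
def _gotoh_kernel(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M_prev = np.empty(m + 1)
    X_prev = np.empty(m + 1)
    Y_prev = np.empty(m + 1)
    M_cur = np.empty(m + 1)
    X_cur = np.empty(m + 1)
    Y_cur = np.empty(m + 1)
    M_prev[0] = 0.0
    X_prev[0] = _NEG
    Y_prev[0] = _NEG
    for j in range(1, m + 1):
        M_prev[j] = _NEG
        X_prev[j] = _NEG
        Y_prev[j] = gap_open + (j - 1) * gap_ext
        tb[0, j] = (2 << 4) if j > 1 else 0
    for i in range(1, n + 1):
        M_cur[0] = _NEG
        Y_cur[0] = _NEG
        X_cur[0] = gap_open + (i - 1) * gap_ext
        tb[i, 0] = (1 << 2) if i > 1 else 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            best = M_prev[j - 1]
            src = 0
            if X_prev[j - 1] > best:
                best = X_prev[j - 1]
                src = 1
            if Y_prev[j - 1] > best:
                best = Y_prev[j - 1]
                src = 2
            M_cur[j] = best + s
            t = src
            best = M_prev[j] + gap_open
            src = 0
            if X_prev[j] + gap_ext > best:
                best = X_prev[j] + gap_ext
                src = 1
            if Y_prev[j] + gap_open > best:
                best = Y_prev[j] + gap_open
                src = 2
            X_cur[j] = best
            t |= src << 2
            best = M_cur[j - 1] + gap_open
            src = 0
            if X_cur[j - 1] + gap_open > best:
                best = X_cur[j - 1] + gap_open
                src = 1
            if Y_cur[j - 1] + gap_ext > best:
                best = Y_cur[j - 1] + gap_ext
                src = 2
            Y_cur[j] = best
            t |= src << 4
            tb[i, j] = t
        M_prev, M_cur = M_cur, M_prev
        X_prev, X_cur = X_cur, X_prev
        Y_prev, Y_cur = Y_cur, Y_prev
    score = M_prev[m]
    state = 0
    if X_prev[m] > score:
        score = X_prev[m]
        state = 1
    if Y_prev[m] > score:
        score = Y_prev[m]
        state = 2
    return score, state, tb


def global_align(
    reference: CircularSequence | str,
    assembly: CircularSequence | str,
    scoring: ScoringScheme = ScoringScheme(),
    max_cells: float = 1e9,
) -> AlignedPair:
    """End-to-end optimal affine-gap alignment of assembly vs reference.

    Terminal gaps are scored like internal ones: after circular rotation
    there is no privileged end, so length differences at the ends are
    genuine indels. Refuses instances whose DP matrix would exceed
    ``max_cells`` cells (mitogenomes sit far below the default guard).
    """
    ref = reference.seq if isinstance(reference, CircularSequence) else reference
    asm = assembly.seq if isinstance(assembly, CircularSequence) else assembly
    if not ref or not asm:
        raise ValueError("both sequences must be nonempty")
    if (len(ref) + 1) * (len(asm) + 1) > max_cells:
        raise AlignmentGuardError(
            f"alignment of {len(ref)} x {len(asm)} bp exceeds the "
            f"{max_cells:.0f}-cell guard"
        )
    ea = np.frombuffer(ref.encode(), dtype=np.uint8)
    eb = np.frombuffer(asm.encode(), dtype=np.uint8)
    score, state, tb = _gotoh_kernel(
        ea, eb,
        float(scoring.match), float(scoring.mismatch),
        float(scoring.gap_open), float(scoring.gap_extend),
    )
    i, j = len(ref), len(asm)
    ref_cols: list = []
    asm_cols: list = []
    while i > 0 or j > 0:
        t = tb[i, j]
        if state == 0:
            src = t & 3
            ref_cols.append(ref[i - 1])
            asm_cols.append(asm[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            src = (t >> 2) & 3
            ref_cols.append(ref[i - 1])
            asm_cols.append(GAP)
            i -= 1
        else:
            src = (t >> 4) & 3
            ref_cols.append(GAP)
            asm_cols.append(asm[j - 1])
            j -= 1
        state = src
    return AlignedPair(
        ref_row="".join(reversed(ref_cols)),
        asm_row="".join(reversed(asm_cols)),
        score=float(score),
    )


def _gap_runs(row: list) -> list:
    """Maximal runs of gap columns in ``row`` as (start, end) pairs."""
    runs = []
    i = 0
    n = len(row)
    while i < n:
        if row[i] == GAP:
            j = i
            while j < n and row[j] == GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def normalize_gaps(pair: AlignedPair) -> AlignedPair:
    """Shift every gap run to its leftmost score-equivalent placement.

    A gap run in one row may move one column left whenever the preceding
    column is aligned (no gap in either row) and the base-carrying row has
    identical characters at the column entering and leaving the run — the
    swap then changes neither ungapped sequence nor any column's
    match/mismatch status. Applied to a fixed point; idempotent.
    """
    ref = list(pair.ref_row)
    asm = list(pair.asm_row)
    changed = True
    while changed:
        changed = False
        for gap_row, base_row in ((ref, asm), (asm, ref)):
            for a, b in _gap_runs(gap_row):
                while (
                    a > 0
                    and gap_row[a - 1] != GAP
                    and base_row[a - 1] != GAP
                    and base_row[a - 1] == base_row[b - 1]
                ):
                    gap_row[a - 1], gap_row[b - 1] = gap_row[b - 1], gap_row[a - 1]
                    a -= 1
                    b -= 1
                    changed = True
    return AlignedPair("".join(ref), "".join(asm), pair.score)


def write_alignment_fasta(pair: AlignedPair, path, ref_id="reference",
                          asm_id="assembly", wrap: int = 70) -> None:
    """Dump the two gapped rows as a 2-record FASTA for inspection."""
    with open(path, "w") as handle:
        for name, row in ((ref_id, pair.ref_row), (asm_id, pair.asm_row)):
            handle.write(f">{name}\n")
            for i in range(0, len(row), wrap):
                handle.write(row[i : i + wrap] + "\n")
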