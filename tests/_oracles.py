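"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive and kept free of the implementation
paths it validates: plain-Python dynamic programs, exhaustive enumeration,
and column-by-column scans.
"""

from __future__ import annotations

import itertools
from typing import List, Tuple

NEG = float("-inf")


def affine_score_bruteforce(
    a: str, b: str, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_ext=-2.0
) -> float:
    """Full-table three-state affine DP, score only (no numba, no tricks)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_ext
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_ext,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_ext,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def all_optimal_alignments(
    a: str, b: str, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_ext=-2.0,
    cap: int = 5000,
) -> List[Tuple[str, str]]:
    """Enumerate every optimal-score global alignment of two short strings."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_ext
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_ext,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_ext,
            )
    best = max(M[n][m], X[n][m], Y[n][m])
    results: List[Tuple[str, str]] = []

    def walk(i, j, state, ra, rb):
        if len(results) >= cap:
            return
        if i == 0 and j == 0:
            if state == "M":
                results.append(("".join(reversed(ra)), "".join(reversed(rb))))
            return
        if state == "M":
            if i == 0 or j == 0:
                return
            s = match if a[i - 1] == b[j - 1] else mismatch
            for prev, tab in (("M", M), ("X", X), ("Y", Y)):
                if tab[i - 1][j - 1] + s == M[i][j]:
                    walk(i - 1, j - 1, prev, ra + [a[i - 1]], rb + [b[j - 1]])
        elif state == "X":
            if i == 0:
                return
            for prev, tab, cost in (
                ("M", M, gap_open), ("X", X, gap_ext), ("Y", Y, gap_open)
            ):
                if tab[i - 1][j] + cost == X[i][j]:
                    walk(i - 1, j, prev, ra + [a[i - 1]], rb + ["-"])
        else:
            if j == 0:
                return
            for prev, tab, cost in (
                ("M", M, gap_open), ("X", X, gap_open), ("Y", Y, gap_ext)
            ):
                if tab[i][j - 1] + cost == Y[i][j]:
                    walk(i, j - 1, prev, ra + ["-"], rb + [b[j - 1]])

    for state, tab in (("M", M), ("X", X), ("Y", Y)):
        if tab[n][m] == best:
            walk(n, m, state, [], [])
    return sorted(set(results))


def p_distance_column_scan(ref_row: str, asm_row: str) -> float:
    """Count differing sites among columns with two real, unambiguous bases."""
    comparable = differing = 0
    for r, s in zip(ref_row, asm_row):
        if r in "ACGT" and s in "ACGT":
            comparable += 1
            if r != s:
                differing += 1
    return differing / comparable


def homopolymer_site_fraction(seq: str) -> float:
    """Fraction of sites inside identical-base runs of length >= 2."""
    inside = 0
    for _, group in itertools.groupby(seq):
        run = sum(1 for _ in group)
        if run >= 2:
            inside += run
    return inside / len(seq)


def count_stops_frame0(seq: str, stops=("TAA", "TAG", "AGA", "AGG")) -> int:
    """Stop codons in frame 0, excluding the final complete codon."""
    n_codons = len(seq) // 3
    return sum(
        1
        for k in range(max(0, n_codons - 1))
        if seq[3 * k : 3 * k + 3] in stops
    )


def mean_sd_two_pass(values):
    """Two-pass mean and sample standard deviation."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var ** 0.5


def best_rotation_by_edit_distance(
    assembly: str, reference: str, window: int = 200
):
    """Exhaustive rotation oracle: minimize edit distance of the leading
    window against the reference's leading window; smallest offset wins."""
    import edlib

    target = reference[:window]
    doubled = assembly + assembly[:window]
    best_r, best_d = 0, None
    for r in range(len(assembly)):
        d = edlib.align(doubled[r : r + window], target, task="distance")[
            "editDistance"
        ]
        if best_d is None or d < best_d:
            best_r, best_d = r, d
    return best_r


def equivalent_gap_placements(ref_row: str, asm_row: str, cap: int = 2000):
    """Closure of an alignment under content-preserving gap slides.

    A gap run may move one column left or right when the displaced base in
    the opposite row is identical at both ends of the run, so neither
    sequence nor any column's match status changes. Breadth-first closure.
    """
    seen = {(ref_row, asm_row)}
    queue = [(ref_row, asm_row)]
    while queue and len(seen) < cap:
        r, s = queue.pop()
        for flip in (False, True):
            gap_row = list(s if flip else r)
            base_row = list(r if flip else s)
            n = len(gap_row)
            i = 0
            while i < n:
                if gap_row[i] != "-":
                    i += 1
                    continue
                j = i
                while j < n and gap_row[j] == "-":
                    j += 1
                moves = []
                if (
                    i > 0
                    and gap_row[i - 1] != "-"
                    and base_row[i - 1] != "-"
                    and base_row[i - 1] == base_row[j - 1]
                ):
                    moves.append((i - 1, j - 1))
                if (
                    j < n
                    and gap_row[j] != "-"
                    and base_row[j] != "-"
                    and base_row[j] == base_row[i]
                ):
                    moves.append((j, i))
                for src, dst in moves:
                    new = gap_row.copy()
                    new[src], new[dst] = new[dst], new[src]
                    cand = (
                        ("".join(base_row), "".join(new))
                        if flip
                        else ("".join(new), "".join(base_row))
                    )
                    if cand not in seen:
                        seen.add(cand)
                        queue.append(cand)
                i = j
    return sorted(seen)
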