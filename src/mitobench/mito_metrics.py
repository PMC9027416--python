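"""Per-assembly accuracy metrics and cross-assembly aggregate statistics.

Identity is measured as the uncorrected p-distance: the proportion of
differing sites among comparable alignment columns. Under the default
pairwise-deletion convention a column is comparable when both rows carry a
non-gap, non-N base, so a comparison whose only discordances are indels has
p-distance 0; the alternative convention, counting gap columns as
differences, sits behind a switch because published per-assembly values
cannot adjudicate between the two without the original alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .aligner import GAP, AlignedPair
from .circular_norm import NormalizationResult
from .error_taxonomy import EXTENSION_CATEGORIES, ErrorProfile

__all__ = [
    "AssemblyReport",
    "AggregateStats",
    "p_distance",
    "summarize",
    "aggregate",
    "REPORT_COLUMNS",
]

GAP_CONVENTIONS = ("pairwise-deletion", "gaps-as-difference")

REPORT_COLUMNS = (
    "assembly",
    "contigs",
    "length",
    "coverage",
    "p_dist",
    "errors",
    "orientation",
    "rotation_offset",
    "disrupted_genes",
)


def p_distance(pair: AlignedPair, gap_convention: str = "pairwise-deletion") -> float:
    """Uncorrected proportion of differing sites between the two rows.

    Pairwise deletion (default): columns with a gap or an N in either row
    are excluded; identical sequences give exactly 0.0. With
    ``gaps-as-difference``, gap columns are kept and counted as differing
    sites (N columns remain excluded). Raises on zero comparable columns.
    """
    if gap_convention not in GAP_CONVENTIONS:
        raise ValueError(f"unknown gap convention {gap_convention!r}")
    comparable = 0
    diffs = 0
    for r, a in zip(pair.ref_row, pair.asm_row):
        if "N" in (r, a):
            continue
        if r == GAP or a == GAP:
            if gap_convention == "gaps-as-difference":
                comparable += 1
                diffs += 1
            continue
        comparable += 1
        if r != a:
            diffs += 1
    if comparable == 0:
        raise ValueError("degenerate alignment: zero comparable columns")
    return diffs / comparable


@dataclass
class AssemblyReport:
    """One benchmark row: identity, length, error profile, provenance."""

    name: str
    circular: bool
    length: int
    p_dist: float
    profile: ErrorProfile
    orientation: str
    rotation_offset: int
    coverage_meta: Optional[float] = None
    disrupted_genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.p_dist < 0:
            raise ValueError("p_dist must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def total_errors(self) -> int:
        return self.profile.total

    @property
    def outside_taxonomy_errors(self) -> int:
        return sum(self.profile[c] for c in EXTENSION_CATEGORIES)

    def to_tsv_row(self) -> str:
        cov = "" if self.coverage_meta is None else f"{self.coverage_meta:g}x"
        return "\t".join(
            [
                self.name,
                "circular" if self.circular else "linear",
                str(self.length),
                cov,
                f"{self.p_dist:.9f}",
                str(self.total_errors),
                self.orientation,
                str(self.rotation_offset),
                ",".join(self.disrupted_genes),
            ]
        )

    def to_dict(self) -> dict:
        return {
            "assembly": self.name,
            "contigs": "circular" if self.circular else "linear",
            "length": self.length,
            "coverage": self.coverage_meta,
            "p_dist": self.p_dist,
            "errors": self.total_errors,
            "orientation": self.orientation,
            "rotation_offset": self.rotation_offset,
            "disrupted_genes": list(self.disrupted_genes),
            "profile": self.profile.to_dict(),
        }


def summarize(
    name: str,
    norm: NormalizationResult,
    pair: AlignedPair,
    profile: ErrorProfile,
    gap_convention: str = "pairwise-deletion",
) -> AssemblyReport:
    """Assemble one report row from the stages of a single comparison."""
    assembly = norm.sequence
    if pair.assembly_seq != assembly.seq:
        raise ValueError(
            "alignment and normalization result disagree on the assembly "
            "sequence; inputs must come from the same comparison"
        )
    return AssemblyReport(
        name=name,
        circular=assembly.is_circular,
        length=len(assembly),
        p_dist=p_distance(pair, gap_convention=gap_convention),
        profile=profile,
        orientation=norm.orientation,
        rotation_offset=norm.rotation_offset,
        coverage_meta=assembly.coverage_meta,
    )


@dataclass(frozen=True)
class AggregateStats:
    """Mean / sample SD / range of error totals across assemblies."""

    n: int
    mean_errors: float
    sd_errors: float
    min_errors: int
    max_errors: int

    def rounded(self, ndigits: int = 2) -> "AggregateStats":
        """Presentation copy with mean and SD rounded."""
        return AggregateStats(
            n=self.n,
            mean_errors=round(self.mean_errors, ndigits),
            sd_errors=round(self.sd_errors, ndigits),
            min_errors=self.min_errors,
            max_errors=self.max_errors,
        )


def aggregate(totals: Sequence[int]) -> AggregateStats:
    """Arithmetic mean, sample SD (n-1 denominator), min and max.

    Rounding happens only at presentation time (see
    :meth:`AggregateStats.rounded`).
    """
    n = len(totals)
    if n < 2:
        raise ValueError("aggregate statistics require at least 2 totals")
    mean = sum(totals) / n
    var = sum((t - mean) ** 2 for t in totals) / (n - 1)
    return AggregateStats(
        n=n,
        mean_errors=mean,
        sd_errors=math.sqrt(var),
        min_errors=min(totals),
        max_errors=max(totals),
    )
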