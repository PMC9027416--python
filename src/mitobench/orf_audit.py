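"""Open-reading-frame audit of protein-coding genes in an assembly.

Frameshifting indels in a nanopore assembly typically surface as internal
stop codons once the gene is translated, which is what makes annotation
servers stumble on such assemblies. Rather than re-annotating each
assembly, reference gene coordinates are projected through the alignment
onto assembly coordinates — deterministic and offline — and each projected
protein-coding gene is translated under the vertebrate mitochondrial code
(NCBI table 2; stop codons TAA, TAG, AGA, AGG). A gene is disrupted when
it contains an internal stop or its projected length shifts the frame; it
counts as undetected when its projection shrinks below half the reference
gene (emulating annotation tools missing heavily damaged short genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from Bio.Seq import Seq

from .aligner import GAP, AlignedPair
from .circular_norm import reverse_complement
from .seq_io import CircularSequence, GeneAnnotation

__all__ = [
    "VERTEBRATE_MITO_STOPS",
    "GeneAudit",
    "project_annotations",
    "audit_orfs",
]

#: Stop codons of the vertebrate mitochondrial genetic code (NCBI table 2).
VERTEBRATE_MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

#: Projected-length fraction below which a gene counts as missed.
DETECTION_FRACTION = 0.5


@dataclass(frozen=True)
class GeneAudit:
    """ORF status of one protein-coding gene in one assembly."""

    gene: str
    projected_interval: Tuple[int, int]
    frame_shift: int  # signed net indel length within the gene, bp
    internal_stops: int
    disrupted: bool
    detected: bool

    def __post_init__(self) -> None:
        if self.internal_stops < 0:
            raise ValueError("internal_stops must be >= 0")
        if self.disrupted != (
            self.internal_stops > 0 or self.frame_shift % 3 != 0
        ):
            raise ValueError(
                "disrupted must equal (internal_stops > 0 or "
                "frame_shift % 3 != 0)"
            )

    def to_tsv_row(self) -> str:
        s, e = self.projected_interval
        interval = f"{s + 1}-{e}" if e > s else "-"
        return "\t".join(
            [
                self.gene,
                "yes" if self.detected else "no",
                interval,
                f"{self.frame_shift:+d}",
                str(self.internal_stops),
                "yes" if self.disrupted else "no",
            ]
        )


def project_annotations(
    pair: AlignedPair, annotations: Sequence[GeneAnnotation]
) -> List[Tuple[str, Tuple[int, int]]]:
    """Map reference gene intervals through the alignment onto the assembly.

    Insertions strictly inside a gene extend its projection; insertions at
    either boundary fall outside it. Deletions shrink the projection; a
    fully deleted gene maps to an empty interval.
    """
    ref_len = len(pair.reference_seq)
    for a in annotations:
        if a.end > ref_len:
            raise ValueError(
                f"annotation {a.gene} ([{a.start}, {a.end})) lies outside "
                f"the reference ({ref_len} bp)"
            )
    # asm_before[i]: assembly bases in columns strictly before the column
    # holding reference base i; asm_through[i]: through that column.
    asm_before = [0] * (ref_len + 1)
    asm_through = [0] * ref_len
    asm_count = 0
    ref_i = 0
    for r, s in zip(pair.ref_row, pair.asm_row):
        if r != GAP:
            asm_before[ref_i] = asm_count
            if s != GAP:
                asm_count += 1
            asm_through[ref_i] = asm_count
            ref_i += 1
        elif s != GAP:
            asm_count += 1
    asm_before[ref_len] = asm_count

    out = []
    for a in annotations:
        start = asm_before[a.start]
        end = asm_through[a.end - 1]
        if end < start:  # gene fully deleted
            end = start
        out.append((a.gene, (start, end)))
    return out


def _count_internal_stops(gene_seq: str) -> int:
    """Stop codons strictly before the final (possibly terminal) codon."""
    n_codons = len(gene_seq) // 3  # incomplete terminal codon ignored
    if n_codons <= 1:
        return 0
    protein = str(Seq(gene_seq[: n_codons * 3]).translate(table=2))
    return protein[:-1].count("*")


def audit_orfs(
    assembly: CircularSequence,
    projections: Sequence[Tuple[str, Tuple[int, int]]],
    annotations: Sequence[GeneAnnotation],
) -> List[GeneAudit]:
    """Translate each projected protein-coding gene and record ORF status.

    Minus-strand genes are reverse-complemented before translation;
    translation runs in frame 0 of the projected interval.
    """
    by_gene: Dict[str, GeneAnnotation] = {a.gene: a for a in annotations}
    audits = []
    for gene, (start, end) in projections:
        ann = by_gene[gene]
        if ann.kind != "PCG":
            continue
        proj_len = end - start
        frame_shift = proj_len - ann.length
        detected = proj_len >= 3 and proj_len >= DETECTION_FRACTION * ann.length
        gene_seq = assembly.seq[start:end]
        if ann.strand == "-":
            gene_seq = reverse_complement(gene_seq)
        internal_stops = _count_internal_stops(gene_seq) if proj_len >= 3 else 0
        audits.append(
            GeneAudit(
                gene=gene,
                projected_interval=(start, end),
                frame_shift=frame_shift,
                internal_stops=internal_stops,
                disrupted=internal_stops > 0 or frame_shift % 3 != 0,
                detected=detected,
            )
        )
    return audits
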