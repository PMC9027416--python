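"""Reading and writing the formats the benchmarking pipeline touches.

Sequences travel as :class:`CircularSequence` records (FASTA on disk, with a
``circular=true`` header token marking topology), gene coordinates as
BED-like six-column TSV tracks, and the published per-assembly accuracy
metrics as a packaged TSV fixture.

Coordinates are 0-based half-open everywhere inside the package; rendered
reports switch to the 1-based closed convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "ALPHABET",
    "CircularSequence",
    "GeneAnnotation",
    "Table1Fixture",
    "REFERENCE_LENGTH_BP",
    "PRIOR_ASSEMBLY_LENGTH_BP",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "load_table1_fixture",
]

#: Alphabet accepted in stored sequences (ambiguity collapsed to N on input).
ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide one-letter codes accepted on input.
_IUPAC = frozenset("ACGTUNRYSWKMBDHV")

#: Length of the short-read gold-standard reference mitogenome (bp).
REFERENCE_LENGTH_BP = 16705

#: Length of the earlier, non-specialized short-read assembly (bp); carries
#: an artifactual insertion relative to the gold standard.
PRIOR_ASSEMBLY_LENGTH_BP = 17639

_GENE_KINDS = ("PCG", "tRNA", "rRNA", "CR")


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide sequence with an explicit circular/linear topology flag.

    Parameters
    ----------
    id:
        Record label (first whitespace-delimited FASTA header token).
    seq:
        Uppercase sequence over ``{A, C, G, T, N}``.
    topology:
        ``"circular"`` or ``"linear"``.
    coverage_meta:
        Optional x-fold coverage passed through from assembler logs; never
        computed here (that would require read mapping).
    """

    id: str
    seq: str
    topology: str = "linear"
    coverage_meta: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.coverage_meta is not None and not self.coverage_meta > 0:
            raise ValueError("coverage_meta must be positive when present")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def with_seq(self, seq: str, id: Optional[str] = None) -> "CircularSequence":
        """Copy of this record with a different sequence (and optional id)."""
        return replace(self, seq=seq, id=self.id if id is None else id)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval on the reference, 0-based half-open."""

    gene: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")
        if self.kind not in _GENE_KINDS:
            raise ValueError(f"{self.gene}: unknown kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene}: invalid interval [{self.start}, {self.end})"
            )
        if self.kind == "PCG" and self.length < 6:
            raise ValueError(f"{self.gene}: PCG shorter than 6 bp")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Table1Fixture:
    """The published per-assembly accuracy metrics (18 long-read rows)."""

    rows: tuple  # of (name, length_bp, p_dist, errors)

    def __post_init__(self) -> None:
        if len(self.rows) != 18:
            raise ValueError("fixture must hold exactly 18 long-read rows")
        for name, length, p_dist, errors in self.rows:
            if errors < 0 or not (0.0 <= p_dist <= 1.0) or length <= 0:
                raise ValueError(f"invalid fixture row {name!r}")

    @property
    def names(self) -> List[str]:
        return [r[0] for r in self.rows]

    @property
    def error_totals(self) -> List[int]:
        return [r[3] for r in self.rows]

    def row(self, name: str):
        for r in self.rows:
            if r[0] == name:
                return r
        raise KeyError(name)


def _clean_sequence(raw: str, record_id: str) -> str:
    """Uppercase, map U->T, collapse non-ACGT IUPAC ambiguity to N."""
    seq = raw.upper().replace("U", "T")
    out = []
    for pos, ch in enumerate(seq):
        if ch in ALPHABET:
            out.append(ch)
        elif ch in _IUPAC:
            out.append("N")
        else:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {ch!r} "
                f"at position {pos}"
            )
    return "".join(out)


def _parse_header_meta(description: str) -> dict:
    meta = {}
    if re.search(r"\bcircular=true\b", description, flags=re.IGNORECASE):
        meta["topology"] = "circular"
    m = re.search(r"\bcoverage=([0-9.]+)", description)
    if m:
        meta["coverage_meta"] = float(m.group(1))
    return meta


def read_fasta(path: Union[str, Path]) -> List[CircularSequence]:
    """Read a (multi-)FASTA file into :class:`CircularSequence` records.

    Topology defaults to linear unless the header carries ``circular=true``;
    an optional ``coverage=<x>`` token is passed through as metadata.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        meta = _parse_header_meta(rec.description)
        out.append(
            CircularSequence(
                id=rec.id,
                seq=_clean_sequence(str(rec.seq), rec.id),
                topology=meta.get("topology", "linear"),
                coverage_meta=meta.get("coverage_meta"),
            )
        )
    return out


def write_fasta(
    records: Iterable[CircularSequence], path: Union[str, Path], wrap: int = 70
) -> None:
    """Write records to FASTA, encoding topology/coverage as header tokens."""
    path = Path(path)
    seq_records = []
    for rec in records:
        tokens = []
        if rec.is_circular:
            tokens.append("circular=true")
        if rec.coverage_meta is not None:
            tokens.append(f"coverage={rec.coverage_meta:g}")
        seq_records.append(
            SeqRecord(Seq(rec.seq), id=rec.id, description=" ".join(tokens))
        )
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(seq_records)


def read_annotations(
    path: Union[str, Path], ref_length: int
) -> List[GeneAnnotation]:
    """Read a BED-like gene track: chrom, start, end, gene, kind, strand.

    Intervals are validated against ``ref_length``; a track is rejected if
    any interval would wrap the circular origin (rotate the reference so
    that no annotation wraps before exporting the track).
    """
    path = Path(path)
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            _, start_s, end_s, gene, kind, strand = parts
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start for {gene}")
            if end > ref_length:
                raise ValueError(
                    f"{path}:{lineno}: {gene} ends at {end}, beyond the "
                    f"reference length {ref_length}; if the gene spans the "
                    "circular origin, rotate the reference so no annotation "
                    "wraps"
                )
            out.append(GeneAnnotation(gene, start, end, strand, kind))
    return sorted(out, key=lambda a: a.start)


def write_annotations(
    annotations: Iterable[GeneAnnotation], path: Union[str, Path],
    chrom: str = "ref",
) -> None:
    with open(path, "w") as handle:
        for a in annotations:
            handle.write(
                f"{chrom}\t{a.start}\t{a.end}\t{a.gene}\t{a.kind}\t{a.strand}\n"
            )


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged per-assembly accuracy metrics (18 long-read rows)."""
    text = (
        resources.files("mitobench") / "data" / "table1_metrics.tsv"
    ).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, _circ, length, _cov, p_dist, errors = line.split("\t")
        rows.append((name, int(length), float(p_dist), int(errors)))
    return Table1Fixture(rows=tuple(rows))
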