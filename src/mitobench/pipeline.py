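"""End-to-end comparison of candidate assemblies against the reference.

One call of :func:`compare_assembly` runs the full benchmark for a single
candidate: circular normalization (strand + rotation), optimal global
alignment, canonical gap placement, error extraction and classification,
p-distance, and — when a gene track is supplied — the ORF audit. The
compare path contains no randomness; identical inputs and configuration
produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .aligner import ScoringScheme, global_align, normalize_gaps
from .circular_norm import normalize
from .error_taxonomy import (
    EXTENSION_CATEGORIES,
    ErrorEvent,
    classify_events,
    extract_events,
    profile,
)
from .mito_metrics import (
    AggregateStats,
    AssemblyReport,
    REPORT_COLUMNS,
    aggregate,
    p_distance,
    summarize,
)
from .orf_audit import GeneAudit, audit_orfs, project_annotations
from .seq_io import CircularSequence, GeneAnnotation

__all__ = ["RunConfig", "ComparisonResult", "compare_assembly",
           "render_report", "render_events", "render_audits"]


@dataclass(frozen=True)
class RunConfig:
    """All switches of the compare path, with module-owned defaults."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    gap_convention: str = "pairwise-deletion"
    hp_criterion: str = "reference-run"
    count_ambiguous: bool = False
    word_size: int = 15
    anchor_len: int = 31
    log_level: str = "INFO"

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match, mismatch=self.mismatch,
            gap_open=self.gap_open, gap_extend=self.gap_extend,
        )

    def fingerprint(self) -> str:
        """Short stable hash of the configuration, logged with reports."""
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self)},
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_file(self, path) -> None:
        with open(path, "w") as handle:
            for f in fields(self):
                handle.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int, "str": str,
                 "bool": lambda v: v in ("True", "true", "1")}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = line.split("=", 1)
                key = key.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                kwargs[key] = casts[types[key]](value.strip())
        return cls(**kwargs)


@dataclass
class ComparisonResult:
    """Everything one assembly-vs-reference comparison produced."""

    report: AssemblyReport
    events: List[ErrorEvent]
    audits: List[GeneAudit]


def compare_assembly(
    reference: CircularSequence,
    assembly: CircularSequence,
    annotations: Optional[Sequence[GeneAnnotation]] = None,
    config: RunConfig = RunConfig(),
) -> ComparisonResult:
    """Benchmark one candidate assembly against the gold standard."""
    norm = normalize(
        assembly, reference, k=config.word_size, anchor_len=config.anchor_len
    )
    pair = normalize_gaps(
        global_align(reference, norm.sequence, scoring=config.scoring)
    )
    events = classify_events(
        extract_events(pair, count_ambiguous=config.count_ambiguous),
        reference,
        hp_criterion=config.hp_criterion,
    )
    report = summarize(
        assembly.id, norm, pair, profile(events),
        gap_convention=config.gap_convention,
    )
    audits: List[GeneAudit] = []
    if annotations:
        projections = project_annotations(pair, annotations)
        audits = audit_orfs(norm.sequence, projections, annotations)
        report.disrupted_genes = [a.gene for a in audits if a.disrupted]
    return ComparisonResult(report=report, events=events, audits=audits)


def render_report(
    reports: Sequence[AssemblyReport],
    config: RunConfig,
    stats: Optional[AggregateStats] = None,
) -> str:
    """Tab-separated benchmark table with an aggregate footer."""
    lines = [f"# mitobench report (config {config.fingerprint()})"]
    lines.append("\t".join(REPORT_COLUMNS))
    for rep in reports:
        lines.append(rep.to_tsv_row())
    if stats is not None:
        r = stats.rounded()
        lines.append(
            f"# aggregate: n={r.n} mean_errors={r.mean_errors:.2f} "
            f"sd_errors={r.sd_errors:.2f} range={r.min_errors}-{r.max_errors}"
        )
    return "\n".join(lines) + "\n"


def render_events(events: Sequence[ErrorEvent]) -> str:
    """Per-event TSV (1-based reference coordinates in output)."""
    lines = ["category\tlength\tref_pos\tbases\thp_nucleotide\thp_run_len\tin_taxonomy"]
    for e in events:
        lines.append(
            "\t".join(
                [
                    e.category.value if e.category else "unclassified",
                    str(e.length),
                    str(e.ref_pos + 1),
                    e.bases,
                    e.hp_nucleotide or "",
                    "" if e.hp_run_len is None else str(e.hp_run_len),
                    "no" if e.category in EXTENSION_CATEGORIES else "yes",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def render_audits(audits: Sequence[GeneAudit]) -> str:
    lines = ["gene\tdetected\tinterval\tframe_shift\tinternal_stops\tdisrupted"]
    for a in audits:
        lines.append(a.to_tsv_row())
    return "\n".join(lines) + "\n"
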