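"""Annotation projection and the protein-coding gene ORF audit."""

import random

import pytest

from mitobench.aligner import AlignedPair, global_align, normalize_gaps
from mitobench.circular_norm import reverse_complement
from mitobench.orf_audit import (
    VERTEBRATE_MITO_STOPS,
    audit_orfs,
    project_annotations,
)
from mitobench.pipeline import compare_assembly
from mitobench.seq_io import CircularSequence, GeneAnnotation

from _oracles import count_stops_frame0


def _identity_pair(seq):
    return AlignedPair(seq, seq, 0.0)


def _column_walk_projection(pair, start, end):
    """Naive per-column oracle for one interval."""
    ref_i = asm_i = 0
    out_start = out_end = None
    for r, a in zip(pair.ref_row, pair.asm_row):
        if ref_i == start and out_start is None and r != "-":
            out_start = asm_i
        if r != "-":
            if ref_i == end - 1:
                out_end = asm_i + (0 if a == "-" else 1)
            ref_i += 1
        if a != "-":
            asm_i += 1
    return out_start, out_end


class TestProjectAnnotations:
    def test_identity_projection(self):
        pair = _identity_pair("ACGTACGTAC")
        ann = [GeneAnnotation("g", 0, 9, "+", "PCG")]
        assert project_annotations(pair, ann) == [("g", (0, 9))]

    def test_insertion_inside_gene_extends_projection(self):
        pair = AlignedPair("ACGT-CGTAC", "ACGTTCGTAC", 0.0)
        ann = [GeneAnnotation("g", 0, 9, "+", "PCG")]
        assert project_annotations(pair, ann) == [("g", (0, 10))]

    def test_insertion_at_boundary_excluded(self):
        pair = AlignedPair("-ACGTACGTA", "TACGTACGTA", 0.0)
        ann = [GeneAnnotation("g", 0, 9, "+", "PCG")]
        assert project_annotations(pair, ann) == [("g", (1, 10))]

    def test_deletion_shrinks_projection(self):
        pair = AlignedPair("ACGTACGTA", "ACG-ACGTA", 0.0)
        ann = [GeneAnnotation("g", 0, 9, "+", "PCG")]
        assert project_annotations(pair, ann) == [("g", (0, 8))]

    def test_fully_deleted_gene_maps_to_empty_interval(self):
        pair = AlignedPair("ACGTACGTACGT", "ACG------GT-", 0.0)
        ann = [GeneAnnotation("g", 3, 9, "+", "PCG")]
        (_, (s, e)) = project_annotations(pair, ann)[0]
        assert s == e == 3

    def test_matches_column_walk_oracle_on_random_indels(self):
        rng = random.Random(8)
        for _ in range(40):
            n = rng.randint(30, 60)
            ref = "".join(rng.choice("ACGT") for _ in range(n))
            # mutate with a few scattered indels
            asm = list(ref)
            for _ in range(rng.randint(1, 4)):
                p = rng.randrange(5, n - 5)
                if rng.random() < 0.5:
                    asm.insert(p, rng.choice("ACGT"))
                elif asm[p] is not None:
                    asm[p] = ""
            asm = "".join(c for c in asm if c)
            pair = normalize_gaps(global_align(ref, asm))
            start = rng.randrange(0, n - 10)
            end = rng.randrange(start + 6, n)
            ann = [GeneAnnotation("g", start, end, "+", "PCG")]
            (_, got) = project_annotations(pair, ann)[0]
            assert got == _column_walk_projection(pair, start, end)

    def test_annotation_outside_reference_rejected(self):
        pair = _identity_pair("ACGTACGTA")
        with pytest.raises(ValueError, match="outside"):
            project_annotations(
                pair, [GeneAnnotation("g", 0, 50, "+", "PCG")]
            )


class TestAuditOrfs:
    def test_stop_codons_match_translation_table_2(self):
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        assert VERTEBRATE_MITO_STOPS == frozenset(
            unambiguous_dna_by_id[2].stop_codons
        )

    def _audit_single(self, gene_seq, strand="+"):
        seq = gene_seq if strand == "+" else reverse_complement(gene_seq)
        assembly = CircularSequence("a", seq, "linear")
        ann = [GeneAnnotation("g", 0, len(seq), strand, "PCG")]
        pair = _identity_pair(seq)
        (audit,) = audit_orfs(assembly, project_annotations(pair, ann), ann)
        return audit

    def test_clean_orf(self):
        audit = self._audit_single("ATGAAATAA")
        assert (audit.internal_stops, audit.disrupted) == (0, False)
        assert audit.detected

    def test_aga_is_a_stop_in_the_vertebrate_mito_code(self):
        audit = self._audit_single("ATGAGAAAATAA")
        assert audit.internal_stops == 1
        assert audit.disrupted

    def test_minus_strand_gene_translated_on_its_strand(self):
        audit = self._audit_single("ATGAGAAAATAA", strand="-")
        assert audit.internal_stops == 1

    def test_incomplete_terminal_codon_ignored(self):
        audit = self._audit_single("ATGAAATAAGG")  # 2 trailing bases
        assert (audit.internal_stops, audit.disrupted) == (0, False)

    def test_zero_errors_audit_clean(self, small_self_comparison):
        audits = small_self_comparison.audits
        assert audits, "small genome must carry protein-coding genes"
        assert all(a.detected and not a.disrupted for a in audits)
        assert all(a.internal_stops == 0 for a in audits)

    def test_single_frameshifting_indel_disrupts_gene(self, small_genome):
        """A 1-bp insertion inside a protein-coding gene shifts the frame
        and the audit flags exactly that gene; the stop count agrees with
        an independent frame-0 codon scan."""
        ref, track = small_genome
        pcgs = [a for a in track if a.kind == "PCG"]
        target = pcgs[2]
        pos = target.start + 10
        asm_seq = ref.seq[:pos] + "A" + ref.seq[pos:]
        assembly = CircularSequence("mut", asm_seq, "circular")
        result = compare_assembly(ref, assembly, track)
        by_gene = {a.gene: a for a in result.audits}
        audit = by_gene[target.gene]
        assert audit.frame_shift % 3 == 1
        assert audit.disrupted
        s, e = audit.projected_interval
        gene_seq = asm_seq[s:e]
        if target.strand == "-":
            gene_seq = reverse_complement(gene_seq)
        assert audit.internal_stops == count_stops_frame0(gene_seq)
        for other in pcgs:
            if other.gene != target.gene:
                assert not by_gene[other.gene].disrupted

    def test_disruption_monotone_in_injected_frameshifts(self, small_genome):
        """More intra-genic frameshifting indels never un-disrupt genes."""
        ref, track = small_genome
        pcgs = [a for a in track if a.kind == "PCG"]
        disrupted_counts = []
        for k in (0, 1, 3, len(pcgs)):
            asm = ref.seq
            for target in sorted(pcgs, key=lambda a: -a.start)[: k]:
                pos = target.start + 12
                asm = asm[:pos] + "A" + asm[pos:]
            result = compare_assembly(
                ref, CircularSequence("m", asm, "circular"), track
            )
            disrupted_counts.append(len(result.report.disrupted_genes))
        assert disrupted_counts == sorted(disrupted_counts)
        assert disrupted_counts[0] == 0
        assert disrupted_counts[-1] == len(pcgs)

    def test_short_projection_counts_as_missed(self):
        assembly = CircularSequence("a", "ATGAAATAA", "linear")
        ann = [GeneAnnotation("g", 0, 9, "+", "PCG")]
        # projection collapsed to 2 bp: gene effectively absent
        (audit,) = audit_orfs(assembly, [("g", (0, 2))], ann)
        assert not audit.detected
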