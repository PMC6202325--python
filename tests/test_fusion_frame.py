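"""Chimeric-transcript construction and frame classification.

The brute-force oracle used throughout this file splices transcript
sequences with Biopython directly (independently of the package's
coordinate machinery), translates the fused cDNA, and decides "in frame"
by recovering the 3' partner's native protein suffix without a premature
stop.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from dgcfusion.annotation_io import GenomeSequence, TranscriptModel
from dgcfusion.fusion_frame import (
    UPSTREAM_OF_CDS,
    BreakpointPair,
    FrameStatus,
    FusionError,
    annotate_candidate,
    build_fusion_transcript,
    classify_frame,
    infer_mrna_breakpoint,
    retained_domains,
    retained_spans,
    translate_fusion,
)
from dgcfusion.annotation_io import DomainRecord
from dgcfusion.simulate import SimulationConfig, simulate_reference


# ---------------------------------------------------------------------------
# independent oracle helpers


def oracle_transcript_seq(genome: GenomeSequence, model: TranscriptModel) -> str:
    seq = "".join(genome.contigs[model.contig][s - 1 : e] for s, e in model.exons)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def oracle_in_frame(genome, m5, t5, m3, t3) -> bool:
    """Brute force: splice, fuse, translate, compare 3' suffix."""
    s5 = oracle_transcript_seq(genome, m5)
    s3 = oracle_transcript_seq(genome, m3)
    fused = s5[:t5] + s3[t3 - 1 :]
    coding = fused[m5.cds_start - 1 :]
    prot = str(Seq(coding[: len(coding) - len(coding) % 3]).translate(to_stop=True))
    native3 = str(Seq(s3[m3.cds_start - 1 : m3.cds_end]).translate(to_stop=True))
    # number of complete native 3' codons downstream of the breakpoint
    d = t3 - m3.cds_start + 1
    first_full = 1 if d <= 1 else (d - 1) // 3 + (1 if (d - 1) % 3 == 0 else 2)
    retained = native3[first_full - 1 :]
    if not retained:
        return False
    return prot.endswith(retained)


# ---------------------------------------------------------------------------


class TestInferMrnaBreakpoint:
    def test_intron4_minus_strand_maps_to_exon4_start(self, anxa2_like):
        # DNA-level break in intron 4 of a minus-strand gene splices to the
        # last base of exon 4 in transcript orientation = genomic exon start.
        assert infer_mrna_breakpoint(anxa2_like, 60_656_550, "5") == 60_656_628

    def test_intron_side3_maps_to_next_exon(self, anxa2_like):
        # 3' side keeps the following exon: first base of tx exon 5 is the
        # genomic END of the lowest-coordinate exon on the minus strand.
        assert infer_mrna_breakpoint(anxa2_like, 60_656_550, "3") == 60_656_499

    def test_exonic_position_passes_through(self, cldn18_like):
        # cryptic junction inside exon 5: used as-is
        assert infer_mrna_breakpoint(cldn18_like, 137_749_947, "5") == 137_749_947

    def test_exon_last_base_is_fixed_point(self, two_exon_plus):
        assert infer_mrna_breakpoint(two_exon_plus, 200, "5") == 200

    def test_idempotent_on_exonic(self, anxa2_like):
        bp = infer_mrna_breakpoint(anxa2_like, 60_656_550, "5")
        assert infer_mrna_breakpoint(anxa2_like, bp, "5") == bp

    def test_outside_span_rejected(self, two_exon_plus):
        with pytest.raises(FusionError, match="outside"):
            infer_mrna_breakpoint(two_exon_plus, 50, "5")


def _flat_gene(name, seq_len, cds_start, cds_end, start=1, strand="+", contig="c1"):
    return TranscriptModel(
        gene_id=name, gene_name=name, transcript_id=f"{name}.t1",
        contig=contig, strand=strand, exons=((start, start + seq_len - 1),),
        cds_start=cds_start, cds_end=cds_end,
    )


class TestBuildFusionTranscript:
    @pytest.fixture
    def toy(self):
        # gene A: 12 nt, CDS 1..12 = ATG GCC AAA TGA
        # gene B: 9 nt, CDS 1..9  = ATG CCC TAA
        genome = GenomeSequence({"c1": "ATGGCCAAATGA" + "ATGCCCTAA"})
        a = _flat_gene("A", 12, 1, 12)
        b = _flat_gene("B", 9, 1, 9, start=13)
        return genome, a, b

    def test_lengths_and_junction(self, toy):
        genome, a, b = toy
        product = build_fusion_transcript(a, 6, b, 16, genome)  # t5=6, t3=4
        assert len(product.cdna) == 6 + (9 - 4 + 1)
        assert product.junction == 6
        assert product.cdna == "ATGGCC" + "CCCTAA"

    def test_concatenation_identity(self, toy):
        genome, a, b = toy
        product = build_fusion_transcript(a, 9, b, 13, genome)
        assert product.cdna == "ATGGCCAAA" + "ATGCCCTAA"

    def test_minus_strand_partner_reverse_complemented(self):
        # minus-strand gene B occupies g.13..21; transcript = revcomp
        genome = GenomeSequence({"c1": "ATGGCCAAATGA" + "TTAGGGCAT"})
        a = _flat_gene("A", 12, 1, 12)
        b = _flat_gene("B", 9, 1, 9, start=13, strand="-")
        # hand reverse-complement of TTAGGGCAT is ATGCCCTAA
        product = build_fusion_transcript(a, 6, b, 21, genome)  # t3=1 at g.21
        assert product.cdna == "ATGGCC" + "ATGCCCTAA"

    def test_intronic_breakpoint_rejected(self, two_exon_plus):
        genome = GenomeSequence({"c1": "A" * 400})
        with pytest.raises(FusionError, match="infer_mrna_breakpoint"):
            build_fusion_transcript(two_exon_plus, 250, two_exon_plus, 101, genome)


class TestClassifyFrame:
    @staticmethod
    def _pair(n5_cds, d3_offset, cds5=(101, 1000), cds3=(51, 2336)):
        """Single-exon models realising the requested (n5_cds, d3_offset)."""
        m5 = _flat_gene("F5", 1200, cds5[0], cds5[1])
        m3 = _flat_gene("F3", 2500, cds3[0], cds3[1], start=2001)
        bp5 = cds5[0] + n5_cds - 1          # plus strand, single exon
        bp3 = 2000 + cds3[0] + d3_offset - 1
        return m5, bp5, m3, bp3

    def test_cldn18_arhgap26_construct_in_frame(self):
        # CDS 1-750 of the 5' partner joined to CDS base 1108 of the 3'
        # partner: 750 = 0 mod 3 and 1107 = 0 mod 3 -> native frame continues.
        m5, bp5, m3, bp3 = self._pair(750, 1108)
        call = classify_frame(m5, bp5, m3, bp3)
        assert call.status is FrameStatus.IN_FRAME
        assert (call.n5_cds, call.d3_offset) == (750, 1108)

    def test_phase_zero_minimal(self):
        m5, bp5, m3, bp3 = self._pair(3, 1)
        assert classify_frame(m5, bp5, m3, bp3).status is FrameStatus.IN_FRAME

    def test_frameshift(self):
        m5, bp5, m3, bp3 = self._pair(100, 1)
        assert classify_frame(m5, bp5, m3, bp3).status is FrameStatus.FRAMESHIFT

    def test_promoter_swap(self):
        m5 = _flat_gene("F5", 1200, 101, 1000)
        m3 = _flat_gene("F3", 2500, 51, 2336, start=2001)
        call = classify_frame(m5, 50, m3, 2010)  # t5 in 5'UTR, t3 upstream of CDS
        assert call.status is FrameStatus.PROMOTER_SWAP
        assert call.d3_offset == UPSTREAM_OF_CDS

    def test_noncoding_when_beyond_cds(self):
        m5 = _flat_gene("F5", 1200, 101, 1000)
        m3 = _flat_gene("F3", 2500, 51, 2336, start=2001)
        assert classify_frame(m5, 1100, m3, 2060).status is FrameStatus.NON_CODING
        assert classify_frame(m5, 500, m3, 2001 + 2400).status is FrameStatus.NON_CODING

    def test_noncoding_model_rejected(self, two_exon_plus):
        nc = TranscriptModel(
            gene_id="N", gene_name="N", transcript_id="N.t1", contig="c1",
            strand="+", exons=((1, 300),),
        )
        with pytest.raises(FusionError, match="coding"):
            classify_frame(nc, 100, two_exon_plus, 101)


class TestTranslateFusion:
    def test_standard_code(self):
        protein, premature, stop = translate_fusion("ATGGCCTAA", 1)
        assert protein == "MA"
        assert stop == 3

    def test_cds_start_beyond_sequence(self):
        with pytest.raises(FusionError):
            translate_fusion("ATG", 10)

    def test_premature_stop_detection(self):
        # stop at codon 2, native stop declared at position 10
        _, premature, _ = translate_fusion("ATGTAACCCTTTTAA", 1, native_stop_offset=13)
        assert premature


class TestRetainedSpans:
    @staticmethod
    def _call(n5_cds, d3_offset):
        from dgcfusion.fusion_frame import FrameCall
        return FrameCall(FrameStatus.IN_FRAME, n5_cds, d3_offset)

    def test_tacc2_like_spans(self):
        # 144 retained coding bases = 48 codons; offset 58 = 3*19 + 1 means
        # the first complete native codon is residue 20.
        aa5, aa3 = retained_spans(self._call(144, 58), 271)
        assert aa5 == (1, 48)
        assert aa3 == (20, 271)

    @pytest.mark.parametrize("d,expected_start", [(1, 1), (4, 2), (5, 3), (6, 3), (7, 3), (58, 20)])
    def test_first_complete_codon(self, d, expected_start):
        _, aa3 = retained_spans(self._call(3, d), 100)
        assert aa3[0] == expected_start

    def test_zero_5prime_span_is_empty(self):
        aa5, _ = retained_spans(self._call(0, 1), 100)
        assert aa5 is None

    def test_requires_in_frame(self):
        from dgcfusion.fusion_frame import FrameCall
        with pytest.raises(FusionError):
            retained_spans(FrameCall(FrameStatus.FRAMESHIFT, 100, 1), 100)


class TestRetainedDomains:
    DOMAINS = [
        DomainRecord("MYO9AL", "RhoGAP", 2100, 2400),
        DomainRecord("MYO9AL", "C1", 1700, 1800),
        DomainRecord("PPAPL", "PAP2", 60, 200),
        DomainRecord("ANXA2L", "Annexin", 30, 90),
    ]

    def test_rhogap_retained_inside_span(self):
        retained, truncated, labels = retained_domains(
            (1, 99), (1994, 2548), "ANXA2L", "MYO9AL", self.DOMAINS
        )
        assert ("RhoGAP", "3'") in retained
        assert "RhoGAP-domain fusion" in labels

    def test_pap2_label(self):
        _, _, labels = retained_domains((1, 48), (20, 271), "TACC2L", "PPAPL", self.DOMAINS)
        assert labels == frozenset({"PAP2-domain fusion"})

    def test_overlap_is_truncated_not_retained(self):
        retained, truncated, labels = retained_domains(
            (1, 50), None, "ANXA2L", "X", self.DOMAINS
        )
        assert retained == []
        assert ("Annexin", "5'") in truncated
        assert labels == frozenset()

    def test_empty_domain_table(self):
        retained, truncated, labels = retained_domains((1, 99), (1, 100), "A", "B", [])
        assert retained == [] and truncated == [] and labels == frozenset()

    def test_monotone_in_span(self):
        # enlarging a retained span never removes a retained domain
        small, _, _ = retained_domains(None, (2000, 2500), "X", "MYO9AL", self.DOMAINS)
        large, _, _ = retained_domains(None, (1500, 2600), "X", "MYO9AL", self.DOMAINS)
        assert set(small) <= set(large)


class TestAnnotateCandidate:
    def test_unknown_gene_named_in_error(self, sim_bundle):
        _, genome, models, domains, _, _ = sim_bundle
        pair = BreakpointPair(
            gene5="NOPE", gene3="G02", contig5="chrS", contig3="chrS",
            genomic_bp5=100, genomic_bp3=200,
        )
        with pytest.raises(FusionError, match="NOPE"):
            annotate_candidate(pair, models, domains, genome)

    def test_planted_truth_recovered(self, sim_bundle):
        _, genome, models, domains, _, truths = sim_bundle
        for truth in truths:
            ann = annotate_candidate(truth.pair, models, domains, genome)
            assert ann.frame_status.value == truth.spec.truth_frame

    def test_degenerate_pair_rejected(self):
        with pytest.raises(FusionError, match="degenerate"):
            BreakpointPair(
                gene5="A", gene3="A", contig5="c1", contig3="c1",
                genomic_bp5=100, genomic_bp3=100,
            )

    def test_in_frame_protein_length_identity(self, sim_bundle):
        # |protein| = floor(n5/3) + |aa3 span| + 1 junction residue if hybrid
        _, genome, models, domains, _, truths = sim_bundle
        for truth in truths:
            ann = annotate_candidate(truth.pair, models, domains, genome)
            if ann.frame_status is not FrameStatus.IN_FRAME:
                continue
            n_junction = 1 if ann.n5_cds % 3 != 0 else 0
            expected = ann.n5_cds // 3 + (ann.aa3_span[1] - ann.aa3_span[0] + 1) + n_junction
            assert len(ann.fusion_protein) == expected


class TestOracleEquivalence:
    def test_random_breakpoints_match_translation_oracle(self):
        """Arithmetic frame calls agree with brute-force translation on
        1,000 random coding-region breakpoint pairs."""
        config = SimulationConfig(seed=23, n_genes=8)
        genome, models, _ = simulate_reference(config)
        coding = [m for m in models.values() if m.is_coding]
        rng = np.random.default_rng(23)
        n_checked = 0
        disagreements = 0
        while n_checked < 1000:
            i, j = rng.choice(len(coding), size=2, replace=False)
            m5, m3 = coding[i], coding[j]
            t5 = int(rng.integers(m5.cds_start, m5.cds_end - 3))
            t3 = int(rng.integers(m3.cds_start, m3.cds_end - 30))
            bp5 = _tx_to_genomic(m5, t5)
            bp3 = _tx_to_genomic(m3, t3)
            call = classify_frame(m5, bp5, m3, bp3)
            if call.status not in (FrameStatus.IN_FRAME, FrameStatus.FRAMESHIFT):
                continue
            n_checked += 1
            oracle = oracle_in_frame(genome, m5, t5, m3, t3)
            said_in_frame = call.status is FrameStatus.IN_FRAME
            # a junction stop makes the oracle say "not in frame" while the
            # phase is congruent; annotate_candidate reports JUNCTION_STOP,
            # so exclude that case from the IN_FRAME side here
            if said_in_frame and not oracle:
                ann = annotate_candidate(
                    BreakpointPair(
                        gene5=m5.gene_name, gene3=m3.gene_name,
                        contig5=m5.contig, contig3=m3.contig,
                        genomic_bp5=bp5, genomic_bp3=bp3,
                    ),
                    {m.transcript_id: m for m in (m5, m3)}, [], genome,
                )
                if ann.frame_status is FrameStatus.JUNCTION_STOP:
                    continue
                disagreements += 1
            elif not said_in_frame and oracle:
                disagreements += 1
        assert disagreements == 0


def _tx_to_genomic(model, tpos):
    from dgcfusion.annotation_io import transcript_to_genomic
    return transcript_to_genomic(model, tpos)
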