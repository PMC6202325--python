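"""Chimeric-transcript construction and reading-frame classification.

Breakpoint semantics (one coordinate per partner, matching the usual
fusion-table format): the 5'-gene coordinate is the **last** transcribed base
retained from the 5' partner, the 3'-gene coordinate is the **first**
retained base of the 3' partner.  Genomic (DNA-level) breakpoints, which
typically fall in introns, are resolved to mRNA-level breakpoints through
:func:`infer_mrna_breakpoint` before any frame arithmetic; exonic DNA
breakpoints are treated as cryptic junctions and used as-is.

Frame classification works on counts alone: with ``n5_cds`` retained coding
bases from the 5' partner and the first retained base at 1-based offset
``d3_offset`` within the 3' CDS, the 3' open reading frame continues in its
native frame iff ``n5_cds % 3 == (d3_offset - 1) % 3``.  A phase-congruent
junction whose hybrid codon happens to encode a stop is reported as
``JUNCTION_STOP`` rather than ``IN_FRAME`` or ``FRAMESHIFT``, preserving the
phase information.  Every classification is double-checked by direct
translation of the fused cDNA (:func:`translate_fusion`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio.Seq import Seq

from dgcfusion.annotation_io import (
    DomainRecord,
    GenomeSequence,
    TranscriptModel,
    genomic_to_transcript,
)

__all__ = [
    "BreakpointPair",
    "FrameStatus",
    "FusionAnnotation",
    "FusionError",
    "UPSTREAM_OF_CDS",
    "infer_mrna_breakpoint",
    "build_fusion_transcript",
    "classify_frame",
    "translate_fusion",
    "retained_spans",
    "retained_domains",
    "annotate_candidate",
]

#: Sentinel for a 3' breakpoint upstream of the 3' partner's CDS (the whole
#: 3' open reading frame is retained).
UPSTREAM_OF_CDS = 0


class FusionError(ValueError):
    """Raised for breakpoints that violate an operation's preconditions."""


class FrameStatus(enum.Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    PROMOTER_SWAP = "promoter_swap"
    NON_CODING = "non_coding"
    JUNCTION_STOP = "junction_stop"


@dataclass(frozen=True)
class BreakpointPair:
    """One caller-reported breakpoint pair.

    ``genomic_bp5`` is the genomic position of the last transcribed base
    retained from the 5' partner; ``genomic_bp3`` the first retained base of
    the 3' partner.  ``provenance`` distinguishes mRNA-level junction
    coordinates from DNA-level rearrangement coordinates.
    """

    gene5: str
    gene3: str
    contig5: str
    contig3: str
    genomic_bp5: int
    genomic_bp3: int
    provenance: str = "mRNA"  # "mRNA" | "genomic"

    def __post_init__(self) -> None:
        if self.genomic_bp5 <= 0 or self.genomic_bp3 <= 0:
            raise FusionError("breakpoint positions must be positive")
        if self.gene5 == self.gene3 and (
            self.contig5 == self.contig3 and self.genomic_bp5 == self.genomic_bp3
        ):
            raise FusionError(
                "degenerate breakpoint pair: identical genes and positions"
            )
        if self.provenance not in ("mRNA", "genomic"):
            raise FusionError(f"unknown provenance {self.provenance!r}")

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass(frozen=True)
class FrameCall:
    status: FrameStatus
    n5_cds: int
    d3_offset: int  # UPSTREAM_OF_CDS when the 3' breakpoint precedes the CDS


@dataclass(frozen=True)
class FusionProduct:
    """Fused cDNA plus the coordinates needed for translation."""

    cdna: str
    junction: int           # transcript coordinate of the last 5'-partner base
    cds_start: int | None   # 1-based within cdna; None on the promoter-swap path
    t5: int
    t3: int


@dataclass(frozen=True)
class FusionAnnotation:
    sample_id: str | None
    gene5: str
    gene3: str
    frame_status: FrameStatus
    n5_cds: int
    d3_offset: int
    aa5_span: tuple[int, int] | None = None
    aa3_span: tuple[int, int] | None = None
    junction_residue: str | None = None
    fusion_protein: str | None = None
    retained_domains: tuple[tuple[str, str], ...] = ()
    truncated_domains: tuple[tuple[str, str], ...] = ()
    class_labels: frozenset[str] = frozenset()
    mrna_bp5: int | None = None
    mrna_bp3: int | None = None


# ---------------------------------------------------------------------------


def infer_mrna_breakpoint(model: TranscriptModel, gpos: int, side: str) -> int:
    """Map a DNA-level breakpoint to the mRNA breakpoint splicing produces.

    Exonic positions are returned unchanged (cryptic/exonic junction).  An
    intronic position on the 5' side maps to the last base of the preceding
    exon (transcript orientation); on the 3' side, to the first base of the
    following exon.  Idempotent on exonic positions.
    """
    if side not in ("5", "3", "5'", "3'"):
        raise FusionError(f"side must be 5' or 3', got {side!r}")
    side = side[0]
    locus = genomic_to_transcript(model, gpos)
    if locus.kind == "outside":
        raise FusionError(
            f"position {gpos} outside the genomic span of {model.transcript_id}"
        )
    if locus.kind == "exonic":
        return gpos
    exons_tx = model.exons_tx_order
    i = locus.intron  # intron i sits between transcript exons i and i+1
    if side == "5":
        s, e = exons_tx[i - 1]
        return e if model.strand == "+" else s
    s, e = exons_tx[i]
    return s if model.strand == "+" else e


def build_fusion_transcript(
    model5: TranscriptModel,
    bp5: int,
    model3: TranscriptModel,
    bp3: int,
    genome: GenomeSequence,
) -> FusionProduct:
    """Concatenate the retained transcript segments into a fused cDNA.

    ``bp5``/``bp3`` must be mRNA-level (exonic) breakpoints; run
    :func:`infer_mrna_breakpoint` first for intronic DNA-level coordinates.
    """
    t5 = _require_exonic(model5, bp5, "5'")
    t3 = _require_exonic(model3, bp3, "3'")
    seq5 = model5.sequence(genome)[:t5]
    seq3 = model3.sequence(genome)[t3 - 1 :]
    cds_start = None
    if model5.is_coding and t5 >= model5.cds_start:
        cds_start = model5.cds_start
    return FusionProduct(cdna=seq5 + seq3, junction=t5, cds_start=cds_start, t5=t5, t3=t3)


def _require_exonic(model: TranscriptModel, gpos: int, side: str) -> int:
    locus = genomic_to_transcript(model, gpos)
    if locus.kind != "exonic":
        raise FusionError(
            f"{side} breakpoint {gpos} is not exonic in {model.transcript_id} "
            f"({locus.kind}); resolve it with infer_mrna_breakpoint first"
        )
    return locus.position


def classify_frame(
    model5: TranscriptModel,
    bp5: int,
    model3: TranscriptModel,
    bp3: int,
) -> FrameCall:
    """Classify the reading frame of a fusion from breakpoint arithmetic.

    Returns the frame status together with ``n5_cds`` (retained 5'-partner
    coding bases) and ``d3_offset`` (1-based offset of the first retained
    base within the 3' CDS, or :data:`UPSTREAM_OF_CDS`).
    """
    if not model5.is_coding or not model3.is_coding:
        raise FusionError("classify_frame requires coding transcript models")
    t5 = _require_exonic(model5, bp5, "5'")
    t3 = _require_exonic(model3, bp3, "3'")

    n5_cds = max(0, t5 - model5.cds_start + 1) if t5 >= model5.cds_start else 0
    d3_offset = t3 - model3.cds_start + 1 if t3 >= model3.cds_start else UPSTREAM_OF_CDS

    if t5 < model5.cds_start and d3_offset == UPSTREAM_OF_CDS:
        return FrameCall(FrameStatus.PROMOTER_SWAP, 0, UPSTREAM_OF_CDS)
    if t5 > model5.cds_end or (t3 > model3.cds_end):
        return FrameCall(FrameStatus.NON_CODING, n5_cds, d3_offset)
    if d3_offset == UPSTREAM_OF_CDS:
        # Breakpoint in the 5' partner CDS but upstream of the 3' CDS: the
        # retained 3'UTR bases sit between the junction and the intact 3'
        # ORF; the native frame continues iff the retained coding length plus
        # the linker length is a whole number of codons.
        linker = model3.cds_start - t3
        congruent = (n5_cds + linker) % 3 == 0
    else:
        congruent = n5_cds % 3 == (d3_offset - 1) % 3
    if not congruent:
        return FrameCall(FrameStatus.FRAMESHIFT, n5_cds, d3_offset)
    return FrameCall(FrameStatus.IN_FRAME, n5_cds, d3_offset)


_STOPS = {"TAA", "TAG", "TGA"}


def translate_fusion(
    cdna: str, cds_start: int, native_stop_offset: int | None = None
) -> tuple[str, bool, int | None]:
    """Translate a fused cDNA from ``cds_start`` (1-based) to the first stop.

    Returns ``(protein, premature_stop, stop_codon_index)`` where
    ``stop_codon_index`` is the 1-based codon number of the stop (None if no
    stop before the sequence end).  ``native_stop_offset``, when given, is
    the 1-based cDNA position where the 3' partner's native stop codon
    begins; a stop strictly 5' of it flags ``premature_stop``.
    """
    if cds_start > len(cdna):
        raise FusionError("CDS start beyond fused sequence")
    coding = cdna[cds_start - 1 :]
    coding = coding[: len(coding) - len(coding) % 3]
    protein: list[str] = []
    stop_index: int | None = None
    for i in range(0, len(coding), 3):
        codon = coding[i : i + 3]
        if codon in _STOPS:
            stop_index = i // 3 + 1
            break
        protein.append(str(Seq(codon).translate()))
    premature = False
    if stop_index is not None and native_stop_offset is not None:
        stop_pos = cds_start + (stop_index - 1) * 3
        premature = stop_pos < native_stop_offset
    elif stop_index is None and native_stop_offset is not None:
        # Never reached a stop at all: the native stop was lost (frameshift
        # ran past it); not "premature", but the suffix check will fail.
        premature = False
    return "".join(protein), premature, stop_index


def retained_spans(call: FrameCall, protein3_length: int) -> tuple[
    tuple[int, int] | None, tuple[int, int] | None
]:
    """Amino-acid spans retained from each partner for an in-frame fusion.

    The 5' span is ``[1, floor(n5_cds / 3)]``; the 3' span starts at the
    first *complete* native codon of the 3' partner and runs to its last
    residue.  The hybrid junction residue (when the junction phase is
    non-zero) belongs to neither span and is reported separately.
    """
    if call.status is not FrameStatus.IN_FRAME:
        raise FusionError("retained_spans requires an IN_FRAME call")
    a = call.n5_cds // 3
    aa5 = (1, a) if a >= 1 else None
    d = call.d3_offset
    if d == UPSTREAM_OF_CDS or d == 1:
        b = 1
    elif (d - 1) % 3 == 0:
        b = (d - 1) // 3 + 1
    else:
        b = (d - 1) // 3 + 2
    aa3 = (b, protein3_length) if b <= protein3_length else None
    return aa5, aa3


def retained_domains(
    aa5_span: tuple[int, int] | None,
    aa3_span: tuple[int, int] | None,
    gene5: str,
    gene3: str,
    domains: list[DomainRecord],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], frozenset[str]]:
    """Domains fully contained in the retained spans, plus class labels.

    A domain is *retained* iff its ``[aa_start, aa_end]`` lies entirely
    inside the retained span of its partner; a domain that merely overlaps
    is reported as *truncated*, never as retained.  Class labels:
    ``"RhoGAP-domain fusion"`` if a RhoGAP domain is retained on either
    side, ``"PAP2-domain fusion"`` likewise for PAP2.
    """
    retained: list[tuple[str, str]] = []
    truncated: list[tuple[str, str]] = []
    for gene, span, side in ((gene5, aa5_span, "5'"), (gene3, aa3_span, "3'")):
        if span is None:
            continue
        lo, hi = span
        for rec in domains:
            if rec.gene_name != gene:
                continue
            if lo <= rec.aa_start and rec.aa_end <= hi:
                retained.append((rec.domain_name, side))
            elif rec.aa_start <= hi and lo <= rec.aa_end:
                truncated.append((rec.domain_name, side))
    labels = set()
    if any(name == "RhoGAP" for name, _ in retained):
        labels.add("RhoGAP-domain fusion")
    if any(name == "PAP2" for name, _ in retained):
        labels.add("PAP2-domain fusion")
    return retained, truncated, frozenset(labels)


def annotate_candidate(
    pair: BreakpointPair,
    models: dict[str, TranscriptModel],
    domains: list[DomainRecord],
    genome: GenomeSequence,
    sample_id: str | None = None,
) -> FusionAnnotation:
    """Full annotation of one breakpoint pair.

    Composes breakpoint resolution, fused-transcript construction, frame
    classification, translation, retained spans, and domain retention.  The
    translation oracle is always run; a disagreement with the arithmetic
    classifier raises an internal-consistency error.
    """
    by_gene: dict[str, TranscriptModel] = {m.gene_name: m for m in models.values()}
    for gene in (pair.gene5, pair.gene3):
        if gene not in by_gene:
            raise FusionError(f"unknown gene symbol {gene!r} in transcript models")
    model5, model3 = by_gene[pair.gene5], by_gene[pair.gene3]

    bp5 = infer_mrna_breakpoint(model5, pair.genomic_bp5, "5")
    bp3 = infer_mrna_breakpoint(model3, pair.genomic_bp3, "3")

    call = classify_frame(model5, bp5, model3, bp3)
    product = build_fusion_transcript(model5, bp5, model3, bp3, genome)

    status = call.status
    protein = None
    aa5 = aa3 = None
    junction_res = None
    ret: tuple = ()
    trunc: tuple = ()
    labels: frozenset[str] = frozenset()

    if status in (FrameStatus.IN_FRAME, FrameStatus.FRAMESHIFT) and product.cds_start:
        protein3 = str(Seq(model3.cds_sequence(genome)).translate()).rstrip("*")
        native_stop_offset = product.junction + (model3.cds_end - 2 - (product.t3 - 1))
        protein, premature, stop_index = translate_fusion(
            product.cdna, product.cds_start, native_stop_offset
        )
        # The recovered native suffix can only be as long as the number of
        # complete native 3'-partner codons the breakpoint retains.
        d = call.d3_offset
        if d in (UPSTREAM_OF_CDS, 1) or (d - 1) % 3 == 0:
            b = 1 if d in (UPSTREAM_OF_CDS, 1) else (d - 1) // 3 + 1
        else:
            b = (d - 1) // 3 + 2
        n_retained_native = max(0, len(protein3) - b + 1)
        suffix = protein3[len(protein3) - min(20, n_retained_native) :] if n_retained_native else ""
        in_frame_by_oracle = (not premature) and protein.endswith(suffix) and (
            len(protein) * 3 >= (model3.cds_end - product.t3 + 1) - 3
        )
        if status is FrameStatus.IN_FRAME:
            if premature:
                # Phase-congruent junction but a stop codon appears before
                # the native 3' ORF resumes (hybrid junction codon, or a
                # retained-5'UTR linker on the 3' side).
                status = FrameStatus.JUNCTION_STOP
            elif not in_frame_by_oracle:
                raise FusionError(
                    f"internal consistency failure for {pair.gene5}-{pair.gene3}: "
                    "arithmetic says IN_FRAME but translation disagrees"
                )
        elif status is FrameStatus.FRAMESHIFT and in_frame_by_oracle:
            raise FusionError(
                f"internal consistency failure for {pair.gene5}-{pair.gene3}: "
                "arithmetic says FRAMESHIFT but translation recovers the native 3' suffix"
            )

    if status is FrameStatus.IN_FRAME:
        protein3_length = model3.cds_length // 3 - 1  # minus the stop codon
        aa5, aa3 = retained_spans(call, protein3_length)
        if call.n5_cds % 3 != 0 and protein is not None:
            junction_res = protein[call.n5_cds // 3] if len(protein) > call.n5_cds // 3 else None
        retained, truncated, labels = retained_domains(
            aa5, aa3, pair.gene5, pair.gene3, domains
        )
        ret, trunc = tuple(retained), tuple(truncated)

    return FusionAnnotation(
        sample_id=sample_id,
        gene5=pair.gene5,
        gene3=pair.gene3,
        frame_status=status,
        n5_cds=call.n5_cds,
        d3_offset=call.d3_offset,
        aa5_span=aa5,
        aa3_span=aa3,
        junction_residue=junction_res,
        fusion_protein=protein,
        retained_domains=ret,
        truncated_domains=trunc,
        class_labels=labels,
        mrna_bp5=bp5,
        mrna_bp3=bp3,
    )
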