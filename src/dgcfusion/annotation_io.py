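"""Reference annotation I/O and genomic <-> transcript coordinate mapping.

Conventions used throughout the package:

* All genomic coordinates are **1-based inclusive** (``g.chr3:137,749,947``
  style).
* For minus-strand transcripts, transcript coordinate 1 is the genomically
  3'-most (highest-coordinate) base of the 3'-most exon; all downstream
  breakpoint arithmetic happens in transcript coordinates.
* Introns are numbered in transcript orientation, 1-based: intron *i* follows
  exon *i*.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "DomainRecord",
    "TxLocus",
    "AnnotationError",
    "load_genome",
    "write_genome",
    "load_gene_models",
    "write_gene_models",
    "select_canonical",
    "genomic_to_transcript",
    "transcript_to_genomic",
    "load_domain_table",
    "write_domain_table",
]

_VALID_ALPHABET = set("ACGTN")


class AnnotationError(ValueError):
    """Raised for malformed reference annotation inputs."""


@dataclass(frozen=True)
class GenomeSequence:
    """Uppercase A/C/G/T/N sequences keyed by contig name, 1-based."""

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise AnnotationError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_ALPHABET
            if bad:
                raise AnnotationError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end]`` (1-based inclusive)."""
        if contig not in self.contigs:
            raise AnnotationError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise AnnotationError(
                f"interval [{start}, {end}] outside contig {contig!r} (length {len(seq)})"
            )
        return seq[start - 1 : end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's exon/CDS structure on a strand.

    ``exons`` are genomic ``(start, end)`` intervals, 1-based inclusive,
    non-overlapping, sorted by genomic start regardless of strand.
    ``cds_start``/``cds_end`` are *transcript* coordinates of the first and
    last coding base; both are ``None`` for non-coding transcripts.
    """

    gene_id: str
    gene_name: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: inverted exon ({s}, {e})"
                )
            if s <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.transcript_id}: cds_start/cds_end must both be set"
            )
        if self.cds_start is not None:
            L = self.length
            if not (1 <= self.cds_start < self.cds_end <= L):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS [{self.cds_start}, "
                    f"{self.cds_end}] outside transcript of length {L}"
                )
            # A CDS length that is not a codon multiple (partial terminal
            # codon, as real annotations occasionally contain) is tolerated;
            # frame arithmetic only depends on the CDS start phase.

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        return self.cds_end - self.cds_start + 1

    @property
    def exons_tx_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def sequence(self, genome: GenomeSequence) -> str:
        """Spliced transcript sequence, 5'->3' (reverse-complemented on minus)."""
        parts = [genome.fetch(self.contig, s, e) for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_sequence(self, genome: GenomeSequence) -> str:
        if not self.is_coding:
            raise AnnotationError(f"transcript {self.transcript_id} is non-coding")
        return self.sequence(genome)[self.cds_start - 1 : self.cds_end]


@dataclass(frozen=True, order=True)
class DomainRecord:
    """A named protein domain of a gene, in 1-based protein coordinates."""

    gene_name: str
    domain_name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not self.domain_name:
            raise AnnotationError("domain_name must be non-empty")
        if not (1 <= self.aa_start <= self.aa_end):
            raise AnnotationError(
                f"domain {self.domain_name} of {self.gene_name}: invalid interval "
                f"[{self.aa_start}, {self.aa_end}]"
            )


@dataclass(frozen=True)
class TxLocus:
    """Where a genomic position falls relative to a transcript.

    ``kind`` is ``"exonic"`` (``position`` set to the 1-based transcript
    coordinate), ``"intronic"`` (``intron`` set to the 1-based intron index
    in transcript orientation), or ``"outside"``.
    """

    kind: str
    position: int | None = None
    intron: int | None = None


# ---------------------------------------------------------------------------
# FASTA


def load_genome(path: str | Path) -> GenomeSequence:
    """Read a (possibly multi-record, wrapped) FASTA into a GenomeSequence."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise AnnotationError(f"duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise AnnotationError(f"contig {rec.id!r} has an empty sequence")
        contigs[rec.id] = seq
    if not contigs:
        raise AnnotationError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF


def _genomic_cds_to_tx(model_exons: Sequence[tuple[int, int]], strand: str,
                       cds_intervals: Sequence[tuple[int, int]]) -> tuple[int, int]:
    """Convert genomic CDS intervals to (cds_start, cds_end) transcript coords."""
    gmin = min(s for s, _ in cds_intervals)
    gmax = max(e for _, e in cds_intervals)
    first = gmin if strand == "+" else gmax
    last = gmax if strand == "+" else gmin
    t_first = _g_to_t(model_exons, strand, first)
    t_last = _g_to_t(model_exons, strand, last)
    if t_first is None or t_last is None:
        raise AnnotationError("CDS interval outside exons")
    return t_first, t_last


def _g_to_t(exons: Sequence[tuple[int, int]], strand: str, gpos: int) -> int | None:
    """Exonic genomic position -> transcript coordinate, else None."""
    if strand == "+":
        offset = 0
        for s, e in exons:
            if s <= gpos <= e:
                return offset + (gpos - s) + 1
            offset += e - s + 1
        return None
    offset = 0
    for s, e in reversed(exons):
        if s <= gpos <= e:
            return offset + (e - gpos) + 1
        offset += e - s + 1
    return None


def load_gene_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Load transcript models from a GTF (GFF2 dialect) file.

    Returns a mapping ``transcript_id -> TranscriptModel``.  CDS features are
    converted to transcript coordinates; transcripts without CDS lines are
    kept as non-coding models (frame operations reject them downstream).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(f"feature missing {exc} attribute") from exc
        gname = feat.attributes.get("gene_name", [gid])[0]
        meta.setdefault(tid, (gid, gname, feat.seqid, feat.strand))
        bucket = exons if feat.featuretype == "exon" else cds
        bucket.setdefault(tid, []).append((feat.start, feat.end))

    models: dict[str, TranscriptModel] = {}
    for tid in sorted(cds.keys() - exons.keys()):
        raise AnnotationError(f"transcript {tid} has CDS but no exons")
    for tid, ex in exons.items():
        gid, gname, contig, strand = meta[tid]
        ex = tuple(sorted(ex))
        cs = ce = None
        if tid in cds:
            for s, e in cds[tid]:
                if not any(es <= s and e <= ee for es, ee in ex):
                    raise AnnotationError(
                        f"transcript {tid}: CDS interval ({s}, {e}) outside exons"
                    )
            cs, ce = _genomic_cds_to_tx(ex, strand, cds[tid])
        models[tid] = TranscriptModel(
            gene_id=gid, gene_name=gname, transcript_id=tid, contig=contig,
            strand=strand, exons=ex, cds_start=cs, cds_end=ce,
        )
    return models


def write_gene_models(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models to GTF with exon and CDS features (GFF2 attribute style)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_name}";'
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.contig}\tdgcfusion\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                for s, e in _tx_cds_to_genomic_intervals(m):
                    fh.write(
                        f"{m.contig}\tdgcfusion\tCDS\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                    )


def _tx_cds_to_genomic_intervals(m: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals covered by the CDS, sorted by genomic start."""
    out: list[tuple[int, int]] = []
    tpos = 0
    for s, e in m.exons_tx_order:
        exon_len = e - s + 1
        lo = max(m.cds_start, tpos + 1)
        hi = min(m.cds_end, tpos + exon_len)
        if lo <= hi:
            if m.strand == "+":
                out.append((s + (lo - tpos - 1), s + (hi - tpos - 1)))
            else:
                out.append((e - (hi - tpos - 1), e - (lo - tpos - 1)))
        tpos += exon_len
    return sorted(out)


def select_canonical(models_for_gene: Iterable[TranscriptModel]) -> TranscriptModel:
    """Pick the transcript with the longest CDS; ties break on transcript_id."""
    models = list(models_for_gene)
    if not models:
        raise AnnotationError("select_canonical: empty model collection")
    gids = {m.gene_id for m in models}
    if len(gids) > 1:
        raise AnnotationError(f"select_canonical: mixed gene_ids {sorted(gids)}")
    return min(models, key=lambda m: (-m.cds_length, m.transcript_id))


# ---------------------------------------------------------------------------
# Coordinate mapping


def genomic_to_transcript(model: TranscriptModel, gpos: int, contig: str | None = None) -> TxLocus:
    """Locate a genomic position relative to a transcript.

    Exonic positions map to a 1-based transcript coordinate respecting
    strand; intronic positions map to the index of the intron in transcript
    orientation (intron *i* follows exon *i*); positions outside the
    transcript's genomic span map to the ``"outside"`` label.
    """
    if contig is not None and contig != model.contig:
        raise AnnotationError(
            f"position on contig {contig!r} but model is on {model.contig!r}"
        )
    lo, hi = model.span
    if gpos < lo or gpos > hi:
        return TxLocus("outside")
    tpos = _g_to_t(model.exons, model.strand, gpos)
    if tpos is not None:
        return TxLocus("exonic", position=tpos)
    # Intronic: find the genomic gap, then number it in transcript orientation.
    starts = [s for s, _ in model.exons]
    i = bisect_right(starts, gpos)  # gpos falls between exons i-1 and i (genomic)
    n_introns = len(model.exons) - 1
    intron = i if model.strand == "+" else n_introns - i + 1
    return TxLocus("intronic", intron=intron)


def transcript_to_genomic(model: TranscriptModel, tpos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` on exonic positions."""
    if not (1 <= tpos <= model.length):
        raise AnnotationError(
            f"transcript position {tpos} outside [1, {model.length}]"
        )
    offset = 0
    for s, e in model.exons_tx_order:
        exon_len = e - s + 1
        if tpos <= offset + exon_len:
            within = tpos - offset - 1
            return s + within if model.strand == "+" else e - within
        offset += exon_len
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Domain tables

_DOMAIN_COLUMNS = ("gene_name", "domain_name", "aa_start", "aa_end")


def load_domain_table(path: str | Path) -> list[DomainRecord]:
    """Read a protein-domain TSV (gene_name, domain_name, aa_start, aa_end).

    Duplicate rows are de-duplicated; an empty file yields an empty list.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_DOMAIN_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise AnnotationError(f"domain table missing columns: {sorted(missing)}")
        seen: dict[DomainRecord, None] = {}
        for row in reader:
            rec = DomainRecord(
                gene_name=row["gene_name"],
                domain_name=row["domain_name"],
                aa_start=int(row["aa_start"]),
                aa_end=int(row["aa_end"]),
            )
            seen.setdefault(rec)
    return list(seen)


def write_domain_table(records: Iterable[DomainRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_DOMAIN_COLUMNS)
        for rec in records:
            writer.writerow([rec.gene_name, rec.domain_name, rec.aa_start, rec.aa_end])
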