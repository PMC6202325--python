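"""Reading fusion-caller candidate tables and forming filtered/consensus sets.

Candidates are consumed from deFuse-style TSV (1-based inclusive
coordinates) or BEDPE (0-based half-open, converted on read).  The
read-support filter keeps candidates with **strictly more** spanning reads
than the threshold (default 3, i.e. "> 3 spanning reads").  Fusions are
identified at the (sample, ordered gene pair) level: caller breakpoint
estimates for one fusion differ by a few bases, so coordinates never key
consensus matching; distinct breakpoints of one pair are kept as isoforms.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from dgcfusion.fusion_frame import BreakpointPair

__all__ = [
    "FusionCandidate",
    "FusionEvent",
    "IntakeError",
    "read_candidates",
    "write_candidates",
    "filter_by_spanning_reads",
    "collapse_by_gene_pair",
    "caller_consensus",
    "flag_read_through",
]

_TSV_COLUMNS = (
    "sample_id", "gene5", "contig5", "pos5", "gene3", "contig3", "pos3",
    "provenance", "spanning_reads",
)


class IntakeError(ValueError):
    """Raised for malformed candidate tables."""


@dataclass(frozen=True)
class FusionCandidate:
    sample_id: str
    pair: BreakpointPair
    spanning_reads: int
    caller: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise IntakeError("sample_id must be non-empty")
        if self.spanning_reads < 0:
            raise IntakeError("spanning_reads must be >= 0")


@dataclass(frozen=True)
class FusionEvent:
    """One fusion in one sample, possibly supported by several breakpoint isoforms."""

    sample_id: str
    gene5: str
    gene3: str
    isoforms: tuple[tuple[int, int], ...]  # sorted (pos5, pos3) pairs
    spanning_reads: int                    # max across isoforms
    callers: tuple[str, ...] = ()

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


def read_candidates(path: str | Path, caller: str = "unknown") -> list[FusionCandidate]:
    """Read candidates from TSV (header row) or BEDPE (.bedpe suffix).

    BEDPE start coordinates are 0-based half-open and are converted to the
    package's 1-based inclusive convention.
    """
    path = Path(path)
    if path.suffix.lower() == ".bedpe":
        return _read_bedpe(path, caller)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise IntakeError(f"{path}: empty candidate table")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise IntakeError(f"{path}: missing required column(s) {sorted(missing)}")
        out = []
        for row in reader:
            reads = int(row["spanning_reads"])
            if reads < 0:
                raise IntakeError(f"{path}: negative spanning_reads {reads}")
            pair = BreakpointPair(
                gene5=row["gene5"], gene3=row["gene3"],
                contig5=row["contig5"], contig3=row["contig3"],
                genomic_bp5=int(row["pos5"]), genomic_bp3=int(row["pos3"]),
                provenance=row["provenance"],
            )
            out.append(FusionCandidate(row["sample_id"], pair, reads, caller))
    return out


def _read_bedpe(path: Path, caller: str) -> list[FusionCandidate]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise IntakeError(f"{path}:{lineno}: BEDPE needs >= 10 columns")
            chrom1, start1, end1, chrom2, start2, end2, name = fields[:7]
            # name column carries sample|gene5|gene3|reads
            try:
                sample, gene5, gene3, reads = name.split("|")
            except ValueError as exc:
                raise IntakeError(
                    f"{path}:{lineno}: name column must be sample|gene5|gene3|reads"
                ) from exc
            pair = BreakpointPair(
                gene5=gene5, gene3=gene3, contig5=chrom1, contig3=chrom2,
                # BEDPE 0-based half-open; the breakpoint base is the interval end
                genomic_bp5=int(end1), genomic_bp3=int(start2) + 1,
                provenance="mRNA",
            )
            out.append(FusionCandidate(sample, pair, int(reads), caller))
    return out


def write_candidates(candidates: Iterable[FusionCandidate], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for c in candidates:
            p = c.pair
            writer.writerow([
                c.sample_id, p.gene5, p.contig5, p.genomic_bp5,
                p.gene3, p.contig3, p.genomic_bp3, p.provenance, c.spanning_reads,
            ])


def filter_by_spanning_reads(
    candidates: Iterable[FusionCandidate], threshold: int = 3
) -> list[FusionCandidate]:
    """Keep candidates with spanning_reads strictly greater than ``threshold``."""
    return [c for c in candidates if c.spanning_reads > threshold]


def collapse_by_gene_pair(candidates: Iterable[FusionCandidate]) -> list[FusionEvent]:
    """Group candidates into per-(sample, ordered gene pair) fusion events.

    Ordered pairs matter: (A, B) and (B, A) in one sample are two events.
    """
    groups: dict[tuple[str, str, str], list[FusionCandidate]] = defaultdict(list)
    for c in candidates:
        groups[(c.sample_id, c.pair.gene5, c.pair.gene3)].append(c)
    events = []
    for (sample, g5, g3), members in sorted(groups.items()):
        isoforms = tuple(sorted({(m.pair.genomic_bp5, m.pair.genomic_bp3) for m in members}))
        callers = tuple(sorted({m.caller for m in members}))
        events.append(FusionEvent(
            sample_id=sample, gene5=g5, gene3=g3, isoforms=isoforms,
            spanning_reads=max(m.spanning_reads for m in members), callers=callers,
        ))
    return events


def caller_consensus(
    candidate_sets: Sequence[Iterable[FusionCandidate]],
    mode: str = "intersection",
) -> list[FusionEvent]:
    """Combine candidate sets from several callers.

    Matching is by (sample, ordered gene pair).  ``intersection`` keeps
    pairs seen by at least two callers; ``union`` keeps everything.  Either
    way each event carries its supporting caller list.
    """
    if not candidate_sets:
        raise IntakeError("caller_consensus needs at least one candidate set")
    if mode not in ("union", "intersection"):
        raise IntakeError(f"unknown consensus mode {mode!r}")
    events = collapse_by_gene_pair(c for cs in candidate_sets for c in cs)
    if mode == "union":
        return events
    return [e for e in events if len(e.callers) >= 2]


def flag_read_through(
    candidates: Iterable[FusionCandidate],
    models: dict,
    max_distance: int = 100_000,
) -> dict[FusionCandidate, bool]:
    """Flag candidates whose partners look like read-through transcription.

    A candidate is flagged when both genes sit on the same contig and
    strand, the 5' gene lies upstream of the 3' gene in transcription
    direction, and the gap between them is at most ``max_distance``.
    Flag only — read-throughs are reported, never auto-dropped.
    """
    by_gene = {m.gene_name: m for m in models.values()}
    out = {}
    for c in candidates:
        m5 = by_gene.get(c.pair.gene5)
        m3 = by_gene.get(c.pair.gene3)
        flag = False
        if m5 is not None and m3 is not None and m5.contig == m3.contig and m5.strand == m3.strand:
            if m5.strand == "+":
                gap = m3.span[0] - m5.span[1]
            else:
                gap = m5.span[0] - m3.span[1]
            flag = 0 <= gap <= max_distance
        out[c] = flag
    return out
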