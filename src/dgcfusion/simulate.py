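"""Synthetic reference, fusion, expression and cohort generation.

Every input the pipeline consumes can be generated here with known ground
truth: a small genome with coding genes on both strands, GTF-style
transcript models, a protein-domain table (including one RhoGAP and one
PAP2 domain), fusion candidate tables whose true frame status is planted
by construction, exon-level expression with 3'-of-breakpoint
overexpression in carriers, and a clinical cohort with mutually exclusive
mutation flags and proportional-hazards survival.

Defaults emulate the study design this package was built around: 384
samples with 13/2/2 carriers of three recurrent in-frame fusions, a
planted fusion hazard ratio of 2.8 on an exponential baseline with median
94.6 months, administrative censoring at 96 months (about half the cohort
experiences an event), and strict mutual exclusivity between fusions and
CDH1/RHOA mutation flags.

Randomness: one integer seed governs everything.  Each stage draws from
its own child stream (``default_rng([seed, stage_index])`` with reference
= 0, fusions = 1, expression = 2, cohort = 3), so re-running a single
stage reproduces its output regardless of which other stages ran.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from dgcfusion.annotation_io import (
    DomainRecord,
    GenomeSequence,
    TranscriptModel,
    transcript_to_genomic,
)
from dgcfusion.candidate_intake import FusionCandidate
from dgcfusion.fusion_frame import BreakpointPair

__all__ = [
    "SimulationError",
    "FusionSpec",
    "FusionTruth",
    "SimulationConfig",
    "simulate_reference",
    "simulate_fusions",
    "simulate_expression",
    "simulate_cohort",
]

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FusionSpec:
    """One planted fusion: gene pair, carrier count, breakpoint placement
    (intronic DNA-level vs exonic cryptic) and the true frame class."""

    gene5: str
    gene3: str
    n_carriers: int
    breakpoint_type: str = "intronic"   # "intronic" | "exonic"
    truth_frame: str = "in_frame"       # "in_frame" | "frameshift" | "promoter_swap"


@dataclass(frozen=True)
class FusionTruth:
    """Ground truth for one planted fusion."""

    spec: FusionSpec
    carriers: tuple[str, ...]
    pair: BreakpointPair
    mrna_bp5: int
    mrna_bp3: int
    first_retained_exon3: int  # transcript-order exon index of the 3' gene

    @property
    def name(self) -> str:
        return f"{self.spec.gene5}-{self.spec.gene3}"


def _default_fusion_specs() -> tuple[FusionSpec, ...]:
    # 13/2/2 carriers in 384 mirrors the three recurrent in-frame fusions;
    # the frameshift plant is a decoy the frame classifier must reject.
    return (
        FusionSpec("G01", "G02", 13, "exonic", "in_frame"),
        FusionSpec("G03", "G04", 2, "intronic", "in_frame"),
        FusionSpec("G05", "G06", 2, "intronic", "in_frame"),
        FusionSpec("G07", "G08", 1, "exonic", "frameshift"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    # reference
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (60, 240)
    intron_length: tuple[int, int] = (60, 300)
    utr_length: tuple[int, int] = (30, 90)
    intergenic_gap: tuple[int, int] = (200, 400)
    strand_fraction_minus: float = 0.5
    contig: str = "chrS"
    # cohort / fusions
    n_samples: int = 384
    fusion_specs: tuple[FusionSpec, ...] = field(default_factory=_default_fusion_specs)
    n_decoy_candidates: int = 6
    decoy_max_reads: int = 3
    carrier_reads: tuple[int, int] = (4, 40)
    # expression
    expression_effect: float = 3.0     # log2-units added 3' of the breakpoint
    expression_sigma: float = 0.5      # per-exon, per-sample log2 noise SD
    gene_mean_range: tuple[float, float] = (3.0, 7.0)
    # clinical flags
    mutual_exclusivity: bool = True
    n_sequenced: int = 229             # carriers + 212 sequenced non-carriers
    cdh1_rate: float = 0.311
    rhoa_rate: float = 0.151
    tp53_rate: float = 0.4
    cin_rate: float = 0.32
    carrier_age: tuple[float, float] = (40.0, 8.0)
    noncarrier_age: tuple[float, float] = (56.0, 10.0)
    # survival
    baseline_median_months: float = 94.6
    fusion_hazard_ratio: float = 2.8
    covariate_hazard_ratios: tuple[tuple[str, float], ...] = (
        ("CIN", 2.3), ("CDH1_mut", 1.8),
    )
    censor_time: float = 96.0          # administrative censoring, months
    dropout_fraction: float = 0.0

    def __post_init__(self) -> None:
        total_carriers = sum(s.n_carriers for s in self.fusion_specs)
        if total_carriers > self.n_samples:
            raise SimulationError("more carriers than samples")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length,
                       self.utr_length, self.intergenic_gap):
            if not (0 < lo <= hi):
                raise SimulationError(f"infeasible length range ({lo}, {hi})")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i:04d}" for i in range(1, self.n_samples + 1))


# ---------------------------------------------------------------------------
# Reference


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NON_STOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + _STOPS[rng.integers(0, 3)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reference(
    config: SimulationConfig,
) -> tuple[GenomeSequence, dict[str, TranscriptModel], list[DomainRecord]]:
    """Generate a contig of non-overlapping coding genes plus a domain table.

    Every transcript has a 5'UTR, a CDS that starts with ATG, contains no
    internal stop and is divisible by 3, and a 3'UTR.  Half the genes
    (on average) sit on the minus strand.  One gene carries a "RhoGAP"
    domain and another a "PAP2" domain in the C-terminal half, so planted
    fusions that retain the 3' region also retain the domain.
    """
    rng = config.rng(0)
    pieces: list[str] = []
    models: dict[str, TranscriptModel] = {}
    cursor = 1
    gene_names = [f"G{i:02d}" for i in range(1, config.n_genes + 1)]
    for gi, gene in enumerate(gene_names):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
                     for _ in range(n_ex)]
        intron_lens = [int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                       for _ in range(n_ex - 1)]
        tx_len = sum(exon_lens)
        utr5 = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
        utr3 = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
        cds_len = tx_len - utr5 - utr3
        cds_len -= cds_len % 3
        utr3 = tx_len - utr5 - cds_len
        if cds_len < 30:
            raise SimulationError(
                f"gene {gene}: length ranges leave CDS of {cds_len} nt; "
                "increase exon lengths or counts"
            )
        cds = _random_cds(rng, cds_len // 3)
        tx_seq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)

        # split into exon chunks in transcript order
        chunks, off = [], 0
        for L in exon_lens:
            chunks.append(tx_seq[off : off + L])
            off += L
        strand = "-" if rng.random() < config.strand_fraction_minus else "+"
        region_parts = []
        for i, chunk in enumerate(chunks):
            region_parts.append(chunk)
            if i < len(intron_lens):
                region_parts.append(_random_seq(rng, intron_lens[i]))
        region = "".join(region_parts)
        if strand == "-":
            region = _revcomp(region)
            glens = exon_lens[::-1]
            gintrons = intron_lens[::-1]
        else:
            glens = exon_lens
            gintrons = intron_lens

        exons = []
        pos = cursor
        for i, L in enumerate(glens):
            exons.append((pos, pos + L - 1))
            pos += L
            if i < len(gintrons):
                pos += gintrons[i]
        pieces.append(region)
        models[f"{gene}.t1"] = TranscriptModel(
            gene_id=gene, gene_name=gene, transcript_id=f"{gene}.t1",
            contig=config.contig, strand=strand, exons=tuple(exons),
            cds_start=utr5 + 1, cds_end=utr5 + cds_len,
        )
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        pieces.append(_random_seq(rng, gap))
        cursor = pos + gap

    if not pieces:  # gene-free reference: keep the contig non-empty
        pieces.append(_random_seq(rng, 100))
    genome = GenomeSequence({config.contig: "".join(pieces)})

    domains: list[DomainRecord] = []
    for spec in config.fusion_specs:
        model3 = models.get(f"{spec.gene3}.t1")
        if model3 is None:
            continue
        plen = model3.cds_length // 3 - 1
        lo = plen // 2 + 1
        hi = max(lo + 4, plen - 3)
        if hi > plen:
            hi = plen
        if spec.truth_frame != "in_frame":
            continue
        name = "PAP2" if domains and any(d.domain_name == "RhoGAP" for d in domains) else "RhoGAP"
        domains.append(DomainRecord(spec.gene3, name, lo, hi))
    # an extra decorative domain on a 5' partner, truncated by fusion
    if config.fusion_specs:
        g5 = config.fusion_specs[0].gene5
        m5 = models.get(f"{g5}.t1")
        if m5 is not None:
            plen5 = m5.cds_length // 3 - 1
            domains.append(DomainRecord(g5, "coiled-coil", max(1, plen5 - 20), plen5))
    return genome, models, domains


# ---------------------------------------------------------------------------
# Fusions


def _cumlens(model: TranscriptModel) -> list[int]:
    out, total = [], 0
    for s, e in model.exons_tx_order:
        total += e - s + 1
        out.append(total)
    return out


def _exon_of_tpos(model: TranscriptModel, tpos: int) -> int:
    for i, cum in enumerate(_cumlens(model), start=1):
        if tpos <= cum:
            return i
    raise SimulationError("transcript position beyond transcript")


def _junction_is_stop(
    model5: TranscriptModel, model3: TranscriptModel, genome: GenomeSequence,
    t5: int, t3: int,
) -> bool:
    n5_cds = t5 - model5.cds_start + 1
    r = n5_cds % 3
    if r == 0:
        return False
    seq5 = model5.sequence(genome)
    seq3 = model3.sequence(genome)
    codon = seq5[t5 - r : t5] + seq3[t3 - 1 : t3 - 1 + (3 - r)]
    return codon in _STOPS


def _pick_exonic_breakpoints(
    rng, model5, model3, genome, truth_frame: str
) -> tuple[int, int]:
    """Transcript coordinates (t5, t3) realising the requested frame truth
    with cryptic (mid-exon) junctions."""
    for _ in range(200):
        t5 = int(rng.integers(model5.cds_start + 30, model5.cds_end - 30))
        r = (t5 - model5.cds_start + 1) % 3
        # keep the 3' breakpoint in the first third of the CDS so that
        # C-terminal domains (RhoGAP/PAP2 pattern) are retained
        lo3 = model3.cds_start
        hi3 = model3.cds_start + max(12, model3.cds_length // 3)
        t3 = int(rng.integers(lo3, hi3))
        d = t3 - model3.cds_start + 1
        if truth_frame == "in_frame":
            t3 += (r - (d - 1)) % 3
        else:
            t3 += (r + 1 - (d - 1)) % 3
        if truth_frame == "in_frame" and _junction_is_stop(model5, model3, genome, t5, t3):
            continue
        return t5, t3
    raise SimulationError("could not place exonic breakpoints for requested truth")


def _pick_intronic_breakpoints(
    rng, model5, model3, genome, truth_frame: str
) -> tuple[int, int, int, int]:
    """DNA-level intronic positions plus the mRNA breakpoints they splice to.

    Searches exon-boundary pairs whose phases realise the requested truth.
    Returns (gpos5, gpos3, t5, t3).
    """
    cum5 = _cumlens(model5)
    cum3 = _cumlens(model3)
    pairs = []
    for i5 in range(len(cum5) - 1):       # break in intron i5+1
        t5 = cum5[i5]                     # last base of exon i5+1 (tx order)
        if not (model5.cds_start + 3 <= t5 <= model5.cds_end - 3):
            continue
        for j3 in range(1, len(cum3)):    # break in intron j3, keep exon j3+1..
            t3 = cum3[j3 - 1] + 1         # first base of exon j3+1
            if not (model3.cds_start <= t3 <= model3.cds_start + model3.cds_length - 30):
                continue
            r = (t5 - model5.cds_start + 1) % 3
            d = t3 - model3.cds_start + 1
            congruent = r == (d - 1) % 3
            want = truth_frame == "in_frame"
            if congruent == want:
                if want and _junction_is_stop(model5, model3, genome, t5, t3):
                    continue
                pairs.append((i5 + 1, j3, t5, t3))
    if not pairs:
        raise SimulationError(
            f"no exon-boundary pair realises {truth_frame} for "
            f"{model5.gene_name}-{model3.gene_name}"
        )
    # prefer early 3' breakpoints so C-terminal domains are retained
    early = [p for p in pairs
             if p[3] <= model3.cds_start + model3.cds_length // 3]
    if early:
        pairs = early
    i5, j3, t5, t3 = pairs[int(rng.integers(0, len(pairs)))]
    gpos5 = _intron_midpoint(model5, i5)
    gpos3 = _intron_midpoint(model3, j3)
    return gpos5, gpos3, t5, t3


def _intron_midpoint(model: TranscriptModel, intron: int) -> int:
    """Genomic midpoint of intron ``intron`` (transcript orientation)."""
    exons_tx = model.exons_tx_order
    a = exons_tx[intron - 1]
    b = exons_tx[intron]
    if model.strand == "+":
        lo, hi = a[1] + 1, b[0] - 1
    else:
        lo, hi = b[1] + 1, a[0] - 1
    return (lo + hi) // 2


def simulate_fusions(
    config: SimulationConfig,
    genome: GenomeSequence,
    models: dict[str, TranscriptModel],
) -> tuple[list[FusionCandidate], list[FusionTruth]]:
    """Plant the configured fusions and add sub-threshold decoy candidates.

    Carriers receive spanning-read counts above the intake threshold;
    decoys (random gene pairs) receive at most ``decoy_max_reads`` and are
    removed by the intake filter.  The true frame class of each planted
    fusion is realised by construction of the breakpoint phases.
    """
    rng = config.rng(1)
    by_gene = {m.gene_name: m for m in models.values()}
    sample_pool = list(config.sample_ids)
    candidates: list[FusionCandidate] = []
    truths: list[FusionTruth] = []
    next_sample = 0
    for spec in config.fusion_specs:
        if spec.gene5 not in by_gene or spec.gene3 not in by_gene:
            raise SimulationError(f"fusion spec genes missing: {spec.gene5}, {spec.gene3}")
        m5, m3 = by_gene[spec.gene5], by_gene[spec.gene3]
        provenance = "mRNA"
        if spec.truth_frame == "promoter_swap":
            if m5.cds_start <= 1:
                raise SimulationError(
                    f"{spec.gene5} has no 5'UTR; promoter_swap truth impossible"
                )
            t5 = int(rng.integers(1, m5.cds_start))
            t3 = 1
            gpos5 = transcript_to_genomic(m5, t5)
            gpos3 = transcript_to_genomic(m3, t3)
        elif spec.breakpoint_type == "exonic":
            t5, t3 = _pick_exonic_breakpoints(rng, m5, m3, genome, spec.truth_frame)
            gpos5 = transcript_to_genomic(m5, t5)
            gpos3 = transcript_to_genomic(m3, t3)
        elif spec.breakpoint_type == "intronic":
            try:
                gpos5, gpos3, t5, t3 = _pick_intronic_breakpoints(
                    rng, m5, m3, genome, spec.truth_frame
                )
                provenance = "genomic"
            except SimulationError:
                # rare gene-pair geometries have no phase-compatible pair of
                # exon boundaries; fall back to cryptic exonic junctions,
                # which can realise any phase
                t5, t3 = _pick_exonic_breakpoints(rng, m5, m3, genome, spec.truth_frame)
                gpos5 = transcript_to_genomic(m5, t5)
                gpos3 = transcript_to_genomic(m3, t3)
        else:
            raise SimulationError(f"unknown breakpoint_type {spec.breakpoint_type!r}")

        carriers = tuple(sample_pool[next_sample : next_sample + spec.n_carriers])
        next_sample += spec.n_carriers
        pair = BreakpointPair(
            gene5=spec.gene5, gene3=spec.gene3,
            contig5=m5.contig, contig3=m3.contig,
            genomic_bp5=gpos5, genomic_bp3=gpos3, provenance=provenance,
        )
        mrna5 = transcript_to_genomic(m5, t5)
        mrna3 = transcript_to_genomic(m3, t3)
        truths.append(FusionTruth(
            spec=spec, carriers=carriers, pair=pair,
            mrna_bp5=mrna5, mrna_bp3=mrna3,
            first_retained_exon3=_exon_of_tpos(m3, t3),
        ))
        for sample in carriers:
            reads = int(rng.integers(config.carrier_reads[0], config.carrier_reads[1] + 1))
            candidates.append(FusionCandidate(sample, pair, reads, caller="simulated"))

    # decoys: random gene pairs with sub-threshold read support
    gene_names = sorted(by_gene)
    for _ in range(config.n_decoy_candidates):
        g5, g3 = rng.choice(gene_names, size=2, replace=False)
        m5, m3 = by_gene[g5], by_gene[g3]
        t5 = int(rng.integers(m5.cds_start, m5.cds_end))
        t3 = int(rng.integers(m3.cds_start, m3.cds_end))
        pair = BreakpointPair(
            gene5=g5, gene3=g3, contig5=m5.contig, contig3=m3.contig,
            genomic_bp5=transcript_to_genomic(m5, t5),
            genomic_bp3=transcript_to_genomic(m3, t3),
            provenance="mRNA",
        )
        sample = sample_pool[int(rng.integers(0, len(sample_pool)))]
        reads = int(rng.integers(0, config.decoy_max_reads + 1))
        candidates.append(FusionCandidate(sample, pair, reads, caller="simulated"))
    return candidates, truths


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimulationConfig,
    models: dict[str, TranscriptModel],
    truths: Sequence[FusionTruth],
) -> pd.DataFrame:
    """Exon-level FPKM matrix with planted 3'-of-breakpoint overexpression.

    Baseline log2 FPKM of each exon is Normal(gene mean, sigma) per sample;
    carriers get ``expression_effect`` extra log2-units on the 3' partner's
    exons at and downstream of the first retained exon.  Values are
    exponentiated back to the FPKM scale (hence always positive).
    """
    rng = config.rng(2)
    samples = list(config.sample_ids)
    rows = []
    index = []
    gene_means = {}
    for tid in sorted(models):
        m = models[tid]
        gene_means[m.gene_name] = rng.uniform(*config.gene_mean_range)
        for i, (s, e) in enumerate(m.exons_tx_order, start=1):
            index.append((m.gene_name, i, m.contig, s, e))
    log2 = np.empty((len(index), len(samples)))
    for r, (gene, exon_i, *_rest) in enumerate(index):
        log2[r] = gene_means[gene] + rng.normal(0.0, config.expression_sigma, len(samples))
    col_of = {s: j for j, s in enumerate(samples)}
    for truth in truths:
        if truth.spec.truth_frame == "frameshift":
            continue
        gene3 = truth.spec.gene3
        for r, (gene, exon_i, *_rest) in enumerate(index):
            if gene == gene3 and exon_i >= truth.first_retained_exon3:
                for sample in truth.carriers:
                    log2[r, col_of[sample]] += config.expression_effect
    fpkm = 2.0 ** log2
    idx = pd.MultiIndex.from_tuples(index, names=["gene", "exon_index", "contig", "start", "end"])
    return pd.DataFrame(fpkm, index=idx, columns=samples)


# ---------------------------------------------------------------------------
# Cohort


def simulate_cohort(
    config: SimulationConfig,
    truths: Sequence[FusionTruth],
) -> pd.DataFrame:
    """Clinical table: fusion flags, mutation/CIN flags, age, survival.

    Fusion flags come from the planted truth.  When mutual exclusivity is
    on, no carrier receives a CDH1 or RHOA mutation; mutation flags exist
    only in the "sequenced" subset (all carriers plus randomly chosen
    non-carriers up to ``n_sequenced``), and are missing elsewhere.
    Survival is exponential with hazard  h0 * HR_fusion^carrier *
    prod(HR_cov^flag), administratively censored at ``censor_time`` with an
    optional uniform-dropout fraction.
    """
    rng = config.rng(3)
    samples = list(config.sample_ids)
    n = len(samples)
    df = pd.DataFrame(index=pd.Index(samples, name="sample_id"))

    carrier_of: dict[str, set[str]] = {}
    all_carriers: set[str] = set()
    for truth in truths:
        if truth.spec.truth_frame != "in_frame":
            continue
        carrier_of[truth.name] = set(truth.carriers)
        all_carriers |= set(truth.carriers)
    for name, carriers in carrier_of.items():
        df[name] = [s in carriers for s in samples]
    is_carrier = np.array([s in all_carriers for s in samples])

    mu_c, sd_c = config.carrier_age
    mu_n, sd_n = config.noncarrier_age
    age = np.where(
        is_carrier,
        rng.normal(mu_c, sd_c, n),
        rng.normal(mu_n, sd_n, n),
    )
    age = np.clip(np.round(age), 20, 90).astype(int)
    df["age"] = age
    df["onset_class"] = np.where(age <= 45, "early", "late")

    n_sequenced = min(config.n_sequenced, n)  # small cohorts: sequence all
    n_seq_noncarrier = max(0, n_sequenced - int(is_carrier.sum()))
    noncarrier_idx = np.flatnonzero(~is_carrier)
    seq_idx = set(np.flatnonzero(is_carrier).tolist())
    seq_idx |= set(rng.choice(noncarrier_idx, size=n_seq_noncarrier, replace=False).tolist())
    sequenced = np.array([i in seq_idx for i in range(n)])

    for flag, rate in (("CDH1_mut", config.cdh1_rate), ("RHOA_mut", config.rhoa_rate),
                       ("TP53_mut", config.tp53_rate)):
        draws = rng.random(n) < rate
        if config.mutual_exclusivity and flag in ("CDH1_mut", "RHOA_mut"):
            draws = draws & ~is_carrier
        col = pd.array([bool(d) if s else pd.NA for d, s in zip(draws, sequenced)],
                       dtype="boolean")
        df[flag] = col
    cin = rng.random(n) < config.cin_rate
    df["CIN"] = pd.array([bool(c) if s else pd.NA for c, s in zip(cin, sequenced)],
                         dtype="boolean")
    df["hpylori"] = rng.random(n) < 0.55
    df["EBV"] = rng.random(n) < 0.03
    df["MSI"] = rng.random(n) < 0.05
    df["metastasis"] = rng.random(n) < 0.3

    h0 = math.log(2) / config.baseline_median_months
    log_h = np.full(n, math.log(h0))
    log_h += np.where(is_carrier, math.log(config.fusion_hazard_ratio), 0.0)
    for cov, hr in config.covariate_hazard_ratios:
        if cov in df.columns:
            flags = df[cov].fillna(False).to_numpy(dtype=bool)
            log_h += np.where(flags, math.log(hr), 0.0)
    t_event = rng.exponential(1.0, n) / np.exp(log_h)
    censor = np.full(n, float(config.censor_time))
    if config.dropout_fraction > 0:
        drop = rng.random(n) < config.dropout_fraction
        censor = np.where(drop, rng.uniform(0, config.censor_time, n), censor)
    observed = np.minimum(t_event, censor)
    df["survival_months"] = np.round(observed, 2)
    df["event"] = t_event <= censor
    return df
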