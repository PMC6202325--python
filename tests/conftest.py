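"""Shared fixtures: hand-built transcript models and a small synthetic bundle."""

from __future__ import annotations

import numpy as np
import pytest

from dgcfusion.annotation_io import GenomeSequence, TranscriptModel
from dgcfusion.simulate import (
    FusionSpec,
    SimulationConfig,
    simulate_expression,
    simulate_fusions,
    simulate_reference,
)


@pytest.fixture
def two_exon_plus() -> TranscriptModel:
    """Plus-strand toy: exons 101-200 and 301-400, CDS 151-200 + 301-350.

    Transcript length 200; CDS occupies transcript coordinates 51..150.
    """
    return TranscriptModel(
        gene_id="TOY1", gene_name="TOY1", transcript_id="TOY1.t1",
        contig="c1", strand="+", exons=((101, 200), (301, 400)),
        cds_start=51, cds_end=150,
    )


@pytest.fixture
def two_exon_minus() -> TranscriptModel:
    """Same genomic intervals on the minus strand."""
    return TranscriptModel(
        gene_id="TOY2", gene_name="TOY2", transcript_id="TOY2.t1",
        contig="c1", strand="-", exons=((101, 200), (301, 400)),
        cds_start=51, cds_end=150,
    )


@pytest.fixture
def anxa2_like() -> TranscriptModel:
    """Minus-strand five-exon model with exon 4 starting at g.60,656,628.

    Intron 4 (transcript orientation) spans g.60,656,500-60,656,627 and
    therefore contains the DNA-level breakpoint g.60,656,550.
    """
    return TranscriptModel(
        gene_id="ANXA2L", gene_name="ANXA2L", transcript_id="ANXA2L.t1",
        contig="chr15", strand="-",
        exons=(
            (60_656_400, 60_656_499),  # tx exon 5
            (60_656_628, 60_656_699),  # tx exon 4
            (60_656_800, 60_656_849),  # tx exon 3
            (60_656_900, 60_656_949),  # tx exon 2
            (60_657_000, 60_657_099),  # tx exon 1
        ),
        cds_start=31, cds_end=330,
    )


@pytest.fixture
def cldn18_like() -> TranscriptModel:
    """Plus-strand model whose exon 5 contains g.137,749,947 (cryptic site)."""
    return TranscriptModel(
        gene_id="CLDN18L", gene_name="CLDN18L", transcript_id="CLDN18L.t1",
        contig="chr3", strand="+",
        exons=(
            (137_749_000, 137_749_099),
            (137_749_200, 137_749_299),
            (137_749_400, 137_749_499),
            (137_749_600, 137_749_699),
            (137_749_900, 137_749_999),  # exon 5
        ),
        cds_start=51, cds_end=400,
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """Seeded synthetic reference + fusions + expression, shared per session."""
    config = SimulationConfig(seed=7)
    genome, models, domains = simulate_reference(config)
    candidates, truths = simulate_fusions(config, genome, models)
    return config, genome, models, domains, candidates, truths


@pytest.fixture(scope="session")
def discovery_config():
    """Discovery-set-like conditions: 80 samples, one carrier per fusion."""
    return SimulationConfig(
        seed=11,
        n_samples=80,
        fusion_specs=(FusionSpec("G01", "G02", 1, "exonic", "in_frame"),),
        n_sequenced=80,
    )
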