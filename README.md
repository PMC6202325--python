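# dgcfusion

Fusion-transcript annotation and cohort statistics for diffuse gastric
cancer (DGC) transcriptomics.

Recurrent gene fusions whose 3' partner contributes a RhoGAP or PAP2
protein domain define an aggressive molecular subgroup of DGC.  Finding
them downstream of a fusion caller takes a chain of small, error-prone
steps: mapping DNA-level rearrangement breakpoints onto spliced
transcripts, deciding whether the chimeric transcript keeps the 3'
partner's open reading frame, checking which protein domains survive the
junction, confirming the carrier overexpresses the 3' partner's exons
downstream of the breakpoint, and relating carrier status to driver
mutations and survival across a cohort.  `dgcfusion` implements that
chain as a tested library for bioinformaticians and biostatisticians
working with fusion candidate tables (deFuse-style TSV or BEDPE), gene
models (GTF), and clinical cohort tables.

## What it computes

**Reading-frame classification.** With `n₅` retained coding bases from
the 5' partner and the first retained base at offset `d₃` (1-based)
within the 3' partner's CDS, the 3' open reading frame continues in its
native frame iff

    n₅ ≡ d₃ − 1  (mod 3)

Candidates are classified `in_frame`, `frameshift`, `promoter_swap`
(breakpoint upstream of the 5' CDS with an intact 3' ORF), `non_coding`,
or `junction_stop` (phase-congruent but the hybrid junction codon is a
stop).  Every call is cross-checked internally by translating the fused
cDNA and requiring the native 3' protein suffix to reappear without a
premature stop.  Domain retention demands full containment of the
domain's amino-acid interval in a retained span; partial overlap is
reported as truncated, never retained.

**Expression imbalance.** Exon-level FPKM is log2(x+1)-transformed and
gene-centered; a breakpoint at exon *k* is scored as
`mean(exons ≥ k) − mean(exons < k)` in the carrier, standardised (z)
against the same contrast in all other samples.

**Cohort layer.** Prevalence/recurrence counting, uncorrected Pearson
chi-square, Fisher's exact test and the Wilcoxon rank-sum test on 2×2 and
group comparisons; Kaplan–Meier estimation with log–log confidence
intervals, the Mantel–Haenszel log-rank test, Cox proportional-hazards
regression (Newton–Raphson on the partial likelihood, Efron ties), and
the Schoenfeld required-events formula

    d = (z₁₋α/₂ + z₁₋β)² / (p(1−p) · ln²HR).

The statistical machinery is implemented from first principles (scipy is
used only for distribution lookups); external survival/statistics
packages appear in the test suite as independent oracles.

**Synthetic data.** A seeded generator produces every input with known
ground truth: a genome with coding genes on both strands, GTF gene
models, domain tables, fusion candidates whose true frame class is
planted by construction, exon matrices with 3'-of-breakpoint
overexpression in carriers, and cohorts with mutually exclusive mutation
flags and proportional-hazards survival.

## Worked example

Survival analysis of a simulated cohort in the package's default
geometry — 384 tumors, 17 fusion carriers, planted carrier hazard ratio
2.8, exponential baseline with median 94.6 months, administrative
censoring at 96 months (`examples/04_survival_analysis.py`):

```
median survival, fusion-positive (n=17): 36.2 months
median survival, fusion-negative (n=367): not reached
log-rank chi-square = 16.73, P = 0.0000
Cox hazard ratio = 2.88 [95% CI 1.69-4.89], Wald P = 0.0001 (planted HR: 2.8)
```

The fitted hazard ratio (2.88) recovers the planted 2.8 within sampling
noise; the carrier group's shorter median survival and the small log-rank
P reflect the planted adverse effect.  The other examples cover breakpoint
annotation (`01`), expression imbalance (`02` — carrier z = 8.2 and
outlier rank 1 of 80 under a +3 log2-unit planted effect), cohort 2×2
statistics from printed counts (`03`), sample-size planning (`04`/`05` —
128 events, 384 tumors at an event rate of 1/3), and the full configured
pipeline (`06`).

A thin CLI wraps the same functions:

```bash
dgcfusion simulate --seed 7 --outdir sim/
dgcfusion annotate --fasta sim/genome.fa --gtf sim/genes.gtf \
    --domains sim/domains.tsv --breakpoints sim/candidates.tsv --out ann.tsv
dgcfusion run --config config.yaml
```

## Layout

- `src/dgcfusion/annotation_io.py` — FASTA/GTF/domain I/O, genomic ↔ transcript coordinates
- `src/dgcfusion/fusion_frame.py` — chimeric transcript construction, frame classification, domain retention
- `src/dgcfusion/candidate_intake.py` — candidate parsing, spanning-read filter, gene-pair collapsing, caller consensus
- `src/dgcfusion/expression.py` — gene centering, imbalance z-scores, outlier ranks
- `src/dgcfusion/cohort.py` — prevalence, recurrence, chi-square / Fisher / Wilcoxon
- `src/dgcfusion/survival.py` — Kaplan–Meier, log-rank, Cox (Efron ties), sample-size planning
- `src/dgcfusion/simulate.py` — seeded synthetic-data generator
- `src/dgcfusion/pipeline.py`, `cli.py` — configured end-to-end runs

See `docs/methods.md` for the modelling assumptions and numerical choices.
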