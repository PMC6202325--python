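# Methods

This note records the models, conventions and numerical choices behind
`dgcfusion`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and breakpoint semantics

All genomic coordinates are 1-based inclusive.  For minus-strand
transcripts, transcript coordinate 1 is the genomically 3'-most base;
introns are numbered in transcript orientation (intron *i* follows exon
*i*).  A breakpoint pair carries one coordinate per partner: the **last**
transcribed base retained from the 5' gene and the **first** retained
base of the 3' gene.

DNA-level (genomic) breakpoints are resolved to mRNA breakpoints before
any frame arithmetic: an intronic 5'-side position maps to the last base
of the preceding exon, an intronic 3'-side position to the first base of
the following exon, both in transcript orientation.  Exonic DNA
breakpoints are treated as cryptic junctions and used as-is — the
biological precedent is a cryptic splice donor inside an exon joining
directly to the 3' partner's acceptor.  The mapping is idempotent on
exonic positions.

Where a gene has several transcript models, the canonical transcript is
the one with the longest CDS (ties break on the lexicographically
smallest transcript id).  This is a package convention — fusion studies
rarely state the isoform anchoring their exon/amino-acid numbering — and
can be overridden by supplying a single-model dictionary.

## Frame classification

Let `n₅` be the number of retained 5'-partner coding bases and `d₃` the
1-based offset of the first retained base within the 3' CDS.  The
decision chain is:

1. breakpoint upstream of the 5' CDS **and** the 3' CDS fully retained →
   `promoter_swap` (the 3' ORF rides on the 5' promoter);
2. 5' breakpoint beyond the 5' stop, or 3' breakpoint beyond the 3' stop
   → `non_coding`;
3. otherwise `in_frame` iff `n₅ ≡ d₃ − 1 (mod 3)` (when the 3'
   breakpoint falls in the 3' gene's 5'UTR, the retained UTR linker
   counts toward the phase: in-frame iff `n₅ + linker ≡ 0 (mod 3)`);
4. a phase-congruent junction whose hybrid codon (or retained-UTR
   linker) encodes a stop is `junction_stop`, kept distinct from
   `frameshift` because the phase information is real;
5. everything else is `frameshift`.

Every annotation also translates the fused cDNA from the 5' CDS start
and demands that an `in_frame` call recover the 3' partner's native
protein suffix (up to the number of completely retained native codons)
with no premature stop; a disagreement raises an internal-consistency
error rather than silently preferring either route.

Retained amino-acid spans for in-frame fusions are `[1, ⌊n₅/3⌋]` on the
5' side and `[b, L₃]` on the 3' side, where `b` is the first *complete*
native codon at or after `d₃` and `L₃` the 3' protein length; the hybrid
junction residue (non-zero phase) belongs to neither span and is
reported separately.  A protein domain is **retained** only when its
interval is fully contained in a span; overlap without containment is
reported as truncated.  Class labels ("RhoGAP-domain fusion",
"PAP2-domain fusion") fire when a domain of that name is retained on
either side.

Fusions are identified at the (sample, ordered gene pair) level;
distinct nearby mRNA breakpoints of one pair are isoforms of a single
fusion for recurrence counting, because caller breakpoint estimates for
the same event differ by a few bases.  The read-support filter keeps
candidates with strictly more than 3 spanning reads (configurable).
Candidates whose partners are same-strand neighbours within 100 kb can
be flagged as possible read-through transcription; the flag is
informational and never auto-drops a candidate, since no principled
distance cutoff exists.

## Expression imbalance

Exon-level FPKM spans orders of magnitude, so values are transformed to
log2(x+1) before per-exon (gene-centred) mean removal; a config flag
switches to linear centering.  The breakpoint score for a carrier at
3'-gene exon *k* is the mean centred value over exons ≥ *k* minus the
mean over exons < *k*; the null distribution is the same contrast in
every other sample, giving `z = (score − null mean)/null sd`.  When the
null has zero spread the z-score is reported as undefined rather than
infinite.  Gene-level expression for outlier ranking is the
exon-length-weighted mean FPKM; ranks are dense and descending (ties
share the better rank).

The carrier's z-score is contaminated when several carriers of the same
fusion sit in the null; single-carrier scenarios (discovery-set
geometry, 80 samples) are therefore the clean setting for the planted
+3 log2-unit recovery property, which is how the tests frame it.

## Cohort statistics

Percentages are rounded half-up to one decimal.  The 2×2 association
test is the uncorrected Pearson chi-square — the variant that reproduces
the reference P values this package's fixtures encode (0.006, 0.08,
0.042); the Yates-corrected variant is available behind a flag and does
not reproduce them.  "Agreement to printed precision" in the tests means
within one unit of the last printed digit, since printed values may be
rounded or truncated.  Fisher's exact two-sided p sums hypergeometric
probabilities no larger than the observed table's (with a 1e-9 relative
guard against floating-point ties).  The Wilcoxon rank-sum test uses the
normal approximation with tie correction and a ½ continuity correction;
exact enumeration is available for small tie-free samples.  Mutation
flags missing for unsequenced samples are excluded test-wise, so each
2×2 is built over the informative ("sequenced") subset only.

One documented inconsistency in the reference counts this package's
examples mirror: a fusion present in 2 of 384 samples is 0.5%, not the
0.1% sometimes printed alongside it; `dgcfusion` always reports the
computed percentage.

## Survival

Kaplan–Meier is the product-limit estimator with Greenwood variance.
The median is the earliest time with S(t) ≤ 0.5 ("not reached" = ∞ when
the curve never crosses); its confidence interval is read off the
pointwise log–log (Brookmeyer–Crowley style) band — a package choice, as
is the log–log transform itself.  The log-rank test is Mantel–Haenszel:
U²/V over distinct event times with hypergeometric variances.

Cox regression maximises the partial likelihood by Newton–Raphson with
step-halving; covariates are mean-centred internally for conditioning
(slopes unchanged).  Efron tie handling is the default — monthly
survival times tie often and Efron is the less biased standard — with
Breslow behind a flag.  Convergence requires the maximum score component
below 1e-8 (at most 50 iterations); when step-halving stalls at float
precision the fit is accepted only if the residual score is negligible
relative to the log-likelihood, otherwise it errors.  Monotone
likelihoods (perfect separation, detected as |β| running past 15) are
flagged with a warning and the clipped coefficients returned.
Confidence intervals and p-values are Wald (`exp(β ± 1.96·SE)`); the
likelihood-ratio statistic is also reported.  A two-subject, two-event,
binary-covariate dataset is always separated — its partial likelihood is
monotone — so the smallest closed-form test case is a three-subject
configuration whose score equation solves to β = −ln 2 ∕ 2.

Sample-size planning uses the Schoenfeld required-events formula
(rounded half-up) and `ceil(events / event rate)` for the cohort size.
At α = 0.05 two-sided, power 0.8, 15% exposure and HR 2 this gives 128
events, hence 384 subjects at an event rate of one third.

## Synthetic-data generator

One integer seed drives everything; each stage (reference = 0, fusions
= 1, expression = 2, cohort = 3) derives its own child stream
(`default_rng([seed, stage])`), so re-running a single stage is
reproducible regardless of which others ran.

*Reference.* Non-overlapping genes on one contig, both strands, each
with a 5'UTR, an ATG-initiated stop-free CDS divisible by 3, and a
3'UTR.  Exons 60–240 nt, introns 60–300 nt, 4–8 exons per gene.  One
gene carries a "RhoGAP" and another a "PAP2" domain in the C-terminal
half so that 3'-retaining fusions keep them.

*Fusions.* The requested frame class is realised by construction:
exonic (cryptic) breakpoints are drawn with the needed phase congruence
directly; intronic breakpoints search exon-boundary pairs with matching
phases and fall back to cryptic junctions in the rare geometry with no
phase-compatible boundary pair.  Junction codons that would introduce a
stop are re-drawn for in-frame plants.  Carriers get 4–40 spanning
reads; decoy candidates (random pairs) get ≤ 3 and are removed by the
intake filter.  Default geometry: three in-frame fusions with 13/2/2
carriers plus one frameshift plant in 384 samples.

*Expression.* Per-exon baseline log2 FPKM is Normal(gene mean, σ = 0.5)
with gene means uniform on [3, 7]; carriers receive the configured
effect (default +3 log2-units) on the 3' partner's exons at and
downstream of the first retained exon; values are exponentiated back to
FPKM, hence never negative.

*Cohort.* Fusion flags come from the planted truth.  Mutation flags
exist only in a "sequenced" subset (all carriers plus sampled
non-carriers, default total 229, capped at the cohort size) and are
drawn at rates 31.1% (CDH1), 15.1% (RHOA) among eligible samples; with
the exclusivity switch on (default), carriers never receive CDH1/RHOA
mutations.  Ages are Normal(40, 8) for carriers and Normal(56, 10)
otherwise, clipped to [20, 90], so carriers skew younger.  Survival is
exponential with baseline median 94.6 months and multiplicative hazards
(fusion HR 2.8; CIN 2.3 and CDH1 1.8 by default), administratively
censored at 96 months — roughly half the cohort experiences an event —
plus an optional uniform-dropout fraction (default 0).  The censoring
scheme is a modelling choice; no reference censoring distribution
exists.

What the generator does **not** emulate: read-level data (no FASTQ or
alignment noise), sequencing-error or coverage models, copy-number
structure, correlated expression between genes, non-proportional
hazards, or informative censoring.  Passing tests therefore demonstrate
correctness of the analysis chain under its stated model, not robustness
to the full messiness of real RNA-seq cohorts.

## Problem sizes used in the automated checks

Oracle equivalence of the frame classifier runs on 1,000 random
coding-region breakpoint pairs.  Cox recovery averages 200 simulated
cohorts (n = 384, 17 exposed); log-rank null calibration uses 500
simulations (n = 120); expression recovery and null calibration use 200
discovery-sized simulations each (n = 80, 4 genes); end-to-end truth
recovery runs 15 seeded pipeline rounds (n = 96).  These sizes give the
binomial/KS margins the assertions need while keeping the whole suite
around a minute on one core.

## Known limitations

GTF parsing covers the GFF2 gene_id/transcript_id dialect only (no
GFF3, no alt contigs).  The frame classifier assumes one canonical
isoform per gene.  No multiple-testing correction is applied across the
cohort report.  Cox regression offers no time-varying covariates,
stratification, or proportionality diagnostics.  Reciprocal fusions and
read-level evidence are out of scope; splice-site strength of cryptic
junctions is not scored.
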