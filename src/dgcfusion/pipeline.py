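"""End-to-end orchestration: intake -> annotation -> expression -> cohort
statistics -> survival, driven by a validated configuration.

The report bundle mirrors the layout of a fusion-study results section: an
annotation table (frame status, retained spans, domains, class labels), a
recurrence/prevalence table, mutual-exclusivity tests against driver
mutation flags, Kaplan-Meier / log-rank / Cox results for the fusion
carrier group, and a machine-readable JSON summary.  Every number in the
summary is produced by a library operation; the report layer only formats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dgcfusion import annotation_io, candidate_intake, cohort as cohort_mod
from dgcfusion import expression as expr_mod
from dgcfusion import fusion_frame, survival as surv_mod

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger("dgcfusion")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    genome: str
    gene_models: str
    domains: str
    candidates: str
    cohort: str | None = None
    exon_matrix: str | None = None
    outdir: str = "dgcfusion_out"
    spanning_read_threshold: int = 3
    recurrence_threshold: int = 2
    chi_square_correction: bool = False
    cox_ties: str = "efron"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for attr in ("genome", "gene_models", "domains", "candidates"):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise ConfigError(f"{attr}: path does not exist: {path}")
        for attr in ("cohort", "exon_matrix"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{attr}: path does not exist: {path}")
        if self.spanning_read_threshold < 0:
            raise ConfigError("spanning_read_threshold must be >= 0")
        if self.recurrence_threshold < 1:
            raise ConfigError("recurrence_threshold must be >= 1")
        if self.cox_ties not in ("efron", "breslow"):
            raise ConfigError(f"unknown cox_ties {self.cox_ties!r}")


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are reported by name; defaults are filled and echoed to
    the log.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    missing = {"genome", "gene_models", "domains", "candidates"} - set(raw)
    if missing:
        raise ConfigError(f"missing required config key(s): {sorted(missing)}")
    config = RunConfig(**raw)
    config.validate()
    log.info("run config: %s", dataclasses.asdict(config))
    return config


def _annotation_row(event, ann) -> dict:
    return {
        "sample_id": event.sample_id,
        "gene5": event.gene5,
        "gene3": event.gene3,
        "n_isoforms": len(event.isoforms),
        "spanning_reads": event.spanning_reads,
        "mrna_bp5": ann.mrna_bp5,
        "mrna_bp3": ann.mrna_bp3,
        "frame_status": ann.frame_status.value,
        "n5_cds": ann.n5_cds,
        "d3_offset": ann.d3_offset,
        "aa5_span": f"{ann.aa5_span[0]}-{ann.aa5_span[1]}" if ann.aa5_span else "",
        "aa3_span": f"{ann.aa3_span[0]}-{ann.aa3_span[1]}" if ann.aa3_span else "",
        "retained_domains": ";".join(f"{n}({s})" for n, s in ann.retained_domains),
        "class_labels": ";".join(sorted(ann.class_labels)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the JSON-ready summary dict.

    Writes ``annotations.tsv``, ``recurrence.tsv``, optional
    ``expression_imbalance.tsv``, and ``summary.json`` under the
    configured output directory.  Deterministic for fixed inputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage: load reference")
    genome = annotation_io.load_genome(config.genome)
    models = annotation_io.load_gene_models(config.gene_models)
    domains = annotation_io.load_domain_table(config.domains)
    canonical = {}
    by_gene: dict[str, list] = {}
    for m in models.values():
        by_gene.setdefault(m.gene_name, []).append(m)
    for gene, group in by_gene.items():
        model = annotation_io.select_canonical(group)
        canonical[model.transcript_id] = model

    log.info("stage: candidate intake")
    candidates = candidate_intake.read_candidates(config.candidates)
    filtered = candidate_intake.filter_by_spanning_reads(
        candidates, config.spanning_read_threshold
    )
    events = candidate_intake.collapse_by_gene_pair(filtered)

    log.info("stage: annotation (%d events)", len(events))
    rows = []
    annotations = []
    for event in events:
        pair = fusion_frame.BreakpointPair(
            gene5=event.gene5, gene3=event.gene3,
            contig5="", contig3="",
            genomic_bp5=event.isoforms[0][0], genomic_bp3=event.isoforms[0][1],
        )
        # contigs were validated at intake; re-derive from the models
        pair = dataclasses.replace(
            pair,
            contig5=next(m.contig for m in canonical.values() if m.gene_name == event.gene5),
            contig3=next(m.contig for m in canonical.values() if m.gene_name == event.gene3),
        )
        ann = fusion_frame.annotate_candidate(
            pair, canonical, domains, genome, sample_id=event.sample_id
        )
        annotations.append((event, ann))
        rows.append(_annotation_row(event, ann))
    ann_df = pd.DataFrame(rows)
    ann_df.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    in_frame = [
        (e, a) for e, a in annotations
        if a.frame_status is fusion_frame.FrameStatus.IN_FRAME
    ]
    sample_counts: dict[str, int] = {}
    for e, _ in in_frame:
        key = f"{e.gene5}-{e.gene3}"
        sample_counts[key] = sample_counts.get(key, 0) + 1
    recurrent = cohort_mod.find_recurrent(sample_counts, config.recurrence_threshold)
    rec_df = pd.DataFrame(
        sorted(
            ({"fusion": k, "n_samples": v, "recurrent": k in recurrent}
             for k, v in sample_counts.items()),
            key=lambda r: (-r["n_samples"], r["fusion"]),
        )
    )
    rec_df.to_csv(outdir / "recurrence.tsv", sep="\t", index=False)

    carriers = sorted({
        e.sample_id for e, _ in in_frame if f"{e.gene5}-{e.gene3}" in recurrent
    })

    summary: dict = {
        "n_candidates": len(candidates),
        "n_above_read_threshold": len(filtered),
        "n_events": len(events),
        "n_in_frame_events": len(in_frame),
        "fusion_sample_counts": sample_counts,
        "recurrent_fusions": sorted(recurrent),
        "carrier_samples": carriers,
        "frame_status_counts": {
            s.value: sum(1 for _, a in annotations if a.frame_status is s)
            for s in fusion_frame.FrameStatus
        },
        "class_label_counts": {
            label: sum(1 for _, a in annotations if label in a.class_labels)
            for label in ("RhoGAP-domain fusion", "PAP2-domain fusion")
        },
    }

    if config.exon_matrix:
        log.info("stage: expression imbalance")
        matrix = expr_mod.load_exon_matrix(config.exon_matrix)
        centered = expr_mod.center_by_gene(matrix)
        expr_rows = []
        for e, a in in_frame:
            if e.sample_id not in matrix.columns:
                continue
            sub = matrix.xs(e.gene3, level="gene", drop_level=False)
            t3_exon = _first_retained_exon(a, canonical, e.gene3)
            n_exons = sub.index.get_level_values("exon_index").max()
            res_entry = {
                "sample_id": e.sample_id, "gene3": e.gene3,
                "breakpoint_exon": t3_exon,
            }
            if 1 < t3_exon <= n_exons:
                res = expr_mod.breakpoint_imbalance_score(
                    centered, e.gene3, t3_exon, e.sample_id
                )
                res_entry.update(score=res.score, z=res.z)
            gene_expr = expr_mod.gene_level_expression(matrix, e.gene3)
            rank, n = expr_mod.outlier_rank(gene_expr, e.sample_id)
            res_entry.update(outlier_rank=rank, n_samples=n)
            expr_rows.append(res_entry)
        expr_df = pd.DataFrame(expr_rows)
        expr_df.to_csv(outdir / "expression_imbalance.tsv", sep="\t", index=False)
        summary["expression"] = expr_rows

    if config.cohort:
        log.info("stage: cohort statistics and survival")
        cohort = cohort_mod.load_cohort(config.cohort)
        carrier_mask = cohort.index.isin(carriers)
        n_total = len(cohort)
        count = int(carrier_mask.sum())
        summary["prevalence"] = {
            "count": count, "n": n_total,
            "percent": cohort_mod.round_percent(count, n_total) if n_total else 0.0,
        }
        cohort = cohort.assign(_fusion_positive=carrier_mask)
        exclusivity = {}
        for flag in ("CDH1_mut", "RHOA_mut"):
            if flag in cohort.columns:
                rep = cohort_mod.mutual_exclusivity_report(
                    cohort, ["_fusion_positive"], flag
                )
                t = rep["table"]
                exclusivity[flag] = {
                    "table": [t.a, t.b, t.c, t.d],
                    "chi_square": rep["chi_square"],
                    "chi_square_p": rep["chi_square_p"],
                    "fisher_p": rep["fisher_p"],
                    "mutated_fraction_fusion_negative":
                        rep["mutated_fraction_fusion_negative"],
                }
        summary["mutual_exclusivity"] = exclusivity

        if "survival_months" in cohort.columns and "event" in cohort.columns:
            time = cohort["survival_months"].to_numpy(dtype=float)
            event = cohort["event"].fillna(False).to_numpy(dtype=bool)
            group = carrier_mask
            surv_block: dict = {}
            if 0 < group.sum() < len(cohort) and event.any():
                km_pos = surv_mod.km_estimate(time[group], event[group])
                km_neg = surv_mod.km_estimate(time[~group], event[~group])
                stat, p = surv_mod.log_rank(time, event, group)
                surv_block.update(
                    median_fusion_positive=_fmt_median(km_pos.median),
                    median_fusion_negative=_fmt_median(km_neg.median),
                    log_rank_chi_square=stat, log_rank_p=p,
                )
                uni = surv_mod.cox_fit(
                    time, event, group.astype(float)[:, None],
                    names=("fusion",), ties=config.cox_ties,
                )
                surv_block["univariate"] = _cox_block(uni)
                multi_cols = [c for c in ("CIN", "CDH1_mut") if c in cohort.columns]
                if multi_cols:
                    sub = cohort[multi_cols].notna().all(axis=1)
                    x = np.column_stack(
                        [group[sub.to_numpy()].astype(float)]
                        + [cohort.loc[sub, c].astype(bool).to_numpy(dtype=float)
                           for c in multi_cols]
                    )
                    try:
                        multi = surv_mod.cox_fit(
                            time[sub.to_numpy()], event[sub.to_numpy()], x,
                            names=("fusion", *multi_cols), ties=config.cox_ties,
                        )
                        surv_block["multivariable"] = _cox_block(multi)
                        surv_block["multivariable_n"] = int(sub.sum())
                    except surv_mod.SurvivalError as exc:
                        surv_block["multivariable_error"] = str(exc)
            summary["survival"] = surv_block

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("report written to %s", outdir)
    return summary


def _first_retained_exon(ann, canonical, gene3: str) -> int:
    model = next(m for m in canonical.values() if m.gene_name == gene3)
    locus = annotation_io.genomic_to_transcript(model, ann.mrna_bp3)
    t3 = locus.position
    total = 0
    for i, (s, e) in enumerate(model.exons_tx_order, start=1):
        total += e - s + 1
        if t3 <= total:
            return i
    return len(model.exons)


def _fmt_median(m: float):
    return "not reached" if m == surv_mod.NOT_REACHED else m


def _cox_block(res) -> dict:
    return {
        name: {
            "coef": float(res.coef[i]),
            "hazard_ratio": float(res.hazard_ratio[i]),
            "ci": [float(res.ci_lower[i]), float(res.ci_upper[i])],
            "p": float(res.wald_p[i]),
        }
        for i, name in enumerate(res.covariates)
    }
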