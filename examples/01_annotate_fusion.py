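"""Annotate a fusion breakpoint pair: frame status, spans, retained domains.

Builds a small synthetic reference with a planted intronic (DNA-level)
breakpoint pair, resolves it to mRNA coordinates, and prints the full
annotation.  An in-frame call means the 3' partner's open reading frame
continues in its native frame after the junction; the retained-domain list
shows which functional domains (e.g. RhoGAP) survive the fusion.
"""

from dgcfusion import annotate_candidate
from dgcfusion.simulate import SimulationConfig, simulate_fusions, simulate_reference

config = SimulationConfig(seed=7)
genome, models, domains = simulate_reference(config)
candidates, truths = simulate_fusions(config, genome, models)

truth = truths[1]  # a fusion planted with intronic DNA-level breakpoints
print(f"fusion {truth.name}: DNA-level breakpoints "
      f"{truth.pair.genomic_bp5} / {truth.pair.genomic_bp3} ({truth.pair.provenance})")

ann = annotate_candidate(truth.pair, models, domains, genome)
print(f"resolved mRNA breakpoints: {ann.mrna_bp5} / {ann.mrna_bp3}")
print(f"frame status:     {ann.frame_status.value}")
print(f"retained 5' span: aa {ann.aa5_span}")
print(f"retained 3' span: aa {ann.aa3_span}")
print(f"retained domains: {ann.retained_domains}")
print(f"class labels:     {sorted(ann.class_labels)}")
print(f"fusion protein:   {len(ann.fusion_protein)} aa "
      f"({ann.fusion_protein[:25]}...)")
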