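"""Two-condition X vs autosome comparison with an injected compensation defect.

The mutant condition multiplies X-linked transcription rates by 1.6 and
autosomal rates by 0.9 (the hallmark of losing condensin-mediated X
repression).  The pipeline recovers both medians from the read data,
reports per-chromosome-class read fractions, and applies the
alternative normalisation based on the autosomal read share.
"""

from nascentx.dosage import (
    ConditionPair,
    autosomal_scaling_factor,
    chromosome_read_fractions,
    summarize_by_class,
)
from nascentx.metrics import gene_body_expression
from nascentx.pipeline import run_tss_stage
from nascentx.signal import MappabilityTrack
from nascentx.simulate import SimConfig, generate_genome, pileups_for_condition

cfg = SimConfig(seed=3)  # full default geometry: X ~ 1/7 of expressed mass
genome, annotations, truth = generate_genome(cfg)
mapp = MappabilityTrack.all_mappable(cfg.chromosomes)

expr = {}
fractions = {}
for condition, seed in (("control", 31), ("mutant", 32)):
    tracks = pileups_for_condition(annotations, truth, cfg, condition, seed=seed)
    stage = run_tss_stage(tracks["groseq"], tracks["tap_plus"],
                          tracks["tap_minus"], annotations, mapp)
    expr[condition] = {
        g.gene_id: gene_body_expression(g, stage.groseq_rpkm, mapp)[0]
        for g in annotations
    }
    fractions[condition] = chromosome_read_fractions(tracks["groseq"], cfg.chrom_class)
    print(f"{condition}: autosomal read fraction "
          f"{fractions[condition]['autosome']:.3f}")

pair = ConditionPair("mutant", "control", expr["mutant"], expr["control"])
summary = summarize_by_class(pair, annotations, min_body=1.0)
print(summary.to_string(index=False))

factor = autosomal_scaling_factor(
    fractions["mutant"]["autosome"], fractions["control"]["autosome"]
)
print(f"autosomal scaling factor (mutant/control read share): {factor:.3f}")
# Median fold changes near 1.6 (X) and 0.9 (autosomes) recover the
# injected defect; dividing mutant expression by the scaling factor
# re-centres autosomes at ~1 under the alternative normalisation.
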