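"""Promoter-proximal pausing and elongation-density metrics per gene.

Simulates one cohort with a strong planted 5' pause (density multiplier
8 over the first 50 bp downstream of the TSS) and one without, then
shows how the pausing ratio (mean signal in [TSS-50, TSS+100) over the
trimmed gene-body mean) separates them, and that the elongation density
index (last 75% over first 25% of the gene) stays near 1 when
polymerase density is uniform along the gene.
"""

import numpy as np

from nascentx.metrics import (
    elongation_density_index,
    gene_body_expression,
    pausing_ratio_5,
)
from nascentx.pipeline import run_tss_stage
from nascentx.signal import MappabilityTrack
from nascentx.simulate import SimConfig, generate_genome, pileups_for_condition

SMALL = dict(
    chromosomes={"chrX": 150_000, "chrI": 300_000},
    chrom_class={"chrX": "X", "chrI": "autosome"},
    n_genes={"chrX": 10, "chrI": 25},
    groseq_depth=400_000,
    tap_plus_depth=120_000,
    tap_minus_depth=30_000,
)

for label, mult in (("paused cohort (x8)", 8.0), ("unpaused cohort (x1)", 1.0)):
    cfg = SimConfig(seed=7, pause_mult=mult, **SMALL)
    genome, annotations, truth = generate_genome(cfg)
    mapp = MappabilityTrack.all_mappable(cfg.chromosomes)
    tracks = pileups_for_condition(annotations, truth, cfg, "control")
    stage = run_tss_stage(tracks["groseq"], tracks["tap_plus"],
                          tracks["tap_minus"], annotations, mapp)
    ratios, paused, edis = [], 0, []
    for g in annotations:
        call = stage.calls.get(g.gene_id)
        if call is None:
            continue
        body, _ = gene_body_expression(g, stage.groseq_rpkm, mapp)
        if body is None or body < 1.0:
            continue
        ratio, is_paused, _ = pausing_ratio_5(g, call, stage.groseq_rpkm, mapp, body)
        if ratio is not None:
            ratios.append(ratio)
            paused += is_paused
        edi, _ = elongation_density_index(g, call, stage.groseq_rpkm, mapp, annotations)
        if edi is not None:
            edis.append(edi)
    print(f"{label}:")
    print(f"  median 5' pausing ratio: {np.median(ratios):.2f}"
          f"   classified paused (ratio>=2, body>=1): {paused}/{len(ratios)}")
    print(f"  mean elongation density index: {np.mean(edis):.3f} (n={len(edis)})")
# A paused gene piles engaged polymerase just downstream of its start;
# the unpaused cohort sits near the x1 pausing baseline (~0.67 here
# because 50 of the 150 window bp lie upstream of initiation) and both
# cohorts elongate uniformly (EDI ~= 1).
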