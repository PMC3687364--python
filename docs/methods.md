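# Methods

## Coordinates and strand arithmetic

All internal coordinates are 0-based, half-open, on the forward reference
strand; GFF3 (1-based inclusive) is converted at the I/O boundary. A gene's
`wb_start`/`wb_stop` are its annotated 5′/3′-end *base positions* (so
`wb_start > wb_stop` on the minus strand). Strand-aware spans are built by a
single helper (`strand_span`) so that "50 bp upstream to 100 bp downstream"
means the same 150 bases on either strand; every window in the package is
expressed this way, which makes strand-mirror symmetry exact and testable.

The TSS search window follows the half-open form `[upstream_limit,
wb_start + 250)` on the plus strand and its exact mirror on the minus
strand. Whether the single base at distance 250 is inside the window is not
scientifically meaningful; the convention here is fixed, documented, and
mirror-symmetric.

## Signal model

Raw tracks are 5′-end pileups: each mapped read contributes one count at its
5′ base (BED start on the plus strand, end−1 on the minus strand), because
the 5′ end best marks the position of the engaged polymerase. Normalisation
divides by millions of uniquely mapped reads (both strands jointly), ×1000
for run-on tracks ("RPKM" — note this is a per-base quantity scaled by
1000/M reads, not a per-kilobase feature aggregate; the name follows field
usage) and ×1 for cap tracks (RPM).

Mappability is exact 30-mer uniqueness: a position is mappable iff the
30-mer starting there (reverse-complemented on the minus strand) occurs
exactly once among the 30-mers of both genome strands and contains no N.
This is a deterministic, slightly stricter surrogate for re-running an
aligner with mismatches; on the i.i.d.-random synthetic genomes the two
definitions coincide (almost every 30-mer is unique). Palindromic 30-mers
match both strands and are therefore never unique. Every regional average in
the package divides by the count of uniquely mappable bases only.

Moving averages use truncated edge windows (no padding): the window at index
i covers `[i − (w−1)//2, i + w//2]` clipped to the vector, so no zero signal
is invented at chromosome ends and output length equals input length.

## TSS calling

Corrected cap signal is TAP⁺ − TAP⁻ per base (RPM); negative values are
kept — subtraction is the only background correction. Z-scores are computed
per chromosome *and per strand* (cap signal is strand-specific; pooling
strands would mix two different background levels — `pool_strands` restores
pooled behaviour if wanted). The top `ceil(N × 5e−5)` values are excluded
from μ/σ (ties at the cut broken by (value, position) so the exclusion is
deterministic), but excluded positions still receive z-scores: they are
precisely the candidate start sites. A zero trimmed SD yields all-zero
z-scores plus a warning record. z₁₀ is the 10-bp moving average of z₁,
computed chromosome-wide; the search is then restricted to each gene's
window.

The caller scans candidates from the downstream end of the window upstream.
Continuity: a 200-bp window anchored at the candidate and extending
*downstream* (towards the gene) must keep a mappability-aware mean run-on
signal ≥ 1 RPKM; the first failure aborts the upstream extension, so a gap
in engaged-polymerase signal makes everything upstream of it unreachable.
Windows with no mappable base count as failures (no evidence of support).
Ties are broken towards the most downstream window and, within the winning
10-bp window (truncated at the search-window edge), towards the most
downstream base — conservative (shortest outron) and deterministic. Calls
landing more than 2 kb upstream of the annotated start carry a review flag;
a curated-override file (force/suppress per gene) replaces the by-eye
review steps of manual workflows.

Small-RNA starts (e.g. piRNA precursors) use a direct rule: the maximum
corrected cap signal within ±10 bp of the mature 5′ end, accepted when its
z₁ exceeds 3; ties go to the most upstream position. Multi-stage consensus:
genes called in ≥2 stages with all calls within 100 bp take the call with
the highest z₁₀; wider spreads keep per-stage calls unmerged.

## Per-gene metrics

Defaults follow the definitions in the README. Numerical conventions worth
noting:

- the 25%/75% split of the elongation density index floors the cut to a
  whole base; the index is excluded under any of three expression floors
  (<1 RPKM in the first 500 bp, the first 25%, or the last 75%) because
  low-count ratios are unstable;
- the mirror symmetry of the index is *not* a plain reciprocal under profile
  reversal — the 75/25 regions are asymmetric. The exact identity (tested)
  is: reversing the profile and complementing the split fraction inverts the
  index;
- pausing windows that overlap another gene's 3′-accumulation region
  [stop−250, stop+750) or sit within 300 bp of an opposite-strand call are
  flagged `neighbor_conflict` instead of being silently kept — an automatic
  stand-in for manual disambiguation;
- divergent maxima use 150-bp windows fully contained in [TSS−500, TSS+500)
  on both strands (windows may straddle the TSS); a zero antisense maximum
  returns `None` with a reason rather than a pseudocount, so summary
  denominators are explicit;
- every `None` carries a coded reason (`too_short`, `low_mappability`,
  `low_expression`, `neighbor_conflict`), keeping filter cascades auditable.

## Metagenes and heat maps

The 5000-position grid keeps 1500 bp unscaled at each end (effects localised
at gene boundaries survive averaging) and rescales the interior to 2000 bins
by *area-weighted* averaging — each bin averages the source bases overlapping
it, weighted by fractional overlap and restricted to mappable bases — so
uniform signal is preserved exactly and mass is conserved. Per-position
averages divide by the number of genes mappable at that position; positions
with no mappable gene are masked (NaN), and the 25-bp smoothing averages
over valid positions only. Heat-map bins sum profile signal per 100 grid
positions; bins with a zero sum in either track are masked rather than
pseudocounted.

## Dosage-compensation comparison

Fold-change summaries report n, median, mean ± SEM and the counts changed
≥1.5-fold in either direction, for mutant/control ratios over genes passing
the caller-chosen expression floor; the even-n median is the mean of the two
central values. The alternative normalisation divides mutant expression by
the ratio of autosomal read fractions between conditions (with the published
proportions 75.9%/85.7% this factor is 0.885 — note the source table prints
an inconsistent intermediate denominator; the proportions are taken as
primary). Significance testing is out of scope; a pass-through p-value
column hooks in externally computed values.

## The synthetic-data generator

The generator emulates the features the pipeline measures, with defaults as
the validated study conditions:

- **geometry** — X 400 kb / 44 genes, autosome 1.8 Mb / 256 genes. The X
  carries ~1/7 of the expressed mass, mirroring the real organism (the X is
  about a sixth of the genome, with autosomes holding ~86% of mapped reads).
  This matters quantitatively: with injected folds of 1.6 (X) and 0.9
  (autosomes), total library mass is conserved only when the X share is
  ≈ 0.14 (1.6·fx + 0.9·(1−fx) ≈ 1), which is what makes the per-gene folds
  recoverable after library-size normalisation. Chromosome lengths allow a
  mean per-gene footprint of ~6.8 kb (gap + outron tail + body + 3′ decay);
- **genes** — lengths uniform 1.5–8 kb on random strands, non-overlapping,
  with clearance reserved so every planted TSS lies inside its search
  window; expression rates log-normal (σ = 1);
- **outrons** — log-normal with median 260 bp and σ = 1.3 (heavy right tail
  to several kb), clipped to [20, 5000];
- **run-on density** — uniform over TSS→stop at the gene's rate, ×5 over the
  final 200 bp plus a 300-bp triangular decay downstream (3′ accumulation),
  optional ×m over the first 50 bp (promoter-proximal pause; default m=1),
  short antisense divergent transcripts initiating 75–150 bp upstream in 70%
  of genes, plus 2% uniform background; 2×10⁶ reads per condition,
  partitioned by multinomial sampling of rate-proportional masses so the
  condition folds act on rates, not post-hoc on counts;
- **cap reads** — 5×10⁵ TAP⁺ reads: 80% TSS spikes (95% within ±2 bp of the
  planted TSS, the rest jittered ±25 bp) and 20% uniform background; 10⁵
  TAP⁻ reads drawn from the background law only;
- **motifs** — TATATAAA planted with its 5′-most base 30 bp upstream of the
  TSS in half the promoters (with a 2-base CC guard just upstream, because a
  random TA there would create a second, shifted exact match that the
  most-upstream tie rule would report instead of the planted element), and
  TCATTC with its adenine at the TSS in half;
- **conditions** — "mutant" multiplies X rates ×1.6 and autosomal rates
  ×0.9.

**Pause fixtures use m = 8.** The classification window [TSS−50, TSS+100)
spans 50 bp upstream of initiation (≈ zero sense density), 50 paused bp and
50 body bp, so its expected ratio is (m+1)/3: m = 4 sits *below* the
paused threshold of 2 (expected 1.67), m = 8 sits comfortably above
(expected 3.0). The fixture therefore plants a strong pause; the threshold
itself is never tuned.

What the generator does *not* model: sequencing error, PCR duplicates,
mappability structure (random sequence is almost everywhere unique),
chromatin-dependent background, overlapping/nested genes, operonic
polycistrons, and trans-spliced leader sequences (only the positional
consequence — the outron — is modelled). Passing tests therefore demonstrate
the correctness of the measurement machinery under known ground truth, not
performance on real libraries, where background is structured and gene
density is higher.

## Problem sizes

The default dataset (two chromosomes, 2.2 Mb, 300 genes, 2×10⁶ run-on and
6×10⁵ cap reads per condition) runs the full pipeline in a few seconds per
condition and keeps the whole validation suite under a minute of compute;
these sizes were chosen so that per-gene medians have sampling error well
inside the tolerances being checked (e.g. median fold recovery to ±0.1).
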