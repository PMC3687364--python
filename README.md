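# nascentx

Analysis of nascent transcription from run-on sequencing in *C. elegans*-like
genomes: transcription start site (TSS) calling from capped-5′-end data,
engaged-polymerase metrics, metagene profiles, core-promoter motif scanning,
and X-versus-autosome dosage-compensation comparisons — all runnable end to
end on a built-in synthetic-data generator with known ground truth.

## The scientific problem

In nematodes, ~70% of mRNAs are trans-spliced: a spliced-leader RNA replaces
the transcript's native 5′ end, so the annotated gene start marks the
trans-splice acceptor site, not where RNA polymerase II actually initiated.
The stretch between the true TSS and the acceptor (the *outron*) is invisible
to mRNA-based methods. Nuclear run-on sequencing maps the 5′ ends of nascent
RNAs from engaged polymerase (GRO-seq); its capped-5′-end variant (GRO-cap)
enriches RNAs carrying a 5′ cap, with a TAP⁺/TAP⁻ treatment pair separating
genuine capped ends from background. Combining the two recovers true TSSs:
a cap-signal peak supported by *continuous* run-on signal back to the
annotated start.

The same data dissect dosage compensation: hermaphrodite X chromosomes are
transcriptionally halved by a condensin-like complex, and disrupting it
(e.g. an *sdc-2* mutant) raises X-linked nascent transcription ~1.6-fold
while autosomes drift slightly down (~0.9).

## Core method

For each chromosome and strand the background-corrected cap signal
`c = TAP⁺ − TAP⁻` (both RPM) is standardised:

    z₁(p) = (c(p) − μ) / σ

with μ, σ computed after discarding the top 0.005% of positions (the
strongest sites would otherwise inflate σ; they still receive z-scores), then
smoothed in a 10-bp moving window (z₁₀). For each eligible gene the caller
scans a window from 250 bp downstream of the annotated start upstream to the
nearest neighbouring transcript (opposite strand: its 5′ end; same strand:
its 3′ end + 100 bp), aborting at the first position where the 200-bp mean
run-on signal drops below 1 RPKM. The call is the highest-z₁ base inside the
best z₁₀ window, accepted above a stage-specific cutoff (4.5, 4.725, 4.764,
5.01).

Downstream metrics (all mappability-aware means of the RPKM run-on track):

- **gene body** — mean over the gene minus 300 bp at each end (genes ≥ 1.1 kb);
- **5′ pausing ratio** — mean over [TSS−50, TSS+100) ÷ body; *paused* if
  ratio ≥ 2 and body ≥ 1 RPKM;
- **3′ pausing ratio** — max 200-bp-window mean in [stop−250, stop+750) ÷ body;
- **elongation density index** — mean(last 75%) ÷ mean(first 25%) of the
  TSS→stop span after trimming 500 bp per end (≥ 2 kb, no same-strand
  neighbour within 1 kb);
- **divergent transcription** — log₂ of maximal sense over antisense 150-bp
  window means within ±500 bp of the TSS;
- **metagenes** — fixed 5000-position grid: 1500 bp unscaled at the 5′ end,
  gene body rescaled to 2000 bins, 1500 bp unscaled at the 3′ end;
- **motifs** — IUPAC consensus scans: TATA (TATAWAWR) 15–45 bp upstream,
  initiator (YCAYTY) with its adenine (+1 base) within ±10 bp of the TSS.

## Worked example

```bash
python examples/01_simulate_and_call_tss.py
```

```
genes simulated:        35
TSS calls made:         35
  exactly at the truth: 35
  within 5 bp:          35
called outron median:   294 bp
```

Thirty-five genes are planted with TSSs upstream of their annotated starts
(outron lengths drawn from a heavy-tailed law with median ≈ 260 bp); the
caller recovers every one at base resolution, and the median called outron
reflects the planted distribution. The other examples cover pausing and
elongation metrics (`02`), metagene profiles and ratio heat maps (`03`),
promoter-motif scans (`04`), and the two-condition dosage-compensation
comparison (`05`), each printing the quantities it computes and a line on
what they mean.

A thin CLI wraps the same stages for shell use:

```bash
nascentx simulate --seed 3 --outdir sim/
nascentx pileup --reads sim/control.groseq.bed --chrom-sizes sim/genome.chrom.sizes --out-prefix sim/groseq
nascentx tss-call --annotations sim/annotations.tsv --chrom-sizes sim/genome.chrom.sizes \
    --groseq sim/groseq --tap-plus sim/tap_plus --tap-minus sim/tap_minus --out-prefix sim/calls
```

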