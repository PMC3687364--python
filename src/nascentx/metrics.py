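"""Per-gene engaged-polymerase metrics.

All quantities are mappability-aware averages of a run-on density track
(RPKM): gene-body expression, promoter-proximal (5') pausing, 3'-end
accumulation, the elongation density index, and upstream divergent
transcription.  Every ineligible result is ``None`` paired with a coded
reason (``too_short``, ``low_mappability``, ``low_expression``,
``neighbor_conflict``) so filter cascades stay auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .genome import AnnotationSet, GeneModel, GenomeInterval, strand_span
from .signal import (
    MappabilityTrack,
    SignalTrack,
    mean_signal,
    sliding_window_means,
)
from .tss import TssCall


@dataclass
class MetricsRecord:
    gene_id: str
    body_rpkm: Optional[float] = None
    pausing5: Optional[float] = None
    paused5: bool = False
    pausing3: Optional[float] = None
    edi: Optional[float] = None
    log2_sense_antisense: Optional[float] = None
    reasons: dict[str, str] = field(default_factory=dict)


def _clamped_interval(chrom: str, strand: str, lo: int, hi: int,
                      chrom_len: int) -> Optional[GenomeInterval]:
    lo, hi = max(lo, 0), min(hi, chrom_len)
    if lo >= hi:
        return None
    return GenomeInterval(chrom, lo, hi, strand)


def gene_body_expression(
    gene: GeneModel,
    track: SignalTrack,
    mappability: Optional[MappabilityTrack] = None,
    mode: str = "trimmed",
    tss: Optional[TssCall] = None,
) -> tuple[Optional[float], Optional[str]]:
    """Mean run-on signal over the gene body; ``(value, reason)``.

    Modes:

    * ``trimmed`` — genes >= 1.1 kb; first and last 300 bp excluded so
      5'/3' accumulation does not inflate the body estimate; >= 250
      uniquely mappable bases required.
    * ``full`` — whole gene model for genes > 250 bp; >= 250 mappable
      bases (the most inclusive expression set).
    * ``mirna`` — primary transcript: called start (or annotated start)
      to the 3' end of the model, >= 25 mappable bases.
    * ``trna`` — annotated span plus 50 bp downstream of the 3' end
      (run-on signal extends past the mature end), >= 25 mappable bases.
    """
    iv = gene.interval
    chrom_len = track.chrom_length(gene.chrom)
    if mode == "trimmed":
        if iv.length < 1100:
            return None, "too_short"
        region = GenomeInterval(gene.chrom, iv.start + 300, iv.end - 300, gene.strand)
        min_mappable = 250
    elif mode == "full":
        if iv.length <= 250:
            return None, "too_short"
        region = iv
        min_mappable = 250
    elif mode == "mirna":
        start_pos = tss.position if tss is not None else gene.wb_start
        if gene.strand == "+":
            region = _clamped_interval(gene.chrom, "+", min(start_pos, iv.start), iv.end, chrom_len)
        else:
            region = _clamped_interval(gene.chrom, "-", iv.start, max(start_pos + 1, iv.end), chrom_len)
        min_mappable = 25
        if region is None:
            return None, "too_short"
    elif mode == "trna":
        if gene.strand == "+":
            region = _clamped_interval(gene.chrom, "+", iv.start, iv.end + 50, chrom_len)
        else:
            region = _clamped_interval(gene.chrom, "-", iv.start - 50, iv.end, chrom_len)
        min_mappable = 25
        if region is None:
            return None, "too_short"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    val = mean_signal(track, region, mappability, min_mappable=min_mappable)
    if val is None:
        return None, "low_mappability"
    return val, None


def neighbor_conflict_5prime(
    gene: GeneModel,
    tss: TssCall,
    annotations: AnnotationSet,
    tss_calls: Optional[Mapping[str, TssCall]] = None,
    three_prime_up: int = 250,
    three_prime_down: int = 750,
    opposite_tss_radius: int = 300,
) -> bool:
    """Flag a 5' pausing window that may collect foreign transcription.

    True when the window [TSS-50, TSS+100) overlaps another same-strand
    gene's 3'-accumulation region [stop-250, stop+750) or lies within
    ``opposite_tss_radius`` of an opposite-strand called start.  This
    automatic flag replaces the by-eye disambiguation of the original
    workflow.
    """
    lo5, hi5 = strand_span(tss.position, gene.strand, 50, 100)
    for other in annotations.genes_on(gene.chrom):
        if other.gene_id == gene.gene_id:
            continue
        if other.strand == gene.strand:
            a, b = strand_span(other.wb_stop, other.strand, three_prime_up, three_prime_down)
            if lo5 < b and a < hi5:
                return True
    if tss_calls:
        for other_id, call in tss_calls.items():
            if other_id == gene.gene_id or call.chrom != gene.chrom:
                continue
            if call.strand != gene.strand and abs(call.position - tss.position) <= opposite_tss_radius:
                return True
    return False


def pausing_ratio_5(
    gene: GeneModel,
    tss: TssCall,
    track: SignalTrack,
    mappability: Optional[MappabilityTrack] = None,
    body: Optional[float] = None,
    body_min_rpkm: float = 1.0,
    ratio_min: float = 2.0,
) -> tuple[Optional[float], bool, Optional[str]]:
    """Promoter-proximal pausing ratio and paused classification.

    Ratio = mean signal over the 150-bp window from 50 bp upstream to
    100 bp downstream of the called start, divided by the trimmed gene
    body expression.  Classified paused when body >= ``body_min_rpkm``
    RPKM and ratio >= ``ratio_min``.  Returns ``(ratio, paused, reason)``.
    """
    if body is None:
        body, reason = gene_body_expression(gene, track, mappability, mode="trimmed")
        if body is None:
            return None, False, reason
    if body <= 0:
        return None, False, "low_expression"
    lo, hi = strand_span(tss.position, gene.strand, 50, 100)
    region = _clamped_interval(gene.chrom, gene.strand, lo, hi, track.chrom_length(gene.chrom))
    if region is None:
        return None, False, "too_short"
    m5 = mean_signal(track, region, mappability, min_mappable=1)
    if m5 is None:
        return None, False, "low_mappability"
    ratio = m5 / body
    paused = (body >= body_min_rpkm) and (ratio >= ratio_min)
    return ratio, paused, None


def pausing_ratio_3(
    gene: GeneModel,
    track: SignalTrack,
    mappability: Optional[MappabilityTrack] = None,
    body: Optional[float] = None,
    span_up: int = 250,
    span_down: int = 750,
    window: int = 200,
) -> tuple[Optional[float], Optional[str]]:
    """3'-end accumulation ratio.

    The highest mappability-aware mean over all ``window``-bp sliding
    windows fully inside the span from ``span_up`` bp upstream to
    ``span_down`` bp downstream of the annotated 3' end, divided by the
    trimmed gene-body expression.  Length/expression floors for summary
    plots are applied by the caller.
    """
    if body is None:
        body, reason = gene_body_expression(gene, track, mappability, mode="trimmed")
        if body is None:
            return None, reason
    if body <= 0:
        return None, "low_expression"
    lo, hi = strand_span(gene.wb_stop, gene.strand, span_up, span_down)
    chrom_len = track.chrom_length(gene.chrom)
    lo, hi = max(lo, 0), min(hi, chrom_len)
    if hi - lo < window:
        return None, "too_short"
    vec = track.get(gene.chrom, gene.strand)[lo:hi]
    mask = mappability.get(gene.chrom, gene.strand)[lo:hi] if mappability is not None else None
    means, _ = sliding_window_means(vec, mask, window)
    if means.size == 0 or np.all(np.isnan(means)):
        return None, "low_mappability"
    return float(np.nanmax(means)) / body, None


def elongation_density_index(
    gene: GeneModel,
    tss: TssCall,
    track: SignalTrack,
    mappability: Optional[MappabilityTrack] = None,
    annotations: Optional[AnnotationSet] = None,
    min_length: int = 2000,
    end_trim: int = 500,
    split: float = 0.25,
    floor_rpkm: float = 1.0,
    neighbor_distance: int = 1000,
) -> tuple[Optional[float], Optional[str]]:
    """Elongation density index: mean over the last 75% / first 25%.

    Computed over the called start -> annotated 3' end span after
    trimming ``end_trim`` bp from each end; the split point is floored
    to a whole base.  Excluded when the span is < ``min_length``, when
    another same-strand gene lies within ``neighbor_distance`` of the
    start (3' accumulation of an upstream gene would contaminate the 5'
    quarter), or when mean RPKM < ``floor_rpkm`` in the first
    ``end_trim`` bp, the first 25%, or the last 75%.
    """
    chrom_len = track.chrom_length(gene.chrom)
    if gene.strand == "+":
        span_lo, span_hi = tss.position, gene.wb_stop + 1
    else:
        span_lo, span_hi = gene.wb_stop, tss.position + 1
    length = span_hi - span_lo
    if length < min_length:
        return None, "too_short"
    if annotations is not None:
        for other in annotations.genes_on(gene.chrom):
            if other.gene_id == gene.gene_id or other.strand != gene.strand:
                continue
            gap = max(other.interval.start - tss.position, tss.position - (other.interval.end - 1))
            if gap <= neighbor_distance:
                return None, "neighbor_conflict"
    # first end_trim bp at the 5' side (checked against the floor)
    lo5, hi5 = strand_span(tss.position, gene.strand, 0, end_trim)
    head = _clamped_interval(gene.chrom, gene.strand, lo5, hi5, chrom_len)
    inner_lo, inner_hi = span_lo + end_trim, span_hi - end_trim
    if inner_hi - inner_lo < 4:
        return None, "too_short"
    inner_len = inner_hi - inner_lo
    cut = math.floor(inner_len * split)
    if cut < 1 or inner_len - cut < 1:
        return None, "too_short"
    if gene.strand == "+":
        first = GenomeInterval(gene.chrom, inner_lo, inner_lo + cut, "+")
        last = GenomeInterval(gene.chrom, inner_lo + cut, inner_hi, "+")
    else:
        first = GenomeInterval(gene.chrom, inner_hi - cut, inner_hi, "-")
        last = GenomeInterval(gene.chrom, inner_lo, inner_hi - cut, "-")
    vals = {}
    for name, region in (("head", head), ("first", first), ("last", last)):
        if region is None:
            return None, "too_short"
        v = mean_signal(track, region, mappability, min_mappable=1)
        if v is None:
            return None, "low_mappability"
        vals[name] = v
    if any(vals[k] < floor_rpkm for k in ("head", "first", "last")):
        return None, "low_expression"
    return vals["last"] / vals["first"], None


def divergent_ratio(
    tss: TssCall,
    sense_track: SignalTrack,
    antisense_track: Optional[SignalTrack] = None,
    search: int = 500,
    window: int = 150,
) -> tuple[Optional[float], Optional[str]]:
    """log2 of maximal sense over maximal antisense transcription at a promoter.

    Maxima are means over ``window``-bp windows fully contained in the
    strand-aware span from ``search`` bp upstream to ``search`` bp
    downstream of the start; the antisense maximum is taken on the
    opposite strand over the same span.  ``None`` with reason
    ``no_antisense`` (or ``no_sense``) when a maximum is zero.
    """
    if antisense_track is None:
        antisense_track = sense_track
    strand = tss.strand
    anti = "-" if strand == "+" else "+"
    lo, hi = strand_span(tss.position, strand, search, search)
    chrom_len = sense_track.chrom_length(tss.chrom)
    lo, hi = max(lo, 0), min(hi, chrom_len)
    if hi - lo < window:
        return None, "too_short"

    def wmax(track: SignalTrack, s: str) -> float:
        means, _ = sliding_window_means(track.get(tss.chrom, s)[lo:hi], None, window)
        return float(np.max(means))

    sense_max = wmax(sense_track, strand)
    anti_max = wmax(antisense_track, anti)
    if anti_max <= 0:
        return None, "no_antisense"
    if sense_max <= 0:
        return None, "no_sense"
    return math.log2(sense_max / anti_max), None


def upstream_divergent_start(
    tss: TssCall,
    corrected: SignalTrack,
    search: int = 500,
) -> Optional[int]:
    """Offset of the divergent initiation site upstream of a start.

    Position of the maximum background-corrected cap signal on the
    opposite strand within ``search`` bp upstream of the start; returned
    as a strand-aware offset (positive = upstream), ties to the smallest
    offset.  ``None`` when no strictly positive signal exists there.
    """
    strand = tss.strand
    anti = "-" if strand == "+" else "+"
    chrom_len = corrected.chrom_length(tss.chrom)
    if strand == "+":
        lo, hi = max(0, tss.position - search), tss.position
    else:
        lo, hi = tss.position + 1, min(chrom_len, tss.position + search + 1)
    if lo >= hi:
        return None
    seg = corrected.get(tss.chrom, anti)[lo:hi]
    if seg.max() <= 0:
        return None
    if strand == "+":
        pos = lo + int(seg.size - 1 - np.argmax(seg[::-1]))  # ties -> closest to TSS
    else:
        pos = lo + int(np.argmax(seg))
    return abs(tss.position - pos)


def compute_metrics(
    annotations: AnnotationSet,
    tss_calls: Mapping[str, TssCall],
    track: SignalTrack,
    mappability: Optional[MappabilityTrack] = None,
    corrected_cap: Optional[SignalTrack] = None,
) -> dict[str, MetricsRecord]:
    """Assemble a :class:`MetricsRecord` per coding gene."""
    out: dict[str, MetricsRecord] = {}
    for gene in annotations:
        if gene.biotype != "coding":
            continue
        rec = MetricsRecord(gene_id=gene.gene_id)
        body, reason = gene_body_expression(gene, track, mappability, mode="trimmed")
        rec.body_rpkm = body
        if reason:
            rec.reasons["body"] = reason
        tss = tss_calls.get(gene.gene_id)
        if tss is not None and body is not None:
            if neighbor_conflict_5prime(gene, tss, annotations, tss_calls):
                rec.reasons["pausing5"] = "neighbor_conflict"
            else:
                ratio, paused, r5 = pausing_ratio_5(gene, tss, track, mappability, body)
                rec.pausing5, rec.paused5 = ratio, paused
                if r5:
                    rec.reasons["pausing5"] = r5
        elif tss is None:
            rec.reasons["pausing5"] = "no_tss"
        if body is not None:
            rec.pausing3, r3 = pausing_ratio_3(gene, track, mappability, body)
            if r3:
                rec.reasons["pausing3"] = r3
        if tss is not None:
            rec.edi, re_ = elongation_density_index(gene, tss, track, mappability, annotations)
            if re_:
                rec.reasons["edi"] = re_
            rec.log2_sense_antisense, rd = divergent_ratio(tss, track)
            if rd:
                rec.reasons["divergence"] = rd
        out[gene.gene_id] = rec
    return out


def write_metrics_tsv(records: Mapping[str, MetricsRecord], path) -> None:
    cols = ["gene_id", "body_rpkm", "pausing5", "paused5", "pausing3",
            "edi", "log2_sense_antisense", "reasons"]

    def fmt(x):
        if x is None:
            return "NA"
        if isinstance(x, bool):
            return "true" if x else "false"
        if isinstance(x, float):
            return f"{x:.6g}"
        return str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for gid in sorted(records):
            r = records[gid]
            reasons = ";".join(f"{k}={v}" for k, v in sorted(r.reasons.items())) or "."
            fh.write("\t".join([
                gid, fmt(r.body_rpkm), fmt(r.pausing5), fmt(r.paused5),
                fmt(r.pausing3), fmt(r.edi), fmt(r.log2_sense_antisense), reasons,
            ]) + "\n")
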