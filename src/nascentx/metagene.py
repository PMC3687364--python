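"""Scaled metagene profiles, anchored averages, and ratio heat maps.

Genes of different lengths are compared on a fixed 5000-position grid:
1500 unscaled positions around the start (1000 bp upstream to 500 bp
downstream of the TSS), 2000 positions of gene body rescaled to 2 kb,
and 1500 unscaled positions around the annotated 3' end (500 bp upstream
to 1000 bp downstream).  Leaving the ends unscaled preserves effects
localised at gene boundaries.  Per-position averages divide by the
number of genes uniquely mappable at that position, then a 25-bp moving
average is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import GeneModel  # noqa: F401  (part of the documented surface)
from .signal import MappabilityTrack, SignalTrack, moving_average
from .tss import TssCall

GRID = 5000
FLANK5_UP, FLANK5_DOWN = 1000, 500   # around TSS
FLANK3_UP, FLANK3_DOWN = 500, 1000   # around annotated 3' end
BODY_BINS = 2000
MIN_GENE_SPAN = 1500


@dataclass
class MetageneProfile:
    """Average profile over the fixed 5000-position grid."""

    mean_signal: np.ndarray   # NaN where no gene is mappable
    n_genes: np.ndarray       # contributing-gene count per position

    @property
    def grid(self) -> np.ndarray:
        return np.arange(GRID)


def _oriented(vec: np.ndarray, strand: str) -> np.ndarray:
    return vec if strand == "+" else vec[::-1]


def _stack_flank(
    values: np.ndarray,
    mask: Optional[np.ndarray],
    anchor: int,
    strand: str,
    up: int,
    down: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Signal and mappability over [anchor-up, anchor+down) in 5'->3' order."""
    n = len(values)
    width = up + down
    out = np.zeros(width)
    ok = np.zeros(width, dtype=bool)
    if strand == "+":
        lo, hi = anchor - up, anchor + down
        a, b = max(lo, 0), min(hi, n)
        if a < b:
            out[a - lo : b - lo] = values[a:b]
            ok[a - lo : b - lo] = True if mask is None else mask[a:b]
    else:
        lo, hi = anchor - down + 1, anchor + up + 1
        a, b = max(lo, 0), min(hi, n)
        if a < b:
            seg = np.zeros(width)
            okseg = np.zeros(width, dtype=bool)
            seg[a - lo : b - lo] = values[a:b]
            okseg[a - lo : b - lo] = True if mask is None else mask[a:b]
            out = seg[::-1]
            ok = okseg[::-1]
    return out, ok


def _resample_area_weighted(
    values: np.ndarray, mask: Optional[np.ndarray], nbins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted rebinning of a base-resolution segment onto ``nbins``.

    Each output bin averages the source bases overlapping it, weighted
    by fractional overlap and restricted to mappable bases; bins with no
    mappable coverage are masked.  Uniform input is exactly preserved.
    """
    m = len(values)
    if mask is None:
        mask = np.ones(m, dtype=bool)
    w = np.where(mask, values, 0.0)
    cum_sig = np.concatenate([[0.0], np.cumsum(w)])
    cum_map = np.concatenate([[0.0], np.cumsum(mask.astype(float))])
    edges = np.linspace(0.0, float(m), nbins + 1)
    grid = np.arange(m + 1, dtype=float)
    sig = np.diff(np.interp(edges, grid, cum_sig))
    cov = np.diff(np.interp(edges, grid, cum_map))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cov > 0, sig / np.maximum(cov, 1e-300), 0.0)
    return out, cov > 0


def scaled_gene_profile(
    gene: GeneModel,
    tss: TssCall,
    track: SignalTrack,
    mappability: Optional[MappabilityTrack] = None,
) -> tuple[Optional[np.ndarray], Optional[np.ndarray], Optional[str]]:
    """One gene's signal on the 5000-position grid; ``(values, mask, reason)``.

    Flanks are copied base-per-base in 5'->3' orientation; the interior
    (TSS+500 to 3'end-500) is rescaled onto 2000 bins by area-weighted
    averaging.  Genes whose TSS->3'end span is < 1.5 kb are skipped.
    """
    strand = gene.strand
    values = track.get(gene.chrom, strand)
    mask = mappability.get(gene.chrom, strand) if mappability is not None else None
    stop = gene.wb_stop
    span = abs(stop - tss.position) + 1
    if span < MIN_GENE_SPAN:
        return None, None, "too_short"

    v5, m5 = _stack_flank(values, mask, tss.position, strand, FLANK5_UP, FLANK5_DOWN)
    v3, m3 = _stack_flank(values, mask, stop, strand, FLANK3_UP, FLANK3_DOWN)

    if strand == "+":
        ilo, ihi = tss.position + FLANK5_DOWN, stop + 1 - FLANK3_UP
    else:
        ilo, ihi = stop + FLANK3_UP, tss.position + 1 - FLANK5_DOWN
    if ihi <= ilo:
        return None, None, "too_short"
    inner_v = _oriented(values[ilo:ihi], strand)
    inner_m = _oriented(mask[ilo:ihi], strand) if mask is not None else None
    vb, mb = _resample_area_weighted(inner_v, inner_m, BODY_BINS)

    profile = np.concatenate([v5, vb, v3])
    pmask = np.concatenate([m5, mb, m3])
    return profile, pmask, None


def average_profiles(
    profiles: Sequence[tuple[np.ndarray, np.ndarray]],
    smooth: int = 25,
) -> MetageneProfile:
    """Mappability-aware per-position mean of per-gene profiles, smoothed.

    At each grid position the divisor is the number of genes mappable
    there; positions where no gene is mappable are NaN.  Smoothing is a
    25-bp moving average computed over valid positions only.
    """
    if not profiles:
        raise ValueError("average_profiles needs at least one profile")
    total = np.zeros(GRID)
    count = np.zeros(GRID)
    for vals, mask in profiles:
        total += np.where(mask, vals, 0.0)
        count += mask
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    valid = count > 0
    if smooth > 1:
        filled = np.where(valid, mean, 0.0)
        num = moving_average(filled, smooth)
        den = moving_average(valid.astype(float), smooth)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        mean = np.where(valid | (den > 0), sm, np.nan)
    return MetageneProfile(mean_signal=mean, n_genes=count.astype(int))


def anchored_profile(
    track: SignalTrack,
    anchors: Iterable[tuple[str, int, str]],
    flank: int,
    mappability: Optional[MappabilityTrack] = None,
    smooth: int = 25,
) -> MetageneProfile:
    """Average signal around arbitrary anchor points.

    Stacks ``[anchor-flank, anchor+flank)`` in strand-aware orientation
    for each ``(chrom, position, strand)`` anchor; positions beyond the
    chromosome edge are masked, not zero-filled.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("anchored_profile needs at least one anchor")
    width = 2 * flank
    total = np.zeros(width)
    count = np.zeros(width)
    for chrom, pos, strand in anchors:
        values = track.get(chrom, strand)
        mask = mappability.get(chrom, strand) if mappability is not None else None
        v, ok = _stack_flank(values, mask, pos, strand, flank, flank)
        total += np.where(ok, v, 0.0)
        count += ok
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    valid = count > 0
    if smooth > 1:
        filled = np.where(valid, mean, 0.0)
        num = moving_average(filled, smooth)
        den = moving_average(valid.astype(float), smooth)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    prof = MetageneProfile(mean_signal=mean, n_genes=count.astype(int))
    return prof


def ratio_heatmap(
    profiles_a: Sequence[tuple[np.ndarray, np.ndarray]],
    profiles_b: Sequence[tuple[np.ndarray, np.ndarray]],
    bin_width: int = 100,
) -> np.ndarray:
    """Per-gene binned log2(a/b) matrix over the metagene grid.

    Each gene's two profiles are summed per ``bin_width`` grid positions
    (mappability-masked positions contribute nothing); the matrix entry
    is log2 of the bin-sum ratio, NaN-masked where either sum is zero.
    Shape: (n_genes, GRID // bin_width).
    """
    if len(profiles_a) != len(profiles_b):
        raise ValueError("profile lists differ in length")
    nbins = GRID // bin_width
    out = np.full((len(profiles_a), nbins), np.nan)
    for i, ((va, ma), (vb, mb)) in enumerate(zip(profiles_a, profiles_b)):
        sa = np.where(ma, va, 0.0)[: nbins * bin_width].reshape(nbins, bin_width).sum(axis=1)
        sb = np.where(mb, vb, 0.0)[: nbins * bin_width].reshape(nbins, bin_width).sum(axis=1)
        ok = (sa > 0) & (sb > 0)
        out[i, ok] = np.log2(sa[ok] / sb[ok])
    return out


def write_profile_tsv(profile: MetageneProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("grid_position\tmean_signal\tn_genes\n")
        for i, (v, n) in enumerate(zip(profile.mean_signal, profile.n_genes)):
            val = "NA" if np.isnan(v) else f"{v:.6g}"
            fh.write(f"{i}\t{val}\t{int(n)}\n")
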