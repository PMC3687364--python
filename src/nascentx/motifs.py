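"""Consensus scanning for core-promoter elements around called TSSs.

Two elements are scanned with IUPAC consensi: the TATA box (TATAWAWR),
searched with its 5'-most base 15-45 bp upstream of the TSS, and the
initiator (Inr, YCAYTY), whose adenine — the +1 nucleotide — is searched
within 10 bp of the TSS in either direction.  De novo motif discovery is
out of scope; only the known consensi are scanned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TATA_CONSENSUS = "TATAWAWR"
INR_CONSENSUS = "YCAYTY"
INR_ANCHOR = 2  # index of the adenine (+1 nucleotide) within YCAYTY


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(seq: str, consensus: str) -> int:
    """Number of positions of ``seq`` outside the IUPAC class of ``consensus``."""
    if len(seq) != len(consensus):
        raise ValueError(f"length mismatch: {len(seq)} vs {len(consensus)}")
    return sum(1 for b, c in zip(seq.upper(), consensus.upper()) if b not in IUPAC[c])


def expand_consensus(consensus: str) -> list[str]:
    """All exact-match sequences of an IUPAC consensus (brute-force expansion)."""
    seqs = [""]
    for c in consensus.upper():
        seqs = [s + b for s in seqs for b in IUPAC[c]]
    return seqs


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    element: str      # "tata" | "inr"
    consensus: str
    offset: int       # tata: upstream distance of 5'-most base; inr: downstream position of the adenine (0 = at TSS)
    mismatches: int
    sequence: str


def _window_seq(genome: Mapping[str, str], chrom: str, strand: str,
                five_prime_pos: int, length: int) -> Optional[str]:
    """Element-length genomic sequence whose 5'-most base sits at ``five_prime_pos``."""
    seq = genome[chrom]
    if strand == "+":
        lo, hi = five_prime_pos, five_prime_pos + length
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi].upper()
    lo, hi = five_prime_pos - length + 1, five_prime_pos + 1
    if lo < 0 or hi > len(seq):
        return None
    return revcomp(seq[lo:hi].upper())


def scan_gene_tata(
    genome: Mapping[str, str], chrom: str, strand: str, tss: int,
    max_mismatch: int = 0, upstream_range: tuple[int, int] = (15, 45),
    consensus: str = TATA_CONSENSUS, anchor: str = "5prime",
) -> Optional[tuple[int, int, str]]:
    """Best TATA hit for one promoter: ``(offset, mismatches, sequence)``.

    The element's 5'-most base is scanned ``upstream_range`` (inclusive)
    bases upstream of the TSS; best = fewest mismatches, ties to the
    most upstream position.  ``anchor='3prime'`` reports the distance of
    the element's 3'-most base instead (both conventions are in use).
    """
    length = len(consensus)
    best = None
    for u in range(upstream_range[0], upstream_range[1] + 1):
        pos = tss - u if strand == "+" else tss + u
        s = _window_seq(genome, chrom, strand, pos, length)
        if s is None or "N" in s:
            continue
        mm = iupac_mismatches(s, consensus)
        if mm <= max_mismatch and (best is None or mm < best[1] or (mm == best[1] and u > best[0])):
            best = (u, mm, s)
    if best is None:
        return None
    u, mm, s = best
    if anchor == "3prime":
        u -= length - 1
    return u, mm, s


def scan_gene_inr(
    genome: Mapping[str, str], chrom: str, strand: str, tss: int,
    max_mismatch: int = 0, radius: int = 10, consensus: str = INR_CONSENSUS,
) -> Optional[tuple[int, int, str]]:
    """Best Inr hit: ``(offset, mismatches, sequence)``.

    The adenine (consensus index 2) is scanned within ``radius`` bp of
    the TSS; offset is downstream-positive with 0 = adenine at the TSS.
    Ties: fewest mismatches, then smallest |offset| (upstream first).
    """
    length = len(consensus)
    candidates = sorted(range(-radius, radius + 1), key=lambda o: (abs(o), o))
    best = None
    for off in candidates:
        a_pos = tss + off if strand == "+" else tss - off
        pos5 = a_pos - INR_ANCHOR if strand == "+" else a_pos + INR_ANCHOR
        s = _window_seq(genome, chrom, strand, pos5, length)
        if s is None or "N" in s:
            continue
        mm = iupac_mismatches(s, consensus)
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (off, mm, s)
            if mm == 0:
                break  # candidates are in tie-preference order
    return best


def scan_promoters(
    tss_list: Iterable[tuple[str, str, int, str]],
    genome: Mapping[str, str],
    element: str,
    max_mismatch: int = 0,
    tata_anchor: str = "5prime",
) -> tuple[list[MotifHit], Counter, list[str]]:
    """Scan every promoter for one element.

    ``tss_list`` holds ``(gene_id, chrom, position, strand)``.  Returns
    ``(best hit per gene, positional histogram of offsets, skipped gene
    ids)``; genes too close to a chromosome edge for any full scan
    window are skipped.
    """
    if element not in ("tata", "inr"):
        raise ValueError(f"unknown element {element!r}")
    hits: list[MotifHit] = []
    skipped: list[str] = []
    histogram: Counter = Counter()
    for gene_id, chrom, pos, strand in tss_list:
        n = len(genome[chrom])
        if element == "tata":
            room = (pos - 45 >= 0 and pos + len(TATA_CONSENSUS) <= n) if strand == "+" \
                else (pos + 45 < n and pos - len(TATA_CONSENSUS) + 1 >= 0)
            if not room:
                skipped.append(gene_id)
                continue
            res = scan_gene_tata(genome, chrom, strand, pos, max_mismatch, anchor=tata_anchor)
            consensus = TATA_CONSENSUS
        else:
            room = 0 <= pos - 10 - INR_ANCHOR and pos + 10 + len(INR_CONSENSUS) <= n
            if not room:
                skipped.append(gene_id)
                continue
            res = scan_gene_inr(genome, chrom, strand, pos, max_mismatch)
            consensus = INR_CONSENSUS
        if res is None:
            continue
        off, mm, s = res
        hits.append(MotifHit(gene_id, element, consensus, off, mm, s))
        histogram[off] += 1
    return hits, histogram, skipped


def write_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\telement\toffset\tmismatches\tsequence\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.element}\t{h.offset}\t{h.mismatches}\t{h.sequence}\n")


def write_histogram_tsv(histogram: Counter, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tcount\n")
        for off in sorted(histogram):
            fh.write(f"{off}\t{histogram[off]}\n")
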