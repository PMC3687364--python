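"""Strand-specific base-resolution signal tracks and mappability.

A :class:`SignalTrack` holds one vector per (chromosome, strand) with one
entry per base.  Raw tracks are 5'-end pileups of mapped reads (the 5'
base most closely marks the position of the transcriptionally engaged
polymerase).  Normalised units follow nuclear run-on practice:

* ``RPKM`` — per-base pileup / (uniquely mapped reads / 1e6) * 1000
  (used for run-on density tracks);
* ``RPM``  — per-base pileup / (uniquely mapped reads / 1e6)
  (used for capped-5'-end tracks).

Note the "K" here is nominal: the value is a per-base quantity scaled by
1000/M reads, not a per-kilobase-of-feature aggregate.

Mappability marks the positions where a k-mer (default k=30, a read
length) whose 5' end lies at that position occurs exactly once among all
k-mers of both genome strands; interval averages divide by uniquely
mappable bases only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genome import GenomeInterval

STRANDS = ("+", "-")

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


class TrackError(ValueError):
    """Raised for invalid track construction or use."""


@dataclass
class SignalTrack:
    """Per-chromosome, per-strand base-resolution signal.

    ``values[chrom][strand]`` is a float vector of chromosome length.
    """

    values: dict[str, dict[str, np.ndarray]]
    units: str = "raw"
    library_size: int = 0

    def chromosomes(self) -> list[str]:
        return sorted(self.values)

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.values[chrom][strand]

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom]["+"])

    def total(self) -> float:
        return float(sum(v.sum() for d in self.values.values() for v in d.values()))

    @classmethod
    def zeros(cls, genome_sizes: Mapping[str, int], units: str = "raw") -> "SignalTrack":
        vals = {
            c: {s: np.zeros(n, dtype=float) for s in STRANDS}
            for c, n in genome_sizes.items()
        }
        return cls(values=vals, units=units, library_size=0)

    def copy(self) -> "SignalTrack":
        vals = {c: {s: v.copy() for s, v in d.items()} for c, d in self.values.items()}
        return SignalTrack(values=vals, units=self.units, library_size=self.library_size)


@dataclass
class MappabilityTrack:
    """Boolean per-position, per-strand unique-alignability of a k-mer 5' end."""

    unique: dict[str, dict[str, np.ndarray]]
    k: int = 30

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.unique[chrom][strand]

    @classmethod
    def all_mappable(cls, genome_sizes: Mapping[str, int], k: int = 30) -> "MappabilityTrack":
        """Fully mappable stand-in except the strand-3' k-1 fringe (no full k-mer)."""
        unique = {}
        for c, n in genome_sizes.items():
            plus = np.ones(n, dtype=bool)
            minus = np.ones(n, dtype=bool)
            plus[max(0, n - k + 1):] = False
            minus[: min(n, k - 1)] = False
            unique[c] = {"+": plus, "-": minus}
        return cls(unique=unique, k=k)


# ---------------------------------------------------------------------------
# pileups and normalisation


def build_five_prime_pileup(
    alignments: Iterable[tuple], genome_sizes: Mapping[str, int]
) -> SignalTrack:
    """Count read 5' ends per base from BED6-style records.

    Each record is ``(chrom, start, end, name, score, strand)`` (name and
    score are ignored; shorter tuples with strand last are accepted).  A
    plus-strand read contributes +1 at ``start``; a minus-strand read at
    ``end - 1`` (its 5' end under the half-open BED convention).
    """
    starts: dict[tuple[str, str], list] = {(c, s): [] for c in genome_sizes for s in STRANDS}
    n = 0
    for rec in alignments:
        chrom, start, end = rec[0], int(rec[1]), int(rec[2])
        strand = rec[-1]
        if chrom not in genome_sizes:
            raise TrackError(f"alignment on unknown chromosome {chrom!r}")
        if not (0 <= start < end <= genome_sizes[chrom]):
            raise TrackError(
                f"alignment [{start},{end}) outside {chrom} (length {genome_sizes[chrom]})"
            )
        pos = start if strand == "+" else end - 1
        starts[(chrom, strand)].append(pos)
        n += 1
    track = SignalTrack.zeros(genome_sizes, units="raw")
    for (chrom, strand), positions in starts.items():
        if positions:
            track.values[chrom][strand] = np.bincount(
                np.asarray(positions), minlength=genome_sizes[chrom]
            ).astype(float)
    track.library_size = n
    return track


def pileup_from_positions(
    positions: Mapping[tuple[str, str], np.ndarray], genome_sizes: Mapping[str, int]
) -> SignalTrack:
    """Fast path for pre-extracted 5'-end position arrays keyed by (chrom, strand)."""
    track = SignalTrack.zeros(genome_sizes, units="raw")
    n = 0
    for (chrom, strand), pos in positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size == 0:
            continue
        if pos.min() < 0 or pos.max() >= genome_sizes[chrom]:
            raise TrackError(f"5' end outside {chrom}")
        track.values[chrom][strand] = np.bincount(
            pos, minlength=genome_sizes[chrom]
        ).astype(float)
        n += int(pos.size)
    track.library_size = n
    return track


def normalize_track(track: SignalTrack, mode: str) -> SignalTrack:
    """Depth-normalise a raw pileup.

    ``groseq_rpkm``: value / (library_size/1e6) * 1000; ``grocap_rpm``:
    value / (library_size/1e6).  The denominator is the total number of
    mapped reads across both strands (the library size).
    """
    if track.library_size <= 0:
        raise TrackError("cannot normalize a track with library_size 0")
    if mode == "groseq_rpkm":
        factor, units = 1000.0 / (track.library_size / 1e6), "RPKM"
    elif mode == "grocap_rpm":
        factor, units = 1.0 / (track.library_size / 1e6), "RPM"
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = track.copy()
    for d in out.values.values():
        for s in STRANDS:
            d[s] = d[s] * factor
    out.units = units
    return out


# ---------------------------------------------------------------------------
# mappability


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return 3 - codes


def compute_mappability(genome: Mapping[str, str], k: int = 30) -> MappabilityTrack:
    """Exact k-mer uniqueness over both strands of the genome.

    Position ``p`` on a strand is mappable iff the k-mer whose 5' end is
    at ``p`` (reverse-complemented on the minus strand) contains no N and
    occurs exactly once among the k-mers of both strands.  A palindromic
    k-mer matches itself on both strands and is therefore never unique.
    """
    if not genome:
        raise TrackError("empty genome")
    for chrom, seq in genome.items():
        if len(seq) < k:
            raise TrackError(f"k={k} exceeds length of chromosome {chrom}")

    plus_codes: dict[str, np.ndarray] = {}
    rc_codes: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    census = []
    for chrom, seq in genome.items():
        b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        n = len(b)
        ok = b >= 0
        b2 = np.where(ok, b, 0).astype(np.uint64)
        m = n - k + 1
        fwd = np.zeros(m, dtype=np.uint64)
        rev = np.zeros(m, dtype=np.uint64)
        nvalid = np.ones(m, dtype=bool)
        for j in range(k):
            fwd = (fwd << np.uint64(2)) | b2[j : j + m]
            rev |= (np.uint64(3) - b2[j : j + m]) << np.uint64(2 * j)
            nvalid &= ok[j : j + m]
        plus_codes[chrom] = fwd
        rc_codes[chrom] = rev
        valid[chrom] = nvalid
        census.append(fwd[nvalid])
        census.append(rev[nvalid])

    allc = np.concatenate(census)
    uniq, counts = np.unique(allc, return_counts=True)

    unique = {}
    for chrom, seq in genome.items():
        n = len(seq)
        m = n - k + 1
        idx = np.searchsorted(uniq, plus_codes[chrom])
        plus_ok = valid[chrom] & (counts[idx] == 1)
        idx_rc = np.searchsorted(uniq, rc_codes[chrom])
        minus_win_ok = valid[chrom] & (counts[idx_rc] == 1)
        plus = np.zeros(n, dtype=bool)
        plus[:m] = plus_ok
        minus = np.zeros(n, dtype=bool)
        # minus-strand 5' end at p covers [p-k+1, p+1): window start p-k+1
        minus[k - 1 :] = minus_win_ok
        unique[chrom] = {"+": plus, "-": minus}
    return MappabilityTrack(unique=unique, k=k)


# ---------------------------------------------------------------------------
# interval statistics


def mean_signal(
    track: SignalTrack,
    interval: GenomeInterval,
    mappability: Optional[MappabilityTrack] = None,
    min_mappable: int = 1,
) -> Optional[float]:
    """Mappability-aware mean signal over an interval.

    Sums the track at uniquely mappable positions and divides by the
    number of mappable positions; returns ``None`` when fewer than
    ``min_mappable`` positions are mappable.  ``mappability=None`` treats
    every position as mappable.
    """
    vec = track.get(interval.chrom, interval.strand)
    if not (0 <= interval.start < interval.end <= len(vec)):
        raise TrackError(f"interval {interval} outside chromosome bounds")
    sl = slice(interval.start, interval.end)
    if mappability is None:
        n = interval.length
        total = float(vec[sl].sum())
    else:
        mask = mappability.get(interval.chrom, interval.strand)[sl]
        n = int(mask.sum())
        if n < min_mappable:
            return None
        total = float(vec[sl][mask].sum())
    if n < min_mappable:
        return None
    return total / n


def moving_average(vector: Sequence[float], window: int) -> np.ndarray:
    """Centered moving average with truncated edge windows.

    The window at index ``i`` covers ``[i - (window-1)//2, i + window//2]``
    clipped to the vector; output length equals input length.  No padding
    is used, so edge values average only the positions that exist.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(vector, dtype=float)
    if window == 1 or v.size == 0:
        return v.copy()
    n = v.size
    left = (window - 1) // 2
    right = window // 2
    cum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.clip(np.arange(n) - left, 0, n)
    hi = np.clip(np.arange(n) + right + 1, 0, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def sliding_window_means(
    values: np.ndarray,
    mask: Optional[np.ndarray],
    window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Means of all fully-contained ``window``-wide windows, mappability-aware.

    Returns ``(means, n_mappable)`` of length ``len(values) - window + 1``;
    windows with no mappable base have mean NaN.
    """
    v = np.asarray(values, dtype=float)
    if mask is None:
        m = np.ones_like(v, dtype=bool)
    else:
        m = np.asarray(mask, dtype=bool)
    cum = np.concatenate([[0.0], np.cumsum(np.where(m, v, 0.0))])
    cnt = np.concatenate([[0], np.cumsum(m.astype(np.int64))])
    nwin = v.size - window + 1
    if nwin <= 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    tot = cum[window:] - cum[:-window]
    n = cnt[window:] - cnt[:-window]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n > 0, tot / np.maximum(n, 1), np.nan)
    return means, n


# ---------------------------------------------------------------------------
# file formats


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, n = line.split("\t")[:2]
            sizes[chrom] = int(n)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_bed6(path):
    """Yield ``(chrom, start, end, name, score, strand)`` tuples from a BED6 file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise TrackError(f"{path}:{lineno}: BED6 needs 6 columns")
            yield parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4], parts[5]


def write_bed6(records: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_bedgraph(track: SignalTrack, prefix: str) -> None:
    """Write one bedGraph per strand: ``<prefix>.plus.bedGraph`` / ``.minus.bedGraph``."""
    for strand, tag in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{tag}.bedGraph", "w") as fh:
            for chrom in track.chromosomes():
                v = track.get(chrom, strand)
                # run-length encode
                change = np.nonzero(np.diff(v))[0] + 1
                bounds = np.concatenate([[0], change, [len(v)]])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    val = v[a]
                    if val != 0:
                        fh.write(f"{chrom}\t{a}\t{b}\t{val:g}\n")


def read_bedgraph(prefix: str, genome_sizes: Mapping[str, int], units: str = "raw") -> SignalTrack:
    """Read a strand pair of bedGraph files written by :func:`write_bedgraph`."""
    track = SignalTrack.zeros(genome_sizes, units=units)
    for strand, tag in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{tag}.bedGraph") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, a, b, val = line.split("\t")[:4]
                track.values[chrom][strand][int(a) : int(b)] = float(val)
    track.library_size = int(round(track.total())) if units == "raw" else 0
    return track


def write_mappability_bed(mappability: MappabilityTrack, path) -> None:
    """Write runs of uniquely mappable positions as BED6 intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(mappability.unique):
            for strand in STRANDS:
                m = mappability.get(chrom, strand).astype(np.int8)
                edges = np.nonzero(np.diff(m))[0] + 1
                bounds = np.concatenate([[0], edges, [len(m)]])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    if m[a]:
                        fh.write(f"{chrom}\t{a}\t{b}\tunique\t0\t{strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an in-memory dict (genomes here are small)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
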