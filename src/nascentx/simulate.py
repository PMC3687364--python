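"""Seedable generator of toy genomes and paired run-on / capped-5'-end reads.

The generator emulates the signal phenomenology the pipeline measures:

* strand-specific engaged-polymerase density covering the outron (true
  TSS to annotated start) and gene body, with a 3'-end accumulation
  plateau and downstream decay;
* short upstream divergent antisense transcripts initiating 75-150 bp
  upstream of the TSS;
* an optional promoter-proximal pause (density multiplier over the
  first 50 bp downstream of the TSS);
* capped-5'-end (TAP+) spikes concentrated within +/-2 bp of planted
  TSSs over a diffuse background, and a TAP- control drawn from the
  same background law only;
* a two-condition design injecting an X-linked fold-change (default
  1.6x) and a mild autosomal decrease (0.9x) into the "mutant"
  condition, applied to sampling rates rather than post-hoc to counts.

Chromosome geometry mirrors the organism under study: the X carries
roughly one-seventh of the expressed mass (as in the real read
fractions), which also makes the injected per-gene folds recoverable
after library-size normalisation.  Random i.i.d. sequence makes exact
30-mer uniqueness coincide with aligner mappability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genome import AnnotationSet, GeneModel, GenomeInterval
from .motifs import revcomp
from .signal import SignalTrack, pileup_from_positions

TATA_PLANT = "TATATAAA"  # an exact TATAWAWR word
INR_PLANT = "TCATTC"     # YCAYTY with the adenine at index 2


class PlacementError(RuntimeError):
    """Requested gene density does not fit on the chromosomes."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset (defaults = the conditions
    the pipeline is validated under)."""

    chromosomes: dict = field(
        default_factory=lambda: {"chrX": 400_000, "chrI": 1_800_000}
    )
    chrom_class: dict = field(
        default_factory=lambda: {"chrX": "X", "chrI": "autosome"}
    )
    n_genes: dict = field(default_factory=lambda: {"chrX": 44, "chrI": 256})
    gene_length: tuple = (1500, 8000)        # uniform, bp
    outron_log_median: float = 260.0         # log-normal median, bp
    outron_log_sigma: float = 1.3            # heavy right tail up to several kb
    outron_clip: tuple = (20, 5000)
    rate_log_sigma: float = 1.0              # per-gene expression, log-normal
    acc3_mult: float = 5.0                   # 3'-end accumulation plateau
    acc3_width: int = 200                    # plateau over the final bp of the gene
    acc3_decay: int = 300                    # linear decay past the 3' end
    pause_mult: float = 1.0                  # 5' pause multiplier ( >=4 for pause fixtures)
    pause_width: int = 50
    divergent_prob: float = 0.7
    divergent_offset: tuple = (75, 150)      # initiation upstream of the TSS
    divergent_mean_len: float = 150.0        # geometric, short
    divergent_strength: float = 0.3          # relative to the gene's rate
    cap_concentration: float = 0.95          # fraction of a gene's TAP+ reads within +/-2 bp
    cap_jitter_wide: int = 25                # spread of the non-concentrated remainder
    tap_plus_depth: int = 500_000
    tap_plus_background_frac: float = 0.2
    tap_minus_depth: int = 100_000
    groseq_depth: int = 2_000_000
    groseq_background_frac: float = 0.02
    dc_fold_x: float = 1.6
    dc_fold_autosome: float = 0.9
    plant_tata_frac: float = 0.5             # fraction of genes given a TATA at -30
    tata_offset: int = 30
    plant_inr_frac: float = 0.5              # fraction given an Inr adenine at 0
    seed: int = 0

    def fold(self, chrom_class: str, condition: str) -> float:
        if condition == "control":
            return 1.0
        if condition != "mutant":
            raise ValueError(f"unknown condition {condition!r}")
        return self.dc_fold_x if chrom_class == "X" else self.dc_fold_autosome


TRUTH_COLUMNS = [
    "gene_id", "chrom", "strand", "chrom_class", "tss", "wb_start", "wb_stop",
    "gene_length", "outron_len", "rate", "pause_mult", "divergent_offset",
    "divergent_len", "tata_offset", "inr_planted",
]


def _draw_outron(rng: np.random.Generator, cfg: SimConfig) -> int:
    u = rng.lognormal(mean=np.log(cfg.outron_log_median), sigma=cfg.outron_log_sigma)
    return int(np.clip(round(u), cfg.outron_clip[0], cfg.outron_clip[1]))


def generate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], AnnotationSet, pd.DataFrame]:
    """Random genome + non-overlapping gene annotations + ground truth.

    Genes are laid down left to right with random intergenic gaps and
    clearance reserved for the outron, the divergent-initiation region
    and the 3' decay, so every planted TSS is reachable by the caller's
    search-window rule.  Raises :class:`PlacementError` when the
    requested genes do not fit.
    """
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    bases = np.array(list("ACGT"))
    for chrom in sorted(config.chromosomes):
        length = config.chromosomes[chrom]
        seq = rng.integers(0, 4, size=length)
        seq_arr = bases[seq]
        cclass = config.chrom_class[chrom]
        n_requested = config.n_genes.get(chrom, 0)
        cursor = 300
        for i in range(n_requested):
            gap = int(rng.integers(200, 1200))
            outron = _draw_outron(rng, config)
            glen = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rate = float(rng.lognormal(mean=0.0, sigma=config.rate_log_sigma))
            has_div = rng.random() < config.divergent_prob
            div_off = int(rng.integers(*config.divergent_offset)) if has_div else -1
            div_len = (
                max(20, int(rng.geometric(1.0 / config.divergent_mean_len)))
                if has_div else 0
            )
            if strand == "+":
                tss = cursor + gap + 300
                start = tss + outron
                end = start + glen
                footprint_end = end + config.acc3_decay + 100
            else:
                low = cursor + gap + config.acc3_decay + 100
                start = low
                end = start + glen
                wb5 = end - 1
                tss = wb5 + outron
                footprint_end = tss + 300
            if footprint_end >= length - 300:
                raise PlacementError(
                    f"cannot place gene {i + 1}/{n_requested} on {chrom} "
                    f"(length {length}); reduce density or enlarge the chromosome"
                )
            gid = f"{chrom}_g{i:04d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    interval=GenomeInterval(chrom, start, end, strand),
                    biotype="coding",
                    chrom_class=cclass,
                )
            )
            tata_off = config.tata_offset if rng.random() < config.plant_tata_frac else -1
            inr = rng.random() < config.plant_inr_frac
            if tata_off > 0:
                # the CC guard prevents shifted overlaps of the planted word
                # (random TA just upstream would form a second exact match)
                _plant(seq_arr, tss, strand, "CC" + TATA_PLANT, upstream=tata_off + 2)
            if inr:
                _plant(seq_arr, tss, strand, INR_PLANT, upstream=2)
            truth_rows.append(
                dict(
                    gene_id=gid, chrom=chrom, strand=strand, chrom_class=cclass,
                    tss=tss, wb_start=start if strand == "+" else end - 1,
                    wb_stop=end - 1 if strand == "+" else start,
                    gene_length=glen, outron_len=outron, rate=rate,
                    pause_mult=config.pause_mult,
                    divergent_offset=div_off, divergent_len=div_len,
                    tata_offset=tata_off, inr_planted=inr,
                )
            )
            cursor = footprint_end
        genome[chrom] = "".join(seq_arr)
    annotations = AnnotationSet(genes, chrom_sizes=dict(config.chromosomes))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genome, annotations, truth


def _plant(seq_arr: np.ndarray, tss: int, strand: str, motif: str, upstream: int) -> None:
    """Write ``motif`` so its 5'-most base sits ``upstream`` bp upstream of the TSS."""
    if strand == "+":
        start = tss - upstream
        for j, b in enumerate(motif):
            seq_arr[start + j] = b
    else:
        start5 = tss + upstream
        rc = revcomp(motif)
        lo = start5 - len(motif) + 1
        for j, b in enumerate(rc):
            seq_arr[lo + j] = b


# ---------------------------------------------------------------------------
# read simulation


def _gene_density(row, cfg: SimConfig) -> tuple[int, np.ndarray]:
    """Per-base sense density over [TSS .. 3'end + decay], 5'->3' order.

    Returns (genomic position of the 5'-most density base on the plus
    reference for later mapping, density vector in transcription order).
    """
    glen_total = abs(row.wb_stop - row.tss) + 1  # outron + gene body
    d = np.ones(glen_total + cfg.acc3_decay)
    if cfg.pause_mult != 1.0:
        d[: cfg.pause_width] *= cfg.pause_mult
    w = min(cfg.acc3_width, glen_total)
    d[glen_total - w : glen_total] *= cfg.acc3_mult
    if cfg.acc3_decay > 0:
        d[glen_total:] = cfg.acc3_mult * np.linspace(1, 0, cfg.acc3_decay, endpoint=False)
    return glen_total, d


def _order_to_genomic(tss: int, strand: str, offsets: np.ndarray) -> np.ndarray:
    """Map transcription-order offsets (0 at TSS) to genomic coordinates."""
    return tss + offsets if strand == "+" else tss - offsets


def simulate_reads(
    annotations: AnnotationSet,
    truth: pd.DataFrame,
    config: SimConfig,
    condition: str = "control",
    seed: Optional[int] = None,
) -> dict[str, dict[tuple[str, str], np.ndarray]]:
    """Sample 5'-end positions for one condition.

    Returns ``{"groseq": positions, "tap_plus": positions,
    "tap_minus": positions}`` where positions map ``(chrom, strand)`` to
    integer arrays.  Total depths are fixed; reads are partitioned over
    genes (and background) by multinomial sampling of rate-proportional
    masses, with condition folds applied to the rates.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    sizes = config.chromosomes
    out: dict[str, dict[tuple[str, str], list]] = {
        name: {(c, s): [] for c in sizes for s in ("+", "-")}
        for name in ("groseq", "tap_plus", "tap_minus")
    }

    # --- run-on track -----------------------------------------------------
    rows = list(truth.itertuples(index=False))
    sense_mass = np.empty(len(rows))
    div_mass = np.empty(len(rows))
    densities = []
    for i, row in enumerate(rows):
        f = config.fold(row.chrom_class, condition)
        glen_total, d = _gene_density(row, config)
        densities.append((glen_total, d))
        sense_mass[i] = row.rate * f * d.sum()
        div_mass[i] = (
            row.rate * f * config.divergent_strength * row.divergent_len
            if row.divergent_offset >= 0 else 0.0
        )
    gene_mass = sense_mass.sum() + div_mass.sum()
    bg_mass = gene_mass * config.groseq_background_frac / (1.0 - config.groseq_background_frac)
    masses = np.concatenate([sense_mass, div_mass, [bg_mass]])
    counts = rng.multinomial(config.groseq_depth, masses / masses.sum())
    n = len(rows)
    for i, row in enumerate(rows):
        c_sense, c_div = counts[i], counts[n + i]
        _glen, d = densities[i]
        if c_sense:
            offs = rng.choice(d.size, size=c_sense, p=d / d.sum())
            pos = _order_to_genomic(row.tss, row.strand, offs)
            out["groseq"][(row.chrom, row.strand)].append(pos)
        if c_div:
            anti = "-" if row.strand == "+" else "+"
            # divergent transcript: antisense, initiating divergent_offset
            # upstream of the TSS and extending further upstream
            offs = rng.integers(0, max(row.divergent_len, 1), size=c_div)
            updist = row.divergent_offset + offs
            pos = row.tss - updist if row.strand == "+" else row.tss + updist
            np.clip(pos, 0, sizes[row.chrom] - 1, out=pos)
            out["groseq"][(row.chrom, anti)].append(pos)
    _scatter_background(out["groseq"], int(counts[-1]), sizes, rng)

    # --- capped 5'-end tracks --------------------------------------------
    f_all = np.array([config.fold(r.chrom_class, condition) for r in rows])
    spike_w = np.array([r.rate for r in rows]) * f_all
    n_spike = int(round(config.tap_plus_depth * (1 - config.tap_plus_background_frac)))
    n_bg_plus = config.tap_plus_depth - n_spike
    spike_counts = rng.multinomial(n_spike, spike_w / spike_w.sum())
    near = np.array([-2, -1, 0, 1, 2])
    near_w = np.array([0.05, 0.15, 0.60, 0.15, 0.05])
    for i, row in enumerate(rows):
        c = int(spike_counts[i])
        if not c:
            continue
        conc = rng.random(c) < config.cap_concentration
        jit = np.empty(c, dtype=np.int64)
        jit[conc] = rng.choice(near, size=int(conc.sum()), p=near_w)
        jit[~conc] = rng.integers(
            -config.cap_jitter_wide, config.cap_jitter_wide + 1, size=int((~conc).sum())
        )
        pos = row.tss + jit if row.strand == "+" else row.tss - jit
        np.clip(pos, 0, sizes[row.chrom] - 1, out=pos)
        out["tap_plus"][(row.chrom, row.strand)].append(pos)
    _scatter_background(out["tap_plus"], n_bg_plus, sizes, rng)
    _scatter_background(out["tap_minus"], config.tap_minus_depth, sizes, rng)

    return {
        name: {
            key: (np.concatenate(v) if v else np.empty(0, dtype=np.int64))
            for key, v in tracks.items()
        }
        for name, tracks in out.items()
    }


def _scatter_background(
    store: dict, n: int, sizes: Mapping[str, int], rng: np.random.Generator
) -> None:
    """Uniform background 5' ends over both strands of the whole genome."""
    if n <= 0:
        return
    chroms = sorted(sizes)
    lens = np.array([sizes[c] for c in chroms], dtype=float)
    per_chrom = rng.multinomial(n, lens / lens.sum())
    for c, cnt in zip(chroms, per_chrom):
        if not cnt:
            continue
        pos = rng.integers(0, sizes[c], size=cnt)
        is_plus = rng.random(cnt) < 0.5
        store[(c, "+")].append(pos[is_plus])
        store[(c, "-")].append(pos[~is_plus])


def pileups_for_condition(
    annotations: AnnotationSet,
    truth: pd.DataFrame,
    config: SimConfig,
    condition: str = "control",
    seed: Optional[int] = None,
) -> dict[str, SignalTrack]:
    """Simulate one condition and build raw 5'-end pileups directly."""
    reads = simulate_reads(annotations, truth, config, condition, seed)
    return {
        name: pileup_from_positions(pos, config.chromosomes)
        for name, pos in reads.items()
    }


# ---------------------------------------------------------------------------
# I/O


def write_reads_bed(
    positions: Mapping[tuple[str, str], np.ndarray],
    path,
    as_alignments: bool = False,
    read_len: int = 30,
    name: str = "read",
) -> None:
    """Write 5'-end positions as BED6.

    Default: 1-base intervals marking the 5' end.  ``as_alignments``
    writes ``read_len``-base intervals with the 5' end at the BED start
    (plus strand) or end-1 (minus strand), for pileup-convention tests.
    """
    with open(path, "w") as fh:
        i = 0
        for (chrom, strand) in sorted(positions):
            for p in positions[(chrom, strand)]:
                p = int(p)
                if as_alignments:
                    a, b = (p, p + read_len) if strand == "+" else (p - read_len + 1, p + 1)
                    a = max(a, 0)
                else:
                    a, b = p, p + 1
                fh.write(f"{chrom}\t{a}\t{b}\t{name}{i}\t0\t{strand}\n")
                i += 1


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
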