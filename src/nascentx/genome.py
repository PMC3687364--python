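"""Gene/transcript data model and coordinate conventions.

All internal coordinates are 0-based half-open, on the forward reference
strand. Strand-aware arithmetic ("upstream", "downstream", 5'/3') is
implemented once here and reused by every downstream stage, so that
off-by-one conventions live in a single place.

External formats:

* GFF3 — 1-based, inclusive; converted at the I/O boundary.
* TSV dialect — columns ``gene_id chrom start end strand biotype
  operon_position trans_spliced chrom_class`` with 0-based half-open
  ``start``/``end``; written and read losslessly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

BIOTYPES = {"coding", "miRNA_primary", "snoRNA", "tRNA", "rRNA", "snRNA", "U21", "operon"}
OPERON_POSITIONS = {"first", "middle", "last", "none"}
CHROM_CLASSES = {"X", "autosome"}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def strand_span(pos: int, strand: str, up: int, down: int) -> tuple[int, int]:
    """Half-open interval covering offsets ``[-up, down)`` around ``pos``.

    Offsets are strand-aware: negative = upstream of ``pos`` (5' side),
    positive = downstream.  ``strand_span(p, "+", 50, 100)`` is
    ``[p-50, p+100)``; on the minus strand the mirrored positions
    ``[p-99, p+51)`` are returned.
    """
    if strand == "+":
        return pos - up, pos + down
    return pos - down + 1, pos + up + 1


def upstream_distance(anchor: int, pos: int, strand: str) -> int:
    """Signed strand-aware distance of ``pos`` upstream of ``anchor``.

    Positive when ``pos`` lies 5' of ``anchor`` on the given strand.
    """
    return anchor - pos if strand == "+" else pos - anchor


@dataclass(frozen=True)
class GeneModel:
    """An annotated transcription unit.

    ``wb_start``/``wb_stop`` are the previously annotated 5'/3'-end base
    positions (for trans-spliced genes the annotated start marks the
    trans-splice acceptor region, not the true initiation site).  On the
    plus strand ``wb_start < wb_stop``; reversed on the minus strand.
    """

    gene_id: str
    interval: GenomeInterval
    biotype: str = "coding"
    operon_position: str = "none"
    trans_spliced: bool = False
    chrom_class: str = "autosome"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if self.operon_position not in OPERON_POSITIONS:
            raise AnnotationError(
                f"{self.gene_id}: unknown operon_position {self.operon_position!r}"
            )
        if self.chrom_class not in CHROM_CLASSES:
            raise AnnotationError(f"{self.gene_id}: unknown chrom_class {self.chrom_class!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def wb_start(self) -> int:
        """Annotated 5'-end base (0-based position, not half-open bound)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def wb_stop(self) -> int:
        """Annotated 3'-end base (0-based position)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


class AnnotationSet:
    """Collection of :class:`GeneModel` with positional indexes.

    Supports deterministic nearest-neighbour queries used by the TSS
    search-window rule.  ``chrom_sizes`` is optional; when present,
    search windows are clamped to chromosome bounds.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_sizes: Optional[dict[str, int]] = None,
    ) -> None:
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        # per-chromosome indexes, sorted by 5' start / 3' end positions
        self._starts: dict[tuple[str, str], list[tuple[int, str]]] = {}
        self._ends: dict[tuple[str, str], list[tuple[int, str]]] = {}
        self._by_chrom: dict[str, list[str]] = {}
        for g in self._genes.values():
            self._starts.setdefault((g.chrom, g.strand), []).append((g.wb_start, g.gene_id))
            self._ends.setdefault((g.chrom, g.strand), []).append((g.wb_stop, g.gene_id))
            self._by_chrom.setdefault(g.chrom, []).append(g.gene_id)
        for idx in (self._starts, self._ends):
            for key in idx:
                idx[key].sort()
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda gid: self._genes[gid].interval.start)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(sorted(self._genes.values(), key=lambda g: (g.chrom, g.interval.start, g.gene_id)))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation set") from None

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [self._genes[gid] for gid in self._by_chrom.get(chrom, [])]

    def nearest_upstream_boundary(
        self, gene: GeneModel
    ) -> tuple[Optional[int], Optional[int]]:
        """Upstream limits for the TSS search window of ``gene``.

        Returns ``(opposite_strand_start, same_strand_gene_end)`` — the
        5'-end position of the closest opposite-strand transcript lying
        strictly upstream of the gene's annotated start, and the 3'-end
        position of the closest same-strand gene strictly upstream.
        Either is ``None`` when no such neighbour exists.
        """
        if gene.gene_id not in self._genes:
            raise KeyError(f"gene {gene.gene_id!r} not in annotation set")
        anchor = gene.wb_start
        opp = "-" if gene.strand == "+" else "+"

        def closest(entries: list[tuple[int, str]], exclude: Optional[str]) -> Optional[int]:
            # entries sorted by position; want nearest strictly-upstream one
            if gene.strand == "+":
                i = bisect.bisect_left(entries, (anchor, "")) - 1
                step = -1
            else:
                i = bisect.bisect_right(entries, (anchor, "\x7f"))
                step = 1
            while 0 <= i < len(entries):
                pos, gid = entries[i]
                if gid != exclude:
                    return pos
                i += step
            return None

        opp_start = closest(self._starts.get((gene.chrom, opp), []), None)
        same_end = closest(self._ends.get((gene.chrom, gene.strand), []), gene.gene_id)
        return opp_start, same_end


# ---------------------------------------------------------------------------
# I/O


_TSV_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand",
    "biotype", "operon_position", "trans_spliced", "chrom_class",
]


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("1", "true", "yes")


def read_annotations(path, dialect: str = "tsv",
                     chrom_sizes: Optional[dict[str, int]] = None) -> AnnotationSet:
    """Read gene annotations from a GFF3 or TSV file.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; the TSV dialect is already internal.
    """
    if dialect == "tsv":
        return _read_tsv(path, chrom_sizes)
    if dialect == "gff3":
        return _read_gff3(path, chrom_sizes)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path, chrom_sizes) -> AnnotationSet:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[: len(_TSV_COLUMNS)] == _TSV_COLUMNS:
                continue  # header
            if len(parts) < len(_TSV_COLUMNS):
                raise AnnotationError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
            try:
                gid, chrom, start, end, strand, biotype, opos, tsf, cclass = parts[:9]
                genes.append(
                    GeneModel(
                        gene_id=gid,
                        interval=GenomeInterval(chrom, int(start), int(end), strand),
                        biotype=biotype,
                        operon_position=opos,
                        trans_spliced=_parse_bool(tsf),
                        chrom_class=cclass,
                    )
                )
            except (ValueError, AnnotationError) as e:
                if isinstance(e, AnnotationError) and "duplicate" in str(e):
                    raise
                raise AnnotationError(f"{path}:{lineno}: {e}") from e
    return AnnotationSet(genes, chrom_sizes)


def _read_gff3(path, chrom_sizes) -> AnnotationSet:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(parts)}")
            chrom, _source, _ftype, start, end, _score, strand, _phase, attrs = parts
            tags = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    tags[k.strip()] = v.strip()
            if "ID" not in tags:
                raise AnnotationError(f"{path}:{lineno}: record lacks ID attribute")
            try:
                interval = GenomeInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as e:
                raise AnnotationError(f"{path}:{lineno}: {e}") from e
            genes.append(
                GeneModel(
                    gene_id=tags["ID"],
                    interval=interval,
                    biotype=tags.get("biotype", "coding"),
                    operon_position=tags.get("operon_position", "none"),
                    trans_spliced=_parse_bool(tags.get("trans_spliced", "false")),
                    chrom_class=tags.get("chrom_class", "autosome"),
                )
            )
    return AnnotationSet(genes, chrom_sizes)


def write_annotations(annotations: AnnotationSet, path, dialect: str = "tsv") -> None:
    """Write annotations in the TSV dialect or as GFF3 (lossless round-trip)."""
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for g in annotations:
                fh.write(
                    "\t".join(
                        [
                            g.gene_id, g.chrom, str(g.interval.start), str(g.interval.end),
                            g.strand, g.biotype, g.operon_position,
                            "true" if g.trans_spliced else "false", g.chrom_class,
                        ]
                    )
                    + "\n"
                )
    elif dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in annotations:
                attrs = (
                    f"ID={g.gene_id};biotype={g.biotype};"
                    f"operon_position={g.operon_position};"
                    f"trans_spliced={'true' if g.trans_spliced else 'false'};"
                    f"chrom_class={g.chrom_class}"
                )
                fh.write(
                    "\t".join(
                        [
                            g.chrom, "nascentx", "gene",
                            str(g.interval.start + 1), str(g.interval.end),
                            ".", g.strand, ".", attrs,
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
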