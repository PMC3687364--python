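"""X versus autosome dosage-compensation comparisons.

Two-condition (mutant vs control) expression tables are reduced to
fold-change summaries per gene class, an alternative normalisation based
on the autosomal share of mapped reads, and X:autosome balance ratios
from gene-level expression and metagene profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotationSet
from .metagene import MetageneProfile
from .signal import SignalTrack, STRANDS


@dataclass
class ConditionPair:
    """Expression tables and read fractions for a mutant/control pair.

    ``expression_a``/``expression_b`` map gene_id -> mean body signal
    (condition a is the mutant; ratios are reported a/b).
    """

    label_a: str
    label_b: str
    expression_a: Mapping[str, float]
    expression_b: Mapping[str, float]
    read_fractions_a: Optional[Mapping[str, float]] = None
    read_fractions_b: Optional[Mapping[str, float]] = None


def chromosome_read_fractions(
    track: SignalTrack, chrom_class: Mapping[str, str]
) -> dict[str, float]:
    """Share of the library on each chromosome class; sums to 1."""
    totals: dict[str, float] = {}
    for chrom in track.values:
        cls = chrom_class[chrom]
        totals[cls] = totals.get(cls, 0.0) + sum(
            float(track.get(chrom, s).sum()) for s in STRANDS
        )
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("track holds no signal")
    return {cls: v / grand for cls, v in totals.items()}


def autosomal_scaling_factor(frac_a: float, frac_b: float) -> float:
    """Scaling factor between autosomal read proportions of two conditions.

    ``frac_a / frac_b``; condition-a expression values are divided by
    this factor to equalise autosomal representation between libraries.
    """
    if not (0 < frac_a <= 1):
        raise ValueError(f"frac_a must be in (0, 1], got {frac_a}")
    if not (0 < frac_b <= 1):
        raise ValueError(f"frac_b must be in (0, 1], got {frac_b}")
    return frac_a / frac_b


def apply_scaling(expression: Mapping[str, float], factor: float) -> dict[str, float]:
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    return {g: v / factor for g, v in expression.items()}


def fold_change_summary(
    pair: ConditionPair,
    gene_ids: Sequence[str],
    label: str = "all",
    fold_cut: float = 1.5,
    pvalues: Optional[Mapping[str, float]] = None,
) -> dict:
    """Summary of per-gene a/b expression ratios for one gene set.

    Reports n, median ratio, mean ratio with its standard error, and the
    counts of genes changed by >= ``fold_cut`` in either direction.  The
    even-n median is the mean of the two central values.  ``pvalues`` is
    a pass-through hook for externally computed significance values.
    """
    ratios = []
    used = []
    for g in gene_ids:
        a = pair.expression_a.get(g)
        b = pair.expression_b.get(g)
        if a is None or b is None or b <= 0 or a < 0:
            continue
        ratios.append(a / b)
        used.append(g)
    if not ratios:
        raise ValueError(f"gene set {label!r} has no eligible genes")
    arr = np.asarray(ratios)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    out = {
        "set": label,
        "n": int(arr.size),
        "median_ratio": float(np.median(arr)),
        "mean_ratio": float(arr.mean()),
        "sem": sem,
        f"n_up_{fold_cut}x": int((arr >= fold_cut).sum()),
        f"n_down_{fold_cut}x": int((arr <= 1.0 / fold_cut).sum()),
    }
    if pvalues is not None:
        out["median_pvalue"] = float(np.median([pvalues[g] for g in used if g in pvalues]))
    return out


def summarize_by_class(
    pair: ConditionPair,
    annotations: AnnotationSet,
    min_body: float = 0.0,
    fold_cut: float = 1.5,
) -> pd.DataFrame:
    """Fold-change summaries for X-linked and autosomal gene sets."""
    rows = []
    for cls in ("X", "autosome"):
        ids = [
            g.gene_id
            for g in annotations
            if g.chrom_class == cls
            and pair.expression_b.get(g.gene_id, 0.0) is not None
            and (pair.expression_b.get(g.gene_id) or 0.0) >= min_body
        ]
        rows.append(fold_change_summary(pair, ids, label=cls, fold_cut=fold_cut))
    return pd.DataFrame(rows)


def x_autosome_balance(
    expression: Mapping[str, float],
    annotations: AnnotationSet,
    profile_x: Optional[MetageneProfile] = None,
    profile_a: Optional[MetageneProfile] = None,
) -> dict:
    """X / autosome balance of one condition.

    Returns the ratio of median gene-level expression (X over autosome)
    and, when metagene profiles are given, the ratio of their mean
    profile signal — the two complementary readouts of chromosome-wide
    balance.
    """
    by_class: dict[str, list[float]] = {"X": [], "autosome": []}
    for g in annotations:
        v = expression.get(g.gene_id)
        if v is not None:
            by_class[g.chrom_class].append(v)
    if not by_class["X"] or not by_class["autosome"]:
        raise ValueError("both chromosome classes must be populated")
    out = {
        "median_expression_ratio": float(
            np.median(by_class["X"]) / np.median(by_class["autosome"])
        ),
        "n_x": len(by_class["X"]),
        "n_autosome": len(by_class["autosome"]),
    }
    if profile_x is not None and profile_a is not None:
        mx = float(np.nanmean(profile_x.mean_signal))
        ma = float(np.nanmean(profile_a.mean_signal))
        if ma == 0:
            raise ValueError("autosomal metagene signal is zero")
        out["metagene_ratio"] = mx / ma
    return out


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)


def write_read_fractions_tsv(fractions: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom_class\tread_fraction\n")
        for cls in sorted(fractions):
            fh.write(f"{cls}\t{fractions[cls]:.6g}\n")
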