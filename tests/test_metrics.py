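"""Gene-body expression, pausing ratios, elongation density, divergence."""

import numpy as np
import pytest

from nascentx.genome import AnnotationSet, GeneModel, GenomeInterval
from nascentx.metrics import (
    divergent_ratio,
    elongation_density_index,
    gene_body_expression,
    pausing_ratio_3,
    pausing_ratio_5,
    upstream_divergent_start,
)
from nascentx.signal import MappabilityTrack, SignalTrack
from nascentx.tss import TssCall


def gene(gid, chrom, start, end, strand, **kw):
    return GeneModel(gene_id=gid, interval=GenomeInterval(chrom, start, end, strand), **kw)


def uniform_track(n, value, chrom="c", both=False):
    t = SignalTrack.zeros({chrom: n}, units="RPKM")
    t.values[chrom]["+"][:] = value
    if both:
        t.values[chrom]["-"][:] = value
    t.library_size = 1
    return t


def tss(gid, pos, strand="+", chrom="c"):
    return TssCall(gid, chrom, strand, pos, 10.0, 10.0)


class TestGeneBody:
    def test_uniform_trimmed_mean(self):
        t = uniform_track(10000, 3.5)
        g = gene("g", "c", 4000, 6000, "+")
        val, reason = gene_body_expression(g, t, mode="trimmed")
        assert val == pytest.approx(3.5) and reason is None

    def test_short_gene_rejected(self):
        t = uniform_track(10000, 3.5)
        g = gene("g", "c", 4000, 5000, "+")  # 1.0 kb < 1.1 kb floor
        val, reason = gene_body_expression(g, t, mode="trimmed")
        assert val is None and reason == "too_short"

    def test_low_mappability_rejected(self):
        t = uniform_track(10000, 3.5)
        m = MappabilityTrack.all_mappable({"c": 10000})
        m.unique["c"]["+"][:] = False
        g = gene("g", "c", 4000, 6000, "+")
        val, reason = gene_body_expression(g, t, m, mode="trimmed")
        assert val is None and reason == "low_mappability"

    def test_trna_mode_hand_sum(self):
        """80-bp tRNA + 50 bp downstream: mean over 130 strand-aware bases."""
        n = 1000
        t = SignalTrack.zeros({"c": n}, units="RPKM")
        vals = np.zeros(n)
        vals[500:580] = 2.0   # the annotated tRNA
        vals[580:630] = 4.0   # read-through past the mature end
        t.values["c"]["+"] = vals
        g = gene("g", "c", 500, 580, "+", biotype="tRNA")
        val, reason = gene_body_expression(g, t, mode="trna")
        hand = (80 * 2.0 + 50 * 4.0) / 130
        assert val == pytest.approx(hand)
        # minus-strand counterpart: downstream extension goes to lower coords
        t.values["c"]["-"] = vals[::-1].copy()
        gm = gene("gm", "c", n - 580, n - 500, "-", biotype="tRNA")
        vm, _ = gene_body_expression(gm, t, mode="trna")
        assert vm == pytest.approx(hand)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            gene_body_expression(gene("g", "c", 0, 2000, "+"), uniform_track(3000, 1), mode="bogus")


class TestPausing5:
    def test_ratio_and_classification(self):
        n = 10000
        t = uniform_track(n, 2.0)
        g = gene("g", "c", 4000, 6000, "+")
        t.values["c"]["+"][3950:4100] = 20.0  # the 150-bp window [TSS-50, TSS+100)
        ratio, paused, reason = pausing_ratio_5(g, tss("g", 4000), t, body=2.0)
        assert ratio == pytest.approx(10.0) and paused

    def test_low_body_blocks_classification(self):
        t = uniform_track(10000, 0.5)
        g = gene("g", "c", 4000, 6000, "+")
        t.values["c"]["+"][3950:4100] = 10.0
        ratio, paused, _ = pausing_ratio_5(g, tss("g", 4000), t, body=0.5)
        assert ratio == pytest.approx(20.0) and not paused

    def test_subthreshold_ratio_not_paused(self):
        t = uniform_track(10000, 5.0)
        g = gene("g", "c", 4000, 6000, "+")
        t.values["c"]["+"][3950:4100] = 9.5  # ratio 1.9
        ratio, paused, _ = pausing_ratio_5(g, tss("g", 4000), t, body=5.0)
        assert ratio == pytest.approx(1.9) and not paused


def brute_force_pausing3(vals, mask, stop, body, strand, up=250, down=750, w=200):
    """All-windows loop oracle for the 3' accumulation ratio."""
    if strand == "+":
        lo, hi = stop - up, stop + down
    else:
        lo, hi = stop - down + 1, stop + up + 1
    best = None
    for s in range(lo, hi - w + 1):
        mm = mask[s : s + w]
        if not mm.any():
            continue
        m = vals[s : s + w][mm].mean()
        best = m if best is None or m > best else best
    return None if best is None else best / body


class TestPausing3:
    def test_uniform_track_ratio_one(self):
        t = uniform_track(10000, 4.0)
        g = gene("g", "c", 4000, 7000, "+")
        ratio, reason = pausing_ratio_3(g, t, body=4.0)
        assert ratio == pytest.approx(1.0)

    def test_planted_plateau_and_oracle(self, rng):
        n = 10000
        t = uniform_track(n, 1.0)
        g = gene("g", "c", 4000, 7000, "+")
        stop = 6999
        t.values["c"]["+"][stop - 100 : stop + 100] = 10.0  # plateau centred at stop
        mask = np.ones(n, dtype=bool)
        ratio, _ = pausing_ratio_3(g, t, body=1.0)
        oracle = brute_force_pausing3(t.get("c", "+"), mask, stop, 1.0, "+")
        assert ratio == pytest.approx(oracle, abs=1e-9)
        assert ratio == pytest.approx(10.0)

    def test_oracle_equivalence_random(self, rng):
        n = 5000
        vals = rng.poisson(2.0, n).astype(float)
        mask = rng.random(n) < 0.8
        t = SignalTrack.zeros({"c": n}, units="RPKM")
        t.values["c"]["+"] = vals
        m = MappabilityTrack.all_mappable({"c": n})
        m.unique["c"]["+"] = mask
        g = gene("g", "c", 1000, 3000, "+")
        ratio, _ = pausing_ratio_3(g, t, m, body=2.0)
        oracle = brute_force_pausing3(vals, mask, 2999, 2.0, "+")
        assert ratio == pytest.approx(oracle, abs=1e-9)


class TestElongationDensityIndex:
    def _fixture(self, n=12000, glen=4000, profile=None, strand="+"):
        t = SignalTrack.zeros({"c": n}, units="RPKM")
        if strand == "+":
            g = gene("g", "c", 4000, 4000 + glen, "+")
            ts = tss("g", 4000)
            if profile is not None:
                t.values["c"]["+"][4000 : 4000 + glen] = profile
            else:
                t.values["c"]["+"][:] = 4.0
        else:
            g = gene("g", "c", n - 4000 - glen, n - 4000, "-")
            ts = tss("g", n - 4001, strand="-")
            if profile is not None:
                t.values["c"]["-"][n - 4000 - glen : n - 4000] = profile[::-1]
            else:
                t.values["c"]["-"][:] = 4.0
        return g, ts, t

    def test_uniform_track_gives_one(self):
        g, ts, t = self._fixture()
        edi, reason = elongation_density_index(g, ts, t)
        assert edi == pytest.approx(1.0)

    def test_short_gene_rejected(self):
        g, ts, t = self._fixture(glen=1900)
        edi, reason = elongation_density_index(g, ts, t)
        assert edi is None and reason == "too_short"

    def test_linear_decay_hand_integration(self):
        """4-kb gene, inner 3 kb splits 750/2250; density decays linearly."""
        glen = 4000
        inner = glen - 1000
        profile = np.full(glen, 4.0)
        # decay from 4 at the 25% boundary to 0 at the inner end
        cut = 500 + inner // 4
        span = glen - 500 - cut
        profile[cut : glen - 500] = np.linspace(4.0, 0.0, span, endpoint=False)
        g, ts, t = self._fixture(profile=profile)
        edi, _ = elongation_density_index(g, ts, t)
        hand = profile[cut : glen - 500].mean() / profile[500:cut].mean()
        assert edi == pytest.approx(hand, abs=1e-9)
        assert edi < 1.0

    def test_mirrored_fixture_with_complementary_split_gives_reciprocal(self):
        """Reversing the profile and complementing the 25% split inverts the index.

        (The 75/25 regions are asymmetric, so a plain mirror is not the
        reciprocal; the exact symmetry swaps the split fraction too.)
        """
        rngl = np.random.default_rng(3)
        profile = rngl.uniform(2.0, 8.0, 4000)
        g, ts, t = self._fixture(profile=profile)
        edi, _ = elongation_density_index(g, ts, t, split=0.25)
        g2, ts2, t2 = self._fixture(profile=profile[::-1])
        edi2, _ = elongation_density_index(g2, ts2, t2, split=0.75)
        assert edi2 == pytest.approx(1.0 / edi, rel=1e-9)

    def test_strand_mirror_invariance(self):
        rngl = np.random.default_rng(4)
        profile = rngl.uniform(2.0, 8.0, 4000)
        gp, tsp, tp = self._fixture(profile=profile, strand="+")
        gm, tsm, tm = self._fixture(profile=profile, strand="-")
        ep, _ = elongation_density_index(gp, tsp, tp)
        em, _ = elongation_density_index(gm, tsm, tm)
        assert em == pytest.approx(ep, rel=1e-12)

    def test_low_expression_floor(self):
        g, ts, t = self._fixture()
        t.values["c"]["+"][4000:4500] = 0.1  # first 500 bp below 1 RPKM
        edi, reason = elongation_density_index(g, ts, t)
        assert edi is None and reason == "low_expression"

    def test_neighbor_within_1kb_excluded(self):
        g, ts, t = self._fixture()
        nb = gene("nb", "c", 2500, 3500, "+")  # ends 500 bp upstream of the TSS
        ann = AnnotationSet([g, nb])
        edi, reason = elongation_density_index(g, ts, t, annotations=ann)
        assert edi is None and reason == "neighbor_conflict"


class TestDivergence:
    def _tracks(self, n=4000, sense_level=0.0, anti_spikes=()):
        t = SignalTrack.zeros({"c": n}, units="RPKM")
        t.values["c"]["+"][:] = sense_level
        for pos, h in anti_spikes:
            t.values["c"]["-"][pos] = h
        t.library_size = 1
        return t

    def test_log2_ratio(self):
        t = self._tracks(sense_level=8.0)
        t.values["c"]["-"][1500:2500] = 2.0
        val, reason = divergent_ratio(tss("g", 2000), t)
        assert val == pytest.approx(2.0)

    def test_symmetric_signal_gives_zero(self):
        t = self._tracks(sense_level=3.0)
        t.values["c"]["-"][:] = 3.0
        val, _ = divergent_ratio(tss("g", 2000), t)
        assert val == pytest.approx(0.0)

    def test_zero_antisense_is_none(self):
        t = self._tracks(sense_level=3.0)
        val, reason = divergent_ratio(tss("g", 2000), t)
        assert val is None and reason == "no_antisense"

    def test_rescaling_invariance(self):
        t = self._tracks(sense_level=8.0)
        t.values["c"]["-"][1500:2500] = 2.0
        base, _ = divergent_ratio(tss("g", 2000), t)
        for d in t.values.values():
            for s in d:
                d[s] = d[s] * 7.3
        scaled, _ = divergent_ratio(tss("g", 2000), t)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_upstream_divergent_start_offset(self):
        t = self._tracks(anti_spikes=[(1880, 5.0)])  # 120 bp upstream of TSS 2000
        assert upstream_divergent_start(tss("g", 2000), t) == 120

    def test_upstream_divergent_no_positive_signal(self):
        t = self._tracks()
        assert upstream_divergent_start(tss("g", 2000), t) is None

    def test_upstream_divergent_tie_prefers_smallest_offset(self):
        t = self._tracks(anti_spikes=[(1800, 5.0), (1920, 5.0)])
        assert upstream_divergent_start(tss("g", 2000), t) == 80


class TestScaleInvariance:
    def test_all_ratios_invariant_under_global_rescale(self):
        """Units cancel in every ratio metric (track x 7.3)."""
        n = 12000
        rngl = np.random.default_rng(9)
        t = SignalTrack.zeros({"c": n}, units="RPKM")
        t.values["c"]["+"] = rngl.uniform(1.5, 6.0, n)
        t.values["c"]["-"] = rngl.uniform(1.5, 6.0, n)
        g = gene("g", "c", 4000, 8000, "+")
        ts = tss("g", 3800)
        body, _ = gene_body_expression(g, t)
        base = (
            pausing_ratio_5(g, ts, t, body=body)[0],
            pausing_ratio_3(g, t, body=body)[0],
            elongation_density_index(g, ts, t)[0],
            divergent_ratio(ts, t)[0],
        )
        for d in t.values.values():
            for s in d:
                d[s] = d[s] * 7.3
        body2, _ = gene_body_expression(g, t)
        assert body2 == pytest.approx(body * 7.3, rel=1e-12)
        scaled = (
            pausing_ratio_5(g, ts, t, body=body2)[0],
            pausing_ratio_3(g, t, body=body2)[0],
            elongation_density_index(g, ts, t)[0],
            divergent_ratio(ts, t)[0],
        )
        for a, b in zip(base, scaled):
            assert b == pytest.approx(a, rel=1e-9)
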