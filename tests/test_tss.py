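"""TSS caller: Z-scores, search windows, calling, small RNAs, merging."""

import math

import numpy as np
import pytest

from nascentx.genome import AnnotationSet, GeneModel, GenomeInterval
from nascentx.signal import MappabilityTrack, SignalTrack, moving_average
from nascentx.tss import (
    TssCall,
    TssCallerConfig,
    apply_curated,
    call_small_rna_tss,
    call_tss,
    chromosome_zscores,
    corrected_grocap,
    define_search_window,
    merge_stage_tss,
)


def track_from(values_by_key, units="RPM", length=None):
    """SignalTrack from {(chrom, strand): array}; missing strands zero."""
    chroms = {}
    for (c, s), v in values_by_key.items():
        chroms.setdefault(c, max(length or 0, len(v)))
        chroms[c] = max(chroms[c], len(v))
    t = SignalTrack.zeros(chroms, units=units)
    for (c, s), v in values_by_key.items():
        t.values[c][s][: len(v)] = np.asarray(v, dtype=float)
    t.library_size = max(int(t.total()), 1)
    return t


def gene(gid, chrom, start, end, strand, **kw):
    return GeneModel(gene_id=gid, interval=GenomeInterval(chrom, start, end, strand), **kw)


class TestCorrectedGrocap:
    def test_subtraction_retains_sign(self):
        plus = track_from({("c", "+"): [5.0, 1.0, 0.0]})
        minus = track_from({("c", "+"): [2.0, 4.0, 0.0]})
        out = corrected_grocap(plus, minus)
        np.testing.assert_allclose(out.get("c", "+"), [3.0, -3.0, 0.0])

    def test_mismatched_chromosomes_error(self):
        a = track_from({("c", "+"): [1.0]})
        b = track_from({("d", "+"): [1.0]})
        with pytest.raises(Exception):
            corrected_grocap(a, b)


def brute_force_z1(values, outlier_fraction):
    """Plain-python trimmed mean/SD standardisation (independent oracle)."""
    n = len(values)
    n_drop = math.ceil(n * outlier_fraction)
    order = sorted(range(n), key=lambda i: (values[i], i))
    keep = [values[i] for i in order[: n - n_drop]] if n_drop else list(values)
    mu = sum(keep) / len(keep)
    sd = math.sqrt(sum((x - mu) ** 2 for x in keep) / len(keep))
    if sd == 0:
        return [0.0] * n
    return [(v - mu) / sd for v in values]


class TestChromosomeZscores:
    def test_constant_track_gives_zero_z(self):
        t = track_from({("c", "+"): [2.0] * 100, ("c", "-"): [2.0] * 100})
        z = chromosome_zscores(t, outlier_fraction=0.0)
        assert np.all(z.get_z1("c", "+") == 0)
        assert z.warnings

    def test_matches_brute_force_with_outlier_drop(self):
        vals = [0.0] * 8 + [4.0, 8.0]
        t = track_from({("c", "+"): vals, ("c", "-"): [0.0] * 10})
        # fraction such that exactly one value (the 8) is dropped
        z = chromosome_zscores(t, outlier_fraction=0.05)
        expect = brute_force_z1(vals, 0.05)
        np.testing.assert_allclose(z.get_z1("c", "+"), expect, atol=1e-12)
        # excluded outlier position still receives a (large) z-score
        assert z.get_z1("c", "+")[9] == max(z.get_z1("c", "+"))

    def test_ceiling_rule_excludes_exactly_two_of_20001(self, rng):
        n = 20_001
        assert math.ceil(n * 5e-5) == 2
        vals = rng.normal(size=n)
        t = track_from({("c", "+"): vals, ("c", "-"): np.zeros(n)})
        z = chromosome_zscores(t, outlier_fraction=5e-5)
        order = np.argsort(vals, kind="stable")
        keep = vals[order[:-2]]
        mu, sd = keep.mean(), keep.std(ddof=0)
        np.testing.assert_allclose(z.get_z1("c", "+"), (vals - mu) / sd, atol=1e-9)

    def test_z10_is_moving_average_of_z1(self, rng):
        vals = rng.poisson(1.0, 500).astype(float)
        t = track_from({("c", "+"): vals, ("c", "-"): np.zeros(500)})
        z = chromosome_zscores(t)
        np.testing.assert_allclose(
            z.get_z10("c", "+"), moving_average(z.get_z1("c", "+"), 10), atol=1e-12
        )

    def test_strands_standardised_independently_by_default(self):
        t = track_from({("c", "+"): [0.0, 0, 0, 10], ("c", "-"): [5.0, 5, 5, 5]})
        z = chromosome_zscores(t, outlier_fraction=0.0)
        # constant minus strand -> zeros there, but plus strand unaffected
        assert np.all(z.get_z1("c", "-") == 0)
        assert z.get_z1("c", "+")[3] > 0


class TestSearchWindow:
    def test_opposite_strand_limit(self):
        g = gene("g", "c", 5000, 9000, "+")
        other = gene("o", "c", 1000, 2001, "-")  # 5' end 2000
        ann = AnnotationSet([g, other], chrom_sizes={"c": 20000})
        win, reason = define_search_window(g, ann)
        assert reason is None
        assert (win.start, win.end) == (2000, 5250)

    def test_same_strand_limit_with_gap(self):
        g = gene("g", "c", 5000, 9000, "+")
        other = gene("o", "c", 2000, 3001, "+")  # 3' end 3000
        ann = AnnotationSet([g, other], chrom_sizes={"c": 20000})
        win, reason = define_search_window(g, ann)
        assert (win.start, win.end) == (3100, 5250)

    def test_nearer_limit_wins(self):
        g = gene("g", "c", 5000, 9000, "+")
        far_opp = gene("o1", "c", 1000, 2001, "-")
        near_same = gene("o2", "c", 2000, 4001, "+")  # end 4000 -> limit 4100
        ann = AnnotationSet([g, far_opp, near_same], chrom_sizes={"c": 20000})
        win, _ = define_search_window(g, ann)
        assert win.start == 4100

    def test_nested_gene_ineligible(self):
        g = gene("g", "c", 5000, 6000, "+")
        host = gene("h", "c", 4000, 9000, "-")
        ann = AnnotationSet([g, host], chrom_sizes={"c": 20000})
        win, reason = define_search_window(g, ann)
        assert win is None and reason == "nested"

    def test_minus_strand_mirror(self):
        L = 20000
        gp = gene("g", "c", 5000, 9000, "+")
        op = gene("o", "c", 1000, 2001, "-")
        annp = AnnotationSet([gp, op], chrom_sizes={"c": L})
        winp, _ = define_search_window(gp, annp)
        # mirrored layout: coordinates x -> L-x, strands flipped
        gm = gene("g", "c", L - 9000, L - 5000, "-")
        om = gene("o", "c", L - 2001, L - 1000, "+")
        annm = AnnotationSet([gm, om], chrom_sizes={"c": L})
        winm, _ = define_search_window(gm, annm)
        assert winm.length == winp.length
        # exact mirror of the inclusive candidate set
        assert (winm.start, winm.end) == (L - winp.end, L - winp.start)


def brute_force_call(gene_model, window, z1, z10, groseq, cfg):
    """Exhaustive reference caller (plain loops, no vector shortcuts)."""
    strand = gene_model.strand
    w = cfg.continuity_window
    n = len(groseq)

    def cont(p):
        a, b = (p, p + w) if strand == "+" else (p - w + 1, p + 1)
        a, b = max(a, 0), min(b, n)
        if a >= b:
            return False
        return np.mean(groseq[a:b]) >= cfg.continuity_min_rpkm

    cands = (
        range(window.end - 1, window.start - 1, -1)
        if strand == "+" else range(window.start, window.end)
    )
    reachable = []
    for p in cands:
        if not cont(p):
            break
        reachable.append(p)
    if not reachable:
        return None
    best_p, best = None, -np.inf
    for p in reachable:
        if z10[p] > best:
            best, best_p = z10[p], p
    if best <= cfg.z10_cutoff:
        return None
    left, right = (cfg.smoothing_window - 1) // 2, cfg.smoothing_window // 2
    a = max(best_p - left, window.start, 0)
    b = min(best_p + right + 1, window.end, n)
    if strand == "+":
        pos = max(range(a, b), key=lambda i: (z1[i], i))
    else:
        pos = max(range(a, b), key=lambda i: (z1[i], -i))
    return pos, best


class TestCallTss:
    def _setup(self, n=8000, spike_at=4200, spike=400.0, groseq_level=5.0, strand="+", seed=0):
        rng = np.random.default_rng(seed)
        cap = rng.poisson(0.02, n).astype(float)
        cap[spike_at] += spike
        groseq = np.full(n, groseq_level)
        if strand == "+":
            g = gene("g", "c", 5000, 7000, "+")
        else:
            g = gene("g", "c", n - 7000, n - 5000, "-")
        cap_t = track_from({("c", strand): cap, ("c", "-" if strand == "+" else "+"): np.zeros(n)})
        z = chromosome_zscores(cap_t)
        gro_t = track_from({("c", strand): groseq}, units="RPKM")
        return g, cap_t, z, gro_t

    def test_planted_spike_recovered_and_matches_oracle(self):
        g, cap, z, gro = self._setup()
        win = GenomeInterval("c", 2000, 5250, "+")
        cfg = TssCallerConfig()
        call = call_tss(g, win, z, gro, None, cfg)
        assert call is not None and call.position == 4200
        oracle = brute_force_call(
            g, win, z.get_z1("c", "+"), z.get_z10("c", "+"), gro.get("c", "+"), cfg
        )
        assert oracle is not None
        assert call.position == oracle[0]
        assert call.z10_at_call == pytest.approx(oracle[1], abs=1e-9)

    def test_oracle_equivalence_on_random_fixtures(self, rng):
        cfg = TssCallerConfig(z10_cutoff=1.5)
        for trial in range(10):
            n = 6000
            cap = rng.poisson(0.05, n).astype(float)
            for _ in range(3):
                cap[rng.integers(1000, 5000)] += rng.integers(5, 60)
            gro_vals = rng.poisson(4.0, n).astype(float)
            gro_vals[rng.integers(1500, 3500) :][:200] = 0.0  # random continuity break
            strand = "+" if trial % 2 == 0 else "-"
            g = (
                gene("g", "c", 4500, 5900, "+")
                if strand == "+" else gene("g", "c", 100, 1500, "-")
            )
            cap_t = track_from({("c", strand): cap, ("c", {"+": "-", "-": "+"}[strand]): np.zeros(n)})
            z = chromosome_zscores(cap_t)
            gro_t = track_from({("c", strand): gro_vals}, units="RPKM")
            win = (
                GenomeInterval("c", 500, 4750, "+")
                if strand == "+" else GenomeInterval("c", 1250, 5500, "-")
            )
            call = call_tss(g, win, z, gro_t, None, cfg)
            oracle = brute_force_call(
                g, win, z.get_z1("c", strand), z.get_z10("c", strand),
                gro_t.get("c", strand), cfg,
            )
            if oracle is None:
                assert call is None
            else:
                assert call is not None
                assert (call.position, call.z10_at_call) == (
                    oracle[0], pytest.approx(oracle[1], abs=1e-9)
                )

    def test_continuity_break_blocks_upstream_spike(self):
        g, cap, z, gro = self._setup()
        gro.values["c"]["+"][4400:4600] = 0.0  # break between spike (4200) and gene start
        win = GenomeInterval("c", 2000, 5250, "+")
        call = call_tss(g, win, z, gro, None, TssCallerConfig())
        assert call is None or call.position > 4600

    def test_no_call_when_z10_below_cutoff(self):
        g, cap, z, gro = self._setup(spike=0.0)
        win = GenomeInterval("c", 2000, 5250, "+")
        assert call_tss(g, win, z, gro, None, TssCallerConfig()) is None

    def test_cutoff_monotonicity(self):
        """Raising the cutoff never creates calls that a lower cutoff lacked."""
        g, cap, z, gro = self._setup(spike=30.0)
        win = GenomeInterval("c", 2000, 5250, "+")
        called = {}
        for cutoff in (1.0, 3.0, 6.0, 12.0, 1e6):
            c = call_tss(g, win, z, gro, None, TssCallerConfig(z10_cutoff=cutoff))
            called[cutoff] = c is not None
        seen_none = False
        for cutoff in (1.0, 3.0, 6.0, 12.0, 1e6):
            if not called[cutoff]:
                seen_none = True
            assert not (seen_none and called[cutoff])

    def test_review_flag_for_distant_calls(self):
        g, cap, z, gro = self._setup(spike_at=2500)  # 2500 bp upstream of start 5000
        win = GenomeInterval("c", 2000, 5250, "+")
        call = call_tss(g, win, z, gro, None, TssCallerConfig())
        assert call is not None and call.review_flag


class TestSmallRnaTss:
    def _tracks(self, n=200, spikes=()):
        cap = np.zeros(n)
        for pos, h in spikes:
            cap[pos] = h
        t = track_from({("c", "+"): cap, ("c", "-"): np.zeros(n)})
        z = chromosome_zscores(t, outlier_fraction=0.0)
        return t, z

    def test_spike_two_bp_upstream_called_with_offset_two(self):
        t, z = self._tracks(spikes=[(98, 50.0)])
        call, offset = call_small_rna_tss("u1", "c", "+", 100, t, z)
        assert call is not None and call.position == 98 and offset == 2

    def test_low_z_rejected(self):
        t = track_from({("c", "+"): np.full(200, 3.0), ("c", "-"): np.zeros(200)})
        z = chromosome_zscores(t, outlier_fraction=0.0)  # constant -> z == 0
        call, offset = call_small_rna_tss("u1", "c", "+", 100, t, z)
        assert call is None

    def test_equal_maxima_pick_most_upstream(self):
        t, z = self._tracks(spikes=[(95, 50.0), (105, 50.0)])
        call, offset = call_small_rna_tss("u1", "c", "+", 100, t, z)
        assert call.position == 95 and offset == 5


class TestMergeStages:
    def _call(self, gid, pos, z10, stage):
        return TssCall(gid, "c", "+", pos, z10, z10, stage_label=stage)

    def test_highest_z10_wins_within_spread(self):
        calls = {
            "e": {"g": self._call("g", 100, 5.0, "e")},
            "l3": {"g": self._call("g", 150, 6.0, "l3")},
        }
        cons, unmerged = merge_stage_tss(calls)
        assert cons["g"].position == 150 and not unmerged

    def test_excess_spread_blocks_consensus(self):
        calls = {
            "e": {"g": self._call("g", 100, 5.0, "e")},
            "l3": {"g": self._call("g", 300, 6.0, "l3")},
        }
        cons, unmerged = merge_stage_tss(calls)
        assert "g" not in cons and len(unmerged["g"]) == 2

    def test_single_stage_passes_through(self):
        calls = {"e": {"g": self._call("g", 100, 5.0, "e")}}
        cons, unmerged = merge_stage_tss(calls)
        assert cons["g"].position == 100


class TestCurated:
    def test_force_and_suppress(self):
        g = gene("g", "c", 5000, 9000, "+")
        h = gene("h", "c", 10000, 12000, "+")
        ann = AnnotationSet([g, h], chrom_sizes={"c": 20000})
        calls = {"g": TssCall("g", "c", "+", 4000, 5.0, 5.0)}
        out = apply_curated(calls, [("g", None, "suppress"), ("h", 9500, "force")], ann)
        assert "g" not in out
        assert out["h"].method == "curated" and out["h"].position == 9500
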