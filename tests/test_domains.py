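"""CTCF anchoring, loop merging, summits, consensus/constitutive/clustered."""

import numpy as np
import pytest

from loopdom.contacts import Interaction
from loopdom.domains import (CtcfSite, DomainCallParams, Loop, call_domains,
                             cluster_merge_loops, clustered_ctcf_sites,
                             consensus_ctcf_sites, constitutive_domains,
                             map_to_ctcf, select_summits, top_k_fallback)
from loopdom.genomics import GenomicInterval, ScoredInterval
from loopdom.simulate import default_config, simulate_annotation, simulate_hic


def _loop(ls, le, rs, re, p=1.0, chrom="c", sample=None):
    return Loop(GenomicInterval(chrom, ls, le), GenomicInterval(chrom, rs, re),
                p_value=p, sample=sample)


def naive_fixed_point(loops, window=1000):
    """Oracle: repeated pairwise merging with restart until no pair qualifies."""
    items = [(l.left, l.right, 1) for l in loops]
    changed = True
    while changed:
        changed = False
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                la, ra, ma = items[a]
                lb, rb, mb = items[b]
                if (la.start < lb.end + window and lb.start < la.end + window
                        and ra.start < rb.end + window
                        and rb.start < ra.end + window):
                    items[a] = (la.union(lb), ra.union(rb), ma + mb)
                    items.pop(b)
                    changed = True
                    break
            if changed:
                break
    return sorted((l.start, l.end, r.start, r.end, m) for l, r, m in items)


def random_loops(rng, n):
    loops = []
    for _ in range(n):
        ls = int(rng.integers(0, 300_000))
        le = ls + int(rng.integers(200, 3000))
        rs = le + int(rng.integers(1000, 120_000))
        re = rs + int(rng.integers(200, 3000))
        loops.append(_loop(ls, le, rs, re, p=float(rng.random())))
    return loops


def domain_key(domains):
    return sorted((d.left.start, d.left.end, d.right.start, d.right.end,
                   d.member_count) for d in domains)


class TestMapToCtcf:
    SITES = [CtcfSite(GenomicInterval("c", 1000, 1019), "forward"),
             CtcfSite(GenomicInterval("c", 51_000, 51_019), "reverse")]

    def _interaction(self, bi, bj):
        return Interaction("c", bi, bj, 5.0, 1e-6, 1e-8, 1e-6, 10_000)

    def test_both_anchors_hit_retained(self):
        loops = map_to_ctcf([self._interaction(0, 5)], self.SITES, pad_bp=0)
        assert len(loops) == 1

    def test_anchor_without_site_dropped(self):
        loops = map_to_ctcf([self._interaction(0, 3)], self.SITES, pad_bp=0)
        assert loops == []

    def test_pad_monotonicity(self):
        inters = [self._interaction(0, 5), self._interaction(1, 5),
                  self._interaction(0, 4), self._interaction(2, 7)]
        kept0 = {(l.left.start, l.right.start)
                 for l in map_to_ctcf(inters, self.SITES, pad_bp=0)}
        kept5 = {(l.left.start, l.right.start)
                 for l in map_to_ctcf(inters, self.SITES, pad_bp=5000)}
        assert kept0 <= kept5


class TestTopKFallback:
    def test_large_significant_set_unchanged(self):
        sig = [_loop(i * 10_000, i * 10_000 + 100, i * 10_000 + 50_000,
                     i * 10_000 + 50_100, p=i * 1e-6) for i in range(1, 30)]
        assert top_k_fallback(sig, None, k=10) == sig[:len(sig)]

    def test_small_significant_set_rescued_from_candidates(self, rng):
        cands = random_loops(rng, 50)
        sig = sorted(cands, key=lambda l: l.p_value)[:3]
        out = top_k_fallback(sig, cands, k=10)
        assert len(out) == 10
        assert max(l.p_value for l in out) <= \
            min(l.p_value for l in cands if l not in out)

    def test_tie_at_rank_boundary_broken_by_position(self):
        tied = [_loop(ls, ls + 100, ls + 10_000, ls + 10_100, p=0.5)
                for ls in (30_000, 10_000, 20_000)]
        out = top_k_fallback([], tied + [_loop(0, 100, 5000, 5100, p=0.1)], k=2)
        assert out[0].p_value == 0.1
        assert out[1].left.start == 10_000


class TestClusterMerge:
    def test_two_identical_loops_merge(self):
        a = _loop(0, 1000, 50_000, 51_000)
        out = cluster_merge_loops([a, a])
        assert len(out) == 1 and out[0].member_count == 2

    def test_distant_loops_untouched(self):
        loops = [_loop(i * 100_000, i * 100_000 + 500,
                       i * 100_000 + 50_000, i * 100_000 + 50_500)
                 for i in range(5)]
        out = cluster_merge_loops(loops)
        assert len(out) == 5 and all(d.member_count == 1 for d in out)

    def test_transitive_chain_collapses_to_one_domain(self):
        # A overlaps B, B overlaps C, A and C do not: union anchors grow
        a = _loop(0, 500, 50_000, 50_500)
        b = _loop(900, 1400, 50_900, 51_400)
        c = _loop(1800, 2300, 51_800, 52_300)
        out = cluster_merge_loops([a, b, c], window=500)
        assert len(out) == 1 and out[0].member_count == 3
        assert out[0].left.start == 0 and out[0].left.end == 2300

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(40):
            loops = random_loops(rng, int(rng.integers(2, 120)))
            got = domain_key(cluster_merge_loops(loops))
            assert got == naive_fixed_point(loops)

    def test_input_order_invariance(self, rng):
        loops = random_loops(rng, 80)
        ref = domain_key(cluster_merge_loops(loops))
        for _ in range(3):
            shuffled = list(loops)
            rng.shuffle(shuffled)
            assert domain_key(cluster_merge_loops(shuffled)) == ref

    def test_output_is_a_fixed_point(self, rng):
        loops = random_loops(rng, 100)
        out = cluster_merge_loops(loops, window=1000)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                both = (a.left.overlaps(b.left, slack=1000)
                        and a.right.overlaps(b.right, slack=1000))
                assert not both


class TestSummits:
    def test_single_member_keeps_own_anchors(self):
        a = _loop(0, 1000, 50_000, 51_000, p=0.5)
        sl, sr, p = select_summits([a])
        assert (sl, sr, p) == (a.left, a.right, 0.5)

    def test_most_significant_member_wins(self):
        weak = _loop(0, 1000, 50_000, 51_000, p=1e-4)
        strong = _loop(200, 1200, 50_200, 51_200, p=1e-9)
        sl, sr, _ = select_summits([weak, strong])
        assert sl == strong.left and sr == strong.right

    def test_exact_tie_takes_leftmost(self):
        a = _loop(500, 1500, 50_000, 51_000, p=1e-5)
        b = _loop(0, 1000, 50_000, 51_000, p=1e-5)
        sl, _, _ = select_summits([a, b])
        assert sl.start == 0

    def test_empty_members_error(self):
        with pytest.raises(ValueError):
            select_summits([])


class TestCallDomains:
    def test_empty_site_list_gives_no_domains(self):
        cfg = default_config(seed=21, n_loops=10,
                             chrom_lengths=(("chr1", 5_000_000),),
                             background_depth=2e5)
        mats, _ = simulate_hic(cfg)
        domains, summary = call_domains(mats["chr1"], [])
        assert domains == [] and summary["n_domains"] == 0

    def test_deterministic_given_same_inputs(self):
        cfg = default_config(seed=22, n_loops=10,
                             chrom_lengths=(("chr1", 5_000_000),),
                             background_depth=2e5)
        mats, _ = simulate_hic(cfg)
        annot = simulate_annotation(cfg)
        d1, _ = call_domains(mats["chr1"], list(annot.sites))
        d2, _ = call_domains(mats["chr1"], list(annot.sites))
        assert domain_key(d1) == domain_key(d2)


class TestConsensusSites:
    MOTIF = CtcfSite(GenomicInterval("c", 1005, 1024, strand="+"), "forward",
                     signal=9.0)

    def _sets(self, n_with, n_total):
        peak = GenomicInterval("c", 1000, 1200)
        sets = {f"ct{k}": [peak] for k in range(n_with)}
        for k in range(n_with, n_total):
            sets[f"ct{k}"] = [GenomicInterval("c", 500_000, 500_200)]
        return sets

    def test_peak_above_threshold_becomes_consensus(self):
        out = consensus_ctcf_sites(self._sets(50, 142), [self.MOTIF])
        snapped = [s for s in out if s.orientation == "forward"]
        assert len(snapped) == 1
        assert snapped[0].interval == self.MOTIF.interval

    def test_peak_below_threshold_excluded(self):
        out = consensus_ctcf_sites(self._sets(10, 142), [self.MOTIF])
        assert all(s.interval.start != 1005 for s in out)

    def test_unmatched_consensus_keeps_peak_span_unclear(self):
        out = consensus_ctcf_sites(self._sets(142, 142), [])
        assert len(out) == 1
        assert out[0].orientation == "unclear"
        assert out[0].interval == GenomicInterval("c", 1000, 1200)


class TestConstitutive:
    def _sets(self, n_present, n_samples=16):
        shared = _loop(10_000, 11_000, 500_000, 501_000)
        sets = {}
        for s in range(n_samples):
            loops = [_loop(2_000_000 + s * 50_000, 2_000_000 + s * 50_000 + 1000,
                           3_000_000 + s * 50_000, 3_000_000 + s * 50_000 + 1000,
                           sample=f"s{s}")]
            if s < n_present:
                loops.append(Loop(shared.left, shared.right, sample=f"s{s}"))
            sets[f"s{s}"] = loops
        return sets

    def _shared_flag(self, union):
        d = next(d for d in union if d.left.start == 10_000)
        return d.constitutive

    @pytest.mark.parametrize("n_present,expected",
                             [(16, True), (8, True), (7, False)])
    def test_fifty_percent_rule(self, n_present, expected):
        union, _ = constitutive_domains(self._sets(n_present))
        assert self._shared_flag(union) is expected

    def test_flag_is_monotone_in_sample_presence(self):
        for n in range(8, 16):
            union, _ = constitutive_domains(self._sets(n))
            assert self._shared_flag(union)


class TestClusteredSites:
    def test_quadratic_curve_transitions_at_half(self):
        m = 101
        peaks = [ScoredInterval("c", 100_000 * i, 100_000 * i + 500,
                                score=(i / (m - 1)) ** 2 + 1e-6)
                 for i in range(m)]
        res = clustered_ctcf_sites(peaks)
        assert res.transition_defined
        assert res.transition_rank == pytest.approx(0.5, abs=1.5 / (m - 1))

    def test_nearby_peaks_merged_before_ranking(self):
        peaks = [ScoredInterval("c", 0, 500, score=5.0),
                 ScoredInterval("c", 10_000, 10_500, score=7.0),
                 ScoredInterval("c", 200_000, 200_500, score=1.0)]
        res = clustered_ctcf_sites(peaks, merge_dist=12_500)
        assert len(res.merged) == 2
        assert max(p.score for p in res.merged) == 12.0

    def test_equal_signals_all_typical_with_undefined_transition(self):
        peaks = [ScoredInterval("c", 100_000 * i, 100_000 * i + 500, score=3.0)
                 for i in range(10)]
        res = clustered_ctcf_sites(peaks)
        assert not res.transition_defined
        assert set(res.labels) == {"typical"}

    def test_bimodal_signal_labelled_accurately(self, rng):
        n = 600
        truth = rng.random(n) < 0.05
        sig = np.where(truth, rng.normal(1000, 100, n), rng.normal(10, 1, n))
        peaks = [ScoredInterval("c", 100_000 * i, 100_000 * i + 500,
                                name=f"p{i}", score=max(float(s), 0.1))
                 for i, s in enumerate(sig)]
        res = clustered_ctcf_sites(peaks)
        by_name = {f"p{i}": bool(t) for i, t in enumerate(truth)}
        acc = np.mean([(lab == "clustered") == by_name[m.name]
                       for m, lab in zip(res.merged, res.labels)])
        assert acc >= 0.9
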