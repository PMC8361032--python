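"""CTCF loop domains: anchoring, redundancy merging, summits, constitutive calls.

A *loop* is a significant contact between two anchors; anchoring to CTCF
sites filters out non-CTCF structures (enhancer-promoter loops etc.).
Redundant loops are merged by a two-step iterative clustering: a fixed number
of preclustering rounds on even/odd rank splits, then complete pairwise
merging until convergence.  Because merged anchors only ever grow, the
procedure converges to the unique fixed point of repeated pairwise merging,
independent of input order.  The *summit* anchors of a merged domain are the
anchors of its most significant member loop and serve as the working
boundaries downstream.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contacts import DecayModel, Interaction, call_significant_interactions, fit_decay
from .genomics import ContactMatrix, GenomicInterval, ScoredInterval

__all__ = [
    "CtcfSite",
    "Loop",
    "Domain",
    "DomainCallParams",
    "map_to_ctcf",
    "top_k_fallback",
    "cluster_merge_loops",
    "select_summits",
    "call_domains",
    "consensus_ctcf_sites",
    "constitutive_domains",
    "clustered_ctcf_sites",
]

ORIENTATIONS = {"forward", "reverse", "unclear"}


@dataclass(frozen=True)
class CtcfSite:
    interval: GenomicInterval
    orientation: str = "unclear"
    source: str = "motif"  # motif | peak | consensus
    signal: float = 0.0

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.source == "motif" and self.orientation == "unclear":
            raise ValueError("motif-derived sites must be oriented")


@dataclass(frozen=True)
class Loop:
    """A CTCF-anchored significant interaction (left anchor upstream)."""

    left: GenomicInterval
    right: GenomicInterval
    p_value: float = 1.0
    q_value: float = float("nan")
    sample: str | None = None

    def __post_init__(self):
        if self.left.chrom != self.right.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.left.start > self.right.start:
            raise ValueError("left anchor must be upstream of right anchor")


@dataclass
class Domain:
    """A merged CTCF loop domain with union and summit anchors."""

    left: GenomicInterval
    right: GenomicInterval
    summit_left: GenomicInterval
    summit_right: GenomicInterval
    best_p: float
    members: tuple[Loop, ...]
    gene_count: int | None = None
    klass: str | None = None          # single | multi | zero
    presence: tuple[bool, ...] | None = None
    constitutive: bool | None = None

    @property
    def member_count(self) -> int:
        return len(self.members)

    @property
    def length(self) -> int:
        """Distance between summit anchor midpoints (working domain length)."""
        return self.summit_right.midpoint - self.summit_left.midpoint

    @property
    def chrom(self) -> str:
        return self.left.chrom

    def span(self) -> GenomicInterval:
        """Summit-midpoint to summit-midpoint interval."""
        return GenomicInterval(self.chrom, self.summit_left.midpoint,
                               self.summit_right.midpoint)


# ---------------------------------------------------------------------------
# CTCF anchoring and the top-k fallback
# ---------------------------------------------------------------------------

def _site_index(sites: Sequence[CtcfSite]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        tmp.setdefault(s.interval.chrom, []).append((s.interval.start, s.interval.end))
    for chrom, spans in tmp.items():
        spans.sort()
        starts = np.array([a for a, _ in spans])
        ends = np.array([b for _, b in spans])
        by_chrom[chrom] = (starts, ends)
    return by_chrom


def _has_site(index, chrom: str, start: int, end: int, pad: int) -> bool:
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    hi = np.searchsorted(starts, end + pad, side="left")
    return bool(np.any(ends[:hi] > start - pad))


def map_to_ctcf(interactions: Sequence[Interaction], sites: Sequence[CtcfSite],
                pad_bp: int = 10_000) -> list[Loop]:
    """Keep interactions whose anchors (extended by ``pad_bp``) each hit a site.

    The anchor intervals stay at bin resolution.  The default pad of one bin
    absorbs the one-bin positional uncertainty of binned loop pixels.
    """
    index = _site_index(sites)
    loops = []
    for it in interactions:
        la, ra = it.anchors()
        if (_has_site(index, la.chrom, la.start, la.end, pad_bp)
                and _has_site(index, ra.chrom, ra.start, ra.end, pad_bp)):
            loops.append(Loop(la, ra, p_value=it.p_value, q_value=it.q_value))
    return loops


def top_k_fallback(significant: Sequence[Loop],
                   candidates: Sequence[Loop] | None = None,
                   k: int = 10_000) -> list[Loop]:
    """Low-depth rescue: take the k most significant candidate loops.

    If fewer than ``k`` loops are significant but the raw candidate set has at
    least ``k``, return the ``k`` smallest-p candidates (ties broken by
    (chrom, left start, right start)); otherwise return the significant set.
    """
    significant = list(significant)
    if len(significant) >= k or candidates is None or len(candidates) < k:
        return significant
    key = lambda l: (l.p_value, l.left.chrom, l.left.start, l.right.start)
    return sorted(candidates, key=key)[:k]


# ---------------------------------------------------------------------------
# two-step iterative merge
# ---------------------------------------------------------------------------

def _anchors_near(al: GenomicInterval, ar: GenomicInterval,
                  bl: GenomicInterval, br: GenomicInterval, window: int) -> bool:
    """Both anchor pairs overlap after symmetric extension by window/2 each."""
    return al.overlaps(bl, slack=window) and ar.overlaps(br, slack=window)


@dataclass
class _Cluster:
    left: GenomicInterval
    right: GenomicInterval
    members: list[Loop]


def _merge_clusters(group: list[_Cluster]) -> _Cluster:
    left = group[0].left
    right = group[0].right
    members: list[Loop] = []
    for c in group:
        left = left.union(c.left)
        right = right.union(c.right)
        members.extend(c.members)
    return _Cluster(left, right, members)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _rank_sort(clusters: list[_Cluster]) -> list[_Cluster]:
    return sorted(clusters, key=lambda c: (c.left.start, c.left.end,
                                           c.right.start, c.right.end))


def _merge_pass(clusters: list[_Cluster], window: int,
                bipartite: bool) -> tuple[list[_Cluster], bool]:
    """One merge round; with ``bipartite`` only even-rank/odd-rank pairs qualify."""
    clusters = _rank_sort(clusters)
    n = len(clusters)
    uf = _UnionFind(n)
    merged_any = False
    # sorted by left start: a partner j > i qualifies only while its left
    # anchor can still reach cluster i's extended left anchor
    for i in range(n):
        ci = clusters[i]
        for j in range(i + 1, n):
            cj = clusters[j]
            if cj.left.start >= ci.left.end + window:
                break
            if bipartite and (i % 2) == (j % 2):
                continue
            if _anchors_near(ci.left, ci.right, cj.left, cj.right, window):
                uf.union(i, j)
                merged_any = True
    if not merged_any:
        return clusters, False
    groups: dict[int, list[_Cluster]] = {}
    for i, c in enumerate(clusters):
        groups.setdefault(uf.find(i), []).append(c)
    return [_merge_clusters(g) for g in groups.values()], True


def cluster_merge_loops(loops: Sequence[Loop], window: int = 1000,
                        n_pre: int = 50) -> list[Domain]:
    """Merge redundant loops into domains (per chromosome independently).

    Step 1 (preclustering): rank loops by position, split into even/odd rank
    sets, merge every qualifying cross-set pair into a union-anchor loop, and
    feed merged + retained loops to the next round; ``n_pre`` rounds.  Ranks
    are recomputed each round.  Step 2 (complete): merge any qualifying pair
    within the remaining single set (self-pairs excluded) until no pair
    qualifies.  Output domains carry all constituent original loops.
    """
    by_chrom: dict[str, list[Loop]] = {}
    for l in loops:
        by_chrom.setdefault(l.left.chrom, []).append(l)
    domains: list[Domain] = []
    for chrom in sorted(by_chrom):
        clusters = [_Cluster(l.left, l.right, [l]) for l in by_chrom[chrom]]
        for _ in range(n_pre):
            clusters, changed = _merge_pass(clusters, window, bipartite=True)
            if not changed:
                break
        while True:
            clusters, changed = _merge_pass(clusters, window, bipartite=False)
            if not changed:
                break
        for c in _rank_sort(clusters):
            sl, sr, best_p = select_summits(c.members)
            domains.append(Domain(c.left, c.right, sl, sr, best_p,
                                  tuple(c.members)))
    return domains


def select_summits(members: Sequence[Loop]
                   ) -> tuple[GenomicInterval, GenomicInterval, float]:
    """Anchors of the most significant member loop (ties: leftmost)."""
    if not members:
        raise ValueError("domain has no member loops")
    best = min(members, key=lambda l: (l.p_value, l.left.start, l.right.start))
    return best.left, best.right, best.p_value


# ---------------------------------------------------------------------------
# end-to-end domain calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainCallParams:
    d_min: int = 30_000
    d_max: int = 2_000_000
    n_strata: int = 100
    q_cut: float = 0.01
    pad_bp: int = 10_000
    window: int = 1000
    n_pre: int = 50
    tail: str = "binomial"
    fallback_k: int | None = None  # enable the top-k rescue when set


def call_domains(matrix: ContactMatrix, sites: Sequence[CtcfSite],
                 params: DomainCallParams = DomainCallParams(),
                 decay: DecayModel | None = None
                 ) -> tuple[list[Domain], dict]:
    """Chain decay fit -> significance -> CTCF anchoring -> merge -> summits."""
    if decay is None:
        decay = fit_decay(matrix, n_strata=params.n_strata,
                          d_min=params.d_min, d_max=params.d_max)
    significant, candidates = call_significant_interactions(
        matrix, decay, q_cut=params.q_cut, tail=params.tail, return_all=True)
    loops = map_to_ctcf(significant, sites, pad_bp=params.pad_bp)
    if params.fallback_k is not None:
        all_loops = map_to_ctcf(candidates, sites, pad_bp=params.pad_bp)
        loops = top_k_fallback(loops, all_loops, k=params.fallback_k)
    domains = cluster_merge_loops(loops, window=params.window, n_pre=params.n_pre)
    summary = {
        "n_interactions": len(significant),
        "n_loops": len(loops),
        "n_domains": len(domains),
        "median_length": (statistics.median(d.length for d in domains)
                          if domains else float("nan")),
    }
    return domains, summary


# ---------------------------------------------------------------------------
# consensus CTCF sites across cell types
# ---------------------------------------------------------------------------

def consensus_ctcf_sites(peak_sets: Mapping[str, Sequence[GenomicInterval]],
                         motifs: Sequence[CtcfSite],
                         min_frac: float = 0.3) -> list[CtcfSite]:
    """Peaks recurring in > ``min_frac`` of cell types, snapped to motifs.

    Peaks are pooled across cell types and clustered by overlap
    (single linkage).  A cluster present in more than ``min_frac`` of the
    unique cell types becomes a consensus site; if it overlaps >= 1 motif it
    adopts the coordinates and orientation of the best-scoring overlapping
    motif, otherwise it keeps the merged peak span with orientation unclear.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    n_types = len(peak_sets)
    pooled = [(iv, ct) for ct, ivs in peak_sets.items() for iv in ivs]
    pooled.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[CtcfSite] = []
    cluster: list[tuple[GenomicInterval, str]] = []
    span: GenomicInterval | None = None

    def _flush():
        if not cluster:
            return
        types = {ct for _, ct in cluster}
        if len(types) / n_types > min_frac:
            hits = [m for m in motifs
                    if m.interval.overlaps(span) and m.orientation != "unclear"]
            if hits:
                best = max(hits, key=lambda m: m.signal)
                out.append(CtcfSite(best.interval, best.orientation,
                                    source="consensus", signal=best.signal))
            else:
                out.append(CtcfSite(span, "unclear", source="consensus",
                                    signal=float(len(types))))

    for iv, ct in pooled:
        if span is not None and iv.overlaps(span):
            cluster.append((iv, ct))
            span = span.union(iv)
        else:
            _flush()
            cluster = [(iv, ct)]
            span = iv
    _flush()
    return out


# ---------------------------------------------------------------------------
# constitutive domains across samples
# ---------------------------------------------------------------------------

def constitutive_domains(domain_sets: Mapping[str, Sequence[Domain | Loop]],
                         min_frac: float = 0.5,
                         window: int = 1000) -> tuple[list[Domain], list[str]]:
    """Union domains across samples with per-sample presence vectors.

    Each sample's domains (their summit anchors, the working boundaries) are
    pooled and re-merged; ``presence[s]`` is true iff >= 1 member of the
    union domain originated from sample ``s``; the constitutive flag requires
    ``mean(presence) >= min_frac``.
    """
    if len(domain_sets) < 2:
        raise ValueError("need at least two samples")
    samples = list(domain_sets)
    pooled: list[Loop] = []
    for s in samples:
        for d in domain_sets[s]:
            if isinstance(d, Domain):
                pooled.append(Loop(d.summit_left, d.summit_right,
                                   p_value=d.best_p, sample=s))
            else:
                pooled.append(Loop(d.left, d.right, p_value=d.p_value, sample=s))
    union = cluster_merge_loops(pooled, window=window)
    for d in union:
        present = {m.sample for m in d.members}
        d.presence = tuple(s in present for s in samples)
        d.constitutive = sum(d.presence) / len(samples) >= min_frac
    return union, samples


# ---------------------------------------------------------------------------
# clustered vs typical CTCF sites (rank-signal tangent point)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusteredSiteResult:
    merged: tuple[ScoredInterval, ...]   # ranked ascending by total signal
    labels: tuple[str, ...]              # "clustered" | "typical", same order
    transition_rank: float | None        # scaled rank of the slope-1 tangent
    transition_defined: bool


def clustered_ctcf_sites(peaks: Sequence[ScoredInterval],
                         merge_dist: int = 12_500) -> ClusteredSiteResult:
    """ROSE-style partition of merged CTCF peaks at the slope-1 tangent.

    Peaks within ``merge_dist`` are merged with summed signal; merged peaks
    are ranked ascending by total signal and both axes rescaled to [0, 1].
    The transition is the first rank where the discrete derivative of scaled
    signal with respect to scaled rank exceeds 1; peaks above it are
    *clustered*, peaks below are *typical*.
    """
    if len(peaks) < 2:
        raise ValueError("need at least two peaks")
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    merged: list[ScoredInterval] = []
    cur = ordered[0]
    for p in ordered[1:]:
        if p.chrom == cur.chrom and p.start - cur.end <= merge_dist:
            cur = ScoredInterval(cur.chrom, cur.start, max(cur.end, p.end),
                                 name=cur.name, score=cur.score + p.score)
        else:
            merged.append(cur)
            cur = p
    merged.append(cur)
    if len(merged) < 2:
        raise ValueError("all peaks merged into one site")
    merged.sort(key=lambda p: (p.score, p.chrom, p.start))
    signal = np.array([p.score for p in merged], dtype=float)
    if signal.sum() <= 0:
        raise ValueError("merged peaks must have positive total signal")
    if np.ptp(signal) == 0:
        return ClusteredSiteResult(tuple(merged), ("typical",) * len(merged),
                                   None, False)
    x = np.linspace(0.0, 1.0, len(merged))
    y = (signal - signal.min()) / np.ptp(signal)
    slopes = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slopes > 1.0)
    if len(above) == 0:
        return ClusteredSiteResult(tuple(merged), ("typical",) * len(merged),
                                   None, False)
    t = int(above[0])
    labels = tuple("clustered" if i > t else "typical"
                   for i in range(len(merged)))
    return ClusteredSiteResult(tuple(merged), labels, float(x[t]), True)
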