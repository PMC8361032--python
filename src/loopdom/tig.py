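"""Topologically isolated genes: domain gene content and enrichment tests.

A domain is classified by the number of protein-coding transcription start
sites (TSSs) that fall strictly inside its summit-midpoint span (half-open:
a TSS exactly at the left midpoint counts, at the right midpoint does not).
Domains with exactly one such TSS are *single-gene* domains and their gene is
a topologically isolated gene (TIG); the single-gene count is tested for
enrichment by permutation (uniform re-placement of domains or genes on their
own chromosomes) and gene-set enrichment uses Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .domains import Domain
from .genomics import Genome, GenomicInterval

__all__ = [
    "GeneRecord",
    "PermutationResult",
    "classify_domains",
    "shuffle_features",
    "permutation_enrichment",
    "fisher_enrichment",
    "ctigs",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    biotype: str = "protein_coding"
    transcription_factor: bool = False
    developmental_regulator: bool = False
    early_developmental_regulator: bool = False

    @property
    def protein_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    mode: str
    n_perm: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _tss_index(genes: Sequence[GeneRecord]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        if g.protein_coding:
            by_chrom.setdefault(g.chrom, []).append(g.tss)
    return {c: np.sort(np.asarray(t)) for c, t in by_chrom.items()}


def _count_in_spans(spans: Sequence[tuple[str, int, int]],
                    tss_index: Mapping[str, np.ndarray]) -> np.ndarray:
    counts = np.zeros(len(spans), dtype=int)
    for i, (chrom, lo, hi) in enumerate(spans):
        tss = tss_index.get(chrom)
        if tss is None:
            continue
        counts[i] = np.searchsorted(tss, hi, side="left") - \
            np.searchsorted(tss, lo, side="left")
    return counts


def classify_domains(domains: Sequence[Domain], genes: Sequence[GeneRecord]
                     ) -> tuple[list[Domain], list[GeneRecord]]:
    """Annotate gene_count/class on each domain and return the TIG list.

    Only protein-coding genes count; the span is [left summit midpoint,
    right summit midpoint).  A TSS lying in two overlapping domains counts
    in each.
    """
    index = _tss_index(genes)
    pc_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.protein_coding:
            pc_by_chrom.setdefault(g.chrom, []).append(g)
    for c in pc_by_chrom:
        pc_by_chrom[c].sort(key=lambda g: g.tss)

    tigs: list[GeneRecord] = []
    seen: set[str] = set()
    spans = [(d.chrom, d.summit_left.midpoint, d.summit_right.midpoint)
             for d in domains]
    counts = _count_in_spans(spans, index)
    for d, n in zip(domains, counts):
        d.gene_count = int(n)
        d.klass = "single" if n == 1 else ("multi" if n >= 2 else "zero")
        if n == 1:
            chrom, lo, hi = d.chrom, d.summit_left.midpoint, d.summit_right.midpoint
            tss = index[chrom]
            j = int(np.searchsorted(tss, lo, side="left"))
            gene = pc_by_chrom[chrom][j]
            if gene.gene_id not in seen:
                seen.add(gene.gene_id)
                tigs.append(gene)
    return list(domains), tigs


# ---------------------------------------------------------------------------
# shuffling and permutation enrichment
# ---------------------------------------------------------------------------

def shuffle_features(features, genome: Genome, mode: str,
                     rng: np.random.Generator):
    """Uniform random re-placement on the feature's own chromosome.

    ``mode="domains"``: each span keeps its length, start ~ Uniform{0..G-L}
    (shuffled spans may overlap each other).  ``mode="genes"``: each TSS is
    re-placed uniformly on its chromosome.
    """
    if mode == "domains":
        out = []
        for span in features:
            chrom, lo, hi = span
            length = hi - lo
            g = genome[chrom]
            if length > g:
                raise ValueError(f"span of {length} bp exceeds {chrom} length")
            start = int(rng.integers(0, g - length + 1))
            out.append((chrom, start, start + length))
        return out
    if mode == "genes":
        return [GeneRecord(g.gene_id, g.chrom, int(rng.integers(0, genome[g.chrom])),
                           g.strand, g.biotype, g.transcription_factor,
                           g.developmental_regulator, g.early_developmental_regulator)
                for g in features]
    raise ValueError(f"unknown shuffle mode {mode!r}")


def permutation_enrichment(domains: Sequence[Domain],
                           genes: Sequence[GeneRecord],
                           genome: Genome, mode: str = "domains",
                           n_perm: int = 999,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None) -> PermutationResult:
    """Permutation test of the single-gene domain count.

    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in {"domains", "genes"}:
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    index = _tss_index(genes)
    spans = [(d.chrom, d.summit_left.midpoint, d.summit_right.midpoint)
             for d in domains]
    observed = int(np.sum(_count_in_spans(spans, index) == 1))
    null = np.empty(n_perm, dtype=int)
    for t in range(n_perm):
        if mode == "domains":
            shuffled = shuffle_features(spans, genome, "domains", rng)
            null[t] = int(np.sum(_count_in_spans(shuffled, index) == 1))
        else:
            sh_genes = shuffle_features(
                [g for g in genes if g.protein_coding], genome, "genes", rng)
            null[t] = int(np.sum(_count_in_spans(spans, _tss_index(sh_genes)) == 1))
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(observed, null, p, mode, n_perm, seed)


# ---------------------------------------------------------------------------
# Fisher enrichment and cTIGs
# ---------------------------------------------------------------------------

def fisher_enrichment(hits_in_category: int, category_size: int,
                      hits_total: int, universe_size: int
                      ) -> tuple[float, float, float]:
    """Two-sided Fisher exact test of a 2x2 gene-set table.

    Returns (fold_enrichment, odds_ratio, p_value) where
    ``fold = (hits_in_category/category_size) / (hits_total/universe_size)``.
    """
    if universe_size <= 0:
        raise ValueError("universe must be non-empty")
    a = hits_in_category
    b = category_size - a
    c = hits_total - a
    d = universe_size - category_size - c
    if min(a, b, c, d) < 0 or a > min(category_size, hits_total):
        raise ValueError("inconsistent counts")
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if hits_total == 0 or category_size == 0:
        fold = float("nan")
    else:
        fold = (a / category_size) / (hits_total / universe_size)
    return float(fold), float(odds), float(p)


def ctigs(domains: Sequence[Domain], genes: Sequence[GeneRecord]
          ) -> list[GeneRecord]:
    """Genes of constitutive single-gene domains (constitutive TIGs)."""
    const = [d for d in domains if d.constitutive]
    _, tig_list = classify_domains(const, genes)
    return tig_list
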