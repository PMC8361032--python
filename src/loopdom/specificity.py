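"""Cell-type-specific regulators and enhancer co-activation.

A gene is called a cell-type-specific regulator when (i) the normalized
Shannon entropy of its TPM profile across samples is below 0.8, (ii) its
maximal TPM exceeds 10, and (iii) it is expressed at least 7-fold above its
across-sample mean in at least one but no more than five samples.  Enhancer
activity is H3K27ac signal normalized per 10 million reads; enhancers whose
maximal normalized signal stays below 5 are treated as inactive.  Within- vs
cross-domain co-activation is measured as the Pearson correlation across
samples between an enhancer's activity and the expression of its paired
gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import Domain
from .genomics import GenomicInterval
from .stats import pearson, rank_sum_p
from .tig import GeneRecord

__all__ = [
    "SpecificityCall",
    "expression_entropy",
    "call_specific_regulators",
    "recurrence_enrichment_curve",
    "relative_activity",
    "normalize_enhancer_signal",
    "filter_active",
    "coactivation_correlation",
]


@dataclass(frozen=True)
class SpecificityCall:
    gene: str
    entropy: float
    max_tpm: float
    n_high_samples: int
    specific: bool


def expression_entropy(tpm_vector) -> float:
    """Normalized Shannon entropy of an expression profile, in [0, 1].

    ``prop = x / sum(x)``; zero proportions contribute nothing; natural log,
    normalized by ``log(len(x))``.  Uniform profiles give 1, one-hot gives 0.
    """
    x = np.asarray(tpm_vector, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a vector of length >= 2")
    if np.any(x < 0):
        raise ValueError("TPM values must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero profile")
    prop = x / total
    nz = prop > 0
    return float(-(prop[nz] * np.log(prop[nz])).sum() / np.log(len(x)))


def call_specific_regulators(matrix: pd.DataFrame,
                             candidate_genes: Sequence[str] | None = None,
                             entropy_cut: float = 0.8,
                             min_max_tpm: float = 10.0,
                             fold: float = 7.0,
                             max_active: int = 5) -> list[SpecificityCall]:
    """Apply the three specificity filters to each candidate gene.

    ``matrix`` is genes x samples TPM.  A gene is specific iff
    entropy < entropy_cut, max TPM > min_max_tpm, and the number of samples
    with TPM >= fold * across-sample mean lies in (0, max_active].
    """
    if candidate_genes is None:
        candidate_genes = list(matrix.index)
    calls = []
    for gene in candidate_genes:
        x = matrix.loc[gene].to_numpy(dtype=float)
        if x.sum() <= 0:
            calls.append(SpecificityCall(gene, float("nan"), float(x.max()), 0, False))
            continue
        ent = expression_entropy(x)
        max_tpm = float(x.max())
        n_high = int(np.sum(x >= fold * x.mean()))
        specific = (ent < entropy_cut and max_tpm > min_max_tpm
                    and 0 < n_high <= max_active)
        calls.append(SpecificityCall(gene, ent, max_tpm, n_high, specific))
    return calls


def recurrence_enrichment_curve(recurrence: pd.Series,
                                specific_set: set[str],
                                bin_size: int = 300
                                ) -> tuple[pd.DataFrame, float, float]:
    """Fold enrichment of specific regulators against TIG recurrence.

    Genes are sorted by recurrence (number of cell types in which the gene is
    a TIG) and partitioned into consecutive bins of ``bin_size`` genes (a
    trailing bin smaller than ``bin_size/2`` is dropped).  Per bin the fold
    is the bin's specific fraction over the overall specific fraction.
    Returns the bin table and the Pearson r, p over the bin points.
    """
    n = len(recurrence)
    if n < bin_size:
        raise ValueError("fewer genes than one bin")
    overall = np.mean([g in specific_set for g in recurrence.index])
    if overall == 0:
        raise ValueError("no specific genes in the universe")
    order = recurrence.sort_values(kind="stable")
    rows = []
    for a in range(0, n, bin_size):
        chunk = order.iloc[a:a + bin_size]
        if len(chunk) < bin_size and len(chunk) < bin_size / 2:
            break
        frac = np.mean([g in specific_set for g in chunk.index])
        rows.append({"mean_recurrence": float(chunk.mean()),
                     "fold_enrichment": float(frac / overall),
                     "n_genes": len(chunk)})
    table = pd.DataFrame(rows)
    r, p = pearson(table["mean_recurrence"], table["fold_enrichment"])
    return table, r, p


def relative_activity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Each entry divided by its row mean; zero-mean rows become NaN."""
    means = matrix.mean(axis=1)
    out = matrix.div(means, axis=0)
    out.loc[means == 0] = np.nan
    return out


def normalize_enhancer_signal(raw: pd.DataFrame,
                              library_sizes: pd.Series) -> pd.DataFrame:
    """Per-sample signal normalized to reads per 10 million."""
    missing = [s for s in raw.columns if s not in library_sizes.index]
    if missing:
        raise ValueError(f"missing library sizes for {missing}")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return raw * (1e7 / library_sizes[raw.columns])


def filter_active(signal: pd.DataFrame, min_max: float = 5.0) -> pd.DataFrame:
    """Drop enhancers whose maximal normalized signal is below ``min_max``."""
    return signal.loc[signal.max(axis=1) >= min_max]


def coactivation_correlation(enhancer_signal: pd.DataFrame,
                             enhancer_intervals: Mapping[str, GenomicInterval],
                             domains: Sequence[Domain],
                             genes: Sequence[GeneRecord],
                             expression: pd.DataFrame,
                             mode: str = "within") -> pd.Series:
    """Per-enhancer Pearson r between activity and paired gene expression.

    ``within`` pairs an enhancer with the gene of its containing constitutive
    single-gene domain; ``cross`` pairs it with the nearest gene (by TSS)
    outside that domain.  Enhancers outside every constitutive single-gene
    domain, and degenerate constant profiles, are excluded.
    """
    if mode not in {"within", "cross"}:
        raise ValueError(f"unknown mode {mode!r}")
    csd = [d for d in domains if d.constitutive and d.klass == "single"]
    samples = [s for s in enhancer_signal.columns if s in expression.columns]
    if len(samples) < 3:
        raise ValueError("need >= 3 shared samples")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.protein_coding:
            by_chrom.setdefault(g.chrom, []).append(g)

    out = {}
    for enh_id, iv in enhancer_intervals.items():
        if enh_id not in enhancer_signal.index:
            continue
        mid = iv.midpoint
        host = next((d for d in csd if d.chrom == iv.chrom
                     and d.summit_left.midpoint <= mid < d.summit_right.midpoint),
                    None)
        if host is None:
            continue
        lo, hi = host.summit_left.midpoint, host.summit_right.midpoint
        if mode == "within":
            partner = next((g for g in by_chrom.get(iv.chrom, ())
                            if lo <= g.tss < hi), None)
        else:
            outside = [g for g in by_chrom.get(iv.chrom, ())
                       if not (lo <= g.tss < hi)]
            partner = min(outside, key=lambda g: abs(g.tss - mid), default=None)
        if partner is None or partner.gene_id not in expression.index:
            continue
        r, _ = pearson(enhancer_signal.loc[enh_id, samples],
                       expression.loc[partner.gene_id, samples])
        if not np.isnan(r):
            out[enh_id] = r
    return pd.Series(out, name=f"r_{mode}", dtype=float)


def compare_coactivation(r_within: pd.Series, r_cross: pd.Series) -> float:
    """Two-sided rank-sum p between within- and cross-domain correlations."""
    return rank_sum_p(r_within.to_numpy(), r_cross.to_numpy())
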