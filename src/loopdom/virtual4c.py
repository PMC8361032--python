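"""Boundary-anchored virtual 4C: profiles, aggregates, group statistics.

Each domain boundary is treated as a 4C viewpoint: the *left row* of a
profile reads the contacts between the neighbourhood of the left summit
boundary and the right boundary bin, the *right row* is the mirror-image
counterpart.  Aggregating rows column-wise across many domains produces the
mean +/- standard-error profile; group differences are tested on the
boundary-to-boundary (center) values with a two-sided rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .contacts import normalize_library_size
from .domains import Domain
from .genomics import ContactMatrix
from .stats import rank_sum_p
from .tig import GeneRecord

__all__ = [
    "BoundaryProfile",
    "AggregateProfile",
    "boundary_profile",
    "aggregate_profiles",
    "compare_groups",
    "boundary_fold_change",
    "strongest_domain_per_gene",
]


@dataclass(frozen=True)
class BoundaryProfile:
    """Per-domain virtual-4C rows of length 2F+1 (center index F)."""

    domain_id: int
    left_row: np.ndarray
    right_row: np.ndarray
    flank_bins: int
    value_kind: str = "normalized_contact"

    @property
    def center(self) -> float:
        return float(self.left_row[self.flank_bins])


@dataclass(frozen=True)
class AggregateProfile:
    """Column-wise mean and standard error across domains."""

    left_mean: np.ndarray
    left_se: np.ndarray
    right_mean: np.ndarray
    right_se: np.ndarray
    n: np.ndarray              # usable rows per left column
    group: str = ""


def boundary_profile(matrix: ContactMatrix, domain: Domain, flank_bins: int,
                     domain_id: int = 0,
                     value_kind: str = "normalized_contact"
                     ) -> BoundaryProfile | None:
    """Virtual-4C rows for one domain; None when the domain is unusable.

    ``left_row[k] = matrix[left_bin - F + k, right_bin]`` and
    ``right_row[k] = matrix[left_bin, right_bin - F + k]``; out-of-range bins
    are NaN.  Domains spanning <= 2F bins, or with boundaries outside the
    matrix, are skipped with a warning.
    """
    f = flank_bins
    lb = matrix.bin_of(domain.summit_left.midpoint)
    rb = matrix.bin_of(domain.summit_right.midpoint)
    n = matrix.n_bins
    if not (0 <= lb < n and 0 <= rb < n):
        warnings.warn(f"domain {domain_id}: boundary outside matrix, skipped")
        return None
    if rb - lb <= 2 * f and f > 0:
        warnings.warn(f"domain {domain_id}: span <= 2*flank bins, skipped")
        return None
    left = np.full(2 * f + 1, np.nan)
    right = np.full(2 * f + 1, np.nan)
    for k in range(2 * f + 1):
        i = lb - f + k
        if 0 <= i < n:
            left[k] = matrix.counts[i, rb]
        j = rb - f + k
        if 0 <= j < n:
            right[k] = matrix.counts[lb, j]
    return BoundaryProfile(domain_id, left, right, f, value_kind)


def aggregate_profiles(profiles: Sequence[BoundaryProfile],
                       group: str = "") -> AggregateProfile:
    """Column means and standard errors (SE = sd/sqrt(n); 0 when n = 1)."""
    profiles = [p for p in profiles if p is not None]
    if not profiles:
        raise ValueError("no usable profiles")

    def _agg(rows: np.ndarray):
        n = np.sum(~np.isnan(rows), axis=0)
        if np.any(n == 0):
            raise ValueError("a column has no usable rows")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(rows, axis=0)
            sd = np.nanstd(rows, axis=0, ddof=1)
        se = np.where(n > 1, sd / np.sqrt(n), 0.0)
        return mean, np.nan_to_num(se), n

    lm, lse, n = _agg(np.vstack([p.left_row for p in profiles]))
    rm, rse, _ = _agg(np.vstack([p.right_row for p in profiles]))
    return AggregateProfile(lm, lse, rm, rse, n, group)


def compare_groups(profiles_a: Sequence[BoundaryProfile],
                   profiles_b: Sequence[BoundaryProfile]) -> float:
    """Two-sided rank-sum p on boundary-to-boundary (center) values."""
    a = [p.center for p in profiles_a if p is not None]
    b = [p.center for p in profiles_b if p is not None]
    return rank_sum_p(a, b)


def boundary_fold_change(matrix_test: ContactMatrix, matrix_ref: ContactMatrix,
                         domains: Sequence[Domain],
                         pseudocount: float = 1.0) -> np.ndarray:
    """Per-domain boundary-to-boundary fold change, depth-normalized.

    Both matrices are library-size normalized to a common total before
    ``FC = (test + eps) / (ref + eps)`` at the boundary-to-boundary pixel.
    """
    if (matrix_test.bin_size != matrix_ref.bin_size
            or matrix_test.counts.shape != matrix_ref.counts.shape):
        raise ValueError("matrices must share binning")
    common = matrix_ref.total_contacts
    t = normalize_library_size(matrix_test, common)
    r = normalize_library_size(matrix_ref, common)
    fc = np.empty(len(domains))
    for i, d in enumerate(domains):
        lb = t.bin_of(d.summit_left.midpoint)
        rb = t.bin_of(d.summit_right.midpoint)
        fc[i] = (t.counts[lb, rb] + pseudocount) / (r.counts[lb, rb] + pseudocount)
    return fc


def strongest_domain_per_gene(domains: Sequence[Domain],
                              genes: Sequence[GeneRecord]
                              ) -> dict[str, Domain]:
    """For each gene inside >= 1 domain, the lowest-p domain (ties: shorter)."""
    best: dict[str, Domain] = {}
    for d in domains:
        lo, hi = d.summit_left.midpoint, d.summit_right.midpoint
        for g in genes:
            if g.chrom == d.chrom and lo <= g.tss < hi:
                cur = best.get(g.gene_id)
                if cur is None or (d.best_p, d.length) < (cur.best_p, cur.length):
                    best[g.gene_id] = d
    return best
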