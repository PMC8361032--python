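"""Contact-matrix statistics: normalization, distance decay, significance.

The significance model follows the standard binned Hi-C approach: the genome-
wide contact count ``N`` is treated as the number of trials, the expected
contact probability of a bin pair is estimated from an equal-occupancy
stratification of genomic distance (with monotone-decay enforcement by
isotonic regression), and the per-pair p-value is the upper binomial tail
``Pr[X >= observed]`` with ``n = N`` and ``p = p_hat(distance)``.  Multiple
testing is corrected by Benjamini-Hochberg across all tested pairs.

The exact tail of a discrete count is conservative by construction, so the
separate :func:`calibration_pvalues` diagnostic returns randomized
probability-integral-transform p-values (``Pr[X > x] + U * Pr[X = x]``),
which are exactly Uniform(0,1) under the null and suitable for checking the
calibration of the fitted decay model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.stats import false_discovery_control

from .genomics import ContactMatrix, GenomicInterval

__all__ = [
    "DecayModel",
    "Interaction",
    "normalize_library_size",
    "balance_matrix",
    "fit_decay",
    "call_significant_interactions",
    "calibration_pvalues",
    "directionality_index",
    "subtract_maps",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_library_size(matrix: ContactMatrix, target_total: float) -> ContactMatrix:
    """Scale every entry by ``target_total / total_contacts``."""
    total = matrix.total_contacts
    if total <= 0:
        raise ValueError("cannot normalize a matrix with zero total contacts")
    scaled = matrix.counts * (target_total / total)
    return ContactMatrix(matrix.chrom, matrix.bin_size, scaled, normalized=True)


def balance_matrix(matrix: ContactMatrix, max_iter: int = 500,
                   tol: float = 1e-6) -> ContactMatrix:
    """Symmetric iterative proportional (Sinkhorn-style) balancing.

    Bins with zero marginal are masked and left untouched; the remaining
    rows/columns are rescaled until their sums agree within ``tol`` (relative).
    Non-convergence emits a warning carrying the residual.
    """
    counts = matrix.counts.copy()
    marg = counts.sum(axis=1)
    mask = marg > 0
    if not np.any(mask):
        return matrix.copy()
    sub = counts[np.ix_(mask, mask)]
    residual = np.inf
    for _ in range(max_iter):
        s = sub.sum(axis=1)
        live = s > 0
        mean_s = s[live].mean()
        residual = float(np.abs(s[live] / mean_s - 1).max())
        if residual < tol:
            break
        scale = np.ones_like(s)
        # damped square-root update keeps the iteration symmetric and stable
        scale[live] = np.sqrt(s[live] / mean_s)
        sub = sub / np.outer(scale, scale)
    else:
        warnings.warn(f"balance_matrix did not converge: residual {residual:.3g}")
    counts[np.ix_(mask, mask)] = sub
    counts = (counts + counts.T) / 2  # kill round-off asymmetry
    return ContactMatrix(matrix.chrom, matrix.bin_size, counts, normalized=True)


# ---------------------------------------------------------------------------
# distance-decay model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stratum:
    d_lo: int      # inclusive, bp
    d_hi: int      # exclusive, bp
    p_hat: float   # expected per-pair contact probability
    n_pairs: int
    contacts: float


@dataclass(frozen=True)
class DecayModel:
    """Equal-occupancy stratified expected contact probability vs distance."""

    strata: tuple[Stratum, ...]
    total_contacts: float
    d_min: int
    d_max: int
    bin_size: int

    def expected_p(self, distance_bp: np.ndarray | float) -> np.ndarray:
        """p_hat for each distance; NaN outside [d_min, d_max)."""
        d = np.atleast_1d(np.asarray(distance_bp, dtype=float))
        edges = np.array([s.d_lo for s in self.strata] + [self.strata[-1].d_hi])
        p = np.array([s.p_hat for s in self.strata])
        idx = np.searchsorted(edges, d, side="right") - 1
        out = np.full(d.shape, np.nan)
        ok = (idx >= 0) & (idx < len(p)) & (d >= self.d_min) & (d < self.d_max)
        out[ok] = p[idx[ok]]
        return out

    def offsets(self) -> np.ndarray:
        """Bin offsets whose genomic distance lies within [d_min, d_max)."""
        k_min = int(np.ceil(self.d_min / self.bin_size))
        k_max = int(np.ceil(self.d_max / self.bin_size)) - 1
        return np.arange(max(k_min, 1), k_max + 1)


def fit_decay(matrix: ContactMatrix, n_strata: int = 100,
              d_min: int = 30_000, d_max: int = 2_000_000) -> DecayModel:
    """Fit the expected contact probability per distance stratum.

    Strata are chosen so each holds approximately the same total contact count
    (equal occupancy); ``p_hat = contacts / (N * n_pairs)`` per stratum, with
    non-increasing monotonicity enforced by weighted isotonic regression.
    """
    n = matrix.n_bins
    bs = matrix.bin_size
    k_min = int(np.ceil(d_min / bs))
    k_max = min(int(np.ceil(d_max / bs)) - 1, n - 1)
    if k_max < k_min:
        raise ValueError("distance range contains no bin offsets")
    offsets = np.arange(max(k_min, 1), k_max + 1)
    per_offset_contacts = np.array(
        [matrix.counts.diagonal(k).sum() for k in offsets])
    per_offset_pairs = n - offsets
    total_in_range = per_offset_contacts.sum()
    if total_in_range <= 0:
        raise ValueError("no contacts in the requested distance range")
    if total_in_range < n_strata:
        warnings.warn(
            f"only {total_in_range:.0f} contacts in range; reducing strata")
        n_strata = max(int(total_in_range), 1)
    n_strata = min(n_strata, len(offsets))

    # greedy equal-occupancy split over offsets
    target = total_in_range / n_strata
    bounds = []  # index ranges [a, b) into offsets
    acc, a = 0.0, 0
    for i, c in enumerate(per_offset_contacts):
        acc += c
        remaining_strata = n_strata - len(bounds)
        remaining_offsets = len(offsets) - i - 1
        if (acc >= target and remaining_offsets >= remaining_strata - 1) \
                or remaining_offsets < remaining_strata - 1:
            bounds.append((a, i + 1))
            a, acc = i + 1, 0.0
            if len(bounds) == n_strata - 1:
                break
    bounds.append((a, len(offsets)))
    bounds = [b for b in bounds if b[1] > b[0]]

    N = matrix.total_contacts
    p_raw, weights, meta = [], [], []
    for a, b in bounds:
        pairs = int(per_offset_pairs[a:b].sum())
        contacts = float(per_offset_contacts[a:b].sum())
        p_raw.append(contacts / (N * pairs))
        weights.append(pairs)
        d_lo = int(offsets[a] * bs) if a > 0 else d_min
        d_hi = int((offsets[b - 1] + 1) * bs) if b < len(offsets) else d_max
        meta.append((d_lo, d_hi, pairs, contacts))

    iso = isotonic_regression(np.asarray(p_raw), weights=np.asarray(weights),
                              increasing=False)
    strata = tuple(
        Stratum(d_lo, d_hi, float(p), pairs, contacts)
        for (d_lo, d_hi, pairs, contacts), p in zip(meta, iso.x))
    return DecayModel(strata, N, d_min, d_max, bs)


# ---------------------------------------------------------------------------
# significance calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    """A tested bin pair with its binomial significance."""

    chrom: str
    bin_i: int
    bin_j: int
    count: float
    expected_p: float
    p_value: float
    q_value: float
    bin_size: int

    @property
    def distance(self) -> int:
        return (self.bin_j - self.bin_i) * self.bin_size

    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        bs = self.bin_size
        return (GenomicInterval(self.chrom, self.bin_i * bs, (self.bin_i + 1) * bs),
                GenomicInterval(self.chrom, self.bin_j * bs, (self.bin_j + 1) * bs))


def _candidate_arrays(matrix: ContactMatrix, decay: DecayModel):
    """All in-range pairs as flat arrays (bin_i, bin_j, count, p_hat)."""
    n = matrix.n_bins
    bi, bj, cnt, phat = [], [], [], []
    for k in decay.offsets():
        if k >= n:
            break
        i = np.arange(n - k)
        bi.append(i)
        bj.append(i + k)
        cnt.append(matrix.counts.diagonal(k))
        p = float(decay.expected_p(k * matrix.bin_size)[0])
        phat.append(np.full(n - k, p))
    return (np.concatenate(bi), np.concatenate(bj),
            np.concatenate(cnt), np.concatenate(phat))


def _binomial_tail(obs: np.ndarray, N: int, p: np.ndarray,
                   model: str = "binomial") -> np.ndarray:
    if model == "binomial":
        return stats.binom.sf(obs - 1, N, p)
    if model == "poisson":
        return stats.poisson.sf(obs - 1, N * p)
    raise ValueError(f"unknown tail model {model!r}")


def call_significant_interactions(matrix: ContactMatrix, decay: DecayModel,
                                  q_cut: float = 0.01, tail: str = "binomial",
                                  return_all: bool = False):
    """Binomial-tail significance over all in-range pairs, BH-adjusted.

    Returns the significant interactions (q < ``q_cut``) sorted by p-value;
    with ``return_all=True`` also returns the full tested candidate list.
    """
    bi, bj, cnt, phat = _candidate_arrays(matrix, decay)
    N = int(round(decay.total_contacts))
    obs = np.rint(cnt).astype(np.int64)
    if np.any(obs > N):
        raise ValueError("observed count exceeds total contacts")
    pvals = np.clip(_binomial_tail(obs, N, phat, tail), 0.0, 1.0)
    qvals = false_discovery_control(pvals, method="bh")

    def _mk(idx) -> list[Interaction]:
        return [Interaction(matrix.chrom, int(bi[t]), int(bj[t]), float(cnt[t]),
                            float(phat[t]), float(pvals[t]), float(qvals[t]),
                            matrix.bin_size) for t in idx]

    sig_idx = np.flatnonzero(qvals < q_cut)
    sig_idx = sig_idx[np.lexsort((bj[sig_idx], bi[sig_idx], pvals[sig_idx]))]
    significant = _mk(sig_idx)
    if not return_all:
        return significant
    order = np.lexsort((bj, bi, pvals))
    return significant, _mk(order)


def calibration_pvalues(matrix: ContactMatrix, decay: DecayModel,
                        rng: np.random.Generator,
                        tail: str = "binomial") -> np.ndarray:
    """Randomized PIT p-values for every in-range pair.

    ``p = Pr[X > x] + U * Pr[X = x]`` is exactly Uniform(0,1) under the null,
    making the null fraction below any level directly comparable to that
    level; used to diagnose the calibration of the fitted decay model.
    """
    _, _, cnt, phat = _candidate_arrays(matrix, decay)
    N = int(round(decay.total_contacts))
    obs = np.rint(cnt).astype(np.int64)
    if tail == "binomial":
        upper = stats.binom.sf(obs, N, phat)
        point = stats.binom.pmf(obs, N, phat)
    else:
        upper = stats.poisson.sf(obs, N * phat)
        point = stats.poisson.pmf(obs, N * phat)
    return np.clip(upper + rng.random(obs.shape) * point, 0.0, 1.0)


# ---------------------------------------------------------------------------
# directionality index and subtraction maps
# ---------------------------------------------------------------------------

def directionality_index(matrix: ContactMatrix, window_bins: int) -> np.ndarray:
    """Signed chi-square-like upstream/downstream contact bias per bin.

    For bin i with upstream sum A (bins [i-w, i)) and downstream sum B
    (bins (i, i+w]), E = (A+B)/2 and
    ``DI = sign(B-A) * ((A-E)^2/E + (B-E)^2/E)``; DI = 0 when A = B = 0.
    Edge bins use truncated windows.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = matrix.n_bins
    di = np.zeros(n)
    for i in range(n):
        a = matrix.counts[i, max(0, i - window_bins):i].sum()
        b = matrix.counts[i, i + 1:min(n, i + window_bins + 1)].sum()
        if a == b:  # covers A=B=0 and exact balance
            continue
        e = (a + b) / 2
        di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return di


def subtract_maps(matrix_a: ContactMatrix, matrix_b: ContactMatrix) -> np.ndarray:
    """Depth-matched signed difference ``a - b * (total_a / total_b)``."""
    if (matrix_a.chrom != matrix_b.chrom
            or matrix_a.bin_size != matrix_b.bin_size
            or matrix_a.counts.shape != matrix_b.counts.shape):
        raise ValueError("matrices must share chromosome, bin size and shape")
    total_b = matrix_b.total_contacts
    if total_b <= 0:
        raise ValueError("reference matrix has zero total contacts")
    scale = matrix_a.total_contacts / total_b
    return matrix_a.counts - matrix_b.counts * scale
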