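"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_p", "pearson"]


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two samples.

    Exact when both groups are small and tie-free, otherwise the normal
    approximation with tie correction.  Degenerate all-tied input gives 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="auto").pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p; (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
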