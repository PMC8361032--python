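"""Boundary sequence features: conservation profiles and variant densities.

Boundary CTCF motifs are profiled in a motif-forward frame (reverse-strand
motifs are flipped) over the motif span plus flanks; per-motif summaries are
the mean conservation inside the motif span.  Variant burden per motif is
split into common and rare by population allele frequency (1% threshold;
exactly 1% counts as common so the boundary case is deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import CtcfSite, Domain
from .genomics import GenomicInterval, SignalTrack
from .stats import rank_sum_p

__all__ = [
    "VariantRecord",
    "ConservationProfile",
    "conservation_profile",
    "compare_motif_conservation",
    "variant_density",
    "boundary_strength_stats",
]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int          # 0-based
    af: float

    def __post_init__(self):
        if not 0 <= self.af <= 1:
            raise ValueError(f"allele frequency out of [0,1]: {self.af}")


@dataclass(frozen=True)
class ConservationProfile:
    mean: np.ndarray          # per-position mean, motif-forward frame
    se: np.ndarray
    n: np.ndarray             # motifs contributing per position
    motif_means: np.ndarray   # per-motif mean inside the motif span
    flank_bp: int
    motif_len: int


def _motif_iv(m) -> GenomicInterval:
    return m.interval if isinstance(m, CtcfSite) else m


def _orientation(m) -> str:
    if isinstance(m, CtcfSite):
        return m.orientation
    return {"+": "forward", "-": "reverse"}.get(m.strand, "unclear")


def conservation_profile(motifs: Sequence, track: SignalTrack,
                         flank_bp: int = 500) -> ConservationProfile:
    """Aggregate per-base conservation around motifs, strand-flipped.

    Every motif contributes the window [start - flank, end + flank); reverse
    motifs are mirrored so that all profiles share the motif-forward frame.
    Motifs with no track coverage at all are excluded.  All motifs must have
    equal length.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    lens = {len(_motif_iv(m)) for m in motifs}
    if len(lens) != 1:
        raise ValueError("motifs must share a common length")
    motif_len = lens.pop()
    width = motif_len + 2 * flank_bp
    rows, motif_means = [], []
    for m in motifs:
        iv = _motif_iv(m)
        vals = track.values(iv.chrom, iv.start - flank_bp, iv.end + flank_bp)
        if np.all(np.isnan(vals)):
            continue
        if _orientation(m) == "reverse":
            vals = vals[::-1]
        inside = vals[flank_bp:flank_bp + motif_len]
        rows.append(vals)
        motif_means.append(np.nanmean(inside) if not np.all(np.isnan(inside))
                           else np.nan)
    if not rows:
        raise ValueError("no motif has track coverage")
    arr = np.vstack(rows)
    n = np.sum(~np.isnan(arr), axis=0)
    mean = np.full(width, np.nan)
    se = np.zeros(width)
    ok = n > 0
    mean[ok] = np.nanmean(arr[:, ok], axis=0)
    multi = n > 1
    se[multi] = np.nanstd(arr[:, multi], axis=0, ddof=1) / np.sqrt(n[multi])
    return ConservationProfile(mean, se, n, np.asarray(motif_means), flank_bp,
                               motif_len)


def compare_motif_conservation(groups: Mapping[str, Sequence], track: SignalTrack,
                               flank_bp: int = 500) -> pd.DataFrame:
    """Pairwise two-sided rank-sum p on motif-region mean conservation."""
    means = {name: conservation_profile(motifs, track, flank_bp).motif_means
             for name, motifs in groups.items()}
    names = list(means)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va = means[a][~np.isnan(means[a])]
            vb = means[b][~np.isnan(means[b])]
            rows.append({"group_a": a, "group_b": b,
                         "p_value": rank_sum_p(va, vb)})
    return pd.DataFrame(rows)


def variant_density(motifs: Sequence, variants: Sequence[VariantRecord],
                    af_cut: float = 0.01) -> pd.DataFrame:
    """Common/rare variant counts per motif span.

    common: AF >= ``af_cut`` (the boundary AF == af_cut is binned as common);
    rare: AF < ``af_cut``.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, float]]] = {}
    for v in variants:
        tmp.setdefault(v.chrom, []).append((v.pos, v.af))
    for chrom, recs in tmp.items():
        recs.sort()
        pos = np.array([p for p, _ in recs])
        af = np.array([a for _, a in recs])
        by_chrom[chrom] = (pos, af)
    rows = []
    for m in motifs:
        iv = _motif_iv(m)
        common = rare = 0
        if iv.chrom in by_chrom:
            pos, af = by_chrom[iv.chrom]
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            sel = af[lo:hi]
            common = int(np.sum(sel >= af_cut))
            rare = int(np.sum(sel < af_cut))
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "common": common, "rare": rare})
    return pd.DataFrame(rows)


def boundary_strength_stats(groups: Mapping[str, Sequence[Domain]],
                            ctcf_track: SignalTrack | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-boundary CTCF signal and interaction strength, with group tests.

    Interaction strength is -log10 of the domain's best p-value; CTCF signal
    is the mean track value over each summit anchor (NaN without a track).
    Returns (per-domain table, pairwise rank-sum table on strength).
    """
    rows = []
    for name, domains in groups.items():
        if len(domains) == 0:
            raise ValueError(f"group {name!r} is empty")
        for d in domains:
            strength = float(-np.log10(max(d.best_p, 1e-300)))
            if ctcf_track is not None:
                left_sig = ctcf_track.mean(d.chrom, d.summit_left.start,
                                           d.summit_left.end)
                right_sig = ctcf_track.mean(d.chrom, d.summit_right.start,
                                            d.summit_right.end)
            else:
                left_sig = right_sig = float("nan")
            rows.append({"group": name, "chrom": d.chrom,
                         "left_start": d.summit_left.start,
                         "right_start": d.summit_right.start,
                         "strength": strength,
                         "ctcf_left": left_sig, "ctcf_right": right_sig})
    table = pd.DataFrame(rows)
    names = list(groups)
    tests = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa = table.loc[table["group"] == a, "strength"]
            pb = table.loc[table["group"] == b, "strength"]
            tests.append({"group_a": a, "group_b": b,
                          "p_value": rank_sum_p(pa, pb)})
    return table, pd.DataFrame(tests)
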