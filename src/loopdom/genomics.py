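"""Genome coordinate model and plain-text genomics IO.

All coordinates are 0-based, half-open internally.  BED/BEDPE/bedGraph files
are read and written natively in that convention; anything 1-based must be
converted at the boundary by the caller.

Supported formats: BED3/BED6 (optionally with a score column), BEDPE
(6+ columns), bedGraph, TSV matrices with header row and label column, and a
triplet contact-matrix text format ``chrom<TAB>bin_i<TAB>bin_j<TAB>value``
that stores the upper triangle only (the reader mirrors it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Genome",
    "ContactMatrix",
    "AnchorPair",
    "SignalTrack",
    "FormatError",
    "read_contacts",
    "write_contacts",
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_table",
    "write_table",
]

#: six significant digits for every float serialized to text
FLOAT_FMT = "%.6g"

VALID_STRANDS = {"+", "-", "unclear", "none"}


class FormatError(ValueError):
    """Raised on malformed input files (carries the offending line number)."""


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "none"

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", slack: int = 0) -> bool:
        """True iff the intervals overlap after symmetric extension by ``slack/2``.

        With slack 0 this is the standard half-open overlap predicate
        ``a.start < b.end and b.start < a.end``.
        """
        if self.chrom != other.chrom:
            return False
        return self.start < other.end + slack and other.start < self.end + slack

    def shifted(self, delta: int) -> "GenomicInterval":
        return replace(self, start=self.start + delta, end=self.end + delta)

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(self.chrom, min(self.start, other.start),
                               max(self.end, other.end))


@dataclass(frozen=True)
class ScoredInterval(GenomicInterval):
    """BED-style interval with an optional name and score."""

    name: str = "."
    score: float = 0.0


class Genome:
    """Ordered map of chromosome name to length (bp)."""

    def __init__(self, lengths: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, dict) else list(lengths)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._lengths = dict(items)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self):
        return len(self._lengths)

    def items(self):
        return self._lengths.items()

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self._lengths[chrom] / bin_size)

    def __eq__(self, other):
        return isinstance(other, Genome) and self._lengths == other._lengths

    def __repr__(self):
        return f"Genome({self._lengths!r})"


class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    ``counts`` is a dense ``(n_bins, n_bins)`` float array; symmetry and
    non-negativity are enforced at construction.  ``total_contacts`` is the sum
    over the upper triangle including the diagonal, i.e. each unordered bin
    pair counted once.
    """

    def __init__(self, chrom: str, bin_size: int, counts: np.ndarray,
                 normalized: bool = False):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(counts, counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self.counts = counts
        self.normalized = normalized

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total_contacts(self) -> float:
        return float(np.triu(self.counts).sum())

    @classmethod
    def zeros(cls, chrom: str, bin_size: int, n_bins: int) -> "ContactMatrix":
        return cls(chrom, bin_size, np.zeros((n_bins, n_bins)))

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, i * self.bin_size, (i + 1) * self.bin_size)

    def bin_of(self, position: int) -> int:
        return position // self.bin_size

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.bin_size, self.counts.copy(),
                             self.normalized)


@dataclass(frozen=True)
class AnchorPair:
    """A BEDPE record: two anchors on (usually) the same chromosome."""

    left: GenomicInterval
    right: GenomicInterval
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if (self.left.chrom == self.right.chrom
                and self.right.start < self.left.start):
            raise ValueError("left anchor must not start after right anchor")


class SignalTrack:
    """Step-wise per-base signal (bedGraph semantics).

    Steps are stored per chromosome as sorted, non-overlapping
    ``(starts, ends, values)`` arrays.  Positions not covered by any step
    have undefined (NaN) signal.
    """

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._steps = {}
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping steps on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty step on {chrom}")
            self._steps[chrom] = (starts, ends, values)

    @classmethod
    def from_intervals(cls, records: Iterable[tuple[str, int, int, float]]
                       ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        steps = {}
        for chrom, recs in by_chrom.items():
            starts, ends, values = zip(*recs)
            steps[chrom] = (np.array(starts), np.array(ends), np.array(values))
        return cls(steps)

    @property
    def chroms(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps[chrom]

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end); NaN where uncovered."""
        out = np.full(end - start, np.nan)
        if chrom not in self._steps:
            return out
        starts, ends, values = self._steps[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start:min(e, end) - start] = v
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over covered bases of [start, end); NaN if none."""
        vals = self.values(chrom, start, end)
        if np.all(np.isnan(vals)):
            return float("nan")
        return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# contact matrix IO (triplet text, upper triangle only)
# ---------------------------------------------------------------------------

def read_contacts(path: str | Path, genome: Genome, bin_size: int,
                  chrom: str | None = None) -> dict[str, ContactMatrix]:
    """Read triplet contact text into per-chromosome matrices.

    Entries given once per unordered bin pair are mirrored into a symmetric
    matrix.  If ``chrom`` is given, only that chromosome is returned (still as
    a single-entry dict).
    """
    mats: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            c, si, sj, sv = parts
            if chrom is not None and c != chrom:
                continue
            if c not in genome:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {c!r}")
            try:
                i, j, v = int(si), int(sj), float(sv)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            n = genome.n_bins(c, bin_size)
            if not (0 <= i < n and 0 <= j < n):
                raise FormatError(f"{path}:{lineno}: bin index out of range for {c}")
            if c not in mats:
                mats[c] = np.zeros((n, n))
            mats[c][i, j] = v
            mats[c][j, i] = v
    chroms = [chrom] if chrom is not None else list(genome)
    out = {}
    for c in chroms:
        n = genome.n_bins(c, bin_size)
        out[c] = ContactMatrix(c, bin_size, mats.get(c, np.zeros((n, n))))
    return out


def write_contacts(matrices: dict[str, ContactMatrix] | ContactMatrix,
                   path: str | Path) -> None:
    """Write the non-zero upper triangle (incl. diagonal) as triplet text."""
    if isinstance(matrices, ContactMatrix):
        matrices = {matrices.chrom: matrices}
    with open(path, "w") as fh:
        for chrom, mat in matrices.items():
            iu, ju = np.triu_indices(mat.n_bins)
            vals = mat.counts[iu, ju]
            nz = vals != 0
            for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
                fh.write(f"{chrom}\t{i}\t{j}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe(path: str | Path) -> list[AnchorPair]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            try:
                left = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                right = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            name = parts[6] if len(parts) > 6 else "."
            score = float(parts[7]) if len(parts) > 7 and parts[7] != "." else 0.0
            records.append(AnchorPair(left, right, name=name, score=score))
    return records


def write_bedpe(records: Sequence[AnchorPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join([
                r.left.chrom, str(r.left.start), str(r.left.end),
                r.right.chrom, str(r.right.start), str(r.right.end),
                r.name, _fmt(r.score),
            ]) + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[ScoredInterval]:
    """Read BED3/BED6; a missing strand column yields strand ``none``."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "none"
            if strand == ".":
                strand = "none"
            try:
                out.append(ScoredInterval(parts[0], int(parts[1]), int(parts[2]),
                                          strand=strand, name=name, score=score))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Sequence[ScoredInterval | GenomicInterval],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "name", ".")
            score = getattr(iv, "score", 0.0)
            strand = iv.strand if iv.strand in {"+", "-"} else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt(score)}\t{strand}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                recs.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return SignalTrack.from_intervals(recs)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """TSV matrix with a header row and a leading label column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
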