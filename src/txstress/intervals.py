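"""Exact interval algebra over genomic coordinates.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end - 1`` and has length
``end - start``. Readers that accept 1-based input convert at the boundary
(:mod:`txstress.io`).

The unit of analysis is a :class:`RegionSet` — a named collection of
:class:`GenomicInterval` on a shared :class:`GenomeLayout`. Copy-number
changes (CNCs) carry a class label (``gain`` or ``loss``); fragile-site
feature sets (ERFS, CFS, breakomes) are plain interval sets.

Operations use per-chromosome sorted sweeps so that results are exact in
base pairs; there is no binning or approximation anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "RegionSet",
    "merge_intervals",
    "overlap_kb",
    "intersect_replicates",
    "nearest_tss_distance",
    "genes_per_region",
]

_VALID_CLASSES = {"gain", "loss", None}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval, optionally labelled gain/loss.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    cnc_class : str or None
        ``"gain"``, ``"loss"`` or ``None`` for unlabelled intervals.
    """

    chrom: str
    start: int
    end: int
    cnc_class: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.cnc_class not in _VALID_CLASSES:
            raise ValueError(f"cnc_class must be 'gain', 'loss' or None, got {self.cnc_class!r}")

    @property
    def length(self) -> int:
        """Interval length in bp (``end - start``)."""
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeLayout:
    """Ordered chromosome names with lengths, plus an optional placement mask.

    The mask marks regions (assembly gaps, excluded chromosomes) that
    randomization must avoid; it plays no role in deterministic interval
    algebra.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        mask: "RegionSet | None" = None,
    ) -> None:
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        self.mask = None
        if mask is not None:
            for iv in mask:
                self._check_bounds(iv)
            self.mask = mask.merged() if not mask.is_merged else mask

    def _check_bounds(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"chromosome {iv.chrom!r} not in genome layout")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chrom_sizes[iv.chrom]}"
            )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return self.chrom_sizes == other.chrom_sizes

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self.chrom_sizes)} chromosomes, {self.total_bp} bp)"


class RegionSet:
    """A named set of genomic intervals on a common genome layout."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        genome: GenomeLayout | None = None,
        name: str = "",
        _merged: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(intervals)
        self.genome = genome
        self.name = name
        self._is_merged = _merged
        if genome is not None:
            for iv in self.intervals:
                genome._check_bounds(iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"RegionSet({len(self)} intervals{label})"

    @property
    def is_merged(self) -> bool:
        return self._is_merged

    @property
    def total_bp(self) -> int:
        """Total covered bp; counts overlapping bases once only after merge."""
        return sum(iv.length for iv in self.merged())

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted ``(n, 2)`` start/end arrays per chromosome."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def merged(self) -> "RegionSet":
        return merge_intervals(self)

    def with_genome(self, genome: GenomeLayout) -> "RegionSet":
        return RegionSet(self.intervals, genome=genome, name=self.name, _merged=self._is_merged)


def merge_intervals(regions: RegionSet) -> RegionSet:
    """Merge overlapping and book-ended intervals per chromosome.

    The result covers exactly the same bases with the minimal number of
    intervals; class labels are dropped (a merged set is pure coverage).
    Idempotent.
    """
    if regions.is_merged:
        return regions
    merged: list[GenomicInterval] = []
    current: GenomicInterval | None = None
    for iv in regions.intervals:  # already sorted by (chrom, start, end)
        if current is not None and iv.chrom == current.chrom and iv.start <= current.end:
            if iv.end > current.end:
                current = GenomicInterval(current.chrom, current.start, iv.end)
        else:
            if current is not None:
                merged.append(current)
            current = GenomicInterval(iv.chrom, iv.start, iv.end)
    if current is not None:
        merged.append(current)
    return RegionSet(merged, genome=regions.genome, name=regions.name, _merged=True)


def _pairwise_overlap_bp(a: np.ndarray, b: np.ndarray) -> int:
    """Total shared bp between two sorted non-overlapping interval arrays."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += int(hi - lo)
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return total


def overlap_kb(query: RegionSet, features: RegionSet) -> float:
    """Kilobases of genome covered by both ``query`` and ``features``.

    Both sets are merged internally, so the result is the exact size of
    the intersection of their coverages divided by 1,000. Symmetric and
    non-negative.
    """
    if (
        query.genome is not None
        and features.genome is not None
        and query.genome != features.genome
    ):
        raise ValueError("query and features are on different genome layouts")
    qa = query.merged().by_chrom()
    fa = features.merged().by_chrom()
    total = 0
    for chrom in qa.keys() & fa.keys():
        total += _pairwise_overlap_bp(qa[chrom], fa[chrom])
    return total / 1000.0


def intersect_replicates(
    a: RegionSet,
    b: RegionSet,
    min_overlap_fraction: float = 0.0,
) -> RegionSet:
    """Intervals of ``a`` supported by a same-class interval of ``b``.

    Replicate support means >= 1 bp overlap with an interval of ``b``
    carrying the same gain/loss label (gain matches gain, loss matches
    loss). ``min_overlap_fraction`` optionally requires the overlap to
    cover at least that fraction of the ``a`` interval.
    """
    for rs in (a, b):
        for iv in rs:
            if iv.cnc_class is None:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} in {rs.name or 'set'} "
                    "lacks a cnc_class; replicate intersection needs gain/loss labels"
                )
    b_by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in b:
        b_by_key.setdefault((iv.chrom, iv.cnc_class), []).append(iv)
    kept = []
    for iv in a:
        need = min_overlap_fraction * iv.length
        for other in b_by_key.get((iv.chrom, iv.cnc_class), ()):
            ov = iv.overlap_bp(other)
            if ov >= 1 and ov >= need:
                kept.append(iv)
                break
    return RegionSet(kept, genome=a.genome, name=a.name)


def nearest_tss_distance(
    regions: RegionSet,
    tss_by_chrom: Mapping[str, Sequence[int]],
    mode: str = "midpoint",
) -> np.ndarray:
    """Distance (kb) from each region to its nearest TSS on the same chromosome.

    ``mode="midpoint"`` (default) measures from the region midpoint;
    ``mode="edge"`` measures the gap to the nearest region edge (0 when a
    TSS falls inside the region). Regions on chromosomes with no gene are
    flagged with NaN rather than 0 — distance is undefined there, not zero.
    """
    if mode not in ("midpoint", "edge"):
        raise ValueError("mode must be 'midpoint' or 'edge'")
    sorted_tss = {c: np.sort(np.asarray(t, dtype=np.int64)) for c, t in tss_by_chrom.items() if len(t)}
    out = np.full(len(regions), np.nan)
    for k, iv in enumerate(regions):
        tss = sorted_tss.get(iv.chrom)
        if tss is None:
            continue
        if mode == "midpoint":
            out[k] = np.abs(tss - iv.midpoint).min() / 1000.0
        else:
            inside = (tss >= iv.start) & (tss < iv.end)
            if inside.any():
                out[k] = 0.0
            else:
                out[k] = min(np.abs(tss - iv.start).min(), np.abs(tss - (iv.end - 1)).min()) / 1000.0
    return out


def genes_per_region(
    regions: RegionSet,
    tss_by_chrom: Mapping[str, Sequence[int]],
    window_bp: int = 0,
) -> np.ndarray:
    """Number of TSSs inside each region extended by ``window_bp`` both ways.

    A deliberately simple window rule (a TSS t is counted when
    ``start - window <= t < end + window``); it does not emulate
    regulatory-domain models such as GREAT's basal-plus-extension rule.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    sorted_tss = {c: np.sort(np.asarray(t, dtype=np.int64)) for c, t in tss_by_chrom.items()}
    counts = np.zeros(len(regions), dtype=np.int64)
    for k, iv in enumerate(regions):
        tss = sorted_tss.get(iv.chrom)
        if tss is None or len(tss) == 0:
            continue
        lo = np.searchsorted(tss, iv.start - window_bp, side="left")
        hi = np.searchsorted(tss, iv.end + window_bp, side="left")
        counts[k] = hi - lo
    return counts
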