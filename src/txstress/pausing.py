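"""RNAPII promoter-proximal pausing statistics from coverage tracks.

The central quantity is the traveling ratio (TR): the RNAPII ChIP signal
density in the promoter-proximal window (by default -30 to +300 bp around
the TSS, in transcription direction) divided by the density over the
remaining gene body (+300 bp to the TES). A high TR means polymerase
accumulates near the promoter — pausing/stalling. The ratio of traveling
ratios (RoTR) additionally normalizes a ChIP TR by the matched input TR,
gene by gene; an alternative mode ratios one condition against another.

Coordinate conventions
----------------------
Genes are half-open. On the "+" strand the TSS is the interval start and
``tss < tes``; on the "-" strand the TSS is the *exclusive end* coordinate
and ``tss > tes`` (BED-style: a minus-strand gene occupies ``[tes, tss)``).
With this convention the promoter window is ``[tss-30, tss+300)`` on "+"
and ``[tss-300, tss+30)`` on "-", and every statistic is exactly mirror
symmetric under reversal of the genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "TravelingRatioRecord",
    "TravelingRatioAnalysis",
    "TravelingRatioResults",
    "interval_density",
    "traveling_ratio",
    "ratio_of_traveling_ratios",
    "call_active_genes",
    "metagene_profile",
    "compare_distributions",
    "cumulative_curve",
]

PROMOTER_UPSTREAM = 30
PROMOTER_DOWNSTREAM = 300


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its TSS and TES (see module docstring for strand rules)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: '+' strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: '-' strand requires tss > tes")

    @property
    def length_bp(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic [start, end) of the gene body including the promoter-proximal part."""
        return (self.tss, self.tes) if self.strand == "+" else (self.tes, self.tss)

    def promoter_window(
        self, upstream: int = PROMOTER_UPSTREAM, downstream: int = PROMOTER_DOWNSTREAM
    ) -> tuple[int, int]:
        if self.strand == "+":
            return (self.tss - upstream, self.tss + downstream)
        return (self.tss - downstream, self.tss + upstream)

    def body_window(self, downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
        """Gene body past the promoter-proximal region; empty if the gene is too short."""
        if self.strand == "+":
            return (self.tss + downstream, self.tes)
        return (self.tes, self.tss - downstream)


class CoverageTrack:
    """Nonnegative binned signal per chromosome (bedGraph semantics).

    ``values[chrom][i]`` is the per-bp signal over bases
    ``[i * bin_width, (i+1) * bin_width)``. Sums over intervals weight
    partial bins by the contained fraction, so densities of
    piecewise-constant signals are independent of the bin width.
    """

    def __init__(self, values: Mapping[str, np.ndarray], bin_width: int = 1) -> None:
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.bin_width = int(bin_width)
        self.values: dict[str, np.ndarray] = {}
        for chrom, v in values.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"track for {chrom!r} must be 1-D")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"track for {chrom!r} has negative or non-finite values")
            self.values[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def extent(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_width

    def interval_sum(self, chrom: str, start: float, end: float) -> float:
        """Signal summed over [start, end); bases outside the track count 0."""
        if chrom not in self.values:
            raise KeyError(f"no coverage for chromosome {chrom!r}")
        v = self.values[chrom]
        bw = self.bin_width
        start = max(float(start), 0.0)
        end = min(float(end), len(v) * bw)
        if end <= start:
            return 0.0
        b0 = int(start // bw)
        b1 = int(np.ceil(end / bw))
        idx = np.arange(b0, b1)
        left = np.maximum(start, idx * bw)
        right = np.minimum(end, (idx + 1) * bw)
        return float(np.dot(v[b0:b1], right - left))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack({c: v * factor for c, v in self.values.items()}, self.bin_width)

    def mirrored(self) -> "CoverageTrack":
        """Track on the reverse-complement genome (bins reversed per chromosome)."""
        return CoverageTrack({c: v[::-1].copy() for c, v in self.values.items()}, self.bin_width)


def interval_density(track: CoverageTrack, chrom: str, start: float, end: float) -> float:
    """Mean per-bp signal over [start, end); the interval must be non-empty."""
    if end <= start:
        raise ValueError(f"zero-length interval {chrom}:{start}-{end}")
    return track.interval_sum(chrom, start, end) / (end - start)


@dataclass
class TravelingRatioRecord:
    """Per-gene promoter/body densities and their ratio."""

    gene_id: str
    promoter_density: float
    body_density: float
    tr: float  # NaN when undefined
    excluded: str | None = None  # reason, or None if the record is usable


def traveling_ratio(
    chip: CoverageTrack,
    gene: GeneModel,
    pseudocount: float = 0.0,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> TravelingRatioRecord:
    """Traveling ratio of one gene on one track.

    Genes whose body (past +300 bp) is shorter than 1 bp are excluded,
    as are genes with zero body density when ``pseudocount == 0``.
    """
    bs, be = gene.body_window(promoter_downstream)
    if be - bs < 1:
        return TravelingRatioRecord(gene.gene_id, np.nan, np.nan, np.nan, "short_gene")
    ps, pe = gene.promoter_window(promoter_upstream, promoter_downstream)
    pd_ = interval_density(chip, gene.chrom, ps, pe)
    bd = interval_density(chip, gene.chrom, bs, be)
    denom = bd + pseudocount
    if denom <= 0:
        return TravelingRatioRecord(gene.gene_id, pd_, bd, np.nan, "zero_body_density")
    return TravelingRatioRecord(gene.gene_id, pd_, bd, (pd_ + pseudocount) / denom, None)


def ratio_of_traveling_ratios(tr_chip: float, tr_input: float) -> float:
    """RoTR = TR(ChIP) / TR(input); NaN when either TR is undefined."""
    if not (np.isfinite(tr_chip) and np.isfinite(tr_input)) or tr_input == 0:
        return float("nan")
    return tr_chip / tr_input


@dataclass
class TravelingRatioResults:
    """Per-gene TR/RoTR table plus exclusion accounting.

    ``records`` columns: gene_id, promoter_density, body_density, tr,
    tr_input, rotr, excluded (reason string or empty).
    """

    records: pd.DataFrame
    pseudocount: float
    promoter_upstream: int
    promoter_downstream: int

    @property
    def included(self) -> pd.DataFrame:
        return self.records[self.records["excluded"] == ""]

    def rotr_values(self) -> np.ndarray:
        v = self.included["rotr"].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    def tr_values(self) -> np.ndarray:
        v = self.included["tr"].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    def exclusion_counts(self) -> dict[str, int]:
        bad = self.records.loc[self.records["excluded"] != "", "excluded"]
        return bad.value_counts().to_dict()

    def summary(self) -> str:
        tr = self.tr_values()
        rotr = self.rotr_values()
        lines = [
            "Traveling-ratio analysis",
            "=" * 38,
            f"genes analysed       {len(self.records)}",
            f"genes included       {len(self.included)}",
            f"exclusions           {self.exclusion_counts() or 'none'}",
            f"promoter window      [-{self.promoter_upstream}, +{self.promoter_downstream}) bp of TSS",
            f"median TR            {np.median(tr):.4g}" if len(tr) else "median TR            n/a",
            f"median RoTR          {np.median(rotr):.4g}" if len(rotr) else "median RoTR          n/a",
        ]
        return "\n".join(lines)

    def compare(self, other: "TravelingRatioResults", values: str = "rotr") -> tuple[float, float]:
        """Wilcoxon rank-sum comparison of TR or RoTR distributions."""
        get = {"rotr": TravelingRatioResults.rotr_values, "tr": TravelingRatioResults.tr_values}[values]
        return compare_distributions(get(self), get(other))


class TravelingRatioAnalysis:
    """Compute per-gene TR and RoTR for a ChIP track with matched input.

    Parameters
    ----------
    chip, input_track : CoverageTrack
        ChIP signal and its input control (input optional; RoTR is NaN
        without it).
    genes : iterable of GeneModel
    pseudocount : float
        Added to both densities; default 0 (zero-density genes excluded).
    """

    def __init__(
        self,
        chip: CoverageTrack,
        input_track: CoverageTrack | None,
        genes: Iterable[GeneModel],
        pseudocount: float = 0.0,
        promoter_upstream: int = PROMOTER_UPSTREAM,
        promoter_downstream: int = PROMOTER_DOWNSTREAM,
    ) -> None:
        self.chip = chip
        self.input_track = input_track
        self.genes = list(genes)
        self.pseudocount = pseudocount
        self.promoter_upstream = promoter_upstream
        self.promoter_downstream = promoter_downstream

    def fit(self) -> TravelingRatioResults:
        rows = []
        for gene in self.genes:
            rec = traveling_ratio(
                self.chip, gene, self.pseudocount, self.promoter_upstream, self.promoter_downstream
            )
            tr_input = np.nan
            rotr = np.nan
            excluded = rec.excluded
            if self.input_track is not None and excluded is None:
                rec_in = traveling_ratio(
                    self.input_track, gene, self.pseudocount,
                    self.promoter_upstream, self.promoter_downstream,
                )
                tr_input = rec_in.tr
                if rec_in.excluded is not None:
                    excluded = f"input_{rec_in.excluded}"
                else:
                    rotr = ratio_of_traveling_ratios(rec.tr, rec_in.tr)
            rows.append(
                (gene.gene_id, rec.promoter_density, rec.body_density, rec.tr,
                 tr_input, rotr, excluded or "")
            )
        records = pd.DataFrame(
            rows,
            columns=["gene_id", "promoter_density", "body_density", "tr", "tr_input", "rotr", "excluded"],
        )
        return TravelingRatioResults(
            records, self.pseudocount, self.promoter_upstream, self.promoter_downstream
        )


def call_active_genes(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    genes: Iterable[GeneModel],
    enrichment_threshold: float = 2.0,
    min_promoter_density: float = 0.3,
    pseudocount: float = 0.01,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> list[GeneModel]:
    """Genes with a clear RNAPII promoter peak: absolute density above
    ``min_promoter_density`` and input enrichment above
    ``enrichment_threshold``."""
    if enrichment_threshold <= 0 or min_promoter_density <= 0:
        raise ValueError("thresholds must be > 0")
    active = []
    for gene in genes:
        ps, pe = gene.promoter_window(promoter_upstream, promoter_downstream)
        pd_chip = interval_density(chip, gene.chrom, ps, pe)
        pd_in = interval_density(input_track, gene.chrom, ps, pe)
        if pd_chip >= min_promoter_density and pd_chip / (pd_in + pseudocount) >= enrichment_threshold:
            active.append(gene)
    return active


def _binned_densities(
    track: CoverageTrack, chrom: str, start: float, end: float, n_bins: int, reverse: bool
) -> np.ndarray:
    edges = np.linspace(start, end, n_bins + 1)
    out = np.array([
        interval_density(track, chrom, edges[i], edges[i + 1]) for i in range(n_bins)
    ])
    return out[::-1] if reverse else out


def metagene_profile(
    track: CoverageTrack,
    genes: Iterable[GeneModel],
    n_body_bins: int = 100,
    flank_bp: int = 2000,
    n_flank_bins: int = 20,
) -> np.ndarray:
    """Average strand-oriented coverage profile over TSS-flank/body/TES-flank.

    Each gene's body is rescaled to ``n_body_bins`` and each flank to
    ``n_flank_bins``; the profile is the per-bin mean density across all
    genes whose body is at least ``n_body_bins`` bp long. Length of the
    result: ``2 * n_flank_bins + n_body_bins``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("metagene_profile needs at least one gene")
    profiles = []
    for g in genes:
        gs, ge = g.interval
        if ge - gs < n_body_bins:
            continue
        rev = g.strand == "-"
        if g.strand == "+":
            up = _binned_densities(track, g.chrom, gs - flank_bp, gs, n_flank_bins, rev)
            body = _binned_densities(track, g.chrom, gs, ge, n_body_bins, rev)
            down = _binned_densities(track, g.chrom, ge, ge + flank_bp, n_flank_bins, rev)
        else:
            up = _binned_densities(track, g.chrom, ge, ge + flank_bp, n_flank_bins, rev)
            body = _binned_densities(track, g.chrom, gs, ge, n_body_bins, rev)
            down = _binned_densities(track, g.chrom, gs - flank_bp, gs, n_flank_bins, rev)
        profiles.append(np.concatenate([up, body, down]))
    if not profiles:
        raise ValueError(f"no gene has a body of at least {n_body_bins} bp")
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

EXACT_MAX_N = 8


def _u_statistic_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration (handles ties via mid-ranks)."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    u_obs = _u_statistic_from_ranks(float(ranks[:n1].sum()), n1)
    n = n1 + n2
    us = np.array([
        _u_statistic_from_ranks(float(ranks[list(comb)].sum()), n1)
        for comb in itertools.combinations(range(n), n1)
    ])
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration of all ``C(n1+n2, n1)`` group assignments when both
    samples have at most 8 observations; otherwise the tie-corrected
    normal approximation. Returns ``(U, p)`` where U is the statistic of
    the first sample. When every value in both samples is identical the
    test is degenerate and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples need at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N:
        return _exact_rank_sum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cumulative_curve(values: Sequence[float]) -> np.ndarray:
    """ECDF as (value, percent of observations <= value) pairs.

    One row per distinct value, sorted ascending; the final percent is
    100. This is the 'cumulative curve / percent of all genes' display
    used for RoTR distributions.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cumulative_curve needs at least one value")
    sv = np.sort(v)
    uniq, counts = np.unique(sv, return_counts=True)
    pct = 100.0 * np.cumsum(counts) / v.size
    return np.column_stack([uniq, pct])
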