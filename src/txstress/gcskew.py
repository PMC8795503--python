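"""GC content, GC skew, and gene stratification.

GC skew, (G - C) / (G + C), measures strand asymmetry in base
composition. Computed on the transcribed (sense) strand, a positive skew
means a G-rich non-template strand — the orientation that favours R-loop
formation behind the elongating polymerase. Genes are stratified into
skew-high / skew-low groups by tail quantiles of the genic skew
distribution, and into short / long groups by gene length, to ask whether
pausing differences concentrate in R-loop-prone or hard-to-replicate
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pausing import GeneModel, PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM

__all__ = [
    "gc_skew",
    "gc_content",
    "genic_gcskew",
    "StratificationConfig",
    "stratify_by_gcskew",
    "stratify_by_length",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _counts(seq: str) -> tuple[int, int, int, int]:
    s = seq.upper()
    return s.count("A"), s.count("C"), s.count("G"), s.count("T")


def gc_skew(sequence: str, strand: str = "+") -> float:
    """(G - C) / (G + C) on the sense strand; NaN when no G or C present.

    For ``strand == "-"`` the reverse complement is taken first, so the
    value always describes the transcribed strand. N bases are ignored.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if strand == "-":
        sequence = reverse_complement(sequence)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    _, c, g, _ = _counts(sequence)
    if g + c == 0:
        return float("nan")
    return (g - c) / (g + c)


def gc_content(sequence: str) -> float:
    """G+C fraction of non-N bases; NaN if the sequence is all N."""
    if not sequence:
        raise ValueError("empty sequence")
    a, c, g, t = _counts(sequence)
    total = a + c + g + t
    if total == 0:
        return float("nan")
    return (g + c) / total


def genic_gcskew(
    sequences: Mapping[str, str],
    genes: Iterable[GeneModel],
    mode: str = "genic",
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
    max_n_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-gene GC content and skew over the genic interval or promoter window.

    ``sequences`` maps chromosome name to its full sequence string.
    ``mode="genic"`` measures TSS..TES; ``mode="promoter_proximal"``
    measures the traveling-ratio promoter window. Intervals with more
    than ``max_n_fraction`` N bases are flagged. Columns: gene_id,
    gc_content, gcskew, flagged.
    """
    if mode not in ("genic", "promoter_proximal"):
        raise ValueError("mode must be 'genic' or 'promoter_proximal'")
    rows = []
    for g in genes:
        if g.chrom not in sequences:
            raise KeyError(f"no sequence for chromosome {g.chrom!r}")
        chrom_seq = sequences[g.chrom]
        if mode == "genic":
            s, e = g.interval
        else:
            s, e = g.promoter_window(promoter_upstream, promoter_downstream)
        s = max(0, s)
        e = min(len(chrom_seq), e)
        seq = chrom_seq[s:e]
        if not seq:
            rows.append((g.gene_id, np.nan, np.nan, True))
            continue
        n_frac = (seq.upper().count("N")) / len(seq)
        skew = gc_skew(seq, g.strand)
        rows.append((g.gene_id, gc_content(seq), skew, n_frac > max_n_fraction or not np.isfinite(skew)))
    return pd.DataFrame(rows, columns=["gene_id", "gc_content", "gcskew", "flagged"])


@dataclass
class StratificationConfig:
    """Quantile and length thresholds for gene grouping."""

    gcskew_low_quantile: float = 0.10
    gcskew_high_quantile: float = 0.90
    length_threshold_bp: int = 100_000
    length_short_quantile: float = 0.20
    length_mid_low_quantile: float = 0.40
    length_mid_high_quantile: float = 0.60
    length_long_quantile: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.gcskew_low_quantile < self.gcskew_high_quantile < 1:
            raise ValueError("need 0 < low quantile < high quantile < 1")


def _quantile_lower(values: np.ndarray, q: float) -> float:
    return float(np.quantile(values, q, method="lower"))


def _quantile_higher(values: np.ndarray, q: float) -> float:
    return float(np.quantile(values, q, method="higher"))


def stratify_by_gcskew(
    universe: pd.DataFrame,
    active_genes: Sequence[str] | None = None,
    config: StratificationConfig | None = None,
) -> dict:
    """Call skew-low / skew-high gene groups from the full genic universe.

    Thresholds are the empirical tail quantiles (default 10% / 90%) of
    the *entire* universe's skew distribution — order statistics, taken
    inclusively: low = {skew <= lower-order-statistic q_low}, high =
    {skew >= higher-order-statistic q_high}. Groups are then intersected
    with ``active_genes`` when given. Returns a dict with ``low``,
    ``high`` (lists of gene ids), the thresholds, and a ``degenerate``
    flag set when all skew values coincide.
    """
    config = config or StratificationConfig()
    df = universe[np.isfinite(universe["gcskew"].to_numpy(dtype=float))]
    if df.empty:
        raise ValueError("universe has no genes with defined GC skew")
    skew = df["gcskew"].to_numpy(dtype=float)
    degenerate = bool(np.all(skew == skew[0]))
    q_low = _quantile_lower(skew, config.gcskew_low_quantile)
    q_high = _quantile_higher(skew, config.gcskew_high_quantile)
    low = df.loc[skew <= q_low, "gene_id"].tolist()
    high = df.loc[skew >= q_high, "gene_id"].tolist()
    if active_genes is not None:
        keep = set(active_genes)
        low = [g for g in low if g in keep]
        high = [g for g in high if g in keep]
    return {
        "low": low,
        "high": high,
        "threshold_low": q_low,
        "threshold_high": q_high,
        "degenerate": degenerate,
    }


def stratify_by_length(
    genes: Iterable[GeneModel],
    config: StratificationConfig | None = None,
    mode: str = "threshold",
) -> dict[str, list[str]]:
    """Group genes by length.

    ``mode="threshold"``: short = length <= 100 kb, long = length >
    100 kb (genes exactly on the boundary count as short).
    ``mode="quantile"``: short = shortest 20%, medium = middle 40-60%,
    long = longest 20% of the gene-length distribution, using the same
    inclusive order-statistic rule as the skew stratification.
    """
    config = config or StratificationConfig()
    genes = list(genes)
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    ids = [g.gene_id for g in genes]
    if mode == "threshold":
        t = config.length_threshold_bp
        return {
            "short": [i for i, l in zip(ids, lengths) if l <= t],
            "long": [i for i, l in zip(ids, lengths) if l > t],
        }
    if mode != "quantile":
        raise ValueError("mode must be 'threshold' or 'quantile'")
    if len(lengths) == 0:
        return {"short": [], "medium": [], "long": []}
    q_short = _quantile_lower(lengths, config.length_short_quantile)
    q_mid_lo = _quantile_lower(lengths, config.length_mid_low_quantile)
    q_mid_hi = _quantile_lower(lengths, config.length_mid_high_quantile)
    q_long = _quantile_higher(lengths, config.length_long_quantile)
    return {
        "short": [i for i, l in zip(ids, lengths) if l <= q_short],
        "medium": [i for i, l in zip(ids, lengths) if q_mid_lo < l <= q_mid_hi],
        "long": [i for i, l in zip(ids, lengths) if l >= q_long],
    }
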