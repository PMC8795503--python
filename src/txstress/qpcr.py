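"""ChIP- and DRIP-qPCR quantification.

Cycle-threshold (Ct) values are log2 measurements of DNA abundance: one
cycle earlier means twice the template. The module provides the standard
transforms — 2^-ddCt relative quantification, percent input (IP signal as
a percentage of the input chromatin, corrected for the input fraction),
fold enrichment of a specific antibody over the IgG control, and
normalization of DRIP signal to a negative-control region — plus a tidy
table workflow: technical triplicates are averaged (flagged when their
range exceeds 0.5 cycles), and biological replicates summarized as
mean +/- SEM.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ddct_fold",
    "percent_input",
    "fold_enrichment_vs_igg",
    "drip_relative",
    "summarize_replicates",
    "qpcr_percent_input_table",
    "chip_fold_enrichment_table",
    "drip_relative_table",
]

REPLICATE_RANGE_FLAG_CYCLES = 0.5


def ddct_fold(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative fold change by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl);
    fold = 2^-ddCt. ddCt = 0 gives 1; each extra cycle halves the fold.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("all Ct means must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.01) -> float:
    """IP signal as a percentage of total input chromatin.

    The input Ct is first adjusted by ``log2(1/input_fraction)`` to
    represent 100% of the material; then
    ``percent = 100 * 2^(adjusted_input_ct - ct_ip)``.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def fold_enrichment_vs_igg(percent_specific: float, percent_igg: float) -> float:
    """Specific-antibody signal over the IgG control; NaN (flagged) when IgG is 0."""
    if percent_igg <= 0:
        return float("nan")
    return percent_specific / percent_igg


def drip_relative(percent_target: float, percent_negctrl: float) -> float:
    """Input-normalized DRIP signal relative to the negative-control region."""
    if percent_negctrl <= 0:
        return float("nan")
    return percent_target / percent_negctrl


def summarize_replicates(ct_values: Sequence[float]) -> tuple[float, bool]:
    """Mean Ct of technical replicates, flagged when the range exceeds 0.5 cycles."""
    v = np.asarray(ct_values, dtype=float)
    if v.size == 0 or not np.isfinite(v).all() or (v <= 0).any():
        raise ValueError("Ct replicates must be finite and > 0")
    return float(v.mean()), bool(v.max() - v.min() > REPLICATE_RANGE_FLAG_CYCLES)


REQUIRED_COLUMNS = {"sample", "region", "antibody", "replicate", "ct"}


def _mean_ct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = REQUIRED_COLUMNS - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    keys = ["sample", "region", "antibody"]
    for key, sub in ct_table.groupby(keys, sort=False):
        mean_ct, flagged = summarize_replicates(sub["ct"].to_numpy())
        frac = float(sub["input_fraction"].iloc[0]) if "input_fraction" in sub else np.nan
        rows.append((*key, mean_ct, flagged, frac))
    return pd.DataFrame(rows, columns=[*keys, "mean_ct", "replicate_flag", "input_fraction"])


def qpcr_percent_input_table(ct_table: pd.DataFrame, input_fraction: float = 0.01) -> pd.DataFrame:
    """Percent input per sample x region x antibody from a tidy Ct table.

    Expects long-format rows (sample, region, antibody, replicate, ct
    [, input_fraction]); the ``input`` antibody rows provide the
    denominator for each sample x region.
    """
    means = _mean_ct_table(ct_table)
    inputs = means[means["antibody"] == "input"].set_index(["sample", "region"])["mean_ct"]
    out = []
    for _, row in means[means["antibody"] != "input"].iterrows():
        key = (row["sample"], row["region"])
        if key not in inputs.index:
            raise ValueError(f"no input Ct for sample={key[0]!r} region={key[1]!r}")
        frac = row["input_fraction"] if np.isfinite(row["input_fraction"]) else input_fraction
        pct = percent_input(row["mean_ct"], float(inputs.loc[key]), frac)
        out.append((row["sample"], row["region"], row["antibody"], pct, row["replicate_flag"]))
    return pd.DataFrame(out, columns=["sample", "region", "antibody", "percent_input", "replicate_flag"])


def chip_fold_enrichment_table(
    percent_table: pd.DataFrame,
    specific_antibody: str,
    igg_antibody: str = "IgG",
) -> pd.DataFrame:
    """Fold enrichment of the specific antibody over IgG, per sample x region."""
    piv = percent_table.pivot_table(
        index=["sample", "region"], columns="antibody", values="percent_input", aggfunc="first"
    )
    for col in (specific_antibody, igg_antibody):
        if col not in piv.columns:
            raise ValueError(f"antibody {col!r} absent from percent-input table")
    fold = piv[specific_antibody].combine(piv[igg_antibody], fold_enrichment_vs_igg)
    out = piv.reset_index()[["sample", "region"]].copy()
    out["fold_vs_igg"] = fold.to_numpy()
    return out


def drip_relative_table(
    percent_table: pd.DataFrame,
    negctrl_region: str,
    antibody: str = "S9.6",
) -> pd.DataFrame:
    """DRIP signal per region normalized within-sample to the negative-control region."""
    sub = percent_table[percent_table["antibody"] == antibody]
    neg = sub[sub["region"] == negctrl_region].set_index("sample")["percent_input"]
    out = []
    for _, row in sub.iterrows():
        if row["sample"] not in neg.index:
            raise ValueError(f"no negative-control measurement for sample {row['sample']!r}")
        out.append(
            (row["sample"], row["region"], drip_relative(row["percent_input"], float(neg.loc[row["sample"]])))
        )
    return pd.DataFrame(out, columns=["sample", "region", "relative_signal"])


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error across biological replicates."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), sem
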