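"""End-to-end orchestration of the synthetic transcription-stress analysis.

``run_pipeline`` drives every stage from one nested config dict:
synthetic inputs -> CNC calling -> replicate intersection -> permutation
enrichment -> traveling ratios and condition comparison -> GC-skew and
length stratification -> qPCR tables. Each stage writes a TSV next to the
others, the fully-resolved config and a run log are saved alongside, and
identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .cnc import call_cnc, calls_to_regionset, summarize_cnc
from .gcskew import StratificationConfig, genic_gcskew, stratify_by_gcskew, stratify_by_length
from .intervals import RegionSet, intersect_replicates
from .pausing import TravelingRatioAnalysis, call_active_genes, compare_distributions, cumulative_curve
from .permutation import PermutationOverlapTest
from .qpcr import chip_fold_enrichment_table, drip_relative_table, qpcr_percent_input_table
from .simulate import SimulationConfig, simulate_all

__all__ = ["default_config", "validate_config", "run_pipeline"]


def default_config(seed: int = 0, outdir: str = "txstress_out") -> dict:
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {},  # overrides for SimulationConfig fields
        "cnc": {"threshold_log2": 0.5, "min_probes": 5},
        "permutation": {"n_perm": 1000},
        "tr": {"pseudocount": 0.0, "promoter_upstream": 30, "promoter_downstream": 300},
        "active_genes": {"enrichment_threshold": 2.0, "min_promoter_density": 0.3},
        "stratification": {
            "gcskew_low_quantile": 0.10,
            "gcskew_high_quantile": 0.90,
            "length_threshold_bp": 100_000,
        },
        "qpcr": {"input_fraction": 0.01, "negctrl_region": "SNRPN", "drip_antibody": "S9.6",
                 "chip_antibody": "gH2AX", "igg_antibody": "IgG"},
    }


def validate_config(config: dict) -> dict:
    """Merge with defaults and reject out-of-range parameters up front."""
    cfg = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and key in cfg:
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    if cfg["permutation"]["n_perm"] < 1:
        raise ValueError("permutation.n_perm must be >= 1")
    if cfg["cnc"]["threshold_log2"] <= 0:
        raise ValueError("cnc.threshold_log2 must be > 0")
    if cfg["cnc"]["min_probes"] < 1:
        raise ValueError("cnc.min_probes must be >= 1")
    s = cfg["stratification"]
    if not 0 < s["gcskew_low_quantile"] < s["gcskew_high_quantile"] < 1:
        raise ValueError("stratification quantiles must satisfy 0 < low < high < 1")
    if cfg["tr"]["pseudocount"] < 0:
        raise ValueError("tr.pseudocount must be >= 0")
    if not 0 < cfg["qpcr"]["input_fraction"] <= 1:
        raise ValueError("qpcr.input_fraction must be in (0, 1]")
    SimulationConfig(seed=cfg["seed"], **cfg["simulate"])  # raises on unknown fields
    return cfg


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run every stage; returns a summary dict (also written to summary.json)."""
    cfg = validate_config(config or {})
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    summary: dict = {"seed": cfg["seed"]}
    t0 = time.time()

    # stage 1: synthetic inputs, then re-read through the public readers
    sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg["simulate"])
    inputs = simulate_all(sim_cfg, outdir / "inputs")
    log(f"simulate: wrote {len(inputs)} input files (seed={cfg['seed']})")
    genome = tio.read_chrom_sizes(inputs["chrom_sizes"])
    genes = tio.read_gene_table(inputs["genes"])
    sequences = tio.read_fasta(inputs["fasta"])
    chip_wt = tio.read_bedgraph(inputs["chip_wt"], genome, sim_cfg.bin_width)
    chip_ko = tio.read_bedgraph(inputs["chip_ko"], genome, sim_cfg.bin_width)
    input_wt = tio.read_bedgraph(inputs["input_wt"], genome, sim_cfg.bin_width)
    input_ko = tio.read_bedgraph(inputs["input_ko"], genome, sim_cfg.bin_width)
    cnc_truth = tio.read_bed(inputs["cnc"], genome, name="cnc_truth")
    features = tio.read_bed(inputs["features"], genome, name="features")
    probes = tio.read_probe_table(inputs["probes"])
    ct_table = tio.read_ct_table(inputs["ct"])

    # stage 2: CNC calling + replicate intersection against the planted truth
    calls = call_cnc(probes, cfg["cnc"]["threshold_log2"], cfg["cnc"]["min_probes"])
    called = calls_to_regionset(calls, genome, name="cnc_called")
    tio.write_bed(called, outdir / "cnc_calls.bed", scores=[c.mean_log2_ratio for c in calls])
    common = intersect_replicates(called, cnc_truth)
    cnc_sum = summarize_cnc(calls, genes)
    summary["cnc"] = {
        "n_calls": cnc_sum["n_calls"], "n_gains": cnc_sum["n_gains"],
        "n_losses": cnc_sum["n_losses"], "percent_genic": cnc_sum["percent_genic"],
        "n_common_with_replicate": len(common),
    }
    log(f"cnc: {cnc_sum['n_calls']} calls ({cnc_sum['n_gains']} gains / "
        f"{cnc_sum['n_losses']} losses), {len(common)} common to both replicates")

    # stage 3: permutation enrichment of gains/losses in the feature set
    perm_rows = []
    n_perm = cfg["permutation"]["n_perm"]
    for cls in ("gain", "loss"):
        sub = RegionSet([iv for iv in cnc_truth if iv.cnc_class == cls], genome, name=cls)
        if len(sub) == 0:
            log(f"permtest: no {cls} regions, skipped")
            continue
        res = PermutationOverlapTest(sub, features, genome).fit(n_perm=n_perm, seed=cfg["seed"])
        row = res.to_dict()
        row["query"] = cls
        perm_rows.append(row)
        pd.DataFrame({"null_overlap_kb": res.null_distribution}).to_csv(
            outdir / f"perm_null_{cls}.tsv", sep="\t", index=False
        )
        log(f"permtest[{cls}]: observed {res.observed_kb:.1f} kb vs null "
            f"{res.null_mean_kb:.1f} kb, {res.direction}, p={res.p_value:.3g}")
    perm_df = pd.DataFrame(perm_rows)
    perm_df.to_csv(outdir / "permutation_results.tsv", sep="\t", index=False)
    summary["permutation"] = perm_rows

    # stage 4: traveling ratios, active genes, condition comparison
    trp = cfg["tr"]
    active = call_active_genes(
        chip_wt, input_wt, genes,
        cfg["active_genes"]["enrichment_threshold"],
        cfg["active_genes"]["min_promoter_density"],
        promoter_upstream=trp["promoter_upstream"],
        promoter_downstream=trp["promoter_downstream"],
    )
    log(f"trstress: {len(active)} active genes of {len(genes)}")
    results = {}
    for cond, chip, inp in (("wt", chip_wt, input_wt), ("ko", chip_ko, input_ko)):
        res = TravelingRatioAnalysis(
            chip, inp, active, pseudocount=trp["pseudocount"],
            promoter_upstream=trp["promoter_upstream"],
            promoter_downstream=trp["promoter_downstream"],
        ).fit()
        results[cond] = res
        res.records.to_csv(outdir / f"tr_{cond}.tsv", sep="\t", index=False)
        curve = cumulative_curve(res.rotr_values())
        pd.DataFrame(curve, columns=["rotr", "percent_of_genes"]).to_csv(
            outdir / f"rotr_cumulative_{cond}.tsv", sep="\t", index=False
        )
        log(f"trstress[{cond}]: {len(res.included)} genes, exclusions {res.exclusion_counts() or 'none'}")
    stat, p = results["wt"].compare(results["ko"], values="tr")
    merged = results["wt"].included.merge(results["ko"].included, on="gene_id", suffixes=("_wt", "_ko"))
    tr_ratio = merged["tr_ko"] / merged["tr_wt"]
    summary["tr"] = {
        "n_active": len(active),
        "median_tr_wt": float(np.median(results["wt"].tr_values())),
        "median_tr_ko": float(np.median(results["ko"].tr_values())),
        "median_tr_ratio_ko_wt": float(np.median(tr_ratio)),
        "wilcoxon_statistic": stat,
        "wilcoxon_p": p,
    }
    log(f"trstress: median TR ko/wt = {summary['tr']['median_tr_ratio_ko_wt']:.3f}, "
        f"rank-sum p = {p:.3g}")

    # stage 5: GC-skew and gene-length stratification of the TR difference
    skew_df = genic_gcskew(sequences, genes, mode="promoter_proximal")
    skew_df.to_csv(outdir / "gcskew.tsv", sep="\t", index=False)
    strat_cfg = StratificationConfig(
        gcskew_low_quantile=cfg["stratification"]["gcskew_low_quantile"],
        gcskew_high_quantile=cfg["stratification"]["gcskew_high_quantile"],
        length_threshold_bp=cfg["stratification"]["length_threshold_bp"],
    )
    groups = stratify_by_gcskew(skew_df, [g.gene_id for g in active], strat_cfg)
    merged["tr_diff"] = merged["tr_ko"] - merged["tr_wt"]
    diff_by_gene = merged.set_index("gene_id")["tr_diff"]
    hi = diff_by_gene[diff_by_gene.index.isin(groups["high"])].to_numpy()
    lo = diff_by_gene[diff_by_gene.index.isin(groups["low"])].to_numpy()
    skew_comp = {}
    if len(hi) and len(lo):
        s_stat, s_p = compare_distributions(hi, lo)
        skew_comp = {"n_high": len(hi), "n_low": len(lo),
                     "median_diff_high": float(np.median(hi)), "median_diff_low": float(np.median(lo)),
                     "wilcoxon_p": s_p}
        log(f"gcskew: TR difference high vs low skew, p = {s_p:.3g}")
    length_groups = stratify_by_length(active, strat_cfg, mode="threshold")
    summary["stratification"] = {
        "n_skew_high": len(groups["high"]), "n_skew_low": len(groups["low"]),
        "skew_comparison": skew_comp,
        "n_short": len(length_groups["short"]), "n_long": len(length_groups["long"]),
    }

    # stage 6: qPCR tables
    qp = cfg["qpcr"]
    pct = qpcr_percent_input_table(ct_table, qp["input_fraction"])
    pct.to_csv(outdir / "qpcr_percent_input.tsv", sep="\t", index=False)
    fold = chip_fold_enrichment_table(pct, qp["chip_antibody"], qp["igg_antibody"])
    fold.to_csv(outdir / "qpcr_fold_vs_igg.tsv", sep="\t", index=False)
    drip = drip_relative_table(pct, qp["negctrl_region"], qp["drip_antibody"])
    drip.to_csv(outdir / "qpcr_drip_relative.tsv", sep="\t", index=False)
    summary["qpcr"] = {
        "drip_relative": {f"{r.sample}:{r.region}": float(r.relative_signal) for r in drip.itertuples()},
    }
    log("qpcr: percent-input, fold-vs-IgG and DRIP-relative tables written")

    # bookkeeping
    summary["elapsed_s"] = round(time.time() - t0, 2)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(copy.deepcopy(cfg), fh, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
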