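"""Synthetic data with the generative structure the analyses assume.

Every pipeline stage can be exercised without any download: a random
genome with promoter windows engineered to hit per-gene GC-skew targets,
Poisson ChIP/input coverage with a per-gene promoter pausing factor, CNC
and fragile-site-like feature interval sets with a controllable planted
overlap fraction, a probe-level log-ratio table with the CNCs embedded,
and qPCR Ct tables generated as log2 abundance plus Gaussian cycle noise.

Generative model for coverage
-----------------------------
Expressed genes receive a body signal rate ``expression_rate`` (signal
per bp) and a promoter-proximal rate ``expression_rate * pi`` where
``pi`` is the condition's pausing factor; everything sits on a small
uniform ``background_rate``. Counts are Poisson per bin and stored as
per-bp rates, so in expectation the traveling ratio of an expressed gene
equals ``(background + rate * pi) / (background + rate)`` — equal to
``pi`` exactly when the background vanishes, and within a few percent of
it at the default background. The input track is uniform at
``input_rate``.

All randomness flows from a single integer seed through independent
`numpy` Generator streams per component, so outputs are reproducible
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, GenomicInterval, RegionSet
from .pausing import CoverageTrack, GeneModel, PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM

__all__ = [
    "SimulationConfig",
    "make_genome_and_genes",
    "simulate_coverage",
    "simulate_cnc_and_features",
    "simulate_qpcr",
    "default_qpcr_truth",
    "simulate_all",
]

BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Desk-scale defaults: 2 chromosomes x 5 Mb, 300 genes, 50 CNCs."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    gene_length_log_mean: float = float(np.log(8_000))
    gene_length_log_sd: float = 0.8
    min_gene_length: int = 1_000
    fraction_expressed: float = 0.7
    fraction_high_skew: float = 0.5
    promoter_skew: Mapping[str, float] = field(default_factory=lambda: {"high": 0.4, "low": -0.4})
    expression_rate: float = 0.5       # signal per bp in gene bodies
    background_rate: float = 0.02      # nonspecific chip signal per bp
    input_rate: float = 0.2            # uniform input signal per bp
    pausing: Mapping[str, float] = field(default_factory=lambda: {"wt": 2.0, "ko": 4.0})
    bin_width: int = 10
    # CNC / feature simulation
    n_features: int = 25
    feature_length: int = 20_000
    n_cnc: int = 50
    cnc_length: int = 2_000
    planted_fraction: float = 0.5
    probe_spacing: int = 200
    probe_noise_sd: float = 0.0
    cnc_amplitude: float = 1.0
    # qPCR
    ct_noise_sd: float = 0.1
    ct_replicates: int = 3
    qpcr_base_ct: float = 12.0

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ["genome", "genes", "coverage_wt", "coverage_ko", "coverage_input", "cnc", "qpcr"]
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _skewed_promoter(rng: np.random.Generator, length: int, target_skew: float, gc_fraction: float = 0.5) -> str:
    """Sense-strand promoter sequence with exact composition hitting the target skew."""
    n_gc = int(round(length * gc_fraction))
    n_g = int(round(n_gc * (1 + target_skew) / 2))
    n_c = n_gc - n_g
    n_at = length - n_gc
    n_a = n_at // 2
    letters = np.array(["G"] * n_g + ["C"] * n_c + ["A"] * n_a + ["T"] * (n_at - n_a))
    rng.shuffle(letters)
    return "".join(letters)


def make_genome_and_genes(
    config: SimulationConfig,
    rng_genome: np.random.Generator | None = None,
    rng_genes: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame, GenomeLayout]:
    """Random genome plus non-overlapping genes with engineered promoter skew.

    Returns (sequences, genes, gene_meta, genome). ``gene_meta`` has one
    row per gene: gene_id, skew_class (high/low), target_skew, expressed.
    Deterministic per seed/streams.
    """
    streams = _streams(config.seed)
    rng_genome = rng_genome or streams["genome"]
    rng_genes = rng_genes or streams["genes"]
    genome = GenomeLayout(config.chrom_sizes())
    seq_arrays = {
        chrom: BASE_BYTES[rng_genome.integers(4, size=length)]
        for chrom, length in genome.chrom_sizes.items()
    }
    genes: list[GeneModel] = []
    meta_rows = []
    if config.n_genes == 0:
        sequences = {c: a.tobytes().decode("ascii") for c, a in seq_arrays.items()}
        meta = pd.DataFrame(columns=["gene_id", "chrom", "skew_class", "target_skew", "expressed"])
        return sequences, genes, meta, genome

    lengths = np.maximum(
        config.min_gene_length,
        rng_genes.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, config.n_genes).astype(int),
    )
    chroms = list(genome.chrom_sizes)
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for k, l in enumerate(lengths):
        per_chrom[chroms[k % len(chroms)]].append(int(l))

    margin = PROMOTER_DOWNSTREAM + PROMOTER_UPSTREAM + 100  # keep promoter windows off neighbours
    gid = 0
    for chrom in chroms:
        ls = per_chrom[chrom]
        L = genome.chrom_sizes[chrom]
        n = len(ls)
        if n == 0:
            continue
        free = L - sum(ls) - margin * (n + 1)
        if free < 0:
            raise ValueError(
                f"cannot place {n} genes totalling {sum(ls)} bp on {chrom} "
                f"({L} bp); use fewer or shorter genes"
            )
        cuts = np.sort(rng_genes.integers(0, free + 1, size=n))
        extra = np.diff(np.concatenate([[0], cuts]))
        pos = margin
        for l, x in zip(ls, extra):
            pos += int(x)
            start, end = pos, pos + l
            strand = "+" if rng_genes.random() < 0.5 else "-"
            gene_id = f"g{gid:04d}"
            if strand == "+":
                gene = GeneModel(gene_id, chrom, "+", start, end)
            else:
                gene = GeneModel(gene_id, chrom, "-", end, start)
            skew_class = "high" if rng_genes.random() < config.fraction_high_skew else "low"
            target = config.promoter_skew[skew_class]
            window = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM
            sense = _skewed_promoter(rng_genes, window, target)
            ps, pe = gene.promoter_window()
            if strand == "+":
                seq_arrays[chrom][ps:pe] = np.frombuffer(sense.encode("ascii"), dtype=np.uint8)
            else:
                from .gcskew import reverse_complement

                seq_arrays[chrom][ps:pe] = np.frombuffer(
                    reverse_complement(sense).encode("ascii"), dtype=np.uint8
                )
            expressed = bool(rng_genes.random() < config.fraction_expressed)
            genes.append(gene)
            meta_rows.append((gene_id, chrom, skew_class, target, expressed))
            gid += 1
            pos = end + margin
    sequences = {c: a.tobytes().decode("ascii") for c, a in seq_arrays.items()}
    meta = pd.DataFrame(meta_rows, columns=["gene_id", "chrom", "skew_class", "target_skew", "expressed"])
    return sequences, genes, meta, genome


def _add_rate(arr: np.ndarray, bw: int, start: int, end: int, rate: float) -> None:
    """Add a per-bp rate over [start, end) with fractional bin weighting."""
    start = max(0, start)
    end = min(len(arr) * bw, end)
    if end <= start:
        return
    b0, b1 = start // bw, int(np.ceil(end / bw))
    idx = np.arange(b0, b1)
    left = np.maximum(start, idx * bw)
    right = np.minimum(end, (idx + 1) * bw)
    arr[b0:b1] += rate * (right - left) / bw


def simulate_coverage(
    genes: Sequence[GeneModel],
    gene_meta: pd.DataFrame,
    genome: GenomeLayout,
    config: SimulationConfig,
    pausing_factor: float | Mapping[str, float],
    rng: np.random.Generator,
) -> CoverageTrack:
    """One ChIP coverage track under the generative model above.

    ``pausing_factor`` is a scalar pi, or a mapping from skew class
    (high/low) to pi, which couples promoter pausing to promoter skew.
    """
    bw = config.bin_width
    mean = {
        c: np.full(int(np.ceil(l / bw)), config.background_rate, dtype=float)
        for c, l in genome.chrom_sizes.items()
    }
    meta = gene_meta.set_index("gene_id")
    for gene in genes:
        row = meta.loc[gene.gene_id]
        if not bool(row["expressed"]):
            continue
        pi = pausing_factor if np.isscalar(pausing_factor) else pausing_factor[row["skew_class"]]
        if pi < 1:
            raise ValueError("pausing factor must be >= 1")
        ps, pe = gene.promoter_window()
        bs, be = gene.body_window()
        _add_rate(mean[gene.chrom], bw, ps, pe, config.expression_rate * float(pi))
        if be > bs:
            _add_rate(mean[gene.chrom], bw, bs, be, config.expression_rate)
    values = {c: rng.poisson(m * bw).astype(float) / bw for c, m in mean.items()}
    return CoverageTrack(values, bin_width=bw)


def simulate_input(genome: GenomeLayout, config: SimulationConfig, rng: np.random.Generator) -> CoverageTrack:
    bw = config.bin_width
    values = {
        c: rng.poisson(config.input_rate * bw, size=int(np.ceil(l / bw))).astype(float) / bw
        for c, l in genome.chrom_sizes.items()
    }
    return CoverageTrack(values, bin_width=bw)


def _place_disjoint(
    n: int,
    length: int,
    genome: GenomeLayout,
    rng: np.random.Generator,
    occupied: list[GenomicInterval],
    max_tries: int = 10_000,
) -> list[tuple[str, int, int]]:
    """Uniform placements avoiding overlap with each other and ``occupied``."""
    chroms = list(genome.chrom_sizes)
    weights = np.array([genome.chrom_sizes[c] - length + 1 for c in chroms], dtype=float)
    if (weights <= 0).all():
        raise ValueError(f"no chromosome can host an interval of {length} bp")
    weights = np.clip(weights, 0, None)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    taken = [(iv.chrom, iv.start, iv.end) for iv in occupied]
    for _ in range(n):
        for _try in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(genome.chrom_sizes[chrom] - length + 1))
            end = start + length
            if all(not (c == chrom and start < e and s < end) for c, s, e in taken + placed):
                placed.append((chrom, start, end))
                break
        else:
            raise ValueError("could not place disjoint intervals; genome too crowded")
    return placed


def simulate_cnc_and_features(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genome: GenomeLayout | None = None,
) -> tuple[RegionSet, RegionSet, "object", dict]:
    """CNC query set, feature set, probe table and ground truth.

    A fraction ``planted_fraction`` of the CNC intervals is placed fully
    inside feature intervals; the rest land uniformly (disjointly) on the
    genome. The probe table carries ``cnc_amplitude`` log-ratio segments
    (positive for gains, negative for losses) exactly at the CNC
    positions, plus Gaussian probe noise of sd ``probe_noise_sd``.
    """
    from .cnc import ProbeTable

    rng = rng or _streams(config.seed)["cnc"]
    genome = genome or GenomeLayout(config.chrom_sizes())
    f = config.planted_fraction
    if not 0 <= f <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    if config.feature_length < config.cnc_length and round(f * config.n_cnc) > 0:
        raise ValueError("features are too small to host planted CNC intervals")

    feat_pos = _place_disjoint(config.n_features, config.feature_length, genome, rng, [])
    features = RegionSet(
        [GenomicInterval(c, s, e) for c, s, e in feat_pos], genome=genome, name="features"
    )

    n_planted = int(round(f * config.n_cnc))
    cnc_pos: list[tuple[str, int, int]] = []
    for _ in range(n_planted):
        for _try in range(10_000):
            c, s, e = feat_pos[int(rng.integers(len(feat_pos)))]
            start = int(rng.integers(s, e - config.cnc_length + 1))
            end = start + config.cnc_length
            if all(not (cc == c and start < ee and ss < end) for cc, ss, ee in cnc_pos):
                cnc_pos.append((c, start, end))
                break
        else:
            raise ValueError("could not plant CNC intervals inside features")
    occupied = [GenomicInterval(c, s, e) for c, s, e in cnc_pos]
    cnc_pos += _place_disjoint(config.n_cnc - n_planted, config.cnc_length, genome, rng, occupied)
    classes = np.array(["gain"] * ((config.n_cnc + 1) // 2) + ["loss"] * (config.n_cnc // 2))
    rng.shuffle(classes)
    cnc = RegionSet(
        [GenomicInterval(c, s, e, cnc_class=cls) for (c, s, e), cls in zip(cnc_pos, classes)],
        genome=genome,
        name="cnc",
    )

    rows = []
    for chrom, length in genome.chrom_sizes.items():
        pos = np.arange(config.probe_spacing // 2, length, config.probe_spacing, dtype=np.int64)
        ratio = rng.normal(0.0, config.probe_noise_sd, size=len(pos)) if config.probe_noise_sd > 0 else np.zeros(len(pos))
        for iv in cnc:
            if iv.chrom != chrom:
                continue
            inside = (pos >= iv.start) & (pos < iv.end)
            ratio[inside] += config.cnc_amplitude if iv.cnc_class == "gain" else -config.cnc_amplitude
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "log2_ratio": ratio}))
    probes = ProbeTable(pd.concat(rows, ignore_index=True))

    truth = {
        "planted_fraction": f,
        "n_planted": n_planted,
        "cnc": [(iv.chrom, iv.start, iv.end, iv.cnc_class) for iv in cnc],
        "features": [(iv.chrom, iv.start, iv.end) for iv in features],
        "amplitude": config.cnc_amplitude,
    }
    return cnc, features, probes, truth


def default_qpcr_truth(input_fraction: float = 0.01) -> pd.DataFrame:
    """A DRIP/ChIP scenario: R-loop and damage signal at two fragile-site
    loci in a helicase-deficient sample, flat at the negative-control region.

    ``abundance`` is the fraction of total material recovered in each
    measurement; the 'input' antibody rows measure the input aliquot
    itself (abundance = input_fraction).
    """
    rows = []
    drip = {
        ("control", "WWOX"): 0.001, ("control", "CDH13"): 0.001, ("control", "SNRPN"): 0.001,
        ("mutant", "WWOX"): 0.005, ("mutant", "CDH13"): 0.004, ("mutant", "SNRPN"): 0.001,
    }
    chip = {
        ("control", "WWOX"): 0.002, ("control", "CDH13"): 0.002, ("control", "SNRPN"): 0.002,
        ("mutant", "WWOX"): 0.010, ("mutant", "CDH13"): 0.008, ("mutant", "SNRPN"): 0.002,
    }
    igg = 0.0005
    for (sample, region), x in drip.items():
        rows.append((sample, region, "S9.6", x))
    for (sample, region), x in chip.items():
        rows.append((sample, region, "gH2AX", x))
        rows.append((sample, region, "IgG", igg))
    for sample in ("control", "mutant"):
        for region in ("WWOX", "CDH13", "SNRPN"):
            rows.append((sample, region, "input", input_fraction))
    df = pd.DataFrame(rows, columns=["sample", "region", "antibody", "abundance"])
    df["input_fraction"] = input_fraction
    return df


def simulate_qpcr(
    truth: pd.DataFrame,
    sd: float = 0.1,
    replicates: int = 3,
    seed: int | np.random.Generator = 0,
    base_ct: float = 12.0,
) -> pd.DataFrame:
    """Ct table from true abundances: Ct = base - log2(abundance) + N(0, sd)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for r in truth.itertuples(index=False):
        true_ct = base_ct - np.log2(r.abundance)
        for rep in range(1, replicates + 1):
            ct = true_ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append((r.sample, r.region, r.antibody, rep, ct, getattr(r, "input_fraction", np.nan)))
    return pd.DataFrame(rows, columns=["sample", "region", "antibody", "replicate", "ct", "input_fraction"])


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic input bundle to ``outdir``; returns file paths.

    Files: genome.fa, chrom.sizes, genes.tsv, chip_{wt,ko}.bedGraph,
    input_{wt,ko}.bedGraph, cnc.bed, features.bed, probes.tsv, ct.tsv,
    ground_truth.json.
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = _streams(config.seed)
    sequences, genes, meta, genome = make_genome_and_genes(config)
    chip_wt = simulate_coverage(genes, meta, genome, config, config.pausing["wt"], streams["coverage_wt"])
    chip_ko = simulate_coverage(genes, meta, genome, config, config.pausing["ko"], streams["coverage_ko"])
    rng_in = streams["coverage_input"]
    input_wt = simulate_input(genome, config, rng_in)
    input_ko = simulate_input(genome, config, rng_in)
    cnc, features, probes, truth = simulate_cnc_and_features(config, streams["cnc"], genome)
    ct = simulate_qpcr(
        default_qpcr_truth(), sd=config.ct_noise_sd, replicates=config.ct_replicates,
        seed=streams["qpcr"], base_ct=config.qpcr_base_ct,
    )

    paths = {}
    paths["fasta"] = outdir / "genome.fa"
    tio.write_fasta(sequences, paths["fasta"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    tio.write_chrom_sizes(genome, paths["chrom_sizes"])
    paths["genes"] = outdir / "genes.tsv"
    tio.write_gene_table(genes, paths["genes"])
    for label, track in (("chip_wt", chip_wt), ("chip_ko", chip_ko),
                         ("input_wt", input_wt), ("input_ko", input_ko)):
        paths[label] = outdir / f"{label}.bedGraph"
        tio.write_bedgraph(track, paths[label], genome)
    paths["cnc"] = outdir / "cnc.bed"
    tio.write_bed(cnc, paths["cnc"])
    paths["features"] = outdir / "features.bed"
    tio.write_bed(features, paths["features"])
    paths["probes"] = outdir / "probes.tsv"
    tio.write_probe_table(probes, paths["probes"])
    paths["ct"] = outdir / "ct.tsv"
    tio.write_ct_table(ct, paths["ct"])
    paths["gene_meta"] = outdir / "gene_meta.tsv"
    meta.to_csv(paths["gene_meta"], sep="\t", index=False)

    truth_all = {
        "seed": config.seed,
        "pausing": dict(config.pausing),
        "promoter_skew": dict(config.promoter_skew),
        "fraction_expressed": config.fraction_expressed,
        "cnc_truth": truth,
        "config": {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in asdict(config).items()},
    }
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth_all, fh, indent=1)
    return paths
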