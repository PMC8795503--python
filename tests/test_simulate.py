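"""Synthetic-data generator: determinism, planted structure, round trips."""

import json

import numpy as np
import pytest

from txstress import io as tio
from txstress.gcskew import gc_skew, genic_gcskew
from txstress.intervals import overlap_kb
from txstress.pausing import TravelingRatioAnalysis
from txstress.simulate import (
    SimulationConfig,
    _streams,
    default_qpcr_truth,
    make_genome_and_genes,
    simulate_cnc_and_features,
    simulate_coverage,
    simulate_input,
    simulate_qpcr,
    simulate_all,
)

SMALL = dict(n_chroms=2, chrom_length=300_000, n_genes=30, gene_length_log_mean=8.0,
             n_features=5, feature_length=8_000, n_cnc=8)


class TestGenomeAndGenes:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        s1, g1, m1, _ = make_genome_and_genes(cfg)
        s2, g2, m2, _ = make_genome_and_genes(cfg)
        assert s1 == s2
        assert [(g.gene_id, g.tss, g.tes, g.strand) for g in g1] == \
               [(g.gene_id, g.tss, g.tes, g.strand) for g in g2]
        assert m1.equals(m2)

    def test_promoter_skew_hits_target(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        seqs, genes, meta, _ = make_genome_and_genes(cfg)
        skew = genic_gcskew(seqs, genes, mode="promoter_proximal").set_index("gene_id")
        for row in meta.itertuples():
            measured = skew.loc[row.gene_id, "gcskew"]
            assert abs(measured - row.target_skew) <= 0.05

    def test_genes_do_not_overlap(self):
        cfg = SimulationConfig(seed=6, **SMALL)
        _, genes, _, _ = make_genome_and_genes(cfg)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_zero_genes_valid(self):
        cfg = SimulationConfig(seed=7, n_genes=0, n_chroms=1, chrom_length=50_000)
        seqs, genes, meta, _ = make_genome_and_genes(cfg)
        assert genes == [] and meta.empty and len(seqs["chr1"]) == 50_000

    def test_overcrowded_config_rejected(self):
        cfg = SimulationConfig(seed=8, n_chroms=1, chrom_length=20_000, n_genes=50)
        with pytest.raises(ValueError, match="fewer or shorter"):
            make_genome_and_genes(cfg)


@pytest.fixture(scope="module")
def world():
    cfg = SimulationConfig(seed=9, n_chroms=2, chrom_length=2_000_000, n_genes=220,
                           gene_length_log_mean=8.5, gene_length_log_sd=0.5)
    seqs, genes, meta, genome = make_genome_and_genes(cfg)
    return cfg, genes, meta, genome


class TestCoverage:
    def test_pi_one_mean_tr_near_unity(self, world):
        cfg, genes, meta, genome = world
        chip = simulate_coverage(genes, meta, genome, cfg, 1.0, np.random.default_rng(1))
        res = TravelingRatioAnalysis(chip, None, genes).fit()
        expressed = set(meta.loc[meta.expressed, "gene_id"])
        tr = res.included[res.included.gene_id.isin(expressed)]["tr"]
        assert len(tr) >= 140
        assert tr.mean() == pytest.approx(1.0, rel=0.05)

    def test_unexpressed_gene_stays_at_background(self, world):
        cfg, genes, meta, genome = world
        chip = simulate_coverage(genes, meta, genome, cfg, 2.0, np.random.default_rng(2))
        silent = set(meta.loc[~meta.expressed, "gene_id"])
        res = TravelingRatioAnalysis(chip, None, genes).fit()
        dens = res.records[res.records.gene_id.isin(silent)]["promoter_density"].dropna()
        assert dens.mean() < 3 * cfg.background_rate

    def test_pausing_factor_recovered_in_rotr(self, world):
        cfg, genes, meta, genome = world
        chip_wt = simulate_coverage(genes, meta, genome, cfg, 2.0, np.random.default_rng(3))
        chip_ko = simulate_coverage(genes, meta, genome, cfg, 4.0, np.random.default_rng(4))
        inp = simulate_input(genome, cfg, np.random.default_rng(5))
        wt = TravelingRatioAnalysis(chip_wt, inp, genes).fit()
        ko = TravelingRatioAnalysis(chip_ko, inp, genes).fit()
        expressed = set(meta.loc[meta.expressed, "gene_id"])
        m = wt.included.merge(ko.included, on="gene_id", suffixes=("_wt", "_ko"))
        m = m[m.gene_id.isin(expressed)]
        ratio = (m["rotr_ko"] / m["rotr_wt"]).median()
        assert ratio == pytest.approx(2.0, rel=0.1)


class TestCncAndFeatures:
    def test_fully_planted_overlap_equals_query_size(self):
        cfg = SimulationConfig(seed=10, planted_fraction=1.0, **SMALL)
        cnc, features, _, _ = simulate_cnc_and_features(cfg)
        assert overlap_kb(cnc, features) == pytest.approx(cnc.total_bp / 1000.0)

    def test_unplanted_overlap_near_feature_fraction(self):
        total_kb = []
        for seed in range(15):
            cfg = SimulationConfig(seed=seed, planted_fraction=0.0,
                                   n_chroms=2, chrom_length=1_000_000,
                                   n_features=10, feature_length=10_000, n_cnc=40)
            cnc, features, _, _ = simulate_cnc_and_features(cfg)
            total_kb.append(overlap_kb(cnc, features))
        # features cover 5% of the genome; query totals 80 kb -> expect ~4 kb
        assert np.mean(total_kb) == pytest.approx(4.0, rel=0.5)

    def test_probe_segments_match_planted_positions(self):
        cfg = SimulationConfig(seed=11, probe_noise_sd=0.0, **SMALL)
        cnc, _, probes, truth = simulate_cnc_and_features(cfg)
        df = probes.df
        hot = df[df.log2_ratio != 0]
        for row in hot.itertuples():
            assert any(
                c == row.chrom and s <= row.pos < e for c, s, e, _cls in truth["cnc"]
            )

    def test_features_too_small_rejected(self):
        cfg = SimulationConfig(seed=12, feature_length=1_000, cnc_length=2_000,
                               planted_fraction=1.0)
        with pytest.raises(ValueError, match="too small"):
            simulate_cnc_and_features(cfg)


class TestQpcrSim:
    def test_noiseless_fold_exact(self):
        truth = default_qpcr_truth()
        ct = simulate_qpcr(truth, sd=0.0, replicates=2, seed=0)
        sub = ct.query("antibody == 'S9.6' and sample == 'mutant'").groupby("region")["ct"].mean()
        fold = 2 ** (sub["SNRPN"] - sub["WWOX"])
        assert fold == pytest.approx(5.0)

    def test_seed_determinism(self):
        truth = default_qpcr_truth()
        a = simulate_qpcr(truth, sd=0.2, replicates=3, seed=5)
        b = simulate_qpcr(truth, sd=0.2, replicates=3, seed=5)
        assert a.equals(b)

    def test_monte_carlo_log_fold_unbiased(self):
        rows = [("s", "t", "S9.6", 0.004), ("s", "n", "S9.6", 0.001)]
        import pandas as pd
        truth = pd.DataFrame(rows, columns=["sample", "region", "antibody", "abundance"])
        rng = np.random.default_rng(13)
        log_folds = []
        for _ in range(400):
            ct = simulate_qpcr(truth, sd=0.1, replicates=1, seed=rng)
            by = ct.set_index("region")["ct"]
            log_folds.append(float(by["n"] - by["t"]))
        se = np.std(log_folds) / np.sqrt(len(log_folds))
        assert abs(np.mean(log_folds) - 2.0) < 3 * se


class TestRoundTrip:
    def test_emitted_files_parse_and_agree(self, tmp_path):
        cfg = SimulationConfig(seed=14, **SMALL)
        paths = simulate_all(cfg, tmp_path)
        genome = tio.read_chrom_sizes(paths["chrom_sizes"])
        assert genome.total_bp == cfg.n_chroms * cfg.chrom_length
        genes = tio.read_gene_table(paths["genes"])
        assert len(genes) == cfg.n_genes
        seqs = tio.read_fasta(paths["fasta"])
        assert {len(s) for s in seqs.values()} == {cfg.chrom_length}
        track = tio.read_bedgraph(paths["chip_wt"], genome, cfg.bin_width)
        assert set(track.chroms) == set(genome.chroms)
        cnc = tio.read_bed(paths["cnc"], genome)
        assert len(cnc) == cfg.n_cnc
        assert all(iv.cnc_class in ("gain", "loss") for iv in cnc)
        probes = tio.read_probe_table(paths["probes"])
        assert len(probes) > 0
        ct = tio.read_ct_table(paths["ct"])
        assert set(ct["antibody"]) >= {"S9.6", "input"}
        truth = json.loads(paths["ground_truth"].read_text())
        assert truth["seed"] == 14

    def test_bedgraph_round_trip_preserves_values(self, tmp_path):
        cfg = SimulationConfig(seed=15, n_chroms=1, chrom_length=50_000, n_genes=5,
                               gene_length_log_mean=7.5)
        seqs, genes, meta, genome = make_genome_and_genes(cfg)
        track = simulate_coverage(genes, meta, genome, cfg, 2.0, np.random.default_rng(6))
        path = tmp_path / "t.bedGraph"
        tio.write_bedgraph(track, path, genome)
        back = tio.read_bedgraph(path, genome, cfg.bin_width)
        np.testing.assert_allclose(back.values["chr1"], track.values["chr1"])
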