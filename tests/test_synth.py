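"""Generator contracts: determinism, no-noise limits, truth consistency."""

import numpy as np
import pytest

from metaepi.io import ValidationError, read_fasta, read_gene_table, read_modifications
from metaepi.modcall import estimate_fraction
from metaepi.motifs import MotifSpec, motif_density, scan_motif
from metaepi.synth import (
    SynthConfig,
    emit_corpus,
    simulate_genome,
    simulate_ipd_observations,
    simulate_phage_set,
    simulate_population,
)


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(meth_prob=1.5)

    def test_infeasible_gene_packing_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(genome_length=1000, genes_per_strand=10, mean_gene_length=200)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(n_samples=1)


class TestGenome:
    def test_fixed_seed_reproducible(self, small_config):
        g1, genes1, t1 = simulate_genome(small_config)
        g2, genes2, t2 = simulate_genome(small_config)
        assert g1.contigs == g2.contigs
        assert genes1.df.equals(genes2.df)
        assert t1.site_frac == t2.site_frac

    def test_planted_density_matches_scan(self, small_corpus):
        g, truth, cfg = small_corpus["genome"], small_corpus["truth"], small_corpus["config"]
        spec = MotifSpec(cfg.motif, cfg.meth_offset)
        assert motif_density(g, spec) == pytest.approx(truth.expected_density)
        assert len(scan_motif(g, spec)) == 2 * len(truth.motif_loci)

    def test_genes_within_bounds_and_nonoverlapping_per_strand(self, small_corpus):
        genes, g = small_corpus["genes"], small_corpus["genome"]
        lengths = dict((cid, len(s)) for cid, s in g.contigs)
        for (cid, strand), grp in genes.df.groupby(["contig_id", "strand"]):
            assert (grp["end"] <= lengths[cid]).all()
            sorted_grp = grp.sort_values("start")
            assert (
                sorted_grp["start"].iloc[1:].to_numpy()
                >= sorted_grp["end"].iloc[:-1].to_numpy()
            ).all()

    def test_truth_fracs_respect_gradient_bounds(self):
        cfg = SynthConfig(seed=5, genome_length=30_000, gradient_h0=0.6,
                          n_samples=2, genes_per_strand=8, mean_gene_length=500)
        _, _, truth = simulate_genome(cfg)
        fr = [f for sf in truth.site_frac.values() for f in sf.values()]
        assert all(f == 0.0 or f >= 1 - 0.6 / 2 for f in fr)


class TestIpd:
    def test_no_noise_limit_recovers_truth_fraction(self):
        # depth -> large: the moment estimate converges to the true fraction
        cfg = SynthConfig(seed=3, genome_length=20_000, n_samples=2,
                          depth_per_strand=10_000, genes_per_strand=8,
                          mean_gene_length=500, motif_rate_per_kb=0.5)
        _, _, truth = simulate_genome(cfg)
        sample = cfg.sample_ids[0]
        table, records = simulate_ipd_observations(truth, cfg, sample)
        for rec in records:
            key = (rec.contig_id, rec.position, rec.strand)
            true_f = truth.site_frac[sample][key]
            assert rec.frac == pytest.approx(true_f, abs=0.02)

    def test_moment_estimator_at_half_fraction(self, rng):
        # f=0.5 with 10,000 molecules: estimator within +/- 0.02
        cfg = SynthConfig(seed=1)
        from metaepi.modcall import ControlKineticModel

        n = 10_000
        meth = rng.random(n) < 0.5
        s2 = np.log(1 + 0.35 ** 2)
        control_draw = rng.lognormal(-s2 / 2, np.sqrt(s2), size=n)
        s2m = np.log(1 + 0.35 ** 2)
        mod_draw = rng.lognormal(np.log(4.0) - s2m / 2, np.sqrt(s2m), size=n)
        x = np.where(meth, mod_draw, control_draw)
        f_hat = estimate_fraction(x, ControlKineticModel(), mu_m=4.0)
        assert f_hat == pytest.approx(0.5, abs=0.02)

    def test_determinism_per_sample(self, small_corpus):
        truth, cfg = small_corpus["truth"], small_corpus["config"]
        t1, r1 = simulate_ipd_observations(truth, cfg, cfg.sample_ids[1])
        t2, r2 = simulate_ipd_observations(truth, cfg, cfg.sample_ids[1])
        assert t1.equals(t2) and r1 == r2


class TestPopulation:
    def test_identical_frequencies_give_zero_truth_fst(self):
        cfg = SynthConfig(seed=2, divergence=0.0, n_samples=4, n_loci=100)
        _, truth = simulate_population(cfg)
        assert truth.true_fst == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_gives_fst_one(self):
        from metaepi.popgen import fst_from_frequencies

        assert fst_from_frequencies([1.0] * 5, [0.0] * 5) == pytest.approx(1.0)

    def test_single_locus_oracle(self):
        from metaepi.popgen import fst_from_frequencies

        # 0.2 vs 0.8 -> 1 - 0.32/0.68
        assert fst_from_frequencies([0.2], [0.8]) == pytest.approx(1 - 0.32 / 0.68)

    def test_counts_consistent_with_truth(self, small_config):
        ac, truth = simulate_population(small_config)
        for s in small_config.sample_ids:
            sub = ac[ac["sample_id"] == s]
            emp = (sub["nC"] / (sub["nA"] + sub["nC"])).mean()
            assert emp == pytest.approx(truth.freqs[s].mean(), abs=0.02)


class TestPhage:
    def test_depletion_factor_scales_density(self, small_config):
        phages, hits, truth = simulate_phage_set(small_config)
        spec = MotifSpec(small_config.motif, small_config.meth_offset)
        for g in phages:
            assert motif_density(g, spec) == pytest.approx(
                truth.phage_densities[g.genome_id]
            )
        normal = [truth.phage_densities[g] for g, c in truth.phage_clades.items() if c == "normal"]
        depleted = [truth.phage_densities[g] for g, c in truth.phage_clades.items() if c == "depleted"]
        # expected ratio holds up to the one-locus rounding granularity
        granularity = 2 * 1000.0 / small_config.phage_length
        assert abs(
            np.mean(depleted) - np.mean(normal) * small_config.depletion_factor
        ) <= granularity

    def test_hits_symmetric_in_pair_sums(self, small_config):
        _, hits, _ = simulate_phage_set(small_config)
        directed = hits.groupby(["query_genome_id", "subject_genome_id"])["bit_score"].sum()
        for (a, b), v in directed.items():
            if a != b:
                assert directed[(b, a)] == pytest.approx(v)


class TestEmit:
    def test_corpus_validates_against_readers(self, tmp_path):
        cfg = SynthConfig(seed=9, genome_length=10_000, n_samples=2,
                          genes_per_strand=5, mean_gene_length=400,
                          n_loci=50, phage_per_clade=3, phage_length=4_000,
                          depth_per_strand=30)
        paths = emit_corpus(cfg, tmp_path / "corpus")
        g = read_fasta(paths["genome"], genome_id="synth")
        assert g.length == 10_000
        genes = read_gene_table(paths["genes"], dialect="gff3")
        assert len(genes) == 10
        for s in cfg.sample_ids:
            records = read_modifications(paths["modifications"][s], dialect="tsv")
            assert records
        from metaepi.io import read_allele_counts, read_hits_table

        assert len(read_allele_counts(paths["allele_counts"])) == 50 * 2
        read_hits_table(paths["hits"])

    def test_emission_byte_identical_across_runs(self, tmp_path):
        cfg = SynthConfig(seed=9, genome_length=8_000, n_samples=2,
                          genes_per_strand=4, mean_gene_length=300,
                          n_loci=20, phage_per_clade=2, phage_length=3_000,
                          depth_per_strand=20)
        p1 = emit_corpus(cfg, tmp_path / "r1")
        p2 = emit_corpus(cfg, tmp_path / "r2")
        from pathlib import Path

        for k in ("genome", "genes", "allele_counts", "hits", "truth"):
            assert Path(p1[k]).read_bytes() == Path(p2[k]).read_bytes()
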