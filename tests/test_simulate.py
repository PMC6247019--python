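"""Properties of the synthetic genome, library, outgrowth and expression generators."""

import numpy as np
import pandas as pd
import pytest

from cofit.fitness import TnSeqFitness, assign_inserts_to_genes, enumerate_ta_sites
from cofit.io import OutgrowthParams
from cofit.simulate import (
    ExpressionSimConfig,
    LibrarySimConfig,
    generate_genome,
    add_conditional_effects,
    simulate_expression,
    simulate_library,
    simulate_outgrowth,
    simulate_tnseq_experiment,
)
from conftest import small_neutral_config


class TestGenerateGenome:
    def test_layout_respects_budgets(self):
        cfg = LibrarySimConfig(n_genes=10, gene_length_mean=900, gene_length_sd=0,
                               intergenic_fraction=0.2)
        genome, genes, truth = generate_genome(cfg, np.random.default_rng(0))
        assert len(genome) >= 10 * 900 / 0.8
        assert len(genes) == 10
        # genes are non-overlapping and inside the genome
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start
        assert genes[-1].end <= len(genome)

    def test_deterministic_fractions_are_exact(self):
        cfg = LibrarySimConfig(n_genes=100, fraction_essential=0.1,
                               fraction_detrimental=0.2, fraction_beneficial=0.05)
        _, _, truth = generate_genome(cfg, np.random.default_rng(0))
        counts = truth.fitness["true_category"].value_counts()
        assert counts["essential"] == 10
        assert counts["detrimental"] == 20
        assert counts["beneficial"] == 5
        assert counts["neutral"] == 65
        neutral = truth.fitness[truth.fitness["true_category"] == "neutral"]
        assert (neutral["true_w"] == 1.0).all()

    def test_same_seed_is_byte_identical(self):
        cfg = LibrarySimConfig(n_genes=30, seed=11)
        g1, a1, t1 = generate_genome(cfg)
        g2, a2, t2 = generate_genome(cfg)
        assert g1.sequence == g2.sequence
        assert a1 == a2
        assert t1.fitness.equals(t2.fitness)

    def test_too_small_genome_rejected(self):
        cfg = LibrarySimConfig(n_genes=10, gene_length_mean=900, gene_length_sd=0,
                               genome_length=5000)
        with pytest.raises(ValueError, match="do not fit"):
            generate_genome(cfg, np.random.default_rng(0))

    def test_gc_content_controls_ta_density(self):
        rng = np.random.default_rng(0)
        lo = generate_genome(LibrarySimConfig(n_genes=50, gc_content=0.3), rng)[0]
        hi = generate_genome(LibrarySimConfig(n_genes=50, gc_content=0.72), rng)[0]
        assert len(enumerate_ta_sites(lo)) / len(lo) > len(enumerate_ta_sites(hi)) / len(hi)


class TestSimulateLibrary:
    def test_full_saturation_hits_every_site(self):
        cfg = small_neutral_config(n_genes=20, saturation=1.0)
        genome, ann, truth = generate_genome(cfg, np.random.default_rng(0))
        lib = simulate_library(genome, ann, truth, cfg, np.random.default_rng(1))
        assert sorted(o.site for o in lib) == enumerate_ta_sites(genome).tolist()

    def test_depth_conservation(self):
        cfg = small_neutral_config(n_genes=20)
        genome, ann, truth = generate_genome(cfg, np.random.default_rng(0))
        lib = simulate_library(genome, ann, truth, cfg, np.random.default_rng(1))
        assert sum(o.count_t0 for o in lib) == cfg.depth

    def test_realized_density_near_expectation(self):
        # binomial oracle: density = saturation * n_TA / genome_length
        cfg = LibrarySimConfig(n_genes=100, fraction_essential=0.0)
        densities = []
        for seed in range(20):
            genome, ann, truth = generate_genome(cfg, np.random.default_rng(seed))
            expected = cfg.saturation * len(enumerate_ta_sites(genome)) / len(genome)
            lib = simulate_library(genome, ann, truth, cfg, np.random.default_rng(seed + 100))
            densities.append((len(lib) / len(genome)) / expected)
        assert all(0.9 <= d <= 1.1 for d in densities)

    def test_essential_genes_receive_no_inserts(self):
        cfg = LibrarySimConfig(n_genes=50, fraction_essential=0.2)
        genome, ann, truth = generate_genome(cfg, np.random.default_rng(3))
        lib = simulate_library(genome, ann, truth, cfg, np.random.default_rng(4))
        essential = [g for g in ann if truth.fitness.loc[g.gene_id, "essential"]]
        hit = assign_inserts_to_genes([o.site for o in lib], essential)
        assert all(genes == () for genes in hit.values())

    def test_zero_ta_sites_rejected(self):
        from cofit.io import Genome, SyntheticTruth

        genome = Genome("g", "GGCC" * 100)
        truth = SyntheticTruth(fitness=pd.DataFrame(
            {"true_w": [], "essential": [], "true_category": []}))
        cfg = small_neutral_config(n_genes=200)
        with pytest.raises(ValueError, match="no TA sites"):
            simulate_library(genome, [], truth, cfg, np.random.default_rng(0))


class TestSimulateOutgrowth:
    def _neutral_setup(self, seed=0):
        cfg = small_neutral_config(n_genes=20)
        genome, ann, truth = generate_genome(cfg, np.random.default_rng(seed))
        lib = simulate_library(genome, ann, truth, cfg, np.random.default_rng(seed + 1))
        return cfg, genome, ann, truth, lib

    def test_neutral_noiseless_preserves_frequencies(self):
        cfg, genome, ann, truth, lib = self._neutral_setup()
        grown = simulate_outgrowth(lib, ann, truth, OutgrowthParams(22), cfg.depth,
                                   noiseless=True)
        assert grown.realized_d == pytest.approx(2.0**22, rel=1e-12)
        for before, after in zip(lib, grown.observations):
            assert after.count_tf == pytest.approx(before.count_t0, rel=1e-9)

    def test_depth_conservation_multinomial(self):
        cfg, genome, ann, truth, lib = self._neutral_setup()
        grown = simulate_outgrowth(lib, ann, truth, OutgrowthParams(22), cfg.depth,
                                   np.random.default_rng(5))
        assert sum(o.count_tf for o in grown.observations) == cfg.depth

    def test_same_seed_identical_counts(self):
        cfg, genome, ann, truth, lib = self._neutral_setup()
        g1 = simulate_outgrowth(lib, ann, truth, OutgrowthParams(22), cfg.depth,
                                np.random.default_rng(9))
        g2 = simulate_outgrowth(lib, ann, truth, OutgrowthParams(22), cfg.depth,
                                np.random.default_rng(9))
        assert g1.observations == g2.observations

    def test_raising_w_raises_expected_final_frequency(self):
        cfg = small_neutral_config(n_genes=20)
        genome, ann, truth = generate_genome(cfg, np.random.default_rng(2))
        lib = simulate_library(genome, ann, truth, cfg, np.random.default_rng(3))
        gene = ann[0].gene_id
        site_in_gene = next(
            o.site for o in lib
            if assign_inserts_to_genes([o.site], [ann[0]])[o.site]
        )
        freqs = {}
        for w in (0.8, 1.0, 1.2):
            fit = truth.fitness.copy()
            fit.loc[gene, "true_w"] = w
            from cofit.io import SyntheticTruth

            grown = simulate_outgrowth(lib, ann, SyntheticTruth(fitness=fit),
                                       OutgrowthParams(20), cfg.depth, noiseless=True)
            freqs[w] = next(o.count_tf for o in grown.observations
                            if o.site == site_in_gene)
        assert freqs[0.8] < freqs[1.0] < freqs[1.2]

    def test_replicates_of_mixed_library_correlate(self):
        # QC intent: with real fitness variation, replicate gene fitness agrees
        cfg = LibrarySimConfig(n_genes=300, depth=200_000, generations=22)
        ss = np.random.SeedSequence(21)
        r1, r2 = (np.random.default_rng(s) for s in ss.spawn(2))
        genome, ann, truth = generate_genome(cfg, r1)
        exp = simulate_tnseq_experiment(genome, ann, truth, cfg,
                                        {"a": "true_w"}, 2, r2)
        tables = [
            TnSeqFitness(list(r.observations), ann, r.outgrowth_params).fit().gene_table
            for r in exp["a"]
        ]
        from cofit.pipeline import replicate_qc

        assert replicate_qc(tables).iloc[0, 1] > 0.9


class TestSimulateExpression:
    def test_determinism_and_shapes(self):
        cfg = ExpressionSimConfig(n_genes=100, seed=5)
        ec1, t1 = simulate_expression(cfg)
        ec2, t2 = simulate_expression(cfg)
        assert ec1.counts.equals(ec2.counts)
        assert t1.expression.equals(t2.expression)
        assert ec1.counts.shape == (100, 3 * 3)  # control + 2 conditions, 3 reps

    def test_rho_share_one_duplicates_response(self):
        cfg = ExpressionSimConfig(n_genes=500, rho_share=1.0, seed=1)
        _, truth = simulate_expression(cfg)
        assert np.allclose(truth.expression["stress_a"], truth.expression["stress_b"])

    def test_null_config_has_no_true_effects(self):
        cfg = ExpressionSimConfig(n_genes=200, responsive_fraction=0.0, seed=2)
        _, truth = simulate_expression(cfg)
        assert (truth.expression == 0).all().all()

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            ExpressionSimConfig(dispersion=0.0)


class TestConditionalEffects:
    def test_effects_only_touch_neutral_genes(self):
        cfg = LibrarySimConfig(n_genes=100)
        _, _, truth = generate_genome(cfg, np.random.default_rng(0))
        truth2 = add_conditional_effects(truth, 0.1, 0.02, (0.1, 0.3),
                                         np.random.default_rng(1))
        fit = truth2.fitness
        changed = fit[fit["true_w_stress"] != fit["true_w"]]
        assert (changed["true_category"] == "neutral").all()
        assert len(changed[changed["true_w_stress"] < changed["true_w"]]) == 10
        assert len(changed[changed["true_w_stress"] > changed["true_w"]]) == 2
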