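import numpy as np
import pandas as pd
import pytest

from cofit.io import GeneAnnotation, Genome, InsertObservation, SyntheticTruth
from cofit.simulate import LibrarySimConfig, generate_genome, simulate_tnseq_experiment
from cofit.fitness import TnSeqFitness


@pytest.fixture
def toy_genome():
    return Genome("chr", "GGTACCTTAAGCTATAGCGC")


@pytest.fixture
def toy_annotation():
    return [
        GeneAnnotation("geneA", 2, 9, "+", seqid="chr"),
        GeneAnnotation("geneB", 12, 19, "-", seqid="chr"),
    ]


@pytest.fixture
def toy_inserts():
    return [
        InsertObservation(3, 100, 80, "lib1"),
        InsertObservation(8, 50, 120, "lib1"),
        InsertObservation(14, 10, 0, "lib1"),
    ]


def small_neutral_config(**overrides):
    """All-neutral small library used by the calibration tests."""
    defaults = dict(
        n_genes=200,
        depth=100_000,
        generations=22,
        fraction_essential=0.0,
        fraction_detrimental=0.0,
        fraction_beneficial=0.0,
    )
    defaults.update(overrides)
    return LibrarySimConfig(**defaults)


def fit_arm(experiment, arm, annotation, genome_length=None):
    """Pool an arm's replicate outgrowths and fit the gene-level model."""
    observations = [o for res in experiment[arm] for o in res.observations]
    params = experiment[arm][0].outgrowth_params
    return TnSeqFitness(observations, annotation, params,
                        genome_length=genome_length).fit()


@pytest.fixture(scope="session")
def default_experiment():
    """One seeded default-scale experiment shared by several tests."""
    cfg = LibrarySimConfig()
    ss = np.random.SeedSequence(7)
    r1, r2 = (np.random.default_rng(s) for s in ss.spawn(2))
    genome, annotation, truth = generate_genome(cfg, r1)
    experiment = simulate_tnseq_experiment(
        genome, annotation, truth, cfg, {"control": "true_w"}, 2, r2
    )
    return cfg, genome, annotation, truth, experiment
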