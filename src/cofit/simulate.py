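"""Synthetic-data generators with known ground truth.

These generators emulate the statistical structure of a saturated mariner
(Himar1) transposon-insertion experiment and of triplicate stressor-response
RNA-seq count matrices, at desk scale:

* a random genome whose GC content controls TA-site density, tiled with
  non-overlapping genes;
* an insertion library hitting a configurable fraction of TA sites
  (default 0.87, the saturation a dense mariner library achieves), with
  symmetric-Dirichlet abundance weights and multinomial sequencing counts;
* a selective outgrowth of 20-25 generations in which the lineage carrying
  insert *i* grows by ``2**(W_i * G)`` (discrete geometric growth; a neutral
  insert doubles every generation), after which the final time point is
  sequenced multinomially — or returned as exact expected frequencies in
  noiseless mode;
* negative-binomial expression matrices for a control plus stressor
  conditions whose true log2 responses share a tunable common component
  (``rho_share``), so the expected cross-condition response correlation is
  known by construction.

Every generator is deterministic given its seed; all randomness flows from a
single top-level seed through numpy ``SeedSequence`` spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fitness import assign_inserts_to_genes, enumerate_ta_sites
from .io import (
    GeneAnnotation,
    Genome,
    InsertObservation,
    OutgrowthParams,
    SyntheticTruth,
)

__all__ = [
    "LibrarySimConfig",
    "ExpressionSimConfig",
    "generate_genome",
    "add_conditional_effects",
    "simulate_library",
    "simulate_outgrowth",
    "OutgrowthSimResult",
    "simulate_tnseq_experiment",
    "simulate_expression",
    "single_effect_library",
]


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


@dataclass
class LibrarySimConfig:
    """Configuration of the genome + insertion-library generator.

    Defaults are chosen to mirror the library structure of a dense mariner
    Tn-seq experiment in a high-GC soil bacterium: 87% TA-site saturation,
    roughly one insert per 56-60 bp of genome, and 8-10 inserts per average
    gene, with read depth scaled down to 5e5 reads per library so a desk-scale
    run keeps per-insert counts in the tens.
    """

    n_genes: int = 1000
    gene_length_mean: float = 550.0
    gene_length_sd: float = 150.0
    min_gene_length: int = 150
    intergenic_fraction: float = 0.15
    gc_content: float = 0.72
    genome_length: Optional[int] = None  # None: computed from the gene budget
    saturation: float = 0.87
    depth: int = 500_000
    generations: Optional[float] = None  # None: sampled uniformly on [20, 25]
    dirichlet_concentration: float = 1.0
    tf_overdispersion: Optional[float] = None  # extra-multinomial noise at t_final
    fraction_essential: float = 0.08
    fraction_detrimental: float = 0.10
    fraction_beneficial: float = 0.02
    detrimental_w_range: tuple = (0.6, 0.9)
    beneficial_w_range: tuple = (1.1, 1.3)
    deterministic_fractions: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.saturation <= 1:
            raise ValueError("saturation must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.intergenic_fraction < 1:
            raise ValueError("intergenic_fraction must lie in [0, 1)")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        total = self.fraction_essential + self.fraction_detrimental + self.fraction_beneficial
        if total > 1:
            raise ValueError("effect-category fractions sum to more than 1")


@dataclass
class ExpressionSimConfig:
    """Configuration of the stressor-response RNA-seq generator.

    Baseline means are log-normal; counts are negative binomial with a common
    dispersion (default 0.05, typical of well-replicated bulk RNA-seq in
    bacteria).  For each stressor condition the true log2 fold-change vector
    is ``sqrt(rho_share)*shared + sqrt(1-rho_share)*private`` over a common
    responsive gene set, so two conditions have expected response correlation
    ``rho_share`` by construction.
    """

    n_genes: int = 2000
    mean_log_mu: float = 5.0
    sd_log_mu: float = 1.0
    dispersion: float = 0.05
    n_replicates: int = 3
    control: str = "control"
    conditions: tuple = ("stress_a", "stress_b")
    rho_share: float = 0.6
    responsive_fraction: float = 0.25
    effect_sd: float = 1.5
    size_factor_sd: float = 0.15
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0 <= self.rho_share <= 1:
            raise ValueError("rho_share must lie in [0, 1]")


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    return rng.choice(alphabet, size=length, p=probs).tobytes().decode("ascii")


def generate_genome(
    config: LibrarySimConfig, rng=None
) -> tuple[Genome, list[GeneAnnotation], SyntheticTruth]:
    """Random genome, non-overlapping gene annotation, and fitness truth.

    Genes are laid out sequentially with intergenic spacers filling the
    configured intergenic fraction.  Each gene draws a true fitness effect
    from the configured mixture: neutral genes carry ``true_w = 1`` exactly,
    detrimental/beneficial genes draw uniformly from their W ranges, and
    essential genes (which will receive no inserts) are flagged.
    """
    rng = _rng(rng if rng is not None else config.seed)
    lengths = np.maximum(
        np.round(rng.normal(config.gene_length_mean, config.gene_length_sd, config.n_genes)),
        config.min_gene_length,
    ).astype(int)
    total_genic = int(lengths.sum())
    needed = math.ceil(total_genic / (1.0 - config.intergenic_fraction))
    genome_length = config.genome_length if config.genome_length else needed
    if genome_length < needed:
        raise ValueError(
            f"{config.n_genes} genes ({total_genic} bp genic) do not fit in a "
            f"{genome_length} bp genome at intergenic fraction "
            f"{config.intergenic_fraction}"
        )
    spacer_total = genome_length - total_genic
    n_gaps = config.n_genes + 1
    base, extra = divmod(spacer_total, n_gaps)
    spacers = np.full(n_gaps, base, dtype=int)
    spacers[:extra] += 1

    width = len(str(config.n_genes))
    genes = []
    pos = 1
    for i, length in enumerate(lengths):
        pos += spacers[i]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(f"g{i + 1:0{width}d}", pos, pos + length - 1, strand)
        )
        pos += length

    n = config.n_genes
    if config.deterministic_fractions:
        n_ess = round(config.fraction_essential * n)
        n_det = round(config.fraction_detrimental * n)
        n_ben = round(config.fraction_beneficial * n)
    else:
        draws = rng.random(n)
        cuts = np.cumsum(
            [config.fraction_essential, config.fraction_detrimental, config.fraction_beneficial]
        )
        n_ess = int((draws < cuts[0]).sum())
        n_det = int(((draws >= cuts[0]) & (draws < cuts[1])).sum())
        n_ben = int(((draws >= cuts[1]) & (draws < cuts[2])).sum())
    order = rng.permutation(n)
    category = np.full(n, "neutral", dtype=object)
    category[order[:n_ess]] = "essential"
    category[order[n_ess : n_ess + n_det]] = "detrimental"
    category[order[n_ess + n_det : n_ess + n_det + n_ben]] = "beneficial"

    true_w = np.ones(n)
    det_mask = category == "detrimental"
    ben_mask = category == "beneficial"
    true_w[det_mask] = rng.uniform(*config.detrimental_w_range, det_mask.sum())
    true_w[ben_mask] = rng.uniform(*config.beneficial_w_range, ben_mask.sum())
    true_w[category == "essential"] = 0.0

    truth = SyntheticTruth(
        fitness=pd.DataFrame(
            {
                "true_w": true_w,
                "essential": category == "essential",
                "true_category": category,
            },
            index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        )
    )
    genome = Genome("genome", _random_sequence(genome_length, config.gc_content, rng))
    return genome, genes, truth


def add_conditional_effects(
    truth: SyntheticTruth,
    fraction_detrimental: float,
    fraction_beneficial: float,
    effect_range: tuple = (0.1, 0.3),
    rng=None,
    column: str = "true_w_stress",
) -> SyntheticTruth:
    """Overlay condition-specific fitness effects on baseline-neutral genes.

    A fraction of the genes that are neutral at baseline become detrimental
    (W reduced by a uniform draw from ``effect_range``) or beneficial
    (W raised likewise) under the stress condition; the result is stored in
    an extra truth column so the two arms can be simulated from the same
    genome.
    """
    rng = _rng(rng)
    fit = truth.fitness.copy()
    stress_w = fit["true_w"].to_numpy(dtype=float).copy()
    neutral_idx = np.flatnonzero((fit["true_category"] == "neutral").to_numpy())
    n_det = round(fraction_detrimental * len(fit))
    n_ben = round(fraction_beneficial * len(fit))
    chosen = rng.choice(neutral_idx, size=n_det + n_ben, replace=False)
    stress_w[chosen[:n_det]] -= rng.uniform(*effect_range, n_det)
    stress_w[chosen[n_det:]] += rng.uniform(*effect_range, n_ben)
    fit[column] = stress_w
    return SyntheticTruth(fitness=fit, expression=truth.expression)


def _essential_site_mask(sites, annotation, truth) -> np.ndarray:
    essential = set(truth.fitness.index[truth.fitness["essential"]])
    if not essential:
        return np.zeros(len(sites), dtype=bool)
    ess_genes = [g for g in annotation if g.gene_id in essential]
    assignment = assign_inserts_to_genes(sites, ess_genes)
    return np.array([bool(assignment[int(s)]) for s in sites])


def _draw_library_sites_weights(genome, annotation, truth, config, rng):
    sites = enumerate_ta_sites(genome)
    if len(sites) == 0:
        raise ValueError("genome contains no TA sites")
    available = sites[~_essential_site_mask(sites, annotation, truth)]
    n_target = min(round(config.saturation * len(sites)), len(available))
    chosen = np.sort(rng.choice(available, size=n_target, replace=False))
    weights = rng.dirichlet(np.full(n_target, config.dirichlet_concentration))
    return chosen, weights


def simulate_library(
    genome: Genome,
    annotation: Sequence[GeneAnnotation],
    truth: SyntheticTruth,
    config: LibrarySimConfig,
    rng=None,
    library_id: str = "lib1",
) -> list[InsertObservation]:
    """Simulate a t0 insertion library (no outgrowth yet).

    A fraction ``saturation`` of all TA sites receives an insert, never inside
    an essential gene; t0 read counts are one multinomial draw of ``depth``
    reads over symmetric-Dirichlet abundance weights.
    """
    rng = _rng(rng if rng is not None else config.seed)
    chosen, weights = _draw_library_sites_weights(genome, annotation, truth, config, rng)
    counts = rng.multinomial(config.depth, weights)
    return [
        InsertObservation(int(site), int(c), None, library_id)
        for site, c in zip(chosen, counts)
    ]


@dataclass
class OutgrowthSimResult:
    """Outgrowth simulation output: observations plus the realized expansion."""

    observations: list
    realized_d: float
    generations: float

    @property
    def outgrowth_params(self) -> OutgrowthParams:
        return OutgrowthParams(self.generations, self.realized_d)


def _true_w_by_site(inserts, annotation, truth, w_column) -> np.ndarray:
    assignment = assign_inserts_to_genes([o.site for o in inserts], annotation)
    w_lookup = truth.fitness[w_column].to_dict()
    out = np.empty(len(inserts))
    for i, obs in enumerate(inserts):
        genes = assignment[obs.site]
        # intergenic inserts are fitness neutral; overlapping genes average
        out[i] = np.mean([w_lookup[g] for g in genes]) if genes else 1.0
    return out


def simulate_outgrowth(
    inserts: Sequence[InsertObservation],
    annotation: Sequence[GeneAnnotation],
    truth: SyntheticTruth,
    params: OutgrowthParams,
    depth: int,
    rng=None,
    noiseless: bool = False,
    overdispersion: Optional[float] = None,
    w_column: str = "true_w",
) -> OutgrowthSimResult:
    """Grow a library for ``params.generations`` and sequence the end point.

    The lineage of insert *i* expands by ``2**(W_i * G)`` from its t0
    frequency (the t0 counts are treated as a census of the population that
    enters the outgrowth); the realized whole-population expansion factor
    ``d`` is reported alongside.  Final counts are one multinomial draw of
    ``depth`` reads over the final frequencies; in noiseless mode the exact
    expected frequencies (times depth) are returned instead.  Optional
    Dirichlet overdispersion adds extra-multinomial noise at t_final.
    """
    rng = _rng(rng)
    g = params.generations
    true_w = _true_w_by_site(inserts, annotation, truth, w_column)
    t0 = np.array([o.count_t0 for o in inserts], dtype=float)
    live = t0 > 0
    x0 = np.where(live, t0, 0.0)
    x0 = x0 / x0.sum()
    growth = x0 * np.exp2(true_w * g)
    realized_d = float(growth.sum())
    freqs = growth / growth.sum()
    if overdispersion is not None:
        jitter_idx = freqs > 0
        alpha = np.maximum(freqs[jitter_idx] * overdispersion, 1e-12)
        jittered = rng.dirichlet(alpha)
        freqs = freqs.copy()
        freqs[jitter_idx] = jittered
    if noiseless:
        tf = freqs * depth
    else:
        tf = rng.multinomial(depth, freqs).astype(float)
    observations = [
        InsertObservation(o.site, o.count_t0, float(c) if noiseless else int(c), o.library_id)
        for o, c in zip(inserts, tf)
    ]
    return OutgrowthSimResult(observations, realized_d, g)


def simulate_tnseq_experiment(
    genome: Genome,
    annotation: Sequence[GeneAnnotation],
    truth: SyntheticTruth,
    config: LibrarySimConfig,
    arms: Mapping[str, str],
    n_replicates: int = 2,
    rng=None,
) -> dict[str, list[OutgrowthSimResult]]:
    """Simulate a multi-arm outgrowth experiment from one master library.

    ``arms`` maps arm name to the truth column holding that arm's true W
    (for example ``{"control": "true_w", "stress": "true_w_stress"}``).  All
    arms and replicates share the master library's insert sites and abundance
    weights — as when one transposon library is split across outgrowth
    flasks — but every (arm, replicate) pair gets its own t0 sequencing draw
    and its own outgrowth end-point draw.  Generations are sampled once per
    experiment on [20, 25] unless fixed in the config.
    """
    rng = _rng(rng if rng is not None else config.seed)
    chosen, weights = _draw_library_sites_weights(genome, annotation, truth, config, rng)
    generations = (
        config.generations
        if config.generations is not None
        else float(rng.uniform(20.0, 25.0))
    )
    params = OutgrowthParams(generations)
    results: dict[str, list[OutgrowthSimResult]] = {}
    for arm, w_column in arms.items():
        results[arm] = []
        for rep in range(1, n_replicates + 1):
            t0 = rng.multinomial(config.depth, weights)
            lib = [
                InsertObservation(int(s), int(c), None, f"{arm}_rep{rep}")
                for s, c in zip(chosen, t0)
            ]
            results[arm].append(
                simulate_outgrowth(
                    lib, annotation, truth, params, config.depth, rng,
                    overdispersion=config.tf_overdispersion, w_column=w_column,
                )
            )
    return results


def simulate_expression(
    config: ExpressionSimConfig, rng=None
) -> tuple["ExpressionCounts", SyntheticTruth]:
    """Simulate stressor-response count matrices with known true responses."""
    from .io import ExpressionCounts

    rng = _rng(rng if rng is not None else config.seed)
    n = config.n_genes
    width = len(str(n))
    genes = pd.Index([f"g{i + 1:0{width}d}" for i in range(n)], name="gene_id")
    baseline = rng.lognormal(config.mean_log_mu, config.sd_log_mu, n)

    n_resp = round(config.responsive_fraction * n)
    responsive = np.zeros(n, dtype=bool)
    responsive[rng.choice(n, size=n_resp, replace=False)] = True
    shared = np.where(responsive, rng.normal(0.0, config.effect_sd, n), 0.0)
    lfc = {}
    for cond in config.conditions:
        private = np.where(responsive, rng.normal(0.0, config.effect_sd, n), 0.0)
        lfc[cond] = (
            math.sqrt(config.rho_share) * shared
            + math.sqrt(1.0 - config.rho_share) * private
        )
    truth = SyntheticTruth(expression=pd.DataFrame(lfc, index=genes))

    dispersion = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (n,))
    columns, data, meta = [], [], []
    for cond in (config.control, *config.conditions):
        cond_lfc = lfc.get(cond, np.zeros(n))
        for rep in range(1, config.n_replicates + 1):
            sf = rng.lognormal(0.0, config.size_factor_sd)
            mu = sf * baseline * np.exp2(cond_lfc)
            size = 1.0 / dispersion
            counts = rng.negative_binomial(size, size / (size + mu))
            columns.append(f"{cond}_{rep}")
            data.append(counts)
            meta.append({"sample": f"{cond}_{rep}", "condition": cond, "replicate": rep})
    counts_df = pd.DataFrame(
        np.column_stack(data), index=genes, columns=columns
    )
    metadata = pd.DataFrame(meta).set_index("sample")
    return ExpressionCounts(counts_df, metadata), truth


def single_effect_library(
    w: float,
    n_background: int = 200,
    t0_count: int = 50,
) -> tuple[Genome, list[GeneAnnotation], SyntheticTruth, list[InsertObservation]]:
    """Deterministic calibration scenario: one non-neutral insert.

    Builds a genome of ``n_background + 1`` regularly spaced TA sites, a
    single one-TA-site focal gene carrying true fitness ``w``, and a flat t0
    library; every other insert is intergenic and therefore neutral.  With a
    noiseless outgrowth the serial-passage estimator recovers ``w`` exactly,
    which makes this the reference scenario for validating the estimator.
    """
    unit = "TAGGCCGG"  # one TA per 8 bp unit
    genome = Genome("calib", unit * (n_background + 1))
    focal = GeneAnnotation("focal", 1, len(unit))
    truth = SyntheticTruth(
        fitness=pd.DataFrame(
            {"true_w": [w], "essential": [False], "true_category": ["effect"]},
            index=pd.Index(["focal"], name="gene_id"),
        )
    )
    inserts = [
        InsertObservation(1 + i * len(unit), t0_count, None, "calib")
        for i in range(n_background + 1)
    ]
    return genome, [focal], truth, inserts
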