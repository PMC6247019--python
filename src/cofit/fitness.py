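"""Tn-seq fitness estimation.

The core computation of the package: enumerate the TA dinucleotides where a
Himar1/mariner transposon can insert, assign observed inserts to genes,
estimate a per-insert serial-passage fitness ``W`` from the change in relative
read frequency over a selective outgrowth, aggregate inserts to genes, and
classify each gene.

Per-insert fitness uses the expansion-corrected serial-passage estimator

    W = ln(N_f * d / N_0) / ln((1 - N_f) * d / (1 - N_0))

where ``N_0``/``N_f`` are the insert's relative read frequencies before and
after the outgrowth and ``d`` is the fold-expansion of the whole population.
``W = 1`` is neutral (the insert grew exactly as fast as the rest of the
population), ``W < 1`` is a fitness defect and ``W > 1`` a benefit.  Under
discrete geometric growth at ``2**W`` per generation, with an otherwise
neutral population, the estimator recovers the true ``W`` exactly.

Inserts that are present at t0 but unobserved at t_final are not dropped
(that would bias detrimental genes toward neutral); they are scored at the
pseudofrequency ``N_f = 0.5 / total_tf`` and flagged ``floored``.
"""

from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import (
    GeneAnnotation,
    GeneFitnessSummary,
    Genome,
    InsertObservation,
    OutgrowthParams,
    read_annotation,
    read_insertion_table,
)

__all__ = [
    "enumerate_ta_sites",
    "assign_inserts_to_genes",
    "insert_fitness",
    "gene_fitness",
    "classify_gene",
    "IneligibleInsertError",
    "InsertFitness",
    "TnSeqFitness",
    "TnSeqFitnessResults",
]

logger = logging.getLogger("cofit")

_TA_RE = re.compile(r"(?=TA)")


class IneligibleInsertError(ValueError):
    """Raised for inserts with ``count_t0 == 0`` (no denominator frequency)."""


class InsertFitness(NamedTuple):
    w: float
    floored: bool


def enumerate_ta_sites(genome: Genome) -> np.ndarray:
    """All TA dinucleotide positions (1-based position of the T).

    Overlapping occurrences are reported individually (``TATA`` -> [1, 3]).
    Windows containing ``N`` are never TA and are therefore skipped.
    """
    return np.array(
        [m.start() + 1 for m in _TA_RE.finditer(genome.sequence)], dtype=np.int64
    )


def assign_inserts_to_genes(
    sites: Iterable[int],
    annotation: Sequence[GeneAnnotation],
    edge_trim: float = 0.0,
) -> dict[int, tuple[str, ...]]:
    """Map each insert site to the genes whose (trimmed) body contains it.

    A site belongs to gene ``g`` iff its T position lies within
    ``[start + trim, end - trim]`` where ``trim = floor(edge_trim * length)``.
    Assignment is strand-independent.  A site outside every gene maps to the
    empty tuple (intergenic); a site inside overlapping genes maps to all of
    them, with a logged warning.
    """
    if not 0 <= edge_trim < 0.5:
        raise ValueError(f"edge_trim must be in [0, 0.5), got {edge_trim}")
    tree = IntervalTree()
    for g in annotation:
        trim = math.floor(edge_trim * g.length)
        lo, hi = g.start + trim, g.end - trim
        if lo <= hi:
            tree[lo : hi + 1] = g.gene_id
    result: dict[int, tuple[str, ...]] = {}
    n_multi = 0
    for site in sites:
        hits = tuple(sorted(iv.data for iv in tree[site]))
        if len(hits) > 1:
            n_multi += 1
        result[int(site)] = hits
    if n_multi:
        logger.warning(
            "%d insert site(s) fall in overlapping genes; assigned to all", n_multi
        )
    return result


def _fitness_from_frequencies(n0, nf, d):
    return np.log(nf * d / n0) / np.log((1.0 - nf) * d / (1.0 - n0))


def insert_fitness(
    obs: InsertObservation,
    totals_t0: float,
    totals_tf: float,
    params: OutgrowthParams,
) -> InsertFitness:
    """Serial-passage fitness of one insert.

    ``totals_t0``/``totals_tf`` are the library-wide read totals from which
    relative frequencies are derived.  Fitness is scale invariant: multiplying
    all counts in a library by a constant leaves ``W`` unchanged.
    """
    if not obs.eligible:
        raise IneligibleInsertError(
            f"site {obs.site}: count_t0 == 0, ineligible for fitness estimation"
        )
    if obs.count_tf is None:
        raise ValueError(f"site {obs.site}: no final-timepoint count")
    n0 = obs.count_t0 / totals_t0
    if n0 >= 1.0:
        raise ValueError(
            f"site {obs.site}: N0 == 1 (single-insert library), fitness undefined"
        )
    floored = False
    if obs.count_tf == 0:
        nf = 0.5 / totals_tf
        floored = True
    else:
        nf = obs.count_tf / totals_tf
        if nf >= 1.0:  # symmetric guard for an insert that swept the library
            nf = 1.0 - 0.5 / totals_tf
            floored = True
    w = _fitness_from_frequencies(n0, nf, params.d)
    return InsertFitness(float(w), floored)


def gene_fitness(
    gene_id: str,
    insert_ws: Sequence[float],
    n_floored: int = 0,
) -> GeneFitnessSummary:
    """Aggregate per-insert fitness values (pooled over replicate libraries).

    ``mean_w`` is the unweighted arithmetic mean, ``sd_w`` the sample standard
    deviation (0 when n = 1).  With zero eligible inserts the summary carries
    NaN statistics and is routed to :func:`classify_gene` on insert count
    alone (the apparent-lethality rule).
    """
    values = [float(w) for w in insert_ws]
    if not values:
        return GeneFitnessSummary(gene_id, [], math.nan, math.nan, 0, n_floored)
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GeneFitnessSummary(
        gene_id, values, float(arr.mean()), sd, len(values), n_floored
    )


def classify_gene(mean_w: float, n_inserts: int, gene_length: int) -> str:
    """Five-way category call for one gene.

    Genes with fewer than four observed insertions are apparently lethal when
    longer than 400 bp, otherwise there is insufficient information.  With at
    least four insertions the mean fitness is thresholded: detrimental below
    0.95, beneficial above 1.05, neutral in between (boundaries inclusive, as
    the outer classes are defined by strict inequalities).
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if n_inserts < 0:
        raise ValueError("n_inserts must be non-negative")
    if n_inserts < 4:
        return "lethal" if gene_length > 400 else "insufficient"
    if mean_w is None or math.isnan(mean_w):
        raise ValueError("mean_w required for genes with >= 4 inserts")
    if mean_w < 0.95:
        return "detrimental"
    if mean_w > 1.05:
        return "beneficial"
    return "neutral"


class TnSeqFitness:
    """Gene-level fitness model for one Tn-seq outgrowth experiment.

    Parameters
    ----------
    inserts
        Insert observations with t0 and t_final counts.  Observations from
        several replicate libraries (distinguished by ``library_id``) are
        estimated per library and pooled per gene.
    annotation
        Gene annotation; inserts outside every gene are treated as intergenic.
    params
        Outgrowth parameters (generations, expansion factor d).
    edge_trim
        Fraction of each gene trimmed from both ends before assignment
        (default 0: the literal gene body).

    Examples
    --------
    >>> model = TnSeqFitness(observations, annotation, OutgrowthParams(22))
    >>> results = model.fit()
    >>> results.gene_table.head()
    """

    def __init__(
        self,
        inserts: Sequence[InsertObservation],
        annotation: Sequence[GeneAnnotation],
        params: OutgrowthParams,
        edge_trim: float = 0.0,
        genome_length: Optional[int] = None,
    ) -> None:
        self.inserts = list(inserts)
        self.annotation = list(annotation)
        self.params = params
        self.edge_trim = edge_trim
        self.genome_length = genome_length

    @classmethod
    def from_files(
        cls,
        annotation_path,
        inserts_path,
        generations: float,
        expansion_factor: Optional[float] = None,
        edge_trim: float = 0.0,
    ) -> "TnSeqFitness":
        return cls(
            read_insertion_table(inserts_path),
            read_annotation(annotation_path),
            OutgrowthParams(generations, expansion_factor),
            edge_trim=edge_trim,
        )

    def fit(self) -> "TnSeqFitnessResults":
        """Estimate per-insert fitness and aggregate to genes."""
        by_library: dict[str, list[InsertObservation]] = defaultdict(list)
        for obs in self.inserts:
            by_library[obs.library_id].append(obs)

        assignment = assign_inserts_to_genes(
            sorted({obs.site for obs in self.inserts}), self.annotation, self.edge_trim
        )

        rows = []
        for lib_id, observations in by_library.items():
            t0 = np.array([o.count_t0 for o in observations], dtype=float)
            tf = np.array(
                [math.nan if o.count_tf is None else o.count_tf for o in observations],
                dtype=float,
            )
            total_t0, total_tf = t0.sum(), np.nansum(tf)
            eligible = (t0 > 0) & ~np.isnan(tf)
            if total_tf <= 0:
                eligible &= False
            n0 = t0 / total_t0 if total_t0 > 0 else t0
            floored = eligible & (tf == 0)
            nf = np.where(tf > 0, tf / max(total_tf, 1.0), 0.5 / max(total_tf, 1.0))
            swept = eligible & (nf >= 1.0)
            nf = np.where(swept, 1.0 - 0.5 / max(total_tf, 1.0), nf)
            floored |= swept
            with np.errstate(divide="ignore", invalid="ignore"):
                w = _fitness_from_frequencies(n0, nf, self.params.d)
            for i, obs in enumerate(observations):
                rows.append(
                    {
                        "site": obs.site,
                        "library_id": lib_id,
                        "count_t0": obs.count_t0,
                        "count_tf": obs.count_tf,
                        "eligible": bool(eligible[i]),
                        "w": float(w[i]) if eligible[i] else math.nan,
                        "floored": bool(floored[i]) if eligible[i] else False,
                    }
                )
        insert_table = pd.DataFrame(rows)
        if not insert_table.empty:
            insert_table["genes"] = insert_table["site"].map(
                lambda s: ",".join(assignment[s]) if assignment[s] else "intergenic"
            )

        gene_values: dict[str, list[float]] = {g.gene_id: [] for g in self.annotation}
        gene_sites: dict[str, set] = {g.gene_id: set() for g in self.annotation}
        gene_floored: dict[str, int] = {g.gene_id: 0 for g in self.annotation}
        if not insert_table.empty:
            eligible_rows = insert_table[insert_table["eligible"]]
            for row in eligible_rows.itertuples(index=False):
                for gid in assignment[row.site]:
                    gene_values[gid].append(row.w)
                    gene_sites[gid].add(row.site)
                    gene_floored[gid] += int(row.floored)
            observed = insert_table.groupby("site")["eligible"].any()
            for site, ok in observed.items():
                if ok:
                    for gid in assignment[site]:
                        gene_sites[gid].add(site)

        summaries = []
        for g in self.annotation:
            summary = gene_fitness(g.gene_id, gene_values[g.gene_id], gene_floored[g.gene_id])
            n_sites = len(gene_sites[g.gene_id])
            summary.category = classify_gene(
                summary.mean_w if n_sites >= 4 else math.nan, n_sites, g.length
            )
            summaries.append(
                {
                    "gene_id": g.gene_id,
                    "mean_w": summary.mean_w,
                    "sd_w": summary.sd_w,
                    "n_inserts": n_sites,
                    "n_values": summary.n_inserts,
                    "n_floored": summary.n_floored,
                    "category": summary.category,
                    "gene_length": g.length,
                }
            )
        gene_table = pd.DataFrame(summaries).set_index("gene_id")
        return TnSeqFitnessResults(self, gene_table, insert_table, gene_values)


class TnSeqFitnessResults:
    """Results of :meth:`TnSeqFitness.fit`.

    Attributes
    ----------
    gene_table
        One row per annotated gene: mean_w, sd_w, n_inserts (distinct eligible
        sites), n_values (pooled per-library fitness values), n_floored,
        category, gene_length.
    insert_table
        One row per insert per library with the per-insert ``w``.
    gene_values
        Mapping gene_id -> list of pooled per-insert fitness values (the
        samples used by downstream t-tests).
    """

    def __init__(self, model, gene_table, insert_table, gene_values) -> None:
        self.model = model
        self.gene_table = gene_table
        self.insert_table = insert_table
        self.gene_values = {k: np.asarray(v, dtype=float) for k, v in gene_values.items()}

    def library_stats(self) -> dict:
        """Library summary statistics (unique sites, density, inserts/gene)."""
        if self.insert_table.empty:
            return {"n_unique_sites": 0}
        observed = self.insert_table[self.insert_table["eligible"]]
        n_sites = observed["site"].nunique()
        stats = {
            "n_unique_sites": int(n_sites),
            "mean_inserts_per_gene": float(self.gene_table["n_inserts"].mean()),
            "n_libraries": int(self.insert_table["library_id"].nunique()),
        }
        if self.model.genome_length:
            stats["bp_per_insert"] = self.model.genome_length / max(n_sites, 1)
        return stats

    def summary(self) -> str:
        counts = self.gene_table["category"].value_counts()
        lines = [
            "Tn-seq gene fitness results",
            "=" * 40,
            f"genes:              {len(self.gene_table)}",
            f"generations:        {self.model.params.generations:g}",
            f"expansion factor d: {self.model.params.d:.4g}",
        ]
        stats = self.library_stats()
        if "mean_inserts_per_gene" in stats:
            lines.append(f"unique insertion sites: {stats['n_unique_sites']}")
            lines.append(f"mean inserts per gene:  {stats['mean_inserts_per_gene']:.2f}")
        if "bp_per_insert" in stats:
            lines.append(f"insertion density:      1 per {stats['bp_per_insert']:.1f} bp")
        lines.append("-" * 40)
        for cat in ("detrimental", "beneficial", "neutral", "lethal", "insufficient"):
            lines.append(f"{cat:>14}: {int(counts.get(cat, 0))}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.gene_table.reset_index()[
            ["gene_id", "mean_w", "sd_w", "n_inserts", "category", "n_floored"]
        ]
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
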