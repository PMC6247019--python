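"""End-to-end orchestration: simulate -> estimate -> compare -> report.

``run_pipeline`` drives the whole comparative fitness-profiling analysis from
one structured YAML/dict configuration and a seed, writing every inter-stage
contract as a TSV so stages can equally consume user-supplied (real) tables.
Outputs are deterministic given (config, seed): two runs produce byte-
identical files.  A run manifest records the seed, a hash of the effective
configuration and every threshold actually applied, so a report is
self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from importlib import metadata as _metadata
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import conditional as cond_mod
from . import expression as expr_mod
from .conditional import ConditionalFitness
from .expression import DifferentialExpression, concordance, response_overlap
from .fitness import TnSeqFitness
from .io import (
    OutgrowthParams,
    SyntheticTruth,
    write_annotation,
    write_expression_counts,
    write_genome,
    write_insertion_table,
    write_truth,
)
from .simulate import (
    ExpressionSimConfig,
    LibrarySimConfig,
    add_conditional_effects,
    generate_genome,
    simulate_expression,
    simulate_tnseq_experiment,
)

__all__ = ["ConfigError", "load_config", "run_pipeline", "replicate_qc"]

logger = logging.getLogger("cofit")


class ConfigError(ValueError):
    """A pipeline configuration violates the documented schema."""


_LIBRARY_FIELDS = {f for f in LibrarySimConfig.__dataclass_fields__} - {"seed"}
_EXPRESSION_FIELDS = {f for f in ExpressionSimConfig.__dataclass_fields__} - {"seed"}

_TNSEQ_EXTRA = {
    "n_replicates": int,
    "edge_trim": float,
    "conditional": dict,
}
_CONDITIONAL_FIELDS = {
    "fraction_detrimental": float,
    "fraction_beneficial": float,
    "effect_range": (list, tuple),
}

DEFAULT_CONFIG: dict = {
    "tnseq": {
        "n_genes": 200,
        "depth": 100_000,
        "generations": 22,
        "n_replicates": 2,
        "edge_trim": 0.0,
        "conditional": {
            "fraction_detrimental": 0.05,
            "fraction_beneficial": 0.01,
            "effect_range": [0.1, 0.3],
        },
    },
    "rnaseq": None,
    "thresholds": {
        "delta_w": cond_mod.DELTA_W_THRESHOLD,
        "alpha": cond_mod.ALPHA,
        "fold_change": expr_mod.FOLD_THRESHOLD,
        "fdr": expr_mod.FDR_THRESHOLD,
        "min_cpm": 1.0,
    },
}


def _check_block(block: Mapping, allowed: set, path: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {unknown}")


def load_config(source) -> dict:
    """Load and validate a pipeline configuration.

    ``source`` may be a mapping or a path to a YAML file.  Unknown fields are
    reported with their full field path; omitted fields take documented
    defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    _check_block(raw, {"tnseq", "rnaseq", "thresholds"}, "config")

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    tn = raw.get("tnseq", {})
    if tn is not None:
        _check_block(tn, _LIBRARY_FIELDS | set(_TNSEQ_EXTRA), "tnseq")
        conditional = tn.get("conditional", cfg["tnseq"]["conditional"])
        if conditional is not None:
            _check_block(conditional, set(_CONDITIONAL_FIELDS), "tnseq.conditional")
        cfg["tnseq"].update(tn)
        cfg["tnseq"]["conditional"] = conditional
    rn = raw.get("rnaseq")
    if rn is not None:
        _check_block(rn, _EXPRESSION_FIELDS, "rnaseq")
        cfg["rnaseq"] = dict(rn)
    th = raw.get("thresholds", {})
    if th:
        _check_block(th, set(DEFAULT_CONFIG["thresholds"]), "thresholds")
        cfg["thresholds"].update(th)

    for key in ("n_genes", "depth"):
        if cfg["tnseq"][key] <= 0:
            raise ConfigError(f"tnseq.{key}: must be a positive number")
    return cfg


def _library_config(tn_cfg: Mapping) -> LibrarySimConfig:
    kwargs = {k: v for k, v in tn_cfg.items() if k in _LIBRARY_FIELDS}
    if "detrimental_w_range" in kwargs:
        kwargs["detrimental_w_range"] = tuple(kwargs["detrimental_w_range"])
    if "beneficial_w_range" in kwargs:
        kwargs["beneficial_w_range"] = tuple(kwargs["beneficial_w_range"])
    try:
        return LibrarySimConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"tnseq: {exc}") from exc


def replicate_qc(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene-level mean fitness across replicates.

    Each table must carry ``mean_w`` and ``n_inserts`` columns indexed by
    gene_id; a gene enters a pair's correlation only when it has at least one
    eligible insert in both replicates.
    """
    if len(tables) < 2:
        raise ValueError("replicate QC requires >= 2 replicate tables")
    names = [f"rep{i + 1}" for i in range(len(tables))]
    corr = pd.DataFrame(np.eye(len(tables)), index=names, columns=names)
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            a, b = tables[i], tables[j]
            shared = a.index.intersection(b.index)
            ok = (
                (a.loc[shared, "n_inserts"] >= 1)
                & (b.loc[shared, "n_inserts"] >= 1)
                & a.loc[shared, "mean_w"].notna()
                & b.loc[shared, "mean_w"].notna()
            )
            genes = shared[ok]
            r = np.nan
            if len(genes) >= 2:
                r = float(
                    np.corrcoef(a.loc[genes, "mean_w"], b.loc[genes, "mean_w"])[0, 1]
                )
            corr.iloc[i, j] = corr.iloc[j, i] = r
    return corr


def _config_hash(cfg: Mapping, seed: int) -> str:
    payload = json.dumps({"config": cfg, "seed": seed}, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label="gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def _fit_arm(results_list, annotation, params, edge_trim, genome_length):
    observations = [o for res in results_list for o in res.observations]
    model = TnSeqFitness(observations, annotation, params, edge_trim, genome_length)
    return model.fit()


def _scorecard(truth: SyntheticTruth, fitted, cond_results) -> pd.DataFrame:
    """Recovery scorecard: classification confusion and fitness RMSE."""
    fit = truth.fitness
    called = fitted.gene_table["category"]
    rows = []
    confusion = pd.crosstab(fit["true_category"], called.loc[fit.index])
    for true_cat in confusion.index:
        for called_cat in confusion.columns:
            rows.append(
                {
                    "metric": "confusion",
                    "true_category": true_cat,
                    "called_category": called_cat,
                    "value": int(confusion.loc[true_cat, called_cat]),
                }
            )
    scored = fit.index[(~fit["essential"]) & (fitted.gene_table["n_inserts"] >= 4)]
    if len(scored):
        err = fitted.gene_table.loc[scored, "mean_w"] - fit.loc[scored, "true_w"]
        rows.append(
            {
                "metric": "fitness_rmse",
                "true_category": "",
                "called_category": "",
                "value": float(np.sqrt(np.mean(err**2))),
            }
        )
    if cond_results is not None and "true_w_stress" in fit.columns:
        truly_conditional = fit.index[
            (fit["true_category"] == "neutral") & (fit["true_w_stress"] < fit["true_w"])
        ]
        found = cond_results.conditional_sets()["conditionally_detrimental"]
        rows.append(
            {
                "metric": "conditional_detrimental_recall",
                "true_category": "",
                "called_category": "",
                "value": (
                    float(len(found & set(truly_conditional)) / len(truly_conditional))
                    if len(truly_conditional)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config, seed: int, outdir) -> Path:
    """Run simulate -> estimate -> compare -> report into ``outdir``.

    ``config`` is a mapping or YAML path (see :func:`load_config`).  The Tn-seq
    stage always runs; the RNA-seq stage runs only when the config carries an
    ``rnaseq`` block.  On failure, partial outputs are removed.
    """
    cfg = load_config(config)
    th = cfg["thresholds"]
    outdir = Path(outdir)
    staging = outdir.with_name(outdir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        _run_stages(cfg, seed, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
    logger.info(
        "pipeline finished: thresholds |dW|>%g alpha=%g fold>%g FDR<%g",
        th["delta_w"], th["alpha"], th["fold_change"], th["fdr"],
    )
    return outdir


def _run_stages(cfg: dict, seed: int, out: Path) -> None:
    th = cfg["thresholds"]
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_cond, rng_tnseq, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # --- Tn-seq stage -----------------------------------------------------
    tn_cfg = cfg["tnseq"]
    lib_cfg = _library_config(tn_cfg)
    genome, annotation, truth = generate_genome(lib_cfg, rng_genome)
    arms = {"control": "true_w"}
    if tn_cfg.get("conditional"):
        c = tn_cfg["conditional"]
        truth = add_conditional_effects(
            truth, c["fraction_detrimental"], c["fraction_beneficial"],
            tuple(c["effect_range"]), rng_cond,
        )
        arms["stress"] = "true_w_stress"
    write_genome([genome], out / "genome.fasta")
    write_annotation(annotation, out / "annotation.gff3")
    write_truth(truth, out / "truth_fitness.tsv")

    n_replicates = int(tn_cfg.get("n_replicates", 2))
    experiment = simulate_tnseq_experiment(
        genome, annotation, truth, lib_cfg, arms, n_replicates, rng_tnseq
    )
    edge_trim = float(tn_cfg.get("edge_trim", 0.0))
    arm_results = {}
    for arm, rep_results in experiment.items():
        for k, res in enumerate(rep_results, start=1):
            write_insertion_table(res.observations, out / f"inserts_{arm}_rep{k}.tsv")
        params = rep_results[0].outgrowth_params
        fitted = _fit_arm(rep_results, annotation, params, edge_trim, len(genome))
        arm_results[arm] = fitted
        fitted.to_tsv(out / f"gene_fitness_{arm}.tsv")
        per_rep = [
            TnSeqFitness([*r.observations], annotation, r.outgrowth_params,
                         edge_trim, len(genome)).fit().gene_table
            for r in rep_results
        ]
        _write_tsv(replicate_qc(per_rep), out / f"qc_replicate_correlation_{arm}.tsv",
                   index_label="replicate")
        logger.info("arm %s: realized d=%.4g over %g generations",
                    arm, params.d, params.generations)

    cond_results = None
    if "stress" in arm_results:
        cond_results = ConditionalFitness(
            arm_results["stress"], arm_results["control"],
            th["delta_w"], th["alpha"],
        ).fit()
        cond_results.to_tsv(out / "conditional_fitness.tsv")
        sets = cond_results.conditional_sets()
        pd.DataFrame(
            [
                {"gene_id": g, "set": name}
                for name, genes in sets.items()
                for g in sorted(genes)
            ],
            columns=["gene_id", "set"],
        ).to_csv(out / "conditional_sets.tsv", sep="\t", index=False)
        logger.info(
            "conditional comparison: m=%d, p<%g, |dW|>%g",
            cond_results.n_genes_tested, cond_results.bonferroni_threshold,
            th["delta_w"],
        )

    _write_tsv(_scorecard(truth, arm_results["control"], cond_results),
               out / "scorecard.tsv", index_label="row")

    # --- RNA-seq stage (optional) ----------------------------------------
    de_files = []
    if cfg["rnaseq"] is not None:
        expr_cfg = ExpressionSimConfig(**{
            k: (tuple(v) if k == "conditions" else v) for k, v in cfg["rnaseq"].items()
        })
        counts, expr_truth = simulate_expression(expr_cfg, rng_expr)
        write_expression_counts(counts, out / "expression_counts.tsv",
                                out / "expression_metadata.tsv")
        write_truth(expr_truth, out / "truth_expression.tsv", which="expression")
        de_tables = {}
        for condition in expr_cfg.conditions:
            de = DifferentialExpression(
                counts, condition, expr_cfg.control, min_cpm=th["min_cpm"]
            ).fit(th["fold_change"], th["fdr"])
            de_tables[condition] = de.table
            de.to_tsv(out / f"de_{condition}.tsv")
            de_files.append(f"de_{condition}.tsv")
            logger.info("DE %s vs %s: %d significant", condition,
                        expr_cfg.control, int(de.table["significant"].sum()))
        if len(expr_cfg.conditions) >= 2:
            rows = []
            conds = list(expr_cfg.conditions)
            for i, ca in enumerate(conds):
                for cb in conds[i + 1:]:
                    ov = response_overlap(de_tables[ca], de_tables[cb],
                                          th["fdr"], th["fold_change"])
                    rows.append({
                        "contrast_a": ca, "contrast_b": cb,
                        "spearman_rho": ov.spearman_rho, "n_union": ov.n_union,
                        "shared_fraction_pct": ov.shared_fraction,
                        "n_significant_a": ov.n_significant_a, "status": ov.status,
                    })
            pd.DataFrame(rows).to_csv(out / "response_overlap.tsv", sep="\t",
                                      index=False, float_format="%.10g")
        if cond_results is not None and set(cond_results.table.index) & set(
            de_tables[expr_cfg.conditions[0]].index
        ):
            labels = concordance(cond_results.table,
                                 de_tables[expr_cfg.conditions[0]],
                                 th["fold_change"], th["fdr"])
            labels.to_frame().to_csv(out / "concordance.tsv", sep="\t",
                                     index_label="gene_id")

    # --- Manifest ---------------------------------------------------------
    try:
        version = _metadata.version("cofit")
    except _metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "package": "cofit",
        "version": version,
        "seed": seed,
        "config_sha256": _config_hash(cfg, seed),
        "config": cfg,
        "thresholds_applied": th,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
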