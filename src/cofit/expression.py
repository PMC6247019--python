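"""Comparative stress-response transcriptomics.

Count filtering, a two-group negative-binomial Wald test for differential
expression, Benjamini-Hochberg FDR, the significance gate (>2-fold change at
FDR < 0.01), cross-stressor response-overlap statistics, and fitness versus
expression concordance labels.

The DE test is a documented stand-in with fully specified behaviour, not a
re-implementation of any published package: library sizes are normalized by
median-of-ratios, log2 fold changes come from normalized group means with a
0.5 pseudocount, per-gene NB dispersions are estimated by method of moments
and moderated toward the across-gene mean (information sharing keeps the
Wald statistic close to its nominal normal reference at triplicate sample
sizes), and p-values come from a two-sided Wald test on the log-mean
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionCounts, FormatError

__all__ = [
    "filter_low_expression",
    "size_factors_median_of_ratios",
    "de_test",
    "bh_fdr",
    "significant_de",
    "response_overlap",
    "OverlapResult",
    "concordance",
    "DifferentialExpression",
    "DEResults",
]

FOLD_THRESHOLD = 2.0
FDR_THRESHOLD = 0.01
DISPERSION_FLOOR = 1e-8


def filter_low_expression(
    ec: ExpressionCounts,
    min_cpm: float = 1.0,
    min_samples: Optional[int] = None,
) -> ExpressionCounts:
    """Drop weakly expressed genes.

    A gene is kept iff its counts-per-million reach ``min_cpm`` in at least
    ``min_samples`` samples (default: the size of the smallest condition
    group).  Raises if every gene would be removed.
    """
    libsize = ec.counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("library sizes must be positive")
    if min_samples is None:
        min_samples = ec.smallest_group_size()
    cpm = ec.counts / libsize * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "low-expression filter removed every gene; review min_cpm/min_samples"
        )
    return ExpressionCounts(ec.counts.loc[keep], ec.metadata)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() == 0:
        # degenerate matrix with zeros everywhere: fall back to total count
        total = arr.sum(axis=0)
        sf = total / np.exp(np.mean(np.log(total)))
        return pd.Series(sf, index=counts.columns)
    ref = np.exp(np.mean(np.log(arr[positive]), axis=1))
    sf = np.median(arr[positive] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns)


def _moment_dispersions(
    y: np.ndarray, groups: list[np.ndarray], floor: float, prior_df: float
) -> np.ndarray:
    """Method-of-moments NB dispersions, moderated toward the across-gene mean."""
    resid_df = sum(len(g) - 1 for g in groups)
    pooled_var = (
        sum((len(g) - 1) * y[:, g].var(axis=1, ddof=1) for g in groups) / resid_df
    )
    mu = np.mean([y[:, g].mean(axis=1) for g in groups], axis=0)
    mu = np.maximum(mu, 1e-8)
    raw = (pooled_var - mu) / mu**2
    prior = float(np.mean(np.maximum(raw, 0.0)))
    moderated = (resid_df * raw + prior_df * prior) / (resid_df + prior_df)
    return np.maximum(moderated, floor)


def de_test(
    ec: ExpressionCounts,
    condition: str,
    control: str,
    prior_df: float = 20.0,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Two-group NB Wald test of ``condition`` against ``control``.

    Returns a DataFrame indexed by gene_id with columns ``base_mean``,
    ``log2fc`` (condition over control), ``dispersion``, ``stat`` and
    ``p_value``.  Adjusted q-values are added downstream by :func:`bh_fdr`.
    """
    samples_a = ec.samples_for(condition)
    samples_b = ec.samples_for(control)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("de_test requires >= 2 replicates per group")
    cols = samples_a + samples_b
    counts = ec.counts[cols]
    sf = size_factors_median_of_ratios(counts)
    y = counts.to_numpy(dtype=float) / sf.to_numpy()
    idx_a = np.arange(len(samples_a))
    idx_b = np.arange(len(samples_a), len(cols))
    n_a, n_b = len(samples_a), len(samples_b)

    mean_a = y[:, idx_a].mean(axis=1)
    mean_b = y[:, idx_b].mean(axis=1)
    alpha = _moment_dispersions(y, [idx_a, idx_b], dispersion_floor, prior_df)

    delta = np.log(mean_a + 0.5) - np.log(mean_b + 0.5)
    var_a = (mean_a + alpha * mean_a**2) / n_a
    var_b = (mean_b + alpha * mean_b**2) / n_b
    var_log = var_a / (mean_a + 0.5) ** 2 + var_b / (mean_b + 0.5) ** 2
    stat = delta / np.sqrt(var_log)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "base_mean": (mean_a * n_a + mean_b * n_b) / (n_a + n_b),
            "log2fc": delta / math.log(2.0),
            "dispersion": alpha,
            "stat": stat,
            "p_value": p,
        },
        index=counts.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significant_de(
    results: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.Series:
    """Signed set of significantly differentially expressed genes.

    Membership requires |log2fc| strictly above ``log2(fold_threshold)`` and
    q strictly below ``fdr_threshold``; the value is the sign of the change.
    """
    if "q_value" not in results.columns:
        raise ValueError("results must carry a q_value column (run bh_fdr first)")
    lfc_gate = results["log2fc"].abs() > math.log2(fold_threshold)
    q_gate = results["q_value"] < fdr_threshold
    sel = results[lfc_gate & q_gate]
    return np.sign(sel["log2fc"]).astype(int)


@dataclass
class OverlapResult:
    """Cross-stressor response overlap between two DE contrasts."""

    spearman_rho: float
    n_union: int
    shared_fraction: float  # percent of A's gated response shared by B
    n_significant_a: int
    status: str = "ok"


def response_overlap(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
    fold_threshold: float = FOLD_THRESHOLD,
) -> OverlapResult:
    """Overlap statistics between two transcriptional responses.

    ``spearman_rho`` is the Spearman rank correlation of log2 fold changes
    over the union of genes significant at FDR < ``fdr_threshold`` in either
    contrast (no fold gate; average ranks for ties).  ``shared_fraction`` is
    the percentage of genes passing the full gate (fold + FDR) in A that pass
    it in B with the same sign.
    """
    if set(de_a.index) != set(de_b.index):
        raise ValueError("DE contrasts cover different gene universes")
    de_b = de_b.loc[de_a.index]
    union = de_a.index[(de_a["q_value"] < fdr_threshold) | (de_b["q_value"] < fdr_threshold)]
    if len(union) == 0:
        return OverlapResult(math.nan, 0, math.nan, 0, "no significant genes")
    rho = stats.spearmanr(de_a.loc[union, "log2fc"], de_b.loc[union, "log2fc"]).statistic
    sig_a = significant_de(de_a, fold_threshold, fdr_threshold)
    sig_b = significant_de(de_b, fold_threshold, fdr_threshold)
    if len(sig_a) == 0:
        return OverlapResult(float(rho), len(union), math.nan, 0, "no gated genes in A")
    shared = sum(1 for g, s in sig_a.items() if g in sig_b.index and sig_b[g] == s)
    return OverlapResult(
        float(rho), len(union), 100.0 * shared / len(sig_a), len(sig_a), "ok"
    )


def concordance(
    conditional: pd.DataFrame,
    de: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.Series:
    """Fitness-expression concordance labels.

    Over the shared gene universe: a gene whose disruption is significantly
    detrimental under the stressor (delta_w < 0) and which is significantly
    upregulated responds *appropriately*; significant downregulation of such
    a gene is *counterproductive*.  Genes whose disruption is beneficial are
    mirrored (downregulation is appropriate).  Everything else, including all
    fitness-neutral genes, is *unclassified*.
    """
    sig_de = significant_de(de, fold_threshold, fdr_threshold)
    labels = {}
    for gid in conditional.index.intersection(de.index):
        row = conditional.loc[gid]
        label = "unclassified"
        if bool(row["significant"]) and gid in sig_de.index:
            direction = sig_de[gid]
            if row["delta_w"] < 0:
                label = "appropriate" if direction > 0 else "counterproductive"
            elif row["delta_w"] > 0:
                label = "appropriate" if direction < 0 else "counterproductive"
        labels[gid] = label
    return pd.Series(labels, name="concordance")


class DifferentialExpression:
    """Two-group differential-expression model.

    Parameters
    ----------
    counts
        :class:`~cofit.io.ExpressionCounts` with at least two replicates in
        both the ``condition`` and the ``control`` group.
    condition, control
        Condition labels from the sample metadata; fold changes are reported
        as condition over control.
    min_cpm, min_samples
        Low-expression filter applied before testing (CPM threshold and the
        number of samples that must reach it).
    """

    def __init__(
        self,
        counts: ExpressionCounts,
        condition: str,
        control: str,
        min_cpm: float = 1.0,
        min_samples: Optional[int] = None,
        prior_df: float = 20.0,
    ) -> None:
        if condition not in counts.conditions or control not in counts.conditions:
            raise ValueError(f"unknown condition: {condition!r} / {control!r}")
        self.counts = counts
        self.condition = condition
        self.control = control
        self.min_cpm = min_cpm
        self.min_samples = min_samples
        self.prior_df = prior_df

    def fit(
        self,
        fold_threshold: float = FOLD_THRESHOLD,
        fdr_threshold: float = FDR_THRESHOLD,
    ) -> "DEResults":
        filtered = filter_low_expression(self.counts, self.min_cpm, self.min_samples)
        table = de_test(filtered, self.condition, self.control, self.prior_df)
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        gate = significant_de(table, fold_threshold, fdr_threshold)
        table["significant"] = table.index.isin(gate.index)
        return DEResults(self, table, fold_threshold, fdr_threshold)


class DEResults:
    """Per-gene DE table: log2fc, p_value, q_value, significance gate."""

    def __init__(self, model, table, fold_threshold, fdr_threshold) -> None:
        self.model = model
        self.table = table
        self.fold_threshold = fold_threshold
        self.fdr_threshold = fdr_threshold

    @property
    def significant(self) -> pd.Series:
        """Signed series (+1 up, -1 down) over the gated significant genes."""
        return significant_de(self.table, self.fold_threshold, self.fdr_threshold)

    def summary(self) -> str:
        sig = self.significant
        return "\n".join(
            [
                f"Differential expression: {self.model.condition} vs {self.model.control}",
                "=" * 50,
                f"genes tested:      {len(self.table)}",
                f"gate:              |fold change| > {self.fold_threshold:g}, "
                f"FDR < {self.fdr_threshold:g}",
                f"significant total: {len(sig)}",
                f"  upregulated:     {int((sig > 0).sum())}",
                f"  downregulated:   {int((sig < 0).sum())}",
            ]
        )

    def to_tsv(self, path) -> None:
        self.table.reset_index().rename(columns={"index": "gene_id"}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
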