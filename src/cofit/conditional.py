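"""Conditional fitness: comparisons across arms and strains.

Genes matter *conditionally* when disrupting them changes fitness only under
a specific condition (for example in the presence of a toxic stressor) or in
a specific genetic background (a wild type that degrades the stressor versus
a mutant that cannot).  Both comparisons run a Welch two-sample t-test on the
per-insert fitness samples of a gene, pooled over replicate libraries, and
call significance with a Bonferroni-corrected threshold combined with a
minimum effect size: |delta W| > 0.05.

The strain comparison additionally removes the contribution of gene
disruption in the absence of the stressor by working with background-
corrected deltas (W with stressor minus W without, per strain); a gene is
*degradation-dependent detrimental* when its disruption is significantly
detrimental in the wild type but not in the non-degrading mutant.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConditionalFitnessResult, StrainComparisonResult

__all__ = [
    "welch_t_test",
    "compare_arms",
    "conditionally_important",
    "compare_strains",
    "ConditionalFitness",
    "ConditionalFitnessResults",
    "StrainComparison",
    "StrainComparisonResults",
]

DELTA_W_THRESHOLD = 0.05
ALPHA = 0.05


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Welch two-sample t-test with a zero-variance degenerate rule.

    When both samples are constant there is no within-sample evidence of
    noise: equal means give p = 1 (no evidence of difference), unequal means
    give p = 0.  Returns (t, p, flag).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=0) == 0.0 and b.std(ddof=0) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "zero-variance"
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0, "zero-variance"
    with warnings.catch_warnings():
        # near-identical samples trigger a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), "ok"


def compare_arms(
    gene_id: str,
    ws_arm_a: Sequence[float],
    ws_arm_b: Sequence[float],
    n_genes_tested: int,
    delta_threshold: float = DELTA_W_THRESHOLD,
    alpha: float = ALPHA,
) -> ConditionalFitnessResult:
    """Gene-level fitness difference between two arms (A minus B).

    Significance requires both |delta_w| > ``delta_threshold`` and a Welch
    t-test p-value below ``alpha / n_genes_tested`` (Bonferroni over the genes
    actually tested in the run).  Genes with fewer than two eligible inserts
    in either arm are reported descriptively with ``flag='untestable'`` and
    are never significant.
    """
    if n_genes_tested < 1:
        raise ValueError("n_genes_tested must be >= 1")
    a = np.asarray(list(ws_arm_a), dtype=float)
    b = np.asarray(list(ws_arm_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        delta = float(a.mean() - b.mean()) if len(a) and len(b) else math.nan
        return ConditionalFitnessResult(
            gene_id, delta, math.nan, math.nan, False, "untestable"
        )
    delta = float(a.mean() - b.mean())
    t, p, flag = welch_t_test(a, b)
    significant = abs(delta) > delta_threshold and p < alpha / n_genes_tested
    return ConditionalFitnessResult(gene_id, delta, t, p, bool(significant), flag)


def conditionally_important(
    results: Mapping[str, ConditionalFitnessResult] | pd.DataFrame,
    categories_without: Mapping[str, str],
) -> dict[str, set]:
    """Gene sets whose disruption matters only in the stress arm.

    ``results`` compares stress (arm A) against no-stress (arm B);
    ``categories_without`` gives each gene's five-way category in the
    *absence* of the stressor.  Conditionally detrimental genes are
    significant with ``delta_w < 0`` yet neutral without the stressor;
    conditionally beneficial genes are the mirror image.
    """
    if isinstance(results, pd.DataFrame):
        results = {
            row.Index: ConditionalFitnessResult(
                row.Index, row.delta_w, row.t_statistic, row.p_value,
                bool(row.significant), row.flag,
            )
            for row in results.itertuples()
        }
    universe_r, universe_c = set(results), set(categories_without)
    if universe_r != universe_c:
        only_r = sorted(universe_r - universe_c)[:10]
        only_c = sorted(universe_c - universe_r)[:10]
        raise ValueError(
            f"gene universe mismatch: only in results {only_r}, "
            f"only in categories {only_c}"
        )
    detrimental, beneficial = set(), set()
    for gid, res in results.items():
        if not res.significant or categories_without[gid] != "neutral":
            continue
        if res.delta_w < 0:
            detrimental.add(gid)
        elif res.delta_w > 0:
            beneficial.add(gid)
    return {
        "conditionally_detrimental": detrimental,
        "conditionally_beneficial": beneficial,
    }


def compare_strains(
    gene_id: str,
    wt_plus: Sequence[float],
    wt_minus: Sequence[float],
    mut_plus: Sequence[float],
    mut_minus: Sequence[float],
    n_genes_tested: int,
    delta_threshold: float = DELTA_W_THRESHOLD,
    alpha: float = ALPHA,
) -> StrainComparisonResult:
    """Background-corrected strain comparison for one gene.

    Per strain, the no-stress mean fitness is subtracted from the stress mean
    fitness (delta_wt, delta_mut).  The between-strain t-test compares the
    stress-arm per-insert samples of the two strains.  A gene is flagged
    degradation-dependent when its disruption is significantly detrimental in
    the wild type (stress vs no stress) but not in the mutant.
    """
    wt_res = compare_arms(gene_id, wt_plus, wt_minus, n_genes_tested, delta_threshold, alpha)
    mut_res = compare_arms(gene_id, mut_plus, mut_minus, n_genes_tested, delta_threshold, alpha)
    wp = np.asarray(list(wt_plus), dtype=float)
    mp = np.asarray(list(mut_plus), dtype=float)
    if len(wp) < 2 or len(mp) < 2:
        return StrainComparisonResult(
            gene_id, wt_res.delta_w, mut_res.delta_w, math.nan, math.nan,
            False, wt_res.significant, mut_res.significant, False,
            "missing-in-strain",
        )
    t, p, flag = welch_t_test(wp, mp)
    significant = p < alpha / n_genes_tested
    wt_detrimental = wt_res.significant and wt_res.delta_w < 0
    mut_detrimental = mut_res.significant and mut_res.delta_w < 0
    return StrainComparisonResult(
        gene_id, wt_res.delta_w, mut_res.delta_w, t, p, bool(significant),
        wt_res.significant, mut_res.significant,
        bool(wt_detrimental and not mut_detrimental), flag,
    )


def _testable(values_a, values_b) -> bool:
    return len(values_a) >= 2 and len(values_b) >= 2


class ConditionalFitness:
    """Two-arm comparison model built from two fitted fitness results.

    Parameters
    ----------
    results_stress, results_control
        :class:`~cofit.fitness.TnSeqFitnessResults` for the stress arm (A)
        and the no-stress arm (B); delta_w is stress minus control.
    """

    def __init__(
        self,
        results_stress,
        results_control,
        delta_threshold: float = DELTA_W_THRESHOLD,
        alpha: float = ALPHA,
    ) -> None:
        self.results_stress = results_stress
        self.results_control = results_control
        self.delta_threshold = delta_threshold
        self.alpha = alpha

    def fit(self) -> "ConditionalFitnessResults":
        va, vb = self.results_stress.gene_values, self.results_control.gene_values
        universe = sorted(set(va) | set(vb))
        n_tested = sum(
            1 for g in universe if _testable(va.get(g, ()), vb.get(g, ()))
        )
        n_tested = max(n_tested, 1)
        rows = []
        for gid in universe:
            res = compare_arms(
                gid, va.get(gid, ()), vb.get(gid, ()), n_tested,
                self.delta_threshold, self.alpha,
            )
            rows.append(
                {
                    "gene_id": gid,
                    "delta_w": res.delta_w,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "flag": res.flag,
                }
            )
        table = pd.DataFrame(rows).set_index("gene_id")
        return ConditionalFitnessResults(self, table, n_tested)


class ConditionalFitnessResults:
    """Per-gene delta_w table with the thresholds actually applied."""

    def __init__(self, model, table: pd.DataFrame, n_genes_tested: int) -> None:
        self.model = model
        self.table = table
        self.n_genes_tested = n_genes_tested

    @property
    def bonferroni_threshold(self) -> float:
        return self.model.alpha / self.n_genes_tested

    def conditional_sets(self) -> dict[str, set]:
        categories = self.model.results_control.gene_table["category"].to_dict()
        table = self.table.loc[sorted(set(self.table.index) & set(categories))]
        return conditionally_important(table, {g: categories[g] for g in table.index})

    def summary(self) -> str:
        sig = self.table[self.table["significant"]]
        sets = self.conditional_sets()
        return "\n".join(
            [
                "Conditional fitness comparison (stress - control)",
                "=" * 50,
                f"genes tested (Bonferroni m): {self.n_genes_tested}",
                f"p threshold:                 {self.bonferroni_threshold:.3g}",
                f"|delta W| threshold:         {self.model.delta_threshold:g}",
                f"significant genes:           {len(sig)}",
                f"conditionally detrimental:   {len(sets['conditionally_detrimental'])}",
                f"conditionally beneficial:    {len(sets['conditionally_beneficial'])}",
            ]
        )

    def to_tsv(self, path) -> None:
        out = self.table.reset_index().copy()
        out["p_bonferroni_threshold"] = self.bonferroni_threshold
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


class StrainComparison:
    """Two-strain, two-arm comparison model.

    Parameters are four fitted :class:`~cofit.fitness.TnSeqFitnessResults`:
    wild type with/without the stressor and mutant with/without.  Genes with
    no testable sample in one strain's stress arm are flagged
    ``missing-in-strain`` and excluded from testing.
    """

    def __init__(
        self,
        wt_stress,
        wt_control,
        mut_stress,
        mut_control,
        delta_threshold: float = DELTA_W_THRESHOLD,
        alpha: float = ALPHA,
    ) -> None:
        self.wt_stress = wt_stress
        self.wt_control = wt_control
        self.mut_stress = mut_stress
        self.mut_control = mut_control
        self.delta_threshold = delta_threshold
        self.alpha = alpha

    def fit(self) -> "StrainComparisonResults":
        all_results = (self.wt_stress, self.wt_control, self.mut_stress, self.mut_control)
        universe = sorted(set().union(*(r.gene_values.keys() for r in all_results)))
        getv = lambda r, g: r.gene_values.get(g, np.empty(0))
        n_tested = sum(
            1
            for g in universe
            if len(getv(self.wt_stress, g)) >= 2 and len(getv(self.mut_stress, g)) >= 2
        )
        n_tested = max(n_tested, 1)
        rows = []
        for gid in universe:
            res = compare_strains(
                gid,
                getv(self.wt_stress, gid), getv(self.wt_control, gid),
                getv(self.mut_stress, gid), getv(self.mut_control, gid),
                n_tested, self.delta_threshold, self.alpha,
            )
            rows.append(
                {
                    "gene_id": gid,
                    "delta_wt": res.delta_wt,
                    "delta_mut": res.delta_mut,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "wt_significant": res.wt_significant,
                    "mut_significant": res.mut_significant,
                    "degradation_dependent": res.degradation_dependent,
                    "flag": res.flag,
                }
            )
        table = pd.DataFrame(rows).set_index("gene_id")
        return StrainComparisonResults(self, table, n_tested)


class StrainComparisonResults:
    def __init__(self, model, table: pd.DataFrame, n_genes_tested: int) -> None:
        self.model = model
        self.table = table
        self.n_genes_tested = n_genes_tested

    @property
    def degradation_dependent_genes(self) -> list[str]:
        return list(self.table.index[self.table["degradation_dependent"]])

    def summary(self) -> str:
        return "\n".join(
            [
                "Strain comparison (background-corrected)",
                "=" * 50,
                f"genes tested (Bonferroni m):    {self.n_genes_tested}",
                f"p threshold:                    {self.model.alpha / self.n_genes_tested:.3g}",
                f"degradation-dependent genes:    {len(self.degradation_dependent_genes)}",
            ]
        )

    def to_tsv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")
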