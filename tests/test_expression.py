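"""DE stand-in behaviour, BH FDR, overlap statistics and concordance labels."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cofit.expression import (
    DifferentialExpression,
    bh_fdr,
    concordance,
    de_test,
    filter_low_expression,
    response_overlap,
    significant_de,
    size_factors_median_of_ratios,
)
from cofit.io import ExpressionCounts
from cofit.simulate import ExpressionSimConfig, simulate_expression


def make_counts(matrix, conditions):
    samples = []
    reps = {}
    for c in conditions:
        reps[c] = reps.get(c, 0) + 1
        samples.append(f"{c}_{reps[c]}")
    counts = pd.DataFrame(
        np.asarray(matrix), columns=samples,
        index=pd.Index([f"g{i+1}" for i in range(len(matrix))], name="gene_id"),
    )
    meta = pd.DataFrame(
        {"condition": conditions, "replicate": [int(s.rsplit("_", 1)[1]) for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionCounts(counts, meta)


class TestFilterLowExpression:
    def test_cpm_threshold(self):
        # 5 genes; gene g5 is below 1 CPM in every sample
        base = np.array([
            [5000, 6000, 5500, 5200],
            [3000, 2500, 2600, 2900],
            [800, 900, 1000, 950],
            [200, 250, 220, 210],
            [0, 1, 0, 0],
        ])
        ec = make_counts(base, ["c", "c", "s", "s"])
        kept = filter_low_expression(ec, min_cpm=1.0)
        assert list(kept.counts.index) == ["g1", "g2", "g3", "g4"]

    def test_zero_threshold_is_identity(self):
        ec = make_counts([[1, 0, 2, 0], [3, 4, 5, 6]], ["c", "c", "s", "s"])
        assert list(filter_low_expression(ec, min_cpm=0).counts.index) == ["g1", "g2"]

    def test_all_removed_raises(self):
        ec = make_counts([[1, 1, 1, 1]], ["c", "c", "s", "s"])
        with pytest.raises(ValueError, match="filter"):
            filter_low_expression(ec, min_cpm=1e9)


class TestBhFdr:
    def brute_force(self, p):
        """Independent reference: literal step-up on the sorted scale."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):
            q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_pvalues(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_brute_force(self, p):
        q = bh_fdr(p)
        assert np.allclose(q, self.brute_force(p))
        assert (q >= np.asarray(p) - 1e-12).all()


class TestDeTest:
    def test_identical_groups_give_zero_log2fc(self):
        block = np.array([[100, 120, 110], [50, 55, 60], [900, 880, 910]])
        ec = make_counts(np.hstack([block, block]), ["c"] * 3 + ["s"] * 3)
        res = de_test(ec, "s", "c")
        assert np.allclose(res["log2fc"], 0.0)

    def test_requires_two_replicates(self):
        ec = make_counts([[10, 20], [30, 40]], ["c", "s"])
        with pytest.raises(ValueError, match="replicates"):
            de_test(ec, "s", "c")

    def test_size_factors_remove_depth_differences(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(5, 1, 300)
        base = rng.poisson(mu[:, None], (300, 6))
        scaled = base.copy()
        scaled[:, 3:] *= 4  # one group sequenced 4x deeper
        ec = make_counts(scaled, ["c"] * 3 + ["s"] * 3)
        sf = size_factors_median_of_ratios(ec.counts)
        assert sf.iloc[3:].mean() / sf.iloc[:3].mean() == pytest.approx(4, rel=0.05)
        res = de_test(ec, "s", "c")
        assert abs(res["log2fc"].median()) < 0.05

    def test_spiked_gene_detected(self):
        cfg = ExpressionSimConfig(n_genes=500, conditions=("s",),
                                  responsive_fraction=0.0, seed=3)
        ec, _ = simulate_expression(cfg)
        counts = ec.counts.copy()
        # spike a moderately expressed gene 4-fold in the stress group
        target = counts.mean(axis=1).sub(200).abs().idxmin()
        counts.loc[target, ec.samples_for("s")] *= 4
        spiked = ExpressionCounts(counts, ec.metadata)
        table = de_test(spiked, "s", "control")
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        sig = significant_de(table)
        assert sig.get(target) == 1


class TestSignificantDe:
    def _table(self, lfc, q):
        return pd.DataFrame({"log2fc": lfc, "q_value": q},
                            index=[f"g{i}" for i in range(len(lfc))])

    def test_gates_are_strict(self):
        table = self._table([1.1, 1.0, 2.0, -1.5], [0.005, 0.005, 0.02, 0.001])
        sig = significant_de(table)
        assert dict(sig) == {"g0": 1, "g3": -1}

    def test_requires_q_column(self):
        with pytest.raises(ValueError):
            significant_de(pd.DataFrame({"log2fc": [1.0]}))


class TestResponseOverlap:
    def _de(self, lfc, q):
        return pd.DataFrame({"log2fc": lfc, "q_value": q},
                            index=[f"g{i}" for i in range(len(lfc))])

    def test_identical_contrasts(self):
        de = self._de([3, -2, 1.5, 0.1], [0.001, 0.001, 0.005, 0.9])
        ov = response_overlap(de, de)
        assert ov.spearman_rho == pytest.approx(1.0)
        assert ov.shared_fraction == pytest.approx(100.0)

    def test_mirrored_contrasts(self):
        a = self._de([3, -2, 1.5, 0.1], [0.001, 0.001, 0.005, 0.9])
        b = a.copy()
        b["log2fc"] = -b["log2fc"]
        ov = response_overlap(a, b)
        assert ov.spearman_rho == pytest.approx(-1.0)
        assert ov.shared_fraction == pytest.approx(0.0)

    def test_hand_computed_six_gene_example(self):
        # significant in A: g0,g1,g2 (q & fold); in B: g1,g2,g3 same-sign for g1,g2
        a = self._de([2.0, 1.5, -3.0, 0.5, 0.2, 0.1],
                     [0.001, 0.002, 0.003, 0.5, 0.9, 0.9])
        b = self._de([0.4, 1.2, -2.5, 2.2, 0.3, 0.2],
                     [0.2, 0.004, 0.001, 0.005, 0.8, 0.9])
        ov = response_overlap(a, b)
        union = ["g0", "g1", "g2", "g3"]
        rho_oracle = stats.pearsonr(
            stats.rankdata(a.loc[union, "log2fc"]),
            stats.rankdata(b.loc[union, "log2fc"]),
        ).statistic
        assert ov.n_union == 4
        assert ov.spearman_rho == pytest.approx(rho_oracle)
        # A's gated set {g0,g1,g2}; g1,g2 shared with same sign -> 2/3
        assert ov.shared_fraction == pytest.approx(100 * 2 / 3)

    def test_empty_union_reported(self):
        de = self._de([0.1, 0.2], [0.5, 0.6])
        ov = response_overlap(de, de)
        assert ov.status == "no significant genes"
        assert math.isnan(ov.spearman_rho)

    def test_label_shuffle_drives_sharing_to_chance(self):
        rng = np.random.default_rng(0)
        n = 2000
        lfc = rng.normal(0, 2, n)
        q = rng.uniform(0, 0.02, n)
        a = self._de(lfc, q)
        fractions = []
        for _ in range(20):
            perm = rng.permutation(n)
            b = self._de(lfc[perm], q[perm])
            fractions.append(response_overlap(a, b).shared_fraction)
        sig = significant_de(a)
        # chance level: P(same gene significant in B with same sign)
        p_up = (sig > 0).sum() / n
        p_dn = (sig < 0).sum() / n
        expected = 100 * (
            (sig > 0).sum() * p_up + (sig < 0).sum() * p_dn
        ) / len(sig)
        assert np.mean(fractions) == pytest.approx(expected, abs=3.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=3, max_size=40))
    def test_spearman_matches_rank_pearson_with_ties(self, vals):
        rng = np.random.default_rng(len(vals))
        other = rng.integers(-5, 6, len(vals)).astype(float)
        x = np.asarray(vals, dtype=float)
        if np.ptp(x) == 0 or np.ptp(other) == 0:
            return  # undefined correlation
        ours = stats.spearmanr(x, other).statistic
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(other)).statistic
        assert ours == pytest.approx(oracle, abs=1e-12)


class TestConcordance:
    def _cond(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def _de(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_labels(self):
        cond = self._cond([
            {"gene_id": "up_good", "delta_w": -0.2, "significant": True},
            {"gene_id": "down_bad", "delta_w": -0.2, "significant": True},
            {"gene_id": "benefit", "delta_w": 0.2, "significant": True},
            {"gene_id": "quiet", "delta_w": -0.01, "significant": False},
        ])
        de = self._de([
            {"gene_id": "up_good", "log2fc": 3.0, "q_value": 0.001},
            {"gene_id": "down_bad", "log2fc": -2.0, "q_value": 0.001},
            {"gene_id": "benefit", "log2fc": -2.0, "q_value": 0.001},
            {"gene_id": "quiet", "log2fc": 4.0, "q_value": 0.001},
        ])
        labels = concordance(cond, de)
        assert labels["up_good"] == "appropriate"
        assert labels["down_bad"] == "counterproductive"
        assert labels["benefit"] == "appropriate"
        assert labels["quiet"] == "unclassified"

    def test_insignificant_expression_unclassified(self):
        cond = self._cond([{"gene_id": "g", "delta_w": -0.2, "significant": True}])
        de = self._de([{"gene_id": "g", "log2fc": 3.0, "q_value": 0.5}])
        assert concordance(cond, de)["g"] == "unclassified"


class TestDifferentialExpressionModel:
    def test_null_simulation_calibrated(self):
        cfg = ExpressionSimConfig(n_genes=1000, conditions=("null",),
                                  responsive_fraction=0.0, seed=8)
        ec, _ = simulate_expression(cfg)
        res = DifferentialExpression(ec, "null", "control").fit()
        ks = stats.kstest(res.table["p_value"], "uniform").statistic
        assert ks < 0.06
        assert len(res.significant) == 0

    def test_summary_counts_directions(self):
        cfg = ExpressionSimConfig(n_genes=400, conditions=("s",), seed=9)
        ec, truth = simulate_expression(cfg)
        res = DifferentialExpression(ec, "s", "control").fit()
        text = res.summary()
        assert "significant total" in text
        sig = res.significant
        # detected genes should be truly responsive in the right direction
        truth_lfc = truth.expression["s"]
        agree = [np.sign(truth_lfc[g]) == s for g, s in sig.items()]
        assert np.mean(agree) > 0.9
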