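"""Pseudobulk DGE: aggregation, NB Wald test, BH/Fisher machinery, radial data."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps

import commshift as cs
from commshift.containers import CountMatrix
from commshift.dge import (aggregate_one_vs_many, expressed_in_either,
                           frac_expressed, make_pseudobulk, median_of_ratios,
                           nb_wald_test, radial_plot_data, select_elevated_genes)
from commshift.stats import bh_adjust, fisher_combine


def _pb(rows: dict, genes=None):
    pb = pd.DataFrame(rows).T
    pb.index = pd.MultiIndex.from_tuples(pb.index, names=["group", "sample"])
    pb.columns = genes or [f"g{j}" for j in range(pb.shape[1])]
    return pb


def _dge(log2fc, p_adj=None, genes=None):
    genes = genes or [f"g{j}" for j in range(len(log2fc))]
    p_adj = p_adj if p_adj is not None else [0.5] * len(log2fc)
    return pd.DataFrame({"log2FC": log2fc, "p": p_adj, "p_adj": p_adj},
                        index=pd.Index(genes, name="gene"))


class TestPseudobulk:
    def _counts(self, X, ann_rows):
        X = np.asarray(X)
        cm = CountMatrix(sp.csr_matrix(X),
                         np.array([f"c{i}" for i in range(X.shape[0])], dtype=object),
                         np.array([f"g{j}" for j in range(X.shape[1])], dtype=object))
        ann = pd.DataFrame(ann_rows, index=cm.cell_ids,
                           columns=["cell_type", "condition", "sample"])
        return cm, ann

    def test_single_cell_groups_pass_through(self):
        cm, ann = self._counts([[1, 2], [3, 4]],
                               [["A", "x", "s1"], ["B", "x", "s1"]])
        pb = make_pseudobulk(cm, ann)
        assert list(pb.loc[("A", "s1")]) == [1, 2]
        assert list(pb.loc[("B", "s1")]) == [3, 4]

    def test_counts_sum_within_group(self):
        cm, ann = self._counts([[3], [4]], [["A", "x", "s1"], ["A", "x", "s1"]])
        assert make_pseudobulk(cm, ann).iloc[0, 0] == 7

    def test_grand_total_conserved(self, planted_dataset):
        _, counts, ann, _ = planted_dataset
        pb = make_pseudobulk(counts, ann)
        assert pb.to_numpy().sum() == counts.values.sum()


class TestBHAndFisher:
    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=57)
        # independent step-up oracle
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        assert np.allclose(bh_adjust(p), adj)

    def test_bh_never_below_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_fisher_closed_form(self):
        # {0.05, 0.05}: statistic -2*2*ln(0.05) = 11.98 on 4 df
        stat = -2 * 2 * np.log(0.05)
        assert stat == pytest.approx(11.9829, abs=1e-3)
        expected = sps.chi2.sf(stat, df=4)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(expected)
        assert expected == pytest.approx(0.0175, abs=5e-4)

    def test_fisher_matches_chi_square_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for k in (2, 5, 11):
            p = rng.uniform(size=k)
            assert fisher_combine(p) == pytest.approx(
                sps.chi2.sf(-2 * np.log(p).sum(), df=2 * k))

    def test_fisher_clamps_zero(self):
        assert 0.0 <= fisher_combine([0.0, 0.5]) <= 1.0


class TestAggregate:
    def test_mean_log2fc(self):
        agg = aggregate_one_vs_many([_dge([1.0]), _dge([3.0])])
        assert agg["mean_log2fc"].iloc[0] == pytest.approx(2.0)

    def test_threshold_counting(self):
        agg = aggregate_one_vs_many([_dge([2.5]), _dge([1.0]), _dge([3.0])])
        assert agg["n_above_threshold"].iloc[0] == 2

    def test_combined_p_is_fisher_of_adjusted(self):
        agg = aggregate_one_vs_many([_dge([1.0], [0.05]), _dge([1.0], [0.05])])
        assert agg["combined_p"].iloc[0] == pytest.approx(fisher_combine([0.05, 0.05]))

    def test_universe_intersection_warns(self):
        a = _dge([1.0, 2.0], genes=["g0", "g1"])
        b = _dge([3.0], genes=["g0"])
        with pytest.warns(UserWarning, match="intersect"):
            agg = aggregate_one_vs_many([a, b])
        assert list(agg.index) == ["g0"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_one_vs_many([])


class TestNBWald:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        profile = rng.poisson(500.0, size=30).astype(int)
        rows = {(g, f"{g}{s}"): profile for g in "AB" for s in range(3)}
        res = nb_wald_test(_pb(rows), "A", "B")
        assert np.allclose(res["log2FC"], 0.0, atol=1e-8)
        assert np.all(res["p"] > 0.999)

    def test_depth_shift_absorbed_by_size_factors(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(800.0, size=50).astype(int)
        rows = {("A", f"A{s}"): 2 * base for s in range(3)}
        rows.update({("B", f"B{s}"): base for s in range(3)})
        pb = _pb(rows)
        sf = median_of_ratios(pb)
        # hand-computed median-of-ratios: A rows at 2x geometric mean scale
        assert sf[:3] / sf[3:] == pytest.approx([2.0] * 3)
        res = nb_wald_test(pb, "A", "B")
        assert np.allclose(res["log2FC"], 0.0, atol=1e-6)

    def test_doubled_gene_recovers_log2fc_one(self):
        rng = np.random.default_rng(2)
        base = rng.integers(500, 5000, size=400)
        rows = {}
        for g in "AB":
            for s in range(4):
                profile = base.copy()
                if g == "A":
                    profile = profile.copy()
                    profile[0] *= 2
                rows[(g, f"{g}{s}")] = profile
        res = nb_wald_test(_pb(rows), "A", "B")
        assert res["log2FC"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert res["p_adj"].iloc[0] < 0.05

    def test_all_zero_genes_excluded(self):
        rows = {("A", "A0"): [10, 0], ("A", "A1"): [12, 0],
                ("B", "B0"): [9, 0], ("B", "B1"): [11, 0]}
        res = nb_wald_test(_pb(rows), "A", "B")
        assert list(res.index) == ["g0"]
        assert res.attrs["excluded_genes"] == ["g1"]

    def test_matches_statsmodels_glm_oracle(self):
        """Dual route: our IRLS vs statsmodels NB GLM on one gene."""
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        y = rng.negative_binomial(10, 10 / (10 + 600.0), size=8).astype(float)
        y[:4] *= 3
        sf = np.ones(8)
        X = np.column_stack([np.ones(8), np.array([1] * 4 + [0] * 4)])
        alpha = 0.1
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        from commshift.dge import _irls_two_group
        lfc, se = _irls_two_group(y[:, None], sf, X[:, 1].astype(bool),
                                  np.array([alpha]))
        assert lfc[0] == pytest.approx(glm.params[1], abs=1e-6)
        assert se[0] == pytest.approx(glm.bse[1], rel=1e-4)

    def test_single_sample_group_warns(self):
        rows = {("A", "A0"): [10], ("B", "B0"): [12], ("B", "B1"): [9]}
        with pytest.warns(UserWarning, match="single sample"):
            nb_wald_test(_pb(rows), "A", "B")


class TestFracExpressed:
    def _setup(self):
        X = np.zeros((20, 2), dtype=int)
        X[:2, 0] = 1          # g0 in 2/10 cells of condition x
        X[10:15, 1] = 1       # g1 in 5/10 cells of condition y only
        cm = CountMatrix(sp.csr_matrix(X),
                         np.array([f"c{i}" for i in range(20)], dtype=object),
                         np.array(["g0", "g1"], dtype=object))
        ann = pd.DataFrame({"cell_type": ["T"] * 20,
                            "condition": ["x"] * 10 + ["y"] * 10,
                            "sample": ["s"] * 20}, index=cm.cell_ids)
        return cm, ann

    def test_fraction_values(self):
        cm, ann = self._setup()
        frac = frac_expressed(cm, ann, keys="condition")
        assert frac.loc["g0", "x"] == pytest.approx(0.2)
        assert frac.loc["g1", "x"] == pytest.approx(0.0)
        assert frac.loc["g1", "y"] == pytest.approx(0.5)

    def test_either_condition_rule(self):
        cm, ann = self._setup()
        frac = frac_expressed(cm, ann, keys="condition")
        kept = expressed_in_either(frac, ["x", "y"], threshold=0.2)
        assert kept == ["g0", "g1"]  # g0 at exactly 0.2, g1 via condition y
        assert expressed_in_either(frac, ["x", "y"], threshold=0.21) == ["g1"]


class TestRadial:
    def test_negative_fold_clipped(self):
        res = _dge([-2.0, 2.0], [0.001, 0.001])
        out = radial_plot_data({"T": res}, ("ctl", "mut"))
        ctl = out[out["condition"] == "ctl"].set_index("gene")
        mut = out[out["condition"] == "mut"].set_index("gene")
        # g0 is down in ctl-over-mut: clipped in the ctl quadrant, kept in mut
        assert ctl.loc["g0", "log2FC"] == 0.0 and ctl.loc["g0", "p_adj"] == 1.0
        assert mut.loc["g0", "log2FC"] == 2.0 and mut.loc["g0", "p_adj"] == 0.001
        assert ctl.loc["g1", "log2FC"] == 2.0 and ctl.loc["g1", "p_adj"] == 0.001

    def test_every_gene_in_every_quadrant(self):
        res = _dge([1.0, -1.0, 0.5])
        out = radial_plot_data({"T": res, "U": res}, ("a", "b"))
        sizes = out.groupby(["cell_type", "condition"]).size()
        assert (sizes == 3).all() and len(sizes) == 4


class TestSelectElevated:
    def test_inclusive_bounds(self):
        agg = pd.DataFrame({"mean_log2fc": [1.0, 0.99], "combined_p": [0.05, 0.01],
                            "n_above_threshold": [1, 1]}, index=["hit", "near"])
        frac = pd.Series([0.2, 0.9], index=["hit", "near"])
        assert select_elevated_genes(agg, frac) == ["hit"]

    def test_empty_input(self):
        agg = pd.DataFrame(columns=["mean_log2fc", "combined_p", "n_above_threshold"])
        assert select_elevated_genes(agg) == []
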