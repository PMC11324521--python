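"""LRI scoring, permutation tests, differential scores and significance filters."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import commshift as cs
from commshift.containers import NormalizedMatrix
from commshift.lri import (LRDatabase, PermutationConfig, count_significant_by_pair,
                           group_means, load_lr_pairs, lri_diff, lri_scores,
                           minmax_scale_pairs, permutation_test_celltype,
                           permutation_test_condition, significant_interactions)


def _norm(X, gene_ids=None, cell_ids=None):
    X = np.asarray(X, dtype=float)
    cell_ids = cell_ids or [f"c{i}" for i in range(X.shape[0])]
    gene_ids = gene_ids or [f"g{j}" for j in range(X.shape[1])]
    return NormalizedMatrix(sp.csr_matrix(X), np.array(cell_ids, dtype=object),
                            np.array(gene_ids, dtype=object))


def _ann(cell_types, conditions, cell_ids=None):
    cell_ids = cell_ids or [f"c{i}" for i in range(len(cell_types))]
    return pd.DataFrame({"cell_type": cell_types, "condition": conditions,
                         "sample": ["s0"] * len(cell_types)},
                        index=pd.Index(cell_ids, name="cell_id"))


class TestLoadPairs:
    def test_bidirectional_collapses_to_first_seen(self):
        norm = _norm(np.ones((10, 2)), gene_ids=["A", "B"])
        table = pd.DataFrame({"ligand": ["A", "B"], "receptor": ["B", "A"]})
        db = load_lr_pairs(table, norm, min_frac=0.0)
        assert db.pairs == (("A", "B"),)

    def test_low_fraction_gene_excluded(self):
        X = np.ones((100, 2))
        X[9:, 0] = 0.0  # ligand expressed in 9% of cells
        norm = _norm(X, gene_ids=["L", "R"])
        table = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        with pytest.raises(ValueError, match="survive"):
            load_lr_pairs(table, norm, min_frac=0.10)

    def test_missing_gene_dropped_with_warning(self):
        norm = _norm(np.ones((10, 2)), gene_ids=["A", "B"])
        table = pd.DataFrame({"ligand": ["A", "ghost"], "receptor": ["B", "B"]})
        with pytest.warns(UserWarning, match="not in matrix"):
            db = load_lr_pairs(table, norm, min_frac=0.0)
        assert db.pairs == (("A", "B"),)


class TestGroupMeans:
    def test_arithmetic_mean(self):
        norm = _norm([[2.0], [4.0]])
        gm = group_means(norm, _ann(["T", "T"], ["x", "x"]))
        assert gm.get("g0", "T", "x") == pytest.approx(3.0)

    def test_single_cell_group(self):
        norm = _norm([[7.0], [1.0]])
        gm = group_means(norm, _ann(["T", "U"], ["x", "x"]))
        assert gm.get("g0", "T", "x") == pytest.approx(7.0)

    def test_all_zero_gene(self):
        norm = _norm([[0.0], [0.0]])
        gm = group_means(norm, _ann(["T", "U"], ["x", "x"]))
        assert gm.get("g0", "T", "x") == 0.0


class TestScores:
    def _means(self, lvals, rvals):
        norm = _norm([[lvals[0], rvals[0]], [lvals[1], rvals[1]]], gene_ids=["L", "R"])
        return group_means(norm, _ann(["S", "V"], ["x", "x"]))

    def test_product(self):
        gm = self._means([2.0, 0.0], [0.0, 3.0])
        scores = lri_scores(gm, LRDatabase((("L", "R"),)))
        rec = scores.set_index(["sender", "receiver"])
        assert rec.loc[("S", "V"), "lri_score"] == pytest.approx(6.0)

    def test_zero_ligand_zeroes_score(self):
        gm = self._means([0.0, 0.0], [5.0, 5.0])
        scores = lri_scores(gm, LRDatabase((("L", "R"),)))
        assert (scores["lri_score"] == 0).all()

    def test_directionality(self):
        gm = self._means([2.0, 1.0], [1.0, 3.0])
        rec = lri_scores(gm, LRDatabase((("L", "R"),))).set_index(["sender", "receiver"])
        assert rec.loc[("S", "V"), "lri_score"] != rec.loc[("V", "S"), "lri_score"]


class TestDiffScore:
    def _gm(self, l_ctl, l_cko, r_ctl, r_cko):
        norm = _norm([[l_ctl, r_ctl], [l_cko, r_cko],
                      [l_ctl, r_ctl], [l_cko, r_cko]], gene_ids=["L", "R"])
        ann = _ann(["S", "S", "V", "V"], ["control", "cKO", "control", "cKO"])
        return group_means(norm, ann)

    def _score(self, gm):
        d = lri_diff(gm, LRDatabase((("L", "R"),)), conditions=("control", "cKO"))
        return d.set_index(["sender", "receiver"]).loc[("S", "V"), "lri_diff_score"]

    def test_both_doubled_gives_one(self):
        assert self._score(self._gm(1.0, 2.0, 3.0, 6.0)) == pytest.approx(1.0, abs=1e-8)

    def test_identity_gives_zero(self):
        assert self._score(self._gm(1.0, 1.0, 3.0, 3.0)) == pytest.approx(0.0, abs=1e-8)

    def test_ligand_only_quadrupled_gives_one(self):
        assert self._score(self._gm(1.0, 4.0, 3.0, 3.0)) == pytest.approx(1.0, abs=1e-8)

    def test_antisymmetric_under_condition_swap(self):
        gm = self._gm(1.0, 3.0, 2.0, 5.0)
        fwd = lri_diff(gm, LRDatabase((("L", "R"),)), conditions=("control", "cKO"))
        rev = lri_diff(gm, LRDatabase((("L", "R"),)), conditions=("cKO", "control"))
        assert np.allclose(fwd["lri_diff_score"], -rev["lri_diff_score"])

    def test_zero_mean_with_zero_epsilon_flagged(self):
        gm = self._gm(0.0, 2.0, 3.0, 3.0)
        d = lri_diff(gm, LRDatabase((("L", "R"),)), epsilon=0.0,
                     conditions=("control", "cKO"))
        sv = d.set_index(["sender", "receiver"]).loc[("S", "V")]
        assert bool(sv["undefined"]) and np.isnan(sv["lri_diff_score"])


def exhaustive_celltype_p(X, gene_ids, types, db_pairs):
    """Brute-force oracle: exact p over all distinct type-label reassignments.

    Enumerates every distinct assignment of the observed label multiset to
    cells, computes the product score per assignment with plain loops, and
    returns p = fraction of assignments with score >= observed.
    """
    X = np.asarray(X, dtype=float)
    genes = {g: j for j, g in enumerate(gene_ids)}
    labels = sorted(set(types))
    n = len(types)

    def score(assign, sender, receiver, lig, rec):
        lcells = [i for i in range(n) if assign[i] == sender]
        rcells = [i for i in range(n) if assign[i] == receiver]
        lmean = sum(X[i, genes[lig]] for i in lcells) / len(lcells)
        rmean = sum(X[i, genes[rec]] for i in rcells) / len(rcells)
        return lmean * rmean

    assignments = sorted(set(itertools.permutations(types)))
    out = {}
    for lig, rec in db_pairs:
        for s in labels:
            for r in labels:
                obs = score(types, s, r, lig, rec)
                ge = sum(score(a, s, r, lig, rec) >= obs for a in assignments)
                out[(s, r, lig, rec)] = ge / len(assignments)
    return out


class TestCelltypePermutation:
    def test_constant_matrix_gives_p_one(self):
        norm = _norm(np.full((8, 2), 3.0), gene_ids=["L", "R"])
        ann = _ann(["S"] * 4 + ["V"] * 4, ["x"] * 8)
        res = permutation_test_celltype(norm, ann, LRDatabase((("L", "R"),)),
                                        PermutationConfig(n_perm=50, seed=0))
        assert (res["p"] == 1.0).all()
        assert (res["z"] == 0.0).all()  # permutation sd is zero

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        X = rng.gamma(2.0, 2.0, size=(6, 3))
        types = ["S", "S", "S", "V", "V", "V"]
        norm = _norm(X, gene_ids=["L", "R", "M"])
        pairs = (("L", "R"), ("M", "R"))
        exact = exhaustive_celltype_p(X, ["L", "R", "M"], types, pairs)
        res = permutation_test_celltype(norm, _ann(types, ["x"] * 6),
                                        LRDatabase(pairs),
                                        PermutationConfig(n_perm=2000, seed=1))
        for _, row in res.iterrows():
            key = (row["sender"], row["receiver"], row["ligand"], row["receptor"])
            assert row["p"] == pytest.approx(exact[key], abs=0.05)

    def test_deterministic_for_fixed_seed(self, normalized):
        norm, ann = normalized
        db = LRDatabase((("g00100", "g00101"),))
        cfg = PermutationConfig(n_perm=100, seed=9)
        a = permutation_test_celltype(norm, ann, db, cfg)
        b = permutation_test_celltype(norm, ann, db, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_single_type_rejected(self):
        norm = _norm(np.ones((4, 2)), gene_ids=["L", "R"])
        with pytest.raises(ValueError, match="cell types"):
            permutation_test_celltype(norm, _ann(["S"] * 4, ["x"] * 4),
                                      LRDatabase((("L", "R"),)))


class TestConditionPermutation:
    def test_sign_flips_p_invariant_under_label_swap(self, normalized):
        norm, ann = normalized
        db = LRDatabase((("g00100", "g00101"),))
        cfg = PermutationConfig(n_perm=200, seed=2)
        fwd = permutation_test_condition(norm, ann, db, cfg,
                                         conditions=("control", "cKO"))
        rev = permutation_test_condition(norm, ann, db, cfg,
                                         conditions=("cKO", "control"))
        assert np.allclose(fwd["lri_diff_score"], -rev["lri_diff_score"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_planted_effect_detected(self, normalized):
        norm, ann = normalized
        db = LRDatabase((("g00100", "g00101"),))
        res = permutation_test_condition(norm, ann, db,
                                         PermutationConfig(n_perm=500, seed=3),
                                         conditions=("control", "cKO"))
        rec = res.set_index(["sender", "receiver"]).loc[("type0", "type1")]
        assert rec["lri_diff_score"] == pytest.approx(2.0, abs=0.4)
        assert rec["p_adj"] <= 0.05


class TestSignificanceFilter:
    def _sets(self):
        lri = pd.DataFrame({
            "sender": ["S"] * 2, "receiver": ["V"] * 2,
            "ligand": ["L1", "L2"], "receptor": ["R1", "R2"],
            "condition": ["control", "control"],
            "p_adj": [0.01, 0.5]})
        diff = pd.DataFrame({
            "sender": ["S"] * 2, "receiver": ["V"] * 2,
            "ligand": ["L1", "L2"], "receptor": ["R1", "R2"],
            "lri_diff_score": [1.5, 2.0], "p_adj": [0.01, 0.01]})
        return lri, diff

    def test_requires_lri_significance_in_one_condition(self):
        lri, diff = self._sets()
        out = significant_interactions(lri, diff)
        assert list(out["ligand"]) == ["L1"]  # L2 fails the LRI p_adj gate

    def test_magnitude_bound(self):
        lri, diff = self._sets()
        diff.loc[0, "lri_diff_score"] = 0.9
        assert significant_interactions(lri, diff).empty

    def test_directional_variant(self):
        lri, diff = self._sets()
        diff.loc[0, "lri_diff_score"] = -1.5
        assert significant_interactions(lri, diff, directional=True).empty
        assert len(significant_interactions(lri, diff, directional=False)) == 1

    def test_empty_inputs(self):
        lri, diff = self._sets()
        out = significant_interactions(lri.iloc[:0], diff.iloc[:0])
        assert out.empty

    def test_count_table_conservation(self):
        lri, diff = self._sets()
        out = significant_interactions(lri, diff)
        table = count_significant_by_pair(out)
        assert table.to_numpy().sum() == len(out)

    def test_count_table_empty(self):
        assert count_significant_by_pair(pd.DataFrame()).empty


class TestMinMax:
    def test_scales_to_unit_interval(self):
        vals = pd.DataFrame({"control": [2.0, 4.0], "cKO": [6.0, 4.0]})
        out = minmax_scale_pairs(vals)
        assert list(out.iloc[0]) == [0.0, 1.0]
        assert list(out.iloc[1]) == [0.0, 0.0]  # constant row convention

    def test_bounds(self):
        rng = np.random.default_rng(10)
        vals = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        out = minmax_scale_pairs(vals)
        assert out.to_numpy().min() >= 0.0 and out.to_numpy().max() <= 1.0
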