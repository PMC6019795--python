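"""Core algorithm: t-statistics against the virtual median cell, the
heterogeneity score, permutation inference, FDR, specificity, Z-score."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import heteropath as hp
from tests.conftest import make_expr


def pooled_sd(a, b):
    """Two-sample pooled standard deviation, written out independently."""
    n1, n2 = len(a), len(b)
    v1 = sum((x - sum(a) / n1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - sum(b) / n2) ** 2 for x in b) / (n2 - 1)
    return math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))


def median(xs):
    xs = sorted(xs)
    n = len(xs)
    return xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2


class TestTissueTStatistics:
    def test_hand_example_two_tissues(self):
        # one gene: {1,2,3} in t1, {4,5,6} in t2
        expr = make_expr([[1, 2, 3, 4, 5, 6]])
        stats = hp.tissue_t_statistics(expr, fc_threshold=1.0)
        m_all = median([1, 2, 3, 4, 5, 6])  # 3.5
        s1 = pooled_sd([1, 2, 3], [1, 2, 3, 4, 5, 6])
        assert stats.m1[0].tolist() == [2.0, 5.0]
        assert stats.m2[0] == m_all
        assert stats.t[0, 0] == pytest.approx((2.0 - 3.5) / (s1 + 1e-8), rel=1e-9)
        assert stats.t[0, 1] == pytest.approx((5.0 - 3.5) / (s1 + 1e-8), rel=1e-9)

    def test_constant_gene_gets_zero(self):
        expr = make_expr([[5.0] * 6])
        stats = hp.tissue_t_statistics(expr, fc_threshold=1.0)
        assert np.all(stats.t == 0)

    def test_zero_numerator_gives_zero_t(self):
        # tissue median equals global median, nonzero variance
        expr = make_expr([[1, 3, 2, 1, 3, 2]])
        stats = hp.tissue_t_statistics(expr, fc_threshold=1.0)
        assert stats.t[0].tolist() == [0.0, 0.0]

    def test_location_shift_invariance(self, planted_fixture):
        expr, _, _ = planted_fixture
        shifted = make_expr(expr.values + 100.0, expr.gene_ids, expr.sample_ids,
                            expr.tissue_of)
        a = hp.tissue_t_statistics(expr)
        b = hp.tissue_t_statistics(shifted)
        np.testing.assert_allclose(a.t, b.t, atol=1e-9)
        np.testing.assert_array_equal(a.pass_fc, b.pass_fc)

    def test_rest_group_mode_differs_but_agrees_in_sign(self):
        expr = make_expr([[1, 2, 3, 7, 8, 9]])
        all_mode = hp.tissue_t_statistics(expr, fc_threshold=1.0, group2="all")
        rest_mode = hp.tissue_t_statistics(expr, fc_threshold=1.0, group2="rest")
        assert np.sign(all_mode.t[0, 0]) == np.sign(rest_mode.t[0, 0])
        assert all_mode.t[0, 0] != rest_mode.t[0, 0]

    def test_single_replicate_fatal(self):
        with pytest.raises(ValueError, match="replicate"):
            hp.TissueDesign(tissues=["a", "b"], replicates={"a": ["s0"], "b": ["s1", "s2"]})

    def test_filter_mask_matches_log2_threshold(self):
        # tissue-vs-global median gaps: 1.0 (passes fc 2) and 0.5 (fails)
        expr = make_expr([[0, 0, 0, 2, 2, 2], [0, 0, 0, 1, 1, 1]])
        stats = hp.tissue_t_statistics(expr, fc_threshold=2.0)
        assert stats.pass_fc[0].tolist() == [True, True]
        assert stats.pass_fc[1].tolist() == [False, False]


class TestHeterogeneityScores:
    def make_stats(self, t, pass_fc, tissues=("t1", "t2")):
        t = np.asarray(t, float)
        return hp.GeneTissueStats(
            gene_ids=[f"g{i}" for i in range(t.shape[0])],
            tissues=list(tissues),
            t=t,
            m1=np.zeros_like(t),
            m2=np.zeros(t.shape[0]),
            s=np.ones_like(t),
            pass_fc=np.asarray(pass_fc, bool),
            fc_threshold=2.0,
        )

    def test_sum_of_absolute_t(self):
        stats = self.make_stats([[3.0, 0.0], [-2.0, 0.0]], [[True, False]] * 2)
        sets = hp.GeneSetCollection(sets={"s": ("", ["g0", "g1"])})
        hs, n = hp.heterogeneity_scores(stats, sets)
        assert hs.loc["s", "t1"] == 5.0  # |+3| + |-2|
        assert hs.loc["s", "t2"] == 0.0
        assert n.loc["s", "t1"] == 2

    def test_all_filtered_scores_zero(self):
        stats = self.make_stats([[3.0, 1.0]], [[False, False]])
        sets = hp.GeneSetCollection(sets={"s": ("", ["g0"])})
        hs, n = hp.heterogeneity_scores(stats, sets)
        assert hs.loc["s"].tolist() == [0.0, 0.0]
        assert n.loc["s"].tolist() == [0, 0]

    def test_unmeasured_set_warns_and_scores_zero(self):
        stats = self.make_stats([[3.0, 1.0]], [[True, True]])
        sets = hp.GeneSetCollection(sets={"ghost": ("", ["nope"])})
        with pytest.warns(UserWarning, match="ghost"):
            hs, _ = hp.heterogeneity_scores(stats, sets)
        assert hs.loc["ghost"].tolist() == [0.0, 0.0]

    def test_additive_over_disjoint_union_and_order_invariant(self, planted_fixture):
        expr, sets, _ = planted_fixture
        stats = hp.tissue_t_statistics(expr)
        a, b = sets.genes("decoy000"), sets.genes("decoy001")
        coll = hp.GeneSetCollection(
            sets={"a": ("", a), "b": ("", b), "ab": ("", a + b),
                  "ab_shuffled": ("", list(reversed(a + b)))}
        )
        hs, _ = hp.heterogeneity_scores(stats, coll)
        np.testing.assert_allclose(hs.loc["ab"], hs.loc["a"] + hs.loc["b"], atol=1e-12)
        np.testing.assert_allclose(hs.loc["ab"], hs.loc["ab_shuffled"], atol=1e-12)

    def test_planted_bidirectional_pathway_ranks_first(self, planted_fixture):
        expr, sets, truth = planted_fixture
        stats = hp.tissue_t_statistics(expr, fc_threshold=2.0)
        hs, _ = hp.heterogeneity_scores(stats, sets)
        assert hs["brain"].idxmax() == "bidir"


def brute_force_permutation_p(values, sizes, set_indices, fc_threshold):
    """Independent oracle: enumerate all distinct assignments of columns to
    labeled tissues and compute the add-one p excluding arrangements whose
    tested-tissue composition equals the observed one."""
    n = values.shape[1]
    fc = math.log2(fc_threshold)

    def hs_for_group(cols, set_idx):
        total = 0.0
        for i in set_idx:
            row = values[i]
            m1 = median([row[c] for c in cols])
            m2 = median(list(row))
            s = pooled_sd([row[c] for c in cols], list(row))
            if (np.var([row[c] for c in cols], ddof=1) < 1e-8
                    and np.var(row, ddof=1) < 1e-8):
                t = 0.0
            else:
                t = (m1 - m2) / (s + 1e-8)
            if abs(m1 - m2) >= fc:
                total += abs(t)
        return total

    def arrangements(idx, szs):
        if len(szs) == 1:
            yield [tuple(idx)]
            return
        for chosen in combinations(idx, szs[0]):
            rest = tuple(i for i in idx if i not in chosen)
            for tail in arrangements(rest, szs[1:]):
                yield [chosen, *tail]

    obs_groups, start = [], 0
    for k in sizes:
        obs_groups.append(tuple(range(start, start + k)))
        start += k

    n_tissues = len(sizes)
    p = np.zeros((len(set_indices), n_tissues))
    for si, set_idx in enumerate(set_indices):
        for j in range(n_tissues):
            hs_obs = hs_for_group(obs_groups[j], set_idx)
            exceed = denom = 0
            for arr in arrangements(tuple(range(n)), list(sizes)):
                if set(arr[j]) == set(obs_groups[j]):
                    continue
                denom += 1
                if hs_for_group(arr[j], set_idx) >= hs_obs:
                    exceed += 1
            p[si, j] = (1 + exceed) / (1 + denom)
    return p


class TestPermutationPvalues:
    def test_matches_brute_force_enumeration_exactly(self):
        # 6 genes, 2 tissues x 2 replicates, 2 gene sets
        rng = np.random.default_rng(42)
        values = rng.normal(5.0, 1.0, size=(6, 4))
        values[0, :2] += 2.0  # give one set some signal
        values[1, :2] -= 2.0
        expr = make_expr(values)
        sets = hp.GeneSetCollection(
            sets={"sA": ("", ["g0", "g1", "g2"]), "sB": ("", ["g3", "g4", "g5"])}
        )
        p, _ = hp.permutation_pvalues(expr, None, sets, fc_threshold=1.5, seed=0)
        expected = brute_force_permutation_p(
            values, [2, 2], [[0, 1, 2], [3, 4, 5]], fc_threshold=1.5
        )
        np.testing.assert_allclose(p.to_numpy(), expected, atol=1e-15)

    def test_zero_hs_gives_p_one(self):
        expr = make_expr(np.full((4, 4), 3.0))
        sets = hp.GeneSetCollection(sets={"s": ("", ["g0", "g1"])})
        p, hs = hp.permutation_pvalues(expr, None, sets, fc_threshold=2.0)
        assert np.all(hs.to_numpy() == 0.0)
        assert np.all(p.to_numpy() == 1.0)

    def test_monte_carlo_close_to_exhaustive(self, planted_fixture):
        expr, sets, _ = planted_fixture
        exact, _ = hp.permutation_pvalues(expr, None, sets, seed=1)
        mc, _ = hp.permutation_pvalues(expr, None, sets, seed=1, n_perm=400,
                                       exhaustive_cap=1)
        planted_exact = exact.loc["bidir", "brain"]
        planted_mc = mc.loc["bidir", "brain"]
        assert planted_mc <= 0.01 and planted_exact <= 0.01

    def test_planted_set_significant_and_decoys_not(self, planted_fixture):
        expr, sets, _ = planted_fixture
        p, hs = hp.permutation_pvalues(expr, None, sets, seed=0)
        assert p.loc["bidir", "brain"] == min(p.to_numpy().ravel())
        assert p.loc["bidir", "brain"] < 0.001
        q = hp.fdr_adjust(p)
        assert q.loc["bidir", "brain"] < 0.05

    def test_bad_n_perm_fatal(self, planted_fixture):
        expr, sets, _ = planted_fixture
        with pytest.raises(ValueError, match="n_perm"):
            hp.permutation_pvalues(expr, None, sets, n_perm=0)


def textbook_bh(p):
    """Step-up BH written from the definition: q_i = min_{j >= i} p_(j) m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = running_min
    return q


class TestFDR:
    def test_all_identical_pvalues(self):
        tab = pd.DataFrame({"t1": [0.3, 0.3], "t2": [0.3, 0.3]})
        assert np.all(hp.fdr_adjust(tab).to_numpy() == pytest.approx(0.3))

    def test_hand_example(self):
        tab = pd.DataFrame({"t": [0.01, 0.02, 0.03, 0.04]})
        np.testing.assert_allclose(hp.fdr_adjust(tab)["t"], [0.04] * 4, atol=1e-15)

    def test_matches_textbook_bh_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 40))
            tab = pd.DataFrame({"t": p})
            np.testing.assert_allclose(
                hp.fdr_adjust(tab)["t"], textbook_bh(p), atol=1e-12
            )


class TestTissueSpecificity:
    def make_stats(self, pass_fc, tissues):
        pass_fc = np.asarray(pass_fc, bool)
        g = pass_fc.shape[0]
        return hp.GeneTissueStats(
            gene_ids=[f"g{i}" for i in range(g)],
            tissues=list(tissues),
            t=np.ones_like(pass_fc, float),
            m1=np.zeros((g, len(tissues))),
            m2=np.zeros(g),
            s=np.ones((g, len(tissues))),
            pass_fc=pass_fc,
            fc_threshold=2.0,
        )

    def test_all_unique_to_one_tissue(self):
        stats = self.make_stats([[1, 0, 0]] * 5, ["brain", "lung", "heart"])
        sets = hp.GeneSetCollection(sets={"s": ("", [f"g{i}" for i in range(5)])})
        assert hp.tissue_specificity(stats, sets)["s"] == "brain"

    def test_exactly_sixty_percent_meets_threshold(self):
        # 5 elements: 3 unique to lung, 2 unique to heart -> lung at 60%
        mask = [[0, 1, 0]] * 3 + [[0, 0, 1]] * 2
        stats = self.make_stats(mask, ["brain", "lung", "heart"])
        sets = hp.GeneSetCollection(sets={"s": ("", [f"g{i}" for i in range(5)])})
        assert hp.tissue_specificity(stats, sets)["s"] == "lung"

    def test_below_threshold_gets_none(self):
        # 4 elements: 2 unique to lung, 2 passing in two tissues -> 50% < 60%
        mask = [[0, 1, 0]] * 2 + [[1, 1, 0]] * 2
        stats = self.make_stats(mask, ["brain", "lung", "heart"])
        sets = hp.GeneSetCollection(sets={"s": ("", [f"g{i}" for i in range(4)])})
        assert hp.tissue_specificity(stats, sets)["s"] is None

    def test_no_heterogeneous_elements_gets_none(self):
        stats = self.make_stats([[0, 0]] * 3, ["t1", "t2"])
        sets = hp.GeneSetCollection(sets={"s": ("", ["g0", "g1", "g2"])})
        assert hp.tissue_specificity(stats, sets)["s"] is None


class TestPathwayZscore:
    def test_formula_recomputed_independently(self, planted_fixture):
        expr, sets, _ = planted_fixture
        z = hp.pathway_zscore(expr, None, sets)
        design = expr.design()
        for tissue in design.tissues:
            cols = design.replicates[tissue]
            fc = expr.data[cols].median(axis=1) - expr.data.median(axis=1)
            mu, sigma = fc.mean(), fc.std(ddof=1)
            for name in ["bidir", "decoy000"]:
                genes = sets.genes(name)
                expected = (fc.loc[genes].mean() - mu) * math.sqrt(len(genes)) / sigma
                assert z.loc[name, tissue] == pytest.approx(expected, abs=1e-12)

    def test_zero_when_set_mean_equals_global_mean(self):
        values = np.zeros((4, 4))
        values[:, 2:] = [[1], [1], [3], [3]]  # all genes same fc within tissue? no:
        expr = make_expr(values)
        # set {g0, g3}: fc (1, 3) mean 2 == global mean of (1,1,3,3)
        sets = hp.GeneSetCollection(sets={"s": ("", ["g0", "g3"])})
        z = hp.pathway_zscore(expr, None, sets)
        assert z.loc["s", "t2"] == pytest.approx(0.0, abs=1e-12)

    def test_duplicating_members_scales_by_sqrt2(self, planted_fixture):
        expr, sets, _ = planted_fixture
        genes = sets.genes("decoy000")
        dup_ids = [g + "_dup" for g in genes]
        data = pd.concat([expr.data, expr.data.loc[genes].set_axis(dup_ids)])
        expr2 = hp.ExpressionMatrix(data=data, tissue_of=expr.tissue_of)
        coll = hp.GeneSetCollection(
            sets={"single": ("", genes), "double": ("", genes + dup_ids)}
        )
        z = hp.pathway_zscore(expr2, None, coll)
        np.testing.assert_allclose(
            z.loc["double"], z.loc["single"] * math.sqrt(2), atol=1e-9
        )

    def test_mean_zero_bidirectional_plant_has_small_z(self, planted_fixture):
        expr, sets, _ = planted_fixture
        z = hp.pathway_zscore(expr, None, sets)
        assert abs(z.loc["bidir", "brain"]) < 1.96


class TestRunHeteropath:
    def test_end_to_end_on_planted_fixture(self, planted_fixture):
        expr, sets, _ = planted_fixture
        table = hp.run_heteropath(expr, None, sets, hp.HeteroPathParams(seed=3))
        brain = table[table["tissue"] == "brain"].reset_index(drop=True)
        assert brain.loc[0, "set"] == "bidir"  # ranked first by HS
        assert brain.loc[0, "q"] < 0.05
        assert abs(brain.loc[0, "z"]) < 1.96
        assert brain.loc[0, "specific_tissue"] == "brain"
        # sorted by HS descending within each tissue
        for _, grp in table.groupby("tissue"):
            assert grp["hs"].is_monotonic_decreasing

    def test_empty_collection_warns_and_returns_empty(self, planted_fixture):
        expr, _, _ = planted_fixture
        with pytest.warns(UserWarning, match="empty"):
            out = hp.run_heteropath(expr, None, hp.GeneSetCollection(sets={}))
        assert out.empty
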