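import math

import numpy as np
import pandas as pd
import pytest

from scmetaboscape import enrichment as en
from scmetaboscape.io import DataError, ExpressionMatrix, PathwayCollection


def _expr(values, units="lognorm"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"c{i}" for i in range(values.shape[1])],
        units=units,
    )


# ---------------------------------------------------------------------------
# independent GSVA oracle: naive loops over the definition


def oracle_gsva(values, set_indices, tau=1.0, kernel="gaussian", max_diff=True):
    """Brute-force kernel-CDF + rank statistic + KS random walk, one score
    per cell, written with scalar loops only."""
    n_genes = len(values)
    n_cells = len(values[0])
    # 1. per-gene cumulative density statistic
    z = [[0.0] * n_cells for _ in range(n_genes)]
    for g in range(n_genes):
        x = values[g]
        mean = sum(x) / n_cells
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n_cells)
        if kernel == "gaussian":
            h = sd / 4.0
            for j in range(n_cells):
                if h <= 0:
                    z[g][j] = 0.5
                else:
                    z[g][j] = sum(
                        0.5 * (1 + math.erf((x[j] - x[k]) / (h * math.sqrt(2))))
                        for k in range(n_cells)
                    ) / n_cells
        elif kernel == "ecdf":
            for j in range(n_cells):
                less = sum(1 for k in range(n_cells) if x[k] < x[j])
                eq = sum(1 for k in range(n_cells) if x[k] == x[j])
                z[g][j] = (less + (eq + 1) / 2.0) / n_cells
    # 2. per-cell ordering by decreasing z, ties by gene index
    scores = []
    member = [g in set_indices for g in range(n_genes)]
    n_out = n_genes - len(set_indices)
    for j in range(n_cells):
        order = sorted(range(n_genes), key=lambda g: (-z[g][j], g))
        # symmetric rank statistic: position k (0-based) -> |(p - k) - p/2|
        stat = [abs((n_genes - k) - n_genes / 2.0) for k in range(n_genes)]
        denom = sum(stat[k] ** tau for k in range(n_genes) if member[order[k]])
        v = 0.0
        vmax = -math.inf
        vmin = math.inf
        for k in range(n_genes):
            if member[order[k]]:
                v += (stat[k] ** tau) / denom
            else:
                v -= 1.0 / n_out
            vmax = max(vmax, v)
            vmin = min(vmin, v)
        if max_diff:
            scores.append(max(vmax, 0.0) + min(vmin, 0.0))
        else:
            scores.append(vmax if abs(vmax) >= abs(vmin) else vmin)
    return scores


class TestGsva:
    def test_identical_cells_get_identical_scores(self):
        col = np.arange(1.0, 11.0)
        expr = _expr(np.column_stack([col, col, col + 1]))
        pw = PathwayCollection({"S": ["g0", "g1", "g2"]})
        sc = en.gsva_scores(expr, pw).scores
        assert sc.iloc[0, 0] == sc.iloc[0, 1]

    def test_top_ranked_set_scores_positive(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (10, 5))
        X[:3, 0] += 10.0  # set genes at the top of cell 0's ranking
        expr = _expr(X)
        pw = PathwayCollection({"top": ["g0", "g1", "g2"]})
        sc = en.gsva_scores(expr, pw).scores
        assert sc.iloc[0, 0] > 0

    @pytest.mark.parametrize("kernel", ["gaussian", "ecdf"])
    @pytest.mark.parametrize("instance_seed", range(10))
    def test_oracle_equivalence_small_instances(self, instance_seed, kernel):
        """Vectorized scores equal the naive kernel-CDF + random-walk
        implementation to 1e-9 on random <=20 genes x <=5 cells instances."""
        rng = np.random.default_rng(instance_seed)
        n_genes = int(rng.integers(5, 21))
        n_cells = int(rng.integers(2, 6))
        X = rng.gamma(2.0, 1.0, (n_genes, n_cells))
        size = int(rng.integers(3, max(4, n_genes // 2)))
        member = sorted(rng.choice(n_genes, size=size, replace=False).tolist())
        expr = _expr(X)
        pw = PathwayCollection({"S": [f"g{i}" for i in member]})
        got = en.gsva_scores(expr, pw, kernel=kernel).scores.values[0]
        want = oracle_gsva(X.tolist(), set(member), kernel=kernel)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_monotone_transformation_invariance_ecdf(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2.0, 1.0, (15, 6))
        pw = PathwayCollection({"S": ["g1", "g4", "g7", "g9"]})
        base = en.gsva_scores(_expr(X), pw, kernel="ecdf").scores
        # strictly monotone per-gene maps: exp, sqrt-shift, cubic
        Y = X.copy()
        Y[::3] = np.exp(Y[::3])
        Y[1::3] = np.sqrt(Y[1::3] + 1.0)
        Y[2::3] = Y[2::3] ** 3
        mapped = en.gsva_scores(_expr(Y), pw, kernel="ecdf").scores
        pd.testing.assert_frame_equal(base, mapped)

    def test_constant_rows_dropped_small_pathway_skipped(self):
        X = np.vstack([np.ones(4), np.arange(4.0), np.arange(4.0) * 2,
                       np.arange(4.0) + 3, np.arange(4.0) ** 2])
        expr = _expr(X)
        pw = PathwayCollection({"ok": ["g1", "g2", "g3"], "tiny": ["g0", "g1"]})
        sc = en.gsva_scores(expr, pw)
        assert sc.scores.index.tolist() == ["ok"]


class TestAucRanking:
    def test_identical_distributions_auc_half(self):
        expr = _expr(np.array([[1.0, 2.0, 1.0, 2.0]]))
        r = en.rank_genes_auc(expr, np.array([True, True, False, False]),
                              np.array([False, False, True, True]))
        assert r.statistic.iloc[0] == pytest.approx(0.0)

    def test_complete_separation(self):
        expr = _expr(np.array([[3.0, 4.0, 1.0, 2.0]]))
        r = en.rank_genes_auc(expr, np.array([True, True, False, False]),
                              np.array([False, False, True, True]))
        assert r.statistic.iloc[0] == pytest.approx(0.5)  # AUC 1.0

    def test_enumerated_pairs(self):
        # a={1,3}, b={2,4}: only (3,2) of 4 pairs has a > b -> AUC 0.25
        expr = _expr(np.array([[1.0, 3.0, 2.0, 4.0]]))
        r = en.rank_genes_auc(expr, np.array([True, True, False, False]),
                              np.array([False, False, True, True]))
        assert r.statistic.iloc[0] == pytest.approx(-0.25)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(0, 1, (20, 12)))
        a = np.zeros(12, bool)
        a[:5] = True
        r1 = en.rank_genes_auc(expr, a, ~a).statistic.sort_index()
        r2 = en.rank_genes_auc(expr, ~a, a).statistic.sort_index()
        np.testing.assert_allclose(r1.values + r2.values, 0.0, atol=1e-12)


class TestPrerankedGsea:
    def _ranked(self):
        stats = pd.Series(np.arange(10, 0, -1, dtype=float) / 10,
                          index=[f"g{i}" for i in range(10)])
        return en.RankedGeneList(stats)

    def test_top_block_matches_brute_force_walk(self):
        ranked = self._ranked()
        sets = PathwayCollection({"top3": ["g0", "g1", "g2"]})
        res = en.preranked_gsea(ranked, sets, n_perm=200, seed=1)
        s = ranked.statistic.values
        member = np.zeros(10, bool)
        member[:3] = True
        hit = np.cumsum(np.where(member, np.abs(s), 0)) / np.abs(s[member]).sum()
        miss = np.cumsum(~member) / 7
        walk = hit - miss
        want = walk[np.argmax(np.abs(walk))]
        assert res.table.loc["top3", "es"] == pytest.approx(want, abs=1e-12)
        assert res.leading_edge["top3"] == ["g0", "g1", "g2"]

    def test_whole_ranking_set_flagged_undefined(self):
        ranked = self._ranked()
        sets = PathwayCollection({"all": [f"g{i}" for i in range(10)]})
        res = en.preranked_gsea(ranked, sets, n_perm=100, seed=1)
        assert np.isnan(res.table.loc["all", "es"])

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(5)
        stats = pd.Series(rng.normal(0, 1, 30), index=[f"g{i}" for i in range(30)])
        sets = PathwayCollection({"S": [f"g{i}" for i in range(0, 30, 4)]})
        res_f = en.preranked_gsea(en.RankedGeneList(stats), sets, n_perm=100, seed=2)
        res_r = en.preranked_gsea(en.RankedGeneList(-stats), sets, n_perm=100, seed=2)
        assert res_f.table.loc["S", "es"] == pytest.approx(
            -res_r.table.loc["S", "es"], abs=1e-12
        )


class TestViWilcoxon:
    def _dataset(self, effect=4.0, seed=0):
        rng = np.random.default_rng(seed)
        n_genes, n_cells = 300, 500
        X = rng.lognormal(1, 1, (n_genes, n_cells))
        labels = np.array(["k0"] * 250 + ["k1"] * 250)
        X[:25, labels == "k0"] *= effect
        ids = [f"c{i}" for i in range(n_cells)]
        expr = ExpressionMatrix(
            np.log1p(X), [f"g{i}" for i in range(n_genes)], ids,
            pd.DataFrame({"cluster": labels}, index=ids), units="lognorm",
        )
        sets = PathwayCollection(
            {"planted": [f"g{i}" for i in range(25)],
             "background": [f"g{i}" for i in range(100, 125)]}
        )
        return expr, sets

    def test_planted_set_detected(self):
        expr, sets = self._dataset()
        out = en.vi_wilcoxon_gene_set_test(expr, "cluster", sets)
        row = out[(out["cluster"] == "k0") & (out["set"] == "planted")].iloc[0]
        assert row["statistic"] > 0
        assert row["q"] < 0.05

    def test_null_sets_calibrated(self):
        rng = np.random.default_rng(9)
        n_genes, n_cells = 400, 200
        X = np.log1p(rng.lognormal(1, 1, (n_genes, n_cells)))
        labels = rng.permutation(np.array(["k0"] * 100 + ["k1"] * 100))
        ids = [f"c{i}" for i in range(n_cells)]
        expr = ExpressionMatrix(X, [f"g{i}" for i in range(n_genes)], ids,
                                pd.DataFrame({"cluster": labels}, index=ids),
                                units="lognorm")
        sets = PathwayCollection(
            {f"S{k}": [f"g{i}" for i in range(k * 10, k * 10 + 10)] for k in range(40)}
        )
        out = en.vi_wilcoxon_gene_set_test(expr, "cluster", sets)
        frac = (out["p"] < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(out))

    def test_identical_clusters_zero_statistic(self):
        X = np.log1p(np.tile(np.arange(1.0, 21.0)[:, None], (1, 20)))
        ids = [f"c{i}" for i in range(20)]
        expr = ExpressionMatrix(X, [f"g{i}" for i in range(20)], ids,
                                pd.DataFrame({"cluster": ["a", "b"] * 10}, index=ids),
                                units="lognorm")
        sets = PathwayCollection({"S": ["g0", "g1", "g2", "g3"]})
        out = en.vi_wilcoxon_gene_set_test(expr, "cluster", sets)
        assert (out["median_log2fc"] == 0).all()
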