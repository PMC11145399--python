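import numpy as np
import pandas as pd
import pytest

from scmetaboscape import pathway_activity as pa
from scmetaboscape import simulate
from scmetaboscape.io import DataError, ExpressionMatrix, PathwayCollection
from scmetaboscape.preprocess import normalize, size_factors


def brute_force_scores(expr_values, gene_ids, labels, pathways, min_genes=3):
    """Independent weighted-mean oracle: plain python loops over the
    definition — per-type gene means, relative expression against the
    unweighted cross-type average, then a 1/multiplicity-weighted mean."""
    types = sorted(set(labels))
    means = {}
    for t in types:
        cols = [j for j, l in enumerate(labels) if l == t]
        means[t] = [
            sum(expr_values[g][j] for j in cols) / len(cols)
            for g in range(len(gene_ids))
        ]
    mult = {}
    for genes in pathways.values():
        for g in genes:
            mult[g] = mult.get(g, 0) + 1
    out = {}
    for name, genes in pathways.items():
        out[name] = {}
        for t in types:
            num = den = 0.0
            used = 0
            for g in genes:
                if g not in gene_ids:
                    continue
                gi = gene_ids.index(g)
                avg = sum(means[tt][gi] for tt in types) / len(types)
                if avg == 0:
                    continue
                r = means[t][gi] / avg
                w = 1.0 / mult[g]
                num += w * r
                den += w
                used += 1
            out[name][t] = num / den if used >= min_genes else float("nan")
    return out


class TestRelativeExpression:
    def test_celltype_means_hand_values(self, toy_expr):
        means = pa.celltype_means(toy_expr)
        assert means.loc["g1", "A"] == 3.0
        assert means.loc["g1", "B"] == 6.0

    def test_single_type_rejected(self, toy_expr):
        means = pa.celltype_means(toy_expr)[["A"]]
        with pytest.raises(DataError):
            pa.relative_expression(means)

    def test_hand_arithmetic(self):
        means = pd.DataFrame({"A": [2.0], "B": [4.0]}, index=["g"])
        rel = pa.relative_expression(means)
        assert rel.loc["g", "A"] == pytest.approx(2 / 3)
        assert rel.loc["g", "B"] == pytest.approx(4 / 3)

    def test_row_average_is_one(self, toy_expr):
        rel = pa.relative_expression(pa.celltype_means(toy_expr))
        finite = rel.dropna()
        np.testing.assert_allclose(finite.mean(axis=1).values, 1.0, atol=1e-12)

    def test_all_zero_gene_undefined(self):
        means = pd.DataFrame({"A": [0.0], "B": [0.0]}, index=["g"])
        rel = pa.relative_expression(means)
        assert rel.isna().all().all()


class TestPathwayScores:
    def test_hand_computed_toy(self):
        # P = {g1 (shared with Q, w=1/2), g2 (exclusive, w=1)}
        rel = pd.DataFrame(
            {"A": [2 / 3, 0.5], "B": [4 / 3, 1.5]}, index=["g1", "g2"]
        )
        pw = PathwayCollection({"P": ["g1", "g2"], "Q": ["g1"]})
        tab = pa.pathway_scores(rel, pw, outlier_rule=None, min_genes=1)
        assert tab.score.loc["P", "A"] == pytest.approx(5 / 9, abs=1e-12)
        assert tab.score.loc["P", "B"] == pytest.approx(13 / 9, abs=1e-12)

    def test_uniform_relative_expression_scores_one(self):
        rel = pd.DataFrame(np.ones((6, 3)), index=[f"g{i}" for i in range(6)],
                           columns=list("ABC"))
        pw = PathwayCollection({"P": ["g0", "g1", "g2"], "Q": ["g3", "g4", "g5"]})
        tab = pa.pathway_scores(rel, pw)
        np.testing.assert_allclose(tab.score.values, 1.0)

    def test_unmeasured_pathway_is_nan_not_zero(self):
        rel = pd.DataFrame(np.ones((3, 2)), index=["g0", "g1", "g2"],
                           columns=["A", "B"])
        pw = PathwayCollection({"P": ["x1", "x2", "x3"], "Q": ["g0", "g1", "g2"]})
        tab = pa.pathway_scores(rel, pw)
        assert tab.score.loc["P"].isna().all()
        assert tab.score.loc["Q"].notna().all()

    def test_weighted_mean_bounds(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(
            rng.uniform(0.1, 3.0, (8, 3)), index=[f"g{i}" for i in range(8)],
            columns=list("ABC"),
        )
        pw = PathwayCollection({"P": [f"g{i}" for i in range(8)]})
        tab = pa.pathway_scores(rel, pw, outlier_rule=None)
        for t in "ABC":
            assert rel[t].min() - 1e-12 <= tab.score.loc["P", t] <= rel[t].max() + 1e-12

    def test_scale_invariance(self, toy_expr, toy_pathways):
        obs1 = pa.score_pipeline(toy_expr, toy_pathways, outlier_rule=None)
        scaled = toy_expr.with_values(toy_expr.values * 7.3)
        obs2 = pa.score_pipeline(scaled, toy_pathways, outlier_rule=None)
        pd.testing.assert_frame_equal(obs1.score, obs2.score)

    @pytest.mark.parametrize("instance_seed", range(25))
    def test_oracle_equivalence_random_instances(self, instance_seed):
        """Scores on small random instances match a brute-force weighted
        mean to 1e-12 (overlapping pathways exercise the weights)."""
        rng = np.random.default_rng(instance_seed)
        n_genes = rng.integers(4, 11)
        n_types = rng.integers(2, 5)
        n_cells = int(n_types * rng.integers(2, 5))
        gene_ids = [f"g{i}" for i in range(n_genes)]
        labels = [f"T{i % n_types}" for i in range(n_cells)]
        values = rng.gamma(2.0, 1.0, (n_genes, n_cells))
        pwdict = {}
        for p in range(rng.integers(1, 4)):
            size = int(rng.integers(3, n_genes + 1))
            members = list(rng.choice(gene_ids, size=size, replace=False))
            pwdict[f"P{p}"] = members
        pw = PathwayCollection(pwdict)
        expr = ExpressionMatrix(
            values, gene_ids, [f"c{i}" for i in range(n_cells)],
            pd.DataFrame({"cell_type": labels}, index=[f"c{i}" for i in range(n_cells)]),
            units="normalized",
        )
        tab = pa.score_pipeline(expr, pw, outlier_rule=None)
        oracle = brute_force_scores(values.tolist(), gene_ids, labels, pwdict)
        for name in pw.names:
            for t in tab.score.columns:
                got = tab.score.loc[name, t]
                want = oracle[name][t]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)


@pytest.fixture(scope="module")
def null_data():
    cfg = simulate.SimulationConfig(
        n_genes=400, n_cells=400, n_cell_types=3, n_pathways=10,
        genes_per_pathway=12, planted_split_fraction=0.0, seed=17,
    )
    expr, truth = simulate.simulate_counts(cfg)
    f = size_factors(expr, method="deconvolution")
    return normalize(expr, f), truth


class TestPermutationTest:
    def test_score_one_gives_p_one(self):
        # all genes identical across types -> every score exactly 1
        ids = [f"c{i}" for i in range(40)]
        anno = pd.DataFrame({"cell_type": ["A", "B"] * 20}, index=ids)
        values = np.tile(np.arange(1.0, 9.0)[:, None], (1, 40))
        expr = ExpressionMatrix(values, [f"g{i}" for i in range(8)], ids, anno,
                                units="normalized")
        pw = PathwayCollection({"P": [f"g{i}" for i in range(4)]})
        obs = pa.score_pipeline(expr, pw, outlier_rule=None)
        assert obs.score.loc["P"].tolist() == [1.0, 1.0]
        tab = pa.permutation_test(expr, pw, obs, n_perm=100, seed=0, outlier=False)
        assert (tab.p_value.loc["P"] == 1.0).all()

    def test_q_at_least_p_and_in_unit_interval(self, null_data):
        norm, truth = null_data
        obs = pa.score_pipeline(norm, truth.pathways)
        tab = pa.permutation_test(norm, truth.pathways, obs, n_perm=100, seed=1)
        p = tab.p_value.values
        q = tab.q_value.values
        ok = np.isfinite(p)
        assert ((p[ok] >= 0) & (p[ok] <= 1)).all()
        assert (q[ok] + 1e-12 >= p[ok]).all()

    def test_null_pvalues_super_uniform(self, null_data):
        """On exchangeable labels the permutation p-values are (super-)
        uniform: empirical CDF at fixed thresholds must not exceed the
        threshold by more than binomial noise."""
        norm, truth = null_data
        obs = pa.score_pipeline(norm, truth.pathways)
        tab = pa.permutation_test(norm, truth.pathways, obs, n_perm=200, seed=2)
        p = tab.p_value.values.ravel()
        p = p[np.isfinite(p)]
        for thr in (0.05, 0.1, 0.25):
            frac = (p < thr).mean()
            # 3 sigma binomial slack
            assert frac <= thr + 3 * np.sqrt(thr * (1 - thr) / len(p))

    def test_n_perm_minimum_enforced(self, toy_expr, toy_pathways):
        obs = pa.score_pipeline(toy_expr, toy_pathways)
        with pytest.raises(Exception):
            pa.permutation_test(toy_expr, toy_pathways, obs, n_perm=10)


class TestHeatTable:
    def test_mask_rule_and_join(self):
        score = pd.DataFrame({"A": [2.0, 1.1]}, index=["P", "Q"])
        q = pd.DataFrame({"A": [0.01, 0.2]}, index=["P", "Q"])
        tumor = pa.ActivityTable(score=score, p_value=q, q_value=q, condition="tumor")
        out = pa.activity_heat_table(tumor, q_max=0.05)
        kept = out[out["pathway"] == "P"]["score"].iloc[0]
        masked = out[out["pathway"] == "Q"]["score"].iloc[0]
        assert kept == 2.0
        assert np.isnan(masked)
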