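import numpy as np
import pandas as pd
import pytest

from scmetaboscape import preprocess, simulate
from scmetaboscape.io import ConfigError, DataError, ExpressionMatrix
from scmetaboscape.preprocess import (
    QCThresholds,
    fit_dropout_model,
    impute_dropouts,
    normalize,
    qc_filter_cells,
    size_factors,
)


def _expr(values, gene_prefix="G", anno=None, units="counts"):
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    cells = [f"c{i}" for i in range(values.shape[1])]
    if anno is not None:
        anno = pd.DataFrame(anno, index=cells)
    return ExpressionMatrix(values, genes, cells, anno, units=units)


class TestQC:
    def _matrix(self):
        # 600 genes so detected-gene counts can straddle 500; one mito gene
        rng = np.random.default_rng(0)
        X = rng.poisson(3.0, (600, 4)).astype(float) + 1.0  # all detected
        genes = [f"G{i}" for i in range(599)] + ["MT-CO1"]
        cells = ["good", "few_genes", "few_umis", "mito_heavy"]
        X[:, 0] = 2.0
        X[100:, 1] = 0.0        # 100 detected genes only
        X[:, 2] = 0.0
        X[:5, 2] = 1.0          # tiny library but below min_genes too
        X[:, 3] = 1.0
        X[-1, 3] = 600.0        # mito fraction 600/1199 > 0.2
        return ExpressionMatrix(X, genes, cells)

    def test_thresholds_remove_failing_cells(self):
        expr = self._matrix()
        kept, report = qc_filter_cells(
            expr, QCThresholds(min_genes=500, min_umis=1000, max_mito_fraction=0.2)
        )
        assert list(kept.column_ids) == ["good"]
        assert report.n_kept == 1

    def test_boundary_is_inclusive(self):
        # exactly 500 genes detected, exactly 1000 UMIs, exactly 20% mito
        X = np.zeros((600, 1))
        X[:499] = 1.6032064128256513  # 499 * x + 200 = 1000 -> x = 800/499
        X[:499] = 800.0 / 499.0
        X[599] = 200.0  # mito gene: 200/1000 = 0.2
        genes = [f"G{i}" for i in range(599)] + ["MT-CO1"]
        expr = ExpressionMatrix(X, genes, ["cell"])
        kept, _ = qc_filter_cells(
            expr, QCThresholds(min_genes=500, min_umis=1000, max_mito_fraction=0.2)
        )
        assert list(kept.column_ids) == ["cell"]

    def test_499_genes_removed(self):
        X = np.zeros((600, 1))
        X[:499] = 10.0
        genes = [f"G{i}" for i in range(600)]
        expr = ExpressionMatrix(X, genes, ["cell"])
        with pytest.raises(DataError):
            qc_filter_cells(expr, QCThresholds(min_genes=500, min_umis=1000))

    def test_idempotent(self):
        expr = self._matrix()
        t = QCThresholds(min_genes=500, min_umis=1000, max_mito_fraction=0.2)
        once, _ = qc_filter_cells(expr, t)
        twice, report = qc_filter_cells(once, t)
        assert report.n_kept == once.n_columns
        np.testing.assert_array_equal(once.values, twice.values)


class TestSizeFactors:
    def test_identical_cells_all_methods_unity(self):
        X = np.tile(np.arange(1.0, 31.0)[:, None], (1, 30))
        expr = _expr(X)
        for method in ("RLE", "upperquartile", "TMM", "deconvolution"):
            f = size_factors(expr, method=method)
            np.testing.assert_allclose(f.values, 1.0, atol=1e-8)

    def test_rle_single_scaled_cell_recovers_ratio(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(1, 0.5, 50)
        X = np.tile(base[:, None], (1, 5))
        X[:, 2] *= 3.0
        f = size_factors(_expr(X), method="RLE")
        ratio = f.values[2] / f.values[0]
        assert ratio == pytest.approx(3.0, rel=1e-9)

    def test_scale_equivariance_ratio(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(10.0, (100, 8)).astype(float) + 1.0
        c = 2.5
        Xs = X.copy()
        Xs[:, 3] *= c
        for method in ("RLE", "upperquartile"):
            f0 = size_factors(_expr(X), method=method).values
            f1 = size_factors(_expr(Xs), method=method).values
            assert f1[3] / f1[0] == pytest.approx(c * f0[3] / f0[0], rel=1e-9)

    def test_deconvolution_recovers_lognormal_factors(self):
        cfg = simulate.SimulationConfig(
            n_genes=2000, n_cells=500, n_cell_types=1, n_pathways=5,
            genes_per_pathway=10, planted_split_fraction=0.0,
            library_size_lognorm=(0.0, 0.5), dropout=False,
            base_mean_scale=4.0, dispersion_lognorm=(-0.7, 0.3), seed=5,
        )
        expr, truth = simulate.simulate_counts(cfg)
        sf = size_factors(expr, method="deconvolution")
        truth_f = truth.true_size_factor.values
        r = np.corrcoef(sf.values, truth_f)[0, 1]
        rel_err = np.median(np.abs(sf.values - truth_f) / truth_f)
        assert r > 0.95
        assert rel_err < 0.05

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            size_factors(_expr(np.ones((3, 3))), method="median-of-medians")


class TestNormalize:
    def test_unit_factors_are_identity(self):
        expr = _expr([[2.0, 4.0], [6.0, 8.0]])
        f = size_factors(_expr(np.ones((5, 2)) * [[1, 1]]), method="upperquartile")
        out = normalize(expr, f)
        np.testing.assert_array_equal(out.values, expr.values)

    def test_division_and_log(self):
        expr = _expr([[2.0], [4.0]])
        f = preprocess.SizeFactors(pd.Series([2.0], index=expr.column_ids), "manual")
        out = normalize(expr, f)
        np.testing.assert_array_equal(out.values[:, 0], [1.0, 2.0])
        logged = normalize(_expr([[0.0]]),
                           preprocess.SizeFactors(pd.Series([1.0], index=["c0"]), "m"),
                           log_transform=True)
        assert logged.values[0, 0] == 0.0

    def test_nonpositive_factor_rejected(self):
        expr = _expr([[1.0]])
        with pytest.raises(DataError):
            preprocess.SizeFactors(pd.Series([0.0], index=expr.column_ids), "m")


@pytest.fixture(scope="module")
def dropout_dataset():
    cfg = simulate.SimulationConfig(
        n_genes=300, n_cells=250, n_cell_types=1, n_samples=1,
        n_pathways=5, genes_per_pathway=10, planted_split_fraction=0.0,
        base_mean_shape=8.0, base_mean_scale=3.0,
        dispersion_lognorm=(-1.2, 0.3),
        dropout_midpoint=2.9, dropout_slope=1.5, seed=7,
    )
    return simulate.simulate_counts(cfg)


class TestDropoutModel:
    def test_constant_positive_gene_has_no_dropout(self):
        X = np.ones((12, 30)) * 5.0
        model = fit_dropout_model(_expr(X, anno={"sample": ["s"] * 30}))
        np.testing.assert_allclose(model.dropout_probability, 0.0, atol=1e-6)

    def test_all_zero_gene_flagged_unimputable(self):
        X = np.ones((12, 30)) * 5.0
        X[3] = 0.0
        model = fit_dropout_model(_expr(X, anno={"sample": ["s"] * 30}))
        assert (model.dropout_probability[3] == 1.0).all()
        assert model.unimputable.iloc[3, 0]

    def test_small_group_skipped(self):
        X = np.ones((5, 5)) * 2.0
        model = fit_dropout_model(_expr(X, anno={"sample": ["s"] * 5}))
        assert model.skipped_groups == ["s"]

    def test_known_dropout_rate_recovered(self, dropout_dataset):
        expr, truth = dropout_dataset
        model = fit_dropout_model(expr, groups="sample")
        true_rate = truth.true_dropout_mask.mean()
        est_rate = model.dropout_probability.mean()
        assert abs(est_rate - true_rate) < 0.10

    def test_type_one_error_on_dropout_free_data(self):
        cfg = simulate.SimulationConfig(
            n_genes=300, n_cells=250, n_cell_types=1, n_samples=1,
            n_pathways=5, genes_per_pathway=10, planted_split_fraction=0.0,
            base_mean_shape=8.0, base_mean_scale=3.0,
            dispersion_lognorm=(-1.2, 0.3), dropout=False, seed=8,
        )
        expr, _ = simulate.simulate_counts(cfg)
        model = fit_dropout_model(expr, groups="sample")
        assert (model.dropout_probability > 0.5).mean() < 0.02

    def test_imputation_leaves_reliable_entries_untouched(self, dropout_dataset):
        expr, _ = dropout_dataset
        model = fit_dropout_model(expr, groups="sample")
        imp = impute_dropouts(expr, model, drop_thre=0.5, apply_gene_gate=False)
        reliable = model.dropout_probability <= 0.5
        np.testing.assert_array_equal(imp.values[reliable], expr.values[reliable])
        assert (imp.values >= 0).all()

    def test_imputation_improves_over_raw_zeros(self, dropout_dataset):
        expr, truth = dropout_dataset
        model = fit_dropout_model(expr, groups="sample")
        imp = impute_dropouts(expr, model, apply_gene_gate=False)
        mask = truth.true_dropout_mask
        lat = np.log1p(truth.pre_dropout_counts[mask])
        r_imp = np.corrcoef(np.log1p(imp.values[mask]), lat)[0, 1]
        # raw zeros are constant on masked entries: correlation 0 by definition
        assert r_imp > 0.2

    def test_no_dropout_model_means_identity(self):
        X = np.ones((12, 30)) * 5.0
        expr = _expr(X, anno={"sample": ["s"] * 30})
        model = fit_dropout_model(expr)
        imp = impute_dropouts(expr, model, apply_gene_gate=False)
        np.testing.assert_array_equal(imp.values, expr.values)
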