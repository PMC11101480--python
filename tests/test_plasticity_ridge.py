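"""Ridge solver, LOOCV penalty selection, training, projection.

The independent oracles: an explicit matrix-inverse primal solve, n explicit
leave-one-out refits, and scikit-learn's Ridge as an external cross-check.
"""

import numpy as np
import pandas as pd
import pytest

from emtridge.containers import ExpressionMatrix, PhenotypeTable
from emtridge.exceptions import CoverageError, ValidationError
from emtridge.plasticity_ridge import (
    RidgeModel,
    average_replicates,
    fit_ridge,
    loocv_predictions,
    loocv_select_lambda,
    predict_scores,
    top_coefficient_genes,
    train_phenotype_model,
)

CONCORDANT = ("morphology", "CDH2", "ZEB1")


def primal_oracle(X, y, lam):
    """Explicit matrix-inverse ridge on centered data (test-side oracle)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Xc = X - X.mean(0)
    yc = y - y.mean()
    p = X.shape[1]
    return np.linalg.inv(Xc.T @ Xc + lam * np.eye(p)) @ Xc.T @ yc


def explicit_loocv_mse(X, y, lam):
    """n explicit leave-one-out refits (test-side oracle)."""
    n = len(y)
    errs = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        fit = fit_ridge(X[mask], y[mask], lam)
        errs.append((y[i] - fit.fitted(X[i : i + 1])[0]) ** 2)
    return float(np.mean(errs))


class TestFitRidge:
    def test_single_gene_closed_form(self):
        x = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([-1.0, 0.0, 1.0])
        assert fit_ridge(x, y, 1.0).coefficients[0] == pytest.approx(2.0 / 3.0)
        assert fit_ridge(x, y, 0.0).coefficients[0] == pytest.approx(1.0)

    def test_matches_matrix_inverse_oracle(self, rng):
        for n, p in [(4, 5), (10, 3), (8, 50), (50, 50)]:
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = fit_ridge(X, y, 0.5)
            assert np.allclose(fit.coefficients, primal_oracle(X, y, 0.5), atol=1e-8)

    def test_dual_equals_primal_for_wide_matrices(self, rng):
        X = rng.normal(size=(6, 40))
        y = rng.normal(size=6)
        for lam in (1e-2, 1.0, 1e3):
            assert np.allclose(
                fit_ridge(X, y, lam).coefficients,
                primal_oracle(X, y, lam),
                atol=1e-8,
            )

    def test_matches_sklearn(self, rng):
        from sklearn.linear_model import Ridge

        X = rng.normal(size=(12, 7))
        y = rng.normal(size=12)
        ours = fit_ridge(X, y, 2.5)
        sk = Ridge(alpha=2.5, fit_intercept=True).fit(X, y)
        assert np.allclose(ours.coefficients, sk.coef_, atol=1e-8)
        assert np.allclose(ours.fitted(X), sk.predict(X), atol=1e-8)

    def test_ols_rank_deficient_rejected(self, rng):
        X = rng.normal(size=(4, 10))
        with pytest.raises(ValidationError, match="rank-deficient"):
            fit_ridge(X, rng.normal(size=4), 0.0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError):
            fit_ridge(rng.normal(size=(4, 3)), rng.normal(size=5), 1.0)

    def test_coefficient_norm_nonincreasing_in_lambda(self, rng):
        X = rng.normal(size=(8, 30))
        y = rng.normal(size=8)
        norms = [
            np.linalg.norm(fit_ridge(X, y, lam).coefficients)
            for lam in np.logspace(-3, 5, 20)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestLoocv:
    def test_shortcut_equals_explicit_refits(self, rng):
        """The central numerical contract, on an 8 x 50 instance."""
        X = rng.normal(size=(8, 50))
        y = rng.normal(size=8)
        grid = np.logspace(-2, 4, 9)
        _, curve = loocv_select_lambda(X, y, grid)
        for lam, mse in curve:
            assert mse == pytest.approx(explicit_loocv_mse(X, y, lam), abs=1e-8)

    def test_noiseless_signal_favors_weak_penalty(self, rng):
        X = rng.normal(size=(8, 5))
        y = X[:, 0].copy()
        lam, _ = loocv_select_lambda(X, y, [0.01, 100.0])
        assert lam == 0.01

    def test_pure_noise_favors_heavy_penalty(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        grid = [0.01, 1e6]
        lam, curve = loocv_select_lambda(X, y, grid)
        # explicit-refit oracle agrees on the ordering
        oracle = {la: explicit_loocv_mse(X, y, la) for la in grid}
        assert lam == min(grid, key=lambda la: oracle[la]) == 1e6

    def test_loo_predictions_match_explicit(self, rng):
        X = rng.normal(size=(8, 20))
        y = rng.normal(size=8)
        lam = 3.0
        preds = loocv_predictions(X, y, lam)
        for i in range(8):
            mask = np.ones(8, bool)
            mask[i] = False
            fit = fit_ridge(X[mask], y[mask], lam)
            assert preds[i] == pytest.approx(fit.fitted(X[i : i + 1])[0], abs=1e-8)

    def test_degenerate_n_rejected(self, rng):
        with pytest.raises(ValidationError):
            loocv_select_lambda(rng.normal(size=(2, 3)), rng.normal(size=2), [1, 2])


class TestTrainAndPredict:
    def test_replicates_averaged_to_eight_folds(self, trained_models):
        assert all(m.n_folds == 8 for m in trained_models)

    def test_six_models_trained(self, trained_models):
        assert len(trained_models) == 6
        assert sorted(m.phenotype_name for m in trained_models) == sorted(
            ["morphology", "CDH2", "ZEB1", "CD24", "CXCR4", "VIM"]
        )

    def test_training_is_deterministic(self, default_bundle, selected_genes):
        a = train_phenotype_model(
            default_bundle.cellline_expression,
            default_bundle.phenotypes,
            "ZEB1",
            selected_genes,
        )
        b = train_phenotype_model(
            default_bundle.cellline_expression,
            default_bundle.phenotypes,
            "ZEB1",
            selected_genes,
        )
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.lam == b.lam

    def test_missing_phenotype_lists_lines(self, default_bundle, selected_genes):
        pheno = PhenotypeTable(
            default_bundle.phenotypes.values.drop(index=["CL3"])
        )
        with pytest.raises(ValidationError, match="CL3"):
            train_phenotype_model(
                default_bundle.cellline_expression, pheno, "ZEB1", selected_genes
            )

    def test_loocv_training_scores_track_latent(self, trained_models, default_bundle):
        """Concordant models' LOO-predicted training scores recover s."""
        from scipy.stats import spearmanr

        for m in trained_models:
            if m.phenotype_name not in CONCORDANT:
                continue
            lines = sorted(m.cv_predictions)
            cv = [m.cv_predictions[ln] for ln in lines]
            s = default_bundle.latent_scores.loc[lines]
            assert spearmanr(cv, s).statistic >= 0.6

    def test_training_standardization_reproduces_fitted(
        self, trained_models, default_bundle
    ):
        m = trained_models[0]
        avg = average_replicates(default_bundle.cellline_expression)
        em = ExpressionMatrix(avg, "cell_line")
        sc = predict_scores(m, em, standardization="training")
        Xz = (
            avg.loc[m.gene_ids].T.to_numpy() - m.train_gene_means
        ) / m.train_gene_sds
        fitted = Xz @ m.coefficients + m.intercept
        assert np.allclose(sc.scores, fitted, atol=1e-10)

    def test_gene_row_order_irrelevant(self, trained_models, default_bundle):
        m = trained_models[0]
        pt = default_bundle.patient_expression
        shuffled = ExpressionMatrix(
            pt.values.sample(frac=1, random_state=3), "tumor"
        )
        a = predict_scores(m, pt).scores
        b = predict_scores(m, shuffled).scores
        assert np.allclose(a, b, atol=1e-12)

    def test_low_gene_coverage_rejected(self, trained_models, default_bundle):
        m = trained_models[0]
        few = default_bundle.patient_expression.values.loc[m.gene_ids[:100]]
        with pytest.raises(CoverageError, match="%"):
            predict_scores(m, ExpressionMatrix(few, "tumor"))

    def test_missing_genes_contribute_zero(self, trained_models, default_bundle):
        """Dropping model genes moves scores exactly by the dropped terms."""
        m = trained_models[0]
        pt = default_bundle.patient_expression
        kept = m.gene_ids[: int(0.6 * len(m.gene_ids))]
        partial = ExpressionMatrix(pt.values.loc[kept], "tumor")
        sc_partial = predict_scores(m, partial).scores
        X = pt.values.loc[kept].to_numpy().T
        means, sds = X.mean(0), X.std(0, ddof=1)
        Z = (X - means) / sds
        beta = m.coefficients[[m.gene_ids.index(g) for g in kept]]
        assert np.allclose(sc_partial, Z @ beta + m.intercept, atol=1e-10)

    def test_model_json_round_trip(self, trained_models, tmp_path):
        m = trained_models[0]
        p = m.to_json(tmp_path / "m.json")
        back = RidgeModel.from_json(p)
        assert back.phenotype_name == m.phenotype_name
        assert np.allclose(back.coefficients, m.coefficients, atol=0, rtol=0)
        assert back.lam == m.lam
        assert back.cv_predictions == pytest.approx(m.cv_predictions)


class TestTopGenes:
    def test_small_example(self):
        model = _toy_model({"A": 2.0, "B": 1.0, "C": -3.0})
        pos, neg = top_coefficient_genes(model, 1)
        assert pos == ["A"] and neg == ["C"]

    def test_all_positive_warns_on_empty_negative(self, caplog):
        import logging

        model = _toy_model({"A": 2.0, "B": 1.0})
        with caplog.at_level(logging.WARNING):
            pos, neg = top_coefficient_genes(model, 1)
        assert neg == []
        assert any("negative" in r.message for r in caplog.records)

    def test_trained_model_yields_25_per_sign(self, trained_models):
        for m in trained_models:
            pos, neg = top_coefficient_genes(m, 25)
            assert len(pos) == 25 and len(neg) == 25
            assert not set(pos) & set(neg)


def _toy_model(coefs: dict) -> RidgeModel:
    genes = list(coefs)
    k = len(genes)
    return RidgeModel(
        phenotype_name="toy",
        gene_ids=genes,
        coefficients=np.array([coefs[g] for g in genes], float),
        intercept=0.0,
        lam=1.0,
        train_gene_means=np.zeros(k),
        train_gene_sds=np.ones(k),
        cv_error_curve=[(1.0, 0.0), (2.0, 1.0)],
        n_folds=8,
    )
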