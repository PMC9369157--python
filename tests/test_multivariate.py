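"""Scaling, PCA/Hotelling screen, OPLS, Q², CV-ANOVA and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedallometry.multivariate import (
    ModelInputError,
    cluster_scores,
    cv_anova,
    hotelling_outliers,
    hotelling_t2,
    opls_fit,
    opls_predict,
    pca_fit,
    q2_cross_validation,
    uv_scale,
)


def pls1_oracle_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent single-component PLS-1: fitted values on training data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    t = Xc @ w
    q = (t @ yc) / (t @ t)
    return t * q + y.mean()


class TestScaling:
    def test_scaled_columns_standardised_and_invertible(self, rng):
        X = pd.DataFrame(rng.normal(5, 3, size=(30, 4)), columns=list("abcd"))
        Z, model = uv_scale(X)
        assert Z.to_numpy().mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-12)
        assert Z.to_numpy().std(axis=0, ddof=1) == pytest.approx(np.ones(4))
        back = model.inverse_transform(Z)
        assert back.to_numpy() == pytest.approx(X.to_numpy(), abs=1e-10)

    def test_already_standardised_input_unchanged(self, rng):
        raw = rng.normal(size=(200, 3))
        raw = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
        X = pd.DataFrame(raw, columns=list("abc"))
        Z, _ = uv_scale(X)
        assert Z.to_numpy() == pytest.approx(raw, abs=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"var": rng.normal(size=20), "flat": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            Z, model = uv_scale(X)
        assert model.dropped == ["flat"] and list(Z.columns) == ["var"]


class TestPca:
    def test_collinear_data_has_one_component(self, rng):
        t = rng.normal(size=50)
        X = np.outer(t, [1.0, -2.0, 0.5])
        model = pca_fit(X, k=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_samples_share_scores(self, rng):
        X = rng.normal(size=(20, 5))
        X[7] = X[3]
        model = pca_fit(X, k=3)
        assert model.scores[7] == pytest.approx(model.scores[3], abs=1e-10)

    def test_full_rank_reconstruction_is_exact(self, rng):
        X = rng.normal(size=(12, 4))
        model = pca_fit(X, k=4)
        recon = model.scores @ model.loadings.T + model.mean
        assert recon == pytest.approx(X, abs=1e-10)

    def test_loadings_orthonormal_variance_nonincreasing(self, rng):
        model = pca_fit(rng.normal(size=(40, 6)), k=4)
        assert model.loadings.T @ model.loadings == pytest.approx(np.eye(4), abs=1e-10)
        assert (np.diff(model.explained_variance) <= 1e-12).all()

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(ModelInputError):
            pca_fit(rng.normal(size=(5, 3)), k=5)

    def test_hotelling_null_flag_rate_near_one_percent(self):
        rng = np.random.default_rng(77)
        flagged = total = 0
        for _ in range(60):
            X = rng.normal(size=(60, 5))
            model = pca_fit(X, k=2)
            flags = hotelling_outliers(model, level=0.99)
            flagged += flags.sum()
            total += len(flags)
        rate = flagged / total
        assert 0.001 < rate < 0.025

    def test_t2_nonnegative(self, rng):
        model = pca_fit(rng.normal(size=(25, 4)), k=2)
        assert (hotelling_t2(model) >= 0).all()


class TestOpls:
    def test_equals_pls1_oracle_without_orthogonal_components(self, rng):
        for _ in range(25):
            n, p = rng.integers(8, 25), rng.integers(2, 8)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            model = opls_fit(pd.DataFrame(X), y, n_ortho=0, cross_validate=False)
            ours = opls_predict(model, pd.DataFrame(X))
            assert ours == pytest.approx(pls1_oracle_predictions(X, y), abs=1e-8)

    def test_linear_signal_dominates_loading(self, rng):
        # One component cannot be exact here: the noise columns correlate
        # with y in-sample, so we assert dominance rather than equality.
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = 3.0 * X["c"].to_numpy()
        model = opls_fit(X, y, n_ortho=0, cross_validate=False)
        assert model.r_squared > 0.9
        load = np.abs(model.loading_pred)
        assert np.argmax(load) == 2
        assert load[2] > 2 * np.sort(load)[-2]

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 20)))
        X.columns = [f"m{j}" for j in range(20)]
        y = X["m0"].to_numpy() + rng.normal(scale=0.5, size=n)
        model = opls_fit(X, y, n_ortho=3, cross_validate=False)
        yc = y - y.mean()
        for j in range(model.n_ortho):
            assert abs(model.ortho_scores[:, j] @ yc) < 1e-8

    def test_training_prediction_r2_equals_model_r2(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        X.columns = list("abcdef")
        y = X["a"].to_numpy() * 2 + rng.normal(scale=0.3, size=30)
        model = opls_fit(X, y, n_ortho=1, cross_validate=False)
        pred = opls_predict(model, X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(model.r_squared, abs=1e-10)

    def test_mean_sample_predicts_mean_response(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = rng.normal(size=30)
        model = opls_fit(X, y, n_ortho=1, cross_validate=False)
        at_mean = pd.DataFrame([model.x_mean], columns=model.columns)
        assert opls_predict(model, at_mean)[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_column_mismatch_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = opls_fit(X, rng.normal(size=20), cross_validate=False)
        with pytest.raises(ModelInputError, match="missing columns"):
            opls_predict(model, X[["a", "b"]])


class TestQ2:
    def test_noise_free_signal_gives_q2_near_one(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=56)})
        y = 2.0 * X["a"].to_numpy() + 1.0
        q2 = q2_cross_validation(X, y, folds=7, n_ortho=0)
        assert q2 == pytest.approx(1.0, abs=1e-10)

    def test_q2_never_exceeds_r2y(self, rng):
        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(42, 6)))
            X.columns = list("abcdef")
            y = X["a"].to_numpy() + rng.normal(scale=rng.uniform(0.2, 2.0), size=42)
            model = opls_fit(X, y, n_ortho=1, folds=7)
            assert model.q_squared <= model.r_squared + 1e-12

    def test_pure_noise_q2_nonpositive_on_average(self, rng):
        q2s = [q2_cross_validation(pd.DataFrame(rng.normal(size=(35, 8))),
                                   rng.normal(size=35), folds=7, n_ortho=1)
               for _ in range(25)]
        assert np.mean(q2s) < 0

    def test_deterministic_folds(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        y = rng.normal(size=30)
        assert q2_cross_validation(X, y, seed=5) == q2_cross_validation(X, y, seed=5)

    def test_too_small_folds_rejected(self, rng):
        with pytest.raises(ModelInputError):
            q2_cross_validation(pd.DataFrame(rng.normal(size=(9, 3))),
                                rng.normal(size=9), folds=5)


class TestCvAnova:
    def test_strong_signal_is_extremely_significant(self, rng):
        X = pd.DataFrame(rng.normal(size=(56, 10)))
        X.columns = [f"m{j}" for j in range(10)]
        y = X["m0"].to_numpy() * 2 + rng.normal(scale=0.2, size=56)
        model = opls_fit(X, y, n_ortho=1)
        assert cv_anova(model, method="f") < 1e-6

    def test_perfect_cv_prediction_limit(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=40)})
        y = -3.0 * X["a"].to_numpy()
        model = opls_fit(X, y, n_ortho=0, folds=5)
        assert cv_anova(model, method="f") < 1e-12

    def test_f_method_conservative_under_null(self):
        """The published F recipe over-covers: null rejection rate stays below alpha."""
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(60):
            X = pd.DataFrame(rng.normal(size=(35, 6)))
            X.columns = list("abcdef")
            model = opls_fit(X, rng.normal(size=35), n_ortho=1)
            ps.append(cv_anova(model, method="f"))
        assert np.mean(np.array(ps) < 0.05) <= 0.05

    def test_randomization_method_calibrated_under_null(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(40):
            X = pd.DataFrame(rng.normal(size=(30, 5)))
            X.columns = list("abcde")
            model = opls_fit(X, rng.normal(size=30), n_ortho=1, cv_seed=int(rng.integers(2**31)))
            ps.append(cv_anova(model, method="randomization", n_rand=49))
        ps = np.array(ps)
        # discrete-uniform on {1/50 .. 50/50}: mean near 0.5, spread near uniform
        assert abs(ps.mean() - 0.5) < 0.17
        assert sps.kstest(ps, "uniform").pvalue > 0.001

    def test_degenerate_response_returns_one_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X["a"].to_numpy()
        model = opls_fit(X, y, n_ortho=0, folds=5)
        model.y_train = np.full(30, 2.0)
        model.cv_predictions = np.full(30, 2.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert cv_anova(model, method="f") == 1.0

    def test_model_without_cv_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = opls_fit(X, rng.normal(size=20), cross_validate=False)
        with pytest.raises(ModelInputError):
            cv_anova(model)


class TestClustering:
    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(loc=0.0, scale=0.3, size=(15, 2))
        b = rng.normal(loc=8.0, scale=0.3, size=(15, 2))
        labels = cluster_scores(np.vstack([a, b]), k=2)
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[15]

    def test_k_equal_n_gives_singletons(self, rng):
        S = rng.normal(size=(8, 2))
        labels = cluster_scores(S, k=8)
        assert len(set(labels)) == 8

    def test_duplicated_samples_co_clustered(self, rng):
        S = rng.normal(size=(10, 2))
        doubled = np.vstack([S, S])
        labels = cluster_scores(doubled, k=3)
        assert (labels[:10] == labels[10:]).all()

    def test_requires_k_or_threshold(self, rng):
        with pytest.raises(ValueError):
            cluster_scores(rng.normal(size=(10, 2)))
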