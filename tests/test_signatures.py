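import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdmtv.errors import DataError
from mdmtv.signatures import (
    correlate_with_covariate,
    correlate_with_covariates,
    predict_feature_loo,
    project_dispersion,
    signature_pca,
    zscore_columns,
)

REGIONS7 = [f"r{i}" for i in range(7)]


def make_matrix(rng, n_rows=7, cols=("dR1/dMTV", "dMTsat/dMTV")):
    return pd.DataFrame(
        rng.normal(size=(n_rows, len(cols))),
        index=[f"r{i}" for i in range(n_rows)],
        columns=list(cols),
    )


class TestZscore:
    def test_hand_zscore(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 5.0]})
        z = zscore_columns(df)
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_columns(df)
        assert list(z.columns) == ["a"]

    def test_all_constant_rejected(self):
        with pytest.raises(DataError):
            zscore_columns(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = make_matrix(rng)
        z1 = zscore_columns(df)
        z2 = zscore_columns(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestPCA:
    def test_matches_independent_eigendecomposition(self):
        # 3x2 worked matrix; oracle is a from-scratch covariance eigsolve
        matrix = pd.DataFrame(
            [[1.0, 2.0], [3.0, 5.0], [4.0, 4.0]],
            index=["r0", "r1", "r2"],
            columns=["u", "v"],
        )
        pca = signature_pca(matrix)
        Z = ((matrix - matrix.mean()) / matrix.std(ddof=1)).to_numpy()
        cov = Z.T @ Z / (Z.shape[0] - 1)
        vals, vecs = np.linalg.eig(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        for k in range(2):
            v = vecs[:, k]
            j = np.flatnonzero(np.abs(v) >= np.abs(v).max() * (1 - 1e-9))[0]
            if v[j] < 0:
                v = -v
            np.testing.assert_allclose(pca.loadings.iloc[:, k], v, atol=1e-10)
            np.testing.assert_allclose(pca.scores.iloc[:, k], Z @ v, atol=1e-10)
        np.testing.assert_allclose(
            pca.explained_variance_ratio, vals / vals.sum(), atol=1e-10
        )

    def test_rank_one_gives_pc1_fraction_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=6)
        matrix = pd.DataFrame({"u": a, "v": 3.0 * a + 1.0})  # perfectly correlated
        pca = signature_pca(matrix)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_uncorrelated_and_ratios_sum_to_one(self):
        rng = np.random.default_rng(2)
        matrix = make_matrix(rng, n_rows=10, cols=("a", "b", "c", "d"))
        pca = signature_pca(matrix)
        corr = np.corrcoef(pca.scores["PC1"], pca.scores["PC2"])[0, 1]
        assert abs(corr) < 1e-10
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pca.explained_variance_ratio) <= 1e-12)

    def test_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(3)
        matrix = make_matrix(rng, n_rows=8, cols=("a", "b", "c"))
        scaled = matrix * pd.Series({"a": 1e3, "b": 2e-4, "c": 7.0})
        p1, p2 = signature_pca(matrix), signature_pca(scaled)
        np.testing.assert_allclose(
            p1.scores.to_numpy(), p2.scores.to_numpy(), atol=1e-10
        )

    def test_too_small_rejected(self):
        with pytest.raises(DataError):
            signature_pca(pd.DataFrame({"a": [1.0, 2.0]}))


class TestDispersionProjection:
    def _setup(self):
        rng = np.random.default_rng(4)
        matrix = make_matrix(rng, n_rows=6, cols=("a", "b"))
        pca = signature_pca(matrix)
        return matrix, pca

    def test_zero_mad_projects_to_zero(self):
        matrix, pca = self._setup()
        mad = pd.DataFrame(0.0, index=matrix.index, columns=matrix.columns)
        out = project_dispersion(mad, pca)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_single_column_mad_proportional_to_loading(self):
        matrix, pca = self._setup()
        mad = pd.DataFrame(0.0, index=matrix.index, columns=matrix.columns)
        mad.loc["r0", "a"] = 2.0
        out = project_dispersion(mad, pca)
        expected = 2.0 / pca.column_sds["a"] * pca.loadings.loc["a", "PC1"]
        assert out.loc["r0", "PC1"] == pytest.approx(expected, abs=1e-12)

    def test_linear_in_mad(self):
        matrix, pca = self._setup()
        rng = np.random.default_rng(5)
        mad = pd.DataFrame(
            rng.uniform(0, 1, size=matrix.shape), index=matrix.index, columns=matrix.columns
        )
        out1 = project_dispersion(mad, pca)
        out2 = project_dispersion(2.0 * mad, pca)
        np.testing.assert_allclose(out2.to_numpy(), 2.0 * out1.to_numpy(), atol=1e-12)

    def test_misaligned_rejected(self):
        matrix, pca = self._setup()
        bad = pd.DataFrame(0.0, index=["x"], columns=matrix.columns)
        with pytest.raises(DataError):
            project_dispersion(bad, pca)


class TestLOOPrediction:
    def test_exact_linear_feature_predicted_perfectly(self):
        rng = np.random.default_rng(6)
        matrix = make_matrix(rng)
        feature = 0.5 * matrix["dR1/dMTV"] + 2.0 * matrix["dMTsat/dMTV"]
        result = predict_feature_loo(matrix, feature)
        np.testing.assert_allclose(result.predicted, feature, atol=1e-8)
        assert result.r2_loo == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_loo_oracle(self):
        rng = np.random.default_rng(7)
        matrix = make_matrix(rng, n_rows=9)
        feature = (
            0.5 * matrix["dR1/dMTV"]
            + 2.0 * matrix["dMTsat/dMTV"]
            + rng.normal(0, 0.3, size=9)
        )
        result = predict_feature_loo(matrix, feature)
        # independent re-implementation of the LOO loop via lstsq
        X = np.column_stack([matrix.to_numpy(), np.ones(9)])
        y = feature.to_numpy()
        preds = []
        for i in range(9):
            mask = np.ones(9, bool)
            mask[i] = False
            beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
            preds.append(X[i] @ beta)
        np.testing.assert_allclose(result.predicted, preds, atol=1e-10)
        r2 = 1 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)
        assert result.r2_loo == pytest.approx(r2, abs=1e-10)

    def test_permuted_features_average_nonpositive_r2(self):
        rng = np.random.default_rng(8)
        matrix = make_matrix(rng)
        feature = 0.5 * matrix["dR1/dMTV"] + 2.0 * matrix["dMTsat/dMTV"]
        r2s = []
        for _ in range(100):
            perm = feature.to_numpy().copy()
            rng.shuffle(perm)
            r2s.append(
                predict_feature_loo(matrix, pd.Series(perm, index=matrix.index)).r2_loo
            )
        assert np.mean(r2s) <= 0.05  # within Monte-Carlo error of <= 0

    def test_held_out_value_never_seen(self):
        rng = np.random.default_rng(9)
        matrix = make_matrix(rng)
        feature = pd.Series(rng.normal(size=7), index=matrix.index)
        base = predict_feature_loo(matrix, feature)
        poisoned = feature.copy()
        poisoned.iloc[3] += 1e6  # only fold 3's own target changes
        out = predict_feature_loo(matrix, poisoned)
        assert out.predicted.iloc[3] == pytest.approx(base.predicted.iloc[3], rel=1e-9)

    def test_fewer_than_four_regions_rejected(self):
        rng = np.random.default_rng(10)
        matrix = make_matrix(rng, n_rows=3)
        with pytest.raises(DataError):
            predict_feature_loo(matrix, pd.Series(np.ones(3), index=matrix.index))


class TestCovariateCorrelation:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        r2_adj, p, q = correlate_with_covariate(x, x, n_comparisons=57)
        assert r2_adj == pytest.approx(1.0)
        assert p < 1e-15

    def test_adjusted_r2_formula_n5(self):
        # construct x, y with raw R^2 = 0.5 at n = 5 via residual control
        rng = np.random.default_rng(12)
        x = rng.normal(size=5)
        xc = x - x.mean()
        resid = rng.normal(size=5)
        resid -= resid.mean()
        resid -= xc * (resid @ xc) / (xc @ xc)  # orthogonal to x
        resid *= np.sqrt((xc @ xc)) / np.linalg.norm(resid)  # SSres = SSfit
        y = xc + resid
        r2_adj, _, _ = correlate_with_covariate(x, y)
        assert r2_adj == pytest.approx(1 - 0.5 * 4 / 3, abs=1e-10)

    def test_orthogonalized_covariate_gives_zero_r2(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        xc = x - x.mean()
        y_orth = y - y.mean() - xc * ((y - y.mean()) @ xc) / (xc @ xc)
        r2_adj, p, _ = correlate_with_covariate(x, y_orth)
        n = 20
        assert r2_adj == pytest.approx(1 - (n - 1) / (n - 2), abs=1e-10)  # raw R2 = 0

    def test_family_padding_matches_single_call(self):
        rng = np.random.default_rng(14)
        x = pd.Series(rng.normal(size=12), index=range(12))
        cov = pd.DataFrame({"g1": rng.normal(size=12)}, index=range(12))
        table = correlate_with_covariates(x, cov, n_comparisons=57)
        _, p, q_single = correlate_with_covariate(x, cov["g1"], n_comparisons=57)
        assert table.loc[0, "q"] == pytest.approx(q_single, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            correlate_with_covariate(np.ones(5), np.arange(5.0))
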