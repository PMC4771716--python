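import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from memscale import (
    CommunityMatrix,
    ExplanatoryMatrix,
    adjusted_r2,
    chisq_transform,
    hellinger_transform,
    partial_residuals,
    pca,
    pra,
    rda,
    rda_permutation_test,
)

from oracles import covariance_eigenvalues, hat_matrix_fit

count_matrices = arrays(
    np.int64, st.tuples(st.integers(4, 12), st.integers(2, 5)),
    elements=st.integers(0, 50),
).filter(lambda Y: np.all(Y.sum(axis=1) > 0) and np.all(Y.sum(axis=0) > 0))


class TestHellinger:
    @pytest.mark.parametrize("row, expected", [
        ((4, 0, 0), (1, 0, 0)),
        ((1, 1, 1, 1), (0.5, 0.5, 0.5, 0.5)),
    ])
    def test_known_rows(self, row, expected):
        out = hellinger_transform(CommunityMatrix(counts=[row]))
        assert np.allclose(out.values[0], expected)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(count_matrices)
    def test_rows_have_unit_sum_of_squares(self, Y):
        out = hellinger_transform(CommunityMatrix(counts=Y))
        assert np.allclose((out.values**2).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_rejected_naming_site(self):
        Y = CommunityMatrix(counts=[[1, 2], [0, 0]], site_ids=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            hellinger_transform(Y)


class TestChisq:
    def test_all_ones_2x2(self):
        # sqrt(4) * 1 / (2 * sqrt(2)) for every cell
        out = chisq_transform(CommunityMatrix(counts=[[1, 1], [1, 1]]))
        assert np.allclose(out.values, 2 / (2 * np.sqrt(2)))

    def test_proportional_rows_collapse(self):
        out = chisq_transform(CommunityMatrix(counts=[[2, 4, 6], [1, 2, 3], [5, 1, 1]]))
        assert np.allclose(out.values[0], out.values[1], atol=1e-12)

    def test_zero_species_column_rejected(self):
        with pytest.raises(ValueError, match="zero total abundance"):
            chisq_transform(CommunityMatrix(counts=[[1, 0], [2, 0]]))


class TestPCA:
    def test_rank_one_data_single_axis(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        Y = np.column_stack([base, 2 * base, -base])
        res = pca(Y)
        assert res.proportion[0] == pytest.approx(1.0, abs=1e-12)

    def test_proportions_sum_to_one(self, rng):
        res = pca(rng.normal(size=(20, 4)))
        assert res.proportion.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_matches_covariance_eigen_oracle(self, rng):
        Y = rng.normal(size=(25, 5))
        res = pca(Y)
        assert np.allclose(res.eigenvalues, covariance_eigenvalues(Y), atol=1e-10)

    def test_site_scores_centered(self, rng):
        res = pca(rng.normal(size=(15, 3)))
        assert np.allclose(res.site_scores.mean(axis=0), 0, atol=1e-10)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError, match="more than one site"):
            pca(np.ones((1, 3)))


class TestAdjustedR2:
    def test_printed_endpoint_rounds(self):
        # selection-table endpoint: cumulative R2 0.46 over 10 variables at 329 sites
        assert round(adjusted_r2(0.46, 329, 10), 2) == 0.44

    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 50, 5) == pytest.approx(1.0)

    def test_zero_r2_goes_negative(self):
        assert adjusted_r2(0.0, 11, 1) == pytest.approx(-1 / 9)

    def test_degenerate_df_rejected(self):
        with pytest.raises(ValueError, match="n > m"):
            adjusted_r2(0.5, 5, 4)


class TestRDA:
    def test_self_explained_r2_is_one(self, rng):
        Y = rng.normal(size=(12, 2))
        res = rda(Y, ExplanatoryMatrix(values=Y.copy()))
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_hat_matrix_oracle_on_toy(self):
        Y = np.array([[1.0, 0.5], [2, 1.2], [0.5, 3], [4, 1], [3, 2], [1, 1]])
        X = np.array([[0.1], [0.9], [0.4], [1.3], [1.0], [0.2]])
        Yhat_oracle, r2_oracle = hat_matrix_fit(Y, X)
        res = rda(Y, ExplanatoryMatrix(values=X))
        Yc = Y - Y.mean(axis=0)
        Yhat = Yc - partial_residuals(Y, ExplanatoryMatrix(values=X))
        assert np.allclose(Yhat, Yhat_oracle, atol=1e-8)
        assert res.r2 == pytest.approx(r2_oracle, abs=1e-10)

    def test_noise_predictor_adjusted_r2_near_zero_on_average(self):
        vals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            res = rda(r.normal(size=(30, 2)), ExplanatoryMatrix(values=r.normal(size=(30, 1))))
            vals.append(res.adj_r2)
        assert abs(np.mean(vals)) < 0.02

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=20)
        X = ExplanatoryMatrix(values=np.column_stack([x, 2 * x]), variable_ids=("a", "a_copy"))
        with pytest.raises(ValueError, match="rank deficient"):
            rda(rng.normal(size=(20, 2)), X)

    def test_constrained_proportions(self, rng):
        Y = rng.normal(size=(25, 3))
        res = rda(Y, ExplanatoryMatrix(values=rng.normal(size=(25, 2))))
        assert res.proportion.sum() == pytest.approx(res.r2, abs=1e-10)
        assert res.proportion_constrained.sum() == pytest.approx(1.0, abs=1e-10)


class TestPartialResiduals:
    def test_spanning_x_gives_zero(self, rng):
        Y = rng.normal(size=(10, 2))
        R = partial_residuals(Y, ExplanatoryMatrix(values=Y.copy()))
        assert np.allclose(R, 0, atol=1e-10)

    def test_orthogonal_to_x_and_pythagoras(self, rng):
        Y = rng.normal(size=(30, 3))
        X = rng.normal(size=(30, 4))
        R = partial_residuals(Y, ExplanatoryMatrix(values=X))
        Xc = X - X.mean(axis=0)
        assert np.max(np.abs(Xc.T @ R)) < 1e-8
        Yc = Y - Y.mean(axis=0)
        ss_fit = np.sum((Yc - R) ** 2)
        assert np.sum(Yc**2) == pytest.approx(ss_fit + np.sum(R**2), abs=1e-8)


class TestPRA:
    def test_orthogonal_x_reduces_to_pca(self, rng):
        # build X exactly orthogonal to the centered Y columns
        Y = rng.normal(size=(20, 2))
        Yc = Y - Y.mean(axis=0)
        basis = np.linalg.qr(np.column_stack([np.ones(20), Yc]))[0]
        raw = rng.normal(size=20)
        x = raw - basis @ (basis.T @ raw)
        res_pra = pra(Y, ExplanatoryMatrix(values=x[:, None]))
        res_pca = pca(Y)
        assert np.allclose(res_pra.eigenvalues, res_pca.eigenvalues, atol=1e-10)
        assert np.allclose(np.abs(res_pra.site_scores), np.abs(res_pca.site_scores), atol=1e-8)

    def test_spanning_x_gives_zero_eigenvalues(self, rng):
        Y = rng.normal(size=(10, 2))
        res = pra(Y, ExplanatoryMatrix(values=Y.copy()))
        assert res.eigenvalues.size == 0

    def test_inertia_decomposition(self, rng):
        Y = rng.normal(size=(25, 3))
        X = ExplanatoryMatrix(values=rng.normal(size=(25, 2)))
        res_rda = rda(Y, X)
        res_pra = pra(Y, X)
        expected = (1 - res_rda.r2) * pca(Y).total_inertia
        assert res_pra.eigenvalues.sum() == pytest.approx(expected, abs=1e-8)


class TestRdaPermutation:
    def test_maximal_observed_gives_minimal_p(self, rng):
        Y = rng.normal(size=(15, 2))
        p = rda_permutation_test(Y, ExplanatoryMatrix(values=Y.copy()), nperm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_seed_reproducible(self, rng):
        Y = rng.normal(size=(20, 2))
        X = ExplanatoryMatrix(values=rng.normal(size=(20, 2)))
        assert rda_permutation_test(Y, X, nperm=99, seed=5) == rda_permutation_test(Y, X, nperm=99, seed=5)

    def test_null_calibration(self):
        # independent X and Y: rejection rate at alpha=0.05 within the
        # binomial 95% CI over 200 runs
        rejections = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            p = rda_permutation_test(r.normal(size=(25, 2)),
                                     ExplanatoryMatrix(values=r.normal(size=(25, 1))),
                                     nperm=99, seed=seed)
            rejections += p <= 0.05
        lo = 200 * 0.05 - 1.96 * np.sqrt(200 * 0.05 * 0.95)
        hi = 200 * 0.05 + 1.96 * np.sqrt(200 * 0.05 * 0.95)
        assert lo <= rejections <= hi
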