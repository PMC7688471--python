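"""OLS and maximum-likelihood spatial lag/error regression, BH correction,
and cluster marker ion selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatmsi.regression import (
    SpatialErrorModel,
    SpatialLagModel,
    bh_adjust,
    fit_ols,
    fit_spatial_error_model,
    fit_spatial_lag_model,
    select_cluster_ions,
)
from spatmsi.spatial import build_weights
from spatmsi.synthetic import _SARSampler, generate_benchmark_dataset

from conftest import grid_coords


@pytest.fixture(scope="module")
def rook30():
    return build_weights(grid_coords(30, 30), threshold=1, style="row_standardized")


class TestOLS:
    def test_exact_linear_data_recovered(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2.0 + 3.0 * np.arange(10.0)
        fit = fit_ols(y, x)
        assert fit.beta == pytest.approx([2.0, 3.0], abs=1e-12)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equation_oracle(self, rng):
        x = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = rng.normal(size=40)
        fit = fit_ols(y, x)
        beta_oracle = np.linalg.solve(x.T @ x, x.T @ y)
        assert fit.beta == pytest.approx(beta_oracle, abs=1e-10)

    def test_row_permutation_leaves_estimates_unchanged(self, rng):
        x = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.normal(size=30)
        perm = rng.permutation(30)
        a, b = fit_ols(y, x), fit_ols(y[perm], x[perm])
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.p_beta == pytest.approx(b.p_beta, abs=1e-12)

    def test_rank_deficient_design_rejected(self):
        x = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="singular"):
            fit_ols(np.arange(10.0), x)


class TestSpatialLagModel:
    def test_loglik_at_zero_rho_equals_ols_gaussian_loglik(self, rng, rook30):
        n = 900
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = x @ [1.0, 2.0] + rng.normal(size=n)
        ols = fit_ols(y, x)
        est = SpatialLagModel(weights=rook30, add_intercept=False).fit(x, y)
        theta0 = np.concatenate([ols.beta, [0.0, np.mean((y - x @ ols.beta) ** 2)]])
        eig = rook30.eigenvalues()
        assert est._full_loglik(theta0, x, y, n, eig) == pytest.approx(ols.loglik, abs=1e-8)

    def test_zero_rho_data_reduce_to_ols(self, rng, rook30):
        n = 900
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = x @ [1.0, 2.0] + rng.normal(size=n)
        fit = fit_spatial_lag_model(y, x, rook30)
        ols = fit_ols(y, x)
        assert abs(fit.rho) < 0.05
        assert fit.beta == pytest.approx(ols.beta, abs=0.05)

    def test_parameter_recovery_on_planted_sar_process(self, rng, rook30):
        sampler = _SARSampler(rook30, 0.5)
        n = 900
        xcov = rng.normal(size=n)
        x = np.column_stack([np.ones(n), xcov])
        rhos, betas = [], []
        for _ in range(20):
            y = sampler._lu.solve(x @ [1.0, 2.0] + rng.normal(size=n))
            fit = fit_spatial_lag_model(y, x, rook30)
            rhos.append(fit.rho)
            betas.append(fit.beta[1])
        assert 0.45 <= np.mean(rhos) <= 0.55
        assert 1.9 <= np.mean(betas) <= 2.1

    def test_logdet_eigenvalue_identity(self):
        w = build_weights(grid_coords(4, 4), threshold=1, style="row_standardized")
        rho = 0.3
        eig_sum = np.sum(np.log1p(-rho * w.eigenvalues()))
        sign, logdet = np.linalg.slogdet(np.eye(16) - rho * w.to_dense())
        assert sign == 1.0
        assert eig_sum == pytest.approx(logdet, abs=1e-10)

    def test_oversized_problem_rejected(self, rng):
        w = build_weights(grid_coords(5, 5), threshold=1, style="row_standardized")
        est = SpatialLagModel(weights=w, eigen_limit=10)
        with pytest.raises(ValueError, match="eigen limit"):
            est.fit(rng.normal(size=(25, 1)), rng.normal(size=25))

    def test_requires_row_standardized_weights(self, rng):
        w = build_weights(grid_coords(5, 5), threshold=1, style="binary")
        with pytest.raises(ValueError, match="row-standardized"):
            SpatialLagModel(weights=w).fit(rng.normal(size=(25, 1)), rng.normal(size=25))


class TestSpatialErrorModel:
    def test_zero_lambda_data_reduce_to_ols(self, rng, rook30):
        n = 900
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = x @ [1.0, 2.0] + rng.normal(size=n)
        fit = fit_spatial_error_model(y, x, rook30)
        ols = fit_ols(y, x)
        assert abs(fit.lambda_err) < 0.05
        assert fit.beta == pytest.approx(ols.beta, abs=0.05)

    def test_lambda_recovery_on_planted_process(self, rng, rook30):
        sampler = _SARSampler(rook30, 0.5)
        n = 900
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        lams, betas = [], []
        for _ in range(20):
            y = x @ [1.0, 2.0] + sampler._lu.solve(rng.normal(size=n))
            fit = fit_spatial_error_model(y, x, rook30)
            lams.append(fit.lambda_err)
            betas.append(fit.beta[1])
        assert abs(np.mean(lams) - 0.5) <= 0.1
        assert 1.9 <= np.mean(betas) <= 2.1


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3])) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        q = bh_adjust(np.full(5, 0.2))
        assert q == pytest.approx(np.full(5, 0.2))

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=25)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_monotone_and_dominates_p(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        # order-preserving
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust(np.array([0.5, 1.2]))


@pytest.fixture(scope="module")
def planted():
    return generate_benchmark_dataset(
        grid=(20, 20), p_informative=1, p_noise=20, delta=1.0,
        rho_gen=0.6, n_slices=5, seed=99,
    )


class TestSelectClusterIons:

    def test_planted_ion_selected_and_nulls_rejected(self, planted):
        ft, labels, truth = planted
        sel = select_cluster_ions(ft, labels, cluster=2, method="SL", lag_distance=1)
        assert set(sel.final) == set(truth.informative)
        assert sel.signs[truth.informative[0]] == 1  # high in the effect class

    def test_constant_ion_never_selected(self, planted):
        ft, labels, truth = planted
        ft2 = ft.replace_matrix(np.column_stack([ft.matrix, np.ones(ft.n_pixels)]),
                                centers=np.append(ft.centers, 999.0))
        sel = select_cluster_ions(ft2, labels, cluster=2, method="SL", lag_distance=1)
        assert 999.0 not in sel.final

    def test_intersection_rule_excludes_partially_significant_ions(self, planted):
        ft, labels, truth = planted
        sel = select_cluster_ions(ft, labels, cluster=2, method="SL", lag_distance=1)
        slices = list(sel.per_slice)
        # an ion significant in some but not all slices must not be final
        union = set().union(*(sel.per_slice_significant(sl) for sl in slices))
        inter = set.intersection(*(sel.per_slice_significant(sl) for sl in slices))
        assert set(sel.final) == inter
        assert all(c not in sel.final for c in union - inter)

    def test_unknown_method_rejected(self, planted):
        ft, labels, _ = planted
        with pytest.raises(ValueError, match="unknown method"):
            select_cluster_ions(ft, labels, cluster=2, method="GWR")

    def test_cluster_absent_from_slice_raises(self, planted):
        ft, labels, _ = planted
        with pytest.raises(ValueError, match="absent"):
            select_cluster_ions(ft, labels, cluster=7, method="OLS")
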