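"""Spatially aware regression and cluster-marker ion selection.

Ion images are spatially autocorrelated, so ordinary least squares (OLS)
on a cluster-indicator design wildly understates the uncertainty of the
cluster effect and floods any selection with false positives.  Two
simultaneous-autoregressive alternatives fix this:

* spatial lag model (SL):    y = rho * W y + X beta + eps
* spatial error model (SE):  y = X beta + u,  u = lambda * W u + eps

with W a row-standardised spatial weight matrix.  Both are fitted by
maximum likelihood via the concentrated log-likelihood over the scalar
autoregressive parameter; the log-determinant term ln|I - rho W| is
evaluated exactly through the cached eigenvalues of W, and Wald standard
errors come from the observed information (numerical Hessian of the full
log-likelihood at the optimum).

Marker ions for a tissue cluster are selected per section by regressing
each ion image on the one-vs-rest cluster indicator, adjusting the
indicator p-values with Benjamini-Hochberg across ions, and intersecting
the significant sets over all sections: an ion counts only if it separates
the cluster in every section examined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .spatial import SpatialWeights, build_weights

__all__ = [
    "RegressionFit",
    "fit_ols",
    "SpatialLagModel",
    "SpatialErrorModel",
    "fit_spatial_lag_model",
    "fit_spatial_error_model",
    "bh_adjust",
    "IonSelection",
    "select_cluster_ions",
]

EIGEN_LIMIT_DEFAULT = 5000


@dataclass
class RegressionFit:
    """Common result container for OLS/SL/SE fits."""

    method: str
    beta: np.ndarray
    se_beta: np.ndarray
    p_beta: np.ndarray
    sigma2: float
    loglik: float
    rho: float | None = None
    lambda_err: float | None = None
    se_rho: float | None = None
    converged: bool = True


def _design(x: np.ndarray, add_intercept: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if add_intercept:
        x = np.hstack([np.ones((x.shape[0], 1)), x])
    return x


def fit_ols(y: np.ndarray, x: np.ndarray, add_intercept: bool = False) -> RegressionFit:
    """Ordinary least squares with classical Wald inference.

    ``x`` is the full design (pass ``add_intercept=True`` to prepend a
    constant).  Gaussian ML log-likelihood is reported so that OLS is
    exactly the rho = 0 (lambda = 0) special case of the spatial models.
    """
    from scipy import stats

    y = np.asarray(y, dtype=float)
    x = _design(x, add_intercept)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("singular design matrix (rank-deficient)")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sse = float(resid @ resid)
    dof = n - p
    s2 = sse / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_beta = np.where(se > 0, 2 * stats.t.sf(np.abs(t), max(dof, 1)), np.where(beta == 0, 1.0, 0.0))
    sigma2_ml = sse / n
    loglik = -0.5 * n * (np.log(2 * np.pi * max(sigma2_ml, 1e-300)) + 1.0)
    return RegressionFit(
        method="OLS", beta=beta, se_beta=se, p_beta=p_beta, sigma2=s2, loglik=loglik
    )


def _feasible_interval(eigvals: np.ndarray, shrink: float = 1e-6) -> tuple[float, float]:
    w_min = eigvals.min()
    w_max = eigvals.max()
    lo = 1.0 / w_min if w_min < 0 else -1.0 + shrink
    hi = 1.0 / w_max if w_max > 0 else 1.0 - shrink
    span = hi - lo
    return lo + shrink * span, hi - shrink * span


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                hess[i, i] = (f(theta + ei) - 2 * f(theta) + f(theta - ei)) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return hess


def _wald(theta: np.ndarray, loglik_fn, n_beta: int) -> tuple[np.ndarray, float]:
    """Standard errors from the observed information matrix."""
    from scipy import stats  # noqa: F401  (used by callers)

    hess = _numerical_hessian(loglik_fn, theta)
    try:
        cov = np.linalg.inv(-hess)
        diag = np.diag(cov).copy()
        if (diag <= 0).any():
            raise np.linalg.LinAlgError
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        warnings.warn("observed information not positive definite; SEs set to NaN")
        se = np.full(len(theta), np.nan)
    return se[:n_beta], float(se[n_beta])


class _BaseSpatialML(RegressorMixin, BaseEstimator):
    """Shared machinery of the SL and SE maximum-likelihood fits."""

    _param_name = "rho"

    def __init__(self, weights: SpatialWeights | None = None, add_intercept: bool = True,
                 eigen_limit: int = EIGEN_LIMIT_DEFAULT, tol: float = 1e-8):
        self.weights = weights
        self.add_intercept = add_intercept
        self.eigen_limit = eigen_limit
        self.tol = tol

    def _prepare(self, X, y):
        if self.weights is None:
            raise ValueError("a row-standardized SpatialWeights object is required")
        if self.weights.style != "row_standardized":
            raise ValueError("spatial ML models require row-standardized weights")
        y = np.asarray(y, dtype=float).ravel()
        x = _design(X, self.add_intercept)
        n = len(y)
        if n != self.weights.n:
            raise ValueError("response length does not match the weight matrix")
        if n > self.eigen_limit:
            raise ValueError(
                f"n = {n} exceeds the eigen limit {self.eigen_limit}; tile the image "
                "or raise eigen_limit"
            )
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("singular design matrix (rank-deficient)")
        eig = self.weights.eigenvalues()
        return x, y, n, eig

    def fit(self, X, y):
        from scipy import stats

        x, y, n, eig = self._prepare(X, y)
        lo, hi = _feasible_interval(eig)

        neg = lambda a: -self._concentrated(a, x, y, n, eig)
        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                       options={"xatol": self.tol})
        a_hat = float(res.x)
        boundary_tol = 1e-4 * (hi - lo)
        converged = bool(res.success) and (lo + boundary_tol < a_hat < hi - boundary_tol)
        if not converged:
            warnings.warn(
                f"{self._param_name} optimizer stopped at the interval boundary "
                f"({a_hat:.6f}); estimates may be unreliable"
            )

        beta, sigma2 = self._coefficients(a_hat, x, y, n)
        theta = np.concatenate([beta, [a_hat, sigma2]])
        ll = lambda th: self._full_loglik(th, x, y, n, eig)
        se_beta, se_a = _wald(theta, ll, x.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se_beta
        p_beta = 2 * stats.norm.sf(np.abs(z))

        self.n_features_in_ = x.shape[1] - int(self.add_intercept)
        self.coef_ = beta[1:] if self.add_intercept else beta
        self.intercept_ = beta[0] if self.add_intercept else 0.0
        self.sigma2_ = sigma2
        self.loglik_ = float(ll(theta))
        self.se_beta_ = se_beta
        self.pvalues_ = p_beta
        self._set_autoreg(a_hat, se_a)
        self.results_ = RegressionFit(
            method=self._method_label,
            beta=beta,
            se_beta=se_beta,
            p_beta=p_beta,
            sigma2=sigma2,
            loglik=self.loglik_,
            rho=a_hat if self._param_name == "rho" else None,
            lambda_err=a_hat if self._param_name == "lambda" else None,
            se_rho=se_a,
            converged=converged,
        )
        return self

    # subclass hooks -------------------------------------------------------
    def _concentrated(self, a, x, y, n, eig):  # pragma: no cover - abstract
        raise NotImplementedError

    def _coefficients(self, a, x, y, n):  # pragma: no cover - abstract
        raise NotImplementedError

    def _full_loglik(self, theta, x, y, n, eig):  # pragma: no cover - abstract
        raise NotImplementedError

    def _set_autoreg(self, a, se):  # pragma: no cover - abstract
        raise NotImplementedError


class SpatialLagModel(_BaseSpatialML):
    """ML spatial lag model y = rho W y + X beta + eps.

    Parameters
    ----------
    weights : SpatialWeights (row-standardized)
    add_intercept : bool, default True
    eigen_limit : int
        Refuse fits beyond this n (dense eigendecomposition cost guard).

    Attributes
    ----------
    coef_, intercept_, rho_, sigma2_, se_beta_, pvalues_, loglik_, results_
    """

    _param_name = "rho"
    _method_label = "SL"

    def _aux(self, x, y):
        # residual-maker applications cached per (x, y) within one fit
        wy = self.weights.lag(y)
        beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
        betad, *_ = np.linalg.lstsq(x, wy, rcond=None)
        e0 = y - x @ beta0
        ed = wy - x @ betad
        return wy, e0, ed

    def _concentrated(self, rho, x, y, n, eig):
        if not hasattr(self, "_cache"):
            self._cache = self._aux(x, y)
        _, e0, ed = self._cache
        e = e0 - rho * ed
        sse = float(e @ e)
        return -0.5 * n * np.log(max(sse, 1e-300) / n) + np.sum(np.log1p(-rho * eig))

    def _coefficients(self, rho, x, y, n):
        wy, _, _ = self._cache
        ay = y - rho * wy
        beta, *_ = np.linalg.lstsq(x, ay, rcond=None)
        resid = ay - x @ beta
        sigma2 = float(resid @ resid) / n
        return beta, sigma2

    def _full_loglik(self, theta, x, y, n, eig):
        beta, rho, sigma2 = theta[:-2], theta[-2], theta[-1]
        if sigma2 <= 0:
            return -np.inf
        if np.any(1.0 - rho * eig <= 0):
            return -np.inf
        wy = self._cache[0]
        resid = y - rho * wy - x @ beta
        return (
            -0.5 * n * np.log(2 * np.pi * sigma2)
            + np.sum(np.log1p(-rho * eig))
            - float(resid @ resid) / (2 * sigma2)
        )

    def _set_autoreg(self, a, se):
        self.rho_ = a
        self.se_rho_ = se

    def fit(self, X, y):
        if hasattr(self, "_cache"):
            del self._cache
        return super().fit(X, y)

    def predict(self, X):
        """Signal part X beta (the systematic component given zero lag)."""
        check_is_fitted(self)
        x = _design(X, self.add_intercept)
        return x @ np.concatenate([[self.intercept_], np.atleast_1d(self.coef_)]) \
            if self.add_intercept else x @ np.atleast_1d(self.coef_)


class SpatialErrorModel(_BaseSpatialML):
    """ML spatial error model y = X beta + u, u = lambda W u + eps.

    The concentrated likelihood uses the spatially filtered regression of
    (I - lambda W) y on (I - lambda W) X.
    """

    _param_name = "lambda"
    _method_label = "SE"

    def _aux(self, x, y):
        return self.weights.lag(y), np.column_stack(
            [self.weights.lag(x[:, j]) for j in range(x.shape[1])]
        )

    def _filtered_fit(self, lam, x, y):
        wy, wx = self._cache
        ys = y - lam * wy
        xs = x - lam * wx
        beta, *_ = np.linalg.lstsq(xs, ys, rcond=None)
        resid = ys - xs @ beta
        return beta, float(resid @ resid)

    def _concentrated(self, lam, x, y, n, eig):
        if not hasattr(self, "_cache"):
            self._cache = self._aux(x, y)
        _, sse = self._filtered_fit(lam, x, y)
        return -0.5 * n * np.log(max(sse, 1e-300) / n) + np.sum(np.log1p(-lam * eig))

    def _coefficients(self, lam, x, y, n):
        beta, sse = self._filtered_fit(lam, x, y)
        return beta, sse / n

    def _full_loglik(self, theta, x, y, n, eig):
        beta, lam, sigma2 = theta[:-2], theta[-2], theta[-1]
        if sigma2 <= 0:
            return -np.inf
        if np.any(1.0 - lam * eig <= 0):
            return -np.inf
        wy, wx = self._cache
        u = y - x @ beta
        wu = wy - wx @ beta
        resid = u - lam * wu
        return (
            -0.5 * n * np.log(2 * np.pi * sigma2)
            + np.sum(np.log1p(-lam * eig))
            - float(resid @ resid) / (2 * sigma2)
        )

    def _set_autoreg(self, a, se):
        self.lambda_ = a
        self.se_lambda_ = se

    def fit(self, X, y):
        if hasattr(self, "_cache"):
            del self._cache
        return super().fit(X, y)

    def predict(self, X):
        check_is_fitted(self)
        x = _design(X, self.add_intercept)
        full = np.concatenate([[self.intercept_], np.atleast_1d(self.coef_)]) \
            if self.add_intercept else np.atleast_1d(self.coef_)
        return x @ full


def fit_spatial_lag_model(y, x, weights: SpatialWeights, add_intercept: bool = False,
                          **kwargs) -> RegressionFit:
    """Functional wrapper returning a :class:`RegressionFit`."""
    est = SpatialLagModel(weights=weights, add_intercept=add_intercept, **kwargs)
    return est.fit(x, y).results_


def fit_spatial_error_model(y, x, weights: SpatialWeights, add_intercept: bool = False,
                            **kwargs) -> RegressionFit:
    est = SpatialErrorModel(weights=weights, add_intercept=add_intercept, **kwargs)
    return est.fit(x, y).results_


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q(i) = min over j >= i of p(j) * m / j (on sorted p), capped at 1.
    Monotone, idempotent, and q >= p elementwise.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


_METHODS = {"OLS": None, "SL": SpatialLagModel, "SE": SpatialErrorModel}


@dataclass
class IonSelection:
    """Per-cluster marker ion selection across sections."""

    cluster: int
    method: str
    alpha: float
    per_slice: dict = field(default_factory=dict)  # slice -> {center: (adj_p, coef)}
    final: list = field(default_factory=list)  # centers significant in every slice
    signs: dict = field(default_factory=dict)  # center -> +1 (high in cluster) / -1

    def per_slice_significant(self, slice_id) -> set:
        return {c for c, (q, _) in self.per_slice[slice_id].items() if q <= self.alpha}


def _indicator_pvalue(y, ind, method, weights):
    """(p-value, coefficient) of the cluster indicator for one ion image."""
    x = np.column_stack([np.ones_like(ind, dtype=float), ind.astype(float)])
    if np.std(y) == 0:
        return 1.0, 0.0
    if method == "OLS":
        fit = fit_ols(y, x)
    else:
        est = _METHODS[method](weights=weights, add_intercept=False)
        fit = est.fit(x, y).results_
    return float(fit.p_beta[1]), float(fit.beta[1])


def select_cluster_ions(
    ft,
    labels: np.ndarray,
    cluster: int,
    slices=None,
    method: str = "SL",
    alpha: float = 0.05,
    lag_distance: float = 5.0,
    eigen_limit: int = EIGEN_LIMIT_DEFAULT,
) -> IonSelection:
    """One-vs-rest marker selection for a tissue cluster.

    Per slice: every ion image is regressed on the binary
    cluster-vs-rest indicator with the chosen method (OLS/SL/SE; spatial
    weights built per slice at ``lag_distance``); indicator p-values are
    BH-adjusted across ions within the slice, and ions with adjusted
    p <= alpha are significant.  The final set is the intersection over all
    slices, with the coefficient sign recording whether the ion is high
    (+1) or low (-1) inside the cluster.

    Parameters
    ----------
    ft : FeatureTable
    labels : per-pixel cluster labels aligned with ``ft.pixels``
    cluster : cluster id of interest
    slices : iterable of slice ids (default: all slices in the table)
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    labels = np.asarray(labels)
    slice_col = ft.pixels["slice_id"].to_numpy()
    if slices is None:
        slices = list(pd.unique(slice_col))

    sel = IonSelection(cluster=cluster, method=method, alpha=alpha)
    sig_sets = []
    coef_by_center: dict[float, list[float]] = {}

    for sl in slices:
        in_slice = slice_col == sl
        if not in_slice.any():
            raise ValueError(f"slice {sl!r} has no pixels")
        ind = (labels[in_slice] == cluster).astype(float)
        if ind.sum() == 0:
            raise ValueError(f"cluster {cluster} absent from slice {sl!r}")
        if ind.sum() == ind.size:
            raise ValueError(f"cluster {cluster} covers all of slice {sl!r}")
        weights = None
        if method != "OLS":
            coords = ft.coords[in_slice]
            weights = build_weights(coords, threshold=lag_distance,
                                    style="row_standardized")
        pvals = np.empty(ft.n_bins)
        coefs = np.empty(ft.n_bins)
        for j in range(ft.n_bins):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals[j], coefs[j] = _indicator_pvalue(
                    ft.matrix[in_slice, j], ind, method, weights
                )
        qvals = bh_adjust(pvals)
        sel.per_slice[sl] = {
            float(c): (float(q), float(b))
            for c, q, b in zip(ft.centers, qvals, coefs)
        }
        sig = {float(c) for c, q in zip(ft.centers, qvals) if q <= alpha}
        sig_sets.append(sig)
        for c, b in zip(ft.centers, coefs):
            coef_by_center.setdefault(float(c), []).append(float(b))

    final = set.intersection(*sig_sets) if sig_sets else set()
    sel.final = sorted(final)
    sel.signs = {c: (1 if np.mean(coef_by_center[c]) > 0 else -1) for c in sel.final}
    return sel
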