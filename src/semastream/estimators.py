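"""scikit-learn style estimators over the multilevel-model core.

All three estimators share the fit/predict contract:

``fit(X, y, Z=None, groups=None)`` — X is the (n, p) fixed-effect design
(include the constant column yourself), Z the (n, r) random-effect
design (defaults to a lone constant column, i.e. a random intercept),
``groups`` the per-row individual identifiers.  ``predict(X, Z, groups)``
returns x'beta + z'b_hat, falling back to x'beta for unseen individuals.

The streaming estimators additionally support ``partial_fit`` with the
same signature; rows are consumed in order, one prequential update per
row.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .em import BatchData, fit_em
from .model import DataPoint, ModelParameters
from .sema import GlobalState, init_warm_start
from .window import SWEMState

__all__ = ["EMRegressor", "SEMARegressor", "SlidingWindowEMRegressor"]


def _check_xyz(X, y, Z, groups):
    X = check_array(X, dtype=float)
    n = X.shape[0]
    if y is not None:
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
    if Z is None:
        Z = np.ones((n, 1))
    else:
        Z = check_array(Z, dtype=float)
        if Z.shape[0] != n:
            raise ValueError("X and Z have inconsistent lengths")
    if groups is None:
        raise ValueError("groups (per-row individual ids) are required")
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise ValueError("X and groups have inconsistent lengths")
    return X, y, Z, groups


class _MixedPredictMixin:
    """Shared x'beta + z'b_hat prediction over a fitted b_hat lookup."""

    def _b_hat_for(self, g):
        raise NotImplementedError

    def predict(self, X, Z=None, groups=None):
        check_is_fitted(self, "beta_")
        X, _, Z, groups = _check_xyz(X, None, Z, groups)
        out = X @ self.beta_
        for i, g in enumerate(groups):
            b = self._b_hat_for(g)
            if b is not None:
                out[i] += float(Z[i] @ b)
        return out


class EMRegressor(_MixedPredictMixin, RegressorMixin, BaseEstimator):
    """Batch EM estimator of the linear multilevel model.

    Parameters
    ----------
    tol : float
        Convergence threshold on the largest absolute parameter change.
    max_iter : int
        Iteration cap.
    start : ModelParameters or None
        Optional start values; by default an OLS-based start is used.
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 800, start=None):
        self.tol = tol
        self.max_iter = max_iter
        self.start = start

    def fit(self, X, y, Z=None, groups=None):
        X, y, Z, groups = _check_xyz(X, y, Z, groups)
        data = BatchData.from_arrays(X, y, Z, groups)
        params, trace = fit_em(data, start=self.start, tol=self.tol,
                               max_iter=self.max_iter)
        from .em import posteriors_at

        self.params_ = params
        self.beta_ = params.beta
        self.phi_ = params.phi
        self.sigma2_ = params.sigma2
        self.trace_ = trace
        self.n_iter_ = len(trace)
        self.random_effects_ = {
            g: post.b_hat for g, post in posteriors_at(params, data).items()
        }
        self.n_features_in_ = X.shape[1]
        return self

    def _b_hat_for(self, g):
        return self.random_effects_.get(g)


class SEMARegressor(_MixedPredictMixin, RegressorMixin, BaseEstimator):
    """Streaming EM (SEMA) estimator: one E-step for the arriving
    individual plus an immediate M-step per data point.

    Parameters
    ----------
    warm_start_n : int or None
        Rows buffered for the warm-start batch EM.  ``None`` switches to
        the automatic rule: wait until X'X has full rank and at least
        ``max(5 p, min_warmup)`` rows arrived.
    sweep_every : int or None
        Cadence of full sweeps over all individuals ("SEMA Update");
        ``None`` disables sweeps (plain SEMA).
    tol, max_iter : warm-start EM controls.
    start : optional ModelParameters for the warm-start EM.
    reinvert_every : direct re-inversion cadence for the maintained
        (X'X)^{-1} (Sherman-Morrison drift control).
    """

    def __init__(self, warm_start_n: int | None = 2000,
                 sweep_every: int | None = None, tol: float = 1e-4,
                 max_iter: int = 800, start=None, min_warmup: int = 100,
                 reinvert_every: int = 100_000):
        self.warm_start_n = warm_start_n
        self.sweep_every = sweep_every
        self.tol = tol
        self.max_iter = max_iter
        self.start = start
        self.min_warmup = min_warmup
        self.reinvert_every = reinvert_every

    def fit(self, X, y, Z=None, groups=None):
        self._reset()
        return self.partial_fit(X, y, Z=Z, groups=groups)

    def partial_fit(self, X, y, Z=None, groups=None):
        X, y, Z, groups = _check_xyz(X, y, Z, groups)
        if not hasattr(self, "_buffer"):
            self._reset()
        for i in range(X.shape[0]):
            self._push(groups[i], X[i], Z[i], y[i])
        self._sync_fitted()
        return self

    def _reset(self):
        self._buffer = []
        self._state = None
        self._since_sweep = 0
        for attr in ("beta_", "phi_", "sigma2_", "params_", "state_",
                     "n_features_in_"):
            if hasattr(self, attr):
                delattr(self, attr)

    def _warmup_complete(self, p: int) -> bool:
        if self.warm_start_n is not None:
            return len(self._buffer) >= self.warm_start_n
        if len(self._buffer) < max(5 * p, self.min_warmup):
            return False
        X = np.stack([pt.x for pt in self._buffer])
        return np.linalg.matrix_rank(X.T @ X) >= p

    def _push(self, g, x, z, y):
        if self._state is None:
            self._buffer.append(DataPoint(g, float(y), x, z))
            if self._warmup_complete(x.shape[0]):
                self._state = init_warm_start(
                    self._buffer, start=self.start, tol=self.tol,
                    max_iter=self.max_iter,
                    reinvert_every=self.reinvert_every,
                )
                self._buffer = []
            return
        self._state.process_raw(g, x, z, y)
        if self.sweep_every is not None:
            self._since_sweep += 1
            if self._since_sweep >= self.sweep_every:
                self._state.sweep()
                self._since_sweep = 0

    def _sync_fitted(self):
        if self._state is None:
            return
        self.state_ = self._state
        self.params_ = self._state.params
        self.beta_ = self._state.params.beta
        self.phi_ = self._state.params.phi
        self.sigma2_ = self._state.params.sigma2
        self.n_features_in_ = self._state.p

    def _b_hat_for(self, g):
        ind = self.state_.individuals.get(g)
        return None if ind is None else ind.b_hat


class SlidingWindowEMRegressor(_MixedPredictMixin, RegressorMixin, BaseEstimator):
    """Sliding-window EM: batch refits over the m most recent points."""

    def __init__(self, window: int = 10_000, refit_every: int = 1000,
                 max_iter: int = 20, warm_start_n: int = 2000,
                 tol: float = 1e-4, start=None):
        self.window = window
        self.refit_every = refit_every
        self.max_iter = max_iter
        self.warm_start_n = warm_start_n
        self.tol = tol
        self.start = start

    def fit(self, X, y, Z=None, groups=None):
        for attr in ("_buffer", "_sw"):
            if hasattr(self, attr):
                delattr(self, attr)
        return self.partial_fit(X, y, Z=Z, groups=groups)

    def partial_fit(self, X, y, Z=None, groups=None):
        X, y, Z, groups = _check_xyz(X, y, Z, groups)
        if not hasattr(self, "_buffer"):
            self._buffer = []
            self._sw = None
        for i in range(X.shape[0]):
            pt = DataPoint(groups[i], float(y[i]), X[i], Z[i])
            if self._sw is None:
                self._buffer.append(pt)
                if len(self._buffer) >= self.warm_start_n:
                    params, _ = fit_em(
                        BatchData.from_points(self._buffer), start=self.start,
                        tol=self.tol, max_iter=800,
                    )
                    self._sw = SWEMState(
                        X.shape[1], Z.shape[1], params, window=self.window,
                        refit_every=self.refit_every, max_iter=self.max_iter,
                    )
                    for buffered in self._buffer:
                        evicted = self._sw.buffer.push(buffered)
                        self._sw._add(buffered, +1.0)
                        if evicted is not None:
                            self._sw._add(evicted, -1.0)
                    self._sw._since_refit = 0
                    self._buffer = []
                continue
            self._sw.process(pt)
        if self._sw is not None:
            self.params_ = self._sw.params
            self.beta_ = self._sw.params.beta
            self.phi_ = self._sw.params.phi
            self.sigma2_ = self._sw.params.sigma2
            self.n_features_in_ = X.shape[1]
            self.state_ = self._sw
        return self

    def _b_hat_for(self, g):
        c = self._sw._cross.get(g)
        if c is None:
            return None
        C = c.ZtZ + self.sigma2_ * np.linalg.inv(self.phi_)
        return np.linalg.solve(C, c.Zty - c.ZtX @ self.beta_)
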