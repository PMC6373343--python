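"""Batch (offline) EM for the linear multilevel model.

This is the classical reference estimator: the E-step imputes the random
effects b_j and accumulates the complete-data sufficient statistics
(CDSS) t1, T2, t3; the M-step solves the closed-form maximizers

    beta   = (sum_j X_j'X_j)^{-1} (sum_j X_j'y_j - t1)
    Phi    = T2 / J
    sigma2 = t3 / n.

Internally the E-step works from per-individual cross-products
(Z'Z, X'Z, Z'y, ...), which is algebraically identical to summing over
raw rows but makes one EM iteration O(J) instead of O(n).  The raw-row
and cross-product routes are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .model import DataPoint, ModelParameters, RandomEffectPosterior, marginal_loglik

__all__ = [
    "CDSS",
    "Block",
    "BatchData",
    "random_effects_posterior",
    "e_step",
    "m_step",
    "fit_em",
]


class Block(NamedTuple):
    """Raw data of one individual: X (n_j x p), Z (n_j x r), y (n_j)."""

    individual_id: object
    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray


@dataclass
class CDSS:
    """Complete-data sufficient statistics.

    t1 (p-vector) feeds beta, T2 (r x r) feeds Phi, t3 (scalar) feeds
    sigma^2.  ``sum_C_inv`` (sum_j C_j^{-1}) is retained for diagnostics.
    """

    t1: np.ndarray
    T2: np.ndarray
    t3: float
    sum_C_inv: np.ndarray

    def validate(self) -> "CDSS":
        if np.max(np.abs(self.T2 - self.T2.T)) > 1e-10:
            raise ValueError("T2 is not symmetric")
        if self.t3 < -1e-8:
            raise ValueError("t3 is negative beyond numerical slack")
        return self


class BatchData:
    """Per-individual raw blocks plus total counts n and J."""

    def __init__(self, blocks: Sequence[Block]):
        self._blocks = list(blocks)
        for b in self._blocks:
            if len(b.y) < 1:
                raise ValueError(f"individual {b.individual_id} has no rows")
        self.J = len(self._blocks)
        self.n = int(sum(len(b.y) for b in self._blocks))
        if self.J:
            self.p = self._blocks[0].X.shape[1]
            self.r = self._blocks[0].Z.shape[1]
        else:
            self.p = self.r = 0

    def blocks(self) -> Sequence[Block]:
        return self._blocks

    @classmethod
    def from_arrays(cls, X, y, Z, groups) -> "BatchData":
        X = np.asarray(X, float)
        Z = np.asarray(Z, float)
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        blocks = []
        # preserve first-appearance order of individuals
        _, first = np.unique(groups, return_index=True)
        for g in groups[np.sort(first)]:
            m = groups == g
            blocks.append(Block(g, X[m], Z[m], y[m]))
        return cls(blocks)

    @classmethod
    def from_points(cls, points: Sequence[DataPoint]) -> "BatchData":
        by_id: dict = {}
        order = []
        for pt in points:
            if pt.individual_id not in by_id:
                by_id[pt.individual_id] = ([], [], [])
                order.append(pt.individual_id)
            xs, zs, ys = by_id[pt.individual_id]
            xs.append(pt.x)
            zs.append(pt.z)
            ys.append(pt.y)
        blocks = [
            Block(g, np.array(by_id[g][0]), np.array(by_id[g][1]),
                  np.array(by_id[g][2]))
            for g in order
        ]
        return cls(blocks)

    def suff_stats(self) -> "_SuffStats":
        return _SuffStats.from_batch(self)


class _SuffStats:
    """Stacked per-individual cross-products; everything an EM iteration needs."""

    __slots__ = ("ids", "ZtZ", "XtZ", "Zty", "yty", "XtX", "Xty", "n", "J", "p", "r")

    @classmethod
    def from_batch(cls, data: BatchData) -> "_SuffStats":
        self = cls()
        self.n, self.J, self.p, self.r = data.n, data.J, data.p, data.r
        self.ids = [b.individual_id for b in data.blocks()]
        self.ZtZ = np.stack([b.Z.T @ b.Z for b in data.blocks()])
        self.XtZ = np.stack([b.X.T @ b.Z for b in data.blocks()])
        self.Zty = np.stack([b.Z.T @ b.y for b in data.blocks()])
        self.yty = np.array([b.y @ b.y for b in data.blocks()])
        self.XtX = sum(b.X.T @ b.X for b in data.blocks())
        self.Xty = sum(b.X.T @ b.y for b in data.blocks())
        return self


def _phi_inverse(phi: np.ndarray) -> np.ndarray:
    sign, _ = np.linalg.slogdet(phi)
    if sign <= 0:
        raise np.linalg.LinAlgError("phi is singular; cannot run the E-step")
    return np.linalg.inv(phi)


def random_effects_posterior(
    params: ModelParameters, X_j, Z_j, y_j
) -> RandomEffectPosterior:
    """Posterior of one individual's random effects at the current parameters.

    C_j = Z_j'Z_j + sigma^2 Phi^{-1};  b_hat_j = C_j^{-1}(Z_j'y_j - Z_j'X_j beta).
    With zero rows the posterior collapses to the prior mean: C_j =
    sigma^2 Phi^{-1}, b_hat_j = 0.
    """
    phi_inv = _phi_inverse(params.phi)
    X_j = np.asarray(X_j, float).reshape(-1, params.p)
    Z_j = np.asarray(Z_j, float).reshape(-1, params.r)
    y_j = np.asarray(y_j, float).reshape(-1)
    C = Z_j.T @ Z_j + params.sigma2 * phi_inv
    C_inv = np.linalg.inv(C)
    b_hat = C_inv @ (Z_j.T @ y_j - Z_j.T @ X_j @ params.beta)
    return RandomEffectPosterior(b_hat, C, C_inv)


def _e_step_core(params: ModelParameters, ss: _SuffStats):
    """Vectorized E-step over stacked per-individual cross-products.

    Returns (CDSS, b_hat (J x r), C_inv (J x r x r)).
    """
    phi_inv = _phi_inverse(params.phi)
    s2 = params.sigma2
    beta = params.beta
    C = ss.ZtZ + s2 * phi_inv  # (J, r, r)
    C_inv = np.linalg.inv(C)
    rhs = ss.Zty - np.einsum("jpa,p->ja", ss.XtZ, beta)
    b = np.einsum("jab,jb->ja", C_inv, rhs)

    t1 = np.einsum("jpa,ja->p", ss.XtZ, b)
    sum_C_inv = C_inv.sum(axis=0)
    T2 = np.einsum("ja,jb->ab", b, b) + s2 * sum_C_inv
    # residual sum of squares via the cross-product expansion of u'u
    rss = (
        ss.yty.sum()
        + float(beta @ ss.XtX @ beta)
        + np.einsum("ja,jab,jb->", b, ss.ZtZ, b)
        - 2.0 * float(ss.Xty @ beta)
        - 2.0 * np.einsum("ja,ja->", ss.Zty, b)
        + 2.0 * float(beta @ t1)
    )
    trace = np.einsum("jab,jba->", C_inv, ss.ZtZ)
    t3 = rss + s2 * trace
    return CDSS(t1, 0.5 * (T2 + T2.T), float(t3), sum_C_inv), b, C_inv


def e_step(params: ModelParameters, data: BatchData):
    """One E-step: CDSS plus the per-individual random-effect posteriors.

    t1 = sum_j X_j'Z_j b_hat_j
    T2 = sum_j b_hat_j b_hat_j' + sigma^2 sum_j C_j^{-1}
    t3 = sum_j u_j'u_j + sigma^2 sum_j tr(C_j^{-1} Z_j'Z_j),
         u_j = y_j - X_j beta - Z_j b_hat_j.
    """
    ss = data.suff_stats() if isinstance(data, BatchData) else data
    cdss, b, C_inv = _e_step_core(params, ss)
    phi_inv = _phi_inverse(params.phi)
    posteriors = {
        ss.ids[j]: RandomEffectPosterior(
            b[j], ss.ZtZ[j] + params.sigma2 * phi_inv, C_inv[j]
        )
        for j in range(ss.J)
    }
    return cdss, posteriors


def m_step(cdss: CDSS, XtX: np.ndarray, Xty: np.ndarray, n: int, J: int) -> ModelParameters:
    """Closed-form maximizers given the CDSS and the global cross-products."""
    if J < 1 or n < 1:
        raise ValueError("need n >= 1 and J >= 1")
    XtX = np.atleast_2d(np.asarray(XtX, float))
    Xty = np.atleast_1d(np.asarray(Xty, float))
    rank = np.linalg.matrix_rank(XtX)
    p = XtX.shape[0]
    if rank < p:
        raise np.linalg.LinAlgError(
            f"X'X is rank deficient ({p - rank} deficient dimensions)"
        )
    beta = np.linalg.solve(XtX, Xty - cdss.t1)
    phi = cdss.T2 / J
    phi = 0.5 * (phi + phi.T)
    sigma2 = cdss.t3 / n
    return ModelParameters(beta, phi, sigma2)


def _default_start(ss: _SuffStats) -> ModelParameters:
    """OLS-based start: beta from pooled least squares, Phi = I * s2_ols."""
    beta = np.linalg.lstsq(ss.XtX, ss.Xty, rcond=None)[0]
    rss = ss.yty.sum() - 2.0 * float(ss.Xty @ beta) + float(beta @ ss.XtX @ beta)
    s2 = max(rss / max(ss.n - ss.p, 1), 1e-8)
    return ModelParameters(beta, np.eye(ss.r) * s2, s2)


def fit_em(
    data: BatchData,
    start: ModelParameters | None = None,
    tol: float = 1e-4,
    max_iter: int = 800,
    track_loglik: bool = False,
):
    """Run EM to convergence.

    Convergence is declared when the largest absolute change over all
    parameters (beta entries, lower-triangular Phi entries, sigma^2)
    drops below ``tol``; defaults tol=1e-4, max_iter=800.

    Returns ``(params, trace)`` where ``trace`` is a list of dicts with
    per-iteration parameters (and the marginal log-likelihood when
    ``track_loglik`` is set).
    """
    ss = data.suff_stats() if hasattr(data, "suff_stats") else data
    if ss.n < 1:
        raise ValueError("empty data")
    if track_loglik and not isinstance(data, BatchData):
        raise ValueError("track_loglik requires raw BatchData")
    params = (start or _default_start(ss)).copy()
    trace = []
    for it in range(max_iter):
        cdss, _, _ = _e_step_core(params, ss)
        new = m_step(cdss, ss.XtX, ss.Xty, ss.n, ss.J)
        if not (
            np.all(np.isfinite(new.beta))
            and np.all(np.isfinite(new.phi))
            and np.isfinite(new.sigma2)
        ):
            raise FloatingPointError(f"EM diverged at iteration {it}")
        rec = {"iteration": it, "beta": new.beta.copy(),
               "phi": new.phi.copy(), "sigma2": new.sigma2}
        if track_loglik:
            rec["loglik"] = marginal_loglik(new, data)
        trace.append(rec)
        delta = new.max_abs_diff(params)
        params = new
        if delta < tol:
            break
    return params, trace


def posteriors_at(params: ModelParameters, data: BatchData) -> dict:
    """Per-individual posteriors at fixed parameters (no CDSS bookkeeping)."""
    _, post = e_step(params, data)
    return post


def suffstats_from_summaries(individuals: dict, XtX, Xty, n: int) -> _SuffStats:
    """Assemble EM-ready sufficient statistics from streamed per-individual
    summaries (as accumulated by the online state) without raw data."""
    ss = _SuffStats.__new__(_SuffStats)
    ss.ids = list(individuals)
    inds = [individuals[k] for k in ss.ids]
    ss.ZtZ = np.stack([i.ZtZ for i in inds])
    ss.XtZ = np.stack([i.XtZ for i in inds])
    ss.Zty = np.stack([i.Zty for i in inds])
    ss.yty = np.array([i.yty for i in inds])
    ss.XtX = np.asarray(XtX, float)
    ss.Xty = np.asarray(Xty, float)
    ss.n = int(n)
    ss.J = len(inds)
    ss.p = ss.XtX.shape[0]
    ss.r = ss.ZtZ.shape[1] if ss.J else 0
    return ss
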