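"""Core types and likelihood computations for the linear multilevel model.

The model for observation *i* of individual *j* is

    y_ij = x_ij' beta + z_ij' b_j + eps_ij,
    b_j   ~ MVN(0, Phi),      eps_ij ~ N(0, sigma^2),

with ``beta`` the p fixed effects shared by everyone, ``b_j`` the r
individual-specific random effects with covariance ``Phi``, and
``sigma^2`` the residual variance.  Intercepts are explicit constant-1
columns of ``x`` (and of ``z`` when a random intercept is modelled);
nothing is added implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg as sla

__all__ = [
    "DataPoint",
    "ModelParameters",
    "RandomEffectPosterior",
    "predict",
    "complete_data_loglik",
    "marginal_loglik",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class DataPoint:
    """One streamed observation.

    ``x`` carries the fixed-effect covariates (length p, including the
    constant 1 for the intercept); ``z`` the random-effect covariates
    (length r).  ``individual_id`` is opaque — any hashable value.
    """

    individual_id: object
    y: float
    x: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))

    def is_finite(self) -> bool:
        return bool(
            np.isfinite(self.y)
            and np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.z))
        )


@dataclass
class ModelParameters:
    """The triplet (beta, Phi, sigma^2) the model estimates."""

    beta: np.ndarray
    phi: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.sigma2 = float(self.sigma2)

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def r(self) -> int:
        return self.phi.shape[0]

    def validate(self) -> "ModelParameters":
        """Check symmetry/PSD of Phi and positivity of sigma^2.

        Not run automatically: the streaming hot path rebuilds parameters
        every data point and validates only at module boundaries.
        """
        if self.phi.shape[0] != self.phi.shape[1]:
            raise ValueError("phi must be square")
        if not np.all(np.isfinite(self.beta)) or not np.all(np.isfinite(self.phi)):
            raise ValueError("non-finite parameter value")
        if np.max(np.abs(self.phi - self.phi.T)) > _SYM_TOL:
            raise ValueError("phi is not symmetric")
        if np.linalg.eigvalsh(self.phi).min() < -_SYM_TOL:
            raise ValueError("phi is not positive semi-definite")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        return self

    def copy(self) -> "ModelParameters":
        return ModelParameters(self.beta.copy(), self.phi.copy(), self.sigma2)

    def max_abs_diff(self, other: "ModelParameters") -> float:
        """Largest absolute change over beta, lower-triangular Phi and sigma^2."""
        il = np.tril_indices(self.r)
        return max(
            float(np.max(np.abs(self.beta - other.beta))),
            float(np.max(np.abs(self.phi[il] - other.phi[il]))),
            abs(self.sigma2 - other.sigma2),
        )


@dataclass
class RandomEffectPosterior:
    """Posterior mean b_hat of the random effects and its precision-like C.

    ``C = Z_j'Z_j + sigma^2 Phi^{-1}`` quantifies the information about
    b_j; its inverse (scaled by sigma^2) is the posterior covariance.
    """

    b_hat: np.ndarray
    C: np.ndarray
    C_inv: np.ndarray

    def __post_init__(self):
        self.b_hat = np.atleast_1d(np.asarray(self.b_hat, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.C_inv = np.atleast_2d(np.asarray(self.C_inv, dtype=float))


def predict(point: DataPoint, params: ModelParameters, b_hat=None) -> float:
    """Model prediction x'beta + z'b_hat for one data point.

    For an individual never seen before, pass ``b_hat=None`` (or zeros):
    the prediction falls back to the population mean x'beta.
    """
    x = point.x
    if x.shape[0] != params.p:
        raise ValueError(
            f"x has length {x.shape[0]} but the model has p={params.p}"
        )
    out = float(x @ params.beta)
    if b_hat is not None:
        b_hat = np.asarray(b_hat, dtype=float)
        if b_hat.shape[0] != params.r:
            raise ValueError(
                f"b_hat has length {b_hat.shape[0]} but the model has r={params.r}"
            )
        if point.z.shape[0] != params.r:
            raise ValueError(
                f"z has length {point.z.shape[0]} but the model has r={params.r}"
            )
        out += float(point.z @ b_hat)
    return out


def _as_blocks(data) -> Sequence[tuple]:
    """Accept a BatchData-like object (with .blocks()) or raw (X, Z, y) triples."""
    if hasattr(data, "blocks"):
        return [(b.X, b.Z, b.y) for b in data.blocks()]
    return [(np.asarray(X, float), np.asarray(Z, float), np.asarray(y, float))
            for X, Z, y in data]


def complete_data_loglik(params: ModelParameters, data, b) -> float:
    """Complete-data log-likelihood, treating the b_j as observed.

        -(n/2) ln sigma^2 - (1/2) sum_ij ((y - x'beta - z'b_j)/sigma)^2
        -(J/2) ln|Phi|    - (1/2) sum_j b_j' Phi^{-1} b_j

    The additive -(n/2)ln(2*pi) and -(J*r/2)ln(2*pi) constants are
    deliberately omitted; do not compare this value against
    :func:`marginal_loglik`, which includes its constants.
    """
    blocks = _as_blocks(data)
    b = [np.atleast_1d(np.asarray(bj, dtype=float)) for bj in b]
    if len(b) != len(blocks):
        raise ValueError("need one random-effect vector per individual")
    sign, logdet_phi = np.linalg.slogdet(params.phi)
    if sign <= 0:
        raise np.linalg.LinAlgError("phi is singular or not positive definite")
    phi_inv = np.linalg.inv(params.phi)
    n = sum(len(y) for _, _, y in blocks)
    J = len(blocks)
    ll = -0.5 * n * np.log(params.sigma2) - 0.5 * J * logdet_phi
    for (X, Z, y), bj in zip(blocks, b):
        resid = y - X @ params.beta - Z @ bj
        ll -= 0.5 * float(resid @ resid) / params.sigma2
        ll -= 0.5 * float(bj @ phi_inv @ bj)
    return float(ll)


def marginal_loglik(params: ModelParameters, data) -> float:
    """Observed-data Gaussian log-likelihood with the b_j integrated out.

    Each individual's response vector is MVN with mean X_j beta and
    covariance V_j = Z_j Phi Z_j' + sigma^2 I.  The 2*pi constants ARE
    included here (this function is compared across EM iterations, where
    constants cancel, and against dense-covariance oracles).
    """
    ll = 0.0
    for idx, (X, Z, y) in enumerate(_as_blocks(data)):
        n_j = len(y)
        V = Z @ params.phi @ Z.T + params.sigma2 * np.eye(n_j)
        resid = y - X @ params.beta
        try:
            cho = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"covariance not positive definite for individual index {idx}"
            ) from exc
        except sla.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance not positive definite for individual index {idx}"
            ) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        quad = float(resid @ sla.cho_solve(cho, resid))
        ll += -0.5 * (n_j * np.log(2.0 * np.pi) + logdet + quad)
    return float(ll)
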