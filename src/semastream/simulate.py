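"""Synthetic data-stream generator for the simulation conditions A-D.

The generator emulates a longitudinal monitoring study: J = 1000
individuals, a stream of n = 50,000 observations drawn by sampling an
individual uniformly at each step, 15 fixed effects and either a single
random intercept (condition A) or a random intercept plus four random
slopes with exchangeable correlation 0, .15 or .5 (conditions B, C, D).

Design matrix layout (p = 15 columns of x):

    0       intercept (constant 1)
    1-5     five level-1 continuous covariates, i.i.d. N(0, 1) per
            observation
    6-8     three dummies of a level-1 four-category factor, categories
            equiprobable, resampled per observation, reference coded
    9-11    three level-2 continuous covariates, MVN(0, I) per individual
    12      dummy of a level-2 two-category factor
    13-14   two dummies of a level-2 three-category factor

z is the intercept column alone (condition A) or the intercept plus the
four level-1 continuous covariates whose fixed effects are
0.1, 0.5, 0.9, 1.3 (conditions B-D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DataPoint, ModelParameters

__all__ = [
    "SimulationCondition",
    "Population",
    "condition_preset",
    "make_population",
    "make_stream",
    "stream_arrays",
    "two_regime_stream",
]

# true fixed effects shared by all four conditions
BETA_TRUE = np.array(
    [100.0, 0.1, 0.5, 0.9, 1.3, 1.7, 2.1, 2.5, 2.9, 3.3, 3.7, 4.1, 4.5, 4.9, 5.3]
)


@dataclass(frozen=True)
class SimulationCondition:
    """True parameter bundle for one simulation condition."""

    name: str
    beta: np.ndarray
    random_effect_variances: tuple
    correlation: float  # exchangeable correlation between random effects
    sigma2: float = 5.0
    J: int = 1000
    n_total: int = 50_000

    @property
    def r(self) -> int:
        return len(self.random_effect_variances)

    @property
    def phi(self) -> np.ndarray:
        """Implied random-effect covariance: cov_ab = cor * sqrt(v_a v_b)."""
        var = np.asarray(self.random_effect_variances, float)
        sd = np.sqrt(var)
        phi = self.correlation * np.outer(sd, sd)
        np.fill_diagonal(phi, var)
        if np.linalg.eigvalsh(phi).min() < 0:
            raise ValueError("implied Phi is indefinite")
        return phi

    @property
    def p(self) -> int:
        return len(self.beta)

    def true_params(self) -> ModelParameters:
        return ModelParameters(self.beta.copy(), self.phi, self.sigma2)


_PRESETS = {
    "A": dict(random_effect_variances=(50.0,), correlation=0.0),
    "B": dict(random_effect_variances=(50.0, 0.2, 0.6, 1.8, 5.0), correlation=0.0),
    "C": dict(random_effect_variances=(50.0, 0.2, 0.6, 1.8, 5.0), correlation=0.15),
    "D": dict(random_effect_variances=(50.0, 0.2, 0.6, 1.8, 5.0), correlation=0.5),
}


def condition_preset(name: str) -> SimulationCondition:
    """Return the named condition (A: random intercept only; B/C/D: five
    variance components with exchangeable correlation 0 / .15 / .5)."""
    key = str(name).upper()
    if key not in _PRESETS:
        raise ValueError(f"unknown condition {name!r}; expected one of A, B, C, D")
    return SimulationCondition(name=key, beta=BETA_TRUE.copy(), **_PRESETS[key])


@dataclass
class Population:
    """Level-2 state of the J individuals: covariates and true b_j."""

    condition: SimulationCondition
    level2: np.ndarray  # (J, 6) level-2 design columns (x columns 9..14)
    b: np.ndarray  # (J, r) true random effects

    @property
    def J(self) -> int:
        return self.level2.shape[0]


def make_population(cond: SimulationCondition, seed) -> Population:
    """Draw the J individuals: level-2 covariates and b_j ~ MVN(0, Phi)."""
    rng = np.random.default_rng(seed)
    J = cond.J
    cont = rng.multivariate_normal(np.zeros(3), np.eye(3), size=J)
    two_cat = (rng.integers(0, 2, size=J) == 1).astype(float)[:, None]
    three_cat = rng.integers(0, 3, size=J)
    three_dum = np.column_stack(
        [(three_cat == 1).astype(float), (three_cat == 2).astype(float)]
    )
    level2 = np.column_stack([cont, two_cat, three_dum])
    b = rng.multivariate_normal(np.zeros(cond.r), cond.phi, size=J)
    return Population(cond, level2, b)


def stream_arrays(pop: Population, cond: SimulationCondition | None = None,
                  n_total: int | None = None, seed=None):
    """Generate a stream as arrays (ids, y, X, Z) — the fast path.

    At each step an individual is drawn uniformly, fresh level-1
    covariates are drawn, and y = x'beta + z'b_j + eps with
    eps ~ N(0, sigma^2).
    """
    cond = cond or pop.condition
    n = int(n_total if n_total is not None else cond.n_total)
    rng = np.random.default_rng(seed)
    J, r = pop.J, cond.r

    ids = rng.integers(0, J, size=n)
    cont1 = rng.standard_normal((n, 5))
    cat1 = rng.integers(0, 4, size=n)
    dum1 = np.column_stack([(cat1 == k).astype(float) for k in (1, 2, 3)])
    X = np.column_stack([np.ones(n), cont1, dum1, pop.level2[ids]])
    if r == 1:
        Z = np.ones((n, 1))
    else:
        Z = np.column_stack([np.ones(n), cont1[:, : r - 1]])
    eps = rng.normal(0.0, np.sqrt(cond.sigma2), size=n)
    y = X @ cond.beta + np.einsum("ij,ij->i", Z, pop.b[ids]) + eps
    return ids, y, X, Z


def make_stream(pop: Population, cond: SimulationCondition | None = None,
                n_total: int | None = None, seed=None):
    """Generate a stream as a list of :class:`DataPoint` records."""
    ids, y, X, Z = stream_arrays(pop, cond, n_total, seed)
    return [
        DataPoint(int(ids[t]), float(y[t]), X[t], Z[t]) for t in range(len(y))
    ]


def two_regime_stream(seed, n_total: int = 8000, J: int = 100,
                      shift: float = 20.0, p: int = 3):
    """Small drift stream for sliding-window tests: the intercept jumps by
    ``shift`` at the midpoint of the stream.  Random intercept only."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, 2.0, size=J)
    beta = np.concatenate([[10.0], rng.uniform(0.5, 1.5, size=p - 1)])
    ids = rng.integers(0, J, size=n_total)
    X = np.column_stack([np.ones(n_total), rng.standard_normal((n_total, p - 1))])
    mean_shift = np.where(np.arange(n_total) >= n_total // 2, shift, 0.0)
    y = X @ beta + b[ids] + mean_shift + rng.normal(0.0, 1.0, size=n_total)
    points = [
        DataPoint(int(ids[t]), float(y[t]), X[t], np.ones(1))
        for t in range(n_total)
    ]
    return points, beta, shift
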