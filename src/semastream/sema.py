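"""SEMA: streaming EM for the linear multilevel model.

Every arriving data point triggers three O(1)-in-n steps:

1. *ingest* — rank-one updates of the arriving individual's stored
   cross-products (Z'Z, X'Z, Z'y, X'X_j, X'y_j, sum y^2) and of the
   global X'X (with its inverse maintained by the Sherman–Morrison
   formula), x'y and counts;
2. an *online E-step for that individual only* — its posterior b_hat_j
   and CDSS contributions (t1j, T2j, t3j) are recomputed at the current
   parameters and swapped into the running totals
   (total <- total - old contribution + new contribution);
3. an *online M-step* — beta = (X'X)^{-1}(x'y - t1~), Phi = T2~/J,
   sigma^2 = t3~/n.

Memory grows with the number of individuals J, never with the number of
data points n: per individual only O(p^2 + p r + r^2) numbers are kept.

A periodic *sweep* ("SEMA Update") re-runs the per-individual E-step for
every stored individual — refreshing contributions of individuals who
have not returned — without revisiting any raw data.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .em import BatchData, fit_em
from .model import DataPoint, ModelParameters

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualSummary",
    "GlobalState",
    "sherman_morrison_update",
    "ingest",
    "online_e_step_individual",
    "online_m_step",
    "process_data_point",
    "init_warm_start",
    "sweep",
]

CHECKPOINT_VERSION = 1


def sherman_morrison_update(inv: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Rank-one inverse update: the exact inverse of (inv^{-1} + x x').

        inv <- inv - (inv x x' inv) / (1 + x' inv x)

    Raises a numerical-degeneracy error when the denominator falls below
    1e-12; the caller should then re-invert the maintained raw X'X.
    """
    inv = np.atleast_2d(np.asarray(inv, float))
    x = np.atleast_1d(np.asarray(x, float))
    w = inv @ x
    denom = 1.0 + float(x @ w)
    if denom <= 1e-12:
        raise np.linalg.LinAlgError(
            "Sherman-Morrison denominator is numerically degenerate"
        )
    return inv - np.outer(w, w) / denom


def _floored_phi_inv(phi: np.ndarray) -> np.ndarray:
    """Invert Phi after flooring its eigenvalues at 1e-8 * trace(Phi)/r.

    Early-stream Phi can be near-singular; the floor keeps the E-step's
    Phi^{-1} finite without noticeably moving a well-conditioned Phi.
    """
    r = phi.shape[0]
    if r == 1:
        v = phi[0, 0]
        floor = max(1e-8 * v, 1e-12)
        return np.array([[1.0 / max(v, floor)]])
    tr = float(np.trace(phi))
    floor = max(1e-8 * tr / r, 1e-12)
    vals, vecs = np.linalg.eigh(0.5 * (phi + phi.T))
    vals = np.maximum(vals, floor)
    return (vecs / vals) @ vecs.T


class IndividualSummary:
    """Aggregated state of one individual (theta_j).

    Holds the exact cross-products of that individual's rows, the current
    posterior (b_hat, C, C_inv as plain arrays for speed) and the CDSS
    contributions last pushed into the global totals.
    """

    __slots__ = (
        "n_j", "ZtZ", "XtZ", "Zty", "XtX", "Xty", "yty",
        "b_hat", "C", "C_inv",
        "contrib_t1", "contrib_T2", "contrib_t3",
    )

    def __init__(self, p: int, r: int):
        self.n_j = 0
        self.ZtZ = np.zeros((r, r))
        self.XtZ = np.zeros((p, r))
        self.Zty = np.zeros(r)
        self.XtX = np.zeros((p, p))
        self.Xty = np.zeros(p)
        self.yty = 0.0
        self.b_hat = np.zeros(r)
        self.C = None
        self.C_inv = None
        self.contrib_t1 = np.zeros(p)
        self.contrib_T2 = np.zeros((r, r))
        self.contrib_t3 = 0.0


class GlobalState:
    """All state SEMA carries through a stream (theta + the theta_j map)."""

    def __init__(self, p: int, r: int, params: ModelParameters,
                 reinvert_every: int = 100_000):
        self.p = p
        self.r = r
        self.n = 0
        self.J = 0
        self.XtX = np.zeros((p, p))
        self.XtX_inv = None  # valid only after warm-up
        self.xy = np.zeros(p)
        self.t1 = np.zeros(p)
        self.T2 = np.zeros((r, r))
        self.t3 = 0.0
        self.params = params
        self.individuals: dict = {}
        self.reinvert_every = int(reinvert_every)
        self._updates_since_reinvert = 0

    # -- streaming steps -------------------------------------------------

    def ingest(self, point: DataPoint) -> None:
        """Absorb one data point into the cross-product accumulators.

        No CDSS contribution or parameter changes yet; non-finite records
        are rejected with a warning and the stream continues.
        """
        if not point.is_finite():
            warnings.warn(
                f"rejecting non-finite data point for individual {point.individual_id}"
            )
            return
        x, z, y = point.x, point.z, point.y
        if x.shape[0] != self.p or z.shape[0] != self.r:
            raise ValueError(
                f"data point has (p={x.shape[0]}, r={z.shape[0]}), "
                f"state expects (p={self.p}, r={self.r})"
            )
        self._ingest_raw(point.individual_id, x, z, y)

    def _ingest_raw(self, individual_id, x, z, y) -> None:
        """Unvalidated ingest used by the hot loop (inputs pre-checked)."""
        ind = self.individuals.get(individual_id)
        if ind is None:
            ind = IndividualSummary(self.p, self.r)
            self.individuals[individual_id] = ind
            self.J += 1
        ind.n_j += 1
        ind.ZtZ += np.outer(z, z)
        ind.XtZ += np.outer(x, z)
        ind.Zty += z * y
        ind.XtX += np.outer(x, x)
        ind.Xty += x * y
        ind.yty += y * y

        self.n += 1
        self.XtX += np.outer(x, x)
        self.xy += x * y
        if self.XtX_inv is not None:
            self._updates_since_reinvert += 1
            if self._updates_since_reinvert >= self.reinvert_every:
                self.XtX_inv = np.linalg.inv(self.XtX)
                self._updates_since_reinvert = 0
            else:
                try:
                    self.XtX_inv = sherman_morrison_update(self.XtX_inv, x)
                except np.linalg.LinAlgError:
                    self.XtX_inv = np.linalg.inv(self.XtX)
                    self._updates_since_reinvert = 0

    def e_step_individual(self, individual_id) -> None:
        """Online E-step for one individual: recompute its posterior and
        swap its CDSS contributions into the running totals."""
        ind = self.individuals[individual_id]
        params = self.params
        s2 = params.sigma2
        beta = params.beta
        phi_inv = _floored_phi_inv(params.phi)
        C = ind.ZtZ + s2 * phi_inv
        try:
            C_inv = np.linalg.inv(C)
        except np.linalg.LinAlgError:
            # regularize Phi harder and retry once
            phi = params.phi + np.eye(self.r) * max(
                1e-6 * np.trace(params.phi) / self.r, 1e-8
            )
            C = ind.ZtZ + s2 * np.linalg.inv(phi)
            try:
                C_inv = np.linalg.inv(C)
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"singular C for individual {individual_id}; E-step skipped"
                )
                return
        b = C_inv @ (ind.Zty - ind.XtZ.T @ beta)

        t1j = ind.XtZ @ b
        T2j = np.outer(b, b) + s2 * C_inv
        t3j = (
            ind.yty
            + float(beta @ (ind.XtX @ beta))
            + float(b @ (ind.ZtZ @ b))
            - 2.0 * float(ind.Xty @ beta)
            - 2.0 * float(ind.Zty @ b)
            + 2.0 * float(beta @ t1j)
            + s2 * float(np.einsum("ab,ba->", C_inv, ind.ZtZ))
        )
        self.t1 += t1j - ind.contrib_t1
        self.T2 += T2j - ind.contrib_T2
        self.t3 += t3j - ind.contrib_t3
        ind.contrib_t1 = t1j
        ind.contrib_T2 = T2j
        ind.contrib_t3 = t3j
        ind.b_hat = b
        ind.C = C
        ind.C_inv = C_inv

    def m_step(self) -> None:
        """Online M-step from the maintained totals."""
        if self.XtX_inv is None:
            raise RuntimeError("warm-up incomplete: X'X inverse not available")
        if self.n < 1 or self.J < 1:
            raise ValueError("need n >= 1 and J >= 1")
        if self.t3 < -1e-6:
            raise ValueError(
                f"t3 = {self.t3} < 0: CDSS totals are inconsistent"
            )
        beta = self.XtX_inv @ (self.xy - self.t1)
        phi = self.T2 / self.J
        phi = 0.5 * (phi + phi.T)
        sigma2 = max(self.t3 / self.n, 1e-10)
        self.params = ModelParameters(beta, phi, sigma2)

    def predict_point(self, point: DataPoint) -> float:
        """Prequential prediction: x'beta + z'b_hat, b_hat = 0 if unseen."""
        ind = self.individuals.get(point.individual_id)
        pred = float(point.x @ self.params.beta)
        if ind is not None:
            pred += float(point.z @ ind.b_hat)
        return pred

    def process(self, point: DataPoint) -> float:
        """Predict (before any update), then ingest + E-step(j) + M-step."""
        pred = self.predict_point(point)
        self.ingest(point)
        self.e_step_individual(point.individual_id)
        self.m_step()
        return pred

    def process_raw(self, individual_id, x, z, y) -> float:
        """Array-path variant of :meth:`process` (inputs pre-validated)."""
        ind = self.individuals.get(individual_id)
        pred = float(x @ self.params.beta)
        if ind is not None:
            pred += float(z @ ind.b_hat)
        self._ingest_raw(individual_id, x, z, y)
        self.e_step_individual(individual_id)
        self.m_step()
        return pred

    def sweep(self) -> None:
        """SEMA Update: E-step for every stored individual, then one M-step.

        Uses only the individual-level aggregates — no raw data revisited.
        """
        for individual_id in self.individuals:
            self.e_step_individual(individual_id)
        self.m_step()

    # -- consistency and serialization ------------------------------------

    def cdss_reconstruction_gap(self) -> float:
        """Max relative gap between CDSS totals and the sum of contributions."""
        t1 = sum(ind.contrib_t1 for ind in self.individuals.values())
        T2 = sum(ind.contrib_T2 for ind in self.individuals.values())
        t3 = sum(ind.contrib_t3 for ind in self.individuals.values())
        scale = max(
            float(np.max(np.abs(self.t1))), float(np.max(np.abs(self.T2))),
            abs(self.t3), 1.0,
        )
        return max(
            float(np.max(np.abs(self.t1 - t1))),
            float(np.max(np.abs(self.T2 - T2))),
            abs(self.t3 - t3),
        ) / scale

    def to_checkpoint(self) -> dict:
        """Self-describing snapshot; floats survive the JSON round trip
        exactly (shortest-repr serialization)."""
        return {
            "version": CHECKPOINT_VERSION,
            "p": self.p,
            "r": self.r,
            "n": self.n,
            "J": self.J,
            "XtX": self.XtX.tolist(),
            "XtX_inv": None if self.XtX_inv is None else self.XtX_inv.tolist(),
            "xy": self.xy.tolist(),
            "t1": self.t1.tolist(),
            "T2": self.T2.tolist(),
            "t3": self.t3,
            "reinvert_every": self.reinvert_every,
            "params": {
                "beta": self.params.beta.tolist(),
                "phi": self.params.phi.tolist(),
                "sigma2": self.params.sigma2,
            },
            "individuals": [
                {
                    "id": k.item() if isinstance(k, np.generic) else k,
                    "n_j": ind.n_j,
                    "ZtZ": ind.ZtZ.tolist(),
                    "XtZ": ind.XtZ.tolist(),
                    "Zty": ind.Zty.tolist(),
                    "XtX": ind.XtX.tolist(),
                    "Xty": ind.Xty.tolist(),
                    "yty": ind.yty,
                    "b_hat": ind.b_hat.tolist(),
                    "contrib_t1": ind.contrib_t1.tolist(),
                    "contrib_T2": ind.contrib_T2.tolist(),
                    "contrib_t3": ind.contrib_t3,
                }
                for k, ind in self.individuals.items()
            ],
        }

    @classmethod
    def from_checkpoint(cls, snap: dict) -> "GlobalState":
        if snap.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {snap.get('version')!r} not supported "
                f"(expected {CHECKPOINT_VERSION})"
            )
        params = ModelParameters(
            np.array(snap["params"]["beta"]),
            np.array(snap["params"]["phi"]),
            snap["params"]["sigma2"],
        )
        state = cls(snap["p"], snap["r"], params,
                    reinvert_every=snap.get("reinvert_every", 100_000))
        state.n = snap["n"]
        state.J = snap["J"]
        state.XtX = np.array(snap["XtX"])
        state.XtX_inv = (
            None if snap["XtX_inv"] is None else np.array(snap["XtX_inv"])
        )
        state.xy = np.array(snap["xy"])
        state.t1 = np.array(snap["t1"])
        state.T2 = np.array(snap["T2"])
        state.t3 = snap["t3"]
        for d in snap["individuals"]:
            key = d["id"]
            ind = IndividualSummary(snap["p"], snap["r"])
            ind.n_j = d["n_j"]
            ind.ZtZ = np.array(d["ZtZ"])
            ind.XtZ = np.array(d["XtZ"])
            ind.Zty = np.array(d["Zty"])
            ind.XtX = np.array(d["XtX"])
            ind.Xty = np.array(d["Xty"])
            ind.yty = d["yty"]
            ind.b_hat = np.array(d["b_hat"])
            ind.contrib_t1 = np.array(d["contrib_t1"])
            ind.contrib_T2 = np.array(d["contrib_T2"])
            ind.contrib_t3 = d["contrib_t3"]
            state.individuals[key] = ind
        return state


def init_warm_start(
    training_points,
    start: ModelParameters | None = None,
    tol: float = 1e-4,
    max_iter: int = 800,
    reinvert_every: int = 100_000,
) -> GlobalState:
    """Build a consistent GlobalState from a training prefix of the stream.

    Runs batch EM on the training points, ingests them into per-individual
    summaries, computes every individual's CDSS contribution at the fitted
    parameters, and inverts X'X once directly.
    """
    points = list(training_points)
    if not points:
        raise ValueError("empty training set")
    data = BatchData.from_points(points)
    if np.linalg.matrix_rank(data.suff_stats().XtX) < data.p:
        raise np.linalg.LinAlgError(
            "X'X is rank deficient after the training set; "
            "use a larger warm-up"
        )
    params, _ = fit_em(data, start=start, tol=tol, max_iter=max_iter)
    state = GlobalState(data.p, data.r, params, reinvert_every=reinvert_every)
    for pt in points:
        state.ingest(pt)
    for individual_id in state.individuals:
        state.e_step_individual(individual_id)
    state.XtX_inv = np.linalg.inv(state.XtX)
    state._updates_since_reinvert = 0
    return state


# ---------------------------------------------------------------------------
# Functional surface: thin wrappers over GlobalState methods.

def ingest(state: GlobalState, point: DataPoint) -> GlobalState:
    state.ingest(point)
    return state


def online_e_step_individual(state: GlobalState, individual_id) -> GlobalState:
    state.e_step_individual(individual_id)
    return state


def online_m_step(state: GlobalState) -> GlobalState:
    state.m_step()
    return state


def process_data_point(state: GlobalState, point: DataPoint):
    """Prequential prediction followed by the per-point SEMA update."""
    return state.process(point), state


def sweep(state: GlobalState) -> GlobalState:
    state.sweep()
    return state
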