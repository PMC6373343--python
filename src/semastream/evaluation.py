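"""Prequential evaluation of streaming estimators and study summaries.

Every post-training data point is predicted *before* it updates any
state; prediction errors accumulate into MAE / RMSE and moving-window
MAE series.  Parameter snapshots are recorded at a configurable cadence
plus fixed reporting checkpoints (mid-stream and stream end).

Methods understood by :func:`prequential_run`:

``sema``         per-point streaming EM;
``sema_update``  SEMA plus a periodic sweep over all individuals;
``em_batched``   batch EM on all data so far, refit every 1000 points
                 (20 iterations, warm-started), run to convergence at the
                 end of the stream;
``swem``         sliding-window EM over the m most recent points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import BatchData, fit_em, suffstats_from_summaries
from .model import DataPoint, ModelParameters
from .sema import GlobalState, init_warm_start
from .window import SWEMState

__all__ = [
    "PredictionLog",
    "running_mean",
    "prequential_run",
    "mae",
    "rmse",
    "moving_mae",
    "empirical_ci",
    "mc_se",
    "run_replication",
    "replicate_study",
]

METHODS = ("sema", "sema_update", "em_batched", "swem")


def running_mean(state, x_t):
    """Online sample mean update: (n, xbar) -> (n+1, xbar + (x - xbar)/(n+1))."""
    n, xbar = state
    if n < 0:
        raise ValueError("count must be non-negative")
    n_new = n + 1
    return n_new, xbar + (x_t - xbar) / n_new


@dataclass
class PredictionLog:
    """One entry per evaluated stream point, in arrival order."""

    t: np.ndarray
    individual_id: np.ndarray
    y: np.ndarray
    y_hat: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def errors(self) -> np.ndarray:
        return self.y_hat - self.y

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "individual_id": self.individual_id,
                "y": self.y,
                "y_hat": self.y_hat,
            }
        )


def mae(log) -> float:
    """Mean absolute prediction error over the log."""
    e = _errors(log)
    return float(np.mean(np.abs(e)))


def rmse(log) -> float:
    """Root-mean-squared prediction error over the log."""
    e = _errors(log)
    return float(np.sqrt(np.mean(e**2)))


def _errors(log) -> np.ndarray:
    e = log.errors() if hasattr(log, "errors") else np.asarray(log, float)
    if len(e) == 0:
        raise ValueError("empty prediction log")
    return e


def moving_mae(log, window: int = 1000, shift: int = 100) -> np.ndarray:
    """MAE over windows of ``window`` points advancing by ``shift``."""
    e = np.abs(_errors(log))
    if window > len(e):
        raise ValueError("window larger than the log")
    starts = range(0, len(e) - window + 1, shift)
    return np.array([e[s : s + window].mean() for s in starts])


def empirical_ci(values, level: float = 0.95):
    """Empirical central interval: linear-interpolated quantiles."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def mc_se(estimates, truth: float) -> float:
    """Monte-Carlo standard error centered on the TRUE value:

        sqrt( (1/(S-1)) sum_s (est_s - truth)^2 ) / sqrt(S)
    """
    est = np.asarray(estimates, float)
    S = est.size
    if S < 2:
        raise ValueError("need at least 2 replications")
    return float(np.sqrt(np.sum((est - truth) ** 2) / (S - 1)) / np.sqrt(S))


def _as_arrays(stream):
    if isinstance(stream, tuple) and len(stream) == 4:
        ids, y, X, Z = stream
        return (np.asarray(ids), np.asarray(y, float),
                np.asarray(X, float), np.asarray(Z, float))
    points = list(stream)
    ids = np.array([pt.individual_id for pt in points])
    y = np.array([pt.y for pt in points])
    X = np.stack([pt.x for pt in points])
    Z = np.stack([pt.z for pt in points])
    return ids, y, X, Z


def _snapshot(n_seen: int, params: ModelParameters) -> dict:
    return {
        "n": n_seen,
        "beta": params.beta.copy(),
        "phi": params.phi.copy(),
        "sigma2": params.sigma2,
    }


def prequential_run(
    method: str,
    stream,
    *,
    train_n: int = 2000,
    checkpoint_every: int = 1000,
    extra_checkpoints=(25_000,),
    start: ModelParameters | None = None,
    em_tol: float = 1e-4,
    em_max_iter: int = 800,
    sweep_every: int = 1000,
    window: int = 10_000,
    refit_every: int = 1000,
    refit_max_iter: int = 20,
):
    """Replay a stream prequentially with one of the four methods.

    The first ``train_n`` points are the warm-start training set (batch
    EM, started from ``start`` when given); predictions are recorded for
    every later point before that point updates any state.  Returns
    ``(PredictionLog, trajectory)`` where the trajectory is a list of
    parameter snapshots at multiples of ``checkpoint_every``, at each of
    ``extra_checkpoints``, and at stream end.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    ids, y, X, Z = _as_arrays(stream)
    n_total = len(y)
    if not 0 < train_n < n_total:
        raise ValueError("train_n must lie strictly inside the stream")
    marks = {m for m in extra_checkpoints if train_n < m <= n_total}
    marks.add(n_total)

    train_points = [
        DataPoint(ids[t], y[t], X[t], Z[t]) for t in range(train_n)
    ]
    preds = np.empty(n_total - train_n)
    trajectory = []

    if method in ("sema", "sema_update"):
        state = init_warm_start(train_points, start=start,
                                tol=em_tol, max_iter=em_max_iter)
        for t in range(train_n, n_total):
            preds[t - train_n] = state.process_raw(ids[t], X[t], Z[t], y[t])
            pos = t + 1
            if method == "sema_update" and (pos - train_n) % sweep_every == 0:
                state.sweep()
            if pos % checkpoint_every == 0 or pos in marks:
                trajectory.append(_snapshot(pos, state.params))
        final_params = state.params
    elif method == "em_batched":
        state = init_warm_start(train_points, start=start,
                                tol=em_tol, max_iter=em_max_iter)
        state.XtX_inv = None  # no rank-one maintenance needed here
        params = state.params
        phi_inv = np.linalg.inv(params.phi)
        for t in range(train_n, n_total):
            ind = state.individuals.get(ids[t])
            pred = float(X[t] @ params.beta)
            if ind is not None:
                C = ind.ZtZ + params.sigma2 * phi_inv
                b = np.linalg.solve(C, ind.Zty - ind.XtZ.T @ params.beta)
                pred += float(Z[t] @ b)
            preds[t - train_n] = pred
            state._ingest_raw(ids[t], X[t], Z[t], y[t])
            pos = t + 1
            if (pos - train_n) % refit_every == 0 or pos == n_total:
                ss = suffstats_from_summaries(
                    state.individuals, state.XtX, state.xy, state.n
                )
                max_it = em_max_iter if pos == n_total else refit_max_iter
                params, _ = fit_em(ss, start=params, tol=em_tol, max_iter=max_it)
                phi_inv = np.linalg.inv(params.phi)
            if pos % checkpoint_every == 0 or pos in marks:
                trajectory.append(_snapshot(pos, params))
        final_params = params
    else:  # swem
        params, _ = fit_em(BatchData.from_points(train_points), start=start,
                           tol=em_tol, max_iter=em_max_iter)
        sw = SWEMState(X.shape[1], Z.shape[1], params, window=window,
                       refit_every=refit_every, max_iter=refit_max_iter)
        for pt in train_points:
            evicted = sw.buffer.push(pt)
            sw._add(pt, +1.0)
            if evicted is not None:
                sw._add(evicted, -1.0)
        sw._since_refit = 0
        for t in range(train_n, n_total):
            preds[t - train_n] = sw.process(
                DataPoint(ids[t], y[t], X[t], Z[t])
            )
            pos = t + 1
            if pos % checkpoint_every == 0 or pos in marks:
                trajectory.append(_snapshot(pos, sw.params))
        final_params = sw.params

    log = PredictionLog(
        t=np.arange(train_n, n_total),
        individual_id=ids[train_n:],
        y=y[train_n:].copy(),
        y_hat=preds,
    )
    # dedupe trajectory snapshots by n, keep latest
    seen = {}
    for snap in trajectory:
        seen[snap["n"]] = snap
    trajectory = [seen[k] for k in sorted(seen)]
    if not trajectory or trajectory[-1]["n"] != n_total:
        trajectory.append(_snapshot(n_total, final_params))
    return log, trajectory


def run_replication(cond, method: str, seed, *, n_total=None, train_n=2000,
                    true_start: bool = True, **kwargs):
    """One full study replication: simulate a stream for ``cond`` and replay
    it prequentially.  With ``true_start`` the warm-start EM begins from
    the data-generating values (the study protocol)."""
    from .simulate import make_population, stream_arrays

    root = np.random.SeedSequence(seed)
    pop_seed, stream_seed = root.spawn(2)
    pop = make_population(cond, pop_seed)
    arrays = stream_arrays(pop, cond, n_total, stream_seed)
    start = cond.true_params() if true_start else None
    return prequential_run(method, arrays, train_n=train_n, start=start,
                           **kwargs)


def replicate_study(conditions, methods, reps: int, seed, *,
                    n_total=None, train_n=2000, **kwargs) -> pd.DataFrame:
    """Scaled-down replication of the simulation protocol.

    Returns a tidy table keyed by (condition, method, replication,
    checkpoint, statistic) covering the reported parameter estimates and
    the stream-level prediction errors.
    """
    rows = []
    root = np.random.SeedSequence(seed)
    for cond_name in conditions:
        from .simulate import condition_preset

        cond = condition_preset(cond_name) if isinstance(cond_name, str) else cond_name
        for rep, child in enumerate(root.spawn(reps)):
            rep_seed = child.generate_state(1)[0] % (2**31)
            for method in methods:
                log, traj = run_replication(
                    cond, method, rep_seed, n_total=n_total,
                    train_n=train_n, **kwargs
                )
                for snap in traj:
                    stats = {
                        "beta_0": snap["beta"][0],
                        "beta_1": snap["beta"][1],
                        "phi_00": snap["phi"][0, 0],
                        "sigma2": snap["sigma2"],
                    }
                    if snap["phi"].shape[0] > 1:
                        stats["phi_11"] = snap["phi"][1, 1]
                    for stat, value in stats.items():
                        rows.append(
                            (cond.name, method, rep, snap["n"], stat, value)
                        )
                rows.append((cond.name, method, rep, len(log.y) + train_n,
                             "mae", mae(log)))
                rows.append((cond.name, method, rep, len(log.y) + train_n,
                             "rmse", rmse(log)))
    return pd.DataFrame(
        rows,
        columns=["condition", "method", "replication", "checkpoint",
                 "statistic", "value"],
    )
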