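"""Sliding-window EM (SWEM): batch EM refit over the m most recent points.

The window is a strict FIFO over data points (not individuals).  An
incremental map of per-individual window cross-products is kept alongside
the buffer so that returning individuals get a window-based b_hat at
prediction time without rescanning the buffer; individuals whose window
count drops to zero disappear from it.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np

from .em import BatchData, fit_em, random_effects_posterior
from .model import DataPoint, ModelParameters

__all__ = ["WindowBuffer", "push_evict", "refit", "SWEMState"]


class WindowBuffer:
    """FIFO buffer of at most ``capacity`` data points."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("window capacity must be >= 1")
        self.capacity = int(capacity)
        self.records: deque = deque()

    def __len__(self) -> int:
        return len(self.records)

    def push(self, point: DataPoint):
        """Append ``point``; return the evicted oldest point, or None."""
        self.records.append(point)
        if len(self.records) > self.capacity:
            return self.records.popleft()
        return None

    def to_batch(self) -> BatchData:
        return BatchData.from_points(self.records)


def push_evict(buffer: WindowBuffer, point: DataPoint) -> WindowBuffer:
    buffer.push(point)
    return buffer


def refit(
    buffer: WindowBuffer,
    start: ModelParameters,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> ModelParameters:
    """Batch EM on the window contents, warm-started from ``start``.

    On a rank-deficient window X'X the previous estimates are kept and a
    warning is emitted.
    """
    data = buffer.to_batch()
    if np.linalg.matrix_rank(data.suff_stats().XtX) < data.p:
        warnings.warn("window X'X is rank deficient; keeping previous estimates")
        return start
    params, _ = fit_em(data, start=start, tol=tol, max_iter=max_iter)
    return params


class _WindowCross:
    __slots__ = ("n_j", "ZtZ", "ZtX", "Zty")

    def __init__(self, p, r):
        self.n_j = 0
        self.ZtZ = np.zeros((r, r))
        self.ZtX = np.zeros((r, p))
        self.Zty = np.zeros(r)


class SWEMState:
    """Streaming driver for SWEM: window, cadence, and window-based b_hat.

    Defaults follow the comparator protocol: window m = 10,000 points,
    refit every 1,000 points with at most 20 EM iterations, warm-started
    from the previous estimates.  Between refits, predictions use the
    last refit parameters with b_hat recomputed from the individual's
    current window rows (zero for individuals absent from the window).
    """

    def __init__(
        self,
        p: int,
        r: int,
        params: ModelParameters,
        window: int = 10_000,
        refit_every: int = 1_000,
        max_iter: int = 20,
    ):
        self.p = p
        self.r = r
        self.params = params
        self.buffer = WindowBuffer(window)
        self.refit_every = int(refit_every)
        self.max_iter = int(max_iter)
        self._since_refit = 0
        self._cross: dict = {}
        self._phi_inv_cache = None  # (params object id, inverse)

    def _add(self, pt: DataPoint, sign: float) -> None:
        c = self._cross.get(pt.individual_id)
        if c is None:
            c = _WindowCross(self.p, self.r)
            self._cross[pt.individual_id] = c
        c.n_j += int(sign)
        c.ZtZ += sign * np.outer(pt.z, pt.z)
        c.ZtX += sign * np.outer(pt.z, pt.x)
        c.Zty += sign * pt.z * pt.y
        if c.n_j <= 0:
            del self._cross[pt.individual_id]

    def predict_point(self, point: DataPoint) -> float:
        pred = float(point.x @ self.params.beta)
        c = self._cross.get(point.individual_id)
        if c is not None:
            cache = self._phi_inv_cache
            if cache is None or cache[0] is not self.params:
                cache = (self.params, np.linalg.inv(self.params.phi))
                self._phi_inv_cache = cache
            C = c.ZtZ + self.params.sigma2 * cache[1]
            b = np.linalg.solve(C, c.Zty - c.ZtX @ self.params.beta)
            pred += float(point.z @ b)
        return pred

    def process(self, point: DataPoint) -> float:
        """Prequential prediction, then window update and cadenced refit."""
        pred = self.predict_point(point)
        evicted = self.buffer.push(point)
        self._add(point, +1.0)
        if evicted is not None:
            self._add(evicted, -1.0)
        self._since_refit += 1
        if self._since_refit >= self.refit_every:
            self.params = refit(self.buffer, self.params, max_iter=self.max_iter)
            self._since_refit = 0
        return pred
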