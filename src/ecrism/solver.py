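"""Fixed-point acceleration: MDIIS with a damped-Picard fallback.

MDIIS (modified direct inversion in the iterative subspace) keeps a short
history of trial vectors and residuals and extrapolates the next trial as the
residual-norm-minimizing linear combination plus a fraction of the combined
residual.  The history is restarted from the best stored vector whenever the
residual grows by more than ``restart_factor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class MDIIS:
    depth: int = 10
    mixing: float = 0.7
    restart_factor: float = 10.0
    _vectors: list[np.ndarray] = field(default_factory=list, repr=False)
    _residuals: list[np.ndarray] = field(default_factory=list, repr=False)
    _norms: list[float] = field(default_factory=list, repr=False)

    def reset(self) -> None:
        self._vectors.clear()
        self._residuals.clear()
        self._norms.clear()

    def step(self, vector: np.ndarray, residual: np.ndarray) -> np.ndarray:
        """Submit the current trial and its residual; return the next trial."""
        rms = float(np.sqrt(np.mean(residual**2)))
        if self._norms and rms > self.restart_factor * min(self._norms):
            # Restart from the best vector seen, with plain damping.
            best = int(np.argmin(self._norms))
            vec = self._vectors[best] + 0.3 * self._residuals[best]
            self.reset()
            return vec
        self._vectors.append(vector.copy())
        self._residuals.append(residual.copy())
        self._norms.append(rms)
        if len(self._vectors) > self.depth:
            self._vectors.pop(0)
            self._residuals.pop(0)
            self._norms.pop(0)
        m = len(self._vectors)
        if m == 1:
            return vector + self.mixing * residual
        # Minimize |sum_i w_i r_i| subject to sum w = 1 (DIIS normal system).
        b = np.empty((m + 1, m + 1))
        b[:m, :m] = np.array(
            [[float(np.dot(ri.ravel(), rj.ravel())) for rj in self._residuals]
             for ri in self._residuals]
        )
        b[m, :m] = 1.0
        b[:m, m] = 1.0
        b[m, m] = 0.0
        rhs = np.zeros(m + 1)
        rhs[m] = 1.0
        try:
            w = np.linalg.solve(b, rhs)[:m]
        except np.linalg.LinAlgError:
            w, *_ = np.linalg.lstsq(b, rhs, rcond=None)
            w = w[:m]
        new = np.zeros_like(vector)
        res = np.zeros_like(vector)
        for wi, vi, ri in zip(w, self._vectors, self._residuals):
            new += wi * vi
            res += wi * ri
        return new + self.mixing * res
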