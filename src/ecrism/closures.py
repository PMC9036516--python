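"""Closure relations linking total and direct correlation functions.

All closures act on the renormalized exponent t = -beta*u + gamma with
gamma = h - c, returning the distribution function g:

* HNC:      g = exp(t)
* PLHNC(C): g = exp(t) for t <= C, exp(C) * (1 + t - C) above (C=0 is KH)
* PSE-n:    g = exp(t) for t < 0, the order-n Taylor partial sum above

Branch selection uses the half-open convention Theta(0) = 0, i.e. t = 0
belongs to the exponential branch's closure value (both branches agree there,
so the choice only fixes bookkeeping, not values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Exponent above which exp() is considered divergent rather than evaluated.
_EXP_CAP = 250.0


class ClosureOverflowError(FloatingPointError):
    """Raised when a closure exponent overflows; signals the solver to damp."""


@dataclass(frozen=True)
class ClosureSpec:
    """Closure family and parameters.

    kind: 'KH', 'PLHNC', 'PSE', or 'HNC'; ``order`` applies to PSE-n only and
    ``plhnc_c`` to PLHNC only.  PSE-1 is identical to KH, and PLHNC with C=0
    is KH.
    """

    kind: str = "PSE"
    order: int = 3
    plhnc_c: float = 0.0

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        if kind not in {"KH", "PLHNC", "PSE", "HNC"}:
            raise ValueError(f"unknown closure kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        if kind == "PSE" and self.order < 1:
            raise ValueError("PSE order must be a positive integer")

    @property
    def label(self) -> str:
        if self.kind == "PSE":
            return f"PSE-{self.order}"
        if self.kind == "PLHNC" and self.plhnc_c != 0.0:
            return f"PLHNC(C={self.plhnc_c:g})"
        return self.kind

    @classmethod
    def parse(cls, text: str) -> "ClosureSpec":
        """Parse 'KH', 'HNC', 'PSE-3', 'PSE3', 'PLHNC'."""
        t = text.strip().upper().replace("_", "-")
        if t.startswith("PSE"):
            tail = t[3:].lstrip("-")
            order = int(tail) if tail else 3
            return cls(kind="PSE", order=order)
        return cls(kind=t)


def _checked_exp(t: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    tm = t if mask is None else np.where(mask, t, 0.0)
    if np.any(tm > _EXP_CAP):
        raise ClosureOverflowError(
            f"closure exponent reached {float(np.max(tm)):.3g} (> {_EXP_CAP:g}); "
            "iteration is diverging, reduce the mixing/damping factor"
        )
    return np.exp(np.minimum(tm, _EXP_CAP))


def apply_closure(t: np.ndarray, closure: ClosureSpec) -> np.ndarray:
    """Evaluate g from the closure exponent t = -beta*u + gamma."""
    t = np.asarray(t, dtype=float)
    kind = closure.kind
    if kind == "HNC":
        return _checked_exp(t)
    if kind in {"KH", "PLHNC"}:
        c = closure.plhnc_c if kind == "PLHNC" else 0.0
        low = t <= c
        expc = math.exp(c)
        return np.where(low, _checked_exp(t, low), expc * (1.0 + t - c))
    # PSE-n: exponential below zero, order-n partial sum above.
    low = t < 0.0
    tmax = float(np.max(t, initial=0.0))
    if tmax > 1e4:
        raise ClosureOverflowError(
            f"PSE-{closure.order} exponent reached {tmax:.3g}; iteration is "
            "diverging, reduce the mixing/damping factor"
        )
    tpos = np.where(low, 0.0, t)
    partial = np.ones_like(t)
    term = np.ones_like(t)
    for k in range(1, closure.order + 1):
        term = term * tpos / k
        partial = partial + term
    return np.where(low, _checked_exp(t, low), partial)
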