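"""Deterministic toy solutes and deliberately slow reference oracles.

Every oracle-vs-production comparison in the test suite goes through the
implementations here; they are O(N^2) direct sums, independent of the FFT /
normal-equation production paths, and refuse instances large enough to hurt.
All pseudo-randomness in the package lives in ``make_fixture`` (seeded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .forcefield import Site, SoluteModel

_KINDS = ("lj_sphere", "dipolar_diatomic", "ammonia_like", "random_cluster")


@dataclass(frozen=True)
class Fixture:
    name: str
    solute: SoluteModel
    seed: int | None = None
    properties: dict = field(default_factory=dict)


def make_fixture(kind: str, seed: int = 0) -> Fixture:
    """Build a named toy solute; regeneration with the same seed is
    bit-identical."""
    if kind == "lj_sphere":
        solute = SoluteModel(
            ("Ar",), np.zeros((1, 3)), (Site("Ar", 0.0, 3.40, 0.996),)
        )
        return Fixture(kind, solute, properties={"neutral": True, "spherical": True})
    if kind == "dipolar_diatomic":
        bond = 1.2
        solute = SoluteModel(
            ("N", "C"),
            np.array([[0.0, 0.0, bond / 2], [0.0, 0.0, -bond / 2]]),
            (Site("N", 0.4, 3.0, 0.5), Site("C", -0.4, 3.2, 0.4)),
        )
        return Fixture(kind, solute, properties={"dipole_e_A": 0.4 * bond})
    if kind == "ammonia_like":
        # C3v umbrella: central N, three equivalent H.
        r_nh, theta = 1.01, math.radians(106.7)
        z = -r_nh * math.cos(theta / 1.35)
        rho = math.sqrt(max(r_nh**2 - z**2, 1e-12))
        pos = [np.zeros(3)]
        for i in range(3):
            ang = 2.0 * math.pi * i / 3.0
            pos.append(np.array([rho * math.cos(ang), rho * math.sin(ang), z]))
        qh = 0.34
        sites = (Site("N", -3 * qh, 3.34, 0.88),) + tuple(
            Site("H", qh, 1.07, 0.065) for _ in range(3)
        )
        return Fixture(kind, SoluteModel(("N", "H", "H", "H"), np.array(pos), sites))
    if kind == "random_cluster":
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        pos = rng.uniform(-2.0, 2.0, size=(n, 3))
        q = rng.uniform(-0.5, 0.5, size=n)
        q -= q.mean()  # neutral overall
        sigma = rng.uniform(2.5, 3.5, size=n)
        eps = rng.uniform(0.1, 1.0, size=n)
        sites = tuple(
            Site(f"X{i}", float(q[i]), float(sigma[i]), float(eps[i])) for i in range(n)
        )
        return Fixture(kind, SoluteModel(("C",) * n, pos, sites), seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}; known: {_KINDS}")


def direct_convolution(c: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Periodic convolution by the O(N^2) direct sum (oracle).

    ``c`` and ``kernel`` are same-shape 3D fields; the result matches
    irfftn(rfftn(c) * rfftn(kernel)) up to floating point.
    """
    if c.shape != kernel.shape:
        raise ValueError("fields must share a shape")
    if np.prod(c.shape) > 16**3:
        raise ValueError("direct_convolution is an oracle; instance too large")
    nx, ny, nz = c.shape
    out = np.zeros_like(c, dtype=float)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                for a in range(nx):
                    for b in range(ny):
                        for d in range(nz):
                            acc += c[a, b, d] * kernel[(i - a) % nx, (j - b) % ny, (k - d) % nz]
                out[i, j, k] = acc
    return out


def direct_esp(charges: np.ndarray, positions: np.ndarray, points: np.ndarray) -> np.ndarray:
    """ESP oracle (a.u.): plain double loop over charges and points."""
    charges = np.asarray(charges, dtype=float)
    positions = np.asarray(positions, dtype=float)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] > 4096 or charges.size > 512:
        raise ValueError("direct_esp is an oracle; instance too large")
    out = np.zeros(points.shape[0])
    for p in range(points.shape[0]):
        acc = 0.0
        for a in range(charges.size):
            r = math.dist(points[p], positions[a]) / constants.BOHR_ANGSTROM
            acc += charges[a] / r
        out[p] = acc
    return out


def naive_constrained_lsq(a: np.ndarray, y: np.ndarray, total: float) -> np.ndarray:
    """Equality-constrained least squares by variable elimination (oracle).

    Minimizes |a q - y|^2 with sum(q) = total by substituting
    q_n = total - sum(q_1..q_{n-1}) and solving the reduced ordinary
    least-squares problem - a different route from the production KKT solve.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = a.shape
    if m > 4096 or n > 64:
        raise ValueError("naive_constrained_lsq is an oracle; instance too large")
    if n == 1:
        return np.array([total])
    last = a[:, -1]
    reduced = a[:, :-1] - last[:, None]
    target = y - total * last
    q_head, *_ = np.linalg.lstsq(reduced, target, rcond=None)
    return np.concatenate([q_head, [total - q_head.sum()]])
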