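"""ESP-fitted solute charges and the solvent background-charge map.

The charge fit minimizes the squared deviation between a target electrostatic
potential (atomic units) sampled outside the van der Waals surface and the
potential of atomic point charges, with the total charge enforced through a
Lagrange multiplier.  Point sets follow the CHELPG construction (regular
cubic lattice clipped to a shell around the molecule) or the Merz-Kollman
construction (points on scaled van der Waals spheres).

The solvent charge map converts 3D-RISM distribution functions into one
background point charge per voxel:

    q(r_i) = sum_gamma q_gamma rho_gamma g_gamma(r_i) * voxel_volume

(site density and voxel volume included so the result is in elementary-charge
units; an optional bulk-subtracted variant uses g - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants
from .rism3d import Correlations3D

#: Bondi van der Waals radii (Å) with the Br radius overridden to 1.75 Å as
#: used for CHELPG fitting; ``SAMPL6_RADII`` switches Br to the 1.3 Å variant.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Br": 1.75, "Kr": 2.02, "I": 1.98, "Xe": 2.16,
}

SAMPL6_RADII: dict[str, float] = {**BONDI_RADII, "Br": 1.30}


def load_radii_table(path) -> dict[str, float]:
    """Read an editable two-column (element radius) text table; '#' comments."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'element radius', got {body!r}")
            table[parts[0]] = float(parts[1])
    return table


@dataclass(frozen=True)
class ESPSample:
    """Electrostatic-potential samples: points in Å, values in atomic units."""

    points: np.ndarray  # (m, 3) Å
    values: np.ndarray  # (m,) a.u.

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (m, 3)")
        if vals.shape != (pts.shape[0],):
            raise ValueError("values length must match points")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "values", vals)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class AtomicCharges:
    """Fitted per-atom charges with the fit residual and a method tag."""

    values: np.ndarray  # (n,) e
    rms_residual: float = 0.0  # a.u.
    method: str = "input"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _radius_for(element: str, radii: dict[str, float]) -> float:
    try:
        return radii[element]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; extend the radii table"
        ) from None


def chelpg_points(
    solute,
    radii: dict[str, float] | None = None,
    shell_spacing: float = 0.3,
    r_max: float = 2.8,
) -> np.ndarray:
    """CHELPG sampling lattice around the molecule, shape (m, 3) in Å.

    Regular cubic lattice of the given spacing, centered on the bounding-box
    center, retaining points that lie outside every atom's van der Waals
    radius but within ``r_max`` of at least one nucleus.  Ordering is the
    deterministic lexicographic lattice order.
    """
    radii = radii or BONDI_RADII
    r_atom = np.array([_radius_for(el, radii) for el in solute.elements])
    if r_max < r_atom.min():
        raise ValueError(
            f"r_max={r_max} Å lies inside the smallest exclusion radius "
            f"({r_atom.min()} Å): empty shell"
        )
    lo = solute.positions.min(axis=0) - r_max
    hi = solute.positions.max(axis=0) + r_max
    center = 0.5 * (solute.positions.min(axis=0) + solute.positions.max(axis=0))
    axes = []
    for a in range(3):
        n_lo = int(math.floor((lo[a] - center[a]) / shell_spacing))
        n_hi = int(math.ceil((hi[a] - center[a]) / shell_spacing))
        axes.append(center[a] + shell_spacing * np.arange(n_lo, n_hi + 1))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = np.linalg.norm(pts[:, None, :] - solute.positions[None, :, :], axis=-1)
    keep = np.all(d >= r_atom[None, :], axis=1) & np.any(d <= r_max, axis=1)
    return pts[keep]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def mk_points(
    solute,
    radii: dict[str, float] | None = None,
    shell_scales: tuple[float, ...] = (1.4, 1.6, 1.8, 2.0),
    density: float = 1.0,
) -> np.ndarray:
    """Merz-Kollman sampling: points on scaled van der Waals spheres
    (``density`` points per Å^2), excluding points inside any other atom's
    scaled sphere.  Deterministic (Fibonacci sphere coverage)."""
    radii = radii or BONDI_RADII
    r_atom = np.array([_radius_for(el, radii) for el in solute.elements])
    out = []
    for scale in shell_scales:
        scaled = scale * r_atom
        for a in range(solute.n_atoms):
            r = scaled[a]
            n = max(8, int(round(density * 4.0 * math.pi * r * r)))
            pts = solute.positions[a] + r * _fibonacci_sphere(n)
            d = np.linalg.norm(pts[:, None, :] - solute.positions[None, :, :], axis=-1)
            keep = np.all(d >= scaled[None, :] - 1e-9, axis=1)
            out.append(pts[keep])
    return np.vstack(out)


def point_charge_esp(charges: np.ndarray, positions: np.ndarray,
                     points: np.ndarray) -> np.ndarray:
    """Forward model: ESP (a.u.) of point charges (e, Å) at sample points (Å)."""
    d = np.linalg.norm(points[:, None, :] - positions[None, :, :], axis=-1)
    d_bohr = d / constants.BOHR_ANGSTROM
    return (np.asarray(charges)[None, :] / d_bohr).sum(axis=1)


def fit_esp_charges(
    sample: ESPSample,
    atom_positions: np.ndarray,
    total_charge: float,
    method: str = "CHELPG",
    *,
    condition_limit: float = 1e12,
) -> AtomicCharges:
    """Constrained least-squares ESP charges.

    Minimizes sum_p (phi_p - sum_a q_a/|r_p - r_a|)^2 subject to
    sum_a q_a = total_charge via the bordered (KKT) normal equations.
    """
    pos = np.asarray(atom_positions, dtype=float)
    n = pos.shape[0]
    if n < 1:
        raise ValueError("need at least one atom")
    if sample.n_points < n + 1:
        raise ValueError(
            f"need at least {n + 1} sample points for {n} atoms, got {sample.n_points}"
        )
    d = np.linalg.norm(sample.points[:, None, :] - pos[None, :, :], axis=-1)
    a = constants.BOHR_ANGSTROM / d  # design matrix, a.u.
    ata = a.T @ a
    cond = np.linalg.cond(ata)
    if cond > condition_limit:
        raise np.linalg.LinAlgError(
            f"ESP fit is ill-conditioned (normal-equation condition ~{cond:.2e}); "
            "add sample points or merge degenerate atoms"
        )
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2.0 * ata
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs = np.zeros(n + 1)
    rhs[:n] = 2.0 * a.T @ sample.values
    rhs[n] = total_charge
    solution = np.linalg.solve(kkt, rhs)
    q = solution[:n]
    rms = float(np.sqrt(np.mean((sample.values - a @ q) ** 2)))
    return AtomicCharges(values=q, rms_residual=rms, method=method)


@dataclass(frozen=True)
class ChargeMap:
    """Background point charges on grid points (Å, elementary charge)."""

    points: np.ndarray  # (m, 3)
    charges: np.ndarray  # (m,)
    threshold: float = 0.0  # a.u., already applied
    dropped_fraction: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        ch = np.asarray(self.charges, dtype=float)
        if ch.shape != (pts.shape[0],):
            raise ValueError("points/charges length mismatch")
        if not 0.0 <= self.dropped_fraction <= 1.0:
            raise ValueError("dropped fraction must lie in [0, 1]")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "charges", ch)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


def solvent_charge_map(corr: Correlations3D, *, bulk_subtract: bool = False) -> ChargeMap:
    """Collapse the solvent-site distributions into one point charge per voxel."""
    grid = corr.grid
    dv = grid.voxel_volume
    weight = np.zeros(grid.dims)
    for t in range(corr.n_types):
        gfield = corr.g[t] - 1.0 if bulk_subtract else corr.g[t]
        weight += corr.site_charges[t] * corr.site_densities[t] * gfield
    charges = (weight * dv).ravel(order="C")
    x, y, z = grid.axes()
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    points = np.column_stack([gx.ravel(order="C"), gy.ravel(order="C"), gz.ravel(order="C")])
    return ChargeMap(points=points, charges=charges)


def drop_small(charge_map: ChargeMap, threshold: float) -> ChargeMap:
    """Retain charges with |q| >= threshold (a.u.), preserving order and
    recording the dropped fraction."""
    if threshold < 0.0:
        raise ValueError("threshold must be non-negative")
    if threshold == 0.0:
        return replace(charge_map, threshold=0.0)
    keep = np.abs(charge_map.charges) >= threshold
    n = charge_map.n_points
    dropped_now = 1.0 - (float(keep.sum()) / n if n else 1.0)
    # Compose with any fraction dropped earlier so repeated application at the
    # same threshold is exactly idempotent.
    prior = charge_map.dropped_fraction
    return ChargeMap(
        points=charge_map.points[keep],
        charges=charge_map.charges[keep],
        threshold=max(threshold, charge_map.threshold),
        dropped_fraction=prior + (1.0 - prior) * dropped_now,
    )
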