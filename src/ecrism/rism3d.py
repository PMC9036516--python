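"""3D-RISM: solvent-site distributions around a rigid solute.

The solute sits in a rectangular box whose faces are at least ``buffer`` away
from every atom; solvent-site fields live on a uniform grid over that box.
The solute-solvent potential is evaluated per solvent site type as the exact
superposition of Lennard-Jones and Coulomb terms, with the Coulomb part split
by an erf smearing into a short-range piece (kept with the LJ core) and a
smooth long-range piece.  The convolution h_t(k) = sum_t' c_t'(k) chi_t't(k)
is evaluated spectrally; the supercell is treated as periodic and the buffer
is the mitigation for image effects (the box-size convergence of the free
energy is the observable check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfftn, rfftn
from scipy.special import erf, erfc

from . import constants
from .closures import ClosureSpec, apply_closure as _closure_g
from .forcefield import Site, SoluteModel, ThermoState, mix_lj
from .rism1d import SolventSusceptibility
from .solver import MDIIS, ConvergenceError

#: erf smearing width for the Coulomb short/long split, Å.
COULOMB_SMEAR = 1.0

#: Separations are clamped to this floor when a voxel coincides with an atom.
MIN_SEPARATION = 0.05


def _fft_friendly(n: int) -> int:
    """Smallest EVEN integer >= n whose prime factors are all in {2, 3, 5, 7}.

    Evenness keeps the solute's registration against the voxel lattice
    identical across buffer sizes, so box-convergence studies are not
    polluted by alternating sub-voxel shifts.
    """
    def smooth(m: int) -> bool:
        for p in (2, 3, 5, 7):
            while m % p == 0:
                m //= p
        return m == 1

    m = max(n + (n % 2), 2)
    while not smooth(m):
        m += 2
    return m


@dataclass(frozen=True)
class Grid3D:
    """Rectangular voxel grid: origin, per-axis spacing and counts.

    Voxel centers are origin + index * spacing with 0-based, half-open
    indexing; the periodic box edge along each axis is dims * spacing.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def box_lengths(self) -> np.ndarray:
        return np.array(self.dims) * np.array(self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a]) for a in range(3)
        )  # type: ignore[return-value]

    def k_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Angular wavenumber axes matching rfftn layout (last axis halved)."""
        nx, ny, nz = self.dims
        kx = 2.0 * math.pi * np.fft.fftfreq(nx, self.spacing[0])
        ky = 2.0 * math.pi * np.fft.fftfreq(ny, self.spacing[1])
        kz = 2.0 * math.pi * np.fft.rfftfreq(nz, self.spacing[2])
        return kx, ky, kz

    def k_magnitude(self) -> np.ndarray:
        kx, ky, kz = self.k_axes()
        return np.sqrt(
            kx[:, None, None] ** 2 + ky[None, :, None] ** 2 + kz[None, None, :] ** 2
        )


def build_grid(solute: SoluteModel, buffer: float = 15.0,
               spacing: float | tuple[float, float, float] = 0.3) -> Grid3D:
    """Box the solute with at least ``buffer`` Å between every atom and each
    face, dims rounded up to FFT-friendly sizes, grid centered on the solute
    bounding box."""
    if buffer <= 0:
        raise ValueError("buffer must be positive")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    lo = solute.positions.min(axis=0) - buffer
    hi = solute.positions.max(axis=0) + buffer
    extent = hi - lo
    if np.any(sp >= extent):
        raise ValueError("spacing is larger than the requested box edge")
    dims = tuple(_fft_friendly(int(math.ceil(extent[a] / sp[a]))) for a in range(3))
    center = 0.5 * (solute.positions.min(axis=0) + solute.positions.max(axis=0))
    origin = tuple(center[a] - 0.5 * dims[a] * sp[a] + 0.5 * sp[a] for a in range(3))
    return Grid3D(origin=origin, spacing=tuple(sp), dims=dims)


@dataclass
class PotentialFields:
    """Per-solvent-site-type interaction fields on a grid.

    ``u_short`` holds LJ plus the erfc short-range Coulomb part; ``phi_long``
    is the smeared long-range electrostatic potential of the whole solute
    (kJ/mol per unit probe charge), so u_long for site t is q_t * phi_long.

    Two long-range representations are carried: the exact open-space field
    (``phi_long``, superposition of erf/r terms) and the periodic Ewald-style
    field (``phi_long_periodic`` with its analytic reciprocal components
    ``phi_long_hat``).  The solver uses the periodic one so that the closure
    and the spectral convolution see the same supercell electrostatics; the
    open one is the reference for potential-accuracy checks.
    """

    grid: Grid3D
    site_types: tuple[str, ...]
    site_charges: np.ndarray
    u_short: np.ndarray = field(repr=False)  # (nt, nx, ny, nz)
    phi_long: np.ndarray = field(repr=False)  # (nx, ny, nz), open space
    phi_long_hat: np.ndarray = field(repr=False)  # rfftn layout, periodic
    phi_long_periodic: np.ndarray = field(repr=False)  # (nx, ny, nz)
    smear: float = COULOMB_SMEAR

    def u_long(self, t: int, periodic: bool = True) -> np.ndarray:
        phi = self.phi_long_periodic if periodic else self.phi_long
        return self.site_charges[t] * phi

    def u_total(self, t: int, periodic: bool = True) -> np.ndarray:
        return self.u_short[t] + self.u_long(t, periodic=periodic)


def solute_site_potentials(
    solute: SoluteModel,
    solvent_sites: list[Site] | tuple[Site, ...],
    grid: Grid3D,
    smear: float = COULOMB_SMEAR,
) -> PotentialFields:
    """Superpose per-atom LJ + Coulomb interactions for each solvent site type.

    The Coulomb term of every atom is split as erfc(r/s)/r + erf(r/s)/r; the
    erf part is accumulated once into ``phi_long`` (it is proportional to the
    probe charge), the rest goes into ``u_short``.
    """
    for s in solvent_sites:
        if s.sigma == 0.0 and s.epsilon != 0.0:
            raise ValueError(f"solvent site {s.label}: zero sigma with nonzero epsilon")
    x, y, z = grid.axes()
    nt = len(solvent_sites)
    shape = grid.dims
    u_short = np.zeros((nt,) + shape)
    phi_long = np.zeros(shape)
    charges = np.array([s.charge for s in solvent_sites])
    for a in range(solute.n_atoms):
        ax, ay, az = solute.positions[a]
        r2 = (
            (x - ax)[:, None, None] ** 2
            + (y - ay)[None, :, None] ** 2
            + (z - az)[None, None, :] ** 2
        )
        r = np.sqrt(r2)
        np.maximum(r, MIN_SEPARATION, out=r)
        inv_r = 1.0 / r
        qa = solute.sites[a].charge
        if qa != 0.0:
            phi_long += (constants.COULOMB * qa) * erf(r / smear) * inv_r
            coul_short = (constants.COULOMB * qa) * erfc(r / smear) * inv_r
        else:
            coul_short = None
        inv_r6 = inv_r**6
        for t in range(nt):
            # One summand per atom so superposition over atoms is bitwise.
            sig, eps = mix_lj(solute.sites[a], solvent_sites[t])
            contrib = np.zeros(shape)
            if eps > 0.0:
                s6 = sig**6 * inv_r6
                contrib = 4.0 * eps * (s6 * s6 - s6)
            if coul_short is not None and charges[t] != 0.0:
                contrib = contrib + charges[t] * coul_short
            u_short[t] += contrib
    phi_long_hat = _periodic_phi_long_hat(solute, grid, smear)
    phi_long_periodic = irfftn(phi_long_hat, s=grid.dims) / grid.voxel_volume
    return PotentialFields(
        grid=grid,
        site_types=tuple(s.label for s in solvent_sites),
        site_charges=charges,
        u_short=u_short,
        phi_long=phi_long,
        phi_long_hat=phi_long_hat,
        phi_long_periodic=phi_long_periodic,
        smear=smear,
    )


def _periodic_phi_long_hat(solute: SoluteModel, grid: Grid3D, smear: float) -> np.ndarray:
    """Reciprocal components of the smeared solute potential in the periodic
    supercell: phi_hat(k) = 4 pi k_e S(k) exp(-k^2 s^2/4)/k^2 with the exact
    structure factor S(k) = sum_a q_a exp(-i k . (R_a - origin)).

    The k = 0 component is set to zero (tinfoil/neutralizing background).
    Scaled so that irfftn(phi_hat)/voxel_volume is the real-space field.
    """
    kx, ky, kz = grid.k_axes()
    shape = (kx.size, ky.size, kz.size)
    s_k = np.zeros(shape, dtype=complex)
    origin = np.asarray(grid.origin)
    for a in range(solute.n_atoms):
        qa = solute.sites[a].charge
        if qa == 0.0:
            continue
        rx, ry, rz = solute.positions[a] - origin
        s_k += qa * (
            np.exp(-1j * kx * rx)[:, None, None]
            * np.exp(-1j * ky * ry)[None, :, None]
            * np.exp(-1j * kz * rz)[None, None, :]
        )
    k2 = (
        kx[:, None, None] ** 2 + ky[None, :, None] ** 2 + kz[None, None, :] ** 2
    )
    kernel = np.zeros(shape)
    nonzero = k2 > 0
    kernel[nonzero] = (
        4.0 * math.pi * constants.COULOMB
        * np.exp(-k2[nonzero] * smear**2 / 4.0) / k2[nonzero]
    )
    return s_k * kernel


def apply_closure(u: np.ndarray, gamma: np.ndarray, closure: ClosureSpec,
                  thermo: ThermoState) -> np.ndarray:
    """Distribution function g from the closure at exponent -beta*u + gamma."""
    if u.shape != gamma.shape:
        raise ValueError("u and gamma must be on the same grid")
    return _closure_g(-thermo.beta * u + gamma, closure)


@dataclass
class Correlations3D:
    """Converged per-site-type 3D fields and solver provenance."""

    grid: Grid3D
    site_types: tuple[str, ...]
    site_densities: np.ndarray  # per type, Å^-3
    site_charges: np.ndarray  # per type, e
    thermo: ThermoState
    closure: ClosureSpec
    u: np.ndarray = field(repr=False)  # total potential, (nt, ...) kJ/mol
    h: np.ndarray = field(repr=False)
    c: np.ndarray = field(repr=False)
    residual_history: list[float] = field(default_factory=list, repr=False)
    converged: bool = True

    @property
    def g(self) -> np.ndarray:
        return self.h + 1.0

    @property
    def n_types(self) -> int:
        return len(self.site_types)


def _collapsed_chi(chi: SolventSusceptibility, kmag: np.ndarray) -> np.ndarray:
    """Collapse the explicit-site chi matrix over symmetry-equivalent sites.

    Returns X with X[t', t] = sum_{j in type t'} chi_{j, rep(t)}(|k|) so that
    h_t = sum_t' c_t' X[t', t].
    """
    types = chi.unique_types
    nt = len(types)
    full = chi.chi_of_k(kmag)  # (ns, ns, ...)
    out = np.empty((nt, nt) + kmag.shape)
    for tp, lab_p in enumerate(types):
        members = chi.type_members(lab_p)
        for t, lab in enumerate(types):
            rep = chi.type_members(lab)[0]
            out[tp, t] = sum(full[j, rep] for j in members)
    return out


def solve_3drism(
    potentials: PotentialFields,
    chi: SolventSusceptibility,
    closure: ClosureSpec | None = None,
    *,
    thermo: ThermoState | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    mdiis_depth: int = 10,
    mdiis_mixing: float = 0.7,
    verbose: bool = False,
) -> Correlations3D:
    """Solve the 3D-RISM fixed point {closure; h = c * chi} on the grid.

    Iterates on the renormalized direct correlation c_s = c + beta*u_long
    with MDIIS acceleration; raises :class:`ConvergenceError` carrying the
    residual trace (with a KH-fallback suggestion) on divergence.
    """
    closure = closure or ClosureSpec("PSE", 3)
    thermo = thermo or (chi.thermo if chi.thermo is not None else ThermoState())
    types = chi.unique_types
    if tuple(types) != tuple(potentials.site_types):
        raise ValueError(
            f"solvent sites of the susceptibility {types} do not match the "
            f"potential fields {list(potentials.site_types)}"
        )
    grid = potentials.grid
    beta = thermo.beta
    nt = len(types)
    kmag = grid.k_magnitude()
    x_chi = _collapsed_chi(chi, kmag)

    # Long-range Coulomb in reciprocal space: analytic periodic components,
    # rescaled to grid-FFT units.  The closure below uses the matching
    # periodic real-space field so both sides see the same electrostatics.
    phi_hat_grid = potentials.phi_long_hat / grid.voxel_volume
    minus_beta_us = -beta * potentials.u_short
    beta_ul_hat = np.array(
        [beta * potentials.site_charges[t] * phi_hat_grid for t in range(nt)]
    )

    # Mayer-function initial guess: equals -beta*u_short in the tail but stays
    # bounded (-1) inside the repulsive core, where the converged c is O(1).
    c_s = np.expm1(np.minimum(minus_beta_us, 30.0))
    mdiis = MDIIS(depth=mdiis_depth, mixing=mdiis_mixing)
    history: list[float] = []
    g = np.empty_like(c_s)
    h_oz = np.empty_like(c_s)
    for iteration in range(1, max_iter + 1):
        c_hat = np.array([rfftn(c_s[t]) for t in range(nt)]) - beta_ul_hat
        for t in range(nt):
            acc = c_hat[0] * x_chi[0, t]
            for tp in range(1, nt):
                acc = acc + c_hat[tp] * x_chi[tp, t]
            h_oz[t] = irfftn(acc, s=grid.dims)
        gamma_star = h_oz - c_s
        try:
            g = _closure_g(minus_beta_us + gamma_star, closure)
        except FloatingPointError as exc:
            raise ConvergenceError(
                f"3D-RISM closure overflow at iteration {iteration} with "
                f"{closure.label}; consider the KH closure or stronger damping: {exc}",
                history,
            ) from exc
        c_s_new = (g - 1.0) - gamma_star
        residual = c_s_new - c_s
        rms = float(np.sqrt(np.mean(residual**2)))
        history.append(rms)
        if verbose:
            print(f"  3D-RISM iter {iteration:4d} rms {rms:.3e}")
        if rms < tol:
            c_s = c_s_new
            break
        c_s = mdiis.step(c_s, residual)
        if not np.all(np.isfinite(c_s)):
            raise ConvergenceError(
                f"3D-RISM produced non-finite fields at iteration {iteration} "
                f"({closure.label}); consider the KH closure", history)
    else:
        raise ConvergenceError(
            f"3D-RISM did not converge in {max_iter} iterations ({closure.label}, "
            f"final rms {history[-1]:.3e}); consider the KH closure", history)

    h = g - 1.0
    u_total = np.array([potentials.u_total(t) for t in range(nt)])
    c = c_s - np.array([beta * potentials.u_long(t) for t in range(nt)])
    densities = np.array([chi.type_density(lab) for lab in types])
    charges = np.array([chi.type_site(lab).charge for lab in types])
    return Correlations3D(
        grid=grid,
        site_types=tuple(types),
        site_densities=densities,
        site_charges=charges,
        thermo=thermo,
        closure=closure,
        u=u_total,
        h=h,
        c=c,
        residual_history=history,
        converged=True,
    )
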