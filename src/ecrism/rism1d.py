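"""Dielectrically consistent 1D-RISM for bulk water.

Solves the site-site Ornstein-Zernike equations for a rigid three-site water
model on a logarithmically cheap radial grid, with the Coulomb tails split
off analytically (erf/erfc renormalization) so that all transformed
quantities are short ranged.  The dielectric consistency follows the
Perkyns-Pettitt construction: an analytic dipolar bridge term zeta(k) is
added to the intramolecular matrix and to the solution, with its amplitude
fixed by the target dielectric constant.

Outputs are the bulk pair functions, the reduced solvent susceptibility
chi(k) = omega(k) + rho*h(k) consumed by the 3D solver, the compressibility
(k=0 route), and the RISM pressure from the direct correlation function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dst
from scipy.special import erf

from . import constants
from .closures import ClosureOverflowError, ClosureSpec, apply_closure
from .forcefield import Site, ThermoState, WaterModel, mix_lj
from .solver import MDIIS, ConvergenceError

#: Default width of the erf charge-smearing used for the Coulomb splitting, Å.
COULOMB_SMEAR = 1.0

#: Width of the Gaussian damping in the dielectric bridge, Å.
DRISM_SMEAR = 0.5


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid with the conjugate DST-I momentum grid.

    r_i = (i+1) dr for i = 0..n-1 and k_j = (j+1) dk with
    dk = pi / ((n_points + 1) dr), the spacing for which the type-I discrete
    sine transform is self-inverse.
    """

    n_points: int = 1024
    dr: float = 0.025

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError("n_points too small")
        if self.dr <= 0:
            raise ValueError("dr must be positive")

    @property
    def dk(self) -> float:
        return math.pi / ((self.n_points + 1) * self.dr)

    @property
    def r(self) -> np.ndarray:
        return self.dr * np.arange(1, self.n_points + 1)

    @property
    def k(self) -> np.ndarray:
        return self.dk * np.arange(1, self.n_points + 1)

    @property
    def r_max(self) -> float:
        return self.n_points * self.dr

    def fourier(self, f: np.ndarray) -> np.ndarray:
        """Radial Fourier (sine) transform f(r) -> f_hat(k), trailing axis."""
        return 2.0 * math.pi * self.dr * dst(self.r * f, type=1) / self.k

    def inverse(self, f_hat: np.ndarray) -> np.ndarray:
        """Inverse radial Fourier transform f_hat(k) -> f(r), trailing axis."""
        return self.dk * dst(self.k * f_hat, type=1) / (4.0 * math.pi**2 * self.r)


def intramolecular_omega(model: WaterModel, grid: RadialGrid) -> np.ndarray:
    """Intramolecular correlation matrix omega_hat(k), shape (3, 3, nk).

    omega_hat_ij(k) = sin(k l_ij)/(k l_ij) for distinct rigid sites at
    distance l_ij, and 1 for i = j.
    """
    dists = _site_distances(model)
    k = grid.k
    ns = dists.shape[0]
    omega = np.empty((ns, ns, k.size))
    for i in range(ns):
        for j in range(ns):
            l = dists[i, j]
            omega[i, j] = 1.0 if l == 0.0 else np.sin(k * l) / (k * l)
    return omega


def _site_distances(model: WaterModel) -> np.ndarray:
    coords = model.site_coordinates()
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _pair_potentials(model: WaterModel, grid: RadialGrid, smear: float):
    """Short-range real-space potentials and analytic long-range transforms.

    Returns (u_short(r), u_long(r), u_long_hat(k)) with shapes (3, 3, n).
    """
    sites = model.sites
    ns = len(sites)
    r, k = grid.r, grid.k
    u_short = np.empty((ns, ns, r.size))
    u_long = np.empty((ns, ns, r.size))
    u_long_hat = np.empty((ns, ns, k.size))
    for i in range(ns):
        for j in range(ns):
            sigma, eps = mix_lj(sites[i], sites[j])
            lj = np.zeros_like(r)
            if eps > 0.0:
                sr6 = (sigma / r) ** 6
                lj = 4.0 * eps * (sr6 * sr6 - sr6)
            qq = constants.COULOMB * sites[i].charge * sites[j].charge
            ul = qq * erf(r / smear) / r
            u_long[i, j] = ul
            u_short[i, j] = lj + qq / r - ul
            u_long_hat[i, j] = 4.0 * math.pi * qq * np.exp(-(k * smear) ** 2 / 4.0) / k**2
    return u_short, u_long, u_long_hat


def _drism_zeta_at(model: WaterModel, grid: RadialGrid, dielectric: float,
                   thermo: ThermoState) -> np.ndarray:
    """Analytic dielectric-consistency bridge zeta_ij(k), shape (3, 3, nk).

    zeta_ij(k) = h_c(k) d_i(k) d_j(k) with d_i(k) = j0(k x_i) j0(k y_i)
    j1(k z_i) evaluated from the site coordinates in the dipole-along-z
    molecular frame, and h_c(k) = A exp(-s^2 k^2 / 4),
    A = (eps/y - 3)/rho, with the dimensionless dipolar strength
    y = (4 pi / 9) beta rho mu^2 k_e.
    """
    mu = model.dipole_moment()
    ns = len(model.sites)
    if mu == 0.0:
        return np.zeros((ns, ns, grid.n_points))
    rho = model.number_density
    y = (4.0 * math.pi / 9.0) * thermo.beta * rho * mu**2 * constants.COULOMB
    amplitude = (dielectric / y - 3.0) / rho
    k = grid.k
    hck = amplitude * np.exp(-((DRISM_SMEAR * k) ** 2) / 4.0)
    coords = model.site_coordinates()
    d = np.empty((ns, k.size))
    for i in range(ns):
        x, ycoord, z = coords[i]
        d[i] = _j0(k * x) * _j0(k * ycoord) * _j1(k * z)
    return hck[None, None, :] * d[:, None, :] * d[None, :, :]


def _j0(x: np.ndarray) -> np.ndarray:
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = np.sin(x[nz]) / x[nz]
    return out


def _j1(x: np.ndarray) -> np.ndarray:
    # (sin x - x cos x) / x^2, -> x/3 as x -> 0
    out = np.asarray(x, dtype=float) / 3.0
    big = np.abs(x) > 1e-4
    xb = x[big]
    out[big] = (np.sin(xb) - xb * np.cos(xb)) / xb**2
    return out


@dataclass
class BulkSolution:
    """Converged bulk site-site correlation functions.

    ``h`` and ``c`` are the full total and direct correlation matrices in
    real space, shape (3, 3, n_r); ``c_short`` is the renormalized direct
    correlation c + beta*u_long that all k = 0 sums are taken from.
    """

    model: WaterModel
    grid: RadialGrid
    thermo: ThermoState
    closure: ClosureSpec
    h: np.ndarray = field(repr=False)
    c: np.ndarray = field(repr=False)
    c_short: np.ndarray = field(repr=False)
    #: h(k) from the final OZ step; the long-range Coulomb part enters it
    #: analytically, so the small-k (dielectric screening) behaviour is exact
    #: rather than limited by the real-space truncation of h.
    h_hat: np.ndarray = field(default=None, repr=False)
    residual: float = 0.0
    n_iterations: int = 0
    dielectric: float | None = None

    @property
    def g(self) -> np.ndarray:
        return self.h + 1.0

    def c_hat_zero_sum(self) -> float:
        """sum_{ij} c_hat_ij(k=0) over all explicit site pairs, Å^3.

        The long-range Coulomb parts cancel exactly over the neutral molecule,
        so only the short-ranged renormalized part contributes.
        """
        r = self.grid.r
        integrand = self.c_short.sum(axis=(0, 1))
        return float(4.0 * math.pi * self.grid.dr * np.sum(r**2 * integrand))


def solve_drism(
    model: WaterModel,
    thermo: ThermoState | None = None,
    grid: RadialGrid | None = None,
    closure: ClosureSpec | None = None,
    *,
    dielectric: float | str | None = "model",
    tol: float = 1e-7,
    max_iter: int = 20000,
    mdiis_depth: int = 10,
    mdiis_mixing: float = 0.7,
    smear: float = COULOMB_SMEAR,
    initial_gamma: np.ndarray | None = None,
    use_ladder: bool = True,
) -> BulkSolution:
    """Solve the 1D site-site RISM equations for a rigid water model.

    ``dielectric="model"`` takes the dielectric constant from the water model
    (DRISM); ``dielectric=None`` disables the dielectric bridge (XRISM); a
    float overrides the target value.

    Closures beyond KH are approached through a continuation ladder
    (KH -> PSE-2 -> PSE-3 -> ... -> target) which mirrors their practical
    convergence behaviour; failures raise :class:`ConvergenceError` with the
    residual history attached.
    """
    thermo = thermo or ThermoState()
    grid = grid or RadialGrid()
    closure = closure or ClosureSpec("KH")
    eps: float | None
    if dielectric == "model":
        eps = model.dielectric
    else:
        eps = dielectric  # type: ignore[assignment]

    ladder = [closure]
    if use_ladder:
        ladder = _closure_ladder(closure)

    gamma = initial_gamma
    sol = None
    for i, cl in enumerate(ladder):
        last = i == len(ladder) - 1
        try:
            sol = _solve_single(
                model, thermo, grid, cl, eps, tol=tol if last else max(tol, 1e-6),
                max_iter=max_iter, mdiis_depth=mdiis_depth,
                mdiis_mixing=mdiis_mixing, smear=smear, initial_gamma=gamma,
            )
        except (ConvergenceError, ClosureOverflowError) as exc:
            if isinstance(exc, ClosureOverflowError) or gamma is None:
                # Retry this rung with charge-scaling continuation.
                sol = _solve_with_charge_ramp(
                    model, thermo, grid, cl, eps, tol=tol if last else max(tol, 1e-6),
                    max_iter=max_iter, mdiis_depth=mdiis_depth,
                    mdiis_mixing=mdiis_mixing, smear=smear,
                )
            else:
                raise
        gamma = sol.h - sol.c_short
    assert sol is not None
    return sol


def _closure_ladder(target: ClosureSpec) -> list[ClosureSpec]:
    if target.kind in {"KH", "PLHNC"}:
        return [target]
    rungs: list[ClosureSpec] = [ClosureSpec("KH")]
    max_order = target.order if target.kind == "PSE" else 4
    for n in range(2, max_order + 1):
        rungs.append(ClosureSpec("PSE", order=n))
    if target.kind == "HNC":
        rungs.append(target)
    elif rungs[-1] != target:
        rungs.append(target)
    # Deduplicate consecutive equal rungs.
    out = [rungs[0]]
    for r in rungs[1:]:
        if r != out[-1]:
            out.append(r)
    return out


def _solve_with_charge_ramp(model, thermo, grid, closure, eps, **kwargs):
    from dataclasses import replace

    gamma = None
    sol = None
    for scale in (0.25, 0.5, 0.75, 1.0):
        scaled = replace(
            model,
            oxygen=replace(model.oxygen, charge=model.oxygen.charge * scale),
            hydrogen=replace(model.hydrogen, charge=model.hydrogen.charge * scale),
        )
        sol = _solve_single(scaled, thermo, grid, closure, eps,
                            initial_gamma=gamma, **kwargs)
        gamma = sol.h - sol.c_short
    return sol


def _solve_single(
    model: WaterModel,
    thermo: ThermoState,
    grid: RadialGrid,
    closure: ClosureSpec,
    dielectric: float | None,
    *,
    tol: float,
    max_iter: int,
    mdiis_depth: int,
    mdiis_mixing: float,
    smear: float,
    initial_gamma: np.ndarray | None,
) -> BulkSolution:
    beta = thermo.beta
    rho = model.number_density
    ns = len(model.sites)
    omega = intramolecular_omega(model, grid)
    u_short, u_long, u_long_hat = _pair_potentials(model, grid, smear)
    has_charges = any(s.charge != 0.0 for s in model.sites)
    if dielectric is not None and has_charges and model.dipole_moment() > 0.0:
        zeta = _drism_zeta_at(model, grid, dielectric, thermo)
    else:
        zeta = np.zeros((ns, ns, grid.n_points))

    # Per-k matrices, shape (nk, ns, ns).
    omega_k = np.ascontiguousarray(omega.transpose(2, 0, 1))
    zeta_k = np.ascontiguousarray(zeta.transpose(2, 0, 1))
    w_eff = omega_k + rho * zeta_k
    eye = np.eye(ns)

    gamma = np.zeros((ns, ns, grid.n_points)) if initial_gamma is None else initial_gamma.copy()
    mdiis = MDIIS(depth=mdiis_depth, mixing=mdiis_mixing)
    history: list[float] = []
    minus_beta_us = -beta * u_short
    beta_ul_hat = beta * u_long_hat

    for iteration in range(1, max_iter + 1):
        t = minus_beta_us + gamma
        g = apply_closure(t, closure)
        h = g - 1.0
        c_short = h - gamma
        c_short_hat = grid.fourier(c_short)
        c_hat = c_short_hat - beta_ul_hat
        c_k = np.ascontiguousarray(c_hat.transpose(2, 0, 1))
        wc = w_eff @ c_k
        rhs = wc @ w_eff
        a = eye[None, :, :] - rho * wc
        h_k = np.linalg.solve(a, rhs) + zeta_k
        h_k = 0.5 * (h_k + h_k.transpose(0, 2, 1))
        gamma_hat_new = h_k.transpose(1, 2, 0) - c_short_hat
        gamma_new = grid.inverse(gamma_hat_new)
        residual = gamma_new - gamma
        rms = float(np.sqrt(np.mean(residual**2)))
        history.append(rms)
        if rms < tol:
            gamma = gamma_new
            break
        gamma = mdiis.step(gamma, residual)
        if not np.all(np.isfinite(gamma)):
            raise ConvergenceError(
                f"1D-RISM iteration produced non-finite values at step {iteration} "
                f"({closure.label})", history)
    else:
        raise ConvergenceError(
            f"1D-RISM did not converge in {max_iter} iterations "
            f"({closure.label}, final rms {history[-1]:.3e})", history)

    t = minus_beta_us + gamma
    g = apply_closure(t, closure)
    h = g - 1.0
    c_short = h - gamma
    c = c_short - beta * u_long
    # One extra OZ pass to record h(k) with analytic long-range content.
    c_short_hat = grid.fourier(c_short)
    c_k = np.ascontiguousarray((c_short_hat - beta_ul_hat).transpose(2, 0, 1))
    wc = w_eff @ c_k
    h_k = np.linalg.solve(eye[None, :, :] - rho * wc, wc @ w_eff) + zeta_k
    h_hat = 0.5 * (h_k + h_k.transpose(0, 2, 1))
    h_hat = np.ascontiguousarray(h_hat.transpose(1, 2, 0))
    return BulkSolution(
        model=model, grid=grid, thermo=thermo, closure=closure,
        h=h, c=c, c_short=c_short, h_hat=h_hat, residual=history[-1],
        n_iterations=len(history), dielectric=dielectric,
    )


@dataclass
class SolventSusceptibility:
    """Reduced site-site solvent susceptibility chi(k) = omega(k) + rho h(k).

    Stored per explicit site pair (symmetric in the pair indices) together
    with everything the 3D solver needs: site parameters, per-site densities,
    the site-type grouping that collapses symmetry-equivalent sites, and the
    analytic intramolecular distances for exact omega evaluation off-grid.
    """

    model_name: str
    closure_label: str
    thermo: ThermoState
    k_grid: np.ndarray = field(repr=False)
    chi_hat: np.ndarray = field(repr=False)  # (ns, ns, nk)
    omega_hat: np.ndarray = field(repr=False)  # (ns, ns, nk)
    rho_h_hat: np.ndarray = field(repr=False)  # (ns, ns, nk)
    site_labels: tuple[str, ...] = ()
    site_densities: np.ndarray = field(default=None, repr=False)  # Å^-3, per explicit site
    site_charges: np.ndarray = field(default=None, repr=False)
    site_sigmas: np.ndarray = field(default=None, repr=False)
    site_epsilons: np.ndarray = field(default=None, repr=False)
    distances: np.ndarray = field(default=None, repr=False)  # (ns, ns) Å
    kappa_t: float = 0.0  # isothermal compressibility, Å^3 mol / kJ
    pressure: float = 0.0  # RISM pressure, kJ/mol/Å^3
    rho_kt: float = 0.0  # rho_molecular k_B T, kJ/mol/Å^3

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def unique_types(self) -> list[str]:
        seen: list[str] = []
        for lab in self.site_labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def type_members(self, type_label: str) -> list[int]:
        return [i for i, lab in enumerate(self.site_labels) if lab == type_label]

    def type_site(self, type_label: str) -> Site:
        i = self.type_members(type_label)[0]
        return Site(type_label, float(self.site_charges[i]),
                    float(self.site_sigmas[i]), float(self.site_epsilons[i]))

    def type_density(self, type_label: str) -> float:
        members = self.type_members(type_label)
        return float(sum(self.site_densities[i] for i in members))

    def chi_of_k(self, kmag: np.ndarray) -> np.ndarray:
        """Interpolate chi onto arbitrary |k| values.

        omega is evaluated analytically from the rigid distances; the
        rho*h(k) part is linearly interpolated with a quadratic k -> 0
        extrapolation, which is what fixes the uniform (k = 0) response.
        """
        kmag = np.asarray(kmag, dtype=float)
        ns = self.n_sites
        out = np.empty((ns, ns) + kmag.shape)
        kg = self.k_grid
        for i in range(ns):
            for j in range(i, ns):
                l = self.distances[i, j]
                om = np.ones_like(kmag) if l == 0.0 else _j0(kmag * l)
                rh = self.rho_h_hat[i, j]
                rh0 = _quadratic_k0(kg, rh)
                interp = np.interp(kmag, np.concatenate(([0.0], kg)),
                                   np.concatenate(([rh0], rh)))
                out[i, j] = om + interp
                out[j, i] = out[i, j]
        return out


def _quadratic_k0(k: np.ndarray, f: np.ndarray) -> float:
    """Extrapolate f(k->0) assuming f = a + b k^2 from the first two points."""
    k1, k2 = k[0], k[1]
    f1, f2 = f[0], f[1]
    b = (f2 - f1) / (k2**2 - k1**2)
    return float(f1 - b * k1**2)


def susceptibility(sol: BulkSolution) -> SolventSusceptibility:
    """Assemble the reduced susceptibility chi = omega + rho*h from a
    converged bulk solution, plus compressibility and pressure."""
    grid = sol.grid
    model = sol.model
    rho = model.number_density
    omega = intramolecular_omega(model, grid)
    h_hat = sol.h_hat if sol.h_hat is not None else grid.fourier(sol.h)
    rho_h = rho * h_hat
    chi = omega + rho_h
    chi = 0.5 * (chi + chi.transpose(1, 0, 2))
    kappa = isothermal_compressibility(sol)
    press, rho_kt = rism_pressure(sol)
    sites = model.sites
    return SolventSusceptibility(
        model_name=model.name,
        closure_label=sol.closure.label,
        thermo=sol.thermo,
        k_grid=grid.k.copy(),
        chi_hat=chi,
        omega_hat=omega,
        rho_h_hat=rho_h,
        site_labels=tuple(s.label for s in sites),
        site_densities=np.full(len(sites), rho),
        site_charges=np.array([s.charge for s in sites]),
        site_sigmas=np.array([s.sigma for s in sites]),
        site_epsilons=np.array([s.epsilon for s in sites]),
        distances=_site_distances(model),
        kappa_t=kappa,
        pressure=press,
        rho_kt=rho_kt,
    )


def isothermal_compressibility(sol: BulkSolution) -> float:
    """Isothermal compressibility from the k = 0 (compressibility) route,
    kappa_T = beta / (rho (1 - rho sum_ij c_hat_ij(0))), in Å^3 mol/kJ."""
    rho = sol.model.number_density
    c0 = sol.c_hat_zero_sum()
    return sol.thermo.beta / (rho * (1.0 - rho * c0))


def rism_pressure(sol: BulkSolution) -> tuple[float, float]:
    """RISM pressure from the direct correlation function.

    P = rho k_B T (n_sites + 1)/2 - (k_B T / 2) rho^2 sum_ij c_hat_ij(0),
    returned together with the ideal molecular term rho k_B T (both in
    kJ/mol/Å^3) used by the PC+ correction.
    """
    rho = sol.model.number_density
    kt = sol.thermo.kt
    n = len(sol.model.sites)
    c0 = sol.c_hat_zero_sum()
    pressure = rho * kt * (n + 1) / 2.0 - 0.5 * kt * rho**2 * c0
    return pressure, rho * kt


def pressure_from_c0(rho: float, kt: float, n_sites: int, c0_sum: float) -> tuple[float, float]:
    """Same pressure expression on raw inputs (used by synthetic oracles)."""
    return rho * kt * (n_sites + 1) / 2.0 - 0.5 * kt * rho**2 * c0_sum, rho * kt
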