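"""Excess chemical potential functionals, partial molar volume, corrections.

Each closed-form functional lives in one function; the quadrature everywhere
is the plain voxel sum matching the solver's discretization:

    dG = k_B T * sum_sites rho_alpha * voxel_volume * sum_vox integrand

Functional integrands (Theta is the Heaviside step with Theta(0) = 0):

* HNC:   h^2/2 - c - h c/2
* KH:    h^2/2 Theta(-h) - c - h c/2
* PSE-n: h^2/2 - c - h c/2 - Theta(t*) t*^(n+1)/(n+1)!   (t* = -beta u + h - c)
* GF:    -c - h c/2  (Gaussian fluctuations; closure-agnostic)

Corrections on top of a base value:

* UC:   dG + a1 * (rho V) + a0, with (a1, a0) from a linear fit of the error
        against the dimensionless partial molar volume.
* PC:   dG - P_RISM * V
* PC+:  dG - (P_RISM - rho k_B T) * V
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .closures import ClosureSpec
from .rism3d import Correlations3D

_FUNCTIONALS = ("HNC", "KH", "PSE", "GF")


@dataclass(frozen=True)
class UCParams:
    """Universal-correction coefficients: slope in kJ/mol per unit of the
    dimensionless partial molar volume and intercept in kJ/mol."""

    a1: float
    a0: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a1) and math.isfinite(self.a0)):
            raise ValueError("UC parameters must be finite")


@dataclass(frozen=True)
class PressureTerms:
    """RISM pressure and the ideal molecular term, both kJ/mol/Å^3."""

    p_rism: float
    rho_kt: float


@dataclass
class FreeEnergyReport:
    """Solvation free energies per functional with corrections and provenance."""

    delta_g: dict[str, float]  # functional label -> kJ/mol
    pmv: float  # Å^3
    dpmv: float  # dimensionless, rho_molecular * pmv
    pressure: float  # kJ/mol/Å^3
    rho_kt: float  # kJ/mol/Å^3
    corrections: dict[str, float] = field(default_factory=dict)  # scheme -> term kJ/mol
    corrected: dict[str, float] = field(default_factory=dict)  # scheme -> value kJ/mol
    closure: str = ""
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "delta_g": dict(self.delta_g),
            "pmv": self.pmv,
            "dpmv": self.dpmv,
            "pressure": self.pressure,
            "rho_kt": self.rho_kt,
            "corrections": dict(self.corrections),
            "corrected": dict(self.corrected),
            "closure": self.closure,
            "provenance": dict(self.provenance),
        }


def _functional_integrand(corr: Correlations3D, functional: str,
                          order: int) -> np.ndarray:
    h, c = corr.h, corr.c
    if functional == "GF":
        return -c - 0.5 * h * c
    if functional == "HNC":
        return 0.5 * h * h - c - 0.5 * h * c
    if functional == "KH":
        core = np.where(h < 0.0, 0.5 * h * h, 0.0)
        return core - c - 0.5 * h * c
    if functional == "PSE":
        t_star = -corr.thermo.beta * corr.u + h - c
        tail = np.where(
            t_star > 0.0,
            np.where(t_star > 0.0, t_star, 0.0) ** (order + 1) / math.factorial(order + 1),
            0.0,
        )
        return 0.5 * h * h - c - 0.5 * h * c - tail
    raise ValueError(f"unknown functional {functional!r}")


def excess_mu(
    corr: Correlations3D,
    functional: str | None = None,
    *,
    order: int | None = None,
    allow_mismatch: bool = False,
) -> float:
    """Excess chemical potential (solvation free energy before corrections).

    ``functional`` defaults to the one matching the closure the fields were
    converged with.  Requesting a different closure-bound functional raises
    unless ``allow_mismatch`` is set; GF is closure-agnostic and always
    permitted.
    """
    closure = corr.closure
    if functional is None:
        functional = closure.kind if closure.kind != "PLHNC" else "KH"
    functional = functional.upper()
    if functional.startswith("PSE-"):
        order = int(functional[4:])
        functional = "PSE"
    if functional not in _FUNCTIONALS:
        raise ValueError(f"unknown functional {functional!r}")
    if functional == "PSE" and order is None:
        order = closure.order
    closure_kind = "KH" if closure.kind == "PLHNC" and closure.plhnc_c == 0.0 else closure.kind
    matches = (
        functional == "GF"
        or functional == closure_kind
        and (functional != "PSE" or order == closure.order)
        or functional == "KH"
        and closure_kind == "PSE"
        and closure.order == 1
    )
    if not matches and not allow_mismatch:
        raise ValueError(
            f"functional {functional} requested on a {closure.label} solution; "
            "pass allow_mismatch=True to override"
        )
    integrand = _functional_integrand(corr, functional, order or 1)
    kt = corr.thermo.kt
    dv = corr.grid.voxel_volume
    total = 0.0
    for t in range(corr.n_types):
        total += corr.site_densities[t] * float(integrand[t].sum())
    return kt * dv * total


def all_functionals(corr: Correlations3D) -> dict[str, float]:
    """Evaluate every functional on the converged fields (mismatches allowed,
    labelled by functional)."""
    out: dict[str, float] = {}
    for name in ("HNC", "KH", "GF"):
        out[name] = excess_mu(corr, name, allow_mismatch=True)
    if corr.closure.kind == "PSE":
        out[f"PSE-{corr.closure.order}"] = excess_mu(corr, "PSE", order=corr.closure.order)
    return out


def partial_molar_volume(corr: Correlations3D, kappa_t: float) -> float:
    """Partial molar volume via the Kirkwood-Buff compressibility route:

    V = k_B T kappa_T (1 - sum_alpha rho_alpha * integral c_alpha dr), Å^3.

    The site sum is taken before integration so the long-range Coulomb parts
    cancel over the neutral solvent molecule.
    """
    kt = corr.thermo.kt
    dv = corr.grid.voxel_volume
    weighted = np.zeros_like(corr.c[0])
    for t in range(corr.n_types):
        weighted += corr.site_densities[t] * corr.c[t]
    c_integral = dv * float(weighted.sum())
    return kt * kappa_t * (1.0 - c_integral)


def correct_uc(delta_g: float, dpmv: float, params: UCParams) -> float:
    """Universal correction: dG + a1 * dpmv + a0."""
    return delta_g + params.a1 * dpmv + params.a0


def fit_uc(
    delta_g_calc: np.ndarray,
    dpmv: np.ndarray,
    delta_g_exp: np.ndarray,
    *,
    pin_intercept: bool = False,
) -> UCParams:
    """Least-squares fit of the error dG_exp - dG_calc against the
    dimensionless partial molar volume.

    With ``pin_intercept`` the intercept a0 is constrained to zero (slope =
    <x y>/<x^2> in closed form).
    """
    x = np.asarray(dpmv, dtype=float)
    y = np.asarray(delta_g_exp, dtype=float) - np.asarray(delta_g_calc, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points to fit the universal correction")
    if np.ptp(x) == 0.0 and not pin_intercept:
        raise ValueError("all dpmv values identical: rank-deficient UC fit")
    if pin_intercept:
        denom = float(np.dot(x, x))
        if denom == 0.0:
            raise ValueError("all dpmv values are zero: cannot fit pinned UC slope")
        return UCParams(a1=float(np.dot(x, y) / denom), a0=0.0)
    a = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    return UCParams(a1=float(coef[0]), a0=float(coef[1]))


def correct_pressure(delta_g: float, pmv: float, terms: PressureTerms,
                     scheme: str = "PC+") -> float:
    """Pressure corrections: PC subtracts the full P_RISM*V work term, PC+
    subtracts (P_RISM - rho k_B T)*V; they differ by rho k_B T V exactly."""
    s = scheme.upper()
    if s == "PC":
        return delta_g - terms.p_rism * pmv
    if s in {"PC+", "PCPLUS"}:
        return delta_g - (terms.p_rism - terms.rho_kt) * pmv
    raise ValueError(f"unknown pressure-correction scheme {scheme!r}")


def build_report(
    corr: Correlations3D,
    kappa_t: float,
    pressure_terms: PressureTerms,
    rho_molecular: float,
    *,
    uc_params: UCParams | None = None,
    provenance: dict | None = None,
) -> FreeEnergyReport:
    """Assemble the full free-energy report: every functional, PMV/DPMV and
    the GF-based UC (if parameters are given) plus PC/PC+ on the closure's
    own functional."""
    delta_g = all_functionals(corr)
    pmv = partial_molar_volume(corr, kappa_t)
    dpmv = rho_molecular * pmv
    closure_label = corr.closure.label
    base_label = closure_label if closure_label in delta_g else "KH"
    base = delta_g[base_label]
    corrections: dict[str, float] = {
        "PC": -pressure_terms.p_rism * pmv,
        "PC+": -(pressure_terms.p_rism - pressure_terms.rho_kt) * pmv,
    }
    corrected = {scheme: base + term for scheme, term in corrections.items()}
    if uc_params is not None:
        term = uc_params.a1 * dpmv + uc_params.a0
        corrections["UC"] = term
        corrected["UC"] = delta_g["GF"] + term
    return FreeEnergyReport(
        delta_g=delta_g,
        pmv=pmv,
        dpmv=dpmv,
        pressure=pressure_terms.p_rism,
        rho_kt=pressure_terms.rho_kt,
        corrections=corrections,
        corrected=corrected,
        closure=closure_label,
        provenance=provenance or {},
    )
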