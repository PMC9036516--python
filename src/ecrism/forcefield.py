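"""Interaction-site force field: water models, solute sites, pair potentials.

Water models are rigid three-site models (O plus two symmetry-equivalent H).
The built-in registry carries the four "coincident" models, in which the H
Lennard-Jones sphere is sized so that its surface coincides with the oxygen
sphere (sigma_H = sigma_O - 2 r_OH, epsilon_H = 0.1 epsilon_O), plus the
modified SPC/E model whose H parameters are an independent literal set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants


@dataclass(frozen=True)
class Site:
    """One interaction site: point charge plus Lennard-Jones sphere."""

    label: str
    charge: float  # elementary charge units
    sigma: float  # Å
    epsilon: float  # kJ/mol

    def __post_init__(self) -> None:
        if self.sigma < 0.0:
            raise ValueError(f"site {self.label}: sigma must be >= 0, got {self.sigma}")
        if self.epsilon < 0.0:
            raise ValueError(f"site {self.label}: epsilon must be >= 0, got {self.epsilon}")


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse thermal energy."""

    temperature: float = 298.15  # K

    @property
    def beta(self) -> float:
        """1/(k_B T) in mol/kJ."""
        return constants.beta(self.temperature)

    @property
    def kt(self) -> float:
        """k_B T in kJ/mol."""
        return constants.K_B * self.temperature


@dataclass(frozen=True)
class WaterModel:
    """Rigid three-site water model.

    The hydrogen site is stored once and replicated by symmetry, which makes
    the two-H equivalence an invariant by construction.
    """

    name: str
    r_oh: float  # Å
    theta_hoh: float  # degrees
    oxygen: Site
    hydrogen: Site
    density: float = 55.343  # mol/dm^3, molecular
    dielectric: float = 78.375

    def __post_init__(self) -> None:
        total = self.oxygen.charge + 2.0 * self.hydrogen.charge
        if abs(total) > 1e-12:
            raise ValueError(f"water model {self.name} is not neutral: total charge {total}")

    @property
    def r_hh(self) -> float:
        """H-H distance from the rigid geometry, Å."""
        return 2.0 * self.r_oh * math.sin(constants.deg_to_rad(self.theta_hoh) / 2.0)

    @property
    def number_density(self) -> float:
        """Molecular number density in Å^-3."""
        return constants.density_molar_to_number(self.density)

    @property
    def sites(self) -> tuple[Site, Site, Site]:
        """Explicit site list (O, H, H); the two H entries are identical."""
        return (self.oxygen, self.hydrogen, self.hydrogen)

    def site_coordinates(self) -> np.ndarray:
        """Site coordinates (3, 3) in a frame with O at the origin and the
        molecular dipole along +z (the HOH bisector)."""
        half = constants.deg_to_rad(self.theta_hoh) / 2.0
        x = self.r_oh * math.sin(half)
        z = self.r_oh * math.cos(half)
        # q_H > 0 for all shipped models, so the dipole points from O toward
        # the H side; orient the H's at positive z.
        return np.array([[0.0, 0.0, 0.0], [x, 0.0, z], [-x, 0.0, z]])

    def dipole_moment(self) -> float:
        """Dipole magnitude in e·Å for the rigid geometry."""
        coords = self.site_coordinates()
        charges = np.array([s.charge for s in self.sites])
        return float(np.linalg.norm(charges @ coords))


@dataclass(frozen=True)
class SoluteModel:
    """Solute as a list of atoms, each with coordinates and site parameters."""

    elements: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n, 3) Å
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if not (len(self.elements) == pos.shape[0] == len(self.sites)):
            raise ValueError("elements, positions and sites must have equal length")
        object.__setattr__(self, "positions", pos)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites])

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def with_charges(self, charges: np.ndarray) -> "SoluteModel":
        """Return a copy with replaced per-atom charges."""
        charges = np.asarray(charges, dtype=float)
        if charges.shape != (self.n_atoms,):
            raise ValueError("charge vector length mismatch")
        new_sites = tuple(replace(s, charge=float(q)) for s, q in zip(self.sites, charges))
        return replace(self, sites=new_sites)


def make_coincident_water(base: WaterModel) -> WaterModel:
    """Apply the coincident-sphere rules to a base water model.

    sigma_H = sigma_O - 2 r_OH places the hydrogen LJ surface on the oxygen
    sphere; epsilon_H = 0.1 epsilon_O.  All other parameters are unchanged.
    """
    sigma_h = base.oxygen.sigma - 2.0 * base.r_oh
    if sigma_h < 0.0:
        raise ValueError(
            f"coincident rule gives negative sigma_H ({sigma_h:.4f} Å) for model "
            f"{base.name}: requires sigma_O > 2 r_OH"
        )
    hydrogen = replace(base.hydrogen, sigma=sigma_h, epsilon=0.1 * base.oxygen.epsilon)
    return replace(base, hydrogen=hydrogen)


def mix_lj(a: Site, b: Site) -> tuple[float, float]:
    """Lorentz-Berthelot combination: arithmetic sigma, geometric epsilon."""
    return 0.5 * (a.sigma + b.sigma), math.sqrt(a.epsilon * b.epsilon)


def pair_potential(r, a: Site, b: Site) -> np.ndarray:
    """Site-site pair potential u(r) = LJ + Coulomb in kJ/mol.

    ``r`` may be a scalar or array of separations in Å; r = 0 is rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("pair_potential requires r > 0")
    sigma, epsilon = mix_lj(a, b)
    lj = np.zeros_like(r)
    if epsilon > 0.0:
        sr6 = (sigma / r) ** 6
        lj = 4.0 * epsilon * (sr6 * sr6 - sr6)
    coul = constants.COULOMB * a.charge * b.charge / r
    return lj + coul


def _coincident(name: str, r_oh: float, theta: float, q_o: float, sigma_o: float,
                eps_o: float) -> WaterModel:
    base = WaterModel(
        name=name,
        r_oh=r_oh,
        theta_hoh=theta,
        oxygen=Site("O", q_o, sigma_o, eps_o),
        hydrogen=Site("H", -q_o / 2.0, 1.0, 0.0),
    )
    return make_coincident_water(base)


#: Built-in water models keyed by name.
WATER_MODELS: dict[str, WaterModel] = {
    "cSPC/E": _coincident("cSPC/E", 1.0000, 109.47, -0.8476, 3.1658, 0.64978),
    "cTIP3P": _coincident("cTIP3P", 0.9572, 104.52, -0.8340, 3.1507, 0.63597),
    "cOPC3": _coincident("cOPC3", 1.0000, 109.47, -0.7300, 3.2037, 0.65270),
    "cPOL3": _coincident("cPOL3", 0.9789, 109.47, -0.8952, 3.1743, 0.68369),
    # mSPC/E does not follow the coincident rule; its H parameters are a
    # literal published set.
    "mSPC/E": WaterModel(
        name="mSPC/E",
        r_oh=1.0000,
        theta_hoh=109.47,
        oxygen=Site("O", -0.8476, 3.1658, 0.64978),
        hydrogen=Site("H", 0.4238, 1.0000, 0.234304),
    ),
}


def get_water_model(name: str) -> WaterModel:
    try:
        return WATER_MODELS[name]
    except KeyError:
        known = ", ".join(sorted(WATER_MODELS))
        raise KeyError(f"unknown water model {name!r}; available: {known}") from None
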