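"""Quantum-backend contract and the embedding energy ledger.

A backend computes, for a solute embedded in external background point
charges, the total energy E_tot (atomic units, REQUIRED to exclude the
point-charge self-energy E_qq) and the solute electrostatic potential at
arbitrary points.  The ledger separates

    E_q = sum_i q_i phi(r_i)        (charge-solute interaction, a.u.)
    E_1 = E_tot - E_q               (solute-internal energy)

and the electronic solvation term dE = E_1(solv) - E_1(gas) converted to
kJ/mol.  E_qq is never computed anywhere, by policy.

A closed-form mock engine with fixed core charges and independent isotropic
atomic polarizabilities stands in for a real quantum backend in tests; its
response energy is -1/2 sum_a alpha_a |E_a|^2 (always <= 0) and its ESP
includes the induced dipoles, so embedding it in the RISM loop exercises the
genuine self-consistency.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .charges import AtomicCharges, ChargeMap, ESPSample, chelpg_points, fit_esp_charges, mk_points
from .forcefield import SoluteModel


@dataclass(frozen=True)
class QMEnergyLedger:
    """Per-calculation energy bookkeeping in atomic units.

    e_1 + e_q = e_tot holds exactly because e_1 is defined as the difference
    (E_qq is omitted by policy: backends must exclude it from e_tot).
    """

    e_tot: float  # a.u.
    e_q: float  # a.u.
    method: str = ""
    basis: str = ""
    e_qq_omitted: bool = True

    @property
    def e_1(self) -> float:
        return self.e_tot - self.e_q

    def as_dict(self) -> dict:
        return {
            "e_tot_au": self.e_tot,
            "e_q_au": self.e_q,
            "e_1_au": self.e_1,
            "e_tot_kjmol": constants.hartree_to_kjmol(self.e_tot),
            "e_q_kjmol": constants.hartree_to_kjmol(self.e_q),
            "e_1_kjmol": constants.hartree_to_kjmol(self.e_1),
            "method": self.method,
            "basis": self.basis,
        }


class QMResult(ABC):
    """Result handle of one backend calculation."""

    e_tot: float  # a.u., excluding point-charge self-energy

    @abstractmethod
    def esp(self, points: np.ndarray) -> np.ndarray:
        """Solute electrostatic potential (a.u.) at points given in Å.

        The potential of the solute only - the external point charges'
        own field is not included."""


class QMBackend(ABC):
    """Contract for quantum engines used in the embedding loop.

    Implementations must: (1) return gas-phase results when the charge list
    is empty; (2) exclude the point-charge self-energy from e_tot; (3) expose
    a solute-only ESP for charge fitting and E_q evaluation.
    """

    method: str = "mock"
    basis: str = "none"
    #: Whether e_tot includes the nuclei/point-charge interaction (it must,
    #: together with the electron/point-charge term, for the ledger split).
    includes_nuclear_point_charge: bool = True

    @abstractmethod
    def run(self, solute: SoluteModel, point_charges: ChargeMap | None = None) -> QMResult:
        ...


class BackendError(RuntimeError):
    """Backend failure, annotated with embedding-cycle context."""


@dataclass
class _MockResult(QMResult):
    e_tot: float
    core_charges: np.ndarray
    positions_bohr: np.ndarray
    induced_dipoles: np.ndarray  # (n, 3) a.u.

    def esp(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3) / constants.BOHR_ANGSTROM
        disp = pts[:, None, :] - self.positions_bohr[None, :, :]
        dist = np.linalg.norm(disp, axis=-1)
        phi = (self.core_charges[None, :] / dist).sum(axis=1)
        phi += ((disp * self.induced_dipoles[None, :, :]).sum(axis=-1) / dist**3).sum(axis=1)
        return phi


@dataclass
class MockPolarizableEngine(QMBackend):
    """Closed-form polarizable point-charge engine (test double).

    Each atom carries a fixed core charge and an independent isotropic
    polarizability (Å^3).  In an external charge field E_a the atom acquires
    mu_a = alpha_a E_a, and

        E_tot = E_core + sum_{a,i} q_a Q_i / r_ai - 1/2 sum_a alpha_a |E_a|^2

    with E_core the internal core-core Coulomb energy.  Zero polarizability
    reduces to pure fixed-charge electrostatics.
    """

    core_charges: np.ndarray = field(default_factory=lambda: np.zeros(1))
    polarizabilities: np.ndarray | float = 0.0  # Å^3, scalar or per atom
    method: str = "mock-polarizable"
    basis: str = "point-charge"
    includes_nuclear_point_charge: bool = True

    def run(self, solute: SoluteModel, point_charges: ChargeMap | None = None) -> _MockResult:
        q = np.asarray(self.core_charges, dtype=float)
        if q.shape != (solute.n_atoms,):
            raise BackendError(
                f"mock engine configured for {q.size} atoms, solute has {solute.n_atoms}"
            )
        alpha = np.broadcast_to(
            np.asarray(self.polarizabilities, dtype=float), (solute.n_atoms,)
        ) / constants.BOHR_ANGSTROM**3  # Å^3 -> a.u.
        pos = solute.positions / constants.BOHR_ANGSTROM
        # Internal core-core energy.
        e_core = 0.0
        for a in range(solute.n_atoms):
            for b in range(a + 1, solute.n_atoms):
                e_core += q[a] * q[b] / float(np.linalg.norm(pos[a] - pos[b]))
        e_int = 0.0
        efield = np.zeros((solute.n_atoms, 3))
        if point_charges is not None and point_charges.n_points:
            cpos = point_charges.points / constants.BOHR_ANGSTROM
            cq = point_charges.charges
            disp = pos[:, None, :] - cpos[None, :, :]  # (n, m, 3)
            dist = np.linalg.norm(disp, axis=-1)
            if np.any(dist < 1e-6):
                raise BackendError("background point charge coincides with an atom")
            e_int = float((q[:, None] * cq[None, :] / dist).sum())
            efield = (cq[None, :, None] * disp / dist[:, :, None] ** 3).sum(axis=1)
        e_resp = -0.5 * float((alpha * (efield**2).sum(axis=1)).sum())
        e_tot = e_core + e_int + e_resp
        return _MockResult(
            e_tot=e_tot,
            core_charges=q,
            positions_bohr=pos,
            induced_dipoles=alpha[:, None] * efield,
        )


def eq_energy(charge_map: ChargeMap, esp_at_points: np.ndarray) -> float:
    """E_q = sum_i q_i phi(r_i) in atomic units."""
    esp = np.asarray(esp_at_points, dtype=float)
    if esp.shape != (charge_map.n_points,):
        raise ValueError(
            f"ESP values ({esp.shape}) do not match the charge map "
            f"({charge_map.n_points} points)"
        )
    return float(np.dot(charge_map.charges, esp))


@dataclass(frozen=True)
class ChargeFitSpec:
    """How to derive atomic charges from a backend's ESP."""

    method: str = "CHELPG"  # CHELPG | MK | input
    radii: dict[str, float] | None = None
    shell_spacing: float = 0.3  # CHELPG lattice spacing, Å
    r_max: float = 2.8  # CHELPG outer shell, Å

    def sample_points(self, solute: SoluteModel) -> np.ndarray:
        m = self.method.upper()
        if m == "CHELPG":
            return chelpg_points(solute, self.radii, self.shell_spacing, self.r_max)
        if m == "MK":
            return mk_points(solute, self.radii)
        raise ValueError(f"unknown charge-fit method {self.method!r}")


def embedded_step(
    backend: QMBackend,
    solute: SoluteModel,
    charge_map: ChargeMap | None,
    fit_spec: ChargeFitSpec | None = None,
    *,
    cycle: int | None = None,
) -> tuple[QMEnergyLedger, AtomicCharges]:
    """One embedded QM calculation: energy ledger plus refreshed ESP charges."""
    fit_spec = fit_spec or ChargeFitSpec()
    try:
        result = backend.run(solute, charge_map)
    except BackendError:
        raise
    except Exception as exc:  # annotate foreign failures with cycle context
        where = f"cycle {cycle}" if cycle is not None else "embedded step"
        raise BackendError(f"backend {backend.method} failed in {where}: {exc}") from exc
    if charge_map is not None and charge_map.n_points:
        e_q = eq_energy(charge_map, result.esp(charge_map.points))
    else:
        e_q = 0.0
    ledger = QMEnergyLedger(
        e_tot=result.e_tot, e_q=e_q, method=backend.method, basis=backend.basis
    )
    pts = fit_spec.sample_points(solute)
    sample = ESPSample(points=pts, values=result.esp(pts))
    fitted = fit_esp_charges(
        sample, solute.positions, solute.total_charge, method=fit_spec.method
    )
    return ledger, fitted


def delta_e_qm(solv: QMEnergyLedger, gas: QMEnergyLedger) -> float:
    """Electronic solvation energy dE = E_1(solv) - E_1(gas) in kJ/mol."""
    if (solv.method, solv.basis) != (gas.method, gas.basis):
        raise ValueError(
            f"inconsistent ledgers: {solv.method}/{solv.basis} vs {gas.method}/{gas.basis}"
        )
    return constants.hartree_to_kjmol(solv.e_1 - gas.e_1)


def ecrism_total(delta_g_rism_corrected: float, delta_e: float) -> float:
    """Total solvation free energy: corrected RISM term plus dE^QM, kJ/mol."""
    return delta_g_rism_corrected + delta_e
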