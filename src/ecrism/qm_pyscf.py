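"""Reference quantum-backend adapter built on PySCF (optional dependency).

Satisfies the :class:`~ecrism.qm_coupling.QMBackend` contract with real
HF/MP2 calculations: the total energy of a solute embedded in background
point charges (PySCF's QM/MM coupling adds the electron- and nucleus-charge
terms but never the charge-charge self-energy, matching the ledger policy)
and the solute-only electrostatic potential evaluated from the converged
density.

PySCF is imported lazily; environments without it can still use every other
part of the package (including the mock engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .charges import ChargeMap
from .forcefield import SoluteModel
from .qm_coupling import BackendError, QMBackend, QMResult

_ESP_BATCH = 4000


@dataclass
class _PyscfResult(QMResult):  # pragma: no cover - requires pyscf
    e_tot: float
    mol: object
    dm: np.ndarray

    def esp(self, points: np.ndarray) -> np.ndarray:
        from pyscf import df, gto

        pts = np.asarray(points, dtype=float).reshape(-1, 3) / constants.BOHR_ANGSTROM
        out = np.empty(pts.shape[0])
        charges = self.mol.atom_charges()
        coords = self.mol.atom_coords()
        for start in range(0, pts.shape[0], _ESP_BATCH):
            chunk = pts[start:start + _ESP_BATCH]
            d = np.linalg.norm(chunk[:, None, :] - coords[None, :, :], axis=-1)
            v_nuc = (charges[None, :] / d).sum(axis=1)
            fakemol = gto.fakemol_for_charges(chunk)
            ints = df.incore.aux_e2(self.mol, fakemol)
            v_elec = np.einsum("ijp,ij->p", ints, self.dm)
            out[start:start + chunk.shape[0]] = v_nuc - v_elec
        return out


@dataclass
class PyscfBackend(QMBackend):  # pragma: no cover - requires pyscf
    """HF or MP2 through PySCF.  For MP2 the (unrelaxed) MP2 one-particle
    density is used for the ESP, so charge fitting and E_q see the same
    electrostatics as the energy."""

    method: str = "HF"
    basis: str = "def2-TZVPPD"
    multiplicity: int = 1
    includes_nuclear_point_charge: bool = True

    def run(self, solute: SoluteModel, point_charges: ChargeMap | None = None) -> _PyscfResult:
        try:
            from pyscf import gto, mp, qmmm, scf
        except ImportError as exc:
            raise BackendError(
                "the pyscf backend requires the optional 'pyscf' package"
            ) from exc
        atom = [
            (el, tuple(pos)) for el, pos in zip(solute.elements, solute.positions)
        ]
        mol = gto.M(
            atom=atom,
            basis=self.basis,
            charge=int(round(solute.total_charge)),
            spin=self.multiplicity - 1,
            unit="Angstrom",
            verbose=0,
        )
        mf = scf.RHF(mol) if self.multiplicity == 1 else scf.ROHF(mol)
        if point_charges is not None and point_charges.n_points:
            mf = qmmm.mm_charge(mf, point_charges.points, point_charges.charges)
        mf.kernel()
        if not mf.converged:
            raise BackendError("SCF did not converge")
        method = self.method.upper()
        if method == "HF":
            return _PyscfResult(e_tot=float(mf.e_tot), mol=mol, dm=mf.make_rdm1())
        if method == "MP2":
            pt = mp.MP2(mf).run()
            dm = pt.make_rdm1(ao_repr=True)
            return _PyscfResult(e_tot=float(pt.e_tot), mol=mol, dm=dm)
        raise BackendError(f"unsupported method {self.method!r} (use HF or MP2)")
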