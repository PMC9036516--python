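"""Physical constants and unit conversions.

This is the single source of truth for every conversion in the package.
Internal unit system: lengths in Å, energies in kJ/mol, charges in units of
the elementary charge, temperatures in K.  The quantum-backend boundary works
in Hartree atomic units; conversions cross it only through the factors below.

Values are CODATA 2018.
"""

from __future__ import annotations

import math

#: Boltzmann constant (= molar gas constant R) in kJ/(mol K).
K_B = 8.314462618e-3

#: Coulomb constant e^2/(4 pi eps0) in kJ Å / (mol e^2):
#: the energy of two elementary charges 1 Å apart.
COULOMB = 1389.3545764438198

#: Hartree in kJ/mol.
HARTREE_KJMOL = 2625.4996394799

#: Bohr radius in Å.
BOHR_ANGSTROM = 0.529177210903

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0.0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (K_B * temperature)


def density_molar_to_number(density_molar: float) -> float:
    """Convert a molar density in mol/dm^3 to a number density in Å^-3."""
    # 1 dm^3 = 1e27 Å^3
    return density_molar * AVOGADRO / 1e27


def hartree_to_kjmol(energy_au: float) -> float:
    return energy_au * HARTREE_KJMOL


def kjmol_to_hartree(energy_kjmol: float) -> float:
    return energy_kjmol / HARTREE_KJMOL


def angstrom_to_bohr(length: float) -> float:
    return length / BOHR_ANGSTROM


def bohr_to_angstrom(length: float) -> float:
    return length * BOHR_ANGSTROM


def deg_to_rad(angle_deg: float) -> float:
    return angle_deg * math.pi / 180.0
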