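"""Readers and writers: solute formats, OpenDX volumes, charge maps,
JSON result bundles, and the HDF5 susceptibility container.

All writers are deterministic: stable ordering and fixed float formatting
(17 significant digits, which round-trips IEEE doubles exactly).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import h5py
import numpy as np

from .forcefield import Site, SoluteModel, ThermoState
from .charges import ChargeMap
from .rism1d import SolventSusceptibility
from .rism3d import Grid3D

logger = logging.getLogger("ecrism")

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "Pt", "Au", "Hg", "Pb", "Bi",
}


class FormatError(ValueError):
    """Malformed input file."""


def _check_element(symbol: str, path, line_no: int) -> str:
    sym = symbol.capitalize()
    if sym not in _ELEMENTS:
        raise FormatError(f"{path}:{line_no}: unknown element {symbol!r}")
    return sym


def read_site_table(path) -> SoluteModel:
    """Whitespace table: element x y z q sigma epsilon, '#' comments."""
    elements, positions, sites = [], [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            body = raw.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 7:
                raise FormatError(
                    f"{path}:{ln}: expected 7 fields "
                    f"(element x y z q sigma epsilon), got {len(parts)}"
                )
            el = _check_element(parts[0], path, ln)
            try:
                x, y, z, q, sigma, epsilon = (float(v) for v in parts[1:])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from None
            elements.append(el)
            positions.append((x, y, z))
            sites.append(Site(el, q, sigma, epsilon))
    if not elements:
        raise FormatError(f"{path}: no atoms found")
    return SoluteModel(tuple(elements), np.array(positions), tuple(sites))


def write_site_table(solute: SoluteModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("# element x y z q sigma epsilon\n")
        for el, pos, site in zip(solute.elements, solute.positions, solute.sites):
            fh.write(
                f"{el} {pos[0]:.17g} {pos[1]:.17g} {pos[2]:.17g} "
                f"{site.charge:.17g} {site.sigma:.17g} {site.epsilon:.17g}\n"
            )


def read_xyz(path) -> tuple[tuple[str, ...], np.ndarray]:
    """Plain XYZ: atom count, comment, then 'element x y z' lines (Å)."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}:1: expected the atom count") from None
    if len(lines) < n + 2:
        raise FormatError(f"{path}: expected {n} atom lines, file is shorter")
    elements, positions = [], []
    for ln in range(2, 2 + n):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln + 1}: expected 'element x y z'")
        elements.append(_check_element(parts[0], path, ln + 1))
        try:
            positions.append(tuple(float(v) for v in parts[1:4]))
        except ValueError as exc:
            raise FormatError(f"{path}:{ln + 1}: {exc}") from None
    return tuple(elements), np.array(positions)


def write_xyz(elements, positions, path, comment: str = "") -> None:
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, pos in zip(elements, positions):
            fh.write(f"{el} {pos[0]:.17g} {pos[1]:.17g} {pos[2]:.17g}\n")


def read_pdb(path) -> tuple[tuple[str, ...], np.ndarray]:
    """Coordinates/elements from a PDB subset (ATOM/HETATM records only).

    Only the first alternate location of each atom is kept (a warning is
    logged when others are discarded)."""
    elements, positions = [], []
    seen_altloc: set[tuple] = set()
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            altloc = line[16:17].strip()
            key = (line[12:16].strip(), line[21:22], line[22:26].strip())
            if altloc and key in seen_altloc:
                dropped += 1
                continue
            if altloc:
                seen_altloc.add(key)
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                raise FormatError(f"{path}:{ln}: malformed coordinates") from None
            symbol = line[76:78].strip() or line[12:16].strip()[:1]
            elements.append(_check_element(symbol, path, ln))
            positions.append((x, y, z))
    if dropped:
        logger.warning("%s: kept first altloc only, dropped %d records", path, dropped)
    if not elements:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return tuple(elements), np.array(positions)


def read_solute(path, fmt: str | None = None) -> SoluteModel:
    """Read a solute; ``fmt`` in {'site_table', 'xyz', 'pdb'} (guessed from
    the suffix when omitted).  XYZ/PDB carry no site parameters - charges and
    LJ parameters are zeroed and must be attached before solvation."""
    if fmt is None:
        name = str(path).lower()
        if name.endswith(".xyz"):
            fmt = "xyz"
        elif name.endswith(".pdb"):
            fmt = "pdb"
        else:
            fmt = "site_table"
    if fmt == "site_table":
        return read_site_table(path)
    if fmt == "xyz":
        elements, positions = read_xyz(path)
    elif fmt == "pdb":
        elements, positions = read_pdb(path)
    else:
        raise ValueError(f"unknown solute format {fmt!r}")
    sites = tuple(Site(el, 0.0, 0.0, 0.0) for el in elements)
    return SoluteModel(elements, positions, sites)


# --- OpenDX volumetric format -------------------------------------------------

def write_dx(fieldarr: np.ndarray, grid: Grid3D, path, comment: str = "") -> None:
    """OpenDX regular-grid scalar field (same dialect as common RISM tools)."""
    data = np.asarray(fieldarr, dtype=float)
    if tuple(data.shape) != tuple(grid.dims):
        raise ValueError(f"field shape {data.shape} does not match grid {grid.dims}")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    dx, dy, dz = grid.spacing
    flat = data.ravel(order="C")
    with open(path, "w") as fh:
        if comment:
            for cl in comment.splitlines():
                fh.write(f"# {cl}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.17g} {oy:.17g} {oz:.17g}\n")
        fh.write(f"delta {dx:.17g} 0 0\n")
        fh.write(f"delta 0 {dy:.17g} 0\n")
        fh.write(f"delta 0 0 {dz:.17g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.17g}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path) -> tuple[np.ndarray, Grid3D]:
    dims = origin = None
    deltas: list[float] = []
    values: list[float] = []
    n_expected = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("attribute") or s.startswith(
                "component"
            ) or s.startswith('object "'):
                continue
            if s.startswith("object 1"):
                dims = tuple(int(v) for v in s.split()[-3:])
            elif s.startswith("origin"):
                origin = tuple(float(v) for v in s.split()[1:4])
            elif s.startswith("delta"):
                deltas.append(max(float(v) for v in s.split()[1:4]))
            elif s.startswith("object 3"):
                n_expected = int(s.split()[-3])
            elif n_expected is not None and len(values) < n_expected:
                values.extend(float(v) for v in s.split())
    if dims is None or origin is None or len(deltas) != 3 or n_expected is None:
        raise FormatError(f"{path}: incomplete DX header")
    if len(values) != n_expected:
        raise FormatError(f"{path}: expected {n_expected} values, got {len(values)}")
    grid = Grid3D(origin=origin, spacing=tuple(deltas), dims=dims)
    return np.array(values).reshape(dims, order="C"), grid


# --- charge maps --------------------------------------------------------------

def write_map(charge_map: ChargeMap, path) -> None:
    """4-column text map: x y z q (Å, elementary charge)."""
    with open(path, "w") as fh:
        fh.write(f"# x y z q  (threshold {charge_map.threshold:.17g} a.u., "
                 f"dropped fraction {charge_map.dropped_fraction:.17g})\n")
        for (x, y, z), q in zip(charge_map.points, charge_map.charges):
            fh.write(f"{x:.17g} {y:.17g} {z:.17g} {q:.17g}\n")


def read_map(path) -> ChargeMap:
    pts, qs = [], []
    threshold = 0.0
    dropped = 0.0
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            s = raw.strip()
            if s.startswith("#"):
                if "threshold" in s:
                    parts = (
                        s.replace("(", " ").replace(")", " ").replace(",", " ").split()
                    )
                    threshold = float(parts[parts.index("threshold") + 1])
                    dropped = float(parts[parts.index("fraction") + 1])
                continue
            if not s:
                continue
            parts = s.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 'x y z q'")
            pts.append(tuple(float(v) for v in parts[:3]))
            qs.append(float(parts[3]))
    return ChargeMap(
        points=np.array(pts).reshape(-1, 3),
        charges=np.array(qs),
        threshold=threshold,
        dropped_fraction=dropped,
    )


# --- result bundles -----------------------------------------------------------

@dataclass
class ResultBundle:
    """Everything one run produced, JSON-serializable at full precision."""

    config: dict
    report: dict
    cycles: list[dict] = field(default_factory=list)
    charge_map_summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def with_timestamp(self) -> "ResultBundle":
        self.provenance.setdefault(
            "timestamp", datetime.now(timezone.utc).isoformat()
        )
        from . import __version__

        self.provenance.setdefault("ecrism_version", __version__)
        return self


def write_report(bundle: ResultBundle, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(bundle), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> ResultBundle:
    with open(path) as fh:
        payload = json.load(fh)
    return ResultBundle(**payload)


# --- susceptibility container -------------------------------------------------

def save_susceptibility(sus: SolventSusceptibility, path) -> None:
    """Self-describing HDF5 container for the 1D-RISM output."""
    with h5py.File(path, "w") as f:
        f.attrs["model_name"] = sus.model_name
        f.attrs["closure"] = sus.closure_label
        f.attrs["temperature"] = sus.thermo.temperature
        f.attrs["kappa_t"] = sus.kappa_t
        f.attrs["pressure"] = sus.pressure
        f.attrs["rho_kt"] = sus.rho_kt
        f.attrs["site_labels"] = list(sus.site_labels)
        f.create_dataset("k_grid", data=sus.k_grid)
        f.create_dataset("chi_hat", data=sus.chi_hat)
        f.create_dataset("omega_hat", data=sus.omega_hat)
        f.create_dataset("rho_h_hat", data=sus.rho_h_hat)
        f.create_dataset("site_densities", data=sus.site_densities)
        f.create_dataset("site_charges", data=sus.site_charges)
        f.create_dataset("site_sigmas", data=sus.site_sigmas)
        f.create_dataset("site_epsilons", data=sus.site_epsilons)
        f.create_dataset("distances", data=sus.distances)


def load_susceptibility(path) -> SolventSusceptibility:
    with h5py.File(path, "r") as f:
        return SolventSusceptibility(
            model_name=str(f.attrs["model_name"]),
            closure_label=str(f.attrs["closure"]),
            thermo=ThermoState(float(f.attrs["temperature"])),
            k_grid=f["k_grid"][...],
            chi_hat=f["chi_hat"][...],
            omega_hat=f["omega_hat"][...],
            rho_h_hat=f["rho_h_hat"][...],
            site_labels=tuple(str(s) for s in f.attrs["site_labels"]),
            site_densities=f["site_densities"][...],
            site_charges=f["site_charges"][...],
            site_sigmas=f["site_sigmas"][...],
            site_epsilons=f["site_epsilons"][...],
            distances=f["distances"][...],
            kappa_t=float(f.attrs["kappa_t"]),
            pressure=float(f.attrs["pressure"]),
            rho_kt=float(f.attrs["rho_kt"]),
        )


def export_susceptibility_text(sus: SolventSusceptibility, path) -> None:
    """Plain-text inspection dump: header plus k and chi columns."""
    labels = sus.site_labels
    with open(path, "w") as fh:
        fh.write(f"# solvent susceptibility: {sus.model_name} ({sus.closure_label}), "
                 f"T = {sus.thermo.temperature:.17g} K\n")
        fh.write(f"# kappa_T = {sus.kappa_t:.17g} A^3 mol/kJ, "
                 f"P_RISM = {sus.pressure:.17g} kJ/mol/A^3\n")
        cols = " ".join(
            f"chi[{labels[i]}{labels[j]}]"
            for i in range(len(labels)) for j in range(i, len(labels))
        )
        fh.write(f"# k {cols}\n")
        for ik, k in enumerate(sus.k_grid):
            row = [f"{k:.17g}"]
            for i in range(len(labels)):
                for j in range(i, len(labels)):
                    row.append(f"{sus.chi_hat[i, j, ik]:.17g}")
            fh.write(" ".join(row) + "\n")
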