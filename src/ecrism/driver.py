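"""The self-consistent EC-RISM loop and conformer averaging.

One cycle: fit solute charges from the current QM density -> solve 3D-RISM
with those charges -> turn the solvent distribution into background point
charges -> run the embedded QM calculation.  The loop starts from a gas-phase
QM calculation and stops when the changes of BOTH tracked energies (the
electronic term dE^QM and the corrected RISM solvation free energy) drop
below the convergence criterion.  The final answer is

    dG = dG_RISM(corrected) + dE^QM
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charges import AtomicCharges, drop_small, solvent_charge_map
from .closures import ClosureSpec
from .forcefield import SoluteModel, ThermoState, get_water_model
from .free_energy import FreeEnergyReport, PressureTerms, UCParams, build_report
from .qm_coupling import ChargeFitSpec, QMBackend, QMEnergyLedger, delta_e_qm, ecrism_total, embedded_step
from .rism1d import RadialGrid, SolventSusceptibility, solve_drism, susceptibility
from .rism3d import build_grid, solute_site_potentials, solve_3drism

_CORRECTIONS = ("PC+", "PC", "UC", "none")


@dataclass(frozen=True)
class ECRISMConfig:
    """Settings of the full loop; the defaults are the recommended setup
    (PSE-3 closure, cTIP3P water, PC+ correction, 15 Å buffer, 0.3 Å grid,
    CHELPG charges, 1e-6 a.u. charge threshold, 0.01 kJ/mol criterion)."""

    buffer: float = 15.0
    spacing: float = 0.3
    closure: str = "PSE-3"
    water_model: str = "cTIP3P"
    solvent_closure: str | None = None  # 1D closure; defaults to ``closure``
    correction: str = "PC+"
    charge_method: str = "CHELPG"
    threshold: float = 1e-6
    convergence: float = 0.01  # kJ/mol, applied to both QM and RISM changes
    max_cycles: int = 20
    temperature: float = 298.15
    rism_tol: float = 1e-6
    bulk_subtract: bool = False
    charge_mixing: float = 0.0  # linear mixing with previous cycle's charges
    uc_params: UCParams | None = None

    def __post_init__(self) -> None:
        if self.correction not in _CORRECTIONS:
            raise ValueError(
                f"unknown correction {self.correction!r}; choose from {_CORRECTIONS}"
            )
        if self.correction == "UC" and self.uc_params is None:
            raise ValueError(
                "correction='UC' requires explicit UCParams; there are no "
                "built-in universal-correction coefficients"
            )
        ClosureSpec.parse(self.closure)  # validate eagerly

    @property
    def closure_spec(self) -> ClosureSpec:
        return ClosureSpec.parse(self.closure)

    @property
    def solvent_closure_spec(self) -> ClosureSpec:
        return ClosureSpec.parse(self.solvent_closure or self.closure)

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(self.temperature)


@dataclass
class CycleRecord:
    """Energies and charge snapshot of one EC-RISM cycle (append-only)."""

    index: int
    report: FreeEnergyReport
    delta_g_corrected: float  # kJ/mol
    ledger: QMEnergyLedger
    delta_e_qm: float  # kJ/mol
    total: float  # kJ/mol
    charges: np.ndarray = field(repr=False)
    max_charge_change: float = float("nan")
    delta_g_change: float = float("nan")
    delta_e_change: float = float("nan")
    map_points: int = 0
    map_dropped_fraction: float = 0.0
    converged: bool = False


@dataclass
class ECRISMResult:
    config: ECRISMConfig
    gas_ledger: QMEnergyLedger
    cycles: list[CycleRecord]
    converged: bool

    @property
    def final(self) -> CycleRecord:
        return self.cycles[-1]

    @property
    def total(self) -> float:
        return self.final.total


_SUSCEPTIBILITY_CACHE: dict[tuple, SolventSusceptibility] = {}


def prepare_susceptibility(
    water_model: str,
    closure: ClosureSpec,
    thermo: ThermoState,
    grid: RadialGrid | None = None,
    *,
    cache: bool = True,
) -> SolventSusceptibility:
    """1D-RISM solve for the requested water model/closure, memoized."""
    grid = grid or RadialGrid()
    key = (water_model, closure.label, thermo.temperature, grid.n_points, grid.dr)
    if cache and key in _SUSCEPTIBILITY_CACHE:
        return _SUSCEPTIBILITY_CACHE[key]
    model = get_water_model(water_model)
    sol = solve_drism(model, thermo, grid, closure)
    sus = susceptibility(sol)
    if cache:
        _SUSCEPTIBILITY_CACHE[key] = sus
    return sus


def solvate_once(
    solute: SoluteModel,
    config: ECRISMConfig,
    sus: SolventSusceptibility | None = None,
):
    """Single classical 3D-RISM calculation on a charged solute.

    Returns (correlations, free-energy report).
    """
    thermo = config.thermo
    sus = sus or prepare_susceptibility(
        config.water_model, config.solvent_closure_spec, thermo
    )
    grid = build_grid(solute, buffer=config.buffer, spacing=config.spacing)
    solvent_sites = [sus.type_site(lab) for lab in sus.unique_types]
    pots = solute_site_potentials(solute, solvent_sites, grid)
    corr = solve_3drism(
        pots, sus, config.closure_spec, thermo=thermo, tol=config.rism_tol
    )
    rho_molecular = get_water_model(config.water_model).number_density
    report = build_report(
        corr,
        sus.kappa_t,
        PressureTerms(sus.pressure, sus.rho_kt),
        rho_molecular,
        uc_params=config.uc_params,
        provenance={
            "water_model": config.water_model,
            "closure": config.closure_spec.label,
            "solvent_closure": config.solvent_closure_spec.label,
            "buffer": config.buffer,
            "spacing": config.spacing,
            "grid_dims": list(corr.grid.dims),
        },
    )
    return corr, report


def _corrected_value(report: FreeEnergyReport, config: ECRISMConfig) -> float:
    if config.correction == "none":
        return report.delta_g[report.closure if report.closure in report.delta_g else "KH"]
    return report.corrected[config.correction]


def run_ecrism(
    solute: SoluteModel,
    backend: QMBackend,
    config: ECRISMConfig | None = None,
    sus: SolventSusceptibility | None = None,
) -> ECRISMResult:
    """Run the full self-consistent loop.

    The solute's LJ parameters are taken from its site table; its charges are
    refreshed every cycle from the backend's ESP.  Histories are appended per
    cycle; if ``max_cycles`` is exhausted the result is returned with
    ``converged=False`` rather than raising.
    """
    config = config or ECRISMConfig()
    thermo = config.thermo
    sus = sus or prepare_susceptibility(
        config.water_model, config.solvent_closure_spec, thermo
    )
    fit_spec = ChargeFitSpec(method=config.charge_method)

    # Gas-phase initialization: energies and the first charge set.
    gas_ledger, fitted = embedded_step(backend, solute, None, fit_spec, cycle=0)
    charges = fitted.values

    cycles: list[CycleRecord] = []
    converged = False
    prev_dg: float | None = None
    prev_de: float | None = None
    for cycle in range(1, config.max_cycles + 1):
        current = solute.with_charges(charges)
        corr, report = solvate_once(current, config, sus)
        dg_corr = _corrected_value(report, config)

        cmap = solvent_charge_map(corr, bulk_subtract=config.bulk_subtract)
        cmap = drop_small(cmap, config.threshold)

        ledger, fitted = embedded_step(backend, solute, cmap, fit_spec, cycle=cycle)
        de = delta_e_qm(ledger, gas_ledger)
        total = ecrism_total(dg_corr, de)

        new_charges = fitted.values
        if config.charge_mixing > 0.0:
            new_charges = (
                (1.0 - config.charge_mixing) * new_charges + config.charge_mixing * charges
            )
        record = CycleRecord(
            index=cycle,
            report=report,
            delta_g_corrected=dg_corr,
            ledger=ledger,
            delta_e_qm=de,
            total=total,
            charges=charges.copy(),
            max_charge_change=float(np.max(np.abs(new_charges - charges))),
            delta_g_change=abs(dg_corr - prev_dg) if prev_dg is not None else float("nan"),
            delta_e_change=abs(de - prev_de) if prev_de is not None else float("nan"),
            map_points=cmap.n_points,
            map_dropped_fraction=cmap.dropped_fraction,
        )
        cycles.append(record)
        if (
            prev_dg is not None
            and record.delta_g_change < config.convergence
            and record.delta_e_change < config.convergence
        ):
            record.converged = True
            converged = True
            break
        prev_dg, prev_de = dg_corr, de
        charges = new_charges
    return ECRISMResult(config=config, gas_ledger=gas_ledger, cycles=cycles, converged=converged)


def boltzmann_average(
    per_conformer: list[tuple[float, float]],
    thermo: ThermoState | None = None,
    window: float = 10.0,
) -> float:
    """Boltzmann-weighted mean of per-conformer solvation free energies.

    ``per_conformer`` holds (reference energy, dG) pairs in kJ/mol; conformers
    more than ``window`` kJ/mol above the most stable one are excluded, the
    rest weighted by exp(-beta (E - E_min)).  The minimum is always retained,
    so the windowed set cannot be empty.
    """
    if not per_conformer:
        raise ValueError("need at least one conformer")
    thermo = thermo or ThermoState()
    energies = np.array([e for e, _ in per_conformer], dtype=float)
    dgs = np.array([g for _, g in per_conformer], dtype=float)
    rel = energies - energies.min()
    keep = rel <= window
    weights = np.exp(-thermo.beta * rel[keep])
    return float(np.dot(weights, dgs[keep]) / weights.sum())
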