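# ecrism

Self-consistent embedded-cluster RISM solvation free energies with atomic
charges: bulk-water 1D-RISM, a 3D-RISM solute solver, free-energy functionals
with pressure/universal corrections, ESP-fitted charges, solvent point-charge
extraction, and the QM↔RISM coupling loop.

## What it does

1. **Bulk solvent (1D-RISM)** — dielectrically consistent site-site RISM for
   rigid three-site water (built-in coincident models cSPC/E, cTIP3P, cOPC3,
   cPOL3 plus mSPC/E), producing the solvent susceptibility χ(k), the
   isothermal compressibility and the RISM pressure (`ecrism.rism1d`).
2. **Solute solvation (3D-RISM)** — KH / PLHNC / PSE-n / HNC closures, MDIIS
   acceleration, erf-split electrostatics with a periodic Ewald-style
   long-range part, buffered FFT grids (`ecrism.rism3d`).
3. **Free energies** — HNC/KH/PSE-n/GF functionals, Kirkwood–Buff partial
   molar volume, and the UC / PC / PC+ corrections (`ecrism.free_energy`).
4. **Charges** — CHELPG / Merz-Kollman ESP fitting with a total-charge
   constraint, and the solvent background-charge map with small-charge
   thresholding (`ecrism.charges`).
5. **Embedding loop** — gas-phase initialization, then charges → 3D-RISM →
   charge map → embedded QM until both the QM and RISM energy changes drop
   below 0.01 kJ/mol (`ecrism.driver`). Quantum engines plug in through a
   small backend contract (`ecrism.qm_coupling`); a closed-form polarizable
   mock engine ships for testing, and `ecrism.qm_pyscf` adapts PySCF when it
   is installed.

## CLI

```bash
# bulk water -> susceptibility container
ecrism solvent --model cSPC/E --closure PSE-3 --out water.h5

# classical 3D-RISM on a solute site table (element x y z q sigma epsilon)
ecrism solvate mol.site --susceptibility water.h5 --buffer 15 --spacing 0.3 \
    --closure PSE-3 --correction PC+ --out report.json

# full self-consistent loop with the mock backend
ecrism ecrism mol.site --susceptibility water.h5 --backend mock \
    --polarizability 0.3 --out run.json

# universal-correction fit and conformer averaging
ecrism fit-uc data.csv --out uc.json
ecrism average conformers.csv --window 10
```

Every flag can also be given via `--config settings.toml` (one table per
subcommand). Exit codes: 2 usage/config error, 3 convergence failure,
4 I/O error.

## Layout

```
src/ecrism/
  constants.py    single source of units/conversions
  forcefield.py   water models, sites, LJ mixing, pair potential
  closures.py     KH / PLHNC / PSE-n / HNC
  solver.py       MDIIS fixed-point acceleration
  rism1d.py       bulk DRISM, susceptibility, pressure, compressibility
  rism3d.py       grids, potentials, 3D solver
  free_energy.py  functionals, PMV, UC/PC/PC+
  charges.py      ESP fitting, solvent charge map, thresholding
  qm_coupling.py  backend contract, energy ledger, mock engine
  qm_pyscf.py     optional PySCF adapter
  driver.py       EC-RISM loop, conformer averaging
  fixtures.py     deterministic toy systems + brute-force oracles
  io.py, cli.py   formats (site table/XYZ/PDB/OpenDX/HDF5/JSON) and CLI
```
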