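# mimosa

Agent-based multiscale metabolic simulation of a filamentous marine
cyanobacterial community with two metabolic cell types (photoautotrophs and
diazotrophs).  Each cell agent solves a scalarized two-objective flux-balance
problem every time step — biomass versus its transacted storage metabolite
(maltose for photoautotrophs, β-aspartyl-arginine for diazotrophs) — with the
objective weights shifted per step from the cell's mass through a normal CDF.
Cells live on a diffusive 2-D ocean grid with Henry's-law gas exchange and
depth-attenuated light, organized into filaments that differentiate, split,
and random-walk.

## Layout

| module | contents |
| --- | --- |
| `mimosa.metabolic_core` | stoichiometric networks, scalarized FBA (single combined objective reaction with an `a : (1-a)` flux-ratio constraint), Pareto-front sweep, objective decomposition, light-dependent linear ATP maintenance model |
| `mimosa.objective_dynamics` | cell-mass distribution, CDF-based objective re-weighting, Pareto-point matching |
| `mimosa.environment` | discrete Gaussian-kernel diffusion (two sequential sweeps, exact mass conservation), atmospheric surface exchange, Beer–Lambert light, equal-share uptake partitioning |
| `mimosa.agents` | cell and filament agents: uptake bounds (incl. the 8 % β-aspartyl-arginine cap), per-step metabolic decisions with catabolism-before-death, division/stationary transitions, filament splitting and movement, intrafilament pool exchange |
| `mimosa.simulation` | configuration, seeding, the fixed-stage scheduler, deterministic CSV/JSON logging |
| `mimosa.fixtures_io` | packaged C/N-balanced toy networks (≤ 12 reactions each), JSON/SBML network I/O, and the brute-force vertex-enumeration LP oracle used to cross-check every solver path |
| `mimosa.parameters` | packaged parameter table (`data/parameters.yaml`) with per-entry `source: paper|default` provenance tags |

## CLI

```bash
# run a simulation (YAML/JSON config; writes cells.csv, grid.csv, manifest.json)
mimosa run --config config.yaml --seed 1 --steps 120 --out out/

# sweep a Pareto front (default 1000 scalarization values) to CSV
mimosa pareto --cell-type photoautotroph --steps 1000 --out front.csv

# validate a configuration without running
mimosa validate-config config.yaml
```

Example config:

```yaml
dt_h: 0.1
n_steps: 120
grid: {width: 25, height: 25, delta_um: 100.0}
light: {I0_uE: 100.0, k: 0.04}
seeding: {n_cells: 150, n_filaments: 10, diazotroph_fraction: 0.3}
seed: 1
```

## Reproducibility notes

- All randomness flows from one seed through named substreams (seeding,
  scheduling, movement, division); identical config + seed gives
  byte-identical logs.
- LP degeneracy is resolved by a documented secondary objective (minimize
  Σ|v| at the fixed optimum) so per-cell flux maps are reproducible.
- The vertex-enumeration oracle in `fixtures_io` independently reproduces
  every scalarized optimum on the toy networks to 1e-8.
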