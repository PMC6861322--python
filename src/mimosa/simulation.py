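"""Scheduler and driver binding environment, agents and the metabolic core.

A step runs a fixed stage order: (1) atmospheric surface exchange, (2) kernel
diffusion for every tracked species, (3) per-filament decisions (next cell
type, splitting, random-walk movement), (4) per-cell metabolic steps in a
seeded random order (including stationary/division transitions and
intrafilament pool exchange), (5) logging.  Identical config and seed yield
byte-identical logs.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import parameters
from .agents import (
    DIAZOTROPH,
    PHOTOAUTOTROPH,
    CellAgent,
    FilamentAgent,
    LocalAvailability,
    TransferRules,
    cell_elements,
    cell_step,
    decide_next_cell_type,
    intrafilament_exchange,
    maybe_divide,
    maybe_go_stationary,
    maybe_split,
    random_walk,
)
from .environment import (
    OceanGrid,
    SurfaceBoundary,
    diffusion_step,
    light_at_depth,
    surface_exchange,
)
from .fixtures_io import toy_network
from .metabolic_core import (
    MaintenanceModel,
    MetabolicNetwork,
    maintenance_flux,
    solve_fba,
)
from .objective_dynamics import MassDistribution, ObjectiveWeights
from .units import amount_to_conc_uM, conc_to_amount_mmol

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "RunLog", "World", "seed_population", "step", "run"]

TRACKED_SPECIES = ["co2", "o2", "n2", "nh4", "maltose", "baa"]

CELL_LOG_COLUMNS = [
    "step", "cell_id", "filament_id", "type", "state", "biomass_g",
    "maltose_mmol", "cyanophycin_mmol", "w_b", "w_m", "z", "nu_obj",
    "died", "divided",
]


@dataclass
class SimulationConfig:
    """Run configuration; unset environment tables fall back to packaged defaults."""

    dt_h: float = 0.1
    n_steps: int = 120
    # environment
    grid_width: int = 25
    grid_height: int = 25
    delta_um: float = 100.0
    light_I0: float = 100.0
    light_k: float = 0.04
    medium_uM: dict[str, float] | None = None
    diffusivities: dict[str, float] | None = None
    henry_constants: dict[str, float] | None = None
    partial_pressures: dict[str, float] | None = None
    dt_diffusion_h: float | None = None  # sub-cycled diffusion step, <= dt_h
    # seeding
    n_cells: int = 150
    n_filaments: int = 10
    diazotroph_fraction: float = 0.3
    cells_per_gridcell: int = 10
    initial_pool_mmol: float = 2e-11
    # agent rules
    refit_maintenance: bool = False
    tie_break: bool = True
    movement_interval: int = 5
    baa_pool_reference_mmol: float = 2e-11
    n_limit_fraction: float = 0.2
    cn_max: float = 8.0
    cn_recovered: float = 6.0
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None
    grid_log_steps: int = 0  # 0: initial+final snapshots only
    flux_map_cells: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if not 0.0 <= self.diazotroph_fraction < 1.0:
            raise ValueError("diazotroph fraction must lie in [0, 1)")
        if self.n_filaments < 1 or self.n_cells < self.n_filaments:
            raise ValueError("need at least one cell per filament")
        if self.dt_diffusion_h is not None and not (
            0 < self.dt_diffusion_h <= self.dt_h
        ):
            raise ValueError("dt_diffusion_h must lie in (0, dt_h]")

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "SimulationConfig":
        """Build from a (possibly nested) YAML/JSON mapping.

        Accepts both flat field names and the nested sections
        ``grid: {width, height, delta_um}``, ``light: {I0_uE, k}`` and
        ``seeding: {n_cells, n_filaments, diazotroph_fraction}``.
        """
        doc = dict(doc)
        flat: dict[str, Any] = {}
        grid = doc.pop("grid", {})
        for src, dst in (("width", "grid_width"), ("height", "grid_height"),
                         ("delta_um", "delta_um")):
            if src in grid:
                flat[dst] = grid[src]
        light = doc.pop("light", {})
        for src, dst in (("I0_uE", "light_I0"), ("k", "light_k")):
            if src in light:
                flat[dst] = light[src]
        seeding = doc.pop("seeding", {})
        for key in ("n_cells", "n_filaments", "diazotroph_fraction"):
            if key in seeding:
                flat[key] = seeding[key]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        flat.update(doc)
        if "flux_map_cells" in flat:
            flat["flux_map_cells"] = tuple(flat["flux_map_cells"])
        return cls(**flat)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["flux_map_cells"] = list(out["flux_map_cells"])
        return out


@dataclass
class RunLog:
    """Per-step population summaries plus a discrete event stream."""

    summaries: list[dict[str, Any]] = field(default_factory=list)
    events: list[dict[str, Any]] = field(default_factory=list)
    cell_rows: list[list[Any]] = field(default_factory=list)

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(self.summaries)

    def cell_frame(self):
        import pandas as pd

        return pd.DataFrame(self.cell_rows, columns=CELL_LOG_COLUMNS)


def _default_medium(henry: dict[str, float],
                    pressures: dict[str, float]) -> dict[str, float]:
    """Artificial-seawater baseline: gases at Henry equilibrium, no fixed N."""
    medium = {s: 0.0 for s in TRACKED_SPECIES}
    for gas in ("co2", "o2", "n2"):
        medium[gas] = henry[gas] * pressures[gas]
    return medium


@dataclass
class World:
    config: SimulationConfig
    grid: OceanGrid
    boundary: SurfaceBoundary
    filaments: list[FilamentAgent]
    networks: dict[str, MetabolicNetwork]
    maintenance: MaintenanceModel
    dist: MassDistribution
    rules: TransferRules
    base_weights: ObjectiveWeights
    experimental_optima: dict[str, dict[str, float]]
    rng_scheduling: np.random.Generator
    rng_movement: np.random.Generator
    rng_division: np.random.Generator
    step_index: int = 0
    next_cell_id: int = 0
    next_filament_id: int = 0
    log: RunLog = field(default_factory=RunLog)

    def cells(self) -> list[CellAgent]:
        return [c for f in self.filaments for c in f.cells]

    def filament_of(self, cell: CellAgent) -> FilamentAgent:
        for f in self.filaments:
            if f.id == cell.filament_id:
                return f
        raise KeyError(f"cell {cell.id} has unknown filament {cell.filament_id}")

    def elemental_totals(self) -> dict[str, float]:
        """C and N inventory (mmol) summed over cells and grid fields."""
        from .fixtures_io import ELEMENTS

        totals = {"C": 0.0, "N": 0.0}
        for c in self.cells():
            for el, v in cell_elements(c).items():
                totals[el] += v
        for species, arr in self.grid.fields.items():
            content = ELEMENTS.get(species, {})
            amount = conc_to_amount_mmol(float(arr.sum()), self.grid.delta_um)
            for el, coef in content.items():
                totals[el] += amount * coef
        return totals


def seed_population(
    config: SimulationConfig, rng: np.random.Generator
) -> list[FilamentAgent]:
    """Lay out filaments of near-equal length with contiguous interior diazocytes.

    Cell count remainders go to the first filaments; each filament's
    diazotroph count is ``round(fraction * length)`` placed as one contiguous
    centered run.  Initial biomass is the distribution mean for every cell.
    Placement is reproducible from the generator state.
    """
    n, nf = config.n_cells, config.n_filaments
    base, rem = divmod(n, nf)
    lengths = [base + (1 if i < rem else 0) for i in range(nf)]
    if min(lengths) < 1:
        raise ValueError("seeding produced an empty filament")
    mean_mass = parameters.get("cell", "mean_mass_g")
    filaments: list[FilamentAgent] = []
    occupied: set[tuple[int, int]] = set()
    cell_id = 0
    for fi, length in enumerate(lengths):
        span = -(-length // config.cells_per_gridcell)  # ceil
        if span > config.grid_width:
            raise ValueError(
                f"filament of {length} cells does not fit a grid of width "
                f"{config.grid_width}"
            )
        row = (1 + fi * 2) % config.grid_height
        x0 = None
        for _ in range(100):
            cand = int(rng.integers(0, config.grid_width - span + 1))
            cells_at = {(cand + k, row) for k in range(span)}
            if not (cells_at & occupied):
                x0 = cand
                break
        if x0 is None:  # deterministic fallback scan
            for cand in range(config.grid_width - span + 1):
                cells_at = {(cand + k, row) for k in range(span)}
                if not (cells_at & occupied):
                    x0 = cand
                    break
        if x0 is None:
            raise ValueError("could not place filaments without overlap")
        occupied |= {(x0 + k, row) for k in range(span)}
        n_dz = round(config.diazotroph_fraction * length)
        dz_start = (length - n_dz) // 2
        cells = []
        for k in range(length):
            ctype = DIAZOTROPH if dz_start <= k < dz_start + n_dz else PHOTOAUTOTROPH
            own = "maltose" if ctype == PHOTOAUTOTROPH else "baa"
            pools = {"maltose": 0.0, "baa": 0.0}
            pools[own] = config.initial_pool_mmol
            cells.append(
                CellAgent(
                    id=cell_id,
                    cell_type=ctype,
                    biomass_g=mean_mass,
                    pools=pools,
                    gx=x0 + k // config.cells_per_gridcell,
                    gy=row,
                    filament_id=fi,
                )
            )
            cell_id += 1
        filaments.append(
            FilamentAgent(id=fi, cells=cells,
                          movement_interval=config.movement_interval)
        )
    return filaments


def initialize(config: SimulationConfig) -> World:
    """Build a fully seeded world from a configuration."""
    henry = config.henry_constants or parameters.get("henry_uM_atm")
    pressures = config.partial_pressures or parameters.get("partial_pressures_atm")
    diffusivities = config.diffusivities or parameters.get("diffusivities_um2_s")
    medium = config.medium_uM
    if medium is None:
        medium = _default_medium(henry, pressures)
    grid = OceanGrid(
        width=config.grid_width,
        height=config.grid_height,
        delta_um=config.delta_um,
        dt_h=config.dt_h,
        diffusivities=dict(diffusivities),
    )
    for species in TRACKED_SPECIES:
        grid.add_field(species, medium.get(species, 0.0))
    boundary = SurfaceBoundary(
        partial_pressures_atm=dict(pressures), henry_uM_atm=dict(henry)
    )
    networks = {ct: toy_network(ct) for ct in (PHOTOAUTOTROPH, DIAZOTROPH)}
    maintenance = MaintenanceModel.from_table(refit=config.refit_maintenance)
    dist = MassDistribution()
    rules = TransferRules.from_table()

    ss = np.random.SeedSequence(config.seed)
    s_seed, s_sched, s_move, s_div = ss.spawn(4)
    filaments = seed_population(config, np.random.default_rng(s_seed))

    # per-type experimental optima for Pareto efficiency: the single-objective
    # optima of the replete toy network at surface light
    optima: dict[str, dict[str, float]] = {}
    for ct, net in networks.items():
        demand = maintenance_flux(config.light_I0, maintenance, ct)
        opt: dict[str, float] = {}
        for a, rxn in ((1.0, net.biomass_rxn), (0.0, net.metabolite_rxn)):
            sol = solve_fba(net, a, maintenance=demand, tie_break=False)
            val = sol[rxn] if sol.optimal else float("nan")
            opt[rxn] = val if np.isfinite(val) and val > 1e-9 else 1.0
        optima[ct] = opt

    return World(
        config=config,
        grid=grid,
        boundary=boundary,
        filaments=filaments,
        networks=networks,
        maintenance=maintenance,
        dist=dist,
        rules=rules,
        base_weights=ObjectiveWeights(0.5, 0.5),
        experimental_optima=optima,
        rng_scheduling=np.random.default_rng(s_sched),
        rng_movement=np.random.default_rng(s_move),
        rng_division=np.random.default_rng(s_div),
        next_cell_id=config.n_cells,
        next_filament_id=config.n_filaments,
    )


def _filament_nitrogen_limited(world: World, filament: FilamentAgent) -> bool:
    cells = filament.alive_cells()
    if not cells:
        return False
    mean_baa = float(np.mean([c.pools.get("baa", 0.0) for c in cells]))
    threshold = world.config.n_limit_fraction * world.config.baa_pool_reference_mmol
    return mean_baa < threshold


def _filament_cn_ratio(filament: FilamentAgent) -> float:
    tot = {"C": 0.0, "N": 0.0}
    for c in filament.alive_cells():
        for el, v in cell_elements(c).items():
            tot[el] += v
    return tot["C"] / tot["N"] if tot["N"] > 0 else float("inf")


def _blocked_by_other_filament(
    filament: FilamentAgent, occupied_other: set[tuple[int, int]]
) -> bool:
    """True when another filament sits on or next to either filament end."""
    if not filament.cells:
        return False
    for cell in (filament.cells[0], filament.cells[-1]):
        for dx, dy in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
            if (cell.gx + dx, cell.gy + dy) in occupied_other:
                return True
    return False


def _filament_stage(world: World) -> None:
    cfg = world.config
    new_filaments: list[FilamentAgent] = []
    for filament in world.filaments:
        if not filament.alive_cells():
            new_filaments.append(filament)
            continue
        cn = _filament_cn_ratio(filament)
        n_limited = _filament_nitrogen_limited(world, filament)
        # diazocyte development opens on diazotroph priority, closes when the
        # filament's C:N recovers
        if filament.diazocyte_developing and cn <= cfg.cn_recovered:
            filament.diazocyte_developing = False
            filament.developing_end = None
        if decide_next_cell_type(filament) == DIAZOTROPH:
            if not filament.diazocyte_developing:
                filament.diazocyte_developing = True
                filament.developing_end = -1
        split = maybe_split(
            filament,
            nitrogen_limited=n_limited,
            cn_ratio_high=cn > cfg.cn_max,
            next_id=world.next_filament_id,
        )
        if split is not None:
            world.next_filament_id += 1
            world.log.events.append(
                {"step": world.step_index, "event": "split",
                 "filament_id": filament.id,
                 "lengths": [len(split[0]), len(split[1])]}
            )
            new_filaments.extend(split)
        else:
            new_filaments.append(filament)
    world.filaments = new_filaments

    occupied = {c.position for f in world.filaments for c in f.cells}
    for filament in world.filaments:
        if not filament.alive_cells():
            continue
        own = {c.position for c in filament.cells}
        blocked = _blocked_by_other_filament(filament, occupied - own)
        if blocked or world.step_index % filament.movement_interval == 0:
            moved = random_walk(
                filament, occupied, world.grid.width, world.grid.height,
                world.rng_movement,
            )
            if moved:
                occupied = (occupied - own) | {c.position for c in filament.cells}
                own = {c.position for c in filament.cells}
                blocked = _blocked_by_other_filament(filament, occupied - own)
                world.log.events.append(
                    {"step": world.step_index, "event": "move",
                     "filament_id": filament.id}
                )
        # extension from the ends stays halted while another filament crowds them
        filament.growth_halted = blocked


def _local_environment(world: World, cell: CellAgent,
                       cohabitants: int) -> dict[str, LocalAvailability]:
    env = {}
    for species, arr in world.grid.fields.items():
        conc = float(arr[cell.gy, cell.gx])
        available = conc_to_amount_mmol(conc, world.grid.delta_um)
        env[species] = LocalAvailability(
            conc_uM=conc,
            available_mmol=available,
            allocation_mmol=available / max(cohabitants, 1),
        )
    return env


def _cell_stage(world: World) -> None:
    cfg = world.config
    cells = [c for c in world.cells() if c.alive]
    order = world.rng_scheduling.permutation(len(cells))
    divided_ids: set[int] = set()
    died_ids: set[int] = set()
    for idx in order:
        cell = cells[idx]
        if not cell.alive:
            continue
        filament = world.filament_of(cell)
        cohab = sum(
            1 for c in world.cells() if c.alive and c.position == cell.position
        )
        env = _local_environment(world, cell, cohab)
        light = light_at_depth(cfg.light_I0, cfg.light_k,
                               world.grid.depth_m(cell.gy))
        result = cell_step(
            cell,
            world.networks[cell.cell_type],
            env,
            base_weights=world.base_weights,
            dist=world.dist,
            maintenance_model=world.maintenance,
            light_I=light,
            rules=world.rules,
            dt_h=cfg.dt_h,
            experimental_optima=world.experimental_optima[cell.cell_type],
            tie_break=cfg.tie_break,
        )
        if result.died:
            died_ids.add(cell.id)
            world.log.events.append(
                {"step": world.step_index, "event": "death", "cell_id": cell.id}
            )
            continue
        for species, removed in result.exchanges_mmol.items():
            arr = world.grid.fields[species]
            new = arr[cell.gy, cell.gx] - amount_to_conc_uM(
                removed, world.grid.delta_um
            )
            arr[cell.gy, cell.gx] = max(0.0, new)

        maybe_go_stationary(cell, world.dist)

        alive = filament.alive_cells()
        at_end = alive and (cell is alive[0] or cell is alive[-1])
        if at_end and not filament.growth_halted:
            daughter = maybe_divide(
                cell, world.dist, world.rng_division, at_end=True,
                daughter_id=world.next_cell_id,
            )
            if daughter is not None:
                world.next_cell_id += 1
                wanted = decide_next_cell_type(filament)
                if wanted == DIAZOTROPH and not filament.diazocyte_developing:
                    wanted = PHOTOAUTOTROPH  # no diazocyte under development
                daughter.cell_type = wanted
                if cell is alive[0]:
                    filament.cells.insert(0, daughter)
                else:
                    filament.cells.append(daughter)
                divided_ids.add(cell.id)
                world.log.events.append(
                    {"step": world.step_index, "event": "division",
                     "cell_id": cell.id, "daughter_id": daughter.id,
                     "daughter_type": daughter.cell_type}
                )

    for filament in world.filaments:
        if len(filament.alive_cells()) >= 2:
            intrafilament_exchange(filament, world.rules)

    _log_cells(world, divided_ids, died_ids)


def _log_cells(world: World, divided_ids: set[int], died_ids: set[int]) -> None:
    rows = []
    nu_xs = []
    for filament in world.filaments:
        for cell in filament.cells:
            w_b = cell.weights.w_b if cell.weights else float("nan")
            w_m = cell.weights.w_m if cell.weights else float("nan")
            nu_obj = (
                cell.last_solution.objective_value
                if cell.last_solution is not None and cell.last_solution.optimal
                else float("nan")
            )
            if cell.alive and cell.last_solution is not None \
                    and cell.last_solution.optimal:
                nu_x = cell.last_solution[
                    world.networks[cell.cell_type].biomass_rxn
                ]
                nu_xs.append(nu_x)
            from .objective_dynamics import cumulative_mass_probability

            z = cumulative_mass_probability(cell.biomass_g, world.dist)
            rows.append([
                world.step_index, cell.id, filament.id, cell.cell_type,
                cell.state, repr(cell.biomass_g),
                repr(cell.pools.get("maltose", 0.0)),
                repr(cell.pools.get("baa", 0.0)),
                repr(w_b), repr(w_m), repr(z), repr(nu_obj),
                int(cell.id in died_ids), int(cell.id in divided_ids),
            ])
    world.log.cell_rows.extend(rows)
    alive = [c for c in world.cells() if c.alive]
    world.log.summaries.append({
        "step": world.step_index,
        "n_alive": len(alive),
        "n_filaments": len(world.filaments),
        "mean_growth_rate_h": float(np.mean(nu_xs)) if nu_xs else 0.0,
        "mean_maltose_mmol": float(
            np.mean([c.pools.get("maltose", 0.0) for c in alive])
        ) if alive else 0.0,
        "mean_baa_mmol": float(
            np.mean([c.pools.get("baa", 0.0) for c in alive])
        ) if alive else 0.0,
        "total_nh4_uM": world.grid.total_mass("nh4"),
        "total_co2_uM": world.grid.total_mass("co2"),
    })


def step(world: World) -> World:
    """Advance the world by one time step (fixed stage order)."""
    try:
        cfg = world.config
        surface_exchange(world.grid, world.boundary)
        sub_dt = cfg.dt_diffusion_h or cfg.dt_h
        n_sub = max(1, round(cfg.dt_h / sub_dt))
        for species in world.grid.fields:
            for _ in range(n_sub):
                diffusion_step(world.grid, species, dt_h=cfg.dt_h / n_sub)
        _filament_stage(world)
        _cell_stage(world)
    except Exception as exc:
        raise RuntimeError(f"simulation step {world.step_index} failed: {exc}") from exc
    world.step_index += 1
    return world


def _write_grid_snapshot(writer: csv.writer, world: World) -> None:
    for species, arr in world.grid.fields.items():
        for y in range(world.grid.height):
            for x in range(world.grid.width):
                writer.writerow(
                    [world.step_index, x, y, species, repr(float(arr[y, x]))]
                )


def run(config: SimulationConfig) -> RunLog:
    """Execute a full simulation, streaming logs to ``config.out_dir`` if set."""
    world = initialize(config)
    out_dir = Path(config.out_dir) if config.out_dir else None
    cell_fh = grid_fh = None
    cell_writer = grid_writer = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "mimosa": __import__("mimosa").__version__,
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        cell_fh = open(out_dir / "cells.csv", "w", newline="")
        cell_writer = csv.writer(cell_fh)
        cell_writer.writerow(CELL_LOG_COLUMNS)
        grid_fh = open(out_dir / "grid.csv", "w", newline="")
        grid_writer = csv.writer(grid_fh)
        grid_writer.writerow(["step", "x", "y", "metabolite", "concentration_uM"])
        _write_grid_snapshot(grid_writer, world)
    try:
        for _ in range(config.n_steps):
            rows_before = len(world.log.cell_rows)
            step(world)
            if cell_writer is not None:
                for row in world.log.cell_rows[rows_before:]:
                    cell_writer.writerow(row)
                cell_fh.flush()
            if (
                grid_writer is not None
                and config.grid_log_steps
                and world.step_index % config.grid_log_steps == 0
            ):
                _write_grid_snapshot(grid_writer, world)
        if grid_writer is not None:
            _write_grid_snapshot(grid_writer, world)
        if out_dir is not None and config.flux_map_cells:
            _write_flux_maps(out_dir, world)
    finally:
        for fh in (cell_fh, grid_fh):
            if fh is not None:
                fh.close()
    return world.log


def _write_flux_maps(out_dir: Path, world: World) -> None:
    with open(out_dir / "flux_maps.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "reaction", "flux"])
        for cell in world.cells():
            if cell.id in world.config.flux_map_cells \
                    and cell.last_solution is not None:
                for rxn, flux in cell.last_solution.fluxes.items():
                    writer.writerow([cell.id, rxn, repr(float(flux))])
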