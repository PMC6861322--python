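"""Cell and filament agents.

Cells carry non-metabolite biomass plus two storage pools (glycogen tracked
as maltose, cyanophycin tracked as beta-aspartyl-arginine).  Every step a
living cell re-weights its objective from its biomass, solves the scalarized
FBA with maintenance fixed by the local light level, and integrates pools,
biomass and environment exchanges forward by one Euler step.  A cell that
cannot meet maintenance even by catabolizing its pools dies.  Filaments
organize cells, decide the next cell type from mean Pareto efficiencies,
split in the middle of the longest homogeneous run, and random-walk rigidly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from . import parameters
from .metabolic_core import (
    FluxSolution,
    MaintenanceModel,
    MetabolicNetwork,
    maintenance_flux,
    pareto_efficiency,
)
from .objective_dynamics import MassDistribution, ObjectiveWeights, shift_weights
from .units import BIOMASS_G_PER_MMOL, amount_to_flux, flux_to_amount

logger = logging.getLogger(__name__)

__all__ = [
    "CellAgent",
    "FilamentAgent",
    "TransferRules",
    "LocalAvailability",
    "CellStepResult",
    "set_uptake_bounds",
    "cell_step",
    "maybe_divide",
    "maybe_go_stationary",
    "decide_next_cell_type",
    "maybe_split",
    "random_walk",
    "intrafilament_exchange",
    "cell_elements",
]

PHOTOAUTOTROPH = "photoautotroph"
DIAZOTROPH = "diazotroph"

#: map grid species -> environment-exchange reaction id in the toy networks
SPECIES_TO_EXCHANGE = {
    "co2": "EX_co2",
    "o2": "EX_o2",
    "nh4": "EX_nh4",
    "n2": "EX_n2",
    "maltose": "EX_malt",
    "baa": "EX_baa",
}
#: map pool species -> internal storage sink reaction id
SPECIES_TO_SINK = {"maltose": "SINK_malt", "baa": "SINK_baa"}
#: the storage species each cell type accumulates (its metabolite objective)
OWN_POOL = {PHOTOAUTOTROPH: "maltose", DIAZOTROPH: "baa"}


@dataclass
class TransferRules:
    """Membrane and intrafilament transfer parameters."""

    transporters: dict[str, dict[str, str]]
    membrane_permeability: dict[str, float]
    baa_cap_fraction: float = 0.08
    intrafilament_rate: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 <= self.baa_cap_fraction <= 1.0:
            raise ValueError("uptake cap fraction must lie in [0, 1]")
        if any(p < 0 for p in self.membrane_permeability.values()):
            raise ValueError("permeabilities must be nonnegative")

    @classmethod
    def from_table(cls) -> "TransferRules":
        return cls(
            transporters=parameters.get("transporters"),
            membrane_permeability=parameters.get("membrane_permeability"),
            baa_cap_fraction=parameters.get("cell", "baa_uptake_cap_fraction"),
            intrafilament_rate=parameters.get("intrafilament", "exchange_rate"),
        )


@dataclass
class LocalAvailability:
    """What one cell sees of one species in its gridcell."""

    conc_uM: float
    available_mmol: float  # total amount in the gridcell
    allocation_mmol: float  # this cell's equal-partition share


@dataclass
class CellAgent:
    id: int
    cell_type: str
    biomass_g: float
    pools: dict[str, float] = field(
        default_factory=lambda: {"maltose": 0.0, "baa": 0.0}
    )
    gx: int = 0
    gy: int = 0
    state: str = "growing"  # growing | stationary | dead
    filament_id: int = -1
    weights: ObjectiveWeights | None = None
    last_solution: FluxSolution | None = None
    pareto_eff: float | None = None

    @property
    def alive(self) -> bool:
        return self.state != "dead"

    @property
    def position(self) -> tuple[int, int]:
        return (self.gx, self.gy)


@dataclass
class CellStepResult:
    """Per-step outcome: environment exchanges plus log quantities."""

    exchanges_mmol: dict[str, float]  # species -> amount removed from gridcell
    died: bool = False
    nu_obj: float = float("nan")
    nu_x: float = float("nan")
    nu_m: float = float("nan")


def cell_elements(cell: CellAgent) -> dict[str, float]:
    """Total C and N inventory (mmol) of one cell: biomass plus pools."""
    from .fixtures_io import BIOMASS_COMPOSITION, ELEMENTS

    biomass_mmol = cell.biomass_g / BIOMASS_G_PER_MMOL
    totals = {
        el: biomass_mmol * coef for el, coef in BIOMASS_COMPOSITION.items()
    }
    for species, amount in cell.pools.items():
        for el, coef in ELEMENTS[species].items():
            totals[el] = totals.get(el, 0.0) + amount * coef
    return totals


def set_uptake_bounds(
    cell: CellAgent,
    network: MetabolicNetwork,
    local_env: Mapping[str, LocalAvailability],
    rules: TransferRules,
    dt_h: float,
) -> dict[str, tuple[float, float]]:
    """Per-species import bounds from local concentrations and transporters.

    Active transporters grant the cell's full equal-partition allocation;
    passive transfer is additionally permeability-limited; species without a
    transporter cannot be imported.  Beta-aspartyl-arginine import is further
    capped at ``baa_cap_fraction`` of the *total* amount available in the
    gridcell.  Bounds are converted to mmol/gDW/h with the cell's mass and
    the time step; export (negative) bounds are left at network defaults.
    """
    modes = rules.transporters.get(cell.cell_type, {})
    overrides: dict[str, tuple[float, float]] = {}
    for species, rxn in SPECIES_TO_EXCHANGE.items():
        if rxn not in network.reactions:
            continue
        j = network.index(rxn)
        avail = local_env.get(species)
        if avail is None:
            overrides[rxn] = (network.lower[j], 0.0)
            continue
        mode = modes.get(species, "none")
        alloc_flux = amount_to_flux(avail.allocation_mmol, cell.biomass_g, dt_h)
        if mode == "active":
            ub = alloc_flux
        elif mode == "passive":
            perm = rules.membrane_permeability.get(species, 0.0)
            ub = min(alloc_flux, perm * avail.conc_uM)
        else:
            ub = 0.0
        if species == "baa":
            cap_flux = amount_to_flux(
                rules.baa_cap_fraction * avail.available_mmol,
                cell.biomass_g, dt_h,
            )
            ub = min(ub, cap_flux)
        # structural transporter capacity still applies
        overrides[rxn] = (network.lower[j], min(max(0.0, ub), network.upper[j]))
    return overrides


def _pool_draw_bound(cell: CellAgent, species: str, dt_h: float) -> float:
    """Largest (negative) sink flux the cell's own pool can sustain."""
    return -amount_to_flux(cell.pools.get(species, 0.0), cell.biomass_g, dt_h)


def cell_step(
    cell: CellAgent,
    network: MetabolicNetwork,
    local_env: Mapping[str, LocalAvailability],
    *,
    base_weights: ObjectiveWeights,
    dist: MassDistribution,
    maintenance_model: MaintenanceModel,
    light_I: float,
    rules: TransferRules,
    dt_h: float,
    experimental_optima: Mapping[str, float] | None = None,
    tie_break: bool = True,
) -> CellStepResult:
    """One metabolic decision for one living cell.

    Order of operations: (1) shift objective weights from the cell's
    non-metabolite biomass; (2) solve the scalarized FBA with the maintenance
    flux fixed from the local light level; (3) on infeasibility, retry with
    the storage sinks reversed (catabolism) and mark the cell dead if still
    infeasible; (4) Euler-integrate biomass and pools; (5) report exchange
    amounts for the environment.
    """
    from .metabolic_core import solve_fba

    if not cell.alive:
        return CellStepResult(exchanges_mmol={})

    if cell.state == "stationary":
        weights = ObjectiveWeights(0.0, 1.0)
    else:
        weights = shift_weights(base_weights, cell.biomass_g, dist)
    cell.weights = weights

    demand = maintenance_flux(light_I, maintenance_model, cell.cell_type)
    bounds = set_uptake_bounds(cell, network, local_env, rules, dt_h)

    own_species = OWN_POOL[cell.cell_type]
    partner_species = "baa" if own_species == "maltose" else "maltose"
    own_sink = SPECIES_TO_SINK[own_species]
    partner_sink = SPECIES_TO_SINK[partner_species]
    # the partner pool (fed by intrafilament transfer) is always drawable
    j = network.index(partner_sink)
    bounds[partner_sink] = (
        _pool_draw_bound(cell, partner_species, dt_h), network.upper[j]
    )
    if cell.state == "stationary":
        bounds[network.biomass_rxn] = (0.0, 0.0)

    sol = solve_fba(network, weights, bounds, maintenance=demand,
                    tie_break=tie_break)
    if not sol.optimal:
        # catabolism: allow the cell to run its own storage sink in reverse
        j = network.index(own_sink)
        bounds[own_sink] = (
            _pool_draw_bound(cell, own_species, dt_h), network.upper[j]
        )
        sol = solve_fba(network, weights, bounds, maintenance=demand,
                        tie_break=tie_break)
    if not sol.optimal:
        cell.state = "dead"
        cell.last_solution = sol
        logger.debug("cell %d died (maintenance %.3g infeasible)", cell.id, demand)
        return CellStepResult(exchanges_mmol={}, died=True)

    nu_x = sol[network.biomass_rxn]
    nu_m = sol[network.metabolite_rxn]
    mass_before = cell.biomass_g
    if cell.state == "growing":
        cell.biomass_g += flux_to_amount(nu_x, mass_before, dt_h) * BIOMASS_G_PER_MMOL
    for species, sink in ((own_species, own_sink), (partner_species, partner_sink)):
        delta = flux_to_amount(sol[sink], mass_before, dt_h)
        cell.pools[species] = max(0.0, cell.pools.get(species, 0.0) + delta)

    exchanges: dict[str, float] = {}
    for species, rxn in SPECIES_TO_EXCHANGE.items():
        if rxn in network.reactions:
            flux = sol[rxn]
            if flux != 0.0:
                exchanges[species] = flux_to_amount(flux, mass_before, dt_h)

    cell.last_solution = sol
    if experimental_optima:
        cell.pareto_eff = pareto_efficiency(sol, experimental_optima)
    return CellStepResult(
        exchanges_mmol=exchanges,
        nu_obj=sol.objective_value,
        nu_x=float(nu_x),
        nu_m=float(nu_m),
    )


def maybe_divide(
    cell: CellAgent,
    dist: MassDistribution,
    rng: np.random.Generator,
    at_end: bool,
    daughter_id: int,
) -> CellAgent | None:
    """Memoryless division check against a fresh truncated-normal threshold.

    A growing end cell divides when its biomass meets or exceeds the drawn
    threshold; biomass and pools are split exactly in half between parent and
    daughter.  Interior cells never divide (filaments extend from the ends).
    """
    if cell.state != "growing":
        return None
    threshold = dist.sample_threshold(rng)
    if not at_end or cell.biomass_g < threshold:
        return None
    cell.biomass_g /= 2.0
    daughter_pools = {}
    for species, amount in cell.pools.items():
        cell.pools[species] = amount / 2.0
        daughter_pools[species] = amount / 2.0
    return CellAgent(
        id=daughter_id,
        cell_type=cell.cell_type,
        biomass_g=cell.biomass_g,
        pools=daughter_pools,
        gx=cell.gx,
        gy=cell.gy,
        state="growing",
        filament_id=cell.filament_id,
    )


def maybe_go_stationary(cell: CellAgent, dist: MassDistribution) -> bool:
    """One-way growing -> stationary switch at twice the mean mass."""
    if cell.state == "growing" and cell.biomass_g >= 2.0 * dist.mean_mass:
        cell.state = "stationary"
        return True
    return False


@dataclass
class FilamentAgent:
    id: int
    cells: list[CellAgent]
    diazocyte_developing: bool = False
    developing_end: int | None = None  # 0 (head) or -1 (tail)
    movement_interval: int = 1
    growth_halted: bool = False

    def __len__(self) -> int:
        return len(self.cells)

    def alive_cells(self) -> list[CellAgent]:
        return [c for c in self.cells if c.alive]

    def counts(self) -> dict[str, int]:
        out = {PHOTOAUTOTROPH: 0, DIAZOTROPH: 0}
        for c in self.alive_cells():
            out[c.cell_type] += 1
        return out


def decide_next_cell_type(filament: FilamentAgent) -> str:
    """Type of the next daughter cell, from mean Pareto efficiency per type.

    A strictly greater diazotroph mean prioritizes diazotroph development;
    ties go to the photoautotroph.  A filament left homogeneous (e.g. after
    a split) prefers the missing cell type.
    """
    cells = filament.alive_cells()
    if not cells:
        raise ValueError("cannot decide next cell type for an empty filament")
    counts = filament.counts()
    if counts[DIAZOTROPH] == 0:
        return DIAZOTROPH
    if counts[PHOTOAUTOTROPH] == 0:
        return PHOTOAUTOTROPH
    means = {}
    for ctype in (DIAZOTROPH, PHOTOAUTOTROPH):
        effs = [c.pareto_eff for c in cells
                if c.cell_type == ctype and c.pareto_eff is not None]
        means[ctype] = float(np.mean(effs)) if effs else 0.0
    return DIAZOTROPH if means[DIAZOTROPH] > means[PHOTOAUTOTROPH] else PHOTOAUTOTROPH


def _longest_homogeneous_run(types: list[str]) -> tuple[int, int]:
    """(start, length) of the first longest run of equal cell types."""
    best_start, best_len = 0, 1
    start = 0
    for i in range(1, len(types) + 1):
        if i == len(types) or types[i] != types[start]:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    return best_start, best_len


def maybe_split(
    filament: FilamentAgent,
    nitrogen_limited: bool,
    cn_ratio_high: bool = False,
    next_id: int | None = None,
) -> tuple[FilamentAgent, FilamentAgent] | None:
    """Split in the middle of the longest homogeneous run when triggered.

    Triggers: nitrogen limitation with no diazocyte under development, or a
    C:N ratio above physiological bounds.  Both products keep cell order and
    are at least two cells long; filaments shorter than four never split.
    """
    if len(filament) < 4:
        return None
    if not ((nitrogen_limited and not filament.diazocyte_developing)
            or cn_ratio_high):
        return None
    types = [c.cell_type for c in filament.cells]
    start, length = _longest_homogeneous_run(types)
    split_at = start + length // 2
    split_at = min(max(split_at, 2), len(filament) - 2)
    left = filament.cells[:split_at]
    right = filament.cells[split_at:]
    f_left = FilamentAgent(
        id=filament.id, cells=left,
        movement_interval=filament.movement_interval,
    )
    f_right = FilamentAgent(
        id=filament.id + 1 if next_id is None else next_id, cells=right,
        movement_interval=filament.movement_interval,
    )
    for c in f_right.cells:
        c.filament_id = f_right.id
    return f_left, f_right


_DIRECTIONS = np.array([(0, -1), (0, 1), (-1, 0), (1, 0)])  # (dx, dy)


def random_walk(
    filament: FilamentAgent,
    occupied: set[tuple[int, int]],
    grid_width: int,
    grid_height: int,
    rng: np.random.Generator,
) -> bool:
    """All-or-nothing rigid translation in one uniformly drawn direction.

    The move happens only if every cell's target gridcell is inside the grid
    and not occupied by another filament; otherwise the filament stays put.
    """
    own = {c.position for c in filament.cells}
    dx, dy = _DIRECTIONS[int(rng.integers(len(_DIRECTIONS)))]
    targets = [(c.gx + dx, c.gy + dy) for c in filament.cells]
    for tx, ty in targets:
        if not (0 <= tx < grid_width and 0 <= ty < grid_height):
            return False
        if (tx, ty) in occupied and (tx, ty) not in own:
            return False
    for c, (tx, ty) in zip(filament.cells, targets):
        c.gx, c.gy = tx, ty
    return True


def intrafilament_exchange(filament: FilamentAgent, rules: TransferRules,
                           species: Iterable[str] = ("maltose", "baa")) -> None:
    """Gradient-driven pool exchange between adjacent living cells.

    Each adjacent pair moves ``rate/2`` of its pool difference downhill;
    total filament inventory per species is conserved exactly and the rate
    (<= 1) guarantees nonnegative pools.
    """
    kappa = rules.intrafilament_rate
    for met in species:
        for a, b in itertools.pairwise(filament.cells):
            if not (a.alive and b.alive):
                continue
            t = kappa * (a.pools.get(met, 0.0) - b.pools.get(met, 0.0)) / 2.0
            a.pools[met] = a.pools.get(met, 0.0) - t
            b.pools[met] = b.pools.get(met, 0.0) + t
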