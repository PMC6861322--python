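"""Constraint-based LP layer.

Single-cell flux balance analysis with a scalarized two-term objective
(biomass vs. transacted storage metabolite), Pareto-front construction over
the scalarization weight, decomposition of the combined objective flux, and
the light-dependent linear ATP maintenance model.

The scalarized objective is ``a * v_X + (1 - a) * v_m`` where ``v_X`` is flux
through the biomass reaction and ``v_m`` flux through the storage-metabolite
sink.  The front is generated by sweeping ``a`` over an inclusive, evenly
spaced grid on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import parameters

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicNetwork",
    "FluxSolution",
    "ParetoFront",
    "MaintenanceModel",
    "NetworkStructureError",
    "InfeasibleFrontError",
    "solve_fba",
    "generate_pareto_front",
    "decompose_objective_flux",
    "fit_maintenance",
    "maintenance_flux",
    "pareto_efficiency",
]

#: feasibility tolerance used when asserting S.v = 0 on returned solutions
MASS_BALANCE_TOL = 1e-6


class NetworkStructureError(ValueError):
    """Raised when a network's arrays or named reactions are inconsistent."""


class InfeasibleFrontError(RuntimeError):
    """Raised when every scalarization weight yields an infeasible LP."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric network with named objective reactions.

    Parameters
    ----------
    reactions, metabolites
        Ordered id lists; ``stoichiometry`` is metabolite x reaction.
    lower, upper
        Per-reaction flux bounds in mmol/gDW/h.
    biomass_rxn, metabolite_rxn, atp_maintenance_rxn
        Ids of the growth objective, the storage-metabolite sink objective,
        and the ATP hydrolysis maintenance reaction.
    """

    reactions: list[str]
    metabolites: list[str]
    stoichiometry: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    biomass_rxn: str
    metabolite_rxn: str
    atp_maintenance_rxn: str
    #: optional per-metabolite elemental composition, e.g. {"co2": {"C": 1}}
    elements: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        m, n = self.stoichiometry.shape
        if n != len(self.reactions):
            raise NetworkStructureError(
                f"stoichiometry has {n} columns for {len(self.reactions)} reactions"
            )
        if m != len(self.metabolites):
            raise NetworkStructureError(
                f"stoichiometry has {m} rows for {len(self.metabolites)} metabolites"
            )
        if self.lower.shape != (n,) or self.upper.shape != (n,):
            raise NetworkStructureError("bound vectors must match reaction count")
        if np.any(self.lower > self.upper):
            bad = [self.reactions[i] for i in np.nonzero(self.lower > self.upper)[0]]
            raise NetworkStructureError(f"lower > upper for reactions {bad}")
        if self.biomass_rxn == self.metabolite_rxn:
            raise NetworkStructureError("biomass and metabolite objectives must differ")
        for rid in (self.biomass_rxn, self.metabolite_rxn, self.atp_maintenance_rxn):
            if rid not in self.reactions:
                raise NetworkStructureError(f"named reaction {rid!r} not in network")

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, rxn: str) -> int:
        return self.reactions.index(rxn)

    def bounds_with(
        self, extra_bounds: Mapping[str, tuple[float, float]] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Bounds after applying per-reaction overrides.

        Overrides replace the structural bounds (runtime callers use them to
        open pool-fed sink draws and to tighten uptake capacities); an
        inverted pair is collapsed to its upper value.
        """
        lb = self.lower.copy()
        ub = self.upper.copy()
        if extra_bounds:
            for rid, (lo, hi) in extra_bounds.items():
                i = self.index(rid)
                lb[i], ub[i] = lo, hi
                if lb[i] > ub[i]:
                    lb[i] = ub[i]
        return lb, ub


@dataclass
class FluxSolution:
    """Result of one scalarized FBA solve."""

    fluxes: pd.Series
    objective_value: float
    status: str  # "optimal" | "infeasible"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn: str) -> float:
        return float(self.fluxes[rxn])


@dataclass
class ParetoFront:
    """Trade-off front over the scalarization weight ``a``.

    Each point stores ``(a, nu_obj, nu_x, nu_m)`` with ``nu_x = a * nu_obj``
    and ``nu_m = (1 - a) * nu_obj``.  Infeasible weights hold NaN fluxes.
    """

    a: np.ndarray
    nu_obj: np.ndarray
    nu_x: np.ndarray
    nu_m: np.ndarray

    @property
    def steps(self) -> int:
        return len(self.a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"a": self.a, "nu_obj": self.nu_obj, "nu_x": self.nu_x, "nu_m": self.nu_m}
        )

    def point(self, i: int) -> tuple[float, float, float, float]:
        return (
            float(self.a[i]),
            float(self.nu_obj[i]),
            float(self.nu_x[i]),
            float(self.nu_m[i]),
        )


def scalarization_rows(
    network: MetabolicNetwork, a: float
) -> tuple[np.ndarray, np.ndarray]:
    """Objective vector and ratio constraint of the scalarized reaction.

    The combined objective reaction produces biomass and storage metabolite
    in proportion ``a : (1 - a)``, so its flux is ``nu_obj = v_X + v_m``
    subject to ``(1 - a) * v_X - a * v_m = 0``; the decomposition
    ``v_X = a * nu_obj``, ``v_m = (1 - a) * nu_obj`` is then exact.
    """
    i_x = network.index(network.biomass_rxn)
    i_m = network.index(network.metabolite_rxn)
    c = np.zeros(network.n_reactions)
    c[i_x] = 1.0
    c[i_m] = 1.0
    ratio = np.zeros(network.n_reactions)
    ratio[i_x] = 1.0 - a
    ratio[i_m] = -a
    return c, ratio


def _weight_a(weights) -> float:
    """Accept a bare scalar ``a`` or an object with ``w_b``/``w_m`` attributes."""
    if hasattr(weights, "w_b"):
        total = weights.w_b + weights.w_m
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"objective weights must sum to 1, got {total}")
        return float(weights.w_b)
    a = float(weights)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"scalarization weight must lie in [0, 1], got {a}")
    return a


def solve_fba(
    network: MetabolicNetwork,
    weights,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    maintenance: float | None = None,
    tie_break: bool = True,
) -> FluxSolution:
    """Maximize the scalarized objective flux subject to ``S.v = 0`` and bounds.

    The scalarized objective is modeled as a single combined reaction whose
    flux splits into biomass and storage-metabolite components in proportion
    ``a : (1 - a)`` (see :func:`scalarization_rows`): the LP maximizes
    ``nu_obj = v_X + v_m`` under the ratio constraint
    ``(1 - a) v_X = a v_m``, so ``v_X = a * nu_obj`` exactly.

    Parameters
    ----------
    weights
        A scalar ``a`` in [0, 1] or an ``ObjectiveWeights`` with
        ``w_b + w_m == 1``.
    extra_bounds
        Per-reaction ``(lb, ub)`` overrides, clipped into the network bounds.
    maintenance
        If given, the ATP maintenance reaction is fixed to this flux
        (clipped into its network bounds).
    tie_break
        Resolve LP degeneracy by a secondary solve minimizing ``sum |v|``
        at the optimal objective value, making flux maps reproducible.

    Returns an infeasible-status solution rather than raising when the LP
    has no feasible point.
    """
    a = _weight_a(weights)
    lb, ub = network.bounds_with(extra_bounds)
    if maintenance is not None:
        i = network.index(network.atp_maintenance_rxn)
        fixed = float(np.clip(maintenance, network.lower[i], network.upper[i]))
        lb[i] = ub[i] = fixed
    c, ratio = scalarization_rows(network, a)
    S = np.vstack([network.stoichiometry, ratio])
    n = network.n_reactions

    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        return FluxSolution(
            fluxes=pd.Series(np.full(n, np.nan), index=network.reactions),
            objective_value=float("nan"),
            status="infeasible",
        )
    nu_obj = float(c @ res.x)
    v = res.x

    if tie_break:
        # Lexicographic second stage: minimize sum |v| with the scalarized
        # objective pinned at its optimum.  Variables are [v, t], t >= |v|.
        obj2 = np.concatenate([np.zeros(n), np.ones(n)])
        eye = np.eye(n)
        A_ub = np.block([[eye, -eye], [-eye, -eye]])
        b_ub = np.zeros(2 * n)
        A_ub = np.vstack([A_ub, np.concatenate([-c, np.zeros(n)])])
        b_ub = np.append(b_ub, -(nu_obj - 1e-9))
        A_eq2 = np.hstack([S, np.zeros_like(S)])
        big = max(1.0, np.max(np.abs(lb)), np.max(np.abs(ub)))
        bounds2 = list(zip(lb, ub)) + [(0.0, big)] * n
        res2 = linprog(
            obj2,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq2,
            b_eq=np.zeros(S.shape[0]),
            bounds=bounds2,
            method="highs",
        )
        if res2.status == 0:
            v = res2.x[:n]

    return FluxSolution(
        fluxes=pd.Series(v, index=network.reactions),
        objective_value=nu_obj,
        status="optimal",
    )


def generate_pareto_front(
    network: MetabolicNetwork,
    steps: int | None = None,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    maintenance: float | None = None,
) -> ParetoFront:
    """Sweep ``a`` over an inclusive even grid on [0, 1].

    ``steps`` counts grid points (both endpoints included); the packaged
    default is 1000.  Raises :class:`InfeasibleFrontError` if every weight is
    infeasible — the fixed maintenance flux is the usual cause.
    """
    if steps is None:
        steps = int(parameters.get("pareto", "steps"))
    if steps < 2:
        raise ValueError("a Pareto front needs at least 2 scalarization steps")
    a_grid = np.linspace(0.0, 1.0, steps)
    nu_obj = np.full(steps, np.nan)
    for i, a in enumerate(a_grid):
        sol = solve_fba(
            network, a, extra_bounds=extra_bounds, maintenance=maintenance,
            tie_break=False,
        )
        if sol.optimal:
            nu_obj[i] = sol.objective_value
    if np.all(np.isnan(nu_obj)):
        raise InfeasibleFrontError(
            "network infeasible at every scalarization weight; the fixed ATP "
            "maintenance flux is the usual cause"
        )
    return ParetoFront(
        a=a_grid, nu_obj=nu_obj, nu_x=a_grid * nu_obj, nu_m=(1.0 - a_grid) * nu_obj
    )


def decompose_objective_flux(a: float, nu_obj: float) -> tuple[float, float]:
    """Split the combined objective flux into ``(mu, nu_m)``.

    ``mu = a * nu_obj`` is the biomass (growth) component and
    ``nu_m = (1 - a) * nu_obj`` the storage-metabolite component.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a must lie in [0, 1], got {a}")
    return a * nu_obj, (1.0 - a) * nu_obj


@dataclass
class MaintenanceModel:
    """Linear light-dependent ATP maintenance demand per cell type.

    ``nu_ATP(I) = m_slope * I + nu0`` clamped at zero from below.  Stores the
    published constants and the two (I, nu_ATP) anchor points; the two are
    mutually inconsistent in the source table, so ``refit=True`` switches to
    constants re-derived from the anchors.
    """

    constants: dict[str, dict[str, float]]
    refit: bool = False

    @classmethod
    def from_table(cls, refit: bool = False) -> "MaintenanceModel":
        tab = parameters.get("maintenance")
        constants = {
            ct: {
                "m_slope": row["m_slope"],
                "nu0": row["nu0"],
                "L0": row["L0"],
                "anchors": ((80.0, row["anchor_80"]), (100.0, row["anchor_100"])),
            }
            for ct, row in tab.items()
        }
        return cls(constants=constants, refit=refit)

    def coefficients(self, cell_type: str) -> tuple[float, float]:
        if cell_type not in self.constants:
            raise KeyError(f"unknown cell type {cell_type!r}")
        row = self.constants[cell_type]
        if self.refit:
            (i1, v1), (i2, v2) = row["anchors"]
            return fit_maintenance(i1, v1, i2, v2)
        return row["m_slope"], row["nu0"]


def fit_maintenance(
    I1: float, nu1: float, I2: float, nu2: float
) -> tuple[float, float]:
    """Point-slope fit of the maintenance line through two (I, nu_ATP) anchors.

    Returns ``(m_slope, nu0)`` with ``m_slope = (nu1 - nu2) / (I1 - I2)`` and
    ``nu0 = -I1 * m_slope + nu1``; the fitted line passes through both anchors
    exactly and is invariant to swapping them.
    """
    if I1 == I2:
        raise ValueError("degenerate maintenance fit: the two light anchors coincide")
    m_slope = (nu1 - nu2) / (I1 - I2)
    nu0 = -I1 * m_slope + nu1
    return m_slope, nu0


def maintenance_flux(I: float, model: MaintenanceModel, cell_type: str) -> float:
    """Evaluate the maintenance line at light ``I``, clamped at 0 from below."""
    if I < 0:
        raise ValueError(f"light intensity must be nonnegative, got {I}")
    m_slope, nu0 = model.coefficients(cell_type)
    return max(0.0, m_slope * I + nu0)


def pareto_efficiency(
    fluxes: FluxSolution, experimental_optima: Mapping[str, float]
) -> float:
    """Mean of realized objective fluxes relative to their experimental optima.

    ``eps = (1/J) * sum_j v_j / v_j_exp`` over the ``J`` objective reactions.
    """
    if not experimental_optima:
        raise ValueError("need at least one objective optimum")
    ratios = []
    for rxn, v_exp in experimental_optima.items():
        if v_exp <= 0:
            raise ValueError(f"experimental optimum for {rxn!r} must be > 0")
        ratios.append(fluxes[rxn] / v_exp)
    return float(np.mean(ratios))
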