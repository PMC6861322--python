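"""Packaged toy metabolic networks, network I/O, and the brute-force LP oracle.

The two toy networks emulate a filamentous marine cyanobacterium's division
of labor: the photoautotroph fixes CO2 into maltose (its storage/export
product) and degrades imported beta-aspartyl-arginine for nitrogen; the
diazotroph respires imported maltose, fixes N2 (8 ATP per ammonium) and
polymerizes beta-aspartyl-arginine (its storage/export product).  Both carry
a light-driven ATP source, an ATP maintenance sink and a lumped biomass
drain, are elementally balanced in C and N by construction, and stay at or
under 12 reactions so the vertex-enumeration oracle remains tractable.

Exchange convention: ``EX_*`` reactions are written import-positive
(flux > 0 moves the species from the local gridcell into the cell) and
``SINK_*`` reactions accumulate into the cell's internal storage pool
(negative flux draws the pool down).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np

from .metabolic_core import MetabolicNetwork, NetworkStructureError

__all__ = [
    "ToyNetworkSpec",
    "ELEMENTS",
    "BIOMASS_COMPOSITION",
    "build_toy_network",
    "toy_network",
    "enumerate_vertices",
    "lp_vertex_oracle",
    "read_network",
    "write_network",
]

#: elemental composition (C, N) of the toy metabolites
ELEMENTS: dict[str, dict[str, float]] = {
    "co2": {"C": 1.0},
    "o2": {},
    "nh4": {"N": 1.0},
    "n2": {"N": 2.0},
    "maltose": {"C": 12.0},
    "baa": {"C": 10.0, "N": 4.0},
    "atp": {},
}

#: C/N content of one mmol of toy biomass (drained by R_biomass)
BIOMASS_COMPOSITION: dict[str, float] = {"C": 5.0, "N": 1.0}

# reaction table per cell type: id -> (stoich, (lb, ub))
_PHOTOAUTOTROPH = {
    "R_light": ({"atp": 1.0, "o2": 0.5}, (0.0, 300.0)),
    "R_malt_syn": ({"co2": -12.0, "atp": -24.0, "maltose": 1.0}, (0.0, 100.0)),
    "R_baa_degrade": (
        {"baa": -1.0, "o2": -10.0, "co2": 10.0, "nh4": 4.0, "atp": 15.0},
        (0.0, 100.0),
    ),
    "R_biomass": ({"co2": -5.0, "nh4": -1.0, "atp": -10.0}, (0.0, 100.0)),
    "R_atpm": ({"atp": -1.0}, (0.0, 1000.0)),
    "EX_co2": ({"co2": 1.0}, (-100.0, 10.0)),
    "EX_o2": ({"o2": 1.0}, (-1000.0, 1000.0)),
    "EX_nh4": ({"nh4": 1.0}, (-100.0, 10.0)),
    "EX_baa": ({"baa": 1.0}, (0.0, 5.0)),
    "SINK_malt": ({"maltose": -1.0}, (0.0, 1000.0)),
    "SINK_baa": ({"baa": -1.0}, (0.0, 1000.0)),
}

_DIAZOTROPH = {
    "R_light": ({"atp": 1.0, "o2": 0.5}, (0.0, 300.0)),
    "R_malt_degrade": (
        {"maltose": -1.0, "o2": -12.0, "co2": 12.0, "atp": 30.0},
        (0.0, 100.0),
    ),
    "R_n2fix": ({"n2": -1.0, "atp": -16.0, "nh4": 2.0}, (0.0, 100.0)),
    "R_baa_syn": (
        {"co2": -10.0, "nh4": -4.0, "atp": -20.0, "baa": 1.0},
        (0.0, 100.0),
    ),
    "R_biomass": ({"co2": -5.0, "nh4": -1.0, "atp": -10.0}, (0.0, 100.0)),
    "R_atpm": ({"atp": -1.0}, (0.0, 1000.0)),
    "EX_o2": ({"o2": 1.0}, (-1000.0, 1000.0)),
    "EX_nh4": ({"nh4": 1.0}, (-100.0, 10.0)),
    "EX_n2": ({"n2": 1.0}, (0.0, 100.0)),
    "EX_malt": ({"maltose": 1.0}, (0.0, 5.0)),
    "SINK_baa": ({"baa": -1.0}, (0.0, 1000.0)),
    "SINK_malt": ({"maltose": -1.0}, (0.0, 1000.0)),
}

_OBJECTIVES = {
    "photoautotroph": {"biomass": "R_biomass", "metabolite": "SINK_malt",
                       "atp_maintenance": "R_atpm"},
    "diazotroph": {"biomass": "R_biomass", "metabolite": "SINK_baa",
                   "atp_maintenance": "R_atpm"},
}


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Recipe for one toy cell-type network.

    ``bound_overrides`` replaces default (lb, ub) pairs per reaction id at
    build time; topology (which pathways exist) is fixed per cell type.
    """

    cell_type: str
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_type not in _OBJECTIVES:
            raise ValueError(
                f"unknown cell type {self.cell_type!r}; "
                f"expected one of {sorted(_OBJECTIVES)}"
            )


def _is_boundary(rxn_id: str, biomass_rxn: str) -> bool:
    return rxn_id.startswith(("EX_", "SINK_")) or rxn_id == biomass_rxn


def build_toy_network(spec: ToyNetworkSpec) -> MetabolicNetwork:
    """Assemble and elementally audit the toy network for one cell type.

    Every internal (non-boundary) reaction must balance C and N exactly;
    violation raises a construction error naming the offending element.
    """
    table = _PHOTOAUTOTROPH if spec.cell_type == "photoautotroph" else _DIAZOTROPH
    objectives = _OBJECTIVES[spec.cell_type]
    reactions = list(table)
    mets = sorted({m for stoich, _ in table.values() for m in stoich})
    S = np.zeros((len(mets), len(reactions)))
    lower = np.zeros(len(reactions))
    upper = np.zeros(len(reactions))
    for j, rid in enumerate(reactions):
        stoich, bounds = table[rid]
        if rid in spec.bound_overrides:
            bounds = spec.bound_overrides[rid]
        lower[j], upper[j] = bounds
        for met, coef in stoich.items():
            S[mets.index(met), j] = coef
    # elemental audit of internal reactions
    for j, rid in enumerate(reactions):
        if _is_boundary(rid, objectives["biomass"]):
            continue
        for element in ("C", "N"):
            total = sum(
                S[i, j] * ELEMENTS[met].get(element, 0.0)
                for i, met in enumerate(mets)
            )
            if abs(total) > 1e-9:
                raise NetworkStructureError(
                    f"reaction {rid!r} unbalanced in {element} by {total}"
                )
    return MetabolicNetwork(
        reactions=reactions,
        metabolites=mets,
        stoichiometry=S,
        lower=lower,
        upper=upper,
        biomass_rxn=objectives["biomass"],
        metabolite_rxn=objectives["metabolite"],
        atp_maintenance_rxn=objectives["atp_maintenance"],
        elements={m: dict(ELEMENTS[m]) for m in mets},
    )


def toy_network(cell_type: str, **overrides) -> MetabolicNetwork:
    """Convenience constructor: ``toy_network('photoautotroph')``."""
    return build_toy_network(ToyNetworkSpec(cell_type, bound_overrides=overrides))


# ---------------------------------------------------------------------------
# brute-force LP oracle


def enumerate_vertices(
    network: MetabolicNetwork,
    weights=None,
    extra_bounds=None,
    maintenance: float | None = None,
    max_free: int = 8,
    tol: float = 1e-9,
) -> np.ndarray:
    """Enumerate all basic feasible solutions of {S.v = 0, lb <= v <= ub}.

    When ``weights`` (a scalarization weight ``a``) is given, the objective
    ratio constraint ``(1 - a) v_X = a v_m`` is appended to the equality
    system so the vertices are those of the scalarized problem.  Fixes
    ``n - rank(S)`` coordinates at one of their bounds, solves the remaining
    square-ish system, and keeps consistent solutions inside the bounds.
    Refuses when the free dimension exceeds ``max_free``.
    """
    from .metabolic_core import scalarization_rows

    lb, ub = network.bounds_with(extra_bounds)
    if maintenance is not None:
        i = network.index(network.atp_maintenance_rxn)
        fixed = float(np.clip(maintenance, network.lower[i], network.upper[i]))
        lb[i] = ub[i] = fixed
    S = network.stoichiometry
    if weights is not None:
        a = float(weights.w_b) if hasattr(weights, "w_b") else float(weights)
        _, ratio = scalarization_rows(network, a)
        S = np.vstack([S, ratio])
    n = network.n_reactions
    rank = np.linalg.matrix_rank(S)
    free = n - rank
    if free > max_free:
        raise ValueError(
            f"free dimension {free} exceeds oracle limit {max_free}"
        )
    vertices: list[np.ndarray] = []
    all_idx = np.arange(n)
    for fixed_idx in combinations(range(n), free):
        fixed_idx = np.array(fixed_idx, dtype=int)
        solve_idx = np.setdiff1d(all_idx, fixed_idx)
        S_fix = S[:, fixed_idx]
        S_solve = S[:, solve_idx]
        for pattern in product((0, 1), repeat=free):
            v_fix = np.where(np.array(pattern) == 0,
                             lb[fixed_idx], ub[fixed_idx])
            if any(p == 1 and lb[i] == ub[i]
                   for p, i in zip(pattern, fixed_idx)):
                continue  # duplicate of the pattern-0 case
            rhs = -S_fix @ v_fix
            x, *_ = np.linalg.lstsq(S_solve, rhs, rcond=None)
            if np.linalg.norm(S_solve @ x - rhs) > tol:
                continue
            if np.any(x < lb[solve_idx] - tol) or np.any(x > ub[solve_idx] + tol):
                continue
            v = np.empty(n)
            v[fixed_idx] = v_fix
            v[solve_idx] = np.clip(x, lb[solve_idx], ub[solve_idx])
            vertices.append(v)
    return np.array(vertices) if vertices else np.empty((0, n))


def lp_vertex_oracle(
    network: MetabolicNetwork,
    weights,
    extra_bounds=None,
    maintenance: float | None = None,
    vertices: np.ndarray | None = None,
) -> tuple[str, float]:
    """Independent optimum of the scalarized objective by exhaustive search.

    Returns ``("optimal", value)`` or ``("infeasible", nan)``.  A precomputed
    ``vertices`` array (from :func:`enumerate_vertices` with the *same*
    weight) can be passed to skip re-enumeration.
    """
    if vertices is None:
        vertices = enumerate_vertices(
            network, weights, extra_bounds=extra_bounds, maintenance=maintenance
        )
    if len(vertices) == 0:
        return "infeasible", float("nan")
    c = np.zeros(network.n_reactions)
    c[network.index(network.biomass_rxn)] = 1.0
    c[network.index(network.metabolite_rxn)] = 1.0
    return "optimal", float(np.max(vertices @ c))


# ---------------------------------------------------------------------------
# network I/O


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Serialize a network to the packaged JSON dialect (lossless)."""
    doc = {
        "metabolites": list(network.metabolites),
        "reactions": [
            {
                "id": rid,
                "bounds": [float(network.lower[j]), float(network.upper[j])],
                "stoich": {
                    met: float(network.stoichiometry[i, j])
                    for i, met in enumerate(network.metabolites)
                    if network.stoichiometry[i, j] != 0.0
                },
            }
            for j, rid in enumerate(network.reactions)
        ],
        "objectives": {
            "biomass": network.biomass_rxn,
            "metabolite": network.metabolite_rxn,
            "atp_maintenance": network.atp_maintenance_rxn,
        },
    }
    if network.elements:
        doc["elements"] = network.elements
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _read_json_network(path: Path) -> MetabolicNetwork:
    doc = json.loads(path.read_text())
    try:
        rxn_docs = doc["reactions"]
        objectives = doc["objectives"]
    except KeyError as exc:
        raise NetworkStructureError(
            f"{path}: missing required top-level key {exc}"
        ) from exc
    for key in ("biomass", "metabolite", "atp_maintenance"):
        if key not in objectives:
            raise NetworkStructureError(
                f"{path}: objectives must name 'biomass', 'metabolite' and "
                f"'atp_maintenance'; missing {key!r}"
            )
    reactions = [r["id"] for r in rxn_docs]
    if "metabolites" in doc:
        mets = list(doc["metabolites"])
    else:
        mets = sorted({m for r in rxn_docs for m in r.get("stoich", {})})
    S = np.zeros((len(mets), len(reactions)))
    lower = np.zeros(len(reactions))
    upper = np.zeros(len(reactions))
    for j, rdoc in enumerate(rxn_docs):
        lb, ub = rdoc["bounds"]
        if lb > ub:
            raise NetworkStructureError(
                f"{path}: reaction {rdoc['id']!r} has lower bound {lb} > "
                f"upper bound {ub}"
            )
        lower[j], upper[j] = lb, ub
        for met, coef in rdoc.get("stoich", {}).items():
            if met not in mets:
                raise NetworkStructureError(
                    f"{path}: reaction {rdoc['id']!r} references unknown "
                    f"metabolite {met!r}"
                )
            S[mets.index(met), j] = coef
    return MetabolicNetwork(
        reactions=reactions,
        metabolites=mets,
        stoichiometry=S,
        lower=lower,
        upper=upper,
        biomass_rxn=objectives["biomass"],
        metabolite_rxn=objectives["metabolite"],
        atp_maintenance_rxn=objectives["atp_maintenance"],
        elements=doc.get("elements", {}),
    )


def _read_sbml_network(path: Path, objectives: dict[str, str] | None) -> MetabolicNetwork:
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading SBML requires the optional 'cobra' extra") from exc
    if not objectives or not all(
        k in objectives for k in ("biomass", "metabolite", "atp_maintenance")
    ):
        raise NetworkStructureError(
            f"{path}: SBML import requires the objective reaction ids "
            "'biomass', 'metabolite' and 'atp_maintenance' to be supplied"
        )
    model = cobra.io.read_sbml_model(str(path))
    reactions = [r.id for r in model.reactions]
    mets = [m.id for m in model.metabolites]
    S = np.zeros((len(mets), len(reactions)))
    met_index = {m: i for i, m in enumerate(mets)}
    lower = np.zeros(len(reactions))
    upper = np.zeros(len(reactions))
    for j, rxn in enumerate(model.reactions):
        lower[j], upper[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
    return MetabolicNetwork(
        reactions=reactions,
        metabolites=mets,
        stoichiometry=S,
        lower=lower,
        upper=upper,
        biomass_rxn=objectives["biomass"],
        metabolite_rxn=objectives["metabolite"],
        atp_maintenance_rxn=objectives["atp_maintenance"],
    )


def read_network(path: str | Path,
                 objectives: dict[str, str] | None = None) -> MetabolicNetwork:
    """Read a network from the JSON dialect or from SBML L3 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        return _read_sbml_network(path, objectives)
    return _read_json_network(path)
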