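"""Metabolic network representation, I/O, flux balance analysis and feasibility.

A :class:`MetabolicNetwork` is a plain stoichiometric model: metabolites with
compartments, reactions with bounds (mmol·gDW⁻¹·h⁻¹) and a kind flag
(``exchange`` / ``transport`` / ``internal``), and an optional objective.
Uptake is a *negative* exchange flux and secretion a positive one; this sign
convention is enforced at load time by the exchange-detection rule (an
exchange reaction consumes exactly one boundary metabolite with coefficient
−1, so inflow into the system appears as negative flux).

Linear programs (FBA, slack minimization) are solved with SciPy's bundled
HiGHS solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

#: feasibility tolerance used for steady-state residuals and bound checks
TOL_FEAS = 1e-6

#: default compartment treated as the system boundary
BOUNDARY_COMPARTMENT = "e"


class NetworkError(ValueError):
    """Structural problem in a network definition."""


class InfeasibleBoundsError(ValueError):
    """A reaction has lower bound > upper bound."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float
    ub: float
    kind: str = "internal"  # exchange | transport | internal
    subsystem: str | None = None

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.lb, self.ub,
                        self.kind, self.subsystem)


@dataclass
class FluxVector:
    """Solution of one FBA problem."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded
    objective_id: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FeasibilityReport:
    feasible: bool
    total_slack: float
    #: reaction id -> (slack below lb, slack above ub), positive entries only
    slacks: dict[str, tuple[float, float]]
    #: reactions with lb > ub, if any (renders the LP moot)
    bound_violations: list[str] = field(default_factory=list)

    @property
    def infeasible_by_bounds(self) -> bool:
        return bool(self.bound_violations)


class MetabolicNetwork:
    """Stoichiometric network with bounds and an optional objective."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective: tuple[str, str] | None = None,
        boundary_compartment: str = BOUNDARY_COMPARTMENT,
        infer_kinds: bool = False,
    ):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.objective = objective  # (reaction_id, "max"|"min")
        self.boundary_compartment = boundary_compartment
        self._validate()
        if infer_kinds:
            self._infer_kinds()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise NetworkError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise NetworkError(f"duplicate reaction ids: {dupes}")
        declared = set(met_ids)
        for rxn in self.reactions:
            unknown = set(rxn.stoich) - declared
            if unknown:
                raise NetworkError(
                    f"reaction {rxn.id!r} references undeclared metabolites: "
                    f"{sorted(unknown)}")
        if self.objective is not None:
            rid, direction = self.objective
            if rid not in set(rxn_ids):
                raise NetworkError(f"objective reaction {rid!r} not in network")
            if direction not in ("max", "min"):
                raise NetworkError(f"objective direction must be max/min, got {direction!r}")

    def _infer_kinds(self) -> None:
        comp = {m.id: m.compartment for m in self.metabolites}
        for rxn in self.reactions:
            mets = list(rxn.stoich)
            comps = {comp[m] for m in mets}
            if len(mets) == 1 and comp[mets[0]] == self.boundary_compartment:
                rxn.kind = "exchange"
            elif self.boundary_compartment in comps and len(comps) > 1:
                rxn.kind = "transport"
            else:
                rxn.kind = "internal"

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(rid) from None

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.kind == "exchange"]

    def exchanged_metabolite(self, rid: str) -> str:
        """The single boundary metabolite of an exchange reaction."""
        rxn = self.reaction(rid)
        if rxn.kind != "exchange" or len(rxn.stoich) != 1:
            raise NetworkError(f"{rid!r} is not a single-metabolite exchange")
        return next(iter(rxn.stoich))

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites × reactions)."""
        midx = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                S[midx[met], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def bound_violations(self) -> list[str]:
        return [r.id for r in self.reactions if r.lb > r.ub]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.metabolites,
            [r.copy() for r in self.reactions],
            self.objective,
            self.boundary_compartment,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicNetwork":
        """Copy with the given reaction bounds replaced."""
        net = self.copy()
        for rid, (lo, hi) in bounds.items():
            rxn = net.reaction(rid)
            rxn.lb, rxn.ub = float(lo), float(hi)
        return net

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return to_dict(self) == to_dict(other)

    def __repr__(self) -> str:
        return (f"<MetabolicNetwork {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions>")


# -- JSON dialect I/O ------------------------------------------------------

def to_dict(network: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in network.metabolites
        ],
        "reactions": [
            {"id": r.id, "stoich": r.stoich, "lb": r.lb, "ub": r.ub,
             "kind": r.kind}
            for r in network.reactions
        ],
        "objective": (
            None if network.objective is None
            else {"reaction": network.objective[0],
                  "direction": network.objective[1]}
        ),
    }


def from_dict(payload: dict) -> MetabolicNetwork:
    mets = [Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
            for m in payload["metabolites"]]
    infer = any("kind" not in r for r in payload["reactions"])
    rxns = [Reaction(r["id"], {k: float(v) for k, v in r["stoich"].items()},
                     float(r["lb"]), float(r["ub"]),
                     r.get("kind", "internal"), r.get("subsystem"))
            for r in payload["reactions"]]
    obj = payload.get("objective")
    objective = None if not obj else (obj["reaction"], obj.get("direction", "max"))
    return MetabolicNetwork(mets, rxns, objective, infer_kinds=infer)


def save_network(network: MetabolicNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_dict(network), indent=1))


def load_network(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Load a network from the JSON dialect or from SBML Level 3.

    ``format`` is ``"json"`` or ``"sbml"``; inferred from the suffix when
    omitted. Exchange/transport kind flags are inferred from boundary
    metabolites when the file does not carry them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        return from_dict(json.loads(path.read_text()))
    if format == "sbml":
        return _from_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def _from_sbml(path: Path) -> MetabolicNetwork:
    from cobra.io import read_sbml_model  # deferred: heavy import

    model = read_sbml_model(str(path))
    mets = [Metabolite(m.id, m.name or "", m.compartment or "c")
            for m in model.metabolites]
    rxns = [Reaction(r.id, {m.id: c for m, c in r.metabolites.items()},
                     float(r.lower_bound), float(r.upper_bound))
            for r in model.reactions]
    boundary = _guess_boundary_compartment(mets, rxns)
    obj = None
    objective_ids = [r.id for r in model.reactions
                     if r.objective_coefficient not in (0, None)]
    if objective_ids:
        direction = "max" if model.objective.direction == "max" else "min"
        obj = (objective_ids[0], direction)
    net = MetabolicNetwork(mets, rxns, obj, boundary_compartment=boundary,
                           infer_kinds=True)
    return net


def _guess_boundary_compartment(mets, rxns) -> str:
    """Compartment of metabolites touched by single-metabolite reactions."""
    comp = {m.id: m.compartment for m in mets}
    counts: dict[str, int] = {}
    for r in rxns:
        if len(r.stoich) == 1:
            c = comp[next(iter(r.stoich))]
            counts[c] = counts.get(c, 0) + 1
    if counts:
        return max(counts, key=counts.get)
    return BOUNDARY_COMPARTMENT


# -- linear programming ----------------------------------------------------

_LINPROG_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible",
                   3: "unbounded", 4: "numerical"}


def fba(network: MetabolicNetwork, objective_id: str | None = None,
        direction: str | None = None) -> FluxVector:
    """Flux balance analysis: optimize ``v[objective]`` s.t. S·v = 0, lb ≤ v ≤ ub.

    Infeasible and unbounded problems are reported through
    :attr:`FluxVector.status`, not raised — except for the structural error of
    a reaction with lb > ub, which raises :class:`InfeasibleBoundsError`.
    """
    if objective_id is None:
        if network.objective is None:
            raise NetworkError("no objective given and network declares none")
        objective_id, declared_direction = network.objective
        direction = direction or declared_direction
    direction = direction or "max"
    bad = network.bound_violations()
    if bad:
        raise InfeasibleBoundsError(
            f"reactions with lb > ub: {bad}")
    rids = network.reaction_ids
    j = rids.index(objective_id)
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    c = np.zeros(len(rids))
    c[j] = -1.0 if direction == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    status = _LINPROG_STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxVector({}, None, status, objective_id)
    fluxes = dict(zip(rids, map(float, res.x)))
    return FluxVector(fluxes, float(res.x[j]), "optimal", objective_id)


def check_feasibility(
    network: MetabolicNetwork,
    relaxable: Iterable[str] | None = None,
) -> FeasibilityReport:
    """Report feasibility; when infeasible, a minimal-total-slack certificate.

    The slack LP widens only the bounds of ``relaxable`` reactions (all
    reactions by default): minimize Σ(s_lo + s_up) subject to S·v = 0 and
    lb_i − s_lo_i ≤ v_i ≤ ub_i + s_up_i for relaxable i, lb_i ≤ v_i ≤ ub_i
    otherwise.
    """
    bad = network.bound_violations()
    if bad:
        return FeasibilityReport(False, float("inf"), {}, bad)
    rids = network.reaction_ids
    relax = list(relaxable) if relaxable is not None else list(rids)
    missing = set(relax) - set(rids)
    if missing:
        raise KeyError(f"relaxable reactions not in network: {sorted(missing)}")
    n = len(rids)
    k = len(relax)
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    ridx = {r: i for i, r in enumerate(rids)}
    rel_idx = [ridx[r] for r in relax]

    # variables: v (n), s_lo (k), s_up (k)
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], 2 * k))])
    b_eq = np.zeros(S.shape[0])
    # -v_i - s_lo_i <= -lb_i  and  v_i - s_up_i <= ub_i  for relaxable i
    A_ub = np.zeros((2 * k, n + 2 * k))
    b_ub = np.zeros(2 * k)
    for row, i in enumerate(rel_idx):
        A_ub[row, i] = -1.0
        A_ub[row, n + row] = -1.0
        b_ub[row] = -lb[i]
        A_ub[k + row, i] = 1.0
        A_ub[k + row, n + k + row] = -1.0
        b_ub[k + row] = ub[i]
    bounds: list[tuple[float | None, float | None]] = []
    rel_set = set(rel_idx)
    for i in range(n):
        bounds.append((None, None) if i in rel_set else (lb[i], ub[i]))
    bounds.extend([(0, None)] * (2 * k))
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        # base network (non-relaxable part) itself inconsistent
        return FeasibilityReport(False, float("inf"), {})
    s_lo = res.x[n:n + k]
    s_up = res.x[n + k:]
    total = float(s_lo.sum() + s_up.sum())
    slacks = {
        relax[i]: (float(s_lo[i]), float(s_up[i]))
        for i in range(k)
        if s_lo[i] > TOL_FEAS or s_up[i] > TOL_FEAS
    }
    feasible = total <= TOL_FEAS * max(1, k)
    return FeasibilityReport(feasible, 0.0 if feasible else total,
                             {} if feasible else slacks)


def steady_state_residual(network: MetabolicNetwork, fluxes: Mapping[str, float]) -> float:
    """‖S·v‖∞ for a flux assignment."""
    S = network.stoichiometric_matrix()
    v = np.array([fluxes[r] for r in network.reaction_ids])
    return float(np.abs(S @ v).max()) if S.size else 0.0
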