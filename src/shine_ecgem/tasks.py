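"""Metabolic task evaluation, normalization and task-level clustering.

A metabolic task scores one cellular capability: with only its declared
source metabolites available for uptake (at the model's bounds), a whitelist
of inorganic exchanges left open, and a demand added for each product, the
task's objective reaction is maximized by FBA. The resulting optimal flux is
the task activity (mmol·gDW⁻¹·h⁻¹).

Closing an exchange here means forbidding uptake (lower bound → 0); secretion
stays open so that forced by-products can always leave the system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .network import (MetabolicNetwork, NetworkError, Reaction,
                      check_feasibility, fba, TOL_FEAS)

#: metabolite ids whose exchanges stay open during task evaluation
DEFAULT_WHITELIST = ("o2_e", "co2_e", "h2o_e", "h_e", "pi_e")

#: bound given to product demand reactions
DEMAND_UB = 1000.0


@dataclass(frozen=True)
class MetabolicTask:
    id: str
    description: str
    sources: tuple[str, ...]        # extracellular metabolite ids, uptake allowed
    products: tuple[str, ...]       # metabolite ids given a demand sink
    objective: str                  # reaction id (may be a DM_<met> demand)
    whitelist: tuple[str, ...] | None = None  # None -> DEFAULT_WHITELIST
    archetype: str | None = None


@dataclass
class TaskResult:
    task_id: str
    value: float
    status: str  # optimal | infeasible | unbounded
    blocked: bool = False  # feasible but no productive flux


@dataclass
class TaskActivityMatrix:
    """Raw and normalized task × model activity values."""

    raw: pd.DataFrame                    # tasks × models
    normalized: pd.DataFrame | None = None
    constant_rows: list[str] = field(default_factory=list)
    statuses: pd.DataFrame | None = None


def _task_environment(network: MetabolicNetwork, task: MetabolicTask,
                      base: MetabolicNetwork | None = None) -> MetabolicNetwork:
    """Working copy of ``network`` with the task's uptake environment applied.

    ``base`` supplies the wide bounds used for whitelisted exchanges (defaults
    to ``network`` itself); source exchanges keep the model's own, possibly
    contextualized, bounds.
    """
    known = set(network.metabolite_ids)
    cited = set(task.sources) | set(task.products)
    missing = cited - known
    if missing:
        raise NetworkError(
            f"task {task.id!r} cites unknown metabolites: {sorted(missing)}")
    if base is None:
        base = network
    whitelist = set(task.whitelist if task.whitelist is not None
                    else DEFAULT_WHITELIST)
    env = network.copy()
    sources = set(task.sources)
    for rxn in env.reactions:
        if rxn.kind != "exchange":
            continue
        met = next(iter(rxn.stoich))
        if met in sources:
            continue  # keep model bounds (uptake allowed at model's rates)
        base_rxn = base.reaction(rxn.id)
        if met in whitelist:
            rxn.lb, rxn.ub = base_rxn.lb, base_rxn.ub
        else:
            # no uptake; secretion open at the base network's capacity so
            # forced by-products can always leave the system
            rxn.lb = 0.0
            rxn.ub = max(base_rxn.ub, 0.0)
    for met in task.products:
        rid = f"DM_{met}"
        if rid not in env.reaction_ids:
            env.reactions.append(
                Reaction(rid, {met: -1.0}, 0.0, DEMAND_UB, "internal",
                         "demand"))
    if task.objective not in env.reaction_ids:
        raise NetworkError(
            f"task {task.id!r}: objective reaction {task.objective!r} "
            "not resolvable")
    return env


def evaluate_task(network: MetabolicNetwork, task: MetabolicTask,
                  base: MetabolicNetwork | None = None) -> TaskResult:
    """Optimal flux of the task objective in the task environment.

    Returns activity 0 with ``blocked=True`` when the environment is feasible
    but the objective carries no productive flux; an infeasible environment is
    flagged through ``status``, never raised.
    """
    env = _task_environment(network, task, base)
    sol = fba(env, task.objective, "max")
    if not sol.optimal:
        return TaskResult(task.id, float("nan"), sol.status)
    value = float(sol.objective_value)
    return TaskResult(task.id, value, "optimal", blocked=value <= TOL_FEAS)


def task_activity_matrix(models: dict[str, MetabolicNetwork],
                         catalog: list[MetabolicTask],
                         bases: dict[str, MetabolicNetwork] | None = None,
                         ) -> TaskActivityMatrix:
    """Raw activity matrix: rows = tasks, columns = models (deterministic)."""
    if len(models) < 2:
        raise ValueError("need at least two models")
    if not catalog:
        raise ValueError("empty task catalog")
    for name, net in models.items():
        report = check_feasibility(net)
        if not report.feasible:
            raise NetworkError(f"model {name!r} is infeasible")
    values = {}
    statuses = {}
    for name, net in models.items():
        base = bases.get(name) if bases else None
        col_v, col_s = {}, {}
        for task in catalog:
            res = evaluate_task(net, task, base)
            col_v[task.id] = res.value
            col_s[task.id] = res.status
        values[name] = col_v
        statuses[name] = col_s
    task_ids = [t.id for t in catalog]
    raw = pd.DataFrame(values).loc[task_ids]
    stat = pd.DataFrame(statuses).loc[task_ids]
    return TaskActivityMatrix(raw=raw, statuses=stat)


def normalize_activity(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-row linear min-max map onto [−1.5, 1.5].

    Constant rows cannot be scaled; they map to all-zeros and are returned in
    the flag list. Idempotent: renormalizing a normalized matrix is a no-op.
    """
    out = raw.copy().astype(float)
    constant = []
    for tid, row in raw.iterrows():
        lo, hi = float(row.min()), float(row.max())
        if hi - lo <= TOL_FEAS:
            out.loc[tid] = 0.0
            constant.append(tid)
        else:
            out.loc[tid] = (row - lo) / (hi - lo) * 3.0 - 1.5
    if constant:
        warnings.warn(f"constant task rows mapped to zero: {constant}",
                      stacklevel=2)
    return out, constant


def cluster_tasks(normalized: pd.DataFrame, k: int | None = None):
    """Complete-linkage Euclidean clustering of task rows.

    Returns ``(linkage_matrix, ordered_matrix)`` and, when ``k`` is given,
    additionally the flat cluster labels.
    """
    from scipy.cluster.hierarchy import fcluster

    Z = linkage(normalized.to_numpy(), method="complete", metric="euclidean")
    order = leaves_list(Z)
    ordered = normalized.iloc[order]
    if k is None:
        return Z, ordered
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                       index=normalized.index, name="cluster")
    return Z, ordered, labels


@dataclass
class TaskRatio:
    task_id: str
    numerator: str
    denominator: str
    value: float
    infinite: bool = False


def task_ratio(raw: pd.DataFrame, task_id: str, model_a: str,
               model_b: str) -> TaskRatio:
    """Raw activity ratio of one task between two models.

    A zero denominator is reported as an infinite ratio with a flag rather
    than raised.
    """
    a = float(raw.loc[task_id, model_a])
    b = float(raw.loc[task_id, model_b])
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError(f"non-finite activities for task {task_id!r}")
    if b == 0.0:
        return TaskRatio(task_id, model_a, model_b,
                         float("inf") if a > 0 else float("nan"), True)
    return TaskRatio(task_id, model_a, model_b, a / b)
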