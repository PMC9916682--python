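"""Phenotype-specific model contextualization.

The baseline network's exchange fluxes are sampled once; each exchange is then
confined to the interquartile interval (Q1, Q3) of its sampled flux
distribution. For exchanges mapped to measured plasma metabolites, the
interval is scaled by the phenotype's mean fold change versus healthy
controls (computed on raw, unnormalized concentrations); the scaled pair is
re-ordered so lower ≤ upper under any sign pattern. If the constrained model
is infeasible, an L1-minimal slack relaxation widens only the constrained
exchange bounds and logs every widened reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, check_feasibility, TOL_FEAS
from .sampling import FluxSampleSet

#: margin added beyond the minimal slack when widening a bound, so the
#: relaxed polytope keeps a non-empty interior for flux sampling
RELAX_MARGIN = 1e-3


@dataclass
class TransportBounds:
    """Interquartile flux bounds per exchange/transport reaction."""

    quartiles: dict[str, tuple[float, float]]  # rid -> (Q1, Q3)

    def __post_init__(self):
        bad = [r for r, (q1, q3) in self.quartiles.items() if q1 > q3]
        if bad:
            raise ValueError(f"Q1 > Q3 for reactions: {bad}")


@dataclass
class FoldChangeVector:
    """Mean fold changes (phenotype / healthy) and their reaction mapping."""

    fc: dict[str, float]            # metabolite -> fold change
    mapping: dict[str, str]         # metabolite -> exchange reaction id
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = {m: v for m, v in self.fc.items()
               if m in self.mapping and not v > 0}
        if bad:
            raise ValueError(f"non-positive fold changes for mapped metabolites: {bad}")

    def by_reaction(self) -> dict[str, float]:
        return {rid: self.fc[met] for met, rid in self.mapping.items()
                if met in self.fc}


@dataclass
class ContextualizedModel:
    """A network with fold-change-scaled exchange bounds, relaxed to feasibility."""

    network: MetabolicNetwork
    base_network: MetabolicNetwork
    applied_bounds: dict[str, tuple[float, float]]
    #: exchanges whose bounds were scaled by a measured fold change
    constrained_reactions: list[str]
    relaxation_log: list[dict] = field(default_factory=list)

    def relaxed(self) -> bool:
        return bool(self.relaxation_log)


def transport_quartiles(sample_set: FluxSampleSet,
                        reaction_ids: list[str]) -> TransportBounds:
    """Q1/Q3 of each reaction's sampled flux distribution.

    Quantiles use the linear-interpolation convention (the default of NumPy,
    R type 7 and the major statistics environments); the same convention is
    used repo-wide for medians and IQRs.
    """
    missing = [r for r in reaction_ids if r not in sample_set.samples.columns]
    if missing:
        raise KeyError(f"reactions absent from samples: {missing}")
    quart = {}
    for rid in reaction_ids:
        col = sample_set.column(rid)
        q1, q3 = np.quantile(col, [0.25, 0.75])
        quart[rid] = (float(q1), float(q3))
    return TransportBounds(quart)


def compute_fold_changes(phenotype_matrix: pd.DataFrame,
                         healthy_matrix: pd.DataFrame,
                         mapping: Mapping[str, str]) -> FoldChangeVector:
    """FC = mean(phenotype)/mean(healthy) per metabolite, on raw concentrations.

    Metabolites without a transport mapping are retained in ``fc`` but listed
    as unmapped. A non-positive healthy mean is an error (no silent epsilon).
    """
    common = [m for m in phenotype_matrix.columns
              if m in healthy_matrix.columns]
    fc = {}
    for met in common:
        h = float(healthy_matrix[met].mean())
        if not h > 0:
            raise ValueError(f"healthy mean non-positive for {met!r}: {h}")
        fc[met] = float(phenotype_matrix[met].mean()) / h
    mapping = {m: r for m, r in mapping.items() if m in fc}
    unmapped = [m for m in common if m not in mapping]
    return FoldChangeVector(fc, dict(mapping), unmapped)


def apply_fold_changes(bounds: TransportBounds,
                       fc: FoldChangeVector) -> dict[str, tuple[float, float]]:
    """Scale each mapped reaction's quartile interval by its fold change.

    Final (lb, ub) = (min, max) of (FC·Q1, FC·Q3) so ordering survives any
    sign pattern; unmapped reactions keep the baseline quartile interval.
    """
    by_rxn = fc.by_reaction()
    missing = [r for r in by_rxn if r not in bounds.quartiles]
    if missing:
        raise KeyError(f"fold changes map to reactions without quartiles: {missing}")
    out = {}
    for rid, (q1, q3) in bounds.quartiles.items():
        scale = by_rxn.get(rid, 1.0)
        lo, hi = scale * q1, scale * q3
        out[rid] = (min(lo, hi), max(lo, hi))
    return out


def relax_to_feasible(network: MetabolicNetwork,
                      constrained_bounds: Mapping[str, tuple[float, float]],
                      constrained_reactions: list[str] | None = None,
                      ) -> ContextualizedModel:
    """Apply constrained bounds; widen minimally (L1) if infeasible.

    Slack is allowed only on the constrained bounds — internal reactions are
    never relaxed. The relaxation log lists exactly the reactions whose final
    bounds differ from the constrained candidate.
    """
    candidate = network.with_bounds(constrained_bounds)
    relaxable = list(constrained_bounds)
    report = check_feasibility(candidate, relaxable=relaxable)
    if report.infeasible_by_bounds:
        raise ValueError(
            f"constrained bounds invalid (lb > ub): {report.bound_violations}")
    if report.feasible:
        return ContextualizedModel(
            candidate, network, dict(constrained_bounds),
            list(constrained_reactions or relaxable), [])
    if not report.slacks and not report.feasible:
        raise ValueError("relaxation LP infeasible: base network is broken")
    log = []
    final = dict(constrained_bounds)
    for rid, (s_lo, s_up) in report.slacks.items():
        lo, hi = final[rid]
        new = (lo - s_lo - (RELAX_MARGIN if s_lo > 0 else 0.0),
               hi + s_up + (RELAX_MARGIN if s_up > 0 else 0.0))
        log.append({"reaction": rid, "original": (lo, hi), "relaxed": new,
                    "slack": s_lo + s_up})
        final[rid] = new
    relaxed = network.with_bounds(final)
    # the widened model must now be feasible within tolerance
    post = check_feasibility(relaxed, relaxable=relaxable)
    if not post.feasible:
        # numerical guard: widen the logged bounds by the tolerance
        for entry in log:
            rid = entry["reaction"]
            lo, hi = final[rid]
            final[rid] = (lo - 10 * TOL_FEAS, hi + 10 * TOL_FEAS)
        relaxed = network.with_bounds(final)
    return ContextualizedModel(relaxed, network, final,
                               list(constrained_reactions or relaxable), log)


def contextualize(network: MetabolicNetwork,
                  baseline_samples: FluxSampleSet,
                  fold_changes: FoldChangeVector) -> ContextualizedModel:
    """End-to-end contextualization of one phenotype model."""
    bounds = transport_quartiles(baseline_samples, network.exchange_ids())
    constrained = apply_fold_changes(bounds, fold_changes)
    mapped_rids = [r for r in fold_changes.by_reaction()
                   if r in constrained]
    return relax_to_feasible(network, constrained, mapped_rids)
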