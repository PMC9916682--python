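"""Shared fixtures: small hand-built networks, the toy network with baseline
samples, the default synthetic cohort, and a brute-force LP oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import shine_ecgem as se
from shine_ecgem.network import MetabolicNetwork, Metabolite, Reaction


# -- small hand-built networks (≤ 6 reactions) ------------------------------

def chain_network(uptake=(-10.0, 0.0), internal_cap=1000.0):
    """EX_A → A_e → A_c → B_c → B_e → EX_B, single linear pathway."""
    mets = [Metabolite("A_e", "", "e"), Metabolite("A_c", "", "c"),
            Metabolite("B_c", "", "c"), Metabolite("B_e", "", "e")]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, uptake[0], uptake[1], "exchange"),
        Reaction("At", {"A_e": -1.0, "A_c": 1.0}, 0, 1000, "transport"),
        Reaction("CONV", {"A_c": -1.0, "B_c": 1.0}, 0, internal_cap, "internal"),
        Reaction("Bt", {"B_c": -1.0, "B_e": 1.0}, 0, 1000, "transport"),
        Reaction("EX_B", {"B_e": -1.0}, 0, 1000, "exchange"),
    ]
    return MetabolicNetwork(mets, rxns, objective=("EX_B", "max"))


def branch_network():
    """A splits into two products with different caps."""
    mets = [Metabolite("A", "", "e"), Metabolite("B", "", "e"),
            Metabolite("C", "", "e")]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, -8, 0, "exchange"),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 5, "internal"),
        Reaction("R2", {"A": -1.0, "C": 2.0}, 0, 4, "internal"),
        Reaction("EX_B", {"B": -1.0}, 0, 1000, "exchange"),
        Reaction("EX_C", {"C": -1.0}, 0, 6, "exchange"),
    ]
    return MetabolicNetwork(mets, rxns, objective=("EX_B", "max"))


def reversible_network():
    """Reversible interconversion with asymmetric bounds."""
    mets = [Metabolite("A", "", "e"), Metabolite("B", "", "e")]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, -4, 2, "exchange"),
        Reaction("R", {"A": -1.0, "B": 1.0}, -3, 7, "internal"),
        Reaction("EX_B", {"B": -1.0}, -1, 1000, "exchange"),
    ]
    return MetabolicNetwork(mets, rxns, objective=("EX_B", "max"))


SMALL_NETWORKS = {
    "chain": chain_network,
    "chain_capped": lambda: chain_network(internal_cap=5.0),
    "branch": branch_network,
    "reversible": reversible_network,
}


# -- brute-force vertex-enumeration oracle ----------------------------------

def fba_vertex_oracle(network, objective_id, direction="max"):
    """LP optimum by enumerating basic feasible points of {S v = 0, lb ≤ v ≤ ub}.

    Vertices have (n − rank S) variables at a bound; all combinations are
    enumerated and checked. Only for ≤ 6 reactions.
    """
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank
    j = network.reaction_ids.index(objective_id)
    best = None
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [i for i in range(n) if i not in fixed]
        for choices in itertools.product(*[(lb[i], ub[i]) for i in fixed]):
            if any(np.isinf(c) for c in choices):
                continue
            rhs = -S[:, fixed] @ np.array(choices)
            sol, res, rk, _ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v = np.zeros(n)
            v[list(fixed)] = choices
            v[free] = sol
            if np.abs(S @ v).max() > 1e-8:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            if best is None:
                best = v[j]
            elif direction == "max":
                best = max(best, v[j])
            else:
                best = min(best, v[j])
    return best


# -- session fixtures --------------------------------------------------------

@pytest.fixture(scope="session")
def toy_network():
    return se.build_toy_ecgem()


@pytest.fixture(scope="session")
def toy_catalog():
    return se.build_toy_task_catalog()


@pytest.fixture(scope="session")
def baseline_samples(toy_network):
    return se.sample_fluxes(toy_network, 400, seed=42)


@pytest.fixture(scope="session")
def default_cohort():
    return se.simulate_cohort(se.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    return se.preprocess(default_cohort.concentrations, seed=1,
                         outlier_subset=default_cohort.patient_ids)


@pytest.fixture(scope="session")
def patient_normalized(default_cohort, preprocessed):
    keep = [p for p in default_cohort.patient_ids
            if p in preprocessed.normalized.index]
    return preprocessed.normalized.loc[keep]


@pytest.fixture(scope="session")
def phenotype_models(toy_network, baseline_samples):
    """Contextualized A-like / D-like models from the two-phenotype design."""
    from shine_ecgem.contextualize import FoldChangeVector
    from shine_ecgem.synthetic import derive_two_phenotype_design

    designs = derive_two_phenotype_design(toy_network, baseline_samples)
    models = {}
    for name, fc in designs.items():
        mapping = {m: r for m, r in se.METABOLITE_EXCHANGE_MAP.items()
                   if m in fc}
        models[name] = se.contextualize(toy_network, baseline_samples,
                                        FoldChangeVector(fc, mapping))
    return models


@pytest.fixture(scope="session")
def task_activities(phenotype_models, toy_catalog):
    return se.task_activity_matrix(
        {k: m.network for k, m in phenotype_models.items()}, toy_catalog,
        bases={k: m.base_network for k, m in phenotype_models.items()})
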