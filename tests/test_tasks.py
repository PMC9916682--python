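"""Metabolic task evaluation, normalization, clustering and ratios."""

import numpy as np
import pandas as pd
import pytest

import shine_ecgem as se
from shine_ecgem.network import NetworkError
from shine_ecgem.tasks import MetabolicTask, evaluate_task

from conftest import chain_network


class TestEvaluateTask:
    def test_linear_chain_yield_equals_uptake_bound(self):
        net = chain_network(uptake=(-5.0, 0.0))
        task = MetabolicTask("c_from_a", "synthesize C from A",
                             sources=("A_e",), products=("B_c",),
                             objective="DM_B_c")
        res = evaluate_task(net, task)
        assert res.value == pytest.approx(5.0, abs=1e-6)

    def test_product_without_producer_is_blocked(self, toy_network):
        task = MetabolicTask("impossible", "thioredoxin without substrate",
                             sources=(), products=("trxrd_c",),
                             objective="DM_trxrd_c")
        # trxrd can only be cycled from trxox; with nothing entering, no flux
        res = evaluate_task(toy_network, task)
        assert res.value == pytest.approx(0.0, abs=1e-6)
        assert res.blocked

    def test_unknown_metabolite_rejected(self, toy_network):
        task = MetabolicTask("bad", "", sources=("nope_e",), products=(),
                             objective="ATPM")
        with pytest.raises(NetworkError, match="nope_e"):
            evaluate_task(toy_network, task)

    def test_never_exceeds_open_model_optimum(self, toy_network, toy_catalog,
                                              phenotype_models):
        for task in toy_catalog:
            if task.objective not in toy_network.reaction_ids:
                continue  # demand objectives do not exist on the open model
            open_opt = se.fba(toy_network, task.objective, "max").objective_value
            for model in phenotype_models.values():
                res = evaluate_task(model.network, task, model.base_network)
                assert res.value <= open_opt + 1e-6, task.id

    def test_tightening_source_weakly_decreases_activity(self, toy_network,
                                                         toy_catalog):
        task = next(t for t in toy_catalog if t.id == "lactate_from_glucose")
        values = []
        for g in (6.0, 3.0, 1.0):
            net = toy_network.with_bounds({"EX_glc": (-g, 0.0)})
            values.append(evaluate_task(net, task).value)
        assert values[0] >= values[1] >= values[2] - 1e-9

    def test_directional_recovery_glycolytic_vs_catabolic(
            self, task_activities):
        raw = task_activities.raw
        glyc = se.task_ratio(raw, "lactate_from_glucose", "A_like", "D_like")
        beta = se.task_ratio(raw, "malonylcoa_synthesis", "A_like", "D_like")
        assert glyc.value > 1.0
        assert beta.value < 1.0


class TestActivityMatrix:
    def test_identical_models_give_identical_columns(self, toy_network,
                                                     toy_catalog):
        tam = se.task_activity_matrix(
            {"m1": toy_network, "m2": toy_network.copy()}, toy_catalog)
        assert np.allclose(tam.raw["m1"], tam.raw["m2"])

    def test_toy_grid_finite_and_unblocked(self, task_activities):
        assert np.isfinite(task_activities.raw.to_numpy()).all()
        assert (task_activities.raw.to_numpy() > 0).all()

    def test_model_order_permutes_columns_only(self, phenotype_models,
                                               toy_catalog):
        nets = {k: m.network for k, m in phenotype_models.items()}
        bases = {k: m.base_network for k, m in phenotype_models.items()}
        a = se.task_activity_matrix(nets, toy_catalog, bases)
        rev = dict(reversed(list(nets.items())))
        b = se.task_activity_matrix(rev, toy_catalog, bases)
        pd.testing.assert_frame_equal(a.raw, b.raw[a.raw.columns])

    def test_infeasible_model_rejected(self, toy_network, toy_catalog):
        broken = toy_network.with_bounds({"EX_glc": (-200.0, -150.0)})
        with pytest.raises(NetworkError, match="infeasible"):
            se.task_activity_matrix({"ok": toy_network, "bad": broken},
                                    toy_catalog)


class TestNormalize:
    def test_linear_map_of_simple_row(self):
        raw = pd.DataFrame([[0.0, 5.0, 10.0]], index=["t"],
                           columns=["a", "b", "c"])
        out, constant = se.normalize_activity(raw)
        assert np.allclose(out.loc["t"], [-1.5, 0.0, 1.5])
        assert constant == []

    def test_constant_row_zeroed_and_flagged(self):
        raw = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                           index=["flat", "varies"], columns=list("abc"))
        with pytest.warns(UserWarning):
            out, constant = se.normalize_activity(raw)
        assert constant == ["flat"]
        assert (out.loc["flat"] == 0).all()

    def test_extrema_attained_for_varying_rows(self, task_activities):
        out, constant = se.normalize_activity(task_activities.raw)
        varying = out.drop(index=constant)
        assert np.allclose(varying.min(axis=1), -1.5)
        assert np.allclose(varying.max(axis=1), 1.5)
        assert (out.to_numpy() >= -1.5 - 1e-12).all()
        assert (out.to_numpy() <= 1.5 + 1e-12).all()

    def test_idempotent(self, task_activities):
        once, _ = se.normalize_activity(task_activities.raw)
        twice, _ = se.normalize_activity(once)
        pd.testing.assert_frame_equal(once, twice)


class TestClusterTasks:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0],
                          [-1.0, 0.0, 1.0]],
                         index=["t1", "t2", "t3"], columns=list("abc"))
        Z, ordered = se.cluster_tasks(m)
        assert Z[0, 2] == pytest.approx(0.0)  # first merge at height 0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(6)
        archetypes = {"glycolytic": [1.4, 0.2, -0.4, -1.2],
                      "catabolic": [-1.3, -0.1, 0.5, 1.2],
                      "redox": [0.1, 1.3, -1.2, -0.2]}
        rows, truth = [], []
        for name, profile in archetypes.items():
            for i in range(4):
                rows.append(np.array(profile) + rng.normal(0, 0.12, 4))
                truth.append(name)
        m = pd.DataFrame(rows, index=[f"task{i}" for i in range(12)],
                         columns=list("wxyz"))
        _, _, labels = se.cluster_tasks(m, k=3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic(self, task_activities):
        norm, _ = se.normalize_activity(task_activities.raw)
        a = se.cluster_tasks(norm)[1]
        b = se.cluster_tasks(norm)[1]
        pd.testing.assert_frame_equal(a, b)


class TestTaskRatio:
    def test_identical_models_unity(self, toy_network, toy_catalog):
        tam = se.task_activity_matrix(
            {"m1": toy_network, "m2": toy_network.copy()}, toy_catalog)
        r = se.task_ratio(tam.raw, "atp_glycolysis", "m1", "m2")
        assert r.value == pytest.approx(1.0)

    def test_plain_arithmetic(self):
        raw = pd.DataFrame({"a": [10.0], "b": [2.0]}, index=["t"])
        assert se.task_ratio(raw, "t", "a", "b").value == pytest.approx(5.0)

    def test_zero_denominator_flagged_infinite(self):
        raw = pd.DataFrame({"a": [10.0], "b": [0.0]}, index=["t"])
        r = se.task_ratio(raw, "t", "a", "b")
        assert r.infinite and np.isinf(r.value)
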