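"""Quartile bounds, fold changes, bound scaling and feasibility relaxation."""

import numpy as np
import pandas as pd
import pytest

import shine_ecgem as se
from shine_ecgem.contextualize import (FoldChangeVector, TransportBounds,
                                       apply_fold_changes)
from shine_ecgem.sampling import FluxSampleSet
from shine_ecgem.tasks import evaluate_task

from conftest import chain_network


def sample_set_from(frame):
    return FluxSampleSet(frame, "hit-and-run", 0, 10, 100)


class TestTransportQuartiles:
    def test_constant_column_degenerates(self):
        frame = pd.DataFrame({"EX_A": np.full(50, 3.0)})
        tb = se.transport_quartiles(sample_set_from(frame), ["EX_A"])
        assert tb.quartiles["EX_A"] == (3.0, 3.0)

    def test_linear_interpolation_convention(self):
        frame = pd.DataFrame({"EX_A": np.arange(1.0, 101.0)})
        tb = se.transport_quartiles(sample_set_from(frame), ["EX_A"])
        q1, q3 = tb.quartiles["EX_A"]
        assert q1 == pytest.approx(25.75)
        assert q3 == pytest.approx(75.25)

    def test_ordering_invariant(self, baseline_samples, toy_network):
        tb = se.transport_quartiles(baseline_samples,
                                    toy_network.exchange_ids())
        assert all(q1 <= q3 for q1, q3 in tb.quartiles.values())

    def test_missing_reaction_rejected(self, baseline_samples):
        with pytest.raises(KeyError):
            se.transport_quartiles(baseline_samples, ["NOPE"])


class TestFoldChanges:
    def test_equal_means_give_unity(self):
        pheno = pd.DataFrame({"glucose": [2.0, 4.0]})
        healthy = pd.DataFrame({"glucose": [3.0, 3.0]})
        fc = se.compute_fold_changes(pheno, healthy, {"glucose": "EX_glc"})
        assert fc.fc["glucose"] == pytest.approx(1.0)

    def test_ratio_of_means(self):
        pheno = pd.DataFrame({"glucose": [10.0, 10.0]})
        healthy = pd.DataFrame({"glucose": [2.0, 2.0]})
        fc = se.compute_fold_changes(pheno, healthy, {"glucose": "EX_glc"})
        assert fc.fc["glucose"] == pytest.approx(5.0)

    def test_nonpositive_healthy_mean_is_error(self):
        pheno = pd.DataFrame({"x": [1.0]})
        healthy = pd.DataFrame({"x": [0.0]})
        with pytest.raises(ValueError, match="x"):
            se.compute_fold_changes(pheno, healthy, {"x": "EX_x"})

    def test_unmapped_metabolites_reported(self):
        pheno = pd.DataFrame({"a": [1.0], "b": [2.0]})
        healthy = pd.DataFrame({"a": [1.0], "b": [1.0]})
        fc = se.compute_fold_changes(pheno, healthy, {"a": "EX_a"})
        assert fc.unmapped == ["b"]
        assert "b" in fc.fc  # retained, not silently dropped

    def test_succinate_shift_recovered_from_default_cohort(
            self, default_cohort, preprocessed):
        """The +1 log2 phenotype-D shift appears as a fold change near 2."""
        truth = default_cohort.true_phenotypes
        members = [p for p in truth[truth == "D"].index
                   if p in preprocessed.raw_imputed.index]
        healthy = preprocessed.raw_imputed.loc[
            [h for h in default_cohort.healthy_ids
             if h in preprocessed.raw_imputed.index]]
        fc = se.compute_fold_changes(preprocessed.raw_imputed.loc[members],
                                     healthy, se.METABOLITE_EXCHANGE_MAP)
        assert 1.8 <= fc.fc["succinate"] <= 2.3


class TestApplyFoldChanges:
    def test_unity_leaves_bounds(self):
        tb = TransportBounds({"EX_A": (-4.0, -1.0), "EX_B": (0.5, 2.0)})
        fc = FoldChangeVector({"a": 1.0}, {"a": "EX_A"})
        out = apply_fold_changes(tb, fc)
        assert out == {"EX_A": (-4.0, -1.0), "EX_B": (0.5, 2.0)}

    def test_uptake_interval_scales_preserving_sign(self):
        tb = TransportBounds({"EX_A": (-4.0, -1.0)})
        fc = FoldChangeVector({"a": 2.0}, {"a": "EX_A"})
        assert apply_fold_changes(tb, fc)["EX_A"] == (-8.0, -2.0)

    def test_ordering_survives_any_sign_pattern(self):
        tb = TransportBounds({"EX_A": (-2.0, 3.0), "EX_B": (1.0, 5.0),
                              "EX_C": (-6.0, -2.0)})
        fc = FoldChangeVector({"a": 3.0, "b": 0.5, "c": 2.5},
                              {"a": "EX_A", "b": "EX_B", "c": "EX_C"})
        out = apply_fold_changes(tb, fc)
        assert all(lo <= hi for lo, hi in out.values())


class TestRelaxation:
    def test_feasible_candidate_untouched(self):
        net = chain_network()
        model = se.relax_to_feasible(net, {"EX_A": (-3.0, -1.0),
                                           "EX_B": (1.0, 3.0)})
        assert model.relaxation_log == []
        assert model.applied_bounds["EX_A"] == (-3.0, -1.0)

    def test_conflicting_uptake_relaxed_with_logged_slack(self):
        net = chain_network(internal_cap=1.0)
        model = se.relax_to_feasible(net, {"EX_A": (-8.0, -2.0),
                                           "EX_B": (0.0, 10.0)})
        assert len(model.relaxation_log) == 1
        entry = model.relaxation_log[0]
        assert entry["reaction"] == "EX_A"
        assert entry["slack"] == pytest.approx(1.0, abs=1e-6)
        assert se.check_feasibility(model.network).feasible

    def test_log_lists_only_changed_bounds(self, toy_network,
                                           baseline_samples):
        tb = se.transport_quartiles(baseline_samples,
                                    toy_network.exchange_ids())
        fc = FoldChangeVector({"glucose": 3.0},
                              {"glucose": "EX_glc"})  # extreme up-scaling
        constrained = apply_fold_changes(tb, fc)
        model = se.relax_to_feasible(toy_network, constrained)
        for entry in model.relaxation_log:
            assert model.applied_bounds[entry["reaction"]] != \
                constrained[entry["reaction"]]
        unchanged = set(constrained) - {e["reaction"]
                                        for e in model.relaxation_log}
        for rid in unchanged:
            assert model.applied_bounds[rid] == constrained[rid]


class TestSelfConsistency:
    def test_all_unity_fold_changes_feasible_without_relaxation(
            self, toy_network, baseline_samples):
        mapping = se.METABOLITE_EXCHANGE_MAP
        fc = FoldChangeVector({m: 1.0 for m in mapping}, dict(mapping))
        model = se.contextualize(toy_network, baseline_samples, fc)
        assert model.relaxation_log == []
        assert se.check_feasibility(model.network).feasible

    def test_doubling_uptake_fold_change_is_monotone(self, toy_network,
                                                     baseline_samples,
                                                     toy_catalog):
        """More available glucose can only widen glucose-consuming tasks."""
        task = next(t for t in toy_catalog if t.id == "atp_glycolysis")
        values = []
        for scale in (0.5, 1.0):
            fc = FoldChangeVector({"glucose": scale}, {"glucose": "EX_glc"})
            model = se.contextualize(toy_network, baseline_samples, fc)
            res = evaluate_task(model.network, task, model.base_network)
            assert res.status == "optimal"
            values.append(res.value)
        assert values[1] >= values[0] - 1e-9

    def test_two_phenotype_design_needs_no_relaxation(self, phenotype_models):
        for name, model in phenotype_models.items():
            assert se.check_feasibility(model.network).feasible, name
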