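"""The five model-extraction methods, against analytic and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import contextgem as cg
from contextgem import cbm, validation
from contextgem.mems import Task
from contextgem.model import build_model


class TestGimme:
    def test_parallel_paths_low_path_unused(self, parallel_model):
        expr = pd.Series({"high_path": 8.0, "low_path": 2.0})
        res = cg.gimme(parallel_model, expr, threshold=5.0, rmf="EX_B",
                       rmf_fraction=0.9)
        assert res.diagnostics["inconsistency_score"] == pytest.approx(0.0)
        assert res.kept_reactions == {"EX_A", "high_path", "EX_B"}

    def test_all_above_threshold_keeps_everything(self, parallel_model):
        expr = pd.Series({r: 9.0 for r in parallel_model.reaction_ids})
        res = cg.gimme(parallel_model, expr, threshold=5.0, rmf="EX_B")
        assert res.diagnostics["inconsistency_score"] == pytest.approx(0.0)
        assert res.kept_reactions == set(parallel_model.reaction_ids)

    def test_forced_low_path_score_is_flux_times_gap(self):
        model = build_model([
            ("EX_A", {"A": 1.0}, 0.0, 10.0),
            ("high_path", {"A": -1.0, "B": 1.0}, 0.0, 0.0),  # capacity 0
            ("low_path", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("EX_B", {"B": -1.0}, 0.0, 1000.0),
        ])
        expr = pd.Series({"high_path": 8.0, "low_path": 2.0})
        res = cg.gimme(model, expr, threshold=5.0, rmf="EX_B",
                       rmf_fraction=1.0)
        # forced flux 10 through the low path at gap (5 - 2) = 3
        assert res.diagnostics["inconsistency_score"] == pytest.approx(30.0)

    def test_rmf_attained_in_context_model(self, parallel_model):
        expr = pd.Series({"high_path": 8.0, "low_path": 2.0})
        res = cg.gimme(parallel_model, expr, threshold=5.0, rmf="EX_B",
                       rmf_fraction=0.9)
        ctx = res.context_model
        c = np.zeros(ctx.n_reactions)
        c[ctx.reaction_index("EX_B")] = 1.0
        opt = cg.fba(ctx, objective=c)
        assert opt.ok and opt.objective_value >= 0.9 * 10.0 - 1e-6

    def test_infeasible_rmf_advises(self, parallel_model):
        parallel_model.lower_bounds[3] = 2000.0  # EX_B lb > ub
        with pytest.raises(cbm.SolverError, match="functionality"):
            cg.gimme(parallel_model, pd.Series(dtype=float), 5.0, rmf="EX_B")


class TestImat:
    def test_competing_high_low(self, parallel_model):
        calls = pd.Series({"high_path": 1.0, "low_path": -1.0})
        res = cg.imat(parallel_model, calls, eps=1.0)
        oracle = validation.imat_objective_bruteforce(parallel_model, calls,
                                                      eps=1.0)
        assert res.diagnostics["objective_value"] == oracle == 2
        assert "low_path" not in res.kept_reactions

    def test_all_high_in_consistent_model(self, chain_model):
        calls = pd.Series(1.0, index=chain_model.reaction_ids)
        res = cg.imat(chain_model, calls, eps=1.0)
        assert res.diagnostics["objective_value"] == 3
        assert res.kept_reactions == set(chain_model.reaction_ids)

    def test_all_moderate_keeps_consistent_subnetwork(self, chain_model):
        calls = pd.Series(0.0, index=chain_model.reaction_ids)
        res = cg.imat(chain_model, calls)
        assert res.diagnostics["objective_value"] == 0
        assert res.kept_reactions == cg.consistent_subnetwork(chain_model)

    def test_reversible_high_counts_backward_flux(self):
        # flow is only possible B → A: EX_B supplies B (negative flux),
        # "rev" must run backwards, EX_A removes A (negative flux)
        model = build_model([
            ("EX_A", {"A": 1.0}, -10.0, 0.0),
            ("rev", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0),
            ("EX_B", {"B": -1.0}, -1000.0, 0.0),
        ])
        calls = pd.Series({"rev": 1.0})
        res = cg.imat(model, calls, eps=1.0)
        assert res.diagnostics["objective_value"] == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_exhaustive_enumeration(self, seed):
        model, calls, _, _ = validation.random_oracle_fixture(seed)
        res = cg.imat(model, calls, eps=1.0)
        oracle = validation.imat_objective_bruteforce(model, calls, eps=1.0)
        assert res.diagnostics["objective_value"] == oracle


class TestFastcore:
    def test_chain_core_forces_whole_path(self):
        model = build_model([
            ("in", {"A": 1.0}, 0.0, 10.0),
            ("AB", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("BC", {"B": -1.0, "C": 1.0}, 0.0, 1000.0),
            ("out", {"C": -1.0}, 0.0, 1000.0),
        ])
        res = cg.fastcore(model, {"AB"})
        assert res.kept_reactions == {"in", "AB", "BC", "out"}

    def test_empty_core_empty_extraction(self, parallel_model):
        assert cg.fastcore(parallel_model, set()).kept_reactions == set()

    def test_parallel_path_excluded(self, parallel_model):
        res = cg.fastcore(parallel_model, {"high_path"})
        assert res.kept_reactions == {"EX_A", "high_path", "EX_B"}

    def test_blocked_core_reaction_named(self):
        model = build_model([
            ("EX_A", {"A": 1.0}, 0.0, 10.0),
            ("EX_A2", {"A": -1.0}, 0.0, 10.0),
            ("dead", {"A": -1.0, "C": 1.0}, 0.0, 1000.0),
        ])
        with pytest.raises(ValueError, match="dead"):
            cg.fastcore(model, {"dead"})

    def test_output_consistent_and_minimal(self):
        for seed in range(6):
            model, _, _, core = validation.random_oracle_fixture(
                seed + 100, allow_reversible=False)
            res = cg.fastcore(model, core)
            assert core <= res.kept_reactions
            sub = cg.extract_submodel(model, res.kept_reactions)
            assert cg.consistent_subnetwork(sub) == res.kept_reactions
            oracle = validation.minimal_consistent_superset(model, core)
            assert len(res.kept_reactions) == len(oracle)


class TestInit:
    def test_weight_signs_select_paths(self, parallel_model):
        w = pd.Series({"EX_A": 0.1, "high_path": 1.0, "low_path": -1.0,
                       "EX_B": 0.1})
        res = cg.init_extract(parallel_model, w)
        assert res.kept_reactions == {"EX_A", "high_path", "EX_B"}

    def test_all_positive_keeps_everything(self, parallel_model):
        w = pd.Series(1.0, index=parallel_model.reaction_ids)
        res = cg.init_extract(parallel_model, w)
        assert res.kept_reactions == set(parallel_model.reaction_ids)

    def test_all_negative_keeps_nothing(self, parallel_model):
        w = pd.Series(-1.0, index=parallel_model.reaction_ids)
        res = cg.init_extract(parallel_model, w)
        assert res.kept_reactions == set()

    def test_kept_reactions_carry_flux(self, parallel_model):
        w = pd.Series({"EX_A": 0.1, "high_path": 1.0, "low_path": -1.0,
                       "EX_B": 0.1})
        res = cg.init_extract(parallel_model, w, eps=1e-4)
        ctx = res.context_model
        assert cg.consistent_subnetwork(ctx, eps=1e-4) == res.kept_reactions

    def test_production_allowance_relaxes_steady_state(self):
        # A is produced but has no consumer: strict steady state blocks the
        # producer, a positive metabolite weight with b_max > 0 rescues it
        model = build_model([("make_A", {"A": 1.0}, 0.0, 10.0)])
        w = pd.Series({"make_A": 1.0})
        strict = cg.init_extract(model, w)
        assert strict.kept_reactions == set()
        relaxed = cg.init_extract(model, w, metabolite_weights={"A": 1.0},
                                  production_allowance=1e-2, eps=1e-3)
        assert relaxed.kept_reactions == {"make_A"}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_enumeration(self, seed):
        model, _, weights, _ = validation.random_oracle_fixture(
            seed + 200, allow_reversible=False)
        res = cg.init_extract(model, weights)
        best, best_sets = validation.init_bruteforce(model, weights)
        achieved = float(sum(weights[r] for r in res.kept_reactions))
        assert achieved == pytest.approx(best, abs=1e-9)
        assert frozenset(res.kept_reactions) in best_sets


class TestTinit:
    def test_task_overrides_negative_weight(self):
        model = build_model([
            ("EX_A", {"A": 1.0}, 0.0, 10.0),
            ("path", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        ])
        w = pd.Series({"EX_A": 0.0, "path": -1.0})
        without = cg.init_extract(model, w)
        assert "path" not in without.kept_reactions
        with_task = cg.tinit(model, w, tasks=[Task("make_B",
                                                   inputs={"A": 10.0},
                                                   outputs={"B": 1.0})])
        assert "path" in with_task.kept_reactions

    def test_empty_task_list_reduces_to_init(self, parallel_model):
        w = pd.Series({"EX_A": 0.1, "high_path": 1.0, "low_path": -1.0,
                       "EX_B": 0.1})
        assert cg.tinit(parallel_model, w, tasks=[]).kept_reactions == \
            cg.init_extract(parallel_model, w).kept_reactions

    def test_unknown_task_metabolite_errors(self, parallel_model):
        task = Task("bad", outputs={"UNOBTAINIUM": 1.0})
        with pytest.raises(KeyError, match="UNOBTAINIUM"):
            cg.tinit(parallel_model, pd.Series(dtype=float), tasks=[task])

    def test_infeasible_task_named(self, parallel_model):
        task = Task("impossible", outputs={"B": 1e6})
        with pytest.raises(ValueError, match="impossible"):
            cg.tinit(parallel_model, pd.Series(dtype=float), tasks=[task])

    def test_tasks_read_from_csv(self, tmp_path):
        path = tmp_path / "tasks.csv"
        path.write_text("task_id,inputs,outputs\n"
                        "t1,A:10;C:2,B:1\n"
                        "t2,,B:0.5\n")
        tasks = cg.read_tasks(path)
        assert tasks[0].inputs == {"A": 10.0, "C": 2.0}
        assert tasks[0].outputs == {"B": 1.0}
        assert tasks[1].inputs == {}


class TestCommonInvariants:
    @pytest.mark.parametrize("seed", [3, 14])
    def test_extraction_is_deterministic_and_well_formed(self, seed):
        model, calls, weights, core = validation.random_oracle_fixture(seed)
        runs = []
        for _ in range(2):
            kept = {
                "imat": cg.imat(model, calls, eps=1.0).kept_reactions,
                "fastcore": cg.fastcore(
                    model, core & cg.consistent_subnetwork(model)
                ).kept_reactions,
                "init": cg.init_extract(model, weights).kept_reactions,
            }
            runs.append(kept)
        assert runs[0] == runs[1]
        for method, kept in runs[0].items():
            assert kept <= set(model.reaction_ids), method

    def test_context_model_equals_extract_submodel(self, parallel_model):
        calls = pd.Series({"high_path": 1.0, "low_path": -1.0})
        res = cg.imat(parallel_model, calls, eps=1.0)
        rebuilt = cg.extract_submodel(parallel_model, res.kept_reactions,
                                      model_id=res.context_model.model_id)
        assert rebuilt == res.context_model
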