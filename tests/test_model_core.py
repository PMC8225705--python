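"""Model container, GPR grammar, submodel extraction, file round-trips."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import contextgem as cg
from contextgem.gpr import GPRParseError, parse_gpr
from contextgem.io import ModelFormatError
from contextgem.model import build_model


class TestGPR:
    @pytest.mark.parametrize("rule, genes", [
        ("g1", {"g1"}),
        ("g1 and g2", {"g1", "g2"}),
        ("g1 AND g2 Or g3", {"g1", "g2", "g3"}),
        ("(g1 and g2) or (g3 and g4)", {"g1", "g2", "g3", "g4"}),
    ])
    def test_parse_collects_genes(self, rule, genes):
        assert parse_gpr(rule).genes() == frozenset(genes)

    def test_or_binds_weaker_than_and(self):
        tree = parse_gpr("g1 and g2 or g3")
        assert tree.op == "or"
        assert {c.op for c in tree.children} == {"and", "gene"}

    def test_empty_rule_is_none(self):
        assert parse_gpr("") is None
        assert parse_gpr("   ") is None
        assert parse_gpr(None) is None

    @pytest.mark.parametrize("rule", ["g1 and", "(g1 or g2", "and g1",
                                      "g1 g2", "()"])
    def test_malformed_rules_raise(self, rule):
        with pytest.raises(GPRParseError):
            parse_gpr(rule)

    def test_roundtrip_through_string(self):
        rule = "(g1 and g2) or g3 or (g4 and (g5 or g6))"
        tree = parse_gpr(rule)
        assert parse_gpr(tree.to_string()) == tree

    @pytest.mark.parametrize("rule, values, expected", [
        ("g1 and g2", {"g1": 3, "g2": 7}, 3),          # AND = min
        ("g1 or g2", {"g1": 3, "g2": 7}, 7),           # OR = max
        ("(g1 and g2) or g3", {"g1": 3, "g2": 7, "g3": 5}, 5),
        ("g1 or g2", {"g1": 3}, 3),                    # missing dropped from OR
        ("g1 and g2", {"g1": 3}, None),                # missing kills AND
    ])
    def test_min_max_evaluation(self, rule, values, expected):
        assert parse_gpr(rule).value(values) == expected


class TestValidate:
    def test_valid_model_empty_report(self, chain_model):
        assert cg.validate_model(chain_model) == []

    def test_bound_violation_names_reaction(self, chain_model):
        chain_model.lower_bounds[1] = 5.0
        chain_model.upper_bounds[1] = 1.0
        report = cg.validate_model(chain_model)
        assert len(report) == 1 and "A_to_B" in report[0]

    def test_wrong_S_shape_reported(self, chain_model):
        chain_model.S = sp.csc_matrix(np.zeros((5, 3)))
        assert any("5 rows" in v for v in cg.validate_model(chain_model))

    def test_dangling_gene_reported(self, labelled_model):
        labelled_model.gene_ids = ["g1", "g2", "g3"]  # drop g4
        report = cg.validate_model(labelled_model)
        assert any("g4" in v and "low_path" in v for v in report)


class TestExtractSubmodel:
    def test_keep_all_is_identity(self, labelled_model):
        sub = cg.extract_submodel(labelled_model, labelled_model.reaction_ids,
                                  model_id=labelled_model.model_id)
        assert sub == labelled_model

    def test_keep_none_is_empty(self, labelled_model):
        sub = cg.extract_submodel(labelled_model, [])
        assert sub.n_reactions == 0 and sub.n_metabolites == 0
        assert sub.gene_ids == []

    def test_orphan_metabolites_pruned(self, chain_model):
        # dropping A→B leaves EX_A (touches A) and EX_B (touches B):
        # hand enumeration says both metabolites stay referenced
        sub = cg.extract_submodel(chain_model, ["EX_A", "EX_B"])
        assert set(sub.metabolite_ids) == {"A", "B"}
        # dropping EX_A and A→B leaves only EX_B: A becomes an orphan
        sub2 = cg.extract_submodel(chain_model, ["EX_B"])
        assert sub2.metabolite_ids == ["B"]

    def test_annotations_carried_over(self, labelled_model):
        sub = cg.extract_submodel(labelled_model, ["high_path", "EX_A"])
        j = sub.reaction_index("high_path")
        assert sub.subsystems[j] == "glycolysis"
        assert sub.gpr_string(j) == "(g1 and g2) or g3"
        assert sub.gene_ids == ["g1", "g2", "g3"]

    def test_idempotent(self, labelled_model):
        keep = ["EX_A", "high_path", "EX_B"]
        once = cg.extract_submodel(labelled_model, keep, model_id="m")
        twice = cg.extract_submodel(once, keep, model_id="m")
        assert once == twice

    def test_unknown_reaction_listed(self, chain_model):
        with pytest.raises(KeyError, match="nope"):
            cg.extract_submodel(chain_model, ["EX_A", "nope"])


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["sbml", "json"])
    def test_toy_fixture_roundtrip(self, labelled_model, tmp_path, fmt):
        path = tmp_path / f"m.{fmt}"
        cg.write_model(labelled_model, path, format=fmt)
        assert cg.read_model(path, format=fmt) == labelled_model

    @pytest.mark.parametrize("fmt", ["sbml", "json"])
    @pytest.mark.parametrize("seed", range(8))
    def test_random_models_roundtrip(self, tmp_path, fmt, seed):
        rng = np.random.default_rng(seed)
        model = cg.make_toy_model(int(rng.integers(1, 5)),
                                  int(rng.integers(1, 5)), seed=seed)
        # flip some bounds to exercise reversibility and negative bounds
        for j in rng.choice(model.n_reactions,
                            size=model.n_reactions // 3, replace=False):
            model.lower_bounds[j] = -model.upper_bounds[j]
        path = tmp_path / f"m{seed}.{fmt}"
        cg.write_model(model, path, format=fmt)
        assert cg.read_model(path, format=fmt) == model

    @pytest.mark.parametrize("fmt", ["sbml", "json"])
    def test_non_ascii_and_hostile_ids_roundtrip(self, tmp_path, fmt):
        model = build_model(
            [("R β-ox/1", {"acetyl-CoA[c]": 1.0}, -5.0, 5.0),
             ("excrétion", {"acetyl-CoA[c]": -1.0}, 0.0, 10.0)],
            gprs={"R β-ox/1": "Gène_1 and g2:variant"},
            subsystems={"R β-ox/1": "β-oxidation"},
            model_id="unicode model")
        path = tmp_path / f"u.{fmt}"
        cg.write_model(model, path, format=fmt)
        assert cg.read_model(path, format=fmt) == model

    def test_empty_subsystems_ok(self, chain_model, tmp_path):
        path = tmp_path / "plain.xml"
        cg.write_model(chain_model, path, format="sbml")
        again = cg.read_model(path)
        assert again.subsystems == ["", "", ""]

    def test_json_missing_bounds_is_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"id": "m", "metabolites": [], '
                        '"reactions": [{"id": "r1", "metabolites": {}}]}')
        with pytest.raises(ModelFormatError, match="r1"):
            cg.read_model(path)

    def test_sbml_parse_failure_names_problem(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<notsbml/>")
        with pytest.raises(ModelFormatError, match="sbml"):
            cg.read_model(path, format="sbml")


class TestCobraCrossValidation:
    """Independent check of the SBML writer/reader against cobrapy."""

    def test_cobra_reads_our_sbml(self, labelled_model, tmp_path):
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "ours.xml"
        cg.write_model(labelled_model, path, format="sbml")
        cm = cobra.io.read_sbml_model(str(path))
        assert len(cm.reactions) == labelled_model.n_reactions
        assert len(cm.metabolites) == labelled_model.n_metabolites
        rxn = cm.reactions.get_by_id("high_path")
        assert rxn.lower_bound == 0.0 and rxn.upper_bound == 1000.0
        assert sorted(g.id for g in rxn.genes) == ["g1", "g2", "g3"]

    def test_we_read_cobra_sbml(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("cross")
        m_a = cobra.Metabolite("A_c", compartment="c")
        r1 = cobra.Reaction("UP", lower_bound=0, upper_bound=10)
        r1.add_metabolites({m_a: 1.0})
        r2 = cobra.Reaction("OUT", lower_bound=-3, upper_bound=1000)
        r2.add_metabolites({m_a: -1.0})
        r2.gene_reaction_rule = "gA and gB"
        cm.add_reactions([r1, r2])
        cm.objective = "OUT"
        path = tmp_path / "cobra.xml"
        cobra.io.write_sbml_model(cm, str(path))
        ours = cg.read_model(path, format="sbml")
        assert ours.n_reactions == 2 and ours.n_metabolites == 1
        j = ours.reaction_index("OUT")
        assert ours.lower_bounds[j] == -3.0
        assert ours.gpr_rules[j].genes() == frozenset({"gA", "gB"})
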