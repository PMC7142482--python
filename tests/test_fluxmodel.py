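import itertools
import re

import numpy as np
import pandas as pd
import pytest

from nmrflux import fluxmodel as fm
from nmrflux.fluxmodel import (
    FluxError,
    GprSyntaxError,
    MetabolicModel,
    ModelValidationError,
    context_subnetwork,
    eval_gpr,
    fba,
    gimme,
    parse_gpr,
    reaction_expression,
    read_model,
    write_model,
)
from nmrflux.synthdata import TOY_NETWORK_KINDS, make_expression_profile, make_toy_network
from oracles import fba_vertex_oracle, gimme_bruteforce


class TestGprParser:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("g1", ("gene", "g1")),
            ("g1 and g2", ("and", [("gene", "g1"), ("gene", "g2")])),
            ("g1 AND (g2 OR g3)", ("and", [("gene", "g1"), ("or", [("gene", "g2"), ("gene", "g3")])])),
            ("(g1)", ("gene", "g1")),
            ("", None),
            (None, None),
        ],
    )
    def test_grammar(self, rule, expected):
        assert parse_gpr(rule) == expected

    @pytest.mark.parametrize("rule", ["g1 and or g2", "g1 and", "(g1", "g1)", "and g1"])
    def test_malformed_rules_report_position(self, rule):
        with pytest.raises(GprSyntaxError) as exc:
            parse_gpr(rule)
        assert exc.value.pos >= 0

    def test_truth_table_oracle_up_to_four_genes(self):
        """min/max evaluation agrees with boolean logic on all 0/100 assignments."""
        genes = ["g1", "g2", "g3", "g4"]
        rules = [
            "g1 and g2",
            "g1 or g2",
            "(g1 or g2) and g3",
            "g1 and (g2 or (g3 and g4))",
            "(g1 and g2) or (g3 and g4)",
        ]
        for rule in rules:
            tree = parse_gpr(rule)
            pyrule = rule.replace("AND", "and").replace("OR", "or")
            for bits in itertools.product([0, 1], repeat=4):
                values = {g: 100.0 * b for g, b in zip(genes, bits)}
                env = {g: bool(b) for g, b in zip(genes, bits)}
                expected = 100.0 * eval(pyrule, {}, env)  # independent boolean route
                assert eval_gpr(tree, values) == expected


class TestReactionExpression:
    def test_and_is_min_or_is_max(self):
        m = make_toy_network("branched")
        m2 = m.copy()
        m2.gpr[1] = "g1 and g2"
        m2.gpr[2] = "g1 or g2"
        expr = reaction_expression(m2, {"g1": 100.0, "g2": 0.0})
        assert expr["route1"] == 0.0
        assert expr["route2"] == 100.0

    def test_nested_rule(self):
        m = make_toy_network("branched")
        m2 = m.copy()
        m2.genes = ["g1", "g2", "g3"]
        m2.gpr[1] = "(g1 or g2) and g3"
        expr = reaction_expression(m2, {"g1": 0.0, "g2": 100.0, "g3": 100.0})
        assert expr["route1"] == 100.0

    def test_empty_rule_is_unconstrained_marker(self):
        m = make_toy_network("chain")
        expr = reaction_expression(m, {"g_ab": 100.0})
        assert expr["uptake"] is None and expr["biomass"] is None


class TestModelValidation:
    def test_bound_inversion_and_bad_gene_reported_together(self):
        with pytest.raises(ModelValidationError) as exc:
            MetabolicModel(
                metabolites=["A"],
                reactions=["r1", "r2"],
                S=np.array([[1.0, -1.0]]),
                lb=np.array([5.0, 0.0]),
                ub=np.array([1.0, 10.0]),
                gpr=["", "ghost_gene"],
                genes=[],
                objective_reaction="r2",
            )
        msg = str(exc.value)
        assert "lb > ub" in msg and "undeclared genes" in msg

    def test_unknown_objective_rejected(self):
        with pytest.raises(ModelValidationError, match="objective"):
            MetabolicModel(["A"], ["r1"], np.array([[1.0]]), np.array([0.0]),
                           np.array([1.0]), [""], [], "nope")


class TestFba:
    def test_chain_bottleneck(self):
        sol = fba(make_toy_network("chain"))
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_closed_exchanges_give_zero(self):
        m = make_toy_network("chain")
        m.ub[0] = 0.0
        sol = fba(m)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_parallel_routes_add(self):
        sol = fba(make_toy_network("branched"))
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_matches_vertex_enumeration_oracle(self, toy_model):
        sol = fba(toy_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(fba_vertex_oracle(toy_model), abs=1e-6)

    def test_mass_balance_and_bounds(self, toy_model):
        sol = fba(toy_model)
        v = sol.fluxes.to_numpy()
        assert np.max(np.abs(toy_model.S @ v)) <= 1e-6
        assert np.all(v >= toy_model.lb - 1e-9) and np.all(v <= toy_model.ub + 1e-9)

    def test_unbounded_reported_as_status(self):
        m = make_toy_network("chain")
        m.ub[:] = np.inf
        sol = fba(m)
        assert sol.status == "unbounded"


class TestGimme:
    def profiles(self, model):
        """All-present, all-absent per gene subsets of interest."""
        return {
            "all": make_expression_profile(model, set(model.genes)),
            "none": make_expression_profile(model, set()),
        }

    def test_all_high_expression_gives_zero_score(self, toy_model):
        expr = reaction_expression(toy_model, self.profiles(toy_model)["all"])
        sol = gimme(toy_model, expr, objective_fraction=0.9)
        assert sol.status == "optimal"
        assert sol.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert sol.objective_value >= 0.9 * fba(toy_model).objective_value - 1e-6

    def test_preferred_route_carries_all_flux(self):
        m = make_toy_network("branched")
        expr = reaction_expression(m, make_expression_profile(m, {"g1"}))
        sol = gimme(m, expr, objective_fraction=0.4)  # target 4 <= route1 capacity
        assert sol.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["route1"] == pytest.approx(4.0, abs=1e-6)
        assert sol.fluxes["route2"] == pytest.approx(0.0, abs=1e-9)

    def test_forced_low_expression_route_is_scored(self):
        m = make_toy_network("branched")
        expr = reaction_expression(m, make_expression_profile(m, {"g1"}))
        # target 5 exceeds route1 capacity 4: one unit must use the absent route
        sol = gimme(m, expr, expr_cutoff=50.0, objective_fraction=0.5)
        assert sol.fluxes["route2"] == pytest.approx(1.0, abs=1e-6)
        assert sol.inconsistency_score == pytest.approx(50.0 * 1.0, abs=1e-6)

    @pytest.mark.parametrize("present", [frozenset(), frozenset({"g1"}), frozenset({"g2"}), None])
    def test_matches_bruteforce_enumeration(self, toy_model, present):
        genes = set(toy_model.genes)
        if present is None:
            present = set(list(sorted(genes))[::2])
        expr = reaction_expression(toy_model, make_expression_profile(toy_model, set(present) & genes))
        for fraction in (0.3, 0.6, 0.9):
            sol = gimme(toy_model, expr, objective_fraction=fraction)
            expected = gimme_bruteforce(toy_model, expr, 50.0, fraction)
            assert sol.status == "optimal"
            assert sol.inconsistency_score == pytest.approx(expected, abs=1e-6)

    def test_score_monotone_in_objective_fraction(self):
        m = make_toy_network("branched")
        expr = reaction_expression(m, make_expression_profile(m, {"g1"}))
        scores = []
        for fraction in np.linspace(0.1, 1.0, 10):
            scores.append(gimme(m, expr, objective_fraction=fraction).inconsistency_score)
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_reversible_reaction_penalty_uses_absolute_flux(self):
        m = make_toy_network("glutathione")
        # only the oxidation branch available: flux through reversible GTHOXID
        expr = reaction_expression(m, make_expression_profile(m, {"g_oplah", "g_oxct"}))
        sol = gimme(m, expr, objective_fraction=0.4)
        assert sol.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["OXPSYN"] > 1e-6
        assert abs(sol.fluxes["GTHOXID"]) <= 1e-9

    def test_zero_objective_model_rejected(self):
        m = make_toy_network("chain")
        m.ub[0] = 0.0
        expr = reaction_expression(m, make_expression_profile(m, set(m.genes)))
        with pytest.raises(FluxError, match="maintained|optimum"):
            gimme(m, expr)


class TestContextSubnetwork:
    def test_full_chain_retained_without_dead_ends(self):
        m = make_toy_network("chain")
        sub, dead = context_subnetwork(m, fba(m))
        assert sub.reactions == m.reactions
        assert dead == []

    def test_zero_solution_gives_empty_subnetwork(self):
        m = make_toy_network("chain")
        sol = fba(m)
        zero = fm.FluxSolution(sol.fluxes * 0.0, 0.0, "optimal")
        sub, dead = context_subnetwork(m, zero)
        assert sub.reactions == [] and sub.metabolites == [] and dead == []

    def test_unused_route_absent_from_subnetwork(self):
        m = make_toy_network("branched")
        expr = reaction_expression(m, make_expression_profile(m, {"g1"}))
        sol = gimme(m, expr, objective_fraction=0.4)
        sub, _ = context_subnetwork(m, sol)
        assert "route2" not in sub.reactions and "route1" in sub.reactions

    def test_dead_end_metabolite_flagged(self):
        m = make_toy_network("mini_tca")
        # truncated flow: succinate produced but not consumed
        v = pd.Series(0.0, index=m.reactions)
        v[["EX_cit", "ACONT", "ICDH", "AKGD"]] = 2.0
        sol = fm.FluxSolution(v, 0.0, "optimal")
        sub, dead = context_subnetwork(m, sol)
        assert dead == ["succ"]  # produced by AKGD only; cit has exchange + consumption


class TestModelIO:
    def test_json_round_trip(self, toy_model, tmp_path):
        p = tmp_path / "m.json"
        write_model(toy_model, p, format="json")
        back = read_model(p)
        assert back.reactions == toy_model.reactions
        assert back.metabolites == toy_model.metabolites
        np.testing.assert_allclose(back.S, toy_model.S)
        np.testing.assert_allclose(back.lb, toy_model.lb)
        assert back.gpr == toy_model.gpr
        assert back.objective_reaction == toy_model.objective_reaction

    def test_sbml_fbc_round_trip(self, toy_model, tmp_path):
        p = tmp_path / "m.xml"
        write_model(toy_model, p, format="sbml_fbc")
        back = read_model(p)
        assert back.reactions == toy_model.reactions
        assert back.metabolites == toy_model.metabolites
        np.testing.assert_allclose(back.S, toy_model.S)
        np.testing.assert_allclose(back.lb, toy_model.lb)
        np.testing.assert_allclose(back.ub, toy_model.ub)
        assert [parse_gpr(g) for g in back.gpr] == [parse_gpr(g) for g in toy_model.gpr]
        assert back.genes == sorted(toy_model.genes)
        assert back.objective_reaction == toy_model.objective_reaction

    def test_sbml_agrees_with_cobra_reader(self, tmp_path):
        """Cross-check our SBML writer/reader against the cobra toolkit."""
        cobra = pytest.importorskip("cobra")
        m = make_toy_network("mini_tca")
        p = tmp_path / "tca.xml"
        write_model(m, p, format="sbml_fbc")
        cm = cobra.io.read_sbml_model(str(p))
        assert sorted(r.id for r in cm.reactions) == sorted(f"R_{r}" for r in m.reactions) or \
               sorted(r.id for r in cm.reactions) == sorted(m.reactions)
        sol = cm.optimize()
        assert sol.objective_value == pytest.approx(fba(m).objective_value, abs=1e-6)

    def test_json_lb_gt_ub_rejected(self, tmp_path):
        m = make_toy_network("chain")
        data = fm.model_to_dict(m)
        data["reactions"][0]["lower_bound"] = 99.0
        p = tmp_path / "bad.json"
        p.write_text(pd.io.json.ujson_dumps(data) if hasattr(pd.io.json, "ujson_dumps") else __import__("json").dumps(data))
        with pytest.raises(ModelValidationError, match="lb > ub"):
            read_model(p)

    def test_sbml_missing_fbc_bounds_named(self, tmp_path):
        m = make_toy_network("chain")
        p = tmp_path / "m.xml"
        write_model(m, p, format="sbml_fbc")
        text = p.read_text()
        stripped = re.sub(r'fbc:lowerFluxBound="[^"]*"\s*', "", text)
        p2 = tmp_path / "nobounds.xml"
        p2.write_text(stripped)
        with pytest.raises(ModelValidationError, match="lowerFluxBound"):
            read_model(p2)

    def test_flux_csv_contains_penalty_annotation(self, tmp_path):
        m = make_toy_network("branched")
        expr = reaction_expression(m, make_expression_profile(m, {"g1"}))
        sol = gimme(m, expr, objective_fraction=0.4)
        p = tmp_path / "flux.csv"
        fm.write_flux_csv(sol, p, expr, 50.0)
        df = pd.read_csv(p, index_col=0)
        assert bool(df.loc["route2", "penalized"])
        assert not bool(df.loc["route1", "penalized"])
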