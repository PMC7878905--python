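"""Toy metabolic models: LP maxima, knockouts, direction calls, concordance."""

import math
from fractions import Fraction

import numpy as np
import pytest

from uromet.fba import (
    MetabolicModel,
    Reaction,
    apply_knockout,
    concordance_binomial_test,
    fba_maximize,
    healthy_reference,
    load_model,
    model_from_dict,
    predict_direction,
    save_model,
)
from uromet.simulate import toy_metabolic_models


@pytest.fixture(scope="module")
def models():
    return toy_metabolic_models()


class TestModelLoading:
    def test_degrader_fixture_shape(self, models):
        m = models["degrader"]
        assert len(m.reactions) == 4
        assert len(m.metabolites) == 3
        S, balanced = m.stoichiometric_matrix()
        assert S.shape == (2, 4)  # met[u] is a boundary species

    def test_json_round_trip(self, models, tmp_path):
        path = tmp_path / "m.json"
        save_model(models["capacity-limited"], path)
        back = load_model(path)
        assert back.reactions == models["capacity-limited"].reactions
        assert back.metabolites == models["capacity-limited"].metabolites

    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            model_from_dict(
                {
                    "metabolites": [{"id": "a", "compartment": "c"}],
                    "reactions": [
                        {"id": "r", "stoichiometry": {"ghost": 1}, "upper_bound": 1}
                    ],
                }
            )

    def test_bad_bounds_and_duplicate_ids_rejected(self):
        met = [{"id": "a", "compartment": "c"}]
        with pytest.raises(ValueError, match="lb > ub"):
            model_from_dict(
                {"metabolites": met,
                 "reactions": [{"id": "r", "stoichiometry": {"a": 1},
                                "lower_bound": 2, "upper_bound": 1}]}
            )
        with pytest.raises(ValueError, match="duplicate"):
            model_from_dict(
                {"metabolites": met,
                 "reactions": [
                     {"id": "r", "stoichiometry": {"a": 1}, "upper_bound": 1},
                     {"id": "r", "stoichiometry": {"a": -1}, "upper_bound": 1},
                 ]}
            )


class TestFbaMaximize:
    def test_linear_chain_limited_by_uptake(self, models):
        res = fba_maximize(models["producer"], "EX_met[u]")
        assert res.status == "optimal"
        assert res.value == pytest.approx(10.0, abs=1e-9)

    def test_unbounded_cycle_detected(self):
        model = MetabolicModel(
            "cycle",
            {"a": "c", "b": "c"},
            [
                Reaction("f", {"a": -1, "b": 1}, -math.inf, math.inf),
                Reaction("g", {"b": -1, "a": 1}, -math.inf, math.inf),
            ],
        )
        assert fba_maximize(model, "f").status == "unbounded"

    def test_forced_imbalance_infeasible(self):
        model = MetabolicModel(
            "stuck",
            {"a": "c"},
            [Reaction("in", {"a": 1}, 5.0, 5.0), Reaction("out", {"a": -1}, 0.0, 1.0)],
        )
        assert fba_maximize(model, "out").status == "infeasible"

    def test_mass_balance_of_optimum(self, models):
        for m in models.values():
            S, _ = m.stoichiometric_matrix()
            res = fba_maximize(m, "EX_met[u]")
            assert res.status == "optimal"

    def test_unknown_objective(self, models):
        with pytest.raises(KeyError):
            fba_maximize(models["producer"], "nope")

    def test_agrees_with_cobrapy_oracle(self, models):
        import cobra

        for name in ("degrader", "producer"):
            m = models[name]
            cm = cobra.Model(name)
            mets = {
                mid: cobra.Metabolite(mid.replace("[", "_").replace("]", ""))
                for mid, comp in m.metabolites.items()
                if comp not in ("u", "bc")
            }
            for r in m.reactions:
                rxn = cobra.Reaction(r.id.replace("[", "_").replace("]", ""))
                cm.add_reactions([rxn])
                rxn.add_metabolites(
                    {mets[k]: v for k, v in r.stoichiometry.items() if k in mets}
                )
                rxn.bounds = (r.lower_bound, min(r.upper_bound, 1e6))
            cm.objective = "EX_met_u"
            sol = cm.optimize()
            ours = fba_maximize(m, "EX_met[u]")
            assert sol.status == "optimal"
            assert ours.value == pytest.approx(sol.objective_value, abs=1e-6)


class TestKnockout:
    def test_bounds_zeroed(self, models):
        ko = apply_knockout(models["degrader"], "GDEG")
        rxn = ko.reaction("DEG_met")
        assert rxn.lower_bound == rxn.upper_bound == 0.0

    def test_all_organs_zeroed(self):
        model = MetabolicModel(
            "two-organ",
            {"a": "c"},
            [
                Reaction("in", {"a": 1}, 0, 10),
                Reaction("liver_r", {"a": -1}, 0, 5, ("G",), "liver"),
                Reaction("kidney_r", {"a": -1}, 0, 5, ("G",), "kidney"),
            ],
        )
        ko = apply_knockout(model, "G")
        assert ko.reaction("liver_r").upper_bound == 0.0
        assert ko.reaction("kidney_r").upper_bound == 0.0

    def test_isozyme_gene_refused(self):
        model = MetabolicModel(
            "iso",
            {"a": "c"},
            [Reaction("in", {"a": 1}, 0, 10), Reaction("r", {"a": -1}, 0, 5, ("G1", "G2"))],
        )
        with pytest.raises(ValueError, match="isozyme"):
            apply_knockout(model, "G1")

    def test_unknown_gene(self, models):
        with pytest.raises(KeyError):
            apply_knockout(models["degrader"], "NOPE")

    def test_knockout_never_increases_objective_without_reconstraint(self, models):
        for name, m in models.items():
            gene = sorted(m.genes())[0]
            base = fba_maximize(m, "EX_met[u]").value
            ko = fba_maximize(apply_knockout(m, gene), "EX_met[u]").value
            assert ko <= base + 1e-9


class TestHealthyReference:
    def test_degrader_enzyme_pinned_at_capacity(self, models):
        healthy = healthy_reference(models["degrader"], "GDEG")
        rxn = healthy.reaction("DEG_met")
        assert rxn.lower_bound == rxn.upper_bound == pytest.approx(8.0, abs=1e-9)

    def test_producer_enzyme_pinned_at_uptake_limit(self, models):
        healthy = healthy_reference(models["producer"], "GPROD")
        rxn = healthy.reaction("SYN_met")
        assert rxn.lower_bound == rxn.upper_bound == pytest.approx(10.0, abs=1e-9)

    def test_blocked_gene_pinned_at_zero(self):
        model = MetabolicModel(
            "blocked",
            {"a": "c", "b": "c"},
            [
                Reaction("r", {"a": -1, "b": 1}, 0, 5, ("G",)),  # no source of a
                Reaction("sink", {"b": -1}, 0, 10),
            ],
        )
        healthy = healthy_reference(model, "G")
        assert healthy.reaction("r").upper_bound == pytest.approx(0.0, abs=1e-9)


class TestPredictDirection:
    def test_degrader_urine_up(self, models):
        pred = predict_direction(models["degrader"], "GDEG", "met", "urine")
        assert (pred.healthy_flux, pred.knockout_flux) == pytest.approx((2.0, 10.0))
        assert pred.direction == "up"

    def test_producer_urine_down(self, models):
        pred = predict_direction(models["producer"], "GPROD", "met", "urine")
        assert (pred.healthy_flux, pred.knockout_flux) == pytest.approx((10.0, 0.0))
        assert pred.direction == "down"

    def test_capacity_limited_urine_unchanged_blood_up(self, models):
        m = models["capacity-limited"]
        urine = predict_direction(m, "GCAP", "met", "urine")
        blood = predict_direction(m, "GCAP", "met", "blood")
        assert urine.direction == "unchanged"
        assert (urine.healthy_flux, urine.knockout_flux) == pytest.approx((1.0, 1.0))
        assert blood.direction == "up"
        assert blood.knockout_flux > blood.healthy_flux

    def test_direction_classes_cover_table_patterns(self, models):
        # the three fixtures deterministically reproduce the up / down /
        # unchanged direction classes of the knockout-vs-observation table
        calls = {
            name: predict_direction(m, sorted(m.genes())[0], "met", "urine").direction
            for name, m in models.items()
        }
        assert calls == {
            "degrader": "up", "producer": "down", "capacity-limited": "unchanged"
        }


class TestConcordance:
    def test_eight_of_nine_enumeration_oracle(self):
        # exact tail: P(X >= 8 | n=9, p=1/3) = (9*2 + 1)/3^9 = 19/19683
        exact = Fraction(0)
        for x in (8, 9):
            exact += Fraction(math.comb(9, x)) * Fraction(1, 3) ** x * Fraction(2, 3) ** (9 - x)
        assert exact == Fraction(19, 19683)
        n_match, p = concordance_binomial_test(
            ["up"] * 8 + ["down"], ["up"] * 9, null_p=1 / 3
        )
        assert n_match == 8
        assert p == pytest.approx(float(exact), rel=1e-12)

    def test_degenerate_null_probabilities(self):
        assert concordance_binomial_test(["up"] * 4, ["up"] * 4, null_p=1.0)[1] == 1.0
        assert concordance_binomial_test(["up"] * 3, ["down"] * 3, null_p=0.5)[1] == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            concordance_binomial_test(["up"], ["up", "down"], 0.5)
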