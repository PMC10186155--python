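"""Model containers, SBML/JSON round-trips and reversible splitting."""

import numpy as np
import pytest
from scipy.optimize import linprog

from nidleflux import fixtures, load_model, net_fluxes, split_reversible
from nidleflux.model_io import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    save_model,
    stoichiometric_matrix,
)


def six_reaction_model():
    """Toy with 6 reactions of which exactly one is a boundary exchange."""
    mets = {
        "A": Metabolite("A", "C6H12O6"),
        "B": Metabolite("B", "C3H4O3"),
        "C": Metabolite("C", "C3H4O3"),
        "Q": Metabolite("Q", "H2O"),
    }
    rxns = {
        "EX_A": Reaction("EX_A", {"A": 1.0}, 0.0, 10.0),
        "R1": Reaction("R1", {"A": -1.0, "B": 1.0, "Q": 1.0}, 0.0, 1000.0, gpr="g1"),
        "R2": Reaction("R2", {"B": -1.0, "C": 1.0}, -1000.0, 1000.0, gpr="g1 or g2"),
        "R3": Reaction("R3", {"A": -1.0, "C": 1.0}, 0.0, 1000.0, gpr="g3 and g4"),
        "R4": Reaction("R4", {"Q": -1.0, "C": -1.0, "B": 1.0}, -3.0, 8.0),
        "BIOMASS": Reaction("BIOMASS", {"C": -1.0, "Q": -2.0}, 0.0, 1000.0),
    }
    return MetabolicModel(mets, rxns, "BIOMASS", id="six")


class TestLoadModel:
    def test_json_round_trip_preserves_structure(self, tmp_path):
        model = six_reaction_model()
        path = tmp_path / "six.json"
        save_model(model, path)
        loaded = load_model(path)
        assert len(loaded.reactions) == 6
        assert sum(r.is_exchange for r in loaded.reactions.values()) == 1
        assert loaded.biomass_reaction_id == "BIOMASS"
        for rid, rxn in model.reactions.items():
            got = loaded.reactions[rid]
            assert got.lower_bound == rxn.lower_bound
            assert got.upper_bound == rxn.upper_bound
            assert got.stoichiometry == rxn.stoichiometry

    def test_sbml_and_json_encodings_agree(self, tmp_path):
        """The same model written as SBML and COBRA-JSON reads back identically."""
        model = six_reaction_model()
        sbml, js = tmp_path / "six.xml", tmp_path / "six.json"
        save_model(model, sbml)
        save_model(model, js)
        from_sbml = load_model(sbml)
        from_json = load_model(js)
        assert set(from_sbml.reactions) == set(from_json.reactions)
        for rid in from_sbml.reactions:
            a, b = from_sbml.reactions[rid], from_json.reactions[rid]
            assert a.lower_bound == b.lower_bound
            assert a.upper_bound == b.upper_bound
            assert a.stoichiometry == b.stoichiometry
            # GPR strings are logically equal (parenthesization may differ)
            from nidleflux import parse_gpr

            assert parse_gpr(a.gpr).root == parse_gpr(b.gpr).root

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError, match="lower bound"):
            MetabolicModel(
                {"A": Metabolite("A")},
                {"R": Reaction("R", {"A": 1.0}, 5.0, 2.0)},
                "R",
            )

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.json")

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ModelValidationError, match="unknown metabolite"):
            MetabolicModel(
                {"A": Metabolite("A")},
                {"R": Reaction("R", {"A": -1.0, "Z": 1.0}, 0.0, 1.0)},
                "R",
            )


class TestCarbonDetection:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C6H12O6", True),
            ("CO2", True),
            ("C", True),
            ("Ca", False),  # calcium, not carbon
            ("CaCO3", True),
            ("H2O", False),
            (None, False),
        ],
    )
    def test_formula_parsing(self, formula, expected):
        assert Metabolite("m", formula).has_carbon() is expected

    def test_override_replaces_formula_detection(self):
        model = six_reaction_model()
        assert model.carbon_exchange_ids() == ["EX_A"]
        model.carbon_exchange_override = frozenset()
        assert model.carbon_exchange_ids() == []


class TestSplitReversible:
    def test_symmetric_bounds(self):
        model, _, _ = fixtures.t2()
        irr = split_reversible(model)
        fwd, bwd = irr.split_map["R3"]
        assert (fwd, bwd) == ("R3__fwd", "R3__bwd")
        assert irr.reactions[fwd].upper_bound == 1000.0
        assert irr.reactions[bwd].upper_bound == 1000.0
        assert irr.reactions[bwd].stoichiometry == {
            m: -c for m, c in irr.reactions[fwd].stoichiometry.items()
        }
        assert irr.reactions[fwd].gpr == irr.reactions[bwd].gpr

    def test_asymmetric_bounds(self):
        model = six_reaction_model()
        irr = split_reversible(model)
        fwd, bwd = irr.split_map["R4"]
        assert irr.reactions[fwd].upper_bound == 8.0
        assert irr.reactions[bwd].upper_bound == 3.0

    def test_irreversible_unchanged(self):
        model = six_reaction_model()
        irr = split_reversible(model)
        assert irr.split_map["R1"] == ("R1", None)
        assert irr.reactions["R1"].upper_bound == 1000.0

    def test_backward_only_keeps_zero_ub_forward(self):
        model = MetabolicModel(
            {"A": Metabolite("A"), "B": Metabolite("B")},
            {
                "R": Reaction("R", {"A": -1.0, "B": 1.0}, -5.0, 0.0),
                "EX": Reaction("EX", {"A": 1.0}, 0.0, 10.0),
                "BIO": Reaction("BIO", {"B": -1.0}, 0.0, 10.0),
            },
            "BIO",
        )
        irr = split_reversible(model)
        fwd, bwd = irr.split_map["R"]
        assert irr.reactions[fwd].upper_bound == 0.0
        assert irr.reactions[bwd].upper_bound == 5.0

    def test_every_original_in_split_map_once(self):
        model = six_reaction_model()
        irr = split_reversible(model)
        assert set(irr.split_map) == set(model.reactions)


class TestNetFluxes:
    def test_pair_and_passthrough(self):
        model, _, _ = fixtures.t2()
        irr = split_reversible(model)
        v = {r: 0.0 for r in irr.reactions}
        v["R3__fwd"], v["R3__bwd"] = 3.0, 1.0
        v["R1"] = 7.0
        net = net_fluxes(irr, v)
        assert net["R3"] == pytest.approx(2.0)
        assert net["R1"] == pytest.approx(7.0)

    def test_backward_dominant_is_negative(self):
        model, _, _ = fixtures.t2()
        irr = split_reversible(model)
        v = {r: 0.0 for r in irr.reactions}
        v["R3__bwd"] = 4.0
        assert net_fluxes(irr, v)["R3"] == pytest.approx(-4.0)

    def test_missing_entry_names_reaction(self):
        model, _, _ = fixtures.t2()
        irr = split_reversible(model)
        with pytest.raises(KeyError, match="missing reaction"):
            net_fluxes(irr, {})


def _random_feasible_flux(model, rng):
    """A vertex of the flux polytope via an LP with a random objective."""
    N, _, rids = stoichiometric_matrix(model)
    bounds = [
        (model.reactions[r].lower_bound, min(model.reactions[r].upper_bound, 1000.0))
        for r in rids
    ]
    res = linprog(
        rng.normal(size=len(rids)),
        A_eq=N,
        b_eq=np.zeros(N.shape[0]),
        bounds=bounds,
        method="highs",
    )
    assert res.status == 0
    return dict(zip(rids, res.x))


class TestSpacePreservation:
    def test_split_of_feasible_vector_is_feasible_and_balanced(self):
        model = six_reaction_model()
        irr = split_reversible(model)
        rng = np.random.default_rng(7)
        Ns, _, split_rids = stoichiometric_matrix(irr)
        for _ in range(10):
            v = _random_feasible_flux(model, rng)
            vs = {}
            for orig, (fwd, bwd) in irr.split_map.items():
                if bwd is None:
                    vs[fwd] = v[orig]
                else:
                    vs[fwd] = max(v[orig], 0.0)
                    vs[bwd] = max(-v[orig], 0.0)
            vec = np.array([vs[r] for r in split_rids])
            assert np.abs(Ns @ vec).max() <= 1e-9
            for rid, val in vs.items():
                assert -1e-12 <= val <= irr.reactions[rid].upper_bound + 1e-9

    def test_net_of_feasible_split_vector_is_balanced(self):
        model = six_reaction_model()
        irr = split_reversible(model)
        rng = np.random.default_rng(11)
        N, _, rids = stoichiometric_matrix(model)
        for _ in range(10):
            vs = _random_feasible_flux(irr, rng)
            net = net_fluxes(irr, vs)
            vec = np.array([net[r] for r in rids])
            assert np.abs(N @ vec).max() <= 1e-9

    def test_split_then_net_is_identity_on_irreversible_model(self):
        model, _, _ = fixtures.t1()  # all reactions irreversible
        irr = split_reversible(model)
        rng = np.random.default_rng(3)
        v = _random_feasible_flux(model, rng)
        assert net_fluxes(irr, v) == pytest.approx(v)
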