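"""The two-step activation MILP, the penalized variant, pFBA and FVA."""

import numpy as np
import pytest

from nidleflux import (
    build_problem,
    classify_reactions,
    fixtures,
    fva,
    nidle_penalized_step1,
    nidle_step1,
    nidle_step2,
    pfba,
    solve_nidle,
    split_reversible,
)
from nidleflux.gpr import ConditionProfile
from nidleflux.model_io import MetabolicModel, Metabolite, Reaction
from nidleflux.optimize import InfeasibleProblemError, uptake_direction
from nidleflux import oracle

from conftest import make_problem


def two_source_model():
    """Two carbon exchanges so the other-source-closed rule is observable."""
    mets = {
        "A": Metabolite("A", "C6H12O6"),
        "G": Metabolite("G", "C3H8O3"),
        "P": Metabolite("P", "C3H4O3"),
    }
    rxns = {
        "EX_A": Reaction("EX_A", {"A": 1.0}, 0.0, 1000.0),
        "EX_G": Reaction("EX_G", {"G": 1.0}, 0.0, 1000.0),
        "RA": Reaction("RA", {"A": -1.0, "P": 1.0}, 0.0, 1000.0, gpr="g1"),
        "RG": Reaction("RG", {"G": -1.0, "P": 1.0}, 0.0, 1000.0, gpr="g2"),
        "BIOMASS": Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0),
    }
    return MetabolicModel(mets, rxns, "BIOMASS", id="two_source")


class TestBuildProblem:
    def test_designated_source_open_others_closed(self):
        model = two_source_model()
        profile = ConditionProfile("c1", {"g1": 1e-3, "g2": 1e-3}, 2.0, "EX_A", 10.0)
        irr, act, prob = make_problem(model, profile)
        ridx = {r: i for i, r in enumerate(prob.reaction_ids)}
        assert prob.ub[ridx["EX_A"]] == 10.0
        assert prob.ub[ridx["EX_G"]] == 0.0

    def test_biomass_equality_mode(self, t1_case):
        prob = t1_case["problem"]
        i = prob.index_of(prob.irr.biomass_reaction_id)
        assert prob.lb[i] == prob.ub[i] == 5.0

    def test_biomass_band_mode(self):
        model, profile, _ = fixtures.t1()
        profile.mu = 1.0
        _, _, prob = make_problem(model, profile, biomass_mode="band")
        i = prob.index_of(prob.irr.biomass_reaction_id)
        assert (prob.lb[i], prob.ub[i]) == (0.95, 1.05)

    def test_uptake_direction_of_exchange(self, t1_case):
        assert uptake_direction(t1_case["irr"], "EX_A") == "EX_A"

    def test_infeasible_mu_reported_at_solve_not_build(self):
        model, profile, _ = fixtures.t1()
        profile.mu = 50.0  # above the uptake bound of 10
        _, _, prob = make_problem(model, profile)
        sol = solve_nidle(prob)
        assert sol.status == "infeasible"
        with pytest.raises(InfeasibleProblemError):
            nidle_step1(prob)

    def test_epsilon_must_be_positive_and_small(self, t1_case):
        model, profile = t1_case["model"], t1_case["profile"]
        irr = split_reversible(model)
        act = classify_reactions(irr, profile)
        with pytest.raises(ValueError):
            build_problem(irr, profile, act, epsilon=0.0)
        with pytest.raises(ValueError):
            build_problem(irr, profile, act, epsilon=2000.0)


class TestStep1:
    def test_t1_both_genes_measured(self, t1_case):
        assert nidle_step1(t1_case["problem"]) == 2

    def test_t1_single_gene_measured(self, canonical_cases):
        assert nidle_step1(canonical_cases["T3"]["problem"]) == 1

    def test_empty_ra_gives_zero(self):
        model, profile, _ = fixtures.t1()
        profile.abundances = {"unrelated": 1.0}
        _, _, prob = make_problem(model, profile)
        assert prob.n_binaries == 0
        assert nidle_step1(prob) == 0

    def test_reversible_pair_never_both_active(self, canonical_cases):
        case = canonical_cases["T2"]
        sol = solve_nidle(case["problem"])
        fwd, bwd = case["irr"].split_map["R3"]
        assert sol.y[fwd] + sol.y[bwd] <= 1

    @pytest.mark.parametrize("name", ["T1", "T2", "T3", "T4"])
    def test_matches_manifest_oracle(self, canonical_cases, name):
        case = canonical_cases[name]
        assert nidle_step1(case["problem"]) == case["manifest"]["expected_z"]


class TestStep2:
    def test_t1_minimum_total_flux(self, t1_case):
        sol = nidle_step2(t1_case["problem"], 2)
        assert sol.status == "optimal"
        assert sol.q == pytest.approx(15.0, abs=1e-6)
        net = sol.net_fluxes(t1_case["irr"])
        eps = sol.epsilon
        assert net["R1"] + net["R2"] == pytest.approx(5.0, abs=1e-9)
        assert min(net["R1"], net["R2"]) >= eps - 1e-9

    def test_t3_routes_through_measured_gene(self, canonical_cases):
        case = canonical_cases["T3"]
        sol = nidle_step2(case["problem"], 1)
        net = sol.net_fluxes(case["irr"])
        eps = sol.epsilon
        assert net["R1"] == pytest.approx(5.0 - net["R2"], abs=1e-9)
        assert net["R2"] <= eps + 1e-9  # unmeasured isozyme limited to residual

    def test_single_path_flux_is_unique(self, single_path_case):
        sol = solve_nidle(single_path_case["problem"])
        net = sol.net_fluxes(single_path_case["irr"])
        assert net["R_KAPP"] == pytest.approx(3.0, abs=1e-9)

    def test_stale_z_reports_infeasible(self, t1_case):
        sol = nidle_step2(t1_case["problem"], 5)  # more than |Ra|
        assert sol.status == "infeasible"

    def test_q_matches_oracle(self, canonical_cases):
        for name, case in canonical_cases.items():
            man = case["manifest"]
            sol = nidle_step2(case["problem"], man["expected_z"])
            assert sol.q == pytest.approx(man["expected_q"], abs=1e-6), name


class TestPenalized:
    def test_coincides_with_standard_when_ri_empty(self, t1_case):
        model, profile = t1_case["model"], t1_case["profile"]
        _, _, pen = make_problem(model, profile, objective_mode="penalized")
        assert len(pen.activity.ri) == 0
        assert nidle_penalized_step1(pen) == nidle_step1(t1_case["problem"])

    def test_unmeasured_isozyme_gets_no_activation(self, canonical_cases):
        model, profile = (
            canonical_cases["T3"]["model"],
            canonical_cases["T3"]["profile"],
        )
        irr, act, pen = make_problem(model, profile, objective_mode="penalized")
        z_p = nidle_penalized_step1(pen)
        assert z_p == 1
        sol = nidle_step2(pen, z_p)
        assert sol.y["R2"] == 0
        assert sol.fluxes["R2"] <= pen.epsilon + 1e-9

    def test_required_ri_path_reduces_objective(self):
        mets = {
            "A": Metabolite("A", "C6H12O6"),
            "B": Metabolite("B", "C3H4O3"),
            "C": Metabolite("C", "C3H4O3"),
        }
        rxns = {
            "EX_A": Reaction("EX_A", {"A": 1.0}, 0.0, 1000.0),
            "RM": Reaction("RM", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, gpr="gx"),
            "RP": Reaction("RP", {"B": -1.0, "C": 1.0}, 0.0, 1000.0, gpr="g1"),
            "BIOMASS": Reaction("BIOMASS", {"C": -1.0}, 0.0, 1000.0),
        }
        model = MetabolicModel(mets, rxns, "BIOMASS", id="ri_path")
        profile = ConditionProfile("c1", {"g1": 1e-3}, 5.0, "EX_A", 10.0)
        _, _, std = make_problem(model, profile)
        _, _, pen = make_problem(model, profile, objective_mode="penalized")
        z = nidle_step1(std)
        z_p = nidle_penalized_step1(pen)
        assert z == 1
        assert z_p == 0  # the Ri reaction is forced active and penalized
        assert z_p == oracle.brute_force_z(pen)
        sol = nidle_step2(pen, z_p)
        assert sol.y["RM"] == 1

    def test_penalized_step1_requires_penalized_problem(self, t1_case):
        with pytest.raises(ValueError):
            nidle_penalized_step1(t1_case["problem"])


class TestPfba:
    def test_t1_total_flux(self, t1_case):
        sol = pfba(t1_case["problem"])
        assert sol.status == "optimal"
        assert sol.q_prime == pytest.approx(15.0, abs=1e-6)

    def test_single_path_equals_unique_flux(self, single_path_case):
        sol = pfba(single_path_case["problem"])
        net = sol.net_fluxes(single_path_case["irr"])
        assert net["R_KAPP"] == pytest.approx(3.0, abs=1e-9)

    def test_q_prime_never_exceeds_q(self, canonical_cases):
        for name, case in canonical_cases.items():
            nidle = solve_nidle(case["problem"])
            parsimonious = pfba(case["problem"])
            assert parsimonious.q_prime <= nidle.q + 1e-6, name


class TestFVA:
    def test_t1_range_spans_the_activation_polytope(self, t1_case):
        sol = solve_nidle(t1_case["problem"])
        res = fva(t1_case["problem"], {"z": sol.z, "q": sol.q}, targets=["R1", "R2"])
        eps = t1_case["problem"].epsilon
        # both isozymes must stay active, so each ranges over [eps, 5 - eps]
        for rid in ("R1", "R2"):
            assert res.minimum[rid] == pytest.approx(eps, abs=1e-6)
            assert res.maximum[rid] == pytest.approx(5.0 - eps, abs=1e-6)

    def test_single_path_has_zero_variability(self, single_path_case):
        prob = single_path_case["problem"]
        sol = solve_nidle(prob)
        res = fva(prob, {"z": sol.z, "q": sol.q})
        for rid, var in res.variability.items():
            assert var == pytest.approx(0.0, abs=1e-6), rid

    def test_incumbent_inside_every_range(self, canonical_cases):
        for name, case in canonical_cases.items():
            prob = case["problem"]
            sol = solve_nidle(prob)
            res = fva(prob, {"z": sol.z, "q": sol.q})
            for rid in res.minimum:
                assert res.minimum[rid] - 1e-6 <= sol.fluxes[rid] <= res.maximum[rid] + 1e-6

    def test_pfba_mode_is_pure_lp(self, t1_case):
        sol = pfba(t1_case["problem"])
        res = fva(t1_case["problem"], {"q_prime": sol.q_prime}, targets=["R1", "R2"], mode="pfba")
        # without activation constraints either isozyme may carry all flux
        for rid in ("R1", "R2"):
            assert res.minimum[rid] == pytest.approx(0.0, abs=1e-6)
            assert res.maximum[rid] == pytest.approx(5.0, abs=1e-6)

    def test_unknown_target_rejected(self, t1_case):
        with pytest.raises(KeyError):
            fva(t1_case["problem"], {"z": 2, "q": 15.0}, targets=["nope"])


class TestSolutionContracts:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_fixture_contracts(self, seed):
        model, profile = fixtures.random_fixture(seed)
        irr, act, prob = make_problem(model, profile)
        sol = solve_nidle(prob)
        assert sol.status == "optimal"
        v = np.array([sol.fluxes[r] for r in prob.reaction_ids])
        assert np.abs(prob.N @ v).max() <= 1e-6
        assert (v >= prob.lb - 1e-9).all() and (v <= prob.ub + 1e-9).all()
        assert sum(sol.y.values()) == sol.z
        eps = prob.epsilon
        for rid, yv in sol.y.items():
            if yv:
                assert sol.fluxes[rid] >= eps - 1e-9
            else:
                assert sol.fluxes[rid] <= eps + 1e-9
        for yf, yb in prob.pairs:
            assert sol.y[prob.y_reactions[yf]] + sol.y[prob.y_reactions[yb]] <= 1

    def test_optima_reproducible_across_runs(self, t1_case):
        prob = t1_case["problem"]
        runs = [solve_nidle(prob) for _ in range(3)]
        assert len({r.z for r in runs}) == 1
        qs = [r.q for r in runs]
        assert max(qs) - min(qs) <= 1e-6 * max(1.0, abs(qs[0]))


class TestEpsilonStability:
    @pytest.mark.parametrize("eps", [1e-6, 1e-5, 1e-4, 1e-3])
    def test_z_stable_across_epsilon(self, canonical_cases, eps):
        """The activation optimum must not depend on the threshold choice."""
        for name, case in canonical_cases.items():
            _, _, prob = make_problem(case["model"], case["profile"], epsilon=eps)
            assert nidle_step1(prob) == case["manifest"]["expected_z"], (name, eps)
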