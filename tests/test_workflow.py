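import warnings

import numpy as np
import pytest

from minmicrobiome import (
    FunctionalitySpec,
    Params,
    build_targets,
    check_reduced_feasible,
    delete_species,
    enumerate_minimal,
    find_minimal_microbiomes,
    joint_fba,
    max_scfa_of_minimal,
    member_growths,
    minimize_membership,
    scfa_fva_max,
    sequential_reduce,
    synthetic,
)
from minmicrobiome.workflow import InfeasibleCommunityError
from conftest import run_steps12


class TestFunctionalitySpec:
    def test_constraints_2_to_4_are_unit_weights(self):
        assert FunctionalitySpec(constraint_id=2).effective_weights == (1.0, 0.0, 0.0)
        assert FunctionalitySpec(constraint_id=3).effective_weights == (0.0, 1.0, 0.0)
        assert FunctionalitySpec(constraint_id=4).effective_weights == (0.0, 0.0, 1.0)

    def test_constraint_1_defaults_to_equal_weights(self):
        assert FunctionalitySpec(constraint_id=1).effective_weights == (1.0, 1.0, 1.0)
        assert FunctionalitySpec(constraint_id=1, weights=(1, 3, 1)).effective_weights == (1, 3, 1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            FunctionalitySpec(constraint_id=5)
        with pytest.raises(ValueError):
            FunctionalitySpec(weights=(-1, 0, 0))
        with pytest.raises(ValueError):
            Params(gr_opt_frac=0.0)
        with pytest.raises(ValueError):
            Params(gr_frac=1.5)


class TestSteps12:
    def test_bound_limited_single_member_growth(self):
        """Substrate uptake 5, monomer yield 2, growth yield 0.5 → growth 2.5."""
        comm, _ = synthetic.make_toy_community(
            synthetic.ToySpec(
                members=(
                    synthetic.MemberSpec("degrader", uptake=5.0, product_yield=2.0, growth_yield=0.5),
                ),
                fibre_supply=10.0,
            )
        )
        res = joint_fba(comm)
        assert res.objective_value == pytest.approx(2.5, rel=1e-9)

    def test_zero_weights_give_zero_scfa_max(self, toy3):
        comm, _ = toy3
        theta = member_growths(comm, joint_fba(comm))
        spec = FunctionalitySpec(constraint_id=1, weights=(0, 0, 0))
        smax, triple = scfa_fva_max(comm, spec, theta, 0.99)
        assert smax == 0.0 and set(triple.values()) == {0.0}

    def test_scfa_max_monotone_in_gr_opt_frac(self, toy9, butyrate_spec):
        """Relaxing the growth floor can only increase the SCFA optimum."""
        comm, _ = toy9
        theta = member_growths(comm, joint_fba(comm))
        values = [
            scfa_fva_max(comm, butyrate_spec, theta, f)[0] for f in (0.99, 0.95, 0.9, 0.8)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] > values[0]  # strictly better when growth competes

    def test_exact_fva_value_on_toy3(self, toy3, butyrate_spec):
        """Analytic: 1% of producer growth buys 0.01·y_g·M/(y_g−y_f) butyrate."""
        comm, _ = toy3
        theta = member_growths(comm, joint_fba(comm))
        smax, _ = scfa_fva_max(comm, butyrate_spec, theta, 0.99)
        assert smax == pytest.approx(0.2, rel=1e-6)

    def test_build_targets_arithmetic(self):
        params = Params(gr_frac=0.8, scfa_frac=0.8)
        t = build_targets({"a": 1.0, "b": 2.0}, 5.0, params)
        assert t.theta_total == pytest.approx(3.0)
        assert t.growth_threshold == pytest.approx(2.4)
        assert t.scfa_threshold == pytest.approx(4.0)
        t0 = build_targets({"a": 1.0}, 5.0, Params(gr_frac=0.0, scfa_frac=0.0))
        assert t0.growth_threshold == 0.0 and t0.scfa_threshold == 0.0
        t1 = build_targets({"a": 1.0}, 5.0, Params(gr_frac=1.0, scfa_frac=1.0))
        assert t1.growth_threshold == 1.0 and t1.scfa_threshold == 5.0


class TestFeasibilityCheck:
    def test_full_community_meets_its_own_targets(self, toy9, butyrate_spec, default_params):
        comm, _ = toy9
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        assert check_reduced_feasible(comm, butyrate_spec, targets)

    def test_losing_the_only_producer_fails(self, toy3, butyrate_spec, default_params):
        comm, _ = toy3
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        delete_species(comm, "butp1")
        assert not check_reduced_feasible(comm, butyrate_spec, targets)

    def test_zero_thresholds_always_pass(self, toy3, butyrate_spec):
        comm, _ = toy3
        _, _, targets = run_steps12(comm, butyrate_spec, Params(gr_frac=0.0, scfa_frac=0.0))
        delete_species(comm, "butp1")
        delete_species(comm, "free1")
        assert check_reduced_feasible(comm, butyrate_spec, targets)


class TestSequentialReduce:
    def test_large_milp_size_deletes_nothing(self, toy9, butyrate_spec, default_params):
        comm, _ = toy9
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        trace = sequential_reduce(comm, butyrate_spec, targets, Params(milp_size=9))
        assert trace.steps == [] and comm.n_active == 9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_freeloaders_go_producers_stay(self, toy3, butyrate_spec, default_params, seed):
        comm, _ = toy3
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        trace = sequential_reduce(comm, butyrate_spec, targets, Params(milp_size=2, seed=seed))
        assert set(trace.final_active) == {"deg1", "butp1"}
        assert check_reduced_feasible(comm, butyrate_spec, targets)

    def test_user_sequence_is_respected(self, toy5, butyrate_spec, default_params):
        comm, _ = toy5
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        seq = ["butp1", "free1", "free2", "butp2", "deg1"]
        trace = sequential_reduce(
            comm, butyrate_spec, targets, Params(milp_size=2, deletion_sequence=seq)
        )
        # butp1 goes first (butp2 covers the function); both final sets feasible
        assert trace.steps[0][:2] == ("butp1", "deleted")
        assert set(trace.final_active) == {"deg1", "butp2"}

    def test_interchangeable_producers_depend_on_sequence(self, butyrate_spec, default_params):
        kept = set()
        for seed in range(6):
            comm, _ = synthetic.toy_5_redundant()
            _, _, targets = run_steps12(comm, butyrate_spec, default_params)
            trace = sequential_reduce(comm, butyrate_spec, targets, Params(milp_size=2, seed=seed))
            assert check_reduced_feasible(comm, butyrate_spec, targets)
            kept |= {s for s in trace.final_active if s.startswith("butp")}
        assert kept <= {"butp1", "butp2"} and kept


class TestMembershipMILP:
    def test_cross_feeding_pair_is_minimal(self, toy3, butyrate_spec, default_params):
        comm, _ = toy3
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        sol = minimize_membership(comm, butyrate_spec, targets)
        assert sol.members == frozenset({"deg1", "butp1"})
        assert sol.provenance["milp_objective"] == pytest.approx(2.0, abs=1e-6)

    def test_zero_thresholds_give_empty_set_with_warning(self, toy3, butyrate_spec):
        comm, _ = toy3
        _, _, targets = run_steps12(comm, butyrate_spec, Params(gr_frac=0.0, scfa_frac=0.0))
        with pytest.warns(UserWarning, match="degenerate"):
            sol = minimize_membership(comm, butyrate_spec, targets)
        assert sol.members == frozenset()

    def test_single_member_identity(self):
        comm, _ = synthetic.make_toy_community(
            synthetic.ToySpec(
                members=(
                    synthetic.MemberSpec("degrader", uptake=5.0, product_yield=2.0, growth_yield=0.5),
                ),
                fibre_supply=10.0,
            )
        )
        spec = FunctionalitySpec(constraint_id=1, weights=(0, 0, 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            _, _, targets = run_steps12(comm, spec, Params(gr_frac=0.8, scfa_frac=0.0))
            sol = minimize_membership(comm, spec, targets)
        assert sol.members == frozenset({"deg1"})

    def test_per_species_mode_respects_individual_floors(self, toy9, butyrate_spec):
        comm, _ = toy9
        params = Params(growth_constraint_mode="per_species", gr_frac=0.5)
        theta, _, targets = run_steps12(comm, butyrate_spec, params)
        sol = minimize_membership(comm, butyrate_spec, targets)
        for sp in sol.members:
            assert sol.per_species_growth[sp] >= 0.5 * theta[sp] - 1e-6

    def test_coupling_only_gate_leaks_at_most_u(self, toy3, butyrate_spec, default_params):
        """The literal formulation leaves |v| ≤ u for excluded members."""
        comm, _ = toy3
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        sol = minimize_membership(comm, butyrate_spec, targets, gate_mode="coupling_only")
        excluded = set(comm.members) - set(sol.members)
        for sp in excluded:
            k = comm.member_index(sp)
            for j in comm.member_reactions(k):
                if comm.reactions[j] != comm.biomass[k]:
                    assert abs(sol.fluxes[comm.reactions[j]]) <= 0.01 + 1e-6


class TestEnumerationAndScfaMax:
    def test_interchangeable_producers_both_enumerated(self, toy5, butyrate_spec, default_params):
        comm, _ = toy5
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        sols = enumerate_minimal(comm, butyrate_spec, targets, max_solutions=10)
        assert {s.members for s in sols} == {
            frozenset({"deg1", "butp1"}),
            frozenset({"deg1", "butp2"}),
        }

    def test_max_solutions_one_matches_minimize(self, toy5, butyrate_spec, default_params):
        comm, _ = toy5
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        only = enumerate_minimal(comm, butyrate_spec, targets, max_solutions=1)
        assert len(only) == 1
        assert len(only[0].members) == len(minimize_membership(comm, butyrate_spec, targets).members)

    def test_max_scfa_at_least_threshold(self, toy9, butyrate_spec, default_params):
        comm, _ = toy9
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        sol = minimize_membership(comm, butyrate_spec, targets)
        best = max_scfa_of_minimal(comm, sol.members, butyrate_spec, targets)
        assert best >= targets.scfa_threshold - 1e-9
        assert best >= sol.scfa_flux - 1e-9

    def test_full_support_recovers_scfa_max(self, toy9, butyrate_spec, default_params):
        comm, _ = toy9
        _, scfa_max, targets = run_steps12(comm, butyrate_spec, default_params)
        best = max_scfa_of_minimal(comm, set(comm.members), butyrate_spec, targets)
        # gr_frac ≤ gr_opt_frac relaxes the growth floor, so at least ϑ is reachable
        assert best >= scfa_max - 1e-6

    def test_unknown_support_member_rejected(self, toy3, butyrate_spec, default_params):
        comm, _ = toy3
        _, _, targets = run_steps12(comm, butyrate_spec, default_params)
        with pytest.raises(ValueError, match="unknown species"):
            max_scfa_of_minimal(comm, {"nobody"}, butyrate_spec, targets)


class TestPipeline:
    def test_solutions_always_contain_a_producer(self, butyrate_spec):
        comm, ann = synthetic.toy_9_demo()
        sols = find_minimal_microbiomes(
            comm.source_models, comm.diet, butyrate_spec,
            Params(seed=11, iterations=3, milp_size=4),
        )
        producers = set(ann["producers"]["butyrate"])
        assert sols
        for sol in sols:
            assert sol.members & producers
            assert sol.members & set(ann["degraders"])

    def test_iterations_cover_redundant_optima(self, butyrate_spec):
        comm, _ = synthetic.toy_5_redundant()
        sols = find_minimal_microbiomes(
            comm.source_models, comm.diet, butyrate_spec,
            Params(seed=0, iterations=6, milp_size=2),
        )
        assert {s.members for s in sols} == {
            frozenset({"deg1", "butp1"}),
            frozenset({"deg1", "butp2"}),
        }

    def test_unreachable_targets_raise(self, toy3, butyrate_spec, default_params):
        comm, _ = toy3
        theta, _, _ = run_steps12(comm, butyrate_spec, default_params)
        # more butyrate than the entire fibre supply could ever yield
        impossible = build_targets(theta, 1000.0, default_params)
        with pytest.raises(InfeasibleCommunityError, match="no sub-community"):
            minimize_membership(comm, butyrate_spec, impossible)
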