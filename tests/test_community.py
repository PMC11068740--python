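import numpy as np
import pytest

from minmicrobiome import (
    FunctionalitySpec,
    Params,
    add_coupling,
    apply_diet,
    build_community,
    delete_species,
    joint_fba,
    member_growths,
    restore_species,
    scfa_fva_max,
)
from minmicrobiome.model_io import Diet
from minmicrobiome import synthetic
from minmicrobiome.solve import community_lp, solve_lp
from conftest import run_steps12


def _deg(uptake=5.0):
    return synthetic.make_toy_member(
        synthetic.MemberSpec("degrader", uptake=uptake, product_yield=2.0, growth_yield=0.5), "deg1"
    )


def _free(uptake=10.0):
    return synthetic.make_toy_member(
        synthetic.MemberSpec("freeloader", uptake=uptake, growth_yield=1.0), "free1"
    )


class TestBuild:
    def test_shared_metabolite_is_pooled_once(self):
        comm = build_community([_deg(), _free()])
        assert comm.community_exchange["EX_monomer(e)"] == "monomer(e)[u]"
        # two member transfers + one community exchange touch the pool row
        row = comm.S.getrow(comm.metabolites.index("monomer(e)[u]")).toarray().ravel()
        touching = [comm.reactions[j] for j in np.nonzero(row)[0]]
        assert sorted(touching) == ["EX_monomer(e)", "EX_monomer(e)_org1", "EX_monomer(e)_org2"]
        # pool balance row encodes: sum of member exchanges - community exchange = 0
        assert row[comm.rxn_index("EX_monomer(e)")] == -1.0
        assert row[comm.rxn_index("EX_monomer(e)_org1")] == 1.0

    def test_tags_are_one_based_and_unique(self):
        comm = build_community([_deg(), _free()])
        assert comm.biomass == {1: "biomass_deg1_org1", 2: "biomass_free1_org2"}

    def test_duplicate_species_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_community([_deg(), _deg()])

    def test_single_member_joint_fba_matches_standalone_cobra_fba(self):
        """Community of one ≡ ordinary FBA (cobrapy as the independent oracle)."""
        model = _deg()
        comm = build_community([model])
        res = joint_fba(comm)
        cm = __import__("minmicrobiome.model_io", fromlist=["to_cobra"]).to_cobra(model)
        oracle = cm.optimize().objective_value
        assert res.objective_value == pytest.approx(oracle, rel=1e-6)

    def test_pool_conservation_at_optimum(self, toy9, butyrate_spec):
        """Eq-4 structure: community exchange equals the member-exchange sum."""
        comm, _ = toy9
        res = joint_fba(comm)
        for ex_id, pool in comm.community_exchange.items():
            total = sum(
                res.fluxes[r]
                for k in range(1, len(comm.members) + 1)
                for r, p in comm.member_exchange[k]
                if p == pool
            )
            assert abs(res.fluxes[ex_id] - total) < 1e-9


class TestCoupling:
    def test_zero_biomass_pins_fluxes_to_threshold(self):
        """A member forced to zero growth can carry at most |v| ≤ u."""
        deg, free = _deg(), _free(uptake=4.0)
        comm = build_community([deg, free])
        apply_diet(comm, Diet(bounds={"EX_fibre(e)": (-5.0, 1000.0)}))
        add_coupling(comm, c=400.0, u=0.01)
        j = comm.rxn_index("biomass_free1_org2")
        comm.lb[j] = comm.ub[j] = 0.0
        p = community_lp(comm, {"GROW_org2": 1.0}, "max")
        res = solve_lp(p)
        assert res.optimal and res.objective_value <= 0.01 + 1e-9

    def test_large_c_approaches_uncoupled_optimum(self):
        models = [_deg(), _free()]
        uncoupled = joint_fba(build_community(models))
        comm = build_community([m.copy() for m in models])
        add_coupling(comm, c=1e6, u=0.01)
        coupled = joint_fba(comm)
        assert coupled.objective_value == pytest.approx(uncoupled.objective_value, rel=1e-4)

    def test_nonpositive_c_rejected(self):
        comm = build_community([_deg()])
        with pytest.raises(ValueError):
            add_coupling(comm, c=0.0)

    def test_both_directions_coupled(self):
        comm = add_coupling(build_community([_deg()]))
        signs = {(r.rxn, r.sign) for r in comm.couplings}
        assert ("EX_monomer(e)_org1", 1) in signs and ("EX_monomer(e)_org1", -1) in signs
        assert not any(r.rxn == "biomass_deg1_org1" for r in comm.couplings)


class TestDeletion:
    def test_delete_then_restore_is_bit_identical(self, toy3):
        comm, _ = toy3
        lb0, ub0 = comm.lb.copy(), comm.ub.copy()
        delete_species(comm, "butp1")
        assert not comm.active[1]
        assert np.all(comm.ub[comm.member_reactions(2)] == 0.0)
        restore_species(comm, "butp1")
        assert np.array_equal(comm.lb, lb0) and np.array_equal(comm.ub, ub0)

    def test_deleting_sole_producer_kills_butyrate(self, toy3, butyrate_spec, default_params):
        comm, _ = toy3
        delete_species(comm, "butp1")
        theta, scfa_max, _ = run_steps12(comm, butyrate_spec, default_params)
        assert scfa_max == pytest.approx(0.0, abs=1e-9)

    def test_deleting_zero_flux_member_keeps_optimum(self, toy3):
        comm, _ = toy3
        res = joint_fba(comm)
        growth = member_growths(comm, res)
        assert growth["free1"] == pytest.approx(0.0, abs=1e-9)  # outcompeted for monomer
        delete_species(comm, "free1")
        assert joint_fba(comm).objective_value == pytest.approx(res.objective_value, rel=1e-9)

    def test_double_delete_and_last_member_guard(self, toy3):
        comm, _ = toy3
        delete_species(comm, "butp1")
        with pytest.raises(ValueError, match="already deleted"):
            delete_species(comm, "butp1")
        delete_species(comm, "free1")
        with pytest.raises(ValueError, match="retain at least one"):
            delete_species(comm, "deg1")


class TestDiet:
    def test_diet_touches_only_community_exchanges(self):
        comm = build_community([_deg(), _free()])
        internal = [j for j in range(len(comm.reactions)) if comm.rxn_species[j] != 0]
        lb0, ub0 = comm.lb[internal].copy(), comm.ub[internal].copy()
        apply_diet(comm, Diet(bounds={"EX_fibre(e)": (-3.0, 7.0)}))
        assert np.array_equal(comm.lb[internal], lb0) and np.array_equal(comm.ub[internal], ub0)
        j = comm.rxn_index("EX_fibre(e)")
        assert (comm.lb[j], comm.ub[j]) == (-3.0, 7.0)

    def test_closed_policy_blocks_unlisted_uptakes(self):
        comm = build_community([_deg(), _free()])
        apply_diet(comm, Diet(bounds={"EX_fibre(e)": (-5.0, 1000.0)}), policy="closed")
        j = comm.rxn_index("EX_monomer(e)")
        assert comm.lb[j] == 0.0 and comm.ub[j] == 1000.0

    def test_empty_closed_diet_means_no_growth(self):
        comm = build_community([_deg(), _free()])
        apply_diet(comm, Diet(bounds={}), policy="closed")
        assert joint_fba(comm).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_open_policy_recovers_unconstrained_optimum(self):
        models = [_deg(), _free()]
        unconstrained = joint_fba(build_community(models)).objective_value
        comm = build_community([m.copy() for m in models])
        apply_diet(comm, Diet(bounds={}), policy="open")
        assert joint_fba(comm).objective_value == pytest.approx(unconstrained, rel=1e-9)

    def test_unknown_diet_entries_warn(self):
        comm = build_community([_deg()])
        with pytest.warns(UserWarning, match="EX_nothing"):
            apply_diet(comm, Diet(bounds={"EX_nothing(e)": (-1.0, 1.0)}))
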