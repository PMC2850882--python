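import numpy as np
import pytest
from hypothesis import given, strategies as st

import p38compete as pc
from p38compete.network import ALTERED_MECHANISMS, Species

BASE_SPECIES = {
    "p38", "ATP", "ATF2", "MK2", "p38:ATP", "p38:ATF2", "p38:MK2",
    "p38:ATP:ATF2", "p38:ATP:MK2", "pATF2", "pMK2", "ADP",
}

ALL_MECHS = [m.value for m in pc.Mechanism]


class TestTopology:
    def test_base_species_enumeration(self, base_network):
        assert set(base_network.names) == BASE_SPECIES
        assert len(base_network.reactions) == 9
        # irreversible reactions are exactly the two catalysis steps
        irrev = [r for r in base_network.reactions if not r.reversible]
        assert sorted(r.name for r in irrev) == [
            "p38:ATP:ATF2 -> pATF2", "p38:ATP:MK2 -> pMK2",
        ]

    @pytest.mark.parametrize("mech", ["altered_atp", "altered_atf2_affinity",
                                      "altered_kcat"])
    def test_altered_state_duplicates_enzyme_branch(self, params, mech):
        net = pc.build_network(params, mech)
        added = set(net.names) - BASE_SPECIES
        assert added == {
            "p38*", "p38*:ATP", "p38*:ATF2", "p38*:MK2",
            "p38*:ATP:ATF2", "p38*:ATP:MK2",
        }
        # MK2 catalysis routes to the altered enzyme; p38* stays altered
        products = {
            r.name: {n for n, _ in r.products}
            for r in net.reactions if not r.reversible
        }
        assert "p38*" in products["p38:ATP:MK2 -> pMK2"]
        assert "p38*" in products["p38*:ATP:MK2 -> pMK2"]
        assert "p38" in products["p38:ATP:ATF2 -> pATF2"]

    def test_substrate_inhibition_adds_deadend_rebinding(self, params):
        net = pc.build_network(params, "substrate_inhibition")
        added = set(net.names) - BASE_SPECIES
        assert added == {
            "p38:pATF2", "p38:pMK2", "p38:ATP:pATF2", "p38:ATP:pMK2",
        }
        # rebinding occurs at the unphosphorylated substrates' rates
        by_name = {r.name: r for r in net.reactions}
        assert by_name["p38 + pMK2"].kr == by_name["p38 + MK2"].kr
        assert by_name["p38 + pATF2"].kr == by_name["p38 + ATF2"].kr
        # phospho-bound complexes never catalyse
        for r in net.reactions:
            if not r.reversible:
                assert "pMK2:" not in r.name and "pATF2:" not in r.name

    def test_pmk2_binds_atf2_at_the_p38_atf2_affinity(self, params):
        net = pc.build_network(params, "pmk2_binds_atf2")
        assert set(net.names) - BASE_SPECIES == {"pMK2:ATF2"}
        by_name = {r.name: r for r in net.reactions}
        assert by_name["pMK2 + ATF2"].kr == by_name["p38 + ATF2"].kr

    def test_mechanism_1_2_reduce_to_base_without_their_extra_reactions(
        self, params, base_network
    ):
        """Removing the phospho-(re)binding reactions (rate -> 0 limit)
        leaves a network reaction-for-reaction identical to base."""
        base_names = set(base_network.names)
        base_sig = {(r.name, r.kf, r.kr) for r in base_network.reactions}
        for mech in ("substrate_inhibition", "pmk2_binds_atf2"):
            net = pc.build_network(params, mech)
            kept = {
                (r.name, r.kf, r.kr)
                for r in net.reactions
                if all(n in base_names
                       for n, _ in (*r.reactants, *r.products))
            }
            assert kept == base_sig

    def test_altered_parameter_direction(self, params):
        # #3/#4 weaken the respective affinity 10-fold; #5 slows catalysis
        for mech, rxn, base_rxn in (
            ("altered_atp", "p38* + ATP", "p38 + ATP"),
            ("altered_atf2_affinity", "p38* + ATF2", "p38 + ATF2"),
        ):
            net = pc.build_network(params, mech)
            by_name = {r.name: r for r in net.reactions}
            assert by_name[rxn].kr == pytest.approx(
                params.altered_factor * by_name[base_rxn].kr
            )
        net = pc.build_network(params, "altered_kcat")
        by_name = {r.name: r for r in net.reactions}
        assert by_name["p38*:ATP:ATF2 -> pATF2"].kf == pytest.approx(
            by_name["p38:ATP:ATF2 -> pATF2"].kf / params.altered_factor
        )


class TestInhibitorTopology:
    def test_selective_affinity_pattern(self, params, selective):
        net = pc.build_network(params, inhibitor=selective)
        by_name = {r.name: r for r in net.reactions}
        kon = params.kon_small_nM
        ki, f = selective.ki, selective.selectivity_f
        # preferred target: MK2-bound complexes at K_I
        assert by_name["p38:MK2 + I"].kr == pytest.approx(ki * kon)
        assert by_name["p38:ATP:MK2 + I"].kr == pytest.approx(ki * kon)
        # everything else at K_I/(1-f)
        for nm in ("p38 + I", "p38:ATP + I", "p38:ATF2 + I", "p38:ATP:ATF2 + I"):
            assert by_name[nm].kr == pytest.approx(ki / (1 - f) * kon)
        # microscopic-reversibility correction on MK2 dissociation
        assert by_name["p38:I + MK2"].kr == pytest.approx(
            (1 - f) * by_name["p38 + MK2"].kr
        )
        # compound-bound complexes are catalytically dead
        for r in net.reactions:
            if not r.reversible:
                assert ":I" not in r.name

    def test_classical_binds_all_forms_equally(self, params, classical):
        net = pc.build_network(params, inhibitor=classical)
        krs = [r.kr for r in net.reactions if r.name.endswith("+ I")]
        assert len(krs) == 6  # every enzyme form binds the compound
        for kr in krs:
            assert kr == pytest.approx(classical.ki * params.kon_small_nM)

    def test_competitive_forbids_atp_compound_cobinding(self, params):
        inh = pc.InhibitorSpec(ki=1.0, inhibitor_class="classical",
                               atp_mode="competitive")
        net = pc.build_network(params, inhibitor=inh)
        assert not any("ATP" in n and n.endswith(":I") for n in net.names)

    def test_perfect_selectivity_removes_free_p38_binding(self, params):
        inh = pc.InhibitorSpec(ki=1.0, selectivity_f=1.0,
                               inhibitor_class="substrate_selective")
        net = pc.build_network(params, inhibitor=inh)
        bound = [n for n in net.names if n.endswith(":I")]
        assert bound and all("MK2" in n for n in bound)

    def test_classical_with_selectivity_is_rejected(self):
        with pytest.raises(pc.ConfigurationError):
            pc.InhibitorSpec(ki=1.0, selectivity_f=0.5,
                             inhibitor_class="classical")

    @pytest.mark.parametrize("kw", [dict(ki=0.0), dict(selectivity_f=1.5),
                                    dict(atp_mode="mixed")])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(pc.ConfigurationError):
            pc.InhibitorSpec(**{"inhibitor_class": "substrate_selective",
                                "selectivity_f": 0.5, **kw})


class TestConservationAndRHS:
    def test_moieties_in_left_nullspace_for_every_configuration(self, params):
        import sympy

        inhibitors = [None,
                      pc.InhibitorSpec(ki=2.0, inhibitor_class="classical"),
                      pc.InhibitorSpec(ki=2.0, selectivity_f=0.9,
                                       inhibitor_class="substrate_selective")]
        for mech in ALL_MECHS:
            for inh in inhibitors:
                net = pc.build_network(params, mech, inh)
                S = sympy.Matrix(net.stoichiometry_matrix().tolist())
                moieties = net.conserved_moieties()
                for w in moieties.values():
                    assert (sympy.Matrix([list(w)]) * S).is_zero_matrix
                # the named moiety vectors are linearly independent members
                # of the left null space (phosphoryl bookkeeping can add
                # further laws, e.g. ADP - pMK2 - pATF2 = const)
                W = sympy.Matrix([list(w) for w in moieties.values()])
                assert W.rank() == len(moieties)
                assert S.rank() <= len(net.species) - len(moieties)

    def test_zero_state_gives_zero_derivative(self, base_network):
        dy = base_network.rhs(0.0, np.zeros(len(base_network.species)))
        assert np.all(dy == 0.0)

    def test_moiety_derivatives_vanish_at_random_states(self, base_network):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.uniform(0, 100, len(base_network.species))
            dy = base_network.rhs(0.0, y)
            for w in base_network.conserved_moieties().values():
                assert abs(w @ dy) < 1e-9 * np.abs(dy).max()

    def test_isolated_bimolecular_step_matches_hand_evaluation(self):
        net = pc.NetworkModel(
            [Species("p38"), Species("ATP"), Species("p38:ATP")],
            [pc.ReactionDef((("p38", 1), ("ATP", 1)), (("p38:ATP", 1),),
                            kf=0.37, kr=None)],
        )
        y = np.array([2.0, 5.0, 1.0])
        dy = net.rhs(0.0, y)
        assert dy[net.index("p38:ATP")] == pytest.approx(0.37 * 2.0 * 5.0)
        assert dy[net.index("p38")] == pytest.approx(-0.37 * 2.0 * 5.0)

    def test_dimension_mismatch_raises(self, base_network):
        with pytest.raises(ValueError):
            base_network.rhs(0.0, np.zeros(3))

    def test_jacobian_matches_finite_differences(self, params, selective):
        net = pc.build_network(params, "altered_kcat", selective)
        rng = np.random.default_rng(3)
        y = rng.uniform(0.0, 50.0, len(net.species))
        J = net.jacobian(0.0, y)
        scale = np.abs(J).max()
        for j in range(0, len(y), 5):
            eps = 1e-6 * max(y[j], 1.0)
            dy = np.zeros_like(y)
            dy[j] = eps
            num = (net.rhs(0.0, y + dy) - net.rhs(0.0, y - dy)) / (2 * eps)
            # FD differences cancel ~1e4-scale fluxes; atol reflects that
            assert np.allclose(J[:, j], num, rtol=1e-6, atol=1e-8 * scale)


@given(
    kd_mk2=st.floats(1.0, 1e3),
    ki=st.floats(0.1, 1e3),
    f=st.floats(0.0, 0.999),
    mech=st.sampled_from(ALL_MECHS),
)
def test_every_generated_network_conserves_all_moieties(kd_mk2, ki, f, mech):
    """Stoichiometric conservation holds at randomised parameters."""
    p = pc.KineticParameters(kd_mk2_nM=kd_mk2)
    inh = pc.InhibitorSpec(ki=ki, selectivity_f=f,
                           inhibitor_class="substrate_selective")
    net = pc.build_network(p, mech, inh)
    net.verify_conservation()  # exact integer left-nullspace test
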