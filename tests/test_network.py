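"""Combinatorial network generation, thermodynamic consistency, SBML."""

import numpy as np
import pytest

from hemicam.allosteric import TargetSpec, lobe_saturation
from hemicam.equilibrium import IntactSystem, LobeSystem, Mixture, solve_free_concentrations
from hemicam.intact import IntactTargetSpec
from hemicam.network import (
    assign_intact_target_affinities,
    build_network,
    enumerate_species,
    network_equilibrium,
    network_saturation,
    stoichiometry_matrix,
    wegscheider_residuals,
)
from hemicam.sbml import export_sbml, import_sbml
from hemicam.synthetic import fixtures


class TestEnumeration:
    def test_intact_apo_model_has_64_species(self, intact):
        assert len(enumerate_species(intact)) == 64

    def test_one_exclusive_target_doubles_the_count(self, intact):
        assert len(enumerate_species(intact, [fixtures("wff_intact")])) == 128

    def test_two_exclusive_targets_triple_the_count(self, intact):
        specs = [fixtures("wff_intact"), fixtures("wf10_intact")]
        assert len(enumerate_species(intact, specs)) == 192

    def test_duplicate_target_names_rejected(self, intact):
        spec = fixtures("wff_intact")
        with pytest.raises(ValueError):
            enumerate_species(intact, [spec, spec])

    def test_species_are_unique(self, intact):
        species = enumerate_species(intact, [fixtures("wff_intact")])
        assert len(set(species)) == len(species)


class TestBuildNetwork:
    def test_single_lobe_network_size(self, tr2c):
        net = build_network(tr2c)
        assert len(net.species) == 8
        assert len(net.reactions) == 12
        kinds = [r.kind for r in net.reactions]
        assert kinds.count("ca_binding") == 8
        assert kinds.count("flip") == 4

    def test_flip_constant_scales_with_bound_calcium(self, tr2c):
        """Each calcium bound on a lobe scales the R->T constant by c."""
        net = build_network(tr2c)
        by_occ = {}
        for r in net.reactions:
            if r.kind != "flip":
                continue
            src = next(s for s in net.species if s.species_id("Lobe") == r.reactants[0])
            by_occ.setdefault(src.n_ca, []).append(1.0 / r.Keq)  # R->T direction
        assert by_occ[0] == [pytest.approx(tr2c.L)]
        for k, vals in by_occ.items():
            for v in vals:
                assert v == pytest.approx(tr2c.L * tr2c.c**k, rel=1e-12)

    def test_target_bound_flip_carries_affinity_ratio(self, tr2c):
        wff = fixtures("wff_lobe")
        net = build_network(tr2c, [wff])
        flips = [
            r for r in net.reactions
            if r.kind == "flip" and r.reactants[0].endswith("_tWFF")
        ]
        assert flips
        for r in flips:
            src = next(s for s in net.species if s.species_id("Lobe") == r.reactants[0])
            expected = (1.0 / (tr2c.L * tr2c.c**src.n_ca)) * (wff.K_Tt / wff.K_Rt)
            assert r.Keq == pytest.approx(expected, rel=1e-12)

    def test_every_cycle_satisfies_detailed_balance(self, intact):
        net = build_network(intact, [fixtures("wff_intact")])
        residuals = wegscheider_residuals(net)
        assert max(abs(v) for v in residuals.values()) < 1e-9


class TestNetworkEquilibrium:
    def test_apo_protein_sits_in_T_state(self, tr2c):
        conc = network_equilibrium(build_network(tr2c), 1e-6, {}, ca_free=0.0)
        t_apo = conc["Lobe_T_A0B0"]
        assert t_apo / 1e-6 >= tr2c.L / (1.0 + tr2c.L)

    def test_lobe_network_half_saturates_with_closed_form(self, tr2c):
        net = build_network(tr2c)
        conc = network_equilibrium(net, 5e-6, {}, ca_free=1.8362668692e-6)
        assert network_saturation(net, conc) == pytest.approx(0.5, abs=1e-6)

    def test_lobe_network_matches_closed_form_on_grid(self, tr2c):
        net = build_network(tr2c)
        for ca in np.geomspace(1e-8, 1e-3, 12):
            conc = network_equilibrium(net, 5e-6, {}, ca_free=float(ca))
            assert abs(network_saturation(net, conc) - lobe_saturation(tr2c, float(ca))) < 1e-10

    def test_free_target_agrees_with_equilibrium_solver(self, tr2c):
        wff = fixtures("wff_lobe")
        net = build_network(tr2c, [wff])
        system = LobeSystem(tr2c, [wff], binding="exclusive")
        mix = Mixture(system=system, protein_total=5e-6, target_totals={"WFF": 7e-6})
        for ca in (1e-7, 2e-6, 1e-4):
            conc = network_equilibrium(net, 5e-6, {"WFF": 7e-6}, ca_free=ca)
            sol = solve_free_concentrations(mix, ca)
            assert conc["free_WFF"] == pytest.approx(sol.free_targets["WFF"], rel=1e-6)

    def test_intact_network_tracks_partition_function(self, intact):
        wff = fixtures("wff_intact")
        net = build_network(intact, [wff])
        system = IntactSystem(intact, [wff])
        for ca in (1e-8, 1e-6, 1e-4):
            for free_t in (0.0, 1e-7, 1e-5):
                conc = network_equilibrium(net, 5e-6, {}, ca_free=ca)
                # clamp the free target by bypassing conservation
                logw = [net.log_weight(s, ca, {"WFF": free_t}) for s in net.species]
                w = np.exp(np.array(logw) - max(logw))
                y_net = float(sum(
                    s.n_ca * wi for s, wi in zip(net.species, w)
                ) / (4.0 * w.sum()))
                y_closed = system.saturation(ca, {"WFF": free_t})
                assert y_net == pytest.approx(y_closed, abs=1e-12)

    def test_protein_conservation(self, tr2c):
        net = build_network(tr2c, [fixtures("wff_lobe")])
        conc = network_equilibrium(net, 5e-6, {"WFF": 7e-6}, ca_free=1e-6)
        total = sum(conc[s.species_id("Lobe")] for s in net.species)
        assert total == pytest.approx(5e-6, rel=1e-10)


class TestAssignIntactAffinities:
    def test_wff_assignment_matches_estimates(self):
        spec = assign_intact_target_affinities(
            "WFF", K_apo=600e-6, K_ca_saturated=0.1e-9, K_TR2C_Rstate=735e-9
        )
        assert spec == IntactTargetSpec("WFF", K_RR=0.1e-9, K_RT=600e-6,
                                        K_TR=735e-9, K_TT=600e-6)
        assert spec == fixtures("wff_intact")

    def test_wf10_assignment_matches_estimates(self):
        spec = assign_intact_target_affinities(
            "WF10", K_apo=200e-6, K_ca_saturated=735e-9, K_TR2C_Rstate=735e-9
        )
        assert spec == fixtures("wf10_intact")

    def test_uniform_affinities_collapse(self):
        spec = assign_intact_target_affinities("t", 1e-6, 1e-6, 1e-6)
        assert spec.K_RR == spec.K_RT == spec.K_TR == spec.K_TT == 1e-6


class TestSBMLRoundTrip:
    def test_apo_intact_document_contents(self, intact, tmp_path):
        net = build_network(intact)
        path = tmp_path / "intact.xml"
        export_sbml(net, path)
        doc = import_sbml(path)
        cam_species = [s for s in doc.species if s.startswith("CaM_")]
        assert len(cam_species) == 64
        assert "Ca" in doc.species

    def test_stoichiometry_matrix_survives_round_trip(self, intact, tmp_path):
        net = build_network(intact, [fixtures("wff_intact")])
        path = tmp_path / "with_target.xml"
        export_sbml(net, path)
        doc = import_sbml(path)
        rows0, rids0, mat0 = stoichiometry_matrix(net)
        rows1, rids1, mat1 = doc.stoichiometry_matrix()
        assert rows0 == rows1
        assert rids0 == rids1
        np.testing.assert_array_equal(mat0, mat1)

    def test_equilibrium_constants_reproduce_allosteric_parameters(self, intact, tmp_path):
        net = build_network(intact)
        path = tmp_path / "intact.xml"
        export_sbml(net, path)
        keq = import_sbml(path).equilibrium_constants()
        # apo flips give back L_N and L_C; singly-loaded flips the c factors
        apo = "CaM_TT_A0B0C0D0"
        assert 1.0 / keq[f"flip_N__{apo}"] == pytest.approx(intact.N.L, rel=1e-12)
        assert 1.0 / keq[f"flip_C__{apo}"] == pytest.approx(intact.C.L, rel=1e-12)
        one_n = "CaM_TT_A1B0C0D0"
        one_c = "CaM_TT_A0B0C1D0"
        assert 1.0 / keq[f"flip_N__{one_n}"] == pytest.approx(
            intact.N.L * intact.N.c, rel=1e-12
        )
        assert 1.0 / keq[f"flip_C__{one_c}"] == pytest.approx(
            intact.C.L * intact.C.c, rel=1e-12
        )
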