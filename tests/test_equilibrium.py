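"""Mass-balance equilibrium solving at total reagent concentrations."""

import numpy as np
import pytest

from hemicam.allosteric import LobeParams, TargetSpec, lobe_saturation
from hemicam.equilibrium import (
    IntactSystem,
    LobeSystem,
    Mixture,
    competing_targets_curve,
    default_ca_grid,
    solve_free_concentrations,
    titration_curve,
)
from hemicam.hill import half_saturation
from hemicam.synthetic import fixtures


def grid_scan_free_target(system, ca, total_t, p_tot, name, n=400_000):
    """Brute-force oracle: scan free target for the conservation root."""
    frees = np.linspace(0.0, total_t, n)
    resid = np.array(
        [total_t - f - p_tot * system.bound_targets(ca, {name: f})[name] for f in frees]
    )
    i = np.argmin(np.abs(resid))
    return frees[i]


class TestSolveFreeConcentrations:
    def test_non_binding_target_stays_free(self, tr2c):
        spec = TargetSpec("inert", K_Rt=1e12, K_Tt=1e12)
        mix = Mixture(
            system=LobeSystem(tr2c, [spec]),
            protein_total=5e-6,
            target_totals={"inert": 1e-6},
        )
        sol = solve_free_concentrations(mix, 1e-6)
        assert sol.free_targets["inert"] == pytest.approx(1e-6, rel=1e-9)

    def test_strong_binding_excess_protein_depletes_target(self, tr2c):
        # sub-nanomolar affinity for the dominant (T) state, protein in excess
        spec = TargetSpec("tight", K_Rt=1e-10, K_Tt=1e-10, stoichiometry="per_molecule")
        mix = Mixture(
            system=LobeSystem(tr2c, [spec]),
            protein_total=100e-6,
            target_totals={"tight": 1e-6},
        )
        sol = solve_free_concentrations(mix, 1e-8)
        assert sol.free_targets["tight"] < 0.01 * 1e-6

    def test_matches_grid_scan_oracle(self, tr2c):
        nav = fixtures("nav_fitted")
        system = LobeSystem(tr2c, [nav])
        total_t, p_tot = 7e-6, 5e-6
        mix = Mixture(system=system, protein_total=p_tot, target_totals={nav.name: total_t})
        for ca in (1e-7, 2e-6, 5e-5):
            sol = solve_free_concentrations(mix, ca)
            oracle = grid_scan_free_target(system, ca, total_t, p_tot, nav.name)
            assert sol.free_targets[nav.name] == pytest.approx(
                oracle, rel=1e-4, abs=2 * total_t / 400_000
            )

    def test_mass_conservation_at_solution(self, tr2c):
        wff = fixtures("wff_lobe")
        mix = Mixture(
            system=LobeSystem(tr2c, [wff]),
            protein_total=5e-6,
            target_totals={"WFF": 7e-6},
        )
        for ca in default_ca_grid(10):
            sol = solve_free_concentrations(mix, float(ca))
            total = sol.free_targets["WFF"] + sol.bound_targets["WFF"]
            assert total == pytest.approx(7e-6, rel=1e-10)
            # exclusivity: bound target never exceeds protein
            assert sol.bound_targets["WFF"] <= 5e-6 * (1 + 1e-12)

    def test_conserved_total_calcium_mode(self, tr2c):
        mix = Mixture(system=LobeSystem(tr2c), protein_total=5e-6,
                      calcium_mode="conserved_total")
        sol = solve_free_concentrations(mix, 8e-6)
        assert sol.ca_free + sol.bound_ca == pytest.approx(8e-6, rel=1e-10)
        assert sol.ca_free < 8e-6


class TestTitrationCurve:
    def test_intact_without_targets_is_mean_of_lobes(self, intact):
        grid = default_ca_grid(60)
        mix = Mixture(system=IntactSystem(intact), protein_total=5e-6)
        curve = titration_curve(mix, grid)
        mean = 0.5 * (lobe_saturation(intact.N, grid) + lobe_saturation(intact.C, grid))
        assert np.max(np.abs(curve.Y - mean)) < 1e-10

    def test_curve_monotone_for_single_protein(self, tr2c):
        nav = fixtures("nav_fitted")
        mix = Mixture(system=LobeSystem(tr2c, [nav]), protein_total=5e-6,
                      target_totals={nav.name: 7e-6})
        curve = titration_curve(mix)
        assert np.all(np.diff(curve.Y) > 0)

    def test_doubling_nav_peptide_gives_no_further_shift(self, tr2c):
        """Raising the peptide:protein ratio from 1:1.4 to 1:2.8 leaves the
        half-saturation essentially unchanged once the effect saturates."""
        nav = fixtures("nav_fitted")
        halves = {}
        for ratio in (1.4, 2.8):
            mix = Mixture(system=LobeSystem(tr2c, [nav]), protein_total=5e-6,
                          target_totals={nav.name: ratio * 5e-6})
            halves[ratio] = half_saturation(
                lambda ca: solve_free_concentrations(mix, ca).Y
            )
        assert abs(np.log10(halves[2.8] / halves[1.4])) < 0.05

    def test_wf10_on_intact_calmodulin_is_biphasic(self, intact):
        """A target that stabilises only the C-lobe's open form splits the
        intact saturation curve into two rises (two maxima of dY/dlog ca)."""
        wf10 = fixtures("wf10_intact")
        mix = Mixture(system=IntactSystem(intact, [wf10]), protein_total=5e-6,
                      target_totals={"WF10": 7e-6})
        grid = default_ca_grid(200)
        curve = titration_curve(mix, grid)
        d = np.gradient(curve.Y, np.log10(grid))
        n_maxima = sum(
            1 for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] > d[i + 1]
        )
        assert n_maxima == 2


class TestCompetingTargets:
    def test_competition_requires_exclusive_binding(self, tr2c):
        ng, cam = fixtures("ng"), fixtures("camkii")
        mix = Mixture(system=LobeSystem(tr2c, [ng, cam], binding="independent"),
                      protein_total=40e-6,
                      target_totals={"Ng": 40e-6, "CaMKII": 100e-6})
        with pytest.raises(ValueError):
            competing_targets_curve(mix)

    def test_single_target_shifts_have_opposite_signs(self, tr2c):
        from hemicam.allosteric import half_saturation_ca

        base = half_saturation_ca(tr2c)
        ng, cam = fixtures("ng"), fixtures("camkii")
        assert ng.e > 1 and cam.e < 1
        shifts = {}
        for spec, total in ((ng, 40e-6), (cam, 100e-6)):
            mix = Mixture(system=LobeSystem(tr2c, [spec], binding="exclusive"),
                          protein_total=40e-6, target_totals={spec.name: total})
            shifts[spec.name] = half_saturation(
                lambda ca: solve_free_concentrations(mix, ca).Y
            )
        assert shifts["Ng"] > base  # T-stabilising: right shift
        assert shifts["CaMKII"] < base  # R-stabilising: left shift

    def test_mixture_nearly_cancels(self, tr2c):
        """With both targets at the benchmark composition the opposing shifts
        almost cancel: the mixed half-saturation lies strictly between the
        single-target extremes and within a factor two of target-free."""
        from hemicam.allosteric import half_saturation_ca

        base = half_saturation_ca(tr2c)
        ng, cam = fixtures("ng"), fixtures("camkii")
        single = {}
        for spec, total in ((ng, 40e-6), (cam, 100e-6)):
            mix = Mixture(system=LobeSystem(tr2c, [spec], binding="exclusive"),
                          protein_total=40e-6, target_totals={spec.name: total})
            single[spec.name] = half_saturation(
                lambda ca: solve_free_concentrations(mix, ca).Y
            )
        both = Mixture(system=LobeSystem(tr2c, [ng, cam], binding="exclusive"),
                       protein_total=40e-6,
                       target_totals={"Ng": 40e-6, "CaMKII": 100e-6})
        curve = competing_targets_curve(both, default_ca_grid(60))
        mixed_half = half_saturation(
            lambda ca: solve_free_concentrations(both, ca).Y
        )
        assert single["CaMKII"] < mixed_half < single["Ng"]
        assert 0.5 <= mixed_half / base <= 2.0
        assert np.all(np.diff(curve.Y) > 0)

    def test_reduces_to_single_target_curve_when_other_absent(self, tr2c):
        ng, cam = fixtures("ng"), fixtures("camkii")
        grid = default_ca_grid(15)
        both = Mixture(system=LobeSystem(tr2c, [ng, cam], binding="exclusive"),
                       protein_total=40e-6,
                       target_totals={"Ng": 40e-6, "CaMKII": 0.0})
        only = Mixture(system=LobeSystem(tr2c, [ng], binding="exclusive"),
                       protein_total=40e-6, target_totals={"Ng": 40e-6})
        np.testing.assert_allclose(
            titration_curve(both, grid).Y, titration_curve(only, grid).Y, rtol=1e-10
        )


class TestMixtureValidation:
    def test_unknown_target_total_rejected(self, tr2c):
        with pytest.raises(ValueError):
            Mixture(system=LobeSystem(tr2c), protein_total=1e-6,
                    target_totals={"ghost": 1e-6})

    def test_negative_totals_rejected(self, tr2c):
        with pytest.raises(ValueError):
            Mixture(system=LobeSystem(tr2c), protein_total=-1e-6)
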