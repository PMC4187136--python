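"""Equilibrium solver: conservation, mass action, complementarity, oracles."""
import math
from dataclasses import replace

import pytest

from conftest import reduced_composition
from gibbs_oracle import minimize_reduced_system

from protocean.scenario import build_composition, default_early_ocean
from protocean.speciation import (
    WATER_MOLES_PER_KG,
    EquilibriumState,
    InfeasibleCompositionError,
    SolverOptions,
    SystemComposition,
    ammonia_redox_equilibrium,
    saturation_index,
    solve_equilibrium,
    verify_state,
)

STRUVITE = "MgNH4PO4:6H2O"


def water_only():
    return SystemComposition(
        element_totals={"H": 2 * WATER_MOLES_PER_KG, "O": WATER_MOLES_PER_KG}
    )


class TestBasics:
    def test_pure_water_is_neutral(self, db):
        state = solve_equilibrium(water_only(), db)
        assert state.pH == pytest.approx(7.00, abs=5e-3)
        assert state.molality("H+") == pytest.approx(state.molality("OH-"), rel=1e-6)
        assert not state.solid_assemblage

    def test_phosphate_buffer_matches_closed_form(self, db):
        # 0.008 NaH2PO4 + 0.002 Na2HPO4 per kg: pH = pKa2 + log10(1/4)
        # = 7.20566 - 0.60206 = 6.60360 under ideal activities
        tot = {
            "H": 2 * WATER_MOLES_PER_KG + 0.018,
            "O": WATER_MOLES_PER_KG + 0.04,
            "Na": 0.012,
            "P": 0.01,
        }
        state = solve_equilibrium(SystemComposition(element_totals=tot), db)
        assert state.pH == pytest.approx(6.60360, abs=1e-3)
        assert not state.solid_assemblage

    def test_infeasible_composition_raises(self, db, ocean):
        comp = build_composition(replace(ocean, total_phosphate=1e-5))
        opts = SolverOptions(
            exclude_species=frozenset(
                r.name for r in db if "P" in r.formula and r.formula["P"] > 0
            )
        )
        with pytest.raises(InfeasibleCompositionError):
            solve_equilibrium(comp, db, opts)

    def test_zero_total_elements_drop_their_species(self, db, ocean):
        comp = build_composition(replace(ocean, mg_molality=0.0, ca_molality=0.0,
                                         mg_ca_ratio_override=None))
        state = solve_equilibrium(comp, db)
        assert all("Mg" not in name and "Ca" not in name
                   for name in state.species_moles)


class TestConservation:
    def test_default_ocean_state_verifies_clean(self, db, ocean):
        comp = build_composition(ocean)
        state = solve_equilibrium(comp, db)
        report = verify_state(state, comp, db)
        assert report.ok, report.summary()
        assert abs(report.charge_residual) < 1e-12

    def test_scale_invariance_times_ten(self, db, ocean):
        comp = build_composition(replace(ocean, mg_ca_ratio_override=10_000,
                                         ammonium_molality=0.2))
        a = solve_equilibrium(comp, db)
        b = solve_equilibrium(comp.scaled(10.0), db)
        assert b.pH == pytest.approx(a.pH, abs=1e-9)
        for name, p in a.gas_partial_pressures.items():
            assert b.gas_partial_pressures[name] == pytest.approx(p, rel=1e-8)
        for name, n in a.species_moles.items():
            assert b.species_moles[name] == pytest.approx(10.0 * n, rel=1e-7)
        for name, si in a.si_table.items():
            assert b.si_table[name] == pytest.approx(si, abs=1e-8)

    def test_perturbed_state_fails_verification(self, db, ocean):
        comp = build_composition(replace(ocean, mg_ca_ratio_override=10_000,
                                         ammonium_molality=0.2))
        state = solve_equilibrium(comp, db)
        assert STRUVITE in state.solid_assemblage
        moved = dict(state.species_moles)
        shift = moved[STRUVITE] * 0.5
        moved[STRUVITE] -= shift
        moved["Mg+2"] += shift
        moved["NH4+"] += shift
        moved["PO4-3"] += shift
        bad = EquilibriumState(
            species_moles=moved,
            solid_assemblage=state.solid_assemblage,
            pH=state.pH,
            gas_partial_pressures=state.gas_partial_pressures,
            total_G=state.total_G,
            composition=state.composition,
            basis_activities=state.basis_activities,
            si_table=state.si_table,
            water_kg=state.water_kg,
            options=state.options,
            frozen_species=state.frozen_species,
        )
        report = verify_state(bad, comp, db)
        assert not report.ok


class TestSaturationIndex:
    def test_present_solids_sit_at_equilibrium(self, db, ocean):
        comp = build_composition(replace(ocean, mg_ca_ratio_override=10_000,
                                         ammonium_molality=0.2))
        state = solve_equilibrium(comp, db)
        for solid in state.solid_assemblage:
            assert abs(saturation_index(state, solid, db)) < 1e-6

    def test_hand_specified_iap(self, db):
        # Mg2+ = NH4+ = PO4-3 = 1e-3 -> SI = -9 + pKsp(fixture) = -9 + 13.25996
        state = EquilibriumState(
            species_moles={}, solid_assemblage=frozenset(), pH=7.0,
            gas_partial_pressures={}, total_G=0.0,
            composition=water_only(),
            basis_activities={"H2O": 1.0, "Mg+2": 1e-3, "NH4+": 1e-3,
                              "PO4-3": 1e-3},
            si_table={}, water_kg=1.0,
        )
        si = saturation_index(state, STRUVITE, db)
        assert si == pytest.approx(-9 + 13.25996, abs=1e-4)

    def test_modern_seawater_never_saturates_struvite(self, db, ocean):
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            state = solve_equilibrium(
                build_composition(replace(ocean, ammonia_fraction=frac)), db
            )
            # with no reduced N at all (fraction 0) struvite is structurally
            # absent from the candidate table; otherwise it must be undersaturated
            assert state.si_table.get(STRUVITE, -math.inf) < 0
            assert STRUVITE not in state.solid_assemblage

    def test_struvite_forms_at_high_mg_ca_and_ammonium(self, db, ocean):
        state = solve_equilibrium(
            build_composition(replace(ocean, mg_ca_ratio_override=10_000,
                                      ammonium_molality=0.2)), db
        )
        assert STRUVITE in state.solid_assemblage


class TestAmmoniaRedox:
    def test_zero_hydrogen_gives_zero_ammonia(self, db):
        assert ammonia_redox_equilibrium(1.0, 0.0, db) == 0.0

    def test_unit_pressures_give_K(self, db):
        # K = 10^(16.450 / (RT ln10)) = 10^2.88192 from the fixture NH3(g)
        assert ammonia_redox_equilibrium(1.0, 1.0, db) == pytest.approx(
            10 ** 2.881915, rel=1e-4
        )

    def test_monotone_in_both_arguments(self, db):
        vals = [ammonia_redox_equilibrium(0.5, p, db) for p in (1e-6, 1e-4, 1e-2)]
        assert vals == sorted(vals)
        vals = [ammonia_redox_equilibrium(p, 1e-3, db) for p in (0.1, 0.5, 0.9)]
        assert vals == sorted(vals)

    def test_struvite_supplants_farringtonite_near_handoff(self, db, ocean):
        # just above the fugacity boundary the ammonium supply crosses the
        # struvite threshold and struvite displaces the magnesium phosphate;
        # the transient two-solid active set must resolve to struvite alone
        spec = replace(ocean, mg_ca_ratio_override=10_000,
                       h2_partial_pressure=1.778e-5)
        state = solve_equilibrium(build_composition(spec), db)
        assert STRUVITE in state.solid_assemblage
        assert "Mg3(PO4)2" not in state.solid_assemblage
        assert verify_state(state, build_composition(spec), db).ok

    def test_struvite_needs_high_hydrogen_fugacity(self, db, ocean):
        # H2-coupled mode: sweeping pH2 upward drives the ocean into the
        # struvite field only at high pH2, and presence is monotone
        present = []
        for ph2 in (1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3):
            spec = replace(ocean, mg_ca_ratio_override=10_000,
                           h2_partial_pressure=ph2)
            state = solve_equilibrium(build_composition(spec), db)
            present.append(STRUVITE in state.solid_assemblage)
        assert present[0] is False
        assert present[-1] is True
        assert present == sorted(present)  # no re-entrant presence


class TestLeChatelier:
    def test_struvite_non_decreasing_in_ammonium(self, db, ocean):
        tmpl = replace(ocean, mg_ca_ratio_override=10_000, total_phosphate=1e-4)
        moles = []
        for i in range(10):
            amm = 0.05 * 10 ** (i / 9)  # 0.05 -> 0.5
            st = solve_equilibrium(
                build_composition(replace(tmpl, ammonium_molality=amm)), db
            )
            moles.append(st.species_moles.get(STRUVITE, 0.0))
        assert all(b >= a - 1e-12 for a, b in zip(moles, moles[1:]))
        assert moles[-1] > moles[0]

    def test_struvite_non_decreasing_in_magnesium(self, db, ocean):
        tmpl = replace(ocean, ammonium_molality=0.3, total_phosphate=1e-4,
                       ca_molality=1e-6)
        moles = []
        for i in range(10):
            mg = 0.05 * 10 ** (i / 9)
            st = solve_equilibrium(
                build_composition(replace(tmpl, mg_molality=mg)), db
            )
            moles.append(st.species_moles.get(STRUVITE, 0.0))
        assert all(b >= a - 1e-12 for a, b in zip(moles, moles[1:]))


class TestGibbsGridOracle:
    @pytest.mark.parametrize(
        "mg,n,p",
        [(0.002, 0.01, 0.005), (0.0005, 0.02, 0.001), (1e-4, 0.005, 5e-4)],
    )
    def test_solver_matches_brute_force_minimum(self, db, reduced_opts, mg, n, p):
        comp = reduced_composition(mg, n, p)
        state = solve_equilibrium(comp, db, reduced_opts)
        oracle = minimize_reduced_system(db, mg, n, p, comp.element_totals["H"])
        tol_e1 = max(oracle.resolution["struvite_mol"] * 3, 1e-9)
        assert state.species_moles.get(STRUVITE, 0.0) == pytest.approx(
            oracle.struvite_mol, abs=tol_e1
        )
        assert state.pH == pytest.approx(oracle.pH, abs=0.05)
        for name in ("Mg+2", "NH4+", "HPO4-2", "PO4-3"):
            assert state.molality(name) == pytest.approx(
                oracle.molalities[name], rel=0.02
            )

    def test_oracle_state_passes_verification_at_grid_tolerance(
        self, db, reduced_opts
    ):
        comp = reduced_composition()
        oracle = minimize_reduced_system(db, 0.002, 0.01, 0.005,
                                         comp.element_totals["H"])
        mols = dict(oracle.molalities)
        mols["OH-"] = oracle.molalities["OH-"]
        state = EquilibriumState(
            species_moles={**mols, STRUVITE: oracle.struvite_mol,
                           "H2O": WATER_MOLES_PER_KG},
            solid_assemblage=frozenset({STRUVITE}),
            pH=oracle.pH,
            gas_partial_pressures={},
            total_G=oracle.total_G,
            composition=comp,
            basis_activities={"H2O": 1.0, "H+": mols["H+"], "Mg+2": mols["Mg+2"],
                              "NH4+": mols["NH4+"], "HPO4-2": mols["HPO4-2"]},
            si_table={}, water_kg=1.0,
            options=SolverOptions(si_tol=0.05, balance_tol=0.05, charge_tol=1e-6),
        )
        report = verify_state(state, comp, db, state.options)
        mass_action = [f for f in report.findings if "mass-action" in f
                       or "SI" in f or "supersaturated" in f]
        assert not mass_action, report.summary()
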