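"""Core data model, ODE assembly and simulation engine."""

import numpy as np
import pytest

from cocktail_pbpk import (
    ChemSpecies,
    DefinitionError,
    DomainError,
    DoseEvent,
    ModelDefinition,
    Process,
    build_ode_system,
    get_family_model,
    mass_balance_report,
    mgkg_to_nmol,
    simulate,
)
from conftest import one_compartment_model


class TestDoseConversion:
    @pytest.mark.parametrize(
        "dose,bw,mw,expected",
        [
            (2.0, 0.025, 325.77, 153.48),   # midazolam cocktail dose
            (5.0, 0.025, 194.19, 643.70),   # caffeine cocktail dose
            (1.0, 1.0, 1e6, 1.0),           # unit sanity: 1 mg at MW 1e6 = 1 nmol
        ],
    )
    def test_mgkg_to_nmol(self, dose, bw, mw, expected):
        assert mgkg_to_nmol(dose, bw, mw) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("bad", [(0.0, 0.025, 300.0), (2.0, -1.0, 300.0), (2.0, 0.025, 0.0)])
    def test_non_positive_inputs_rejected(self, bad):
        with pytest.raises(DomainError):
            mgkg_to_nmol(*bad)


class TestDefinitionValidation:
    def test_undeclared_species_is_named_in_error(self, midazolam_model):
        m = midazolam_model.copy()
        m.processes.append(
            Process(kind="total_hepatic_clearance", substrate="X", source="hepatocyte",
                    target="unknown_sink", params={"cl": 0.1}, product="unknown_sink")
        )
        with pytest.raises(DefinitionError, match="'X'"):
            build_ode_system(m)

    def test_cyclic_metabolite_graph_rejected(self, midazolam_model):
        m = midazolam_model.copy()
        m.processes.append(
            Process(kind="enzymatic_first_order", substrate="1-hydroxymidazolam-glucuronide",
                    source="hepatocyte", target="hepatocyte", params={"cl": 0.1},
                    gene="Cyp3a11", product="midazolam")
        )
        with pytest.raises(DefinitionError, match="cycl"):
            build_ode_system(m)

    def test_midazolam_family_state_layout(self, midazolam_model):
        system = build_ode_system(midazolam_model)
        # 3 chemical species x (5 compartments + 3 sinks)
        assert system.n_state == 24
        assert system.index("plasma", "midazolam") == 0
        assert system.index("urine", "midazolam") == 5

    def test_mm_transport_linear_limit(self):
        # vmax 10, km 1000, Cu 1 -> rate = 10/(1001) = 0.00999 nmol/min
        m = one_compartment_model()
        m.processes = [
            Process(kind="mm_transport", substrate="drug", source="plasma",
                    target="rest_of_body", params={"vmax": 10.0, "km": 1000.0})
        ]
        system = build_ode_system(m)
        y = np.zeros(system.n_state)
        y[system.index("plasma", "drug")] = 1.0  # volume 1 L -> C = Cu = 1 nmol/L
        dy = system.rhs(0.0, y)
        assert dy[system.index("plasma", "drug")] == pytest.approx(-0.00999, rel=1e-3)

    def test_roundtrip_json(self, midazolam_model):
        again = ModelDefinition.from_json(midazolam_model.to_json())
        assert again.to_dict() == midazolam_model.to_dict()


class TestSimulate:
    def test_mono_exponential_closed_form(self, single_compartment, bolus_100):
        """One-compartment reduction matches C0*exp(-(cl/V)*t) to rel 1e-6."""
        t = np.linspace(0.0, 240.0, 49)
        tc = simulate(build_ode_system(single_compartment), bolus_100, t)
        expected = 100.0 * np.exp(-0.01 * t)
        np.testing.assert_allclose(tc.concentration("plasma", "drug"), expected, rtol=1e-6)

    def test_empty_dose_list_gives_zero_timecourse(self, single_compartment):
        tc = simulate(build_ode_system(single_compartment), [], np.linspace(0, 60, 7))
        assert np.all(tc.states == 0.0)

    def test_determinism_bitwise(self, midazolam_model, midazolam_doses):
        system = build_ode_system(midazolam_model)
        grid = np.linspace(0, 120, 25)
        a = simulate(system, midazolam_doses, grid)
        b = simulate(system, midazolam_doses, grid)
        assert a.states.tobytes() == b.states.tobytes()

    def test_sink_monotonicity(self, midazolam_model, midazolam_doses, fine_grid):
        tc = simulate(build_ode_system(midazolam_model), midazolam_doses, fine_grid)
        for sink in ("urine", "bile", "unknown_sink"):
            for sp in midazolam_model.species_names():
                assert np.all(np.diff(tc.amount(sink, sp)) >= -1e-7)

    def test_dose_at_grid_point_recorded_post_bolus(self, single_compartment):
        doses = [DoseEvent(species="drug", time=0.0, amount=100.0),
                 DoseEvent(species="drug", time=60.0, amount=50.0)]
        tc = simulate(build_ode_system(single_compartment), doses, np.array([0.0, 30.0, 60.0, 90.0]))
        c = tc.concentration("plasma", "drug")
        assert c[0] == pytest.approx(100.0)
        # at t=60 the second bolus is already on board
        assert c[2] == pytest.approx(100.0 * np.exp(-0.6) + 50.0, rel=1e-6)


class TestLinearity:
    def test_doubling_dose_doubles_concentrations_below_km(self):
        """With transporters far below saturation the system is linear."""
        m = get_family_model("torsemide")
        grid = np.linspace(0, 120, 13)
        system = build_ode_system(m)
        small = [DoseEvent(species="torsemide", time=0.0, amount=0.01)]
        double = [DoseEvent(species="torsemide", time=0.0, amount=0.02)]
        tc1 = simulate(system, small, grid)
        tc2 = simulate(system, double, grid)
        mask = tc1.states[1:] > 1e-12
        np.testing.assert_allclose(tc2.states[1:][mask], 2.0 * tc1.states[1:][mask], rtol=1e-4)

    def test_linearity_fails_under_saturation(self):
        """At cocktail dose the uptake carrier saturates: doubling the dose
        must NOT double the hepatocyte exposure."""
        m = get_family_model("torsemide")
        grid = np.linspace(0, 120, 13)
        system = build_ode_system(m)
        full = [DoseEvent(species="torsemide", time=0.0, amount=143.5)]
        twice = [DoseEvent(species="torsemide", time=0.0, amount=287.0)]
        tc1 = simulate(system, full, grid)
        tc2 = simulate(system, twice, grid)
        hep1 = tc1.amount("hepatocyte", "hydroxy-torsemide")[-1]
        hep2 = tc2.amount("hepatocyte", "hydroxy-torsemide")[-1]
        assert hep2 < 1.9 * hep1


class TestMassBalance:
    def test_noise_free_simulation_conserves_dose(self, midazolam_model, midazolam_doses, fine_grid):
        tc = simulate(build_ode_system(midazolam_model), midazolam_doses, fine_grid)
        report = mass_balance_report(tc, midazolam_doses)
        assert np.abs(report["rel_deviation"]).max() <= 1e-6

    def test_sequential_boluses_tracked_piecewise(self, single_compartment):
        doses = [DoseEvent(species="drug", time=0.0, amount=100.0),
                 DoseEvent(species="drug", time=60.0, amount=100.0)]
        tc = simulate(build_ode_system(single_compartment), doses, np.array([0.0, 30.0, 60.0, 120.0]))
        report = mass_balance_report(tc, doses)
        np.testing.assert_allclose(report["cum_dose_nmol"], [100.0, 100.0, 200.0, 200.0])
        assert np.abs(report["rel_deviation"]).max() <= 1e-6

    def test_empty_doses_with_nonzero_tc_flagged(self, single_compartment, bolus_100):
        tc = simulate(build_ode_system(single_compartment), bolus_100, np.linspace(0, 60, 7))
        with pytest.raises(DefinitionError, match="empty dose list"):
            mass_balance_report(tc, [])


class TestChemSpeciesInvariants:
    @pytest.mark.parametrize("field,value", [("fraction_unbound", 0.0), ("fraction_unbound", 1.5),
                                             ("molecular_weight", -1.0), ("passive_exchange_cl", -0.1)])
    def test_invalid_species_rejected(self, field, value):
        sp = ChemSpecies(name="x", molecular_weight=100.0, fraction_unbound=0.5)
        setattr(sp, field, value)
        with pytest.raises(DefinitionError):
            sp.validate()
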