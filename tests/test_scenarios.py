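"""Cirrhosis scaling rules, hypothesis variants and physiology knobs."""

import numpy as np
import pytest

from cocktail_pbpk import (
    ConfigError,
    DomainError,
    HypothesisSpec,
    ScalingMap,
    SelectorError,
    apply_cirrhosis,
    apply_hypothesis,
    auc_trapezoid,
    build_ode_system,
    get_family_model,
    scale_physiology,
    simulate,
)

G = "1-hydroxymidazolam-glucuronide"


class TestApplyCirrhosis:
    def test_cyp_clearance_reduced_to_fraction(self):
        m = get_family_model("caffeine")
        ix = m.find_processes(gene="Cyp1a2")[0]
        before = m.processes[ix].params["cl"]
        out = apply_cirrhosis(m, ScalingMap(), cyp_fraction=0.11)
        assert out.processes[ix].params["cl"] == pytest.approx(0.11 * before, rel=1e-12)

    def test_ugt_processes_unchanged(self, midazolam_model):
        out = apply_cirrhosis(midazolam_model, ScalingMap(), cyp_fraction=0.11)
        ix = midazolam_model.find_processes(gene="Ugt")[0]
        assert out.processes[ix].params["cl"] == midazolam_model.processes[ix].params["cl"]

    def test_transporter_scaled_by_log2fc(self, midazolam_model):
        sc = ScalingMap().set_from_log2fc("Abcc4", 3.95)
        out = apply_cirrhosis(midazolam_model, sc, cyp_fraction=1.0)
        ix = midazolam_model.find_processes(gene="Abcc4")[0]
        ratio = out.processes[ix].params["vmax"] / midazolam_model.processes[ix].params["vmax"]
        assert ratio == pytest.approx(2.0 ** 3.95, rel=1e-12)
        assert sc.provenance["Abcc4"] == "from_log2fc(3.95)"

    def test_input_model_not_mutated(self, midazolam_model):
        snapshot = midazolam_model.to_json()
        apply_cirrhosis(midazolam_model, ScalingMap().set_fixed("Abcc3", 5.0), cyp_fraction=0.11)
        assert midazolam_model.to_json() == snapshot

    def test_unmatched_scaling_gene_warns_not_raises(self, midazolam_model):
        with pytest.warns(UserWarning, match="Slco1b2"):
            apply_cirrhosis(midazolam_model, ScalingMap().set_fixed("Slco1b2", 0.5))

    def test_invalid_cyp_fraction(self, midazolam_model):
        with pytest.raises(DomainError):
            apply_cirrhosis(midazolam_model, ScalingMap(), cyp_fraction=0.0)


class TestApplyHypothesis:
    def test_h3_scales_sinusoidal_export_only(self, midazolam_model):
        out = apply_hypothesis(midazolam_model, HypothesisSpec(id="H3", theta=110.0))
        for gene, factor in (("Abcc3", 110.0), ("Abcc4", 110.0), ("Abcc2", 1.0)):
            ix = midazolam_model.find_processes(gene=gene)[0]
            ratio = out.processes[ix].params["vmax"] / midazolam_model.processes[ix].params["vmax"]
            assert ratio == pytest.approx(factor, rel=1e-12)

    def test_h1_scales_ugt_step(self, midazolam_model):
        out = apply_hypothesis(midazolam_model, HypothesisSpec(id="H1", theta=28.0))
        ix = midazolam_model.find_processes(gene="Ugt")[0]
        ratio = out.processes[ix].params["cl"] / midazolam_model.processes[ix].params["cl"]
        assert ratio == pytest.approx(28.0, rel=1e-12)

    def test_h2_scales_canalicular_export(self, midazolam_model):
        out = apply_hypothesis(midazolam_model, HypothesisSpec(id="H2", theta=0.1))
        ix = midazolam_model.find_processes(gene="Abcc2")[0]
        ratio = out.processes[ix].params["vmax"] / midazolam_model.processes[ix].params["vmax"]
        assert ratio == pytest.approx(0.1, rel=1e-12)

    def test_species_restriction_in_codeine_family(self):
        m = get_family_model("codeine")
        spec = HypothesisSpec(id="H1", theta=3.9, species="codeine-6-glucuronide")
        out = apply_hypothesis(m, spec)
        ix_c6g = m.find_processes(gene="Ugt", product="codeine-6-glucuronide")[0]
        ix_m3g = m.find_processes(gene="Ugt", product="morphine-3-glucuronide")[0]
        assert out.processes[ix_c6g].params["cl"] == pytest.approx(3.9 * m.processes[ix_c6g].params["cl"])
        assert out.processes[ix_m3g].params["cl"] == m.processes[ix_m3g].params["cl"]

    def test_no_glucuronide_means_selector_error(self):
        with pytest.raises(SelectorError, match="H3"):
            apply_hypothesis(get_family_model("caffeine"), HypothesisSpec(id="H3", theta=10.0))

    def test_commutes_with_cirrhosis_on_disjoint_targets(self, midazolam_model):
        sc = ScalingMap().set_fixed("Abcc2", 0.5)
        spec = HypothesisSpec(id="H3", theta=10.0)
        a = apply_hypothesis(apply_cirrhosis(midazolam_model, sc, 0.11), spec)
        b = apply_cirrhosis(apply_hypothesis(midazolam_model, spec), sc, 0.11)
        assert a.to_json() == b.to_json()


class TestIdentity:
    def test_null_scenario_is_bit_identical(self, midazolam_model, midazolam_doses):
        """cyp_fraction=1, empty scaling and theta=1 must reproduce the
        reference simulation exactly."""
        variant = apply_hypothesis(
            apply_cirrhosis(midazolam_model, ScalingMap(), cyp_fraction=1.0),
            HypothesisSpec(id="H3", theta=1.0),
        )
        grid = np.linspace(0, 120, 25)
        ref = simulate(build_ode_system(midazolam_model), midazolam_doses, grid)
        out = simulate(build_ode_system(variant), midazolam_doses, grid)
        assert ref.states.tobytes() == out.states.tobytes()


class TestMonotonicity:
    def test_h3_theta_grid_moves_glucuronide_out_of_hepatocyte(self, midazolam_model, midazolam_doses):
        grid = np.linspace(0, 120, 61)
        aucs, hep = [], []
        for theta in (1.0, 3.0, 10.0, 30.0, 110.0):
            mm = apply_hypothesis(midazolam_model, HypothesisSpec(id="H3", theta=theta))
            tc = simulate(build_ode_system(mm), midazolam_doses, grid)
            aucs.append(auc_trapezoid(grid, tc.concentration("plasma", G)))
            hep.append(np.trapezoid(tc.amount("hepatocyte", G), grid))
        assert np.all(np.diff(aucs) > 0)
        assert np.all(np.diff(hep) < 0)


class TestScalePhysiology:
    def test_identity_knob(self, midazolam_model, midazolam_doses):
        out = scale_physiology(midazolam_model, {"liver_blood_flow_fraction": 1.0})
        grid = np.linspace(0, 60, 13)
        a = simulate(build_ode_system(midazolam_model), midazolam_doses, grid)
        b = simulate(build_ode_system(out), midazolam_doses, grid)
        assert a.states.tobytes() == b.states.tobytes()

    def test_halved_liver_flow_reduces_hepatic_clearance(self, midazolam_model, midazolam_doses):
        grid = np.linspace(0, 120, 61)
        ref = simulate(build_ode_system(midazolam_model), midazolam_doses, grid)
        slow = scale_physiology(midazolam_model, {"liver_blood_flow_fraction": 0.5})
        out = simulate(build_ode_system(slow), midazolam_doses, grid)
        a_ref = auc_trapezoid(grid, ref.concentration("plasma", "midazolam"))
        a_out = auc_trapezoid(grid, out.concentration("plasma", "midazolam"))
        assert a_out > a_ref

    def test_doubled_plasma_volume_halves_initial_concentration(self, midazolam_model, midazolam_doses):
        big = scale_physiology(midazolam_model, {"plasma_volume_fraction": 2.0})
        grid = np.linspace(0, 30, 4)
        a = simulate(build_ode_system(midazolam_model), midazolam_doses, grid)
        b = simulate(build_ode_system(big), midazolam_doses, grid)
        ratio = b.concentration("plasma", "midazolam")[0] / a.concentration("plasma", "midazolam")[0]
        assert ratio == pytest.approx(0.5, rel=1e-12)

    def test_unknown_knob_rejected(self, midazolam_model):
        with pytest.raises(ConfigError, match="unknown physiology knob"):
            scale_physiology(midazolam_model, {"kidney_volume_fraction": 0.5})
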