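"""The two-conformation assay simulator."""
import dataclasses

import numpy as np
import pytest

from scepharm.binding import fit_competition, fit_saturation, inverse_cheng_prusoff
from scepharm.functional import fit_one_site, fit_two_site_stim, normalize_plate
from scepharm.synthetic import (
    GroundTruth,
    SimulationConfig,
    expected_functional_pct,
    functional_components,
    make_study_fixture,
    simulate_binding_plate,
    simulate_functional_curve,
)


class TestGroundTruthValidation:
    def test_affinity_range(self):
        with pytest.raises(ValueError, match="outside"):
            GroundTruth("x", "neutral", logKd_cce=-13.5)

    def test_nonbinder_must_be_silent(self):
        with pytest.raises(ValueError, match="zero efficacy"):
            GroundTruth("x", "nonbinder", efficacy_cce=0.1)
        with pytest.raises(ValueError, match="absent or >= -5"):
            GroundTruth("x", "nonbinder", logKd_cce=-8.0)

    def test_biphasic_needs_lower_sce_affinity(self):
        with pytest.raises(ValueError, match="lower affinity"):
            GroundTruth("x", "biphasic", logKd_cce=-7.0, logKd_sce=-8.0,
                        efficacy_cce=0.1, efficacy_sce=0.1)

    def test_config_grid_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SimulationConfig(ground_truth=(), concentration_grid=(1e-9, 1e-9))


class TestDeterminism:
    def test_same_config_and_seed_bit_identical(self, two_conf_config):
        a = simulate_functional_curve(two_conf_config, "sce_partial")
        b = simulate_functional_curve(two_conf_config, "sce_partial")
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.controls["basal"], b.controls["basal"])

    def test_different_seed_differs(self, two_conf_config):
        other = dataclasses.replace(two_conf_config, seed=8)
        a = simulate_functional_curve(two_conf_config, "sce_partial")
        b = simulate_functional_curve(other, "sce_partial")
        assert not np.array_equal(a.signal, b.signal)

    def test_fixture_bit_identical_across_calls(self):
        b1 = make_study_fixture(3)
        b2 = make_study_fixture(3)
        assert len(b1.experiments) == len(b2.experiments)
        for e1, e2 in zip(b1.experiments, b2.experiments):
            assert (e1.kind, e1.cell_line, e1.compound_id) == \
                   (e2.kind, e2.cell_line, e2.compound_id)
            if e1.series is not None:
                assert np.array_equal(e1.series.signal, e2.series.signal)


class TestForwardModel:
    def test_signals_finite_and_nonnegative(self, two_conf_config):
        for cpd in ("ref_agonist", "sce_partial", "inert"):
            s = simulate_functional_curve(two_conf_config, cpd)
            assert np.all(np.isfinite(s.signal)) and np.all(s.signal >= 0)
        b = simulate_binding_plate(two_conf_config, "blocker")
        assert np.all(np.isfinite(b.signal)) and np.all(b.signal >= 0)

    def test_expression_scaling_is_monotone(self):
        gt = GroundTruth("p", "sce_agonist", logKd_cce=-9.77,
                         logKd_sce=-7.20, efficacy_sce=0.3)
        last_emax, last_ec = 0.0, 0.0
        for r in (0.5, 1.0, 2.0, 5.0, 14.5):
            (comp,) = functional_components(gt, r)
            assert comp["emax"] >= last_emax  # proportionately greater
            assert last_ec == 0.0 or comp["log_ec50"] <= last_ec  # left shifted
            last_emax, last_ec = comp["emax"], comp["log_ec50"]

    def test_neutral_compound_is_flat_at_basal(self, noiseless):
        s = simulate_functional_curve(noiseless, "blocker")
        curve = normalize_plate(s)
        assert np.allclose(curve.response, 0.0, atol=1e-9)

    def test_biphasic_expectation_matches_closed_form(self, noiseless):
        # two stimulatory sites at 10^-9.27 and 10^-7.24 M with 23.7% via
        # site 1: the expectation at 10^-8.2 M equals the two-site equation
        gt = GroundTruth("b", "biphasic", logKd_cce=-9.24, efficacy_cce=0.2,
                         logKd_sce=-7.16, efficacy_sce=0.178)
        comps = functional_components(gt, 1.0)
        c = np.array([10.0 ** -8.2])
        expected = sum(k["emax"] * c / (c + 10.0 ** k["log_ec50"]) for k in comps)
        got = expected_functional_pct(noiseless, "both_sites", c)
        assert got[0] == pytest.approx(expected[0], rel=1e-12)

    def test_dip_curve_dips_below_control_then_rises(self, noiseless):
        s = simulate_functional_curve(noiseless, "sce_partial",
                                      fixed_reference=("ref_agonist", 30e-9))
        curve = normalize_plate(s)
        mean = curve.response.mean(axis=1)
        control = curve.control_pct
        assert mean.min() < control - 20.0          # inhibition limb
        assert mean[-1] > mean.min() + 20.0         # stimulation limb
        assert curve.meta["fixed_reference"] == ("ref_agonist", 30e-9)

    def test_reference_without_agonism_rejected(self, noiseless):
        with pytest.raises(ValueError, match="no agonism"):
            simulate_functional_curve(noiseless, "sce_partial",
                                      fixed_reference=("blocker", 30e-9))

    def test_unknown_compound_rejected(self, noiseless):
        with pytest.raises(KeyError):
            simulate_functional_curve(noiseless, "missing")


class TestBindingSimulation:
    def test_half_inhibition_at_inverse_cheng_prusoff_point(self):
        # competitor logKd -9.29 against 0.71 nM radioligand with KD 0.17 nM:
        # specific binding is halved at KD*(1 + 0.71/0.17)
        truth = (GroundTruth("c", "neutral", logKd_cce=-9.29),)
        cfg = SimulationConfig(ground_truth=truth, noise_sd=0.0, seed=0,
                               radioligand_conc=0.71e-9, radioligand_logKd=np.log10(0.17e-9))
        half = inverse_cheng_prusoff(10.0 ** -9.29, 0.71e-9, 0.17e-9)
        pct = 100.0 * (1.0 - np.array([half]) / (np.array([half]) + half))
        assert pct[0] == pytest.approx(50.0)
        s = simulate_binding_plate(cfg, "c")
        fit = fit_competition(s)
        assert 10.0 ** fit.logIC50 == pytest.approx(half, rel=1e-6)

    def test_nonbinder_is_flat_and_censored(self, noiseless):
        s = simulate_binding_plate(noiseless, "inert")
        fit = fit_competition(s)
        assert fit.is_censored

    def test_nonpositive_radioligand_rejected(self, noiseless):
        bad = dataclasses.replace(noiseless, radioligand_conc=0.0)
        with pytest.raises(ValueError, match="positive"):
            simulate_binding_plate(bad, "blocker")


class TestNoiselessRoundTrips:
    """Simulator -> fit closes the loop to optimizer tolerance."""

    def test_saturation(self, noiseless):
        cfg = dataclasses.replace(noiseless, radioligand_logKd=np.log10(0.42e-9))
        fit = fit_saturation(simulate_binding_plate(cfg, mode="saturation"))
        assert fit.logKd == pytest.approx(np.log10(0.42e-9), abs=1e-4)
        assert 10.0 ** fit.logKd * 1e9 == pytest.approx(0.42, abs=0.05)

    def test_competition(self, noiseless):
        fit = fit_competition(simulate_binding_plate(noiseless, "blocker"))
        expected = np.log10(inverse_cheng_prusoff(
            10.0 ** -9.47, noiseless.radioligand_conc, 10.0 ** noiseless.radioligand_logKd))
        assert fit.logIC50 == pytest.approx(expected, abs=1e-4)

    def test_one_site(self, noiseless):
        curve = normalize_plate(simulate_functional_curve(noiseless, "sce_partial"))
        (comp,) = functional_components(noiseless.truth_for("sce_partial"), 1.0)
        fit = fit_one_site(curve)
        assert fit.logEC50 == pytest.approx(comp["log_ec50"], abs=1e-4)
        assert fit.Emax_pct == pytest.approx(comp["emax"], abs=1e-3)

    def test_two_site(self, noiseless):
        curve = normalize_plate(simulate_functional_curve(noiseless, "both_sites"))
        c1, c2 = functional_components(noiseless.truth_for("both_sites"), 1.0)
        fit = fit_two_site_stim(curve)
        assert fit.logEC1_50 == pytest.approx(c1["log_ec50"], abs=1e-4)
        assert fit.logEC2_50 == pytest.approx(c2["log_ec50"], abs=1e-4)


class TestStudyFixture:
    @pytest.fixture(scope="class")
    def bundle(self):
        return make_study_fixture(1)

    def test_full_compound_panel(self, bundle):
        assert len(bundle.table_outcomes) == 19
        assert set(bundle.table_outcomes) <= set(bundle.ground_truth)

    def test_every_outcome_class_represented(self, bundle):
        assert set(bundle.table_outcomes.values()) == {
            "no_interaction", "neutral_antagonist", "cce_agonist",
            "sce_agonist", "biphasic_agonist",
        }

    def test_bunolol_analog_is_neutral_at_both_conformations(self, bundle):
        gt = bundle.ground_truth["VL03"]
        assert gt.mode == "neutral"
        assert gt.efficacy_cce == gt.efficacy_sce == 0.0
        assert gt.logKd_cce is not None and gt.logKd_sce is not None

    def test_mutant_panel_has_no_secondary_conformation(self, bundle):
        for gt in bundle.ground_truth_mutant.values():
            assert gt.logKd_sce is None and gt.efficacy_sce == 0.0
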