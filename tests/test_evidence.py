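"""The A-D evidence rubric and compound classification."""
import pytest

from scepharm.core import AffinityEstimate, Censor
from scepharm.evidence import (
    CompoundLineData,
    classify_compound,
    compare_lines,
    evaluate_evidence,
    pool_profiles,
)
from scepharm.functional import DipFit, FlatFit, ModelChoice, OneSiteFit, TwoSiteFit


def _one_site_choice(log_ec50, emax, se=0.02):
    fit = OneSiteFit(log_ec50, emax, se, rss=100.0, n_points=39)
    return ModelChoice("one_site", 1.0, 0.5, {"one_site": fit},
                       {"log_conc_max": -5.0})


def _two_site_choice(ec1, ec2, n, total):
    fit = TwoSiteFit(ec1, ec2, n, total, rss=100.0, n_points=39)
    return ModelChoice("two_site", 30.0, 1e-6, {"two_site": fit},
                       {"log_conc_max": -5.0})


def _flat_choice():
    return ModelChoice("flat", 0.1, 0.9, {"flat": FlatFit(0.0, 100.0, 39)},
                       {"log_conc_max": -5.0})


def _dip_choice(chosen, ic50=-8.6, ec50=-7.5):
    fit = DipFit(0.0, 73.0, ic50, ec50, 50.0, rss=100.0, n_points=39)
    return ModelChoice(chosen, 10.0, 1e-4 if chosen == "dip" else 0.5, {"dip": fit})


def _aff(log_kd, method="competition_cheng_prusoff", se=0.05, **kw):
    return AffinityEstimate(log_kd, method=method, se=se, **kw)


def _data(**kw):
    base = dict(compound_id="cpd", cell_line="L")
    base.update(kw)
    return CompoundLineData(**base)


class TestCallA:
    def test_sce_partial_agonist_is_positive(self):
        # EC50 -7.54 vs functional KD -9.87: 2.33 log gap
        d = _data(affinities=[_aff(-9.87, method="stephenson")],
                  functional_choice=_one_site_choice(-7.54, 54.2))
        p = evaluate_evidence(d)
        assert p.A.call == "positive"
        assert p.A.gap == pytest.approx(2.33, abs=1e-9)
        assert p.A.detail["kd_method"] == "stephenson"

    def test_small_gap_is_negative(self):
        # 0.81 log gap does not reach the 10-fold criterion
        d = _data(affinities=[_aff(-8.00, method="stephenson")],
                  functional_choice=_one_site_choice(-7.19, 9.7 + 10))
        p = evaluate_evidence(d)
        assert p.A.call == "negative"
        assert p.A.gap == pytest.approx(0.81, abs=1e-9)

    def test_ec50_equal_to_kd_is_negative(self):
        d = _data(affinities=[_aff(-8.0)], functional_choice=_one_site_choice(-8.0, 50.0))
        assert evaluate_evidence(d).A.call == "negative"

    def test_functional_kd_preferred_over_binding(self):
        d = _data(affinities=[_aff(-9.29), _aff(-9.87, method="stephenson")],
                  functional_choice=_one_site_choice(-7.54, 54.2))
        assert evaluate_evidence(d).A.detail["kd_method"] == "stephenson"

    def test_two_site_curve_uses_first_component(self):
        d = _data(affinities=[_aff(-8.20)],
                  functional_choice=_two_site_choice(-8.34, -6.44, 62.5, 56.7))
        p = evaluate_evidence(d)
        assert p.A.call == "negative"  # EC50_1 sits at the CCE KD

    def test_ec50_near_top_concentration_is_indeterminate(self):
        d = _data(affinities=[_aff(-8.0)], functional_choice=_one_site_choice(-5.2, 30.0))
        assert evaluate_evidence(d).A.call == "indeterminate"

    def test_missing_affinity_is_indeterminate(self):
        d = _data(functional_choice=_one_site_choice(-7.5, 50.0))
        assert evaluate_evidence(d).A.call == "indeterminate"

    @pytest.mark.parametrize("gap", [0.0, 0.5, 1.0, 2.0, 3.0])
    def test_monotone_in_gap(self, gap):
        # widening the EC50/KD separation never flips A positive -> negative
        d = _data(affinities=[_aff(-9.5)],
                  functional_choice=_one_site_choice(-9.5 + gap, 50.0))
        call = evaluate_evidence(d).A.call
        if gap >= 1.0:
            assert call == "positive"
        else:
            assert call == "negative"


class TestCallB:
    def test_resistant_response_is_positive(self):
        # reference antagonist: KD -7.37 vs the test agonist, -9.47 vs the
        # reference agonist: a 2.10 log worsening
        d = _data(antagonist_vs_self=_aff(-7.37, method="gaddum"),
                  antagonist_vs_reference=_aff(-9.47, method="gaddum"))
        p = evaluate_evidence(d)
        assert p.B.call == "positive"
        assert p.B.gap == pytest.approx(2.10, abs=1e-9)

    def test_equal_kds_negative(self):
        d = _data(antagonist_vs_self=_aff(-9.54, method="gaddum"),
                  antagonist_vs_reference=_aff(-9.47, method="gaddum"))
        assert evaluate_evidence(d).B.call == "negative"

    def test_missing_shift_is_indeterminate(self):
        assert evaluate_evidence(_data()).B.call == "indeterminate"


class TestCallsCD:
    def test_two_site_choice_is_c_positive(self):
        d = _data(functional_choice=_two_site_choice(-9.27, -7.24, 23.7, 23.3))
        assert evaluate_evidence(d).C.call == "positive"

    def test_dip_requires_fixed_reference_design(self):
        assert evaluate_evidence(_data()).D.call == "indeterminate"
        d = _data(dip_choice=_dip_choice("dip"))
        assert evaluate_evidence(d).D.call == "positive"
        d = _data(dip_choice=_dip_choice("one_site"))
        assert evaluate_evidence(d).D.call == "negative"


class TestClassification:
    def test_neutral_antagonist(self):
        d = _data(affinities=[_aff(-8.91)], functional_choice=_flat_choice())
        p = evaluate_evidence(d)
        assert classify_compound(p) == "neutral_antagonist"

    def test_no_interaction_when_everything_censored(self):
        d = _data(affinities=[_aff(float("nan"), censored=Censor(">", -4.0))],
                  functional_choice=_flat_choice())
        assert classify_compound(evaluate_evidence(d)) == "no_interaction"

    def test_weak_affinity_does_not_count_as_interaction(self):
        # a 30 uM 'affinity' is in the declared non-binding region
        d = _data(affinities=[_aff(-4.5, method="gaddum")],
                  functional_choice=_flat_choice())
        assert classify_compound(evaluate_evidence(d)) == "no_interaction"

    def test_biphasic_wins_over_sce(self):
        d = _data(affinities=[_aff(-9.0)],
                  functional_choice=_two_site_choice(-9.0, -6.5, 40.0, 60.0),
                  dip_choice=_dip_choice("dip"))
        assert classify_compound(evaluate_evidence(d)) == "biphasic_agonist"

    def test_sce_agonist_via_a_and_b(self):
        d = _data(affinities=[_aff(-9.87, method="stephenson")],
                  functional_choice=_one_site_choice(-7.54, 54.2),
                  antagonist_vs_self=_aff(-7.37, method="gaddum"),
                  antagonist_vs_reference=_aff(-9.47, method="gaddum"))
        assert classify_compound(evaluate_evidence(d)) == "sce_agonist"

    def test_sce_agonist_via_a_with_untestable_b(self):
        d = _data(affinities=[_aff(-8.21)], functional_choice=_one_site_choice(-6.55, 26.5))
        assert classify_compound(evaluate_evidence(d)) == "sce_agonist"

    def test_cce_agonist_when_all_negative(self):
        d = _data(affinities=[_aff(-8.00)],
                  functional_choice=_one_site_choice(-8.3, 62.0),
                  antagonist_vs_self=_aff(-9.4, method="gaddum"),
                  antagonist_vs_reference=_aff(-9.47, method="gaddum"))
        assert classify_compound(evaluate_evidence(d)) == "cce_agonist"

    def test_small_emax_is_not_agonism(self):
        d = _data(affinities=[_aff(-8.2)], functional_choice=_one_site_choice(-6.5, 3.2))
        assert classify_compound(evaluate_evidence(d)) == "neutral_antagonist"

    def test_contradictory_profile_raises(self):
        # affinity was measured and censored everywhere, yet an agonist
        # curve was fitted: flagged for audit
        d = _data(affinities=[_aff(float("nan"), censored=Censor(">", -4.0))],
                  functional_choice=_one_site_choice(-7.0, 50.0))
        with pytest.raises(ValueError, match="contradictory"):
            classify_compound(evaluate_evidence(d))

    def test_agonist_without_affinity_data_still_classifies(self):
        d = _data(functional_choice=_one_site_choice(-7.0, 50.0))
        assert classify_compound(evaluate_evidence(d)) == "cce_agonist"

    def test_determinism(self):
        d = _data(affinities=[_aff(-9.87, method="stephenson")],
                  functional_choice=_one_site_choice(-7.54, 54.2))
        a = evaluate_evidence(d)
        b = evaluate_evidence(d)
        assert (a.letters, classify_compound(a)) == (b.letters, classify_compound(b))


class TestPoolingAndContrast:
    def _profiles(self):
        low = evaluate_evidence(_data(
            cell_line="low",
            affinities=[_aff(-9.77)],
            functional_choice=_one_site_choice(-7.54, 54.2),
            antagonist_vs_self=_aff(-7.37, method="gaddum"),
            antagonist_vs_reference=_aff(-9.47, method="gaddum"),
        ))
        high = evaluate_evidence(_data(
            cell_line="high",
            affinities=[_aff(-9.77)],
            functional_choice=_one_site_choice(-8.46, 94.0),
        ))
        return low, high

    def test_positive_anywhere_pools_positive(self):
        low, high = self._profiles()
        pooled = pool_profiles([low, high])
        assert pooled.A.call == "positive"
        assert pooled.B.call == "positive"
        assert pooled.letters == "AB"

    def test_pooling_different_compounds_rejected(self):
        low, high = self._profiles()
        high.compound_id = "other"
        with pytest.raises(ValueError, match="different compounds"):
            pool_profiles([low, high])

    def test_identical_profiles_show_no_loss(self):
        low, _ = self._profiles()
        report = compare_lines(low, low)
        assert report.lost == [] and report.gained == []
        assert not report.sce_lost

    def test_mutant_losing_a_and_b_flags_sce_lost(self):
        wt, _ = self._profiles()
        mut = evaluate_evidence(_data(
            cell_line="mut",
            affinities=[_aff(-9.57)],
            functional_choice=_one_site_choice(-9.67, 27.9),
            antagonist_vs_self=_aff(-9.30, method="gaddum"),
            antagonist_vs_reference=_aff(-9.44, method="gaddum"),
        ))
        report = compare_lines(wt, mut)
        assert report.lost == ["A", "B"]
        assert report.second_classification == "cce_agonist"
        assert report.sce_lost

    def test_mismatched_compound_ids_rejected(self):
        wt, _ = self._profiles()
        other = evaluate_evidence(_data(compound_id="other"))
        with pytest.raises(ValueError, match="mismatched"):
            compare_lines(wt, other)
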