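"""Concentration-response normalization, curve fits and model selection."""
import numpy as np
import pytest

from scepharm.core import ConcentrationSeries
from scepharm.functional import (
    NormalizedCurve,
    dip_response,
    fit_dip,
    fit_flat,
    fit_one_site,
    fit_two_site_stim,
    normalize_plate,
    one_site_response,
    select_cr_model,
    two_site_response,
)

GRID = 10.0 ** np.arange(-11.0, -4.75, 0.5)


def _curve(y, noise=0.0, seed=0, n_rep=3, conc=GRID, **meta):
    rng = np.random.default_rng(seed)
    resp = np.asarray(y)[:, None] + rng.normal(0, noise, (len(conc), n_rep))
    return NormalizedCurve("cpd", conc, resp, meta=meta)


# ---------------------------------------------------------------------------
# normalization

class TestNormalize:
    def _raw(self):
        sig = np.full((5, 3), 1250.0)
        conc = GRID[:5]
        return ConcentrationSeries(
            "cpd", conc, sig,
            controls={"basal": np.full(6, 250.0), "positive": np.full(6, 2250.0)},
            meta={"assay": "functional"},
        )

    def test_positive_maps_to_100_and_basal_to_0(self):
        raw = self._raw()
        raw.signal[0, :] = 2250.0
        raw.signal[1, :] = 250.0
        curve = normalize_plate(raw)
        assert curve.response[0, 0] == pytest.approx(100.0)
        assert curve.response[1, 0] == pytest.approx(0.0)
        assert curve.basal_pct == 0.0

    def test_no_window_is_an_error(self):
        raw = self._raw()
        raw.controls["positive"] = np.full(6, 200.0)
        with pytest.raises(ValueError, match="window"):
            normalize_plate(raw)

    def test_normalization_is_affine_order_preserving(self):
        raw = self._raw()
        raw.signal = np.linspace(300, 2000, 15).reshape(5, 3)
        curve = normalize_plate(raw)
        assert np.all(np.diff(curve.response.ravel()) > 0)


# ---------------------------------------------------------------------------
# one-site

class TestOneSite:
    def test_noiseless_recovery(self):
        # full agonist: log EC50 -8.07, maximum 106.2% of the positive control
        curve = _curve(one_site_response(GRID, 106.2, -8.07))
        fit = fit_one_site(curve)
        assert fit.logEC50 == pytest.approx(-8.07, abs=1e-6)
        assert fit.Emax_pct == pytest.approx(106.2, abs=1e-4)
        assert fit.identifiable

    def test_flat_curve_flagged_unidentifiable(self):
        fit = fit_one_site(_curve(np.zeros(GRID.size)))
        assert fit.Emax_pct == pytest.approx(0.0, abs=1e-3)
        assert not fit.identifiable

    def test_noisy_fit_matches_grid_search_oracle(self):
        curve = _curve(one_site_response(GRID, 50.0, -7.5), noise=5.0, seed=11)
        fit = fit_one_site(curve)
        conc, y = curve.flat_y()
        ec_grid = np.linspace(-9.0, -6.0, 200)
        emax_grid = np.linspace(30.0, 70.0, 200)
        rss = np.array([
            [np.sum((one_site_response(conc, e, le) - y) ** 2) for le in ec_grid]
            for e in emax_grid
        ])
        _, j = np.unravel_index(np.argmin(rss), rss.shape)
        assert abs(fit.logEC50 - ec_grid[j]) < 0.02


# ---------------------------------------------------------------------------
# two-site

class TestTwoSite:
    def test_noiseless_recovery_of_biphasic_parameters(self):
        # biphasic agonist: EC50s -9.27 / -7.24 with 23.7% via site 1
        curve = _curve(two_site_response(GRID, 23.3, -9.27, -7.24, 23.7))
        fit = fit_two_site_stim(curve)
        assert fit.logEC1_50 == pytest.approx(-9.27, abs=1e-3)
        assert fit.logEC2_50 == pytest.approx(-7.24, abs=1e-3)
        assert fit.site1_pct == pytest.approx(23.7, abs=1e-2)
        assert not fit.collapsed

    def test_single_site_limit_reduces_to_one_site(self):
        y = two_site_response(GRID, 54.2, -7.54, -5.0, 100.0)
        assert np.allclose(y, one_site_response(GRID, 54.2, -7.54))
        y0 = two_site_response(GRID, 54.2, -9.0, -7.54, 0.0)
        assert np.allclose(y0, one_site_response(GRID, 54.2, -7.54))

    def test_noisy_rss_within_one_percent_of_grid_oracle(self):
        curve = _curve(two_site_response(GRID, 60.0, -9.0, -7.0, 40.0), noise=3.0, seed=5)
        fit = fit_two_site_stim(curve)
        conc, y = curve.flat_y()
        # profile the two linear amplitudes on a (logEC1, logEC2) grid
        best = np.inf
        for e1 in np.linspace(-10.5, -8.0, 60):
            for e2 in np.linspace(-8.0, -5.5, 60):
                X = np.column_stack([conc / (conc + 10.0 ** e1), conc / (conc + 10.0 ** e2)])
                beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                if res.size and res[0] < best:
                    best = res[0]
        assert fit.rss <= best * 1.01

    def test_collapse_is_reported(self):
        fit = fit_two_site_stim(_curve(one_site_response(GRID, 50.0, -7.5)))
        assert fit.collapsed


# ---------------------------------------------------------------------------
# dip

class TestDip:
    def test_noiseless_recovery(self):
        y = dip_response(GRID, 0.0, 73.0, -8.6, -7.54, 54.2)
        curve = _curve(y, fixed_reference=("ref", 30e-9))
        curve.control_pct = 73.0
        fit = fit_dip(curve)
        assert fit.logIC50 == pytest.approx(-8.6, abs=1e-4)
        assert fit.logEC50 == pytest.approx(-7.54, abs=1e-4)
        assert fit.Smax_pct == pytest.approx(54.2, abs=1e-3)
        assert fit.has_dip

    def test_pure_inhibition_matches_isolated_limb(self):
        y = dip_response(GRID, 0.0, 80.0, -8.0, -2.5, 0.0)
        curve = _curve(y, fixed_reference=("ref", 30e-9))
        curve.control_pct = 80.0
        fit = fit_dip(curve)
        assert fit.logIC50 == pytest.approx(-8.0, abs=1e-3)
        assert fit.Smax_pct == pytest.approx(0.0, abs=0.1)

    def test_degenerate_components_reduce_to_one_site(self):
        # control == basal removes the inhibitory term analytically
        y = dip_response(GRID, 0.0, 0.0, -8.0, -7.0, 42.0)
        assert np.allclose(y, one_site_response(GRID, 42.0, -7.0))

    def test_control_not_above_basal_is_an_error(self):
        curve = _curve(np.zeros(GRID.size), fixed_reference=("ref", 30e-9))
        curve.control_pct = -1.0
        with pytest.raises(ValueError, match="exceed basal"):
            fit_dip(curve)


# ---------------------------------------------------------------------------
# model selection

class TestModelSelection:
    def test_noiseless_one_site_is_not_called_two_site(self):
        choice = select_cr_model(_curve(one_site_response(GRID, 50.0, -7.5),
                                        noise=1.0, seed=0))
        assert choice.chosen == "one_site"

    def test_flat_curve_is_flat(self):
        choice = select_cr_model(_curve(np.zeros(GRID.size), noise=3.0, seed=1))
        assert choice.chosen == "flat"

    def test_clear_biphasic_is_two_site(self):
        y = two_site_response(GRID, 80.0, -9.2, -6.8, 45.0)
        choice = select_cr_model(_curve(y, noise=5.0, seed=2))
        assert choice.chosen == "two_site"
        fit = choice.candidates["two_site"]
        assert fit.logEC2_50 - fit.logEC1_50 >= 1.0

    def test_dip_curve_chosen_with_reference_present(self):
        y = dip_response(GRID, 0.0, 73.0, -8.6, -7.5, 54.0)
        curve = _curve(y, noise=5.0, seed=3, fixed_reference=("ref", 30e-9))
        curve.control_pct = 73.0
        choice = select_cr_model(curve)
        assert choice.chosen == "dip"
        assert choice.candidates["dip"].has_dip

    def test_pure_inhibition_with_reference_is_not_a_dip(self):
        y = dip_response(GRID, 0.0, 73.0, -8.0, -2.5, 0.0)
        curve = _curve(y, noise=5.0, seed=4, fixed_reference=("ref", 30e-9))
        curve.control_pct = 73.0
        choice = select_cr_model(curve)
        assert choice.chosen != "dip"

    @pytest.mark.parametrize("seed", range(6))
    def test_rss_nesting_on_noisy_curves(self, seed):
        curve = _curve(one_site_response(GRID, 60.0, -7.8), noise=5.0, seed=seed)
        flat = fit_flat(curve)
        one = fit_one_site(curve)
        two = fit_two_site_stim(curve, one_site=one)
        assert two.rss <= one.rss + 1e-9
        assert one.rss <= flat.rss + 1e-9
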