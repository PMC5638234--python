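"""Surrogate fitting, marginal curves, rescaling, shape and psi_gs50."""
import math

import numpy as np
import pytest

from stomatafit.exceptions import SpeciesExcluded, UndefinedSignal
from stomatafit.models import WeibullCurve, weibull_survival
from stomatafit.partial_dependence import (classify_shape, closure_anchor,
                                           default_psi_grid, fit_surrogate,
                                           partial_dependence,
                                           psi_gs50_from_curve, rescale_curve)

from .conftest import make_dataset


def monotone_dataset(n=150, seed=0, b=3.0, c=2.0):
    """gs driven purely by a known Weibull closure of psi (no noise)."""
    ds = make_dataset("mono", n=n, seed=seed)
    psi = -np.linspace(0.05, 3.5, n)
    ds.data["psi_md"] = psi
    ds.data["gs"] = 0.3 * weibull_survival(psi, WeibullCurve(b=b, c=c))
    return ds


class TestSurrogate:
    def test_requires_three_distinct_psi(self):
        ds = make_dataset(n=30, seed=1)
        ds.data["psi_md"] = -1.0
        ds.data["psi_pd"] = np.nan
        with pytest.raises(SpeciesExcluded):
            fit_surrogate(ds, n_trees=20, seed=0)

    def test_in_sample_r2_on_clean_monotone_data(self):
        ds = monotone_dataset()
        surr = fit_surrogate(ds, n_trees=100, seed=0)
        pred = surr.predict(surr.design)
        ss = 1 - np.sum((pred - surr.gs) ** 2) / np.sum(
            (surr.gs - surr.gs.mean()) ** 2)
        assert ss >= 0.95

    def test_deterministic_given_seed(self):
        ds = monotone_dataset()
        g = default_psi_grid(ds, 20)
        c1 = partial_dependence(fit_surrogate(ds, n_trees=50, seed=3), g)
        c2 = partial_dependence(fit_surrogate(ds, n_trees=50, seed=3), g)
        assert np.array_equal(c1, c2)

    def test_missing_assimilation_filled(self):
        ds = monotone_dataset()
        ds.data["A"] = np.nan
        surr = fit_surrogate(ds, n_trees=30, seed=0)
        assert np.isfinite(surr.design["A"]).all()


class TestPartialDependence:
    def test_flat_when_gs_independent_of_psi(self):
        ds = make_dataset(n=200, seed=4)
        rng = np.random.default_rng(0)
        ds.data["gs"] = 0.2 + 0.0 * ds.data["psi_md"] + rng.normal(0, 1e-6, 200)
        surr = fit_surrogate(ds, n_trees=100, seed=0)
        curve = partial_dependence(surr, default_psi_grid(ds, 30))
        assert np.ptp(curve) <= 0.02 * curve.mean()

    def test_known_closure_recovered(self):
        ds = monotone_dataset(b=3.0, c=2.5)
        surr = fit_surrogate(ds, seed=0)
        grid = default_psi_grid(ds)
        raw = partial_dependence(surr, grid)
        assert raw[0] > raw[-1]  # decreasing overall
        scaled, _ = rescale_curve(raw, ds)
        shape, fits = classify_shape(grid, scaled)
        assert shape != "erratic"
        popt, _ = fits["weibull-like"]
        assert popt[1] == pytest.approx(2.5, rel=0.2)  # scale c recovered

    def test_diagnostic_marginal_on_assimilation(self):
        ds = make_dataset(n=150, seed=9)
        ds.data["gs"] = 0.01 * ds.data["A"]  # gs rises with A only
        surr = fit_surrogate(ds, n_trees=80, seed=0)
        grid = np.linspace(ds.data["A"].min(), ds.data["A"].max(), 15)
        curve = partial_dependence(surr, grid, variable="A")
        assert curve[-1] > curve[0]

    def test_empty_grid_rejected(self):
        ds = monotone_dataset()
        surr = fit_surrogate(ds, n_trees=20, seed=0)
        with pytest.raises(Exception):
            partial_dependence(surr, np.array([]))


class TestRescale:
    def test_span_matches_observed_closure(self):
        # species with max gs 100 and stressed min 40 spans [0.4, 1]
        ds = make_dataset(n=50, seed=6)
        ds.data["gs"] = np.linspace(0.04, 0.10, 50)
        ds.data["PAR"] = 1500.0
        ds.data["Cs"] = 400.0
        raw = np.linspace(0.10, 0.04, 20)
        scaled, flags = rescale_curve(raw, ds)
        assert scaled[0] == pytest.approx(1.0)
        assert scaled[-1] == pytest.approx(0.4)
        assert not flags

    def test_zero_minimum_spans_to_zero(self):
        ds = make_dataset(n=50, seed=6)
        ds.data["gs"] = np.linspace(0.0, 0.10, 50)
        raw = np.linspace(0.10, 0.02, 20)
        scaled, _ = rescale_curve(raw, ds)
        assert scaled.min() == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_no_closure_flagged(self):
        ds = make_dataset(n=30, seed=6)
        ds.data["gs"] = 0.2
        raw = np.full(10, 0.2)
        scaled, flags = rescale_curve(raw, ds)
        assert np.all(scaled == 1.0)
        assert "no-closure-observed" in flags

    def test_order_preserving(self):
        ds = make_dataset(n=50, seed=7)
        raw = np.array([0.3, 0.28, 0.2, 0.22, 0.1, 0.05])
        scaled, _ = rescale_curve(raw, ds)
        assert np.argmax(scaled) == np.argmax(raw)
        assert np.argmin(scaled) == np.argmin(raw)

    def test_filter_fallback_warns(self):
        ds = make_dataset(n=30, seed=8)
        # bimodal CO2: nothing lies within 10% of the median
        ds.data["Cs"] = np.where(np.arange(30) % 2 == 0, 100.0, 1000.0)
        with pytest.warns(RuntimeWarning):
            low, note = closure_anchor(ds)
        assert "fallback" in note


class TestShapeAndGs50:
    def test_weibull_evaluation_classified_weibull(self):
        grid = np.linspace(0, -4, 40)
        y = weibull_survival(grid, WeibullCurve(b=2.5, c=1.8))
        shape, _ = classify_shape(grid, y)
        assert shape == "weibull-like"

    def test_white_noise_is_erratic(self):
        rng = np.random.default_rng(12)
        grid = np.linspace(0, -3, 30)
        shape, _ = classify_shape(grid, 0.5 + 0.2 * rng.standard_normal(30))
        assert shape == "erratic"

    def test_increasing_curve_is_erratic(self):
        grid = np.linspace(0, -3, 20)
        shape, _ = classify_shape(grid, np.linspace(0.2, 1.0, 20))
        assert shape == "erratic"

    def test_linear_interpolation_hand_value(self):
        grid = np.array([0.0, -0.5, -1.0, -2.0, -3.0])
        y = np.array([1.0, 0.8, 0.6, 0.4, 0.3])
        psi50, extrap = psi_gs50_from_curve(grid, y, "weibull-like")
        assert psi50 == pytest.approx(-1.5)
        assert not extrap

    def test_closed_form_crossing(self):
        b, c = 2.2, 2.0
        grid = np.linspace(0, -4, 200)
        y = weibull_survival(grid, WeibullCurve(b=b, c=c))
        psi50, _ = psi_gs50_from_curve(grid, y, "weibull-like")
        assert psi50 == pytest.approx(-c * math.log(2) ** (1 / b), abs=0.02)

    def test_unreached_level_extrapolates_with_flag(self):
        b, c = 2.0, 3.0
        grid = np.linspace(0, -2.0, 40)  # curve bottoms around 0.64
        y = weibull_survival(grid, WeibullCurve(b=b, c=c))
        assert y.min() > 0.55
        psi50, extrap = psi_gs50_from_curve(grid, y, "weibull-like")
        assert extrap
        assert psi50 == pytest.approx(-c * math.log(2) ** (1 / b), abs=0.15)

    def test_erratic_curve_has_no_gs50(self):
        grid = np.linspace(0, -3, 20)
        with pytest.raises(UndefinedSignal):
            psi_gs50_from_curve(grid, np.ones(20), "erratic")
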