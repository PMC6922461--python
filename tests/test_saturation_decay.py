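"""One-site binding, absolute calibration, and exponential decay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligandquant import (CalibrationCurve, DegenerateDataError,
                         ExponentialDecay, SaturationBinding, half_life,
                         ligands_per_cell)
from ligandquant.saturation import exp_decay, one_site
from ligandquant.simulate import GroundTruth, gen_decay_series


def make_count(L=3e6):
    # back-derive an inflection that yields the requested count
    x0 = L * 1e6 * 3 / (1e-4 * 6.02214076e23)
    return ligands_per_cell(x0, 1e-4, 1e6, 3)


class TestSaturationBinding:
    def test_noiseless_exact_recovery(self):
        x = np.geomspace(1e-8, 1e-5, 8)
        fit = SaturationBinding(x, one_site(x, 1000.0, 1e-6)).fit()
        assert fit.converged
        assert fit.bmax == pytest.approx(1000.0, rel=1e-6)
        assert fit.kd_app == pytest.approx(1e-6, rel=1e-6)

    def test_half_saturation_identity(self):
        x = np.geomspace(1e-8, 1e-5, 8)
        fit = SaturationBinding(x, one_site(x, 1000.0, 1e-6)).fit()
        assert fit.predict(fit.kd_app) == pytest.approx(fit.bmax / 2, rel=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        """Unweighted fit lands on the dense two-parameter grid optimum."""
        x = np.geomspace(1e-8, 1e-5, 10)
        y = one_site(x, 800.0, 5e-7) * (1 + 0.05 * rng.standard_normal(10))
        fit = SaturationBinding(x, y, weighting="none").fit()
        bgrid = np.linspace(0.8 * y.max(), 1.5 * y.max(), 500)
        kgrid = np.geomspace(x.min(), x.max(), 1000)
        pred = (bgrid[:, None, None] * x[None, None, :]
                / (kgrid[None, :, None] + x[None, None, :]))
        sse = np.sum((pred - y[None, None, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.bmax == pytest.approx(bgrid[i], rel=0.01)
        assert fit.kd_app == pytest.approx(kgrid[j], rel=0.01)
        assert fit.sse <= sse[i, j] + 1e-9 * sse[i, j]

    def test_monotone_predictions(self):
        x = np.geomspace(1e-9, 1e-5, 12)
        fit = SaturationBinding(x, one_site(x, 500.0, 1e-7)).fit()
        grid = np.geomspace(1e-10, 1e-4, 100)
        assert np.all(np.diff(fit.predict(grid)) > 0)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            SaturationBinding([1e-9, 1e-8, 1e-7, 1e-6], [0, 0, 0, 0])

    def test_kd_recovery_median_under_10pct(self):
        """8 concentrations at 10% CV: median |KD error| stays below 10%."""
        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = np.geomspace(5e-9, 5e-5, 8)
            y = one_site(x, 1000.0, 5e-7) * (1 + 0.1 * r.standard_normal(8))
            errs.append(abs(SaturationBinding(x, y).fit().kd_app - 5e-7) / 5e-7)
        assert np.median(errs) <= 0.10


class TestCalibration:
    def test_substitution_preserves_half_saturation(self):
        x = np.geomspace(1e-9, 1e-5, 8)
        fit = SaturationBinding(x, one_site(x, 500.0, 2e-7)).fit()
        curve = CalibrationCurve.from_fit(fit, make_count(3e6))
        at_kd, _ = curve.ligands_at(curve.kd_app)
        assert curve.kd_app == pytest.approx(fit.kd_app, rel=1e-12)
        assert at_kd == pytest.approx(curve.bmax_absolute / 2, rel=1e-9)

    def test_asymptote_is_absolute_count(self):
        x = np.geomspace(1e-9, 1e-5, 8)
        fit = SaturationBinding(x, one_site(x, 500.0, 2e-7)).fit()
        curve = CalibrationCurve.from_fit(fit, make_count(3e6))
        far, _ = curve.ligands_at(1e4 * curve.kd_app)
        assert far == pytest.approx(curve.bmax_absolute, rel=1e-4)
        zero, _ = curve.ligands_at(0.0)
        assert zero == 0.0

    def test_calibration_is_idempotent(self):
        x = np.geomspace(1e-9, 1e-5, 8)
        fit = SaturationBinding(x, one_site(x, 500.0, 2e-7)).fit()
        count = make_count(1e6)
        c1 = CalibrationCurve.from_fit(fit, count)
        c2 = CalibrationCurve.from_fit(fit, count)
        assert c1.bmax_absolute == c2.bmax_absolute
        assert c1.kd_app == c2.kd_app

    def test_extrapolation_flagged(self):
        x = np.geomspace(1e-9, 1e-6, 8)
        fit = SaturationBinding(x, one_site(x, 500.0, 2e-7)).fit()
        curve = CalibrationCurve.from_fit(fit, make_count(1e6),
                                          fitted_range=(1e-9, 1e-6))
        _, inside = curve.ligands_at(5e-7)
        _, outside = curve.ligands_at(5e-6)
        assert not inside and outside

    def test_rejects_nonpositive_count(self):
        x = np.geomspace(1e-9, 1e-6, 8)
        fit = SaturationBinding(x, one_site(x, 500.0, 2e-7)).fit()
        with pytest.raises(ValueError):
            CalibrationCurve.from_fit(fit, _zero_count())


def _zero_count():
    c = make_count(1.0)
    c.ligands_per_cell = 0.0
    return c


class TestDecay:
    def test_noiseless_half_life_exact(self):
        t = np.linspace(0, 2400, 13)
        y = exp_decay(t, 1.0, 0.2, math.log(2) / 800)
        fit = ExponentialDecay(t, y).fit()
        assert fit.converged
        assert fit.half_life == pytest.approx(800.0, rel=1e-6)
        assert fit.k == pytest.approx(math.log(2) / 800, rel=1e-6)

    def test_predicted_value_at_time_zero_is_y0(self):
        t = np.linspace(0, 2400, 13)
        y = exp_decay(t, 1.0, 0.2, math.log(2) / 800)
        fit = ExponentialDecay(t, y).fit()
        assert fit.predict(0.0) == pytest.approx(fit.y0, rel=1e-9)

    def test_half_life_recovery_within_5pct(self):
        """True half-life 820 min, 3% noise: median error below 5%."""
        errs = []
        for seed in range(50):
            series = gen_decay_series(
                GroundTruth(k=math.log(2) / 820, plateau=0.1, seed=seed),
                noise_cv=0.03)
            fit = ExponentialDecay.from_series(series).fit()
            errs.append(abs(fit.half_life - 820) / 820)
        assert np.median(errs) <= 0.05

    def test_non_decaying_data_flagged(self):
        t = np.linspace(0, 100, 8)
        with pytest.warns(UserWarning):
            fit = ExponentialDecay(t, np.full(8, 1.0)).fit()
        assert not fit.converged or fit.k < 1e-6

    def test_from_peak_drops_initial_rise(self):
        t = np.linspace(0, 2400, 25)
        y = exp_decay(t, 1.1, 0.2, math.log(2) / 800)
        y[0] = 0.9   # apparent rise in the first interval
        fit = ExponentialDecay(t, y, from_peak=True).fit()
        assert fit.half_life == pytest.approx(800.0, rel=1e-6)


@given(k=st.floats(1e-6, 10.0))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_half_life_algebraic_identity(k):
    assert half_life(k) * k == pytest.approx(math.log(2), rel=1e-12)


def test_half_life_examples_and_domain():
    assert half_life(math.log(2)) == pytest.approx(1.0, rel=1e-12)
    assert half_life(math.log(2) / 800) == pytest.approx(800.0, rel=1e-12)
    with pytest.raises(ValueError):
        half_life(0.0)
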