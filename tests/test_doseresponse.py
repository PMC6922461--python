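"""Background correction, gating, and log-logistic EC50 fitting."""

import numpy as np
import pytest

from ligandquant import (DoseResponseExperiment, LogLogistic, fold_change,
                         gate_percent_positive, log_logistic,
                         normalize_to_max, subtract_background,
                         summarize_ec50)
from ligandquant.simulate import GroundTruth, gen_dose_response_experiment


def make_experiment(bottom=0.0, top=1.0, ec50=1.7e4, slope=1.2, n=9,
                    span=(1e3, 1e6), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    doses = np.geomspace(*span, n)
    y = log_logistic(doses, bottom, top, np.log10(ec50), slope)
    if noise:
        y = y * (1 + noise * rng.standard_normal(n))
    return DoseResponseExperiment(doses=doses, responses=y)


class TestBackgroundSubtraction:
    def test_scalar_control(self):
        corrected, neg = subtract_background([120.0], 20.0)
        assert corrected[0] == 100.0 and not neg[0]

    def test_below_detection_imputed_to_zero_first(self):
        """A below-detection well becomes 0, so correction goes negative
        and is retained with a flag rather than clipped."""
        corrected, neg = subtract_background([3.0], 20.0, detection_limit=5.0)
        assert corrected[0] == -20.0 and neg[0]

    def test_vector_case_matches_elementwise_oracle(self, rng):
        s = rng.uniform(0, 200, 20)
        c = rng.uniform(0, 50, 20)
        corrected, neg = subtract_background(s, c)
        np.testing.assert_allclose(corrected, s - c)
        np.testing.assert_array_equal(neg, (s - c) < 0)

    def test_missing_controls_rejected(self):
        with pytest.raises(ValueError):
            subtract_background([1.0, 2.0], None)


class TestGating:
    def test_null_case_near_zero(self, rng):
        events = rng.normal(100, 10, 5000)
        pct = gate_percent_positive(events, events, quantile=0.99)
        assert pct == 0.0   # identical distributions, floored at zero

    def test_counting_oracle_on_constructed_events(self):
        control = np.arange(1000).astype(float)     # quantile is explicit
        sample = np.full(500, 2000.0)               # all above control max
        pct = gate_percent_positive(sample, control, quantile=0.99)
        threshold = np.quantile(control, 0.99)
        oracle = (100.0 * np.mean(sample > threshold)
                  - 100.0 * np.mean(control > threshold))
        assert pct == pytest.approx(oracle, abs=1e-12)

    def test_quantile_one_uses_control_max(self):
        control = np.array([1.0, 2.0, 3.0])
        sample = np.array([2.5, 3.5])
        pct = gate_percent_positive(sample, control, quantile=1.0)
        assert pct == pytest.approx(50.0)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            gate_percent_positive([], [1.0])


class TestLogLogisticFit:
    def test_half_max_at_ec50(self):
        fit = LogLogistic(make_experiment()).fit()
        assert fit.predict(fit.ec50) == pytest.approx(
            (fit.top + fit.bottom) / 2, rel=1e-9)

    def test_noiseless_recovery_tcr_scale(self):
        """Exact recovery of an EC50 of 17,000 ligands/cell."""
        fit = LogLogistic(make_experiment(ec50=1.7e4, slope=1.2)).fit()
        assert fit.converged
        assert fit.bottom == pytest.approx(0.0, abs=1e-8)
        assert fit.top == pytest.approx(1.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(1.7e4, rel=1e-6)
        assert fit.hillslope == pytest.approx(1.2, rel=1e-6)

    def test_fixed_slope_noiseless_recovery(self):
        exp = make_experiment(bottom=5.0, top=100.0, ec50=1e4, slope=1.0)
        fit = LogLogistic(exp, fix_hillslope=True).fit()
        assert fit.hill_fixed and fit.hillslope == 1.0
        assert fit.ec50 == pytest.approx(1e4, rel=1e-6)
        assert fit.bottom == pytest.approx(5.0, rel=1e-6)

    def test_variable_fit_with_unit_slope_matches_fixed(self):
        exp = make_experiment(slope=1.0)
        var = LogLogistic(exp).fit()
        fix = LogLogistic(exp, fix_hillslope=True).fit()
        assert var.ec50 == pytest.approx(fix.ec50, rel=1e-5)
        assert var.hillslope == pytest.approx(1.0, rel=1e-5)

    def test_fixed_slope_nesting_inequality(self):
        exp = make_experiment(slope=1.4, noise=0.08, seed=3)
        var = LogLogistic(exp, weighting="none").fit()
        fix = LogLogistic(exp, fix_hillslope=True, weighting="none").fit()
        assert fix.sse >= var.sse - 1e-9 * max(var.sse, 1.0)

    def test_monotone_curve_for_positive_slope(self):
        fit = LogLogistic(make_experiment(noise=0.05, seed=2)).fit()
        grid = np.geomspace(1.0, 1e8, 200)
        assert np.all(np.diff(fit.predict(grid)) >= 0)

    def test_ec50_invariant_to_response_rescaling(self):
        exp = make_experiment(noise=0.05, seed=7)
        a = LogLogistic(exp).fit()
        scaled = DoseResponseExperiment(doses=exp.doses,
                                        responses=exp.responses * 37.0)
        b = LogLogistic(scaled).fit()
        assert b.ec50 == pytest.approx(a.ec50, rel=1e-6)
        assert b.top == pytest.approx(37.0 * a.top, rel=1e-6)

    def test_ec50_scales_with_dose_axis(self):
        exp = make_experiment(noise=0.05, seed=7)
        a = LogLogistic(exp).fit()
        scaled = DoseResponseExperiment(doses=exp.doses * 4.0,
                                        responses=exp.responses)
        b = LogLogistic(scaled).fit()
        assert b.ec50 == pytest.approx(4.0 * a.ec50, rel=1e-6)

    def test_out_of_range_ec50_flagged(self):
        doses = np.geomspace(1e5, 1e6, 6)   # far below the transition
        y = log_logistic(doses, 0, 1, np.log10(1e9), 1.0)
        with pytest.warns(UserWarning, match="outside 10x"):
            fit = LogLogistic(DoseResponseExperiment(
                doses=doses, responses=y)).fit()
        assert not fit.ec50_in_range

    def test_variable_slope_recovery_median_under_10pct(self):
        """8 log-spaced doses, duplicate wells, 10% CV: median relative
        EC50 error across 200 seeded experiments stays within 10%."""
        errs = []
        for seed in range(200):
            exp = gen_dose_response_experiment(
                GroundTruth(ec50=2e5, hillslope=1.2, top=1000.0, seed=seed))
            fit = LogLogistic(exp).fit()
            errs.append(abs(fit.ec50 - 2e5) / 2e5)
        assert np.median(errs) <= 0.10

    def test_fixed_slope_recovery_within_15pct(self):
        """CAR-like MFI readouts at 10% CV, unit Hill slope."""
        errs = []
        for seed in range(100):
            exp = gen_dose_response_experiment(
                GroundTruth(ec50=500.0, hillslope=1.0, top=2000.0,
                            background=100.0, seed=seed),
                readout_unit="MFI_AU")
            fit = LogLogistic(exp, fix_hillslope=True).fit()
            errs.append(abs(fit.ec50 - 500.0) / 500.0)
        assert np.median(errs) <= 0.15


class TestNormalization:
    def test_max_becomes_exactly_one(self):
        exp = DoseResponseExperiment(doses=[1., 10., 100.],
                                     responses=[0., 50., 100.])
        normed = normalize_to_max(exp)
        np.testing.assert_allclose(normed.responses, [0.0, 0.5, 1.0])
        assert normed.normalized

    def test_idempotent(self):
        exp = DoseResponseExperiment(doses=[1., 10., 100.],
                                     responses=[0.0, 0.5, 1.0])
        normed = normalize_to_max(exp)
        np.testing.assert_allclose(normed.responses, exp.responses)

    def test_fit_ec50_invariant_under_normalization(self):
        exp = make_experiment(top=430.0, noise=0.05, seed=11)
        raw = LogLogistic(exp).fit()
        normed = LogLogistic(normalize_to_max(exp)).fit()
        assert normed.ec50 == pytest.approx(raw.ec50, rel=1e-6)

    def test_nonpositive_max_rejected(self):
        exp = DoseResponseExperiment(doses=[1., 10.], responses=[-5., -1.])
        with pytest.raises(ValueError):
            normalize_to_max(exp)


class TestSummaries:
    def test_mean_and_sample_sd(self):
        fits = [LogLogistic(make_experiment(ec50=e)).fit()
                for e in (1e5, 2e5, 3e5)]
        s = summarize_ec50(fits)
        assert s.mean == pytest.approx(2e5, rel=1e-5)
        assert s.sd == pytest.approx(1e5, rel=1e-5)
        assert s.n == 3

    def test_single_fit_sd_zero(self):
        s = summarize_ec50([LogLogistic(make_experiment(ec50=5e4)).fit()])
        assert s.mean == pytest.approx(5e4, rel=1e-5)
        assert s.sd == 0.0

    def test_matches_direct_oracle(self, rng):
        vals = rng.uniform(1e4, 1e6, 6)
        fits = [LogLogistic(make_experiment(ec50=v)).fit() for v in vals]
        s = summarize_ec50(fits)
        assert s.mean == pytest.approx(np.mean(vals), rel=1e-4)
        assert s.sd == pytest.approx(np.std(vals, ddof=1), rel=1e-4)

    def test_all_unconverged_rejected(self):
        fit = LogLogistic(make_experiment()).fit()
        fit.converged = False
        with pytest.raises(ValueError):
            summarize_ec50([fit])


class TestFoldChange:
    @pytest.mark.parametrize("a, b, ratio, fold", [
        (1_000_000, 200_000, 5.0, 5),       # valency comparison
        (43e-6, 6.8e-6, 6.3235, 6),         # affinity comparison
        (1_000_000, 190_000, 5.2632, 5),    # tag-affinity EC50 comparison
        (7.0, 7.0, 1.0, 1),
    ])
    def test_ratio_and_nearest_integer(self, a, b, ratio, fold):
        r, f = fold_change(a, b)
        assert r == pytest.approx(ratio, rel=1e-4)
        assert f == fold

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
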