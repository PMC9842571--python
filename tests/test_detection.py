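"""Detection functions: closed forms, truncation, MLE, ESW, AIC selection."""

import math

import numpy as np
import pytest

from disturbsamp.detection import (DetectionFunction, KeyFunctionSpec,
                                   candidate_specs, fit_detection,
                                   half_normal_esw, half_normal_sigma_mle,
                                   right_truncate, select_model)

from conftest import hn_sample


def _manual_fit(key, key_params, w):
    """A DetectionFunction with parameters set directly (no data)."""
    f = DetectionFunction(key, truncation_w=w)
    f.key_params_ = np.asarray(key_params, dtype=float)
    f.adjustment_coefs_ = np.empty(0)
    f.w_ = w
    return f


class TestShapes:
    @pytest.mark.parametrize("key, params, x, expected", [
        ("uniform", [], 37.0, 1.0),
        ("half_normal", [25.0], 25.0, math.exp(-0.5)),
        ("half_normal", [25.0], 0.0, 1.0),
        ("hazard_rate", [30.0, 3.0], 30.0, 1.0 - math.exp(-1.0)),
    ])
    def test_closed_form_values(self, key, params, x, expected):
        assert _manual_fit(key, params, 100.0).predict(x) == pytest.approx(expected, abs=1e-12)

    def test_domain_error_outside_truncation(self):
        f = _manual_fit("half_normal", [25.0], 100.0)
        with pytest.raises(ValueError):
            f.predict(150.0)
        with pytest.raises(ValueError):
            f.predict(-1.0)

    def test_g_at_zero_is_one_after_adjustment_rescaling(self, rng):
        x = hn_sample(300, 20.0, 80.0, rng)
        fit = fit_detection(x, KeyFunctionSpec("half_normal", "cosine", 1), w=80.0)
        assert fit.predict(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            KeyFunctionSpec("gaussian", "cosine", 0)
        with pytest.raises(ValueError):
            KeyFunctionSpec("uniform", "cosine", 4)


class TestESW:
    def test_uniform_esw_equals_truncation(self):
        fit = DetectionFunction("uniform", truncation_w=100.0).fit(np.linspace(1, 99, 30))
        assert fit.esw_ == pytest.approx(100.0)
        assert fit.esw_se_ == 0.0

    def test_half_normal_esw_matches_erf_form(self, rng):
        x = hn_sample(400, 25.0, 100.0, rng)
        fit = DetectionFunction("half_normal", truncation_w=100.0).fit(x)
        closed = half_normal_esw(float(fit.key_params_[0]), 100.0)
        assert fit.esw_ == pytest.approx(closed, rel=1e-8)
        # sigma=25, w=100: mu = sigma sqrt(pi/2) erf(w / sigma sqrt 2) ~ 31.33 m
        assert half_normal_esw(25.0, 100.0) == pytest.approx(31.33, abs=0.01)

    def test_halving_sigma_halves_esw_when_w_large(self):
        assert half_normal_esw(10.0, 1000.0) == pytest.approx(
            half_normal_esw(20.0, 1000.0) / 2.0, rel=1e-10)


class TestTruncation:
    def test_quantile_rule_keeps_95(self):
        w, kept = right_truncate(np.arange(1.0, 101.0), "quantile", q=0.95)
        assert w == 95.0
        assert len(kept) == 95

    def test_degenerate_all_equal(self):
        w, kept = right_truncate(np.full(10, 7.0), "quantile")
        assert w == 7.0 and len(kept) == 10

    def test_detection_floor_inverts_pilot_fit(self, rng):
        x = hn_sample(20000, 25.0, 200.0, rng)
        w, _ = right_truncate(x, "detection_floor", g_min=0.15)
        assert w == pytest.approx(25.0 * math.sqrt(2.0 * math.log(1 / 0.15)), rel=0.02)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            right_truncate([])


class TestFitting:
    def test_half_normal_mle_closed_form(self):
        x = np.array([10.0, 20.0, 30.0])
        fit = fit_detection(x, KeyFunctionSpec("half_normal", "cosine", 0), w=1000.0)
        assert fit.converged_
        assert fit.key_params_[0] == pytest.approx(math.sqrt(1400 / 3), rel=1e-4)

    def test_parameter_recovery_within_3se(self, rng):
        x = hn_sample(500, 30.0, 150.0, rng)
        fit = DetectionFunction("half_normal", truncation_w=150.0).fit(x)
        sigma_hat = float(fit.key_params_[0])
        se = sigma_hat / math.sqrt(2 * len(x))  # asymptotic SE of the HN scale
        assert abs(sigma_hat - 30.0) < 3 * se

    def test_identical_data_identical_fit(self, rng):
        x = hn_sample(200, 25.0, 100.0, rng)
        f1 = DetectionFunction("hazard_rate", truncation_w=100.0).fit(x)
        f2 = DetectionFunction("hazard_rate", truncation_w=100.0).fit(x)
        assert f1.loglik_ == f2.loglik_
        assert np.array_equal(f1.key_params_, f2.key_params_)

    def test_aic_identity(self, rng):
        x = hn_sample(200, 25.0, 100.0, rng)
        fit = DetectionFunction("half_normal", truncation_w=100.0).fit(x)
        assert fit.aic_ == pytest.approx(2 * 1 - 2 * fit.loglik_)

    def test_quadrature_self_consistency(self, rng):
        from scipy import integrate
        x = hn_sample(300, 25.0, 100.0, rng)
        fit = fit_detection(x, KeyFunctionSpec("half_normal", "cosine", 1), w=100.0)
        quad = integrate.quad(lambda t: float(fit.predict(t)), 0.0, fit.w_, limit=200)[0]
        assert quad / fit.esw_ == pytest.approx(1.0, abs=1e-8)

    def test_too_few_distances_error(self):
        with pytest.raises(ValueError):
            DetectionFunction("half_normal", truncation_w=50.0).fit([10.0])


class TestSelection:
    def test_candidate_enumeration(self):
        specs = candidate_specs()
        assert len(specs) == 21
        assert sum(s.key == "uniform" and s.n_adjustments == 0 for s in specs) == 1

    def test_nested_aic_bound(self, rng):
        # adding one adjustment can lower the loglik penalty by at most its
        # 2-point parameter cost: AIC(child) >= AIC(parent) - eps
        x = hn_sample(400, 25.0, 100.0, rng)
        parent = fit_detection(x, KeyFunctionSpec("half_normal", "cosine", 0), w=100.0)
        child = fit_detection(x, KeyFunctionSpec("half_normal", "cosine", 1), w=100.0)
        if child.converged_ and parent.converged_:
            assert child.aic_ >= parent.aic_ - 2.0 - 1e-6
            assert child.loglik_ >= parent.loglik_ - 1e-6

    def test_selects_lowest_aic_converged(self, rng):
        x = hn_sample(500, 25.0, 100.0, rng)
        specs = [KeyFunctionSpec("half_normal", "cosine", 0),
                 KeyFunctionSpec("uniform", "cosine", 1),
                 KeyFunctionSpec("hazard_rate", "cosine", 0)]
        best = select_model(x, 100.0, candidates=specs)
        fits = [fit_detection(x, s, 100.0) for s in specs]
        best_aic = min(f.aic_ for f in fits if f.converged_)
        assert best.aic_ == pytest.approx(best_aic)

    def test_tie_breaks_prefer_fewer_parameters(self):
        # uniform/0 and uniform/0 duplicates aside, force a tie by comparing
        # the sort key directly on synthetic fits
        from disturbsamp.detection import _KEY_ORDER
        assert _KEY_ORDER["uniform"] < _KEY_ORDER["half_normal"] < _KEY_ORDER["hazard_rate"]

    def test_no_convergence_raises_with_details(self):
        from disturbsamp.detection import DetectionError
        x = np.full(5, 10.0)  # a single distinct distance cannot identify a scale
        with pytest.raises(DetectionError, match="half_normal"):
            select_model(x, 20.0, candidates=[KeyFunctionSpec("half_normal", "cosine", 0)])
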