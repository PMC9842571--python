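"""Density estimation: size-bias regression, CDS arithmetic, passage
selection and the corrected-density estimator."""

import math

import numpy as np
import pytest

from disturbsamp.bayes import EncounterRateModel
from disturbsamp.density import (SizeBiasRegression, corrected_density,
                                 encounter_rate_variance, estimate_density,
                                 estimate_group_density, passage_density,
                                 select_passages, size_bias_expected_size)
from disturbsamp.detection import KeyFunctionSpec
from disturbsamp.simulate import SimulationConfig, simulate_survey


class TestSizeBias:
    def test_flat_sizes_use_the_mean(self):
        es, se, method = size_bias_expected_size([5] * 20, np.arange(1.0, 21.0))
        assert method == "mean"
        assert es == pytest.approx(5.0)

    def test_negative_slope_triggers_regression(self):
        rng = np.random.default_rng(42)
        x = np.arange(0.0, 101.0, 2.0)
        sizes = np.maximum(1, np.round(np.exp(2.0 - 0.02 * x + rng.normal(0, 0.05, len(x)))))
        es, se, method = size_bias_expected_size(sizes, x)
        assert method == "regression"
        # back-transform at the line exceeds the raw mean (bias correction)
        assert es > float(np.mean(sizes))
        assert se > 0

    def test_two_points_forces_mean(self):
        es, se, method = size_bias_expected_size([4, 6], [10.0, 20.0])
        assert method == "mean_forced"
        assert es == pytest.approx(5.0)

    def test_detection_covariate_variant(self, rng):
        from disturbsamp.detection import DetectionFunction
        from conftest import hn_sample
        x = hn_sample(100, 25.0, 100.0, rng)
        fit = DetectionFunction("half_normal", truncation_w=100.0).fit(x)
        sizes = np.maximum(1, np.round(np.exp(2.0 - 0.015 * x)))
        sb = SizeBiasRegression(covariate="detection", detection_fit=fit).fit(x, sizes)
        assert sb.expected_size_ > 0

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            size_bias_expected_size([1, 2], [1.0])


class TestGroupDensity:
    def test_point_estimate_arithmetic(self):
        # 100 groups over 100 km with a 50 m strip half-width: 10 groups/km^2
        dg, se = estimate_group_density(np.full(10, 10.0), np.full(10, 10.0), 50.0, 0.0)
        assert dg == pytest.approx(10.0)
        assert se == 0.0  # identical transects: no encounter-rate variance

    def test_zero_counts(self):
        dg, se = estimate_group_density(np.zeros(5), np.ones(5), 40.0)
        assert dg == 0.0 and se == 0.0

    def test_zero_effort_errors(self):
        with pytest.raises(ValueError):
            estimate_group_density([1.0], [0.0], 40.0)

    def test_r2_variance_matches_direct_formula(self):
        counts = np.array([0.0, 2.0, 1.0, 4.0])
        efforts = np.array([1.0, 1.0, 2.0, 1.0])
        er, var = encounter_rate_variance(counts, efforts)
        L, K = efforts.sum(), 4
        direct = K / (L**2 * (K - 1)) * np.sum(efforts**2 * (counts / efforts - er) ** 2)
        assert er == pytest.approx(7.0 / 5.0)
        assert var == pytest.approx(direct)


class TestDensityEstimate:
    def test_product_and_lognormal_ci(self):
        est = estimate_density(5.45, 0.0, 16.53, 0.0)
        assert est.density == pytest.approx(5.45 * 16.53)  # ~90.1 ind/km^2
        assert est.ci95 == (pytest.approx(est.density), pytest.approx(est.density))

    def test_ci_closed_form_at_cv_03(self):
        # cv = 0.3, D = 100: C = exp(1.96 sqrt(ln 1.09)), CI ~ (56.1, 178.2)
        est = estimate_density(100.0, 30.0, 1.0, 0.0)
        c = math.exp(1.96 * math.sqrt(math.log(1.09)))
        assert est.ci95[0] == pytest.approx(100.0 / c, rel=1e-9)
        assert est.ci95[1] == pytest.approx(100.0 * c, rel=1e-9)
        assert est.ci95[0] == pytest.approx(56.1, abs=0.5)
        assert est.ci95[1] == pytest.approx(178.2, abs=0.5)

    def test_nonfinite_cv_errors(self):
        with pytest.raises(ValueError):
            estimate_density(1.0, float("inf"), 1.0, 0.0)

    def test_cv_combines_components(self):
        est = estimate_density(10.0, 1.0, 5.0, 0.5)
        assert est.cv == pytest.approx(math.sqrt(0.01 + 0.01))


class TestPassageSelection:
    def _fake_model(self, draws_by_passage):
        m = EncounterRateModel()
        m.passages_ = sorted(draws_by_passage)
        m.eta_draws_ = {r: np.asarray(d, dtype=float) for r, d in draws_by_passage.items()}
        return m

    def test_identical_passages_all_retained(self, rng):
        d = rng.lognormal(0, 0.1, 4000)
        m = self._fake_model({2: d, 3: d.copy(), 4: d.copy()})
        assert select_passages(m, (2, 3, 4)) == [2, 3, 4]

    def test_depressed_passage_dropped(self, rng):
        lo = rng.normal(0.5, 0.02, 4000)
        hi = rng.normal(1.0, 0.02, 4000)
        m = self._fake_model({2: lo, 3: hi, 4: hi + rng.normal(0, 0.005, 4000)})
        assert select_passages(m, (2, 3, 4)) == [3, 4]

    def test_single_passage_errors(self, rng):
        m = self._fake_model({3: rng.lognormal(0, 0.1, 100)})
        with pytest.raises(ValueError):
            select_passages(m, (3,))


@pytest.fixture(scope="module")
def survey():
    cfg = SimulationConfig(n_transects=150)
    return cfg, simulate_survey(cfg, seed=77)


class TestEndToEndDensity:
    def test_estimated_sizes_never_lower_density(self, survey):
        _, ds = survey
        hn = [KeyFunctionSpec("half_normal", "cosine", 0)]
        # alpha=0 forces the mean branch in both, isolating the size effect
        d_obs = passage_density(ds, [3], size_kind="observed", candidates=hn, alpha=0.0)
        d_est = passage_density(ds, [3], size_kind="estimated", candidates=hn, alpha=0.0)
        assert d_est.density >= d_obs.density
        assert d_est.group_density == pytest.approx(d_obs.group_density)

    def test_corrected_density_substitutes_largest_estimated_size(self, survey):
        _, ds = survey
        hn = [KeyFunctionSpec("half_normal", "cosine", 0)]
        est = corrected_density(ds, candidates=hn,
                                sampler_kwargs=dict(chains=2, iterations=500,
                                                    warmup=250, seed=4))
        best = max((ds.observations[ds.observations.passage == r].estimated_size.mean(), r)
                   for r in (2, 3, 4)
                   if len(ds.observations[ds.observations.passage == r]))
        assert est.expected_size == pytest.approx(best[0])
        assert f"P{best[1]}" in est.size_method
        assert est.density == pytest.approx(est.group_density * est.expected_size)
        assert est.ci95[0] < est.density < est.ci95[1]

    def test_small_sample_flagged(self):
        cfg = SimulationConfig(n_transects=12, true_group_density=4.0)
        ds = simulate_survey(cfg, seed=9)
        hn = [KeyFunctionSpec("half_normal", "cosine", 0)]
        est = passage_density(ds, [3], candidates=hn)
        assert est.n_groups < 20
        assert any("small sample" in w for w in est.warnings)
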