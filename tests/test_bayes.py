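"""Bayesian passage models: parameter recovery, filters, contrasts."""

import numpy as np
import pytest

from disturbsamp.bayes import (EncounterRateModel, GroupSizeModel,
                               passage_contrasts)
from disturbsamp.studies import dataset_from_counts, dataset_from_sizes

FAST = dict(chains=2, iterations=800, warmup=400, nwalkers=8)


def _nb_counts(rng, eta, phi, n):
    return rng.negative_binomial(phi, phi / (phi + eta), size=n)


class TestEncounterRateModel:
    def test_recovers_known_rates(self):
        rng = np.random.default_rng(314)
        truth = {1: 0.9, 2: 0.9, 3: 1.2, 4: 1.2}
        ds = dataset_from_counts({r: _nb_counts(rng, eta, 2.0, 300)
                                  for r, eta in truth.items()})
        model = EncounterRateModel(seed=1, **FAST).fit(ds)
        for _, row in model.summary_.iterrows():
            assert row.eta_lo95 <= truth[row.passage] <= row.eta_hi95
            # loose diagnostic bound at this reduced test budget; the default
            # 4x2000/1000 budget targets R-hat < 1.01
            assert row.rhat_eta < 1.1

    def test_poisson_counts_push_phi_large(self):
        rng = np.random.default_rng(99)
        counts = rng.poisson(1.0, size=1000)
        ds = dataset_from_counts({2: counts})
        model = EncounterRateModel(passages=(2,), seed=2, **FAST).fit(ds)
        assert np.quantile(model.phi_draws_[2], 0.05) > 5.0

    def test_effort_offset(self):
        # same counts on 2 km walks mean half the rate per km
        rng = np.random.default_rng(5)
        counts = _nb_counts(rng, 2.0, 5.0, 400)
        ds1 = dataset_from_counts({2: counts}, effort_km=1.0)
        ds2 = dataset_from_counts({2: counts}, effort_km=2.0)
        m1 = EncounterRateModel(passages=(2,), seed=3, **FAST).fit(ds1)
        m2 = EncounterRateModel(passages=(2,), seed=3, **FAST).fit(ds2)
        assert np.mean(m1.eta_draws_[2]) == pytest.approx(
            2.0 * np.mean(m2.eta_draws_[2]), rel=0.05)

    def test_wide_prior_matches_empirical_rate(self):
        # with a diffuse prior the posterior mean rate approaches n/L
        rng = np.random.default_rng(11)
        counts = _nb_counts(rng, 1.1, 2.0, 1000)
        ds = dataset_from_counts({2: counts})
        model = EncounterRateModel(passages=(2,), seed=4, prior_eta_sd=10.0, **FAST).fit(ds)
        assert np.mean(model.eta_draws_[2]) == pytest.approx(counts.mean(), rel=0.02)

    def test_too_few_walks_skipped(self):
        ds = dataset_from_counts({2: np.array([1]), 3: np.arange(10)})
        model = EncounterRateModel(passages=(2, 3), seed=5, **FAST).fit(ds)
        assert model.passages_ == [3]


class TestGroupSizeModel:
    def test_recovers_lognormal_location(self):
        rng = np.random.default_rng(2718)
        sizes = rng.lognormal(2.0, 0.5, size=200)
        ds = dataset_from_sizes({2: sizes})
        model = GroupSizeModel(passages=(2,), size_kind="estimated", seed=6, **FAST).fit(ds)
        row = model.summary_.iloc[0]
        assert row.mu_lo95 <= 2.0 <= row.mu_hi95
        assert row.rhat_mu < 1.05

    def test_location_identified_from_tight_data(self):
        rng = np.random.default_rng(12)
        sizes = np.exp(2.0 + rng.normal(0, 0.01, size=150))
        ds = dataset_from_sizes({3: sizes})
        model = GroupSizeModel(passages=(3,), size_kind="estimated", seed=7, **FAST).fit(ds)
        assert np.mean(model.mu_draws_[3]) == pytest.approx(2.0, abs=0.05)

    def test_passage_one_is_excluded(self):
        rng = np.random.default_rng(13)
        ds = dataset_from_sizes({1: rng.lognormal(2, 0.3, 50),
                                 2: rng.lognormal(2, 0.3, 50)})
        model = GroupSizeModel(passages=(1, 2), size_kind="estimated", seed=8, **FAST).fit(ds)
        assert model.passages_ == [2]
        with pytest.raises(ValueError):
            model.sizes_per_walk(ds, 1)

    def test_natural_mean_reported(self):
        rng = np.random.default_rng(14)
        ds = dataset_from_sizes({2: rng.lognormal(2.0, 0.5, 300)})
        model = GroupSizeModel(passages=(2,), size_kind="estimated", seed=9, **FAST).fit(ds)
        nat = model.summary_.iloc[0].natural_mean
        assert nat == pytest.approx(np.exp(2.0 + 0.125), rel=0.1)


class TestContrasts:
    def test_identical_chains_give_zero_contrast(self):
        model = EncounterRateModel()
        d = np.random.default_rng(0).lognormal(0, 0.2, 1000)
        model.passages_ = [2, 3]
        model.eta_draws_ = {2: d, 3: d.copy()}
        cs = passage_contrasts(model)
        assert np.all(cs.draws[(2, 3)] == 0.0)

    def test_antisymmetry_drawwise(self):
        rng = np.random.default_rng(21)
        ds = dataset_from_counts({2: rng.poisson(1.0, 100), 3: rng.poisson(1.3, 100)})
        model = EncounterRateModel(passages=(2, 3), seed=10, **FAST).fit(ds)
        cs = passage_contrasts(model)
        assert np.array_equal(cs.draws[(2, 3)], -cs.draws[(3, 2)])

    def test_exchangeable_passages_contain_zero(self):
        rng = np.random.default_rng(22)
        ds = dataset_from_counts({2: _nb_counts(rng, 1.0, 2.0, 300),
                                  3: _nb_counts(rng, 1.0, 2.0, 300)})
        model = EncounterRateModel(passages=(2, 3), seed=11, **FAST).fit(ds)
        lo, hi = passage_contrasts(model).interval(2, 3, 0.95)
        assert lo < 0 < hi

    def test_separated_rates_exclude_zero(self):
        rng = np.random.default_rng(23)
        ds = dataset_from_counts({2: _nb_counts(rng, 0.9, 2.0, 300),
                                  3: _nb_counts(rng, 1.35, 2.0, 300)})
        model = EncounterRateModel(passages=(2, 3), seed=12, **FAST).fit(ds)
        lo, hi = passage_contrasts(model).interval(3, 2, 0.95)
        assert lo > 0

    def test_mismatched_draws_error(self):
        model = EncounterRateModel()
        model.passages_ = [2, 3]
        model.eta_draws_ = {2: np.ones(100), 3: np.ones(200)}
        with pytest.raises(ValueError, match="draw counts"):
            passage_contrasts(model)

    def test_single_passage_errors(self):
        model = EncounterRateModel()
        model.passages_ = [2]
        model.eta_draws_ = {2: np.ones(100)}
        with pytest.raises(ValueError):
            passage_contrasts(model)
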