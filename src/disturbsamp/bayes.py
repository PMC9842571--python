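"""Bayesian per-passage models of encounter rate and group size.

Encounter rates: the per-walk group count (sighted group events plus
heard-only records) on transect i in passage r is modelled as

    n_i ~ NegativeBinomial(mean = eta_r * effort_i, overdispersion = phi_r)

with variance m + m^2/phi, i.e. counts with a multiplicative effort offset,
so eta_r is the mean encounter rate (groups/km) of passage r and phi_r the
passage's overdispersion.  Group sizes: the per-walk mean observed (or
estimated) group size GS_i among walks with at least one sighting, in
passages 2-4, is modelled as GS_i ~ Lognormal(mu_r, sigma_r); passage 1 is
excluded because sizes were recorded opportunistically there.

Priors are weakly informative and overridable: eta_r ~ Lognormal(0, 1.5),
1/phi_r ~ HalfNormal(1) (weakly informative on the variance-inflation
scale), mu_r ~ Normal(0, 2.5), sigma_r ~ HalfNormal(1.5).

Sampling uses emcee ensembles: ``chains`` independent ensembles of
``nwalkers`` walkers each are run for ``iterations`` moves with ``warmup``
discarded (defaults 4 x 2000, 1000 warm-up), and R-hat is computed across
the independent ensembles with arviz.  Posterior contrasts between passages
are draw-wise differences of the passage means.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .survey import SurveyDataset

logger = logging.getLogger("disturbsamp")


def _run_ensembles(log_prob: Callable[[np.ndarray], np.ndarray], ndim: int,
                   center: np.ndarray, seed: int, chains: int, iterations: int,
                   warmup: int, nwalkers: int,
                   spread: np.ndarray | float = 0.5) -> np.ndarray:
    """Run independent emcee ensembles; returns draws (chains, kept*walkers, ndim).

    ``spread`` sets the walker initialization scale around ``center`` and
    should be commensurate with the posterior scale (a ball much wider than
    the posterior stalls the affine-invariant moves on sharply peaked
    targets).
    """
    seeds = np.random.SeedSequence(seed).generate_state(chains)
    out, accept = [], []
    for c in range(chains):
        rs = np.random.RandomState(int(seeds[c]) % (2**32))
        p0 = center + np.asarray(spread) * rs.randn(nwalkers, ndim)
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
        sampler.random_state = rs.get_state()
        sampler.run_mcmc(p0, iterations, progress=False)
        chain = sampler.get_chain(discard=warmup)  # (kept, walkers, ndim)
        out.append(chain.reshape(-1, ndim))
        accept.append(float(np.mean(sampler.acceptance_fraction)))
    return np.stack(out), float(np.mean(accept))  # (chains, draws, ndim)


def _rhat(draws: np.ndarray, names: list[str]) -> dict[str, float]:
    """Split-R-hat across independent ensembles for each parameter."""
    ds = az.convert_to_dataset({n: draws[:, :, i] for i, n in enumerate(names)})
    r = az.rhat(ds)
    return {n: float(r[n].values) for n in names}


class _PassageModelBase(BaseEstimator):
    def __init__(self, chains: int = 4, iterations: int = 2000, warmup: int = 1000,
                 nwalkers: int = 8, seed: int = 0, species: str | None = None):
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.nwalkers = nwalkers
        self.seed = seed
        self.species = species

    def _check_budget(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")

    def _diagnose(self, r: int, draws: np.ndarray, names: list[str]) -> dict:
        rh = _rhat(draws, names)
        bad = {k: v for k, v in rh.items() if v > 1.01}
        if bad:
            logger.warning("passage %s: R-hat above 1.01 for %s", r, bad)
        return rh

    def mean_draws(self, passage: int) -> np.ndarray:
        """Posterior draws of the natural-scale passage mean (for contrasts)."""
        raise NotImplementedError


class EncounterRateModel(_PassageModelBase):
    """Negative-binomial encounter-rate model fitted independently per passage.

    After :meth:`fit`: ``passages_`` (fitted passages), ``eta_draws_`` and
    ``phi_draws_`` (dict passage -> pooled posterior draws), ``rhat_``,
    ``summary_`` (DataFrame of posterior means and 95% credible intervals).
    """

    def __init__(self, chains: int = 4, iterations: int = 2000, warmup: int = 1000,
                 nwalkers: int = 8, seed: int = 0, species: str | None = None,
                 prior_eta_sd: float = 1.5, prior_inv_phi_scale: float = 1.0,
                 include_heard: bool = True, passages: tuple = (1, 2, 3, 4)):
        super().__init__(chains, iterations, warmup, nwalkers, seed, species)
        self.prior_eta_sd = prior_eta_sd
        self.prior_inv_phi_scale = prior_inv_phi_scale
        self.include_heard = include_heard
        self.passages = passages

    def counts_per_walk(self, ds: SurveyDataset, passage: int) -> tuple[np.ndarray, np.ndarray]:
        """Group counts (events + heard-only) and efforts per walk of a passage."""
        t = ds.transects[ds.transects.passage == passage]
        ev = ds.group_events([passage], self.species)
        counts = ev.groupby("transect_id").size()
        if self.include_heard:
            h = ds.heard[ds.heard.passage == passage]
            if self.species is not None:
                h = h[h.species == self.species]
            hc = h.groupby("transect_id").size()
            counts = counts.add(hc, fill_value=0)
        n = counts.reindex(t.transect_id, fill_value=0).to_numpy(dtype=float)
        return n, t.effort_km.to_numpy(dtype=float)

    def fit(self, ds: SurveyDataset, y=None) -> "EncounterRateModel":
        self._check_budget()
        seeds = np.random.SeedSequence(self.seed).generate_state(len(self.passages))
        self.passages_ = []
        self.eta_draws_, self.phi_draws_, self.rhat_, self.acceptance_ = {}, {}, {}, {}
        rows = []
        for k, r in enumerate(self.passages):
            counts, efforts = self.counts_per_walk(ds, r)
            if len(counts) < 2:
                logger.warning("passage %s: fewer than 2 walks, skipped", r)
                continue
            lp = self._make_log_prob(counts, efforts)
            center = np.array([math.log(max(np.sum(counts) / np.sum(efforts), 0.05)), 0.0])
            # init spread ~ posterior scale: se(log eta) ~ 1/sqrt(total count)
            se_log_eta = 1.0 / math.sqrt(max(np.sum(counts), 1.0))
            spread = np.array([max(3.0 * se_log_eta, 0.05), 0.5])
            draws, accept = _run_ensembles(lp, 2, center, int(seeds[k]) % (2**31),
                                           self.chains, self.iterations, self.warmup,
                                           self.nwalkers, spread=spread)
            self.rhat_[r] = self._diagnose(r, draws, ["log_eta", "log_phi"])
            self.acceptance_[r] = accept
            eta = np.exp(draws[:, :, 0].ravel())
            phi = np.exp(draws[:, :, 1].ravel())
            self.eta_draws_[r], self.phi_draws_[r] = eta, phi
            self.passages_.append(r)
            rows.append({
                "passage": r, "n_walks": len(counts),
                "eta_mean": eta.mean(), "eta_lo95": np.quantile(eta, 0.025),
                "eta_hi95": np.quantile(eta, 0.975),
                "phi_mean": phi.mean(), "phi_lo95": np.quantile(phi, 0.025),
                "phi_hi95": np.quantile(phi, 0.975),
                "rhat_eta": self.rhat_[r]["log_eta"], "rhat_phi": self.rhat_[r]["log_phi"],
                "acceptance": accept,
            })
        self.summary_ = pd.DataFrame(rows)
        return self

    def _make_log_prob(self, counts: np.ndarray, efforts: np.ndarray):
        eta_sd, inv_scale = self.prior_eta_sd, self.prior_inv_phi_scale
        # NB(mean m, overdispersion phi) log-pmf written out with gammaln so
        # the count-only term is precomputed (the sampler evaluates this for
        # every walker at every move)
        lgam_k1 = gammaln(counts + 1.0)

        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            log_eta, log_phi = theta[:, 0], theta[:, 1]
            out = np.full(len(theta), -np.inf)
            ok = (np.abs(log_eta) < 30) & (np.abs(log_phi) < 30)
            if not ok.any():
                return out
            eta, phi = np.exp(log_eta[ok]), np.exp(log_phi[ok])
            m = eta[:, None] * efforts[None, :]
            ph = phi[:, None]
            ll = (gammaln(counts[None, :] + ph) - gammaln(ph) - lgam_k1[None, :]
                  + ph * np.log(ph / (ph + m))
                  + counts[None, :] * np.log(m / (ph + m))).sum(axis=1)
            # priors: eta ~ Lognormal(0, eta_sd), i.e. log_eta ~ N(0, eta_sd);
            # 1/phi ~ HalfNormal(inv_scale) -- weakly informative on the
            # variance-inflation scale (a half-normal on phi itself pulls the
            # weakly identified overdispersion toward the Poisson limit and
            # narrows the rate intervals); density in u = log phi space
            lp = (-0.5 * (log_eta[ok] / eta_sd) ** 2
                  - np.exp(-2.0 * log_phi[ok]) / (2.0 * inv_scale**2) - log_phi[ok])
            out[ok] = ll + lp
            return out

        return log_prob

    def mean_draws(self, passage: int) -> np.ndarray:
        return self.eta_draws_[passage]


class GroupSizeModel(_PassageModelBase):
    """Lognormal model of the per-walk mean group size, per passage (P2-P4).

    ``size_kind='observed'`` uses directly seen individuals; ``'estimated'``
    additionally counts animals localised acoustically.  Natural-scale
    passage means exp(mu + sigma^2/2) are reported alongside the log-scale
    location, since a lognormal's location parameter is not its mean.
    """

    def __init__(self, chains: int = 4, iterations: int = 2000, warmup: int = 1000,
                 nwalkers: int = 8, seed: int = 0, species: str | None = None,
                 size_kind: str = "observed", prior_mu_mean: float = 0.0,
                 prior_mu_sd: float = 2.5, prior_sigma_scale: float = 1.5,
                 passages: tuple = (2, 3, 4)):
        super().__init__(chains, iterations, warmup, nwalkers, seed, species)
        self.size_kind = size_kind
        self.prior_mu_mean = prior_mu_mean
        self.prior_mu_sd = prior_mu_sd
        self.prior_sigma_scale = prior_sigma_scale
        self.passages = passages

    def sizes_per_walk(self, ds: SurveyDataset, passage: int) -> np.ndarray:
        if passage == 1:
            raise ValueError("passage 1 is excluded from group-size models")
        col = {"observed": "observed_size", "estimated": "estimated_size"}[self.size_kind]
        o = ds.observations[ds.observations.passage == passage]
        if self.species is not None:
            o = o[o.species == self.species]
        if len(o) == 0:
            return np.empty(0)
        return o.groupby("transect_id")[col].mean().to_numpy(dtype=float)

    def fit(self, ds: SurveyDataset, y=None) -> "GroupSizeModel":
        self._check_budget()
        passages = [r for r in self.passages if r != 1]
        seeds = np.random.SeedSequence(self.seed).generate_state(len(passages))
        self.passages_ = []
        self.mu_draws_, self.sigma_draws_, self.rhat_, self.acceptance_ = {}, {}, {}, {}
        rows = []
        for k, r in enumerate(passages):
            gs = self.sizes_per_walk(ds, r)
            if len(gs) < 2:
                logger.warning("passage %s: fewer than 2 walks with sightings, dropped", r)
                continue
            lp = self._make_log_prob(gs)
            sd_log = float(np.std(np.log(gs)))
            center = np.array([float(np.mean(np.log(gs))), math.log(max(sd_log, 0.02))])
            # init spread ~ posterior scale: se(mu) ~ sd(log gs)/sqrt(n)
            se_mu = max(sd_log, 0.02) / math.sqrt(len(gs))
            spread = np.array([max(3.0 * se_mu, 1e-3), 0.5])
            draws, accept = _run_ensembles(lp, 2, center, int(seeds[k]) % (2**31),
                                           self.chains, self.iterations, self.warmup,
                                           self.nwalkers, spread=spread)
            self.rhat_[r] = self._diagnose(r, draws, ["mu", "log_sigma"])
            self.acceptance_[r] = accept
            mu = draws[:, :, 0].ravel()
            sigma = np.exp(draws[:, :, 1].ravel())
            self.mu_draws_[r], self.sigma_draws_[r] = mu, sigma
            self.passages_.append(r)
            nat = np.exp(mu + 0.5 * sigma**2)
            rows.append({
                "passage": r, "n_walks": len(gs),
                "mu_mean": mu.mean(), "mu_lo95": np.quantile(mu, 0.025),
                "mu_hi95": np.quantile(mu, 0.975),
                "sigma_mean": sigma.mean(),
                "natural_mean": nat.mean(), "natural_lo95": np.quantile(nat, 0.025),
                "natural_hi95": np.quantile(nat, 0.975),
                "rhat_mu": self.rhat_[r]["mu"], "rhat_sigma": self.rhat_[r]["log_sigma"],
                "acceptance": accept,
            })
        self.summary_ = pd.DataFrame(rows)
        return self

    def _make_log_prob(self, gs: np.ndarray):
        mu0, mu_sd, sig_scale = self.prior_mu_mean, self.prior_mu_sd, self.prior_sigma_scale
        log_gs = np.log(gs)
        sum_log_gs = float(np.sum(log_gs))
        n = len(gs)

        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            mu, log_sigma = theta[:, 0], theta[:, 1]
            out = np.full(len(theta), -np.inf)
            ok = (np.abs(mu) < 50) & (np.abs(log_sigma) < 20)
            if not ok.any():
                return out
            sigma = np.exp(log_sigma[ok])
            z = (log_gs[None, :] - mu[ok, None]) / sigma[:, None]
            ll = -0.5 * (z**2).sum(axis=1) - n * np.log(sigma) - sum_log_gs - 0.5 * n * math.log(2 * math.pi)
            lp = (-0.5 * ((mu[ok] - mu0) / mu_sd) ** 2
                  - 0.5 * (sigma / sig_scale) ** 2 + log_sigma[ok])
            out[ok] = ll + lp
            return out

        return log_prob

    def mean_draws(self, passage: int) -> np.ndarray:
        return np.exp(self.mu_draws_[passage] + 0.5 * self.sigma_draws_[passage] ** 2)


@dataclasses.dataclass
class ContrastSet:
    """Pairwise posterior contrasts of passage means.

    ``draws[(r, rp)]`` holds the draw-wise difference mean(r) - mean(rp);
    antisymmetry contrast(r, rp) == -contrast(rp, r) holds draw-wise.
    ``summary`` has one row per ordered pair with the posterior mean, 90%
    and 95% equal-tailed credible intervals, and P(contrast > 0).
    """

    draws: dict
    summary: pd.DataFrame

    def interval(self, r: int, rp: int, level: float = 0.95) -> tuple[float, float]:
        d = self.draws[(r, rp)]
        a = (1.0 - level) / 2.0
        return float(np.quantile(d, a)), float(np.quantile(d, 1.0 - a))


def passage_contrasts(model: _PassageModelBase) -> ContrastSet:
    """Draw-wise pairwise differences of natural-scale passage means."""
    passages = list(model.passages_)
    if len(passages) < 2:
        raise ValueError("need at least 2 fitted passages for contrasts")
    means = {r: model.mean_draws(r) for r in passages}
    sizes = {len(v) for v in means.values()}
    if len(sizes) != 1:
        raise ValueError("mismatched posterior draw counts across passages")
    draws, rows = {}, []
    for i, r in enumerate(passages):
        for rp in passages[i + 1:]:
            d = means[r] - means[rp]
            draws[(r, rp)] = d
            draws[(rp, r)] = -d
            rows.append({
                "pair": f"P{r}-P{rp}", "mean": float(d.mean()),
                "lo90": float(np.quantile(d, 0.05)), "hi90": float(np.quantile(d, 0.95)),
                "lo95": float(np.quantile(d, 0.025)), "hi95": float(np.quantile(d, 0.975)),
                "p_positive": float((d > 0).mean()),
            })
    return ContrastSet(draws=draws, summary=pd.DataFrame(rows))


def fit_encounter_rate_model(ds: SurveyDataset, **kwargs) -> EncounterRateModel:
    return EncounterRateModel(**kwargs).fit(ds)


def fit_group_size_model(ds: SurveyDataset, **kwargs) -> GroupSizeModel:
    return GroupSizeModel(**kwargs).fit(ds)
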