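# Methods

## The problem

Repeated-passage line-transect surveys of arboreal primates confound the
quantity of interest (density) with the animals' reaction to the survey
itself: cutting and walking a transect makes groups flee or hide, so
passages walked soon after cutting yield fewer encounters and smaller
observed groups.  The package separates the ingredients of a defensible
density estimate under these conditions: per-passage inference on encounter
rates and group sizes, conventional distance sampling on the pooled
undepressed passages, and explicit correction of the expected group size.

## Data model

A survey is three tables.  *Walks*: one row per (transect, passage) with
effort (km), time of day and days since cutting (P2 is by design the same
day as the cut, P4 at least three days later).  *Observations*: one row per
species per sighted group with the perpendicular distance of the group
centre to the line and two sizes — `observed_size` (animals seen; the
maximum over independent observers) and `estimated_size` (seen plus heard
but unseen; the observer mean, floored at the observed count).
Poly-specific (mixed-species) groups are rows sharing a `group_event_id`
and the same distance; encounter rates count group *events*, species-level
analyses use the species rows.  *Heard-only*: groups heard vocalising but
never seen, in three coarse bins (close < 100 m, far 100–500 m, very far
> 500 m); they contribute to encounter rates but never to detection-function
fitting, which needs measured distances.  Distances are stored in
centimetres (as recorded in the field) and converted to metres exactly once,
at the detection-model boundary (`survey.CM_PER_M`).

## Passage models

Per-walk group counts are modelled as negative binomial,
`n_i ~ NB(mean = eta_r * effort_i, overdispersion = phi_r)` — counts with a
multiplicative effort offset, so `eta_r` is the passage's mean encounter
rate in groups/km and the variance is `m + m^2/phi`.  Per-walk mean group
sizes (walks with at least one sighting; passages 2–4 only, because sizes
on the cutting walk are recorded opportunistically) are lognormal,
`GS_i ~ Lognormal(mu_r, sigma_r)`.  Since a lognormal's location parameter
is not its mean, natural-scale means `exp(mu + sigma^2/2)` are reported
alongside `mu`, and posterior contrasts between passages are draw-wise
differences of the natural-scale means.

Priors are weakly informative and overridable:
`eta_r ~ Lognormal(0, 1.5)` (median 1 group/km, 95% mass ~0.05–19),
`1/phi_r ~ HalfNormal(1)`, `mu_r ~ Normal(0, 2.5)`,
`sigma_r ~ HalfNormal(1.5)`.  The overdispersion prior is placed on the
reciprocal because `phi` is only weakly identified when per-walk counts are
small (mean < 1): a half-normal on `phi` itself concentrates mass at large
`phi`, pulling the posterior toward the Poisson limit, understating the
count variance `m + m^2/phi` and making the rate intervals overconfident
(posterior mean `phi` of 3–8 against a generating value of 1.5 in
simulation); on the `1/phi` (variance-inflation) scale the same simulations
recover calibrated contrast intervals.

Sampling uses emcee's affine-invariant ensembles: by default 4 independent
ensembles of 8 walkers, 2000 moves each with the first 1000 discarded;
split-R̂ is computed across the independent ensembles with arviz and a
warning is raised above 1.01.  Walkers are initialised in a ball around the
data's crude MLE whose radius is matched to the posterior scale
(≈ 3 posterior SDs): affine-invariant moves stall when the initial cloud is
orders of magnitude wider than a sharply peaked target.  Replicate
simulation studies use a reduced budget (2 ensembles of 16 walkers × 800
moves, 400 discarded — wide ensembles keep tail-quantile Monte Carlo noise
small where interval endpoints drive decisions; a minimal 2 × 8 × 400/200
budget where only posterior means matter), which loosens R̂ to ≈ 1.05
without visibly moving the summaries these studies consume.

## Detection functions and densities

Standard CDS: key functions uniform (0 parameters), half-normal
`exp(-x^2/2sigma^2)` (1), hazard-rate `1 - exp(-(x/sigma)^(-b))` (2, with
`b >= 1`), optionally multiplied by `1 + sum_j a_j cos(j pi x / w)` (cosine)
or `1 + sum_j a_j (x/w)^(2j)` (simple polynomial), rescaled so `g(0) = 1`
and clipped at zero (fits needing clipping are flagged).  Adjustment orders
start at 1 for the uniform key and at 2 otherwise (an order-1 term
duplicates the key's own shape).  The likelihood is
`sum ln g(x_i) - n ln mu` with `mu` evaluated by 128-node Gauss–Legendre
quadrature (exact to well below 1e-8 relative for these smooth integrands;
verified against the half-normal erf form).  Optimisation is L-BFGS-B from 5 dispersed starts
seeded deterministically from a hash of the data, so identical data give
identical fits.  Fitted functions must be monotone non-increasing on a
1000-point grid; violations are reported as non-converged rather than
silently accepted.  Model selection fits every key × series × 0–3
adjustment combination (21 distinct forms) and takes the lowest AIC among
converged fits, breaking ties by fewer parameters, then uniform <
half-normal < hazard-rate.  The ESW standard error is a delta-method
propagation of the observed-information covariance through the quadrature.

Right truncation is automated — the analyst's usual "inspect the histogram"
step is not reproducible — with two standard rules: the empirical 95%
quantile (inverted-CDF convention, default) or the distance where a pilot
half-normal fit falls to `g = 0.15`.  The rule used is recorded in output.

Group density is `D_g = n / (2 mu L)` with the effort-weighted
between-transect ("R2") encounter-rate variance; expected group size comes
from OLS of `ln(size)` on distance back-transformed at the line
(`exp(b0 + s^2/2)`) when the slope is significant at alpha = 0.1, else the
arithmetic mean.  Regressing on distance follows the field protocol
wording; a variant regressing on `g(x)` (the Distance-software convention)
is available via `SizeBiasRegression(covariate="detection")`.  Individual
density is the product, with `cv^2 = cv^2(n/L) + cv^2(mu) + cv^2(E[s])` and
lognormal 95% limits `(D/C, D*C)`, `C = exp(1.96 sqrt(ln(1+cv^2)))`.
Passage-specific estimates use passage-specific effort.

## Corrected density

1. Fit the encounter-rate model and keep the passages whose rate is not
   credibly below the best passage's.  "Credibly below" is an equal-tailed
   credible interval of the contrast (best − r) excluding zero.  The
   default level is 0.95: with K candidate passages there are K−1
   selected-contrast comparisons, and with two tied-best passages a 95%
   interval falsely discards one of them in ≈ 5% of surveys (≈ 10% at the
   90% level, which is exposed via `contrast_level` for analysts who prefer
   a more aggressive discard rule).  Passage 1 never enters: it has no
   measured distances.
2. Pool the retained passages' observations and refit a single detection
   function from scratch (no averaging of per-passage fits); estimate group
   density on the pooled effort.
3. Replace the expected group size by the **largest per-passage mean
   estimated size** for the species, on the argument that the passage with
   the most complete counts is closest to the true size; its standard error
   (that passage's SE of the mean) is carried into the density CV, which
   honestly prices the small samples this rule often selects.

Fewer than 20 pooled sightings yields an estimate flagged with a
small-sample warning, not an error.

## Categorical tests

Pairwise Pearson chi-squared statistics (no continuity correction) on
passage × heard-distance-category tables; zero-marginal rows/columns are
dropped with a warning.  P-values are asymptotic or Monte Carlo from tables
resampled with both margins fixed (random assignment of the column-label
multiset to the row-label multiset; default B = 2000, seeded).  The two
conventions can disagree noticeably for sparse bins like "very far" —
published p-values for such tables often do not match the asymptotic value
of their own statistic, which is why the statistic, not the p-value, is the
quantity to reproduce.  Spearman correlation uses average ranks and the
t-approximation.

## Synthetic surveys

The generator (`simulate.SimulationConfig`) emulates the study conditions:
378 transects of 1 km, passages 1–3 everywhere and P4 on a ~13% subsample;
true group density 12 groups/km² and lognormal true sizes
(`mu = 2.2, sigma = 0.8`, natural mean ≈ 12.4) chosen so that encounter
rates (~1 group/km), mean perpendicular distances (~17–20 m at
`sigma* = 25 m`) and observed sizes (~8–10.5) match the published
per-passage summaries; availability multipliers (0.75, 0.75, 1, 1) and
per-animal visibilities (0.60, 0.65, 0.75, 0.85) encode disturbance decaying
over passages; a heard-only Poisson channel at 0.45 groups/km with category
probabilities (0.535, 0.44, 0.025); 6% poly-specific events; five species
labels with weights matching the observed mix.  Counts are negative binomial
(`phi* = 1.5`, reproducing the ~46–54% zero-count walks of the study);
distances are uniform in the strip and sightings are half-normal thinned
(half-normal truth keeps a closed-form MLE available as an oracle; a
hazard-rate truth is an option).  Estimated sizes add a Poisson count of
heard members with mean `0.7 (true − observed)` — the 0.7 is an arbitrary
fixed default that nothing in the study constrains.  `true_values()` returns
the closed-form expectations (quadrature/erf for the mean sighting
probability, exact pmf sums for the rounded-floored lognormal sizes) used by
recovery tests.

What the generator does **not** emulate: spatial animal movement and
avoidance dynamics (disturbance is a per-passage multiplier, not a
mechanistic response), distance-measurement error, species differences in
detectability or vocality, observer heterogeneity, and size-biased
*availability* (an optional logit-visibility-vs-distance slope exercises the
size-bias regression, off by default).  Passing recovery tests therefore
demonstrates internal consistency of the estimators under the stated
stochastic structure, not robustness to these field realities.

## Calibration studies and problem sizes

The seeded studies in `disturbsamp.studies` (run by the test suite and by
`scripts/acceptance.py`):

* closed-form checks — half-normal MLE vs `sqrt(mean x^2)` (n = 500,
  truncation ≥ 10 sigma-hat) and quadrature ESW vs the erf form;
* AIC key recovery — 100 replicates of n = 1000 untruncated half-normal
  distances (sigma = 30) against all 21 candidate forms.  Exhaustive AIC
  selection among flexible adjustment families recovers the generating *key*
  only in a modest majority of replicates: two-to-three-term cosine series
  approximate a half-normal to within ~1–2 log-likelihood units at this n,
  so near-ties flip by sampling noise.  This is the flip side of CDS
  "pooling robustness" — in the same replicates the mis-selected winners
  estimate the effective strip width as accurately (≈ 2% mean relative
  error) as the correctly selected half-normal — so key identity, unlike
  the ESW, is not a reliably recoverable quantity here;
* prior-predictive calibration — 100 replicates each for the
  encounter-rate model (30 walks; truths drawn from the fitting priors) and
  the group-size model, recording 95%-interval coverage and the rank of the
  truth among thinned draws (chi-squared uniformity check, 8 bins).  The
  size-model study conditions both the generating and fitting priors to the
  physically meaningful regime (`mu ~ N(2, 0.5)`, `sigma ~ HalfNormal(0.5)`)
  because group sizes are floored at one animal, and calibration requires
  generating from the prior actually fitted;
* passage retention — 100 surveys of 300 transects with availability
  (0.5, 0.5, 1, 1) and the vocal channel off (heard-only records arrive at a
  passage-independent rate and would only dilute the contrast the study
  isolates), counting surveys retaining exactly {P3, P4};
* corrected-density recovery — 100 undisturbed surveys (availability and
  visibility ≡ 1, 300 transects), counting `|D-hat − D| ≤ 2 SE`; the
  candidate set is the generating half-normal family, since key recovery is
  the selection study's job;
* end-to-end determinism — two pipeline runs with one seed must produce
  byte-identical report bundles.

Replicate studies use the reduced sampler budget above; the full default
budget applies to ordinary analyses.

## Numerical choices and limitations

Ties in AIC are resolved toward parsimony; degenerate size regressions
(constant response or design) fall back to the mean; `right_truncate` with
all-equal distances returns that distance and keeps everything; empty
surveys summarise to zeros rather than erroring.  All randomness flows from
a single top-level seed through `numpy.random.SeedSequence` spawning.
Report CSVs are written rounded to 4 significant digits alongside
full-precision `*_full.csv` twins; the JSON manifest (versions, seeds,
truncation rule, selected models) suffices to re-run a bundle
bit-identically.

Known limitations: no covariate (MCDS) detection functions, left
truncation, or binned-distance likelihoods; no bootstrap variance or
spatially explicit models; the ESW standard error relies on the asymptotic
observed-information approximation, which is optimistic for small n; and
the corrected density's max-of-means size rule is upward biased by selection
(order statistics of noisy means), a price accepted in exchange for
robustness against hiding-depressed counts — its carried SE makes the bias
small relative to the interval width in the calibration study.
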