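# disturbsamp

Line-transect distance sampling under **survey-inherent disturbance**.

Walking and cutting line transects disturbs the animals being counted.
In multi-passage primate surveys — where each transect is cut open on the
first walk (P1), re-walked the same afternoon (P2), the next day (P3) and
again several days later (P4) — encounter rates and observed group sizes are
depressed on the passages closest to the cutting, so densities estimated
from those passages underestimate the truth.  `disturbsamp` implements the
full analysis chain for such surveys, motivated by multi-passage monitoring
of five diurnal primate species (colobines, mangabeys and guenons) in
Salonga National Park, DRC:

* **Survey containers** — validated tables of transect walks, sighted
  groups (with perpendicular distances in cm and observed vs acoustically
  supplemented *estimated* group sizes), and heard-only detections binned
  into three distance categories.
* **Bayesian passage models** — per-passage encounter rates
  `n_i ~ NegBin(eta_r * effort_i, phi_r)` and per-walk mean group sizes
  `GS_i ~ Lognormal(mu_r, sigma_r)` (P1 excluded), with draw-wise pairwise
  posterior contrasts between passages.
* **Detection functions** — conventional distance sampling: uniform,
  half-normal and hazard-rate keys with cosine or simple-polynomial
  adjustments (0–3 terms), automated right truncation, maximum likelihood,
  AIC model selection, and the effective strip half-width
  `mu = \int_0^w g(x) dx`.
* **Densities** — `D = n / (2 mu L) * E[s]` with size-bias regression of
  `ln(size)` on distance (alpha = 0.1), between-transect encounter-rate
  variance, delta-method CVs and lognormal confidence limits.
* **Corrected density** — the disturbance-aware estimator: discard passages
  whose posterior encounter rate is credibly below the best passage's, pool
  the rest, refit the detection function, and substitute the largest
  passage-mean estimated group size.
* **Categorical tests** — pairwise Pearson chi-squared tests on the
  heard-distance tables (asymptotic or fixed-margin Monte Carlo p) and
  Spearman correlation of observed vs estimated sizes.
* **Synthetic surveys** — a generator with per-passage availability and
  visibility multipliers emulating disturbance, negative-binomial group
  counts, lognormal sizes and a heard-only channel, so every stage is
  testable against known truth.

## Worked example

```python
from disturbsamp import (SimulationConfig, simulate_survey, summarize_by_passage,
                         corrected_density, true_values)

cfg = SimulationConfig(n_transects=300, availability=(0.5, 0.5, 1.0, 1.0))
ds = simulate_survey(cfg, seed=42)

print(summarize_by_passage(ds)[["passage", "n_transects", "effort_km",
                                "encounter_rate"]].to_string(index=False))
est = corrected_density(ds, sampler_kwargs=dict(seed=42))
print(f"retained: {est.passages}, corrected density "
      f"{est.density:.1f} ind/km^2 (95% CI {est.ci95[0]:.1f}-{est.ci95[1]:.1f}); "
      f"truth {true_values(cfg)['true_individual_density']:.1f}")
```

prints (exactly, for this seed):

```
passage  n_transects  effort_km  encounter_rate
     P1          300      300.0        0.783333
     P2          300      300.0        0.900000
     P3          300      300.0        1.216667
     P4           40       40.0        0.925000
  Total          940      940.0        0.964894
retained: (3, 4), corrected density 128.2 ind/km^2 (95% CI 104.6-157.0); truth 149.1
```

Passages 1–2 (walked on the day the transect was cut) show the depressed
encounter rate the generator planted (availability 0.5 vs 1.0); the
corrected estimator discards P2 as credibly lower, pools P3+P4, and its 95%
interval covers the true density of 149.1 individuals/km².

The same analyses are available from the shell:

```bash
disturbsamp simulate --seed 42 --out data/
disturbsamp summarize --data data/
disturbsamp fit-detection --data data/ --passage 3+4 --truncation quantile:0.95
disturbsamp corrected-density --data data/ --seed 42
disturbsamp run --seed 42 --out run1/        # full report bundle
```

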