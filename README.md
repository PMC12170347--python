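# recensus

Statistical reconstruction of privacy-perturbed census count tables and
small-area disease prevalence estimation, with a synthetic-census module for
fully reproducible end-to-end studies.

## The problem

National statistics agencies release census tabulations through platforms
that perturb every published cell to protect respondents: bounded integer
noise is injected and small counts are suppressed (published as zero). For a
rare condition — such as diabetes among children, with on the order of 1–5
cases per 1000 — the finest-scale tables (statistical areas of a few hundred
people) are almost entirely noise and zeros. But the same platform publishes
the *same* underlying counts aggregated to every coarser level of the nested
statistical geography (SA1-like up to state) and along socioeconomic-decile
and remoteness margins. Because each table is an independently perturbed view
of one latent set of fine-unit counts, the redundancy across levels can be
exploited to reconstruct the fine-scale truth.

`recensus` implements the full pipeline:

1. **Reconstruction.** The latent true case count `y_i` in each fine unit
   and age group is explored by MCMC, with the exact observation likelihood
   `P(published | true)` of the perturbation mechanism evaluated at *every*
   published cell containing the unit (its own, every ancestor level, and
   both covariate margins).
2. **Small-area smoothing.** A blocked Gibbs scheme feeds the latent counts
   back against a geospatial prevalence model: for age groups 0–9 and 15–19,

   `logit p_i = β₀ + β_ses·(decile_i − 5.5) + γ[remoteness_i] + u_i`

   with `u` a zero-mean Gaussian spatial field (exponential covariance
   `σ_u²·exp(−d/ρ)`) and `γ` five sum-to-zero remoteness effects. The 10–14
   group is a logit-scale mixture `η_mid = w·η_young + (1−w)·η_old` with the
   mixing weight `w` learned from the data. Counts are binomial in the
   stated-response denominators.
3. **Reporting.** Per-unit posterior prevalence summaries with a confidence
   classification (higher confidence when posterior sd < 25% of the median),
   national median/IQR per 1000, coarse-level posterior count intervals,
   credible-interval outlier tests against register tables (including the
   censor-below-20 / round-to-ten disclosure rule of community register
   maps), and labelled-count ratio statistics.

Because unit-level extracts of the real data sources (census health item,
hospital diabetes register, community register map) are not redistributable,
the package ships a synthetic-census generator that reproduces their full
structure — three response categories, five-level nesting, covariate
margins, perturbation, register thinning and disclosure control — so every
stage is testable end to end.

## Worked example

```python
import numpy as np
import recensus as rc

# synthetic ground truth: 400 fine units, ~1.8 / 5.2 cases per 1000
cfg = rc.SimConfig(seed=1)
h, truth = rc.simulate_truth(cfg)

# publish every level and margin through the privacy mechanism
pcfg = rc.PerturbConfig()                    # ±2 noise, suppress ≤ 2
tables = rc.publish_tables(h, truth, pcfg, seed=10_001)

# reconstruct: blocked Gibbs, 2 chains x 6000 iterations
samples = rc.run_chain(tables, h, pcfg, rc.PriorSpec(), rc.MCMCConfig(),
                       n_stated=truth.n_stated)

ps = rc.prevalence_summary(samples, kind="model", hierarchy=h)
for prod in ("0-14", "15-19"):
    ns = rc.national_summary(ps, prod)
    lo, hi = ns["iqr_per_1000"]
    print(f"ages {prod}: median {ns['median_per_1000']:.2f} "
          f"[{lo:.2f}-{hi:.2f}] per 1000 across {ns['n_units']} units")

w = samples.stacked_scalar("w")
lo, hi = np.quantile(w, [0.025, 0.975])
print(f"mixing weight w: {np.median(w):.2f} ({lo:.2f}-{hi:.2f})")
```

prints (seed 1):

```
ages 0-14: median 1.53 [1.29-1.80] per 1000 across 400 units
ages 15-19: median 4.26 [3.60-4.98] per 1000 across 400 units
mixing weight w: 0.93 (0.73-1.00)
```

The national medians recover the generative prevalence scale (the truth was
simulated at ~1.8 and ~5.2 per 1000 before covariate effects, which pull the
population-weighted level down), and the mixing weight credible interval
covers its generating value 0.9 — the middle age group behaves almost
entirely like the youngest, as expected when its cases are dominated by the
same disease type. Comparing reconstructed coarse counts with an emulated
near-complete hospital register at the L3 level gives a count-count Pearson
correlation of 0.85 with 1 of 20 units outside its 95% credible interval,
and the reconstruction reduces fine-unit RMSE against the truth from 0.514
(raw published counts) to 0.424 — suppressed-to-zero cells with true cases
are imputed back.

A command line mirrors the library:

```sh
recensus simulate    --config cfg.yaml --out sim/
recensus reconstruct --tables sim/tables.csv --hierarchy sim/hierarchy.csv \
                     --config cfg.yaml --out post/
recensus summarize   --samples post/ --out summary.csv
recensus compare     --samples post/ --hierarchy sim/hierarchy.csv \
                     --register sim/register_hospital.csv --level L3 \
                     --ages 0-9 --out comparison.csv
```

## Layout

| module | contents |
| --- | --- |
| `recensus.hierarchy` | nested areal system, aggregation matrices, external correspondences, CSV/GeoJSON IO |
| `recensus.perturbation` | privacy mechanism forward model, exact observation likelihood, register disclosure rule |
| `recensus.synthetic` | synthetic census generator, table publication, register emulation |
| `recensus.model` | prevalence model: covariance, linear predictors, mixture, joint density |
| `recensus.mcmc` | blocked Gibbs sampler, posterior container, convergence diagnostics |
| `recensus.summaries` | prevalence summaries, national statistics, register comparison, ratio statistics |
| `recensus.cli` | `recensus` command-line entry point |

See `docs/methods.md` for the statistical details and design decisions.
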