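# Methods

## The observation model

A latent integer count `y` (cases in one fine areal unit, age group and
response category) is never published directly. Every published cell —
the unit's own fine-level cell, its ancestors at each coarser level of the
nested geography, and the socioeconomic-decile and remoteness margins — is
an independent draw from the perturbation mechanism:

1. draw integer noise `ε` from a symmetric pmf on `{−d..+d}`;
2. floor at zero: `o' = max(0, y + ε)`;
3. suppress: publish `0` if `o' ≤ τ`, else publish `o'`;
4. true zeros publish as zero deterministically (`zero_fixed`).

The likelihood `P(o | y)` is available in closed form
(`perturbation_loglik`): for `o > τ` it is the noise pmf at `o − y`; the
published value `0` carries the aggregated mass of suppression and
flooring, `P(ε ≤ τ − y)`; values `0 < o ≤ τ` are impossible. Defaults are
`d = 2`, pmf `(0.1, 0.2, 0.4, 0.2, 0.1)`, `τ = 2`, `zero_fixed = true`.
These were chosen to reproduce the two qualitative phenomena of real
perturbed extracts — frequent published zeros hiding small true counts, and
near-exact large counts — and are config-switchable. Cells are perturbed
independently everywhere; real platforms repeat identical perturbations for
identical cells, so independence overstates the information in duplicated
margins slightly. This is a known simplification.

Community register maps use a different disclosure rule, also implemented
exactly (`ndss_censor_round`): counts below 20 are censored, the rest
rounded to the nearest ten, ties half-up (the real tool's tie rule is
undocumented).

## The prevalence model

For the youngest (0–9) and oldest (15–19) age groups separately,

```
logit p_i = β0 + β_ses · (decile_i − 5.5) + γ[rem_i] + u_i
```

- `β_ses` per decile (deciles centred at 5.5); linearity in decile is a
  modelling choice, not a claim about the index.
- `γ`: five remoteness effects constrained to sum to zero, parameterised by
  4 free coordinates.
- `u`: a single spatial field shared by both age models, zero-mean Gaussian
  with exponential (Matérn ν = ½) covariance `σ_u² exp(−d_ij/ρ)` on
  fine-unit centroids, jitter `1e−8·σ_u²` on the diagonal. An exponential
  kernel on centroids keeps the implementation dependency-free at desk
  scale; the kernel is isolated in `gp_covariance` and switchable.
- 10–14 group: logit-scale mixture `η_mid = w·η_young + (1−w)·η_old`,
  `w ∈ (0,1)` learned. Logit-scale mixing keeps `p_mid` between the two
  endpoint models and makes `w` identifiable from counts alone; mixing on
  the probability or model-index level would be alternatives, and the
  choice matters little when `w` is near an endpoint.
- Counts: `y ~ Binomial(n_stated, p)` where `n_stated` is the
  stated-response denominator (respondents who answered the item), not the
  population — prevalence is defined among respondents, and non-response
  bias is explicitly out of model.

Priors (all on the unconstrained scale): `N(0, 2²)` for intercepts, the
socioeconomic slope and each free remoteness coordinate (logit scale is
tight, so these are weakly informative), `N(log 1, 1²)` for `log σ_u`,
`N(log 50 km, 1²)` for `log ρ`, uniform for `w`. These defaults are this
package's own substitutes; they are declared in `PriorSpec` and fully
configurable.

## The sampler

Latent state is fine-level only: every coarser observed cell is a
deterministic sum of fine counts, so aggregation coherence is exact by
construction. One cycle:

1. **Count block.** For each fine unit × age group, a Metropolis proposal
   `y' = y ± k` (`k` geometric, mean `count_proposal_sd`; moves outside
   `[0, n_stated]` rejected). The acceptance ratio combines the
   perturbation likelihood at every published cell containing the unit —
   running aggregates are updated incrementally in integer arithmetic and
   re-verified against a from-scratch recomputation every 1000 sweeps — and
   the binomial model term. Implemented as a numba kernel; infeasible
   states carry a large finite penalty instead of −∞ so a chain started
   outside the likelihood support climbs into it, after which the penalty
   is never paid again and the stationary distribution is exact.
2. **Field block.** Elliptical slice sampling of `u` under its GP prior
   and the binomial likelihood — exact, tuning-free, always terminates.
3. **Scalar block.** Coordinate-wise adaptive random-walk Metropolis on
   `β0_young, β0_old, β_ses`, the 4 free `γ` coordinates, `log σ_u` and
   `logit w` (adaptation toward acceptance 0.44 during burn-in only, so the
   post-burn-in chain is a fixed Markov kernel). Three additional moves
   address directions that centred samplers explore poorly when the data
   are weak:
   - a *location interweaving* move shifting both intercepts by `δ` and the
     field by `−δ` (the field has no sum constraint, so its mean trades off
     against the intercepts along a likelihood ridge);
   - a *scale interweaving* (non-centred) move proposing
     `(σ_u', u·σ_u'/σ_u)` jointly, run 6× per cycle — this removes the
     funnel between the field and its scale;
   - a *whitened range* move proposing `ρ'` while holding the standardised
     innovations `L(ρ)⁻¹u/σ_u` fixed — in centred form the 400-dimensional
     field pins the conditional posterior of `ρ` and a plain random walk
     barely moves.

   All are standard Metropolis–Hastings moves leaving the posterior
   invariant. Without them, split-R̂ for the intercepts and field
   hyperparameters sat between 1.2 and 1.6 at the default chain length;
   with them the default run reaches R̂ ≤ 1.02 with effective sample sizes
   of a few hundred for the regression parameters.

Defaults: 2 chains × 6000 iterations, 2000 burn-in, thinning 4 (1000 stored
draws per chain), seed 20210810. Denominators are treated as known — taken
from the synthetic truth in simulation studies, or derived as published
positives + negatives at the fine level otherwise; their relative
perturbation is negligible at denominator scale, so they are not jointly
reconstructed. Convergence diagnostics (rank-normalised split-R̂ and bulk
ESS, computed via arviz) are exposed through `diagnostics`.

## The synthetic census

`simulate_truth` draws a complete ground truth that mirrors the fitted
model: fine-unit centroids uniform on a square (default 500 km side, planar
coordinates, no geodesy), spatially contiguous nesting built by recursive
axis splits (400 fine units → 100 → 20 → 4 → 1 by default), covariates
assigned block-wise at the L3 level — remoteness ordered by distance from
the "urban" corner with block counts allocated 40/25/20/10/5% by largest
remainder so no category is empty (empty factor levels would make the
sum-to-zero decomposition unidentifiable in a way real national data never
is), deciles uniform per block with ±1 unit jitter — the field drawn from
the exponential-covariance GP, and populations 30–120 per age group per
unit, consistent with fine statistical areas of a few hundred residents
split across childhood ages. Stated-response rates are uniform on
(0.88, 0.95) per unit, matching the observed ~92% response to a census
health item; not-stated counts are published as a third category.
Generative defaults put prevalence near 1.8 per 1000 (ages 0–9) and 5.2 per
1000 (ages 15–19) — the scale of juvenile diabetes — with `β_ses = −0.05`
per decile (disadvantage increases risk), remoteness effects
`(−0.2, −0.1, 0, 0.1, 0.2)` increasing with remoteness, `σ_u = 0.3`,
`ρ = 50 km`, and mixing weight 0.9.

Register emulation: a hospital-style register is binomial thinning of true
counts at capture 0.999 per L3 unit (ages 0–9, 10–14); a community-style
register thins at capture 0.85, aggregates to a synthetic external
partition (bands cutting across the hierarchy, as administrative areas cut
across statistical ones, whole-unit assignment only) and applies the
censor/round rule for ages 0–9 and 10–19.

What the generator does **not** emulate: deterministic repeated
perturbation of identical cells, cross-border double registration,
population-weighted correspondence splitting, age-varying response rates,
and any real geography. Passing tests therefore demonstrate correctness of
the algorithms under the stated generative assumptions, not fidelity to any
particular country's data.

## What the studies show

With ten replicates at the default scale (seeds 1–10, one ~60 s run each):

- 95% credible intervals cover the generating intercept, socioeconomic
  slope, field scale and mixing weight in at least 8 of 10 replicates, and
  the posterior medians of `w` centre on the generating 0.9.
- The posterior median fine-count reconstruction has lower RMSE against the
  truth than the raw published tables in ≥9 of 10 replicates, and cells
  published as zero with two or more true cases are imputed back to ≥1 —
  the signature of borrowing strength across levels.
- Pooled per-unit 95% credible intervals for true prevalence are
  approximately calibrated (coverage ~0.95).
- Single-cell stationary distributions match brute-force enumeration
  posteriors to total variation < 0.02 over 10⁵ sweeps.

## Numerical and reporting choices

- Quantiles everywhere are linear interpolation of order statistics.
- Coarse-count credible intervals are reported as
  `[floor(q2.5), ceil(q97.5)]`; display medians round to integers.
- The confidence classification (`higher` iff posterior sd < 0.25 ×
  posterior median) is scale-invariant.
- `prevalence_summary` offers two prevalence definitions: the realised
  count ratio `Σy/Σn` per draw (`kind="count"`, used for calibration
  checks against realised truth), and the model surface `expit(η)`
  (`kind="model"`, used for maps and national summaries — at small-area
  scale the count ratio is degenerate at 0 for most units because expected
  cases per unit are < 1). National headline figures use the per-unit
  posterior medians of the model surface; per-unit posterior means are also
  emitted for mapping.
- Register CrI outlier tests compare against the register value *as
  printed* (censored/rounded), since that is what a reader of the public
  map would test; suppressed entries are never flagged.
- Pearson correlations in register comparisons are on raw counts, not
  rates.
- Degenerate inputs: zero denominators flag the unit and exclude it from
  national summaries; constant chains are flagged in diagnostics rather
  than reported numerically.

## Known limitations

- Independence of perturbations across published cells overstates the
  information content of duplicated margins (conservative for privacy,
  mildly optimistic for reconstruction accuracy).
- Denominators are conditioned on, not reconstructed.
- The mixture level (logit vs probability vs model-index) is a convention;
  only the logit form is implemented.
- Hyperparameter posteriors (`σ_u`, `ρ`) remain weakly identified at the
  default data scale; their effective sample sizes are an order of
  magnitude below the regression parameters', and occasional replicates
  show split-R̂ up to ~1.1 for them at the default chain length. Longer
  chains sharpen this; the regression-level conclusions are insensitive.
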