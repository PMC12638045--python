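# Methods

## The model

`bayescount` fits a partially pooled count regression to tables of labelled
cell counts indexed by brain region, experimental group, animal and
(optionally) hemisphere. Counts are modelled as Poisson draws whose log
rate decomposes into a fixed effect θ_{r,g} (region × group mean log
count), a per-observation random effect γ_i, and an exposure offset
E_i = log(area_i) so that rates scale with the recorded section area. The
random effects are zero-mean Gaussian with a region × group scale τ_{r,g},
which is what produces partial pooling: the data estimate τ, and τ in turn
determines how strongly individual observations are shrunk toward their
group mean. The model is deliberately over-parameterised (θ and γ jointly
determine the rate); the hierarchical prior on γ is what identifies the
decomposition.

Assumptions worth stating plainly:

- counts are conditionally independent given the rates — no spatial or
  between-region correlation is modelled (a multivariate random effect is a
  known extension but out of scope here);
- animal-level structure is expressed through one random effect per
  *observation*, so in a two-hemisphere design the two samples from one
  animal get independent effects. Sharing a γ across hemispheres of an
  animal is a defensible alternative; it is not implemented;
- areas are measured without error; a missing `area` column degrades
  gracefully to exposure 0 with a logged warning.

### Robustness variants

Two mechanisms handle data that violate the plain Poisson/normal model:

- **Horseshoe random-effect prior.** Each γ_i gets a local scale multiplier
  κ_i ~ HalfNormal(1), so surprising observations can escape shrinkage
  while the bulk remains regularised. A half-normal local scale is used
  rather than the traditional half-Cauchy: the Cauchy tail is heavy enough
  to stall gradient-based samplers, and the half-normal keeps the
  qualitative local-global behaviour.
- **Zero-inflated Poisson likelihood.** With probability π a count is an
  anomalous zero (e.g. a failed registration), otherwise Poisson. The
  Bernoulli indicator is marginalised out analytically, so the sampled
  posterior has only continuous parameters. Zero inflation can only add
  mass at zero; a hurdle model (which can also remove it) is intentionally
  not provided.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `s` | τ hyperprior scale is log(s) | 1.05 | places 95% of the τ prior below log 1.1, i.e. ~10% within-group variation at the upper end — moderately informative, and a real aid when animals are few |
| `theta_prior_location` | centre of the Normal prior on each θ | data-derived: log of the dataset-wide mean count per unit area | keeps the prior weakly informative on the right scale without user input |
| `theta_prior_scale` | sd of the θ prior (log scale) | 5 | ~e^±10 around the centre at 2 sd: dominated by any data |
| `pi_prior` | Beta prior on π (ZIP only) | (1, 1) | uniform; π is well identified whenever rates are not tiny |
| `use_exposure` | include E_i | true | set false only if areas are meaningless for the dataset |

The θ and π priors are this package's own choices — the model family does
not dictate them — and both are exposed in `ModelConfig`.

## Sampling

The sampler is a self-contained No-U-Turn sampler (NUTS): multinomial
sampling over the trajectory with biased progressive weighting, a
generalised U-turn criterion, dual-averaging step-size adaptation toward a
0.8 acceptance target, and a diagonal metric estimated over expanding
warm-up windows (75/25·2^k/50 for long warm-ups, proportional for short
ones). Gradients of the unconstrained log posterior are analytic.

Transformations: τ and κ are sampled as logs, π on the logit scale, each
with its Jacobian; γ is non-centred (γ_i = τ·κ·z_i with z_i ~ Normal(0,1)),
which removes the funnel that makes centred hierarchical models diverge
when τ approaches zero. A transition whose energy error exceeds 1000 is
recorded as divergent; divergences are always reported, never dropped, and
if they exceed 1% of retained draws the fit is repeated once at a 0.95
acceptance target with a logged notice. The default schedule is 4 chains ×
8000 iterations with the first half as warm-up, i.e. 16,000 retained
draws. Split R-hat and bulk ESS come from arviz; R-hat > 1.01 is flagged.

Chain seeds are spawned from a single `SamplerConfig.seed`, so a fixed seed
and dataset reproduce draws exactly.

## Summaries

- **HDI**: among all contiguous windows of ⌈prob·n⌉ sorted draws, the
  narrowest; ties (possible only for discrete or degenerate samples) break
  toward the lowest lower bound.
- **log₂ fold change**: per-draw (θ_{r,g1} − θ_{r,g2})/ln 2. Derived from θ
  alone rather than posterior-predictive counts: the contrast of interest
  is the population-level rate ratio, and exposures and random effects
  cancel by construction.
- **Welch comparator**: an uncorrected Welch's t-test on per-sample
  log₂(count/area + 0.5). The pseudo-count keeps zeros defined and is
  applied *only* to the comparator, never to the Bayesian model; both the
  transform and the pseudo-count are configurable. No multiple-testing
  correction is applied anywhere — this mirrors the comparator the package
  is meant to be set against, and is not a recommendation.
- **Pooling profile**: E[exp(γ_i) | θ, τ, y_i] on a τ grid, by adaptive
  quadrature of the unnormalised conditional density (nested over κ in
  horseshoe mode). The integrand can be a very narrow spike when either
  scale is small, so the implementation locates the mode by grid
  refinement, estimates the peak width from the log-density drop, and
  integrates peak and tails separately. Intended at demonstration scale
  (a handful of observations), not for large tables.

## The synthetic-data generator

`synthetic_data.simulate` draws from exactly the generative process above:
γ from its normal, areas uniform over a range, Poisson counts, then
optional multiplicative rate outliers (applied before the Poisson draw)
and anomalous-zero overwrites (applied after, matching ZIP mixture
semantics). Two presets emulate the case-study shapes: 23 regions ×
4 groups × 10 animals (920 rows, counts in the low hundreds, a ~×1.4
elevation in the sham-novel group) and 50 regions × (3 + 2) animals ×
2 hemispheres (500 rows, KO at ~×0.45 of HET, 6% anomalous zeros). The
uniform area distribution and the multiplicative outlier mechanism are this
package's constructions — real data only warrant "areas differ" and
"outliers occur".

What the generator does **not** emulate: between-region correlation,
spatial structure within regions, heavy-tailed animal effects, or
systematic area/count confounding. Passing recovery tests therefore show
the machinery is correct under the stated model, not that the model suits
any particular real dataset.

## Verification strategy and problem sizes

Every numerical component is checked against an independent oracle: the
HDI against exhaustive window enumeration, Welch's test against separately
coded textbook formulas, the pooling quadrature against dense Riemann
sums, and the sampler against 1-D deterministic quadrature of the same
unnormalised density in a single-cell configuration with a near-degenerate
τ prior. Coverage calibration runs three replicate fits at the 920-row
case-study scale with shortened chains (2 × 1600 iterations), scoring 276
θ HDIs against a binomial test at 0.95; the replicates draw their τ truth
from the fitting hyperprior, the condition under which credible-interval
coverage is exact by construction. These sizes keep the whole suite at a
few minutes while leaving the checks statistically meaningful.

## Known limitations

- The sampler is single-process; chains run sequentially.
- R-hat/ESS are computed on all parameters including the per-observation
  γ and κ, which is conservative but slow for very large tables.
- `pooling_profile` is O(quadrature) per (τ, observation) pair and is a
  demonstration tool, not a bulk routine.
- Fold-change contrasts assume both groups were fitted in one model; there
  is no cross-model contrast machinery.
- The Welch comparator's transform (log₂ of area-normalised counts with a
  0.5 pseudo-count) is one defensible choice among several; conclusions
  sensitive to it should be checked against alternatives.
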