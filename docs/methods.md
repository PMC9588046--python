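# Methods

This note documents the models, the synthetic world, the estimation
procedures, and the numerical choices behind `contextchoice`, in the order
data flows through the pipeline.

## 1. Value, choice and rating models

**Divisive normalization.** An option displaying rating `r_i` inside a set
with displayed ratings `{r_j}` has value

    v_i = r_i / (sigma + omega * sum_j r_j)

with semi-saturation `sigma > 0` (stars) and context weight `omega >= 0`
(unitless). At `omega = 0` values are proportional to ratings and a softmax
chooser satisfies IIA exactly; for `omega > 0` richer contexts compress
value differences, producing both the negative mean-set effect on
ratings-maximizing choice and the negative distractor effect in the
top-two analysis. Choices are softmax with temperature `tau > 0`,
computed with max-subtraction for overflow safety.

A comparative-statics fact that matters for interpretation: the *measured*
logistic mean-set slope is non-monotone in `omega`. Its magnitude grows
while `omega * sum_j r_j < sigma` (the unsaturated regime) and shrinks
beyond that point, because further context weight mostly flattens choice
overall. The field-data default (`sigma = 1`, `omega = 0.5`) sits deep in
the saturated regime — the context effect is strong but extra `omega`
weakens its measured slope.

**Prediction-error ratings.** Experienced utility is a symmetric draw
centred on the chosen option's unrounded running mean,
`u ~ Normal(prior_mean, sigma_u^2)`; the contextual expectation is
`E = prior_mean − kappa * (context_mean − 3)`, anchored at the scale
midpoint 3 so that `kappa` (stars per star) is directly the deviation
slope; the emitted rating is `u − (E − prior_mean)`, clamped to [1, 5] and
rounded half-away-from-zero to whole stars when `discretize` is on.
Clamping attenuates the measured slope near the scale bounds but never
flips its sign (property-tested on a grid).

## 2. The synthetic world

Cities hold Gaussian spatial clusters of restaurants. Each
(cluster, category) scene draws its own quality offset
`Normal(0, cluster_quality_sd)`; restaurant latent qualities are truncated
normal around `quality_mean + offset` on [1, 5]. Defaults (one decision
about each, made once):

| parameter | default | why |
|---|---|---|
| clusters_per_city | 300 | ~900 independent sets, so binned statistics are composition-stable |
| set size (range) | 3–7 | the observed range of per-category neighborhood sets |
| quality_mean / sd | 3.6 / 0.6 | centres set means near 3.6 with realistic spread across the 1–5 scale |
| cluster_quality_sd | 0.6 | set means span roughly 2.5–4.6, populating all four analysis bins |
| seed reviews per restaurant | Uniform(5, 60) | review-count dispersion is what lets small-n restaurants display 1.0 or 5.0; with a constant count the display lattice saturates at 4.5 and tied maxima dominate high-mean sets |
| sigma_u | 0.5 | half-star experience noise; also keeps near-ceiling restaurants able to display 5.0, which removes a rounding artifact (a tie-at-4.5 bump in the 4.0–4.2 set-mean range) |
| sigma, omega, tau | 1, 0.5, 0.05 | a strong, clearly detectable context effect with ~60–70% target-choice rates |
| kappa | 0.4 | a rating-deviation slope comfortably above estimation noise at ~10^4 events |

Review timestamps are unique integers (a strict total order is required
for "reviews up to the point of that review"); review text is a bag of
lowercase category-term tokens in which the true category is 3x as salient
as the other assigned terms — only term counts are consumed downstream.

The stream simulators are pure functions of (world, config, seed). The
review stream updates running means online (each choice sees the state
excluding the review it emits); the check-in stream reuses the choice
mechanism on a static state without user identities; the order stream uses
static per-restaurant displays keyed by city-wide (city, cuisine) sets.

What the generator does *not* emulate: natural language, review filtering,
social effects, multi-category consideration, geographic realism beyond
Gaussian blobs, and non-stationary user tastes. Passing tests therefore
show the pipeline recovers the mechanisms it models, not that real data
contain them.

### Null-world temperature

IIA-null worlds (`omega = 0`) use `tau = 0.5`: with normalization off,
values are raw stars (gaps ~0.5) rather than normalized values (gaps
~0.05), so the temperature scales up by the same factor to keep choice
stochasticity comparable; at the default `tau` the null world's choices are
deterministic and the top-two response degenerates.

### Rating-slope recovery world

`kappa` recovery uses a continuous-rating world with mid-range qualities
(`quality_mean = 3.0`, sds 0.4, `sigma_u = 0.4`): the closed-form deviation
slope holds exactly only away from the [1, 5] clamp, so the recovery
conditions keep ratings interior. At 50k events the fitted slope lands
within a few percent of 0.4 and a `kappa = 0` world's CI covers zero.

## 3. Choice-set reconstruction

**Category inference** counts case-insensitive whole-word (phrase for
multi-word terms) occurrences of each assigned term in the restaurant's
review texts; the umbrella term "Restaurants" identifies restaurants but
never competes. Ties break by count, then assigned-term order, then
lexicographically; empty text falls back to the first term with a logged
warning; no non-umbrella terms is a distinct, fatal-per-business error.

**DBSCAN** is implemented from the classic definitions (Euclidean distance
in decimal degrees, core iff >= min_pts total weight within eps including
self, border points joining the first discovering cluster under a fixed
index order) and validated against a brute-force O(n^2) reference on
random instances. Clustering input is one point per review; identical
coordinates are collapsed to unique points with per-restaurant review
weights, which is exactly equivalent and much faster.

**Tuning** sets `eps` to the median (configurable quantile) 4-th
nearest-neighbor distance of the city's restaurant coordinates and
`min_pts` to `max(3, round(fraction * review_points))` with fraction
0.001 — about three typical restaurants' review mass, a density threshold
that recovers ~10 restaurants per cluster on the default world (the
calibration band is 8–15).

**Filters:** review-based decisions require >= 100 reviews by the user,
the user's most-reviewed city, a set of >= 3 restaurants, and >= 3 unique
displayed ratings at decision time; check-ins apply the set-level rules
only; orders require (city, cuisine) sets of >= 5 restaurants. Every
exclusion is tallied by reason and kept + excluded = total per source.

## 4. Context measures

Displayed ratings are prefix means strictly before the decision instant,
excluding the focal review, rounded to the nearest half star (midpoints
round up; set-level statistics use the rounded values deciders saw, while
the rating deviation uses the unrounded prior mean, which is about the
option's running value rather than its display). Set variance is the
population variance — the set is the whole context, not a sample. `gap12`
removes one instance of the maximum (tied maxima give 0); the distractor
mean averages everything below the top two order statistics.

**Distractor (IIA) analysis.** Only choices of a top-two option in sets of
>= 3 enter. Two measurement details follow from what an IIA chooser
implies: records with a *tied maximum* are dropped (any top-two choice
there is ratings-maximizing by definition, so the top-vs-second response
is uninformative), and the model controls `gap12` and `log(k2)` (options
tied at the second-highest rating) because the null top-vs-second log-odds
are exactly `gap/tau − log(k2)` and both correlate with the distractor
mean across sets. With these controls the `omega = 0` null's 95% CI covers
zero in ~96% of replicate worlds; without them the null is biased.

## 5. Inference

All analysis models take every fixed effect as a per-user random effect.
Two paths share one output schema (estimate, 95% CI, two-sided tail
probability per term, per-user conditional coefficients, diagnostics):

- **fast** (default): pooled ML via statsmodels (OLS / binomial GLM) with
  cluster-robust standard errors by user; per-user effects via a one-step
  empirical-Bayes update — a penalized Newton step from the pooled fit per
  user, shrunk elementwise by `tau^2 / (tau^2 + V)` with `tau^2` the
  method-of-moments between-user variance. For Gaussian responses the
  sampling variances use the *within*-user residual variance (the pooled
  residual is inflated by between-user heterogeneity). `tau^2` is floored
  at 2% of the mean sampling variance so that weak heterogeneity shrinks
  hard but never collapses every subject to the same value, which would
  leave downstream individual-difference analyses degenerate.
- **mcmc**: a Gibbs / Metropolis-within-Gibbs sampler for the full
  random-slopes hierarchy `beta_u ~ Normal(mu, diag(tau^2))` with
  Normal(0, 10^2) priors on standardized fixed effects and half-Normal(5)
  priors on random-effect SDs. Gaussian responses use conjugate updates
  with `mu` drawn from its *collapsed* conditional (random effects
  integrated out via Woodbury), which removes the centered-parametrization
  funnel; logistic user blocks use random-walk Metropolis preconditioned
  by local curvature; `tau` uses an adaptive log-scale random walk floored
  at 1e-3. Split-R-hat and ESS come from arviz; fits with R-hat > 1.05 are
  flagged, not silently returned. Logistic separation falls back to a
  lightly ridge-penalized Newton fit with a warning.

Predictors are standardized internally and coefficients reported on the
input scale. Counts are log-transformed, text lengths log(1+x). Check-in
and order analyses fit pooled models (their records carry no usable user
identity at set level). Constant predictors are dropped with a warning
rather than failing, since small or degenerate worlds can produce them.

**Concordance (experiment).** Subject-level choice-context effects
(conditional per-participant `mean_set` coefficients) are median-split and
robust-regressed (Huber IRLS) against subject-level expectation-rating
context effects; the slope's two-sided p-value and CI come from a
case-resampling bootstrap (1000 draws).

## 6. The laboratory-experiment emulation and its limits

Each simulated participant completes 275 trials (135 choice, 135 rating, 5
catch) on snapshots drawn from the world's eligible sets. Participants draw
`(omega_p, c_p)` from a bivariate normal with configurable SDs and
correlation; `c_p` is the expectation slope on the 0–100 satisfaction
scale (`satisfaction = 10 + 15 * r_highlighted − c_p * mean(others) +
Normal(0, 6)`, clipped to [0, 100]). Catch trials (pick the top-rated
option) are answered correctly except with the configured lapse
probability; participants below 60% catch accuracy are excluded.

Experiment choices use their own value sensitivity
(`sigma = 6`, `tau = 0.025`, `omega_p ~ Normal(0.2, 0.1)` clipped at 0):
this places the whole participant population in the unsaturated
normalization regime, where a larger context weight strengthens the
measured context effect — the direction the contextual account describes
— and yields target rates (~85%) above the field data's, as hypothetical
choices on explicit displays tend to be.

**Known limitation.** With 135 binary choice trials the per-participant
sampling sd of the standardized mean-set slope is >= 0.2, while the slope
heterogeneity any setting of the divisive-normalization mechanism can
produce across participants is bounded near 0.1 (sharper temperatures
raise slope magnitudes but push choices toward determinism and destroy
binary information). Subject-level choice effects therefore have
reliability well under 0.2, and the choice–rating concordance — though
positive in expectation under positively correlated mechanisms — is
noise-dominated at 100 participants: its sign is unstable across seeds and
its bootstrap p rarely reaches 0.05. The group-level effects (negative
choice context effect, negative expectation-rating context effect) are
large and stable; only the individual-difference correlation is
underpowered by design of the trial budget. The corresponding acceptance
test asserts the idealized property and is expected to fail; it is kept
rather than weakened.

## 7. Problem sizes and determinism

Default analyses run one city with ~4,500 restaurants, ~150k seed reviews,
200 users × 100 decisions (~20k events, ~8k eligible after filters), and a
100-participant experiment; recovery runs use 500 users (~50k events);
replicate-world batteries use 50 small worlds (60 users × 50 events). All
randomness in a run descends from one master seed, and repeated runs with
the same configuration are bit-identical on the fast path.
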