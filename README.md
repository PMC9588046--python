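# contextchoice

Context-dependent choice and valuation analysis for consumer review
streams, with a synthetic ground-truth world for validating every stage.

## The problem

When people pick a restaurant, the value of an option appears to depend on
the other options around it — the *context*. Two behavioral signatures of
this are (1) **choice context effects**: deciders pick the highest-rated
option less often when the whole choice set is highly rated, violating the
independence of irrelevant alternatives (IIA) that a plain logit chooser
would satisfy; and (2) **valuation context effects**: the star rating a
person leaves after visiting diverges from the restaurant's running mean in
proportion to how good the surrounding options were, as if the rating were
a prediction error against a contextually lowered expectation.

`contextchoice` is for researchers who want to measure these effects in
large review streams (Yelp-Open-Dataset-style JSON Lines, check-in records,
delivery-order CSVs) or in laboratory choice/rating experiments. Because the
real datasets are proprietary, the package ships a first-class synthetic
world generator with controllable context dependence, so every pipeline
stage is testable end to end against known ground truth.

## The model

Options are displayed as half-star-rounded running means `r_i`. Choices are
drawn from a softmax over divisively normalized values

    v_i = r_i / (sigma + omega * sum_j r_j),        p_i ∝ exp(v_i / tau)

where `omega >= 0` is the context weight (`omega = 0` recovers a plain
logit and exact IIA) and `sigma > 0` is the semi-saturation constant.
Post-choice ratings follow a prediction-error rule

    rating = Normal(prior_mean, sigma_u) + kappa * (context_mean − 3)

so `kappa` is exactly the slope of the rating deviation (user stars minus
the chosen option's unrounded prior mean) on the set mean excluding the
chosen option.

The analysis side reconstructs choice sets as (spatial cluster × primary
category) partitions — a self-implemented DBSCAN over review-weighted
coordinates plus frequency-based category inference from review text —
computes each decision's displayed-rating snapshot ("reviews up to, but not
including, the focal review"), derives the context statistics, and fits
per-user random-effects regressions (cluster-robust fast path, or a
self-contained Gibbs/Metropolis MCMC path).

## Worked example

```python
from contextchoice.cli_io import RunConfig, run_pipeline
from contextchoice.synthetic_world import WorldConfig

report = run_pipeline(RunConfig(world=WorldConfig(), seed=1))
print(report.fits["choice_context"]["terms"]["mean_set"])
print(report.binned["ratings_by_set_mean"]["target_rate"])
print(report.clustering["mean_cluster_occupancy"])
```

prints (seed 1):

```
{'estimate': -0.3739, 'ci_low': -0.4585, 'ci_high': -0.2893, 'tail_prob': 4.7e-18}
[0.7379, 0.6405, 0.6291, 0.5892]
10.43
```

The mean-set coefficient is the choice context effect: each extra star of
set mean lowers the log-odds of a ratings-maximizing ("target") choice by
0.37 — negative and clearly bounded away from zero, as the generator's
`omega = 0.5` implies. The binned target rates fall monotonically across
the four set-mean bins (≤3, 3–3.5, 3.5–4, >4 stars). Tuned density
clustering recovers neighborhoods of about 10 restaurants each, and the
same run also produces the distractor (IIA-violation) fit, the rating
deviation fit, and an emulated 275-trial choice/rating experiment.

The same pipeline runs from the shell:

```bash
contextchoice simulate --preset default --seed 7 --out runs/7
contextchoice build-sets --businesses runs/7/businesses.jsonl \
    --reviews runs/7/reviews.jsonl --out runs/7/sets.tsv
contextchoice analyze --preset default --seed 7 --out runs/7
```

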