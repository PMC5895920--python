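# adaudit

Placebo-controlled analysis of advertising-audience estimates against
regional health statistics.

Advertising platforms expose *reach estimates*: the number of monthly
active users matching a targeting selection — a geography, demographic
constraints, and a conjunction of interests — reported rounded to a
granularity (±20 users) for k-anonymity. Aggregate counts of users
interested in, say, *Diabetic diet* vary across US states in ways that can
track real disease prevalence, which makes them tempting as a cheap
surveillance signal for conditions like diabetes, obesity, food
sensitivities or alcoholism. They are also confounded: states differ in
platform adoption and engagement, so *any* popular interest — reading,
music, technology — correlates with health outcomes through latent factors
that have nothing to do with the condition.

`adaudit` implements the audit methodology for this setting:

* **Normalization.** A raw count becomes a share against one of three
  reference populations: all platform users (`FB_pop`), users interested in
  the platform itself (`FB_int`), or users holding a broad health baseline
  interest (`FW_int`).
* **Correlation screen.** For each index *f* (an interest under a
  normalization) and health index *h* (a condition prevalence), the Pearson
  coefficient *r<sub>fh</sub>* across the 50 states, with the two-tailed
  significance from *t = r·√(n−2)/√(1−r²)* on *n−2* df, and a Bonferroni
  family-wise threshold *α/k* where *k* counts the hypotheses tested.
* **Placebo envelope.** Each condition's *placebo interests* — popular
  generic interests with no plausible causal link — establish the
  background correlation level; a *marker interest* is only flagged as
  interesting if its |r| exceeds the placebo envelope max<sub>placebo</sub>|r|.
* **Lift.** For two selections A, B with counts N<sub>A</sub>,
  N<sub>B</sub>, N<sub>AB</sub> over a base population N<sub>pop</sub>,
  lift(A,B) = P(A∩B)/(P(A)·P(B)) = N<sub>AB</sub>·N<sub>pop</sub>/(N<sub>A</sub>·N<sub>B</sub>),
  the multiplicative deviation from independence (1 = independent).
* **Regression.** OLS models of prevalence from interest shares (plus
  optional control covariates), selected by backward elimination minimizing
  the least-squares AIC *n·ln(RSS/n) + 2(p+1)*, reported with adjusted R².
* **Synthetic world.** The original per-state audience snapshot was never
  deposited, so the package ships a generative stand-in: state-level latent
  health (*z*) and engagement (*u*) factors with correlation ρ, logistic
  prevalence and interest-propensity models, a planted pairwise lift matrix
  with feasibility capping, and granularity rounding on every emitted
  count. It answers queries exactly like a stored snapshot, so the whole
  pipeline runs unchanged on data with known ground truth.

## Worked example

The packaged snapshot carries the published September-2016 US-wide audience
totals (granularity 20):

```python
>>> import adaudit as ad
>>> snap = ad.us_audience_2016()
>>> us = ad.AudienceQuery(geography="US")
>>> snap.audience(us)                                    # all US adults on the platform
194000000
>>> snap.audience(us.with_interests(["Plus-size clothing"]))
9100000
>>> ad.normalized_share(snap, "Facebook", "US")          # FB_int reference as a share of FB_pop
0.42783505154639173
```

Running the screen on a synthetic world with an engagement–health
confounder (ρ = 0.7) reproduces the placebo phenomenon — the generic
placebo correlates almost as strongly as the condition marker:

```python
>>> from adaudit.world import confounded_world_config, generate_world
>>> world = generate_world(confounded_world_config(rho=0.7, seed=1))
>>> res = ad.InterestPrevalenceScreen(world, world.taxonomy, world.health_table).fit()
>>> print(res.summary())
Interest-prevalence correlation screen
  regions per record: n = 50
  hypotheses tested:  k = 2
  Bonferroni threshold: p < 2.50e-02 (alpha = 0.05)

normalization                         FB_pop
condition role    interest
diabetes  marker  diabetic diet  .52 (<.001)
          placebo technology     .46 (<.001)

placebo envelope [diabetes / FB_pop]: max placebo |r| = 0.464
  marker 'diabetic diet': r = +0.525 (p = <.001) — exceeds placebo envelope
```

The marker here was planted at a population correlation of 0.40 and the
placebo loads only the engagement factor — yet the placebo attains r = .46
purely through the ρ = 0.7 confound. This is why marker correlations must
be judged against the placebo envelope, not against zero.

Backward-AIC regression on a marker-recovery world:

```python
>>> from adaudit.world import marker_recovery_config
>>> w = generate_world(marker_recovery_config(seed=1))
>>> fit = ad.PrevalenceRegression.from_provider(
...     w, w.taxonomy, w.health_table, "obesity").fit(method="backward")
>>> print(fit.summary())
OLS prevalence model: obesity ~ 2 feature(s), n = 50
  R^2 = 0.5391   adj. R^2 = 0.5195   AIC = -376.707
  ...
```

## Command line

```bash
adaudit simulate  -c config.yml                 # materialize a synthetic universe
adaudit correlate -c config.yml --normalization FB_pop,FB_int,FW_int
adaudit lift      -c config.yml --top-k 20
adaudit regress   -c config.yml --standardize
adaudit report    -c config.yml                 # all of the above
```

The YAML config names either a `snapshot` (JSON Lines audience dump, plus
`health` CSV and `taxonomy` JSON) or a `simulation` block (a world
specification). Logs go to stderr, results to `output_dir`. Exit codes:
0 ok, 2 usage/config problem, 3 data problem.

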