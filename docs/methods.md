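# Methods

## The audit problem

The package relates two kinds of regional aggregates. On one side are
advertising *reach estimates*: counts of platform users matching a
targeting selection (geography × gender × age bracket × ethnic affinity ×
an interest conjunction), reported rounded to a granularity *g* (default
20) so that no query can isolate fewer than *g* individuals. On the other
side are public-health statistics: per-state prevalence fractions for
conditions such as diabetes, obesity, food sensitivities and alcoholism.
The methodological point is confound control: platform adoption and
engagement vary regionally, so interest audiences correlate with health
outcomes even when the interest has no causal tie to the condition.
*Placebo interests* estimate that background level empirically, and marker
correlations are judged against the resulting envelope.

## Statistical machinery

**Shares.** An interest count in a cell (geography, demographics) is
divided by a reference count in the same cell: all users (`FB_pop`), users
interested in the platform (`FB_int`), or users with the broad
fitness-and-wellness baseline interest (`FW_int`). Shares may exceed 1 by
rounding slack; they are flagged in the log, never clipped, because
clipping would bias correlations computed downstream.

**Correlation screen.** Pearson r between the share vector and the
prevalence vector across regions (the District of Columbia is excluded by
default), two-tailed p from the exact t transform
`t = r·sqrt(n−2)/sqrt(1−r²)` with n−2 degrees of freedom. Display tiers
use exclusive bounds (p < .001, < .01, < .05, else ns); renderers print p
to 3 decimals below .01 and 2 otherwise. The Bonferroni factor k counts
every (interest, condition, normalization) triple actually tested —
normalizations multiply k — and can be overridden when a different
hypothesis accounting is wanted. A constant share vector makes r undefined;
such a cell aborts only its own record (with a logged warning naming the
interest), while a zero reference count is treated as a data error and
propagates with the cell identified.

**Placebo envelope.** Per (condition, normalization): the maximum |r| over
placebo records. Markers are annotated with `exceeds_placebo = |r| >
envelope`; baseline interests are reported separately since they measure
general health awareness, not background engagement.

**Lift.** `lift(A,B) = N_AB · N_pop / (N_A · N_B)` with all four counts
taken from the same base population (default: US-wide, unconstrained).
When B is a demographic restriction, N_B is the base audience inside that
slice and N_AB the A-audience inside it. A joint count exceeding a marginal
by more than one granularity step is an inconsistency error; joint counts
within rounding slack are tolerated. Records whose smallest count is below
2g carry a low-precision flag instead of being suppressed, because
suppression would silently bias ranked tables. Ranking is a stable sort
with lexicographic (A, B) tie-breaks.

**Regression.** OLS via least squares with an explicit intercept. The
information criterion is the least-squares AIC `n·ln(RSS/n) + 2(p+1)` with
the additive likelihood constant dropped (it cancels in comparisons at
fixed n); RSS is floored at 1e−12 so perfect fits yield a finite score.
Backward elimination removes, one feature at a time, the feature whose
removal gives the lowest AIC, only while that AIC strictly improves on the
current model's; equal-AIC removals do not fire, removed features never
re-enter, and ties between candidate removals break lexicographically, so
the procedure is deterministic given the design. Features are used
unstandardized by default with an opt-in standardize flag (z-scoring); OLS
fits are invariant to this up to coefficient scaling, and elimination
order is unaffected because AIC depends only on RSS.

## The synthetic world

No per-state audience snapshot is publicly deposited, so the simulator is
the test bed. Its generative model:

* State factors: health `z_s ~ N(0,1)`; engagement
  `u_s = ρ·z_s + sqrt(1−ρ²)·ξ_s`. ρ is the confounding channel.
* Prevalence: `h_cs = expit(μ_c + β_c·z_s + σ_c·ε_cs)`.
* Interest propensity per demographic segment:
  `p_is = expit(θ_i + offset_seg + λ_i·z_s + κ_i·u_s + τ_i·e_is)`, with
  λ the marker loading, κ the engagement loading, and τ idiosyncratic
  state-level noise.
* Pairs: `P(A∩B) = min(ω_AB·p_A·p_B, min(p_A,p_B))` — a planted lift with
  feasibility capping. Conjunctions of three or more interests are outside
  generative scope and error out; no analysis stage needs them.
* Counts are exact expectations (population × adoption × segment share ×
  propensity) rounded to the granularity — sampling noise is deliberately
  omitted so that planted parameters have closed-form observable
  consequences, which keeps oracle checks exact.

Demographic segments are the 2×4×4 grid of gender × age bracket × ethnic
affinity with uniform shares by default; no attempt is made to mimic real
US demographics, which the property tests do not need. Randomness uses one
root seed with substreams keyed per state, per condition and per interest,
so adding an interest to a configuration does not perturb existing draws.

**What the simulator does not emulate.** Real reach estimates come from a
black-box classifier over billions of users: they carry sampling noise,
temporal drift, demographic-dependent interest semantics, and an opaque
joint distribution over interests (the planted ω matrix is an
abstraction — copula-based alternatives would be richer but are not needed
for the properties tested). A true count below the granularity is reported
as its rounded value (possibly 0); whether the real API suppresses such
cells instead is unknown, and this is an emulation approximation. Passing
tests therefore establish that the estimators recover what this generative
model plants, not that real platform data satisfy the model.

## Study conditions and calibration

Loadings for the planted scenarios are derived analytically. With a
noiseless share (a monotone function of z) and prevalence noise σ inside
the logistic link's near-linear regime, the model-implied share–prevalence
correlation is approximately `β/sqrt(β²+σ²)`, so σ is solved from the
target r. The scenarios:

* **Marker recovery** — one marker planted at r ≈ 0.75 over 50 states of
  10⁶ adults at adoption 0.6; the pipeline-estimated r should fall in the
  Fisher-z 95% band [0.59, 0.86] in ≥ 90% of 200 seeds.
* **Placebo confound** — ρ = 0.7 with a placebo whose engagement loading κ
  equals the marker's health loading λ. The placebo's implied correlation
  is ρ times the marker's, so the marker–placebo gap is (1−ρ)·r_marker;
  the marker is planted at r ≈ 0.40, which keeps the gap (≈ 0.12) inside
  the ≤ 0.15 comparability band while leaving the confound clearly visible
  (placebo |r| ≈ 0.27 at n = 50). A stronger marker would mechanically
  widen the gap — the phenomenon being reproduced is that a causally inert
  interest attains a correlation of the same order as a genuine marker.
* **Lift recovery** — constant propensities (p = 0.05) and a planted
  ω = 2.0 in a single 10⁷-adult region, so the estimator's only error is
  rounding; recovery is within ±5% and degrades gracefully as populations
  shrink toward the granularity.
* **Null calibration** — zero loadings with idiosyncratic share noise
  τ = 0.3; over 500 seeds the Bonferroni-significant fraction of records
  stays at or below α.

Problem sizes (200 / 100 / 500 worlds, n = 200 regression designs, 100
selection replicates) were chosen to keep Monte-Carlo standard errors well
below the asserted margins while the whole suite runs in well under a
minute.

## Numerical choices and degenerate inputs

* Granularity rounding: nearest multiple, exact halves away from zero (the
  reported precision implies nearest-multiple but no tie rule; away-from-
  zero is symmetric and matches integer intuition at the half-step).
* Rounding error bounds used in invariants: a single rounded count is
  within g/2 of its exact value, so gender partitions (2 parts vs 1 total)
  agree within 2g and conjunctions are monotone within g.
* Pearson r is computed by scipy; the two-tailed p is computed from the t
  transform directly (and cross-checked against scipy's in the tests).
  Inputs shorter than 3 or constant are rejected rather than returning
  NaN.
* Prevalences are fractions in [0,1] everywhere in memory; percent
  conversion is a rendering concern only.
* Health-table CSVs are re-read with round-trip float parsing so
  write-read cycles are lossless.
* Collinearity is detected by rank; the offending columns are named via
  pivoted QR before the error is raised.

## Known limitations

* The simulator is cross-sectional; longitudinal drift between audience
  snapshots and health statistics (a real concern for this data source) is
  out of scope.
* Ecological correlations across states say nothing about individual-level
  association; nothing in the package should be read as individual risk.
* Only Pearson correlation is offered by design; rank-based measures are
  deliberately excluded from the screen's scope.
* The packaged 2016 snapshot contains US-wide totals only; per-state
  analyses on real data require the user to supply their own snapshot in
  the JSON Lines format.
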