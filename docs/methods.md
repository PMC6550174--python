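# Methods

This note documents the models implemented in `foodwatch`, the design of
the synthetic world they are exercised on, the default parameters and why
they were chosen, and the numerical and statistical conventions used
throughout.

## 1. Detection pipeline

### Query classifier (web search model)

The classifier is a binary maximum-entropy model, i.e. logistic
regression on sparse text features: P(illness | query) = σ(b + wᵀx).

*Features.* Namespaced string tokens — `q:` unigrams and adjacent
bigrams of the lowercased query (split on non-alphanumerics, no
stemming), `t:`/`s:` the same for each result title and snippet, `u:`
URL path tokens with scheme and boilerplate (`www`, `com`, ...) removed,
and `c:` concept-tag indicators — are mapped into D = 50,000 dimensions
by signed feature hashing. The hash is the 8-byte BLAKE2b digest of the
UTF-8 token read as a big-endian integer h: index = h mod D, sign from
the top bit of h. BLAKE2b is fully specified and unkeyed, so feature
indices are identical across processes, platforms and library versions —
a serialized model is portable. Signing makes colliding features cancel
in expectation rather than accumulate bias; colliding values sum. D is
configurable downward for small experiments.

*Weak labels.* Training requires no human annotation. A page is
*topical* when its foodborne-illness concept prominence is ≥ 0.5 (the
threshold is a configuration knob; prominence is a property of the page
catalog). A query is a training positive iff at least one of its clicks
landed on a topical page with dwell ≥ 30 s; "significant time spent" has
no canonical quantification, and 30 s is the familiar short-click /
long-click boundary in log analysis. Duplicate query strings collapse to
one example. Negatives are sampled from the remaining stream in
proportion to occurrence frequency (traffic weighting, implemented as
weighted sampling without replacement over unique strings) at a default
1:4 positive:negative ratio. Positives, negatives, and the evaluation
sample are disjoint at the string level by construction; a pool too small
to satisfy a request raises an explicit shortfall error rather than
silently shrinking.

*Training.* The penalized objective is Σᵢ log(1 + exp(−yᵢ(b + wᵀxᵢ)))
+ (λ/2)‖w‖², yᵢ ∈ {−1, +1}, with the bias unregularized and λ = 1 by
default. Optimization uses a trust-region Newton method (`trust-ncg`)
with analytic gradient and Hessian-vector products, so the second-order
step never materializes a D×D matrix. Convergence is declared at
gradient norm ≤ tol = 1e−8 (the optimizer may stop slightly above this
when the trust region collapses; the final gradient norm, iteration
count, loss trace and a converged flag are recorded in the model
metadata). Training is deterministic given its inputs. A single-class
training set is rejected with an explicit error.

*Evaluation.* ROC AUC uses the rank (Mann–Whitney) definition with tied
scores counted ½. F1 is reported at a threshold policy — `fixed:0.5` by
default, or `max_f1` over a validation split. The evaluation sample
mirrors a class-imbalance-aware design: half drawn (traffic-weighted)
from a high-recall pool of queries that clicked topical pages, half
traffic-weighted from the full stream, all unique and disjoint from
training. The default sample size is 200 queries, a scaled-down analogue
of a production-size panel chosen to keep the full pipeline run under a
minute; AUC standard error at this size is ≈ 0.02–0.03.

### Rater panel and agreement

Six independent judgements per evaluated query: three medical doctors
and three non-MDs, each flipping the hidden truth label with a
role-specific error rate. Ground truth is the majority of all six; a 3–3
tie is resolved by the majority of the three MD votes (always defined).
Agreement is Krippendorff's alpha with the nominal metric, computed from
the standard coincidence-matrix formulation; items with fewer than two
judgements are excluded, and both rater groups are pooled. Ordinal and
interval alpha variants are out of scope.

### Location model

A user becomes a case at their **first** query scoring ≥ 0.5 — counting
is user-level, not query-level, so prolific searchers do not inflate
incidence. Candidates are all visits in the closed window [t − W, t]
with W = 3 days (both endpoints included; W spans visit time to query
time). Users with no in-window visit are dropped and counted. Per
restaurant over the analysis period, `n_visitors` is the number of
distinct visiting users and `n_flagged` the number of distinct visitors
with a subsequent in-window illness query; a user contributes at most
once per restaurant. The signal is the proportion n_flagged/n_visitors.

*Differential privacy.* Both user counts are released via the Laplace
mechanism with sensitivity 1 (adding or removing one user changes each
count by at most 1): noise scale 1/ε, noisy counts clamped at 0, and the
noisy proportion recomputed and clipped to [0, 1] (0 when the noisy
visitor count is 0). Flagging ranks on noisy proportions when ε is
finite and on true proportions when privacy is disabled (ε ≤ 0). The
default budget is ε = 5. The choice is driven by the scale of the
released statistic: at the default simulation size per-restaurant
flagged counts are only a few users, so a scale-1 (ε = 1) perturbation
is as large as the signal itself and venue ranking degrades to noise;
ε = 5 keeps the noise standard deviation (√2/ε ≈ 0.28 users) an order of
magnitude below typical counts. In a metropolitan deployment the same
relative-noise argument would be satisfied by a far smaller ε, because
the counts are orders of magnitude larger.

*Flagging.* Keep restaurants with ≥ 40 distinct visitors (proportions
over smaller denominators are dominated by sampling noise) and
proportion ≥ a cutoff (default 0 — pure ranking); sort by proportion
descending, then flagged count descending, then id; truncate to the
top 20.

*Attribution.* Each case is attributed to the candidate restaurant with
the maximal signal proportion — one concrete reading of "relative signal
strength"; a weighted posterior over candidates would be an alternative.
Ties go to the most recent visit. The recency rank is the position of
the attributed restaurant among the case's distinct prior restaurants in
most-recent-first order (a repeated restaurant takes the position of its
most recent visit), histogrammed over bins 1, 2, 3, 4+. Signals are not
recomputed leave-one-out when attributing a case's own restaurant.

### Inspection-outcome statistics

An inspection is *unsafe* iff its grade is Fail or Pass-with-Conditions,
or it recorded ≥ 1 critical violation; the mapping is fully
configurable (the severity catalogues behind real grading schemes vary
by jurisdiction). Summaries report n, unsafe count, and percent unsafe
per trigger group — flag-driven (FINDER), COMPLAINT, ROUTINE, and
BASELINE = COMPLAINT ∪ ROUTINE — overall and per risk level, with
percentages rounded half-up to one decimal to match conventional table
formatting. Empty strata are omitted.

Effects: crude odds ratios are the 2×2 cross-product with Wald 95% CI on
the log scale and Haldane–Anscombe +0.5 correction (flagged) when a cell
is zero; a zero margin is an error. Adjusted odds ratios come from
maximum-likelihood binomial logistic regression with dummy-coded city
and risk-level fixed effects (Wald CIs, matching the usual reporting
style; profile-likelihood intervals are not used). Complete separation
or non-convergence raises an explicit error naming a sparse stratum when
one can be identified. Adjusted mean violation counts use OLS with the
same fixed effects and *marginal standardization*: the adjusted mean for
a group is the average model prediction over the pooled covariate
distribution with group membership set counterfactually
(covariates-at-means is selectable). Risk-distribution comparisons use
the Pearson chi-square on the 2×3 table (df = 2, no continuity
correction). Grade-level effects use a baseline-category multinomial
logit with Pass as reference, reporting exponentiated exposure
coefficients (relative-risk ratios) per non-reference grade.

One caveat about the published two-city reference counts bundled in
`foodwatch.datasets`: the complaint group's printed percentage (39.4%)
does not match its own printed counts (508/1291 = 39.35% → 39.3 at
one-decimal half-up rounding), and the experimental-design narrative
reports baseline risk-level counts (6225/2532/2967) that disagree with
the summary table (5702/2325/2759). The package carries the summary-table
values and reproduces percentages from counts exactly as computed; the
39.3/39.4 discrepancy is surfaced, not patched.

## 2. The synthetic world

The simulator generates every log the pipeline consumes, with the
statistical structure the detector assumes and full ground truth
retained for validation.

*Registry and population.* Restaurants carry a city (two cities by
default), an a-priori risk level (high/medium/low at 0.5/0.3/0.2), and a
latent unsafe state assigned to exactly round(n × unsafe_fraction)
restaurants — an exact count rather than per-restaurant Bernoulli so
small-world tests are deterministic. Per-visit transmission probability
is 0.02 (unsafe) vs 0.002 (safe), each jittered ±20% multiplicatively;
the ranges stay disjoint.

*Visits.* Per-user homogeneous Poisson at 0.2 visits/user/day (dining
out every five days on average), with restaurant choice by Zipf weights
(exponent 1) over the registry — a heavy-tailed popularity profile that
creates the popular-venue/rare-venue contrast aggregation must cope
with.

*Infections.* Each visit converts independently with the restaurant's
transmission probability; every infection traces to exactly one source
restaurant. Onset delay is Uniform(0, 3) days by default — only the
3-day bound is epidemiologically anchored, so the default takes the
least-informative shape on that support; a log-normal truncated to
[0, 3] via inverse-CDF sampling is selectable. No onset ever exceeds
the window (this is asserted as an invariant).

*Queries.* Three sources: (1) each infection is reported with
probability 0.7, producing one to a few illness queries starting shortly
after onset (query times may therefore trail the visit horizon by up to
the incubation window plus the reporting delay); (2) uninfected users
issue illness-topic queries at 0.001/user/day — the hypochondriac /
curious-searcher path that exercises classifier false positives; (3) all
users issue benign queries at 0.3/user/day, 15% of which are off-topic
lookalikes sharing surface tokens with the illness vocabulary ("food
network recipes", "stomach exercises", ...). Query strings are composed
from prefix/core/suffix part lists so the stream contains thousands of
distinct strings, and 10% of queries receive a random character
perturbation (substitution, deletion, transposition or duplication),
emulating typos. Illness queries retrieve topical pages and click one
with probability 0.85 at exponential dwell (mean 90 s, so ~72% of clicks
clear the 30 s anchor); benign queries click background pages at short
dwell (mean 20 s); lookalikes click a topical page with probability 0.02
at mean 10 s dwell, injecting a small amount of weak-label noise.
Hidden truth labels mark topical relevance (is this query about
foodborne illness), not infection status; the classifier never sees
them.

*Raters.* Flip error rates 0.03 (MD) and 0.06 (non-MD). With the
evaluation sample's roughly balanced class mix these produce alpha in
the 0.8 neighbourhood, the "high agreement" regime the panel is meant to
emulate.

*Inspections.* Flagged restaurants are inspected at period end; each
restaurant receives a routine inspection with probability 0.9 at a
uniform date; each infection generates a complaint with probability
0.05, and the complainant names their most recently visited restaurant
(misattribution probability 1.0 by default — the documented
blame-the-last-restaurant bias; lowering it routes complaints to the
true source). The recorded outcome is unsafe with probability 0.85
(sensitivity) for latently unsafe venues and 0.10 (1 − specificity)
otherwise, making the routine-group unsafe share ≈ 0.2·0.85 + 0.8·0.10
= 0.25. Grades and violation counts are drawn conditionally on the
recorded outcome and are consistent with the default outcome mapping by
construction (safe inspections record zero critical violations).

*Reproducibility.* One master seed; every stage draws from
`default_rng([seed, stage_offset])` with fixed per-stage offsets, so
stages are independently reproducible and adding a stage does not
perturb the others. Identical (config, seed) gives byte-identical
outputs, including the metrics file.

### What the simulator does not emulate

No geography or travel realism; no person-to-person or multi-pathogen
transmission; no seasonality or day-of-week structure; no real web-page
text (pages are catalog entries with concept prominences, so "page
content" features reduce to titles and snippets); an English-like
synthetic vocabulary far smaller and cleaner than a real query stream;
no adversarial or spam traffic. Consequently, a near-perfect classifier
AUC here demonstrates that the weak-labeling-plus-hashing pipeline is
implemented correctly and recovers the latent topical structure — not
that real-world query classification is this easy, where reported
performance is materially lower (AUC ≈ 0.85). Likewise flag precision
and attribution accuracy on the synthetic world characterize the method
under its own assumptions, not field performance.

## 3. Problem sizes used by the tests

The reference regression world is the default configuration: 200
restaurants (20% unsafe), 5,000 users, 60 days — about 60k visits, 90k
queries, and 300–500 infections depending on which popularity ranks the
unsafe venues land on. It is generated once per test session. Calibration
checks use 100 replicates of n = 5,000 logistic regressions and 10,000
Laplace draws. Unit tests run on worlds of a few hundred users. The full
suite completes in a few minutes on one CPU; the acceptance script in
about two.

## 4. Known limitations

- The attribution rule is argmax over candidate proportions; a
  probabilistic posterior combining signal strength with visit recency
  would use strictly more information.
- Weak-label deduplication is by exact query string; near-duplicates
  (typo variants) remain distinct examples.
- Adjusted odds ratios from the synthetic inspection logs have wide
  intervals because the flagged group is small (top-20) by design.
- The DP mechanism protects the two released counts per restaurant; it
  does not account for an adversary combining repeated daily releases
  (no composition accounting across days).
- Noisy proportions are clipped to [0, 1]; the clamp introduces a small
  upward bias for true counts near zero, which is the standard
  post-processing trade-off.
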