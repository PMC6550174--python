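# foodwatch

Syndromic surveillance of foodborne illness from web-search and location
event logs.

Health departments mostly find unsafe restaurants through routine
inspections and consumer complaints. Both are slow, and complaints are
often mistargeted because people tend to blame the *last* restaurant they
visited, while incubation delays of up to about three days mean the true
source is frequently an earlier one. `foodwatch` implements, end to end,
the alternative: detect illness-indicative search queries with a weakly
supervised classifier, link each flagged user back to every restaurant
they visited within the incubation window, aggregate a per-restaurant
incidence proportion under differential privacy, rank venues for
inspection, and evaluate the flagging policy against inspection outcomes.
Because real search and location logs are proprietary, the package ships a
seeded synthetic-world simulator that produces every log the pipeline
consumes, with ground truth (latently unsafe restaurants, true infection
sources, true query topicality) retained for validation. It is aimed at
computational epidemiologists and public-health data scientists who want
to study or extend search-based outbreak detection at desk scale.

## The model

**Web search model (WSM).** A log-linear maximum-entropy (binary
logistic) classifier estimates, for a query *q* with hashed sparse
features *x*,

    P(illness | q) = σ(b + wᵀx),

where features are namespaced word unigrams/bigrams from the query text,
result titles, snippets and URL tokens, plus concept-tag indicators,
signed-hashed into D = 50,000 dimensions. Training needs **no human
labels**: queries whose clicks led to ≥ 30 s of dwell on pages where
foodborne-illness concepts are prominent become positives; negatives are
traffic-weighted samples from the rest of the stream. Weights maximize
the L2-penalized log-likelihood via a trust-region Newton method.

**Location model.** A user becomes a case at their first query with
score ≥ 0.5; every restaurant visited in the closed window [t − W, t]
(W = 3 days) is a candidate source. For restaurant *r*, the signal is

    p̂(r) = (# distinct visitors who later showed search evidence of illness) /
           (# distinct visitors),

a *user*-level (not query-level) proportion. Counts are released through
the Laplace mechanism (sensitivity 1, scale 1/ε) and clamped at zero.
Restaurants are ranked by the (noisy) proportion; each case is attributed
to its candidate with the strongest relative signal, ties going to the
most recent visit.

**Policy evaluation.** Inspection outcomes are labeled safe/unsafe from
grades and severity-coded violation counts; the package tabulates percent
unsafe per trigger group (flag-driven vs complaint vs routine), estimates
crude and covariate-adjusted odds ratios (binomial logistic regression
with city and risk-level fixed effects), adjusted mean violation counts
(OLS with marginal standardization), risk-distribution chi-square tests,
and relative-risk ratios from multinomial logit over the Pass /
Pass-with-Conditions / Fail grades. Rater panels (3 MDs + 3 non-MDs per
query) are aggregated by majority vote with MD tie-break, and agreement is
quantified by Krippendorff's alpha (nominal).

## Worked example

Run the full pipeline on the default synthetic world (200 restaurants of
which 20% are latently unsafe, 5,000 users, 60 days):

```python
from foodwatch.config import PipelineConfig
from foodwatch.pipeline import run_pipeline

metrics = run_pipeline(PipelineConfig(), seed=1, out_dir="demo_run")
counts = metrics["counts"]
loc = metrics["location_model"]
ev = metrics["wsm_eval"]
print("visits:", counts["visits"], " infections:", counts["infections"],
      " queries:", counts["queries"])
print("WSM ROC AUC vs hidden truth:",
      round(ev["vs_hidden_truth"]["roc_auc"], 3))
print("inter-rater alpha:", round(ev["krippendorff_alpha"], 3))
print("illness cases linked:", loc["cases"])
print("restaurants flagged:", loc["flagged"])
print("flag precision vs latent state:",
      round(loc["flag_precision_vs_latent"], 2))
print("last-restaurant attribution share:",
      round(metrics["attribution"]["rank_histogram"]["1"], 2))
```

prints (about half a minute on one CPU):

```
visits: 60035  infections: 462  queries: 90344
WSM ROC AUC vs hidden truth: 1.0
inter-rater alpha: 0.793
illness cases linked: 532
restaurants flagged: 20
flag precision vs latent state: 0.65
last-restaurant attribution share: 0.79
```

Reading the numbers: the weakly supervised classifier separates truly
illness-related queries essentially perfectly on this synthetic
vocabulary (real query streams are harder); six-rater agreement sits in
the "high agreement" range; 532 users were linked to at least one
restaurant visited within 3 days before their first illness-scored query;
of the 20 restaurants flagged for inspection, 65% are truly unsafe —
about 3× the 20% base rate — and 79% of cases are attributed to the last
restaurant visited, i.e. for roughly a fifth of cases the likely source
is *not* the most recent visit, which is why complaint-driven inspections
mistarget.

The same pipeline is scriptable from the shell:

```
foodwatch --config my.yaml --seed 1 --out run1 run-all
foodwatch --out run1 report
```

with stagewise subcommands (`simulate`, `build-labels`, `train`, `score`,
`evaluate-wsm`, `evaluate-raters`, `flag`, `attribute`,
`evaluate-inspections`, `report`) that operate on the same directory
layout. Every output file carries the code version, seed and
configuration hash.

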