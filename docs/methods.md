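# Methods

## The measurement model

The analysis unit is the city-hour cell: all resolved, scored tweets from
one city in one local-time hour.  For each cell we observe the tweet count
n and the counts flagged positive, negative and social.  Positive and
negative flags are independent (a tweet can carry both), so the two
proportions are modelled separately throughout and never combined into one
scale; a low positive proportion means an absence of positive affect, not
the presence of negative affect.

Baselines are ordinary least-squares regressions of a cell proportion on a
factor subset:

    p = β₀ + Σ_c β_c·1{city=c} + Σ_h β_h·1{hour=h} + Σ_d β_d·1{dow=d}
        + Σ_w β_w·1{weather=w} + β_s·p_social + ε

Categorical factors are dummy-coded against fixed references — the first
city alphabetically, hour 0, Monday, clear weather — and the social share
enters as a continuous covariate.  Hour, day-of-week and weather use their
full canonical level sets (24, 7 and 7 levels) regardless of which levels a
particular training table happens to contain, so coefficient counts are
stable: with 100 cities the full model has 136 coefficients.  A linear
model on the proportion scale is deliberately simple — it keeps single- and
multi-factor models directly comparable and makes expected counts
interpretable — at the cost of unbounded predictions under extrapolation,
which the deviation stage handles by clamping.

Fits are unweighted by default.  Whether cells should be weighted by tweet
volume is genuinely open (cells with more tweets have less sampling noise,
but weighting lets high-volume cities dominate the baseline); `weight_by_n`
exposes the weighted variant without changing the default.

Model evaluation is strictly temporal: the first part of the period trains,
the remainder tests.  Held-out quality is the Pearson correlation between
predicted and observed proportions, with a 95 % CI from the Fisher z
transform, z = atanh r ± 1.96/√(n−3).  A constant prediction vector (the
intercept-only baseline) leaves r undefined; it is reported as 0 with a
degenerate flag rather than an error so baselines stay comparable.

## Deviation detection

For a test cell with count n and observed flagged count O, the model
expectation is E = clamp(p̂, ε, 1−ε)·n with ε = 10⁻⁶; the clamp keeps the
statistic finite when the linear model extrapolates outside [0, 1].  The
deviation statistic is the 1-df chi-square goodness of fit over the two
categories {flagged, not flagged}:

    χ² = (O−E)²/E + (O−E)²/(n−E)

with the tail p-value from the χ²₁ distribution and direction from the sign
of O−E.  Cells are ranked by descending χ² within each outcome; ranking by
the statistic rather than the p-value is monotone-equivalent at 1 df and
avoids floating-point underflow for extreme deviations.  Ties break by
earlier time, then city label, making the ranking order-invariant.

Rarity is reported as a recurrence interval: RI = D / (number of deviations
with strictly larger χ²), where D is the number of observation days.  The
strictly-larger convention reproduces both canonical worked examples — a
magnitude exceeded twice in 60 days has RI = 30; exceeded 60 times, RI = 1
— and gives the top-ranked deviation the sentinel ">D".

Event merging operates on deviations with p < α (default 0.05, no
multiple-testing correction — the method ranks rather than tests, and a
Bonferroni option would only relabel the same ordering).  Within one
outcome and direction: deviations in the same country are grouped by local
date, runs of consecutive dates are unioned, and each resulting cluster is
labelled by its maximum-χ² member.  Scope follows the cluster's extent:
a singleton stays an hour-city event; one city and one date is a day-city
event; several cities on one date is a day-country event; several dates is
a multi-day-country event.  "Same time" for country merging means
overlapping local dates.

## The synthetic generator

The generator emulates the structure the pipeline is designed to measure,
with full ground truth.  Tweet counts per city-hour are Poisson(λ); each
tweet's probability of carrying positive sentiment is the additive linear
predictor base + city + hour + dow + weather + slope·social, clamped to
[0, 1], with an independent predictor for negative sentiment; injected
events add a signed shift over a contiguous window of local hours in one
city, and the ground truth records both the with-event and event-free
(baseline) truth per cell.  Additive effects on the proportion scale match
the analysis model exactly, so regression recovery is exactly identified —
a deliberate choice over a logistic link, which would make "recovered
coefficient equals configured effect" only approximate.

Defaults: grand-mean proportions 0.40 positive / 0.28 negative (typical of
large English-language tweet samples); city offsets of a few percentage
points drawn once from the seed; mild circadian cycles peaking in the
evening (positive) and near midnight (negative); a Friday-positive weekly
pattern; small weather effects; social slope +0.10 on positive and −0.02 on
negative sentiment; 25 % social tweets; 10 % unresolvable profile
locations; 1 % celebrity accounts; 5 % non-English records.  Weather is a
sticky categorical chain: with probability 0.8 the previous hour's category
persists, else a uniform redraw from the 7 categories.

Tweet text is assembled from a filler vocabulary disjoint from the
generated lexicon; a tweet intended positive embeds a positive lexicon term
(strength ≥ 2), likewise for negative, so scoring generated text recovers
intended labels exactly.  This round-trip is a correctness device, not
realism: the generator does not model real language, user-level
longitudinal behaviour, retweet cascades, or demographic composition.
Passing tests therefore demonstrate that the pipeline measures the
structure it claims to measure when that structure is present — not that
real streams contain only this structure.

Two generation paths share one truth model: `generate_tweets` produces the
full record-level stream for end-to-end tests, and `generate_cells` samples
cell tables directly (binomial counts given the Poisson n), which is what
makes 200-replicate coverage studies and 100-run power studies cheap.  A
`noiseless=True` mode sets observed proportions equal to the truth for
exact-recovery checks.

## Numerical and design choices

- Sentiment aggregation over multiple lexicon hits uses the MAX strength
  per polarity.  Dictionary scorers differ here (max vs capped sum); max is
  the common sentence-level convention and the alternative is injectable.
  No boosters, negators, emoticons or spelling correction: the package's
  claims concern aggregation and detection, not lexical nuance.
- Tokenization: lowercase, split on non-alphanumeric runs — fixed so golden
  tests are bit-stable.
- Interaction labels: retweets and quotes are broadcast even when they
  carry mentions; then replies or mentions make a tweet social; else
  broadcast.
- Celebrity filter is inclusive at the 300,000-follower bound.
- City resolution is a deterministic alias-table lookup (whole normalized
  string, then its leading comma segment); no network geocoding.  Timezone
  offsets are fixed (no DST); a DST-aware table can be supplied via the
  gazetteer.
- Zero-tweet cells are omitted, not imputed; `min_n` (default 1) exposes
  sparse-cell filtering because the chi-square test is fragile at tiny
  expected counts.
- Rank-deficient designs raise an error naming the collinear columns
  (pivoted-QR identification) rather than silently dropping terms.
- Missing weather rows default to "clear" with a logged warning; duplicate
  weather keys are an input error.

## Problem sizes

The test suite and examples run at desk scale by design: 4–15 cities over
1–4 weeks at 30–150 tweets per city-hour, giving streams of ~5×10⁴–10⁵
tweets and cell tables of 10³–10⁴ rows.  The statistical acceptance checks
use ~5,000 cells for null calibration, 200 replicate fits for CI coverage,
and 100 seeded runs for detection power — sizes at which the binomial
tolerance bands stated in the tests are meaningful.

## Known limitations

- The ecological design cannot attribute deviations to individuals, and
  no demographic reweighting is attempted.
- The linear probability model can predict outside [0, 1]; the ε-clamp
  makes detection robust to this but the baseline itself remains linear.
- OLS inference assumes homoskedastic errors; cell-level binomial noise is
  mildly heteroskedastic (variance p(1−p)/n), which the coverage tests show
  is benign at the default volumes but would matter for very uneven cells.
- Country-level merging joins any same-country, same-direction significant
  deviations on overlapping dates, even if causally unrelated.
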