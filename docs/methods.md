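# Methods

## Problem and model

`infovigil` implements an early-warning pipeline for toxicovigilance from
social-media chatter. The premise: when a fraudulent health product (a fake
cure, test kit, or the entity selling it) gains traction, mentions of its
name surge in the public post stream *before* a regulator reacts with a
warning letter. The pipeline turns a timestamped post stream into per-phrase
daily rate series and flags anomalous increases with a one-sided
control-chart rule.

### From posts to rates

For each canonical key phrase (and all of its curated spelling variants,
grouped under the canonical form), the matcher counts the number of posts
per UTC calendar day containing the phrase as a word-boundary-delimited
substring; a post counts at most once per phrase. With `c_t` matching posts
out of `X_t` total posts on day *t*, the daily relative frequency is

    x_t = 1000 · c_t / X_t     (mentions per 1000 posts).

Normalizing by daily volume removes the large shared swings in overall
chatter. Days with zero collected posts yield `x_t = 0` and an explicit gap
flag rather than a missing value: the detector requires a dense calendar
axis, and analysts can discount flags adjacent to gap days. Phrases with
fewer than 10 whole-period mentions (variants included) are excluded —
such products were evidently never promoted successfully.

### The detector

For a series `x_1..x_n` (day 1 = start of collection):

* trailing moving average `μ_i` over the last `w` days including day *i*
  (window shortened at the start, so `μ_1 = x_1`). A trailing — not
  centered — window is used because real-time surveillance cannot see the
  future; it also forces the day-1 residual to zero.
* residual `e_i = x_i − μ_i`;
* progressive standard deviation over *all* residuals since day 1:

      σ_n = sqrt( (ẽ_1² + Σ_{i=2..n} e_i²) / n ),

  with the population divisor *n* (this reproduces `σ_1 = 0` exactly at
  `n = 1`; whether to use `n` or `n−1` is a genuinely open convention and
  is recorded here as the package's choice);
* day *i* is a signal iff `e_i > k · max(σ_i, floor)` — one-sided, since
  only *increases* in chatter are of interest. The floor (0.001 per 1000,
  so an effective minimum threshold of `k·0.001`) prevents the limit from
  collapsing to zero on long all-zero histories.

**Day-1 bias.** Because `σ_1 = 0`, the first days of every series would be
trivially easy to flag, inflating apparent early-detection performance. To
remove that advantage, an artificial nonzero SD is injected on day 1:

    b = std( x_1 − μ_1, …, x_1 − μ_4 ) / k,

the population SD of day 1's value against the first four moving averages,
scaled down by the same `k` used in the control limit. `b` *replaces*
`ẽ_1` in the progressive sum, so it persists inside every later `σ_n` —
deliberately making early detection harder, particularly for phrases whose
early history is all zeros. The bias can only shrink or delay the flag set,
never extend it (σ with the bias dominates σ without it pointwise; this is
property-tested). With fewer than two observed days there is no spread and
`b = 0`.

**Self-masking of very early bursts.** Because `σ_i` includes day *i*'s own
residual, `σ_n ≥ |e_n|/√n`, so no day can fire before `n > k²` (day 10 at
`k = 3`) no matter how large the jump — and a huge early burst inflates the
progressive SD permanently, which can mask the whole series. This is a
real, documented property of the progressive rule, visible in the simulated
study replay as a handful of never-anomalous phrases with very early
bursts.

Defaults (`w = 14`, `k = 3`, floor `0.001`, bias on) are the conservative
operating point; `parameter_sweep` covers the `w ∈ {7,10,14}` ×
`k ∈ {2, 2.5, 3}` grid. Lowering `k` or `w` trades false alarms for
sensitivity; the intended deployment reviews all signals manually, so the
rule is biased toward recall.

### Evaluation

Each phrase's first-signal date is compared with its first warning-letter
date (when a product appears in several letters only the earliest counts —
the conservative convention): `early` (signal strictly before the letter),
`within_week` (letter day through letter + 7, both ends inclusive; the
bound is configurable because the inclusive/exclusive convention is not
forced by anything), `late`, or `none`. Aggregate accuracy is
`#early / #total`. No confidence intervals are attached: the phrase set is
a complete small population, not a sample, and false-positive accounting is
out of scope.

## The lexicon fixtures

`data/table1_keyphrases.csv` carries the 44 retained product/entity phrases
with types (`treatment`, `test_kit`, `entity`) and first-letter dates;
`data/table2_variants.csv` carries the eight published variant lists.
Variant lists are attached to the two phrases present in both tables.
Validation enforces: unique canonical phrases, no variant claimed by two
phrases (a hard error — every count must be attributable to exactly one
product), normalized phrase text (NFC, lowercase, collapsed whitespace)
identical to the matcher's normalization. The `naive_variant_expansion`
helper (whitespace forms plus single-token deletions/transpositions for
tokens longer than 4 characters) is fallback plumbing for lexicons without
curated variants; it is off by default and the shipped fixtures do not use
it.

## Synthetic data generator

`synthetic_data` emulates exactly the statistical structure the detector
assumes, and nothing more:

* daily total volumes `X_t` lognormal around a configurable mean
  (default 2,000,000/day, log-SD 0.2 — heavy-tailed day-to-day variation
  at the scale of a firehose-like COVID stream);
* per-phrase mention counts Poisson with mean `X_t · rate / 1000`
  (default baseline 0.5/1000, a typical mid-tier chattered product);
  optional negative-binomial overdispersion via a Gamma-Poisson mixture;
* promotion bursts: multiplicative rate increases (step or linear ramp) at
  a known onset day, the ground truth for power studies;
* `simulate_stream` emits an actual JSONL post stream whose re-count
  reproduces the simulated table *exactly*: filler text is drawn from a
  nonsense vocabulary checked against the lexicon at emission time, and
  each assigned post embeds the canonical phrase or one of its variants.

What the generator does **not** emulate: real language, retweet cascades,
bots, duplicated content, gradual organic popularity growth, or correlated
cross-phrase chatter. Passing tests therefore demonstrate correctness of
the counting/detection machinery and the detector's power against abrupt
bursts on stationary baselines — not performance on real streams, where
gradual rises can stay under the limit and media events can synchronize
phrases.

## Numerical choices

* Progressive SD is computed incrementally via cumulative sums and is
  required (and tested) to agree with naive full recomputation to 1e-9
  over year-long series.
* Threshold comparisons are strict (`e > k·max(σ, floor)`), matching the
  "more than k SDs" reading; a residual exactly at the limit does not fire.
* Zero-volume days: `x = 0` plus a gap flag (never NaN).
* Unparseable timestamps are skipped and tallied, never fatal.
* Matching is word-boundary substring (boundary = string edge or
  non-alphanumeric character). Token-set matching was rejected because
  curated variants include fused forms (`chlorinedioxide`) that tokenizers
  would split differently; plain substring matching was rejected because it
  produces false hits inside longer words. The matching rule is this
  package's documented choice.
* Posts are binned by UTC date, the native timezone of the `created_at`
  format; no deduplication of retweets (none is part of the method).

## Study replay in `scripts/acceptance.py`

The acceptance script simulates the full 317-day study window for all 44
packaged phrases (seeded, ~2M posts/day): each phrase receives a
heterogeneous baseline (lognormal around 0.5/1000) and one 20-fold,
14-day burst. Three quarters of the products are promoted ahead of the
regulator (onset 5–25 days before the letter); the rest see news-driven
chatter rising only at the letter itself (0–3 days after) — a scenario
choice reflecting how post-letter media coverage drives part of real
chatter. It then reports early-detection accuracy, the within-week share,
how many phrases were ever anomalous, the Monte-Carlo power profile
(sensitivity, median delay, null false-alarm rate over 100 replicates),
and the exact stream round trip. Problem sizes (317 × 44 for the replay,
120 × 4 × 100 for the benchmark) keep the whole run under a few seconds
while leaving the per-day statistics at full study scale.

## Known limitations

* The detector's self-masking of very early large bursts (above) is
  inherent to including the current day in the progressive SD; excluding
  it would be the stricter control-chart convention but is not what this
  rule does.
* The progressive SD never forgets: one large burst inflates σ for the
  rest of the series, suppressing later signals for the same phrase. The
  rule is designed for *first*-signal extraction, not ongoing monitoring.
* Normalization by daily totals means a phrase surge coinciding with an
  equal surge in overall volume is invisible.
* Evaluation measures only the timing of the first signal against the
  letter date; it has no notion of precision/false discovery on real data.
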