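# Methods

This note documents the models and procedures implemented in `xldiff`, the
choices made where the design was genuinely open, and what the synthetic
corpus does and does not emulate.

## Event model and preprocessing

An event is one retweet: timestamp, retweeting user, retweeted user, the
collection stream it came from (`en` or `ja`), text, and embedded URLs.
Month assignment uses the UTC calendar; a collection gathered through an API
has no meaningful local timezone, and UTC is the only reproducible
convention.  Self-retweets are retained in the stream (they are real events
and carry text and URLs) but are neutral for influence, since "retweeted by
more unique users" refers to *other* users.

Native language: a user seen in only one stream belongs to that community; a
user seen in both gets the majority stream of their events, with an exact tie
broken by the language of their earliest event and a timestamp tie resolving
to English.  Any deterministic rule would do; this one uses only information
in the event stream itself.

URL canonicalization lowercases scheme and host, drops the fragment, strips
the tracking parameters `utm_*`, `fbclid` and `gclid` (the same article is
routinely shared with varying tags and must collide to one canonical URL),
preserves all other query parameters in order, and removes trailing slashes
from a bare path.  The transform is idempotent, which the test suite fuzzes.
Strings with no parseable host are logged and excluded from URL analyses
rather than failing the run.

## Influence and rank churn

Monthly influence is unique-retweeter in-degree on the deduplicated retweet
graph (built with networkx).  Ranking ties break lexicographically by user
identifier — degrees are integers, so ties are common at the tail and the
RBO inputs must be reproducible.

Rank Biased Overlap is evaluated both truncated and extrapolated.  Defaults
p = 0.9 and depth 10 follow the standard convention of the RBO literature
and match top-10 rankings; note that under the truncated variant identical
lists score 1 − p^10 ≈ 0.651, not 1 — plots of truncated series should be
read against that ceiling.  The implementation is checked exhaustively
against a brute-force prefix-overlap oracle over all list pairs of length
≤ 5 on a 6-symbol alphabet.

## Stance propagation

Labels spread from seed users (hop 0) by the majority-retweet rule: at hop
h, each unlabelled user who retweeted at least one user labelled by the end
of hop h−1 counts their retweets (with multiplicity) of pro- versus
anti-labelled sources; strict majority assigns that stance, an exact tie
assigns `undetermined`.  Three choices deserve note:

* **Multiplicity, not unique neighbours** — "retweeted a pro-use user more
  times" is a count of events, so one source retweeted three times outweighs
  two sources retweeted once each.
* **Frozen labels** — once assigned, a label is never re-evaluated.  This
  makes the result independent of iteration order within a hop and of later
  arrivals of contrary mass.
* **Undetermined users do not transmit** — the conservative reading: an
  undetermined user carries no stance signal to forward.

Propagation runs on the full-period graph per language, matching
population-wide coverage reporting.  Coverage is 100·(n_pro+n_anti)/total
users; the pro *share* is reported among labelled users (the share among all
users is recoverable from the same counts — both denominators are retained
because reports of such shares are often ambiguous).

## Cross-lingual diffusion timing

Only events by pro-use-labelled users enter the URL analysis.  Per URL and
community the package keeps a daily retweet series on UTC calendar days; a
URL is *shared* when both communities have at least one event.  Day 0 is the
first post in the community matching the URL's language; the observation is
the other community's first-post day minus day 0, and likewise for the
earliest day attaining the maximum of the other community's daily series
(peak ties resolve to the earliest day).  No minimum-retweet filter is
applied by default.  YouTube URLs can be excluded — YouTube tailors language
to the viewer's location, so their detected language is unreliable — and the
pipeline reports fits both ways, with each direction (en-URL adopted by ja,
ja-URL adopted by en) fitted independently as well as pooled.

URL language resolution is a precedence chain: explicit override table, then
a pluggable detector callable (e.g. a langdetect wrapper; anything mapping a
string to a language code), then a deterministic heuristic — Japanese
codepoints in the URL or a `.jp` host mean `ja`, otherwise `en`.

## Asymmetric Laplace fit

Day differences are sharply peaked with exponential tails of different
weights, the signature the asymmetric Laplace distribution (ALD) captures.
Parameterization: location m (days), rate λ (1/days), asymmetry κ, with
density λ/(κ+1/κ)·exp(−λκ(x−m)) above m and λ/(κ+1/κ)·exp(−(λ/κ)(m−x))
below; mass below m is κ²/(1+κ²); κ = 1 is the symmetric Laplace.  This is
the same convention as `scipy.stats.laplace_asymmetric` with scale 1/λ.

The MLE is computed exactly rather than by numeric search: for fixed m,
writing A = Σ(xᵢ−m)⁺ and B = Σ(m−xᵢ)⁺, the conditional optima are
κ̂ = (B/A)^(1/4) and λ̂ = n/(κ̂A + B/κ̂); the profile likelihood in m is
piecewise and attains its maximum at a sample point, so m is profiled over
the observed values (vectorized with prefix sums, O(n log n)).  Ties resolve
to the smallest candidate, making the fit deterministic.  Degenerate inputs
(fewer than 10 points, or all equal) are rejected.  Boundary candidates
where A or B vanishes are kept finite by clipping κ to [1e−6, 1e6]; they
never win the likelihood on non-degenerate data.  Tests verify the fit
reaches at least scipy's numerically optimized likelihood and that the
asymmetric fit never scores below the best symmetric Laplace.

## Synthetic corpus generator

The generator is the package's validation instrument: every downstream
statistic has a configured, recoverable target.

* **Communities** — two user pools of unequal size (defaults 2,000 English,
  1,000 Japanese, 12 months); all retweeting is within-community, as the two
  streams are collected separately.
* **Heavy-tailed influence** — each user draws a Pareto(α = 1.1)
  attractiveness weight; retweet sources are drawn proportional to weight,
  so a small core dominates the monthly top-10 and the RBO series sits well
  above a reshuffled null.
* **Stance homophily** — each user is latently pro-use with probability 0.6
  (near the observed pro share among labelled users); a retweet targets a
  same-stance source with probability `homophily` (default 0.9), which is
  what makes majority-retweet propagation recover the truth.
* **Activity** — Poisson(2) background retweets per user per month.
* **URLs** — a pool (default 500) with per-URL language (70% English, since
  most cross-shared links are English-language), shared by pro-use users
  only; ~5% are YouTube links to exercise the exclusion path.  Daily counts
  start at a Poisson peak on the first-post day and decay geometrically
  (ratio 0.5), so the peak day coincides with or lands just after the first
  post.  Roughly a third of URL-bearing events carry `utm_` decorations or
  fragments to exercise canonicalization.
* **Cross-lingual adoption** — with probability `crosslingual_share_prob`
  the other community adopts a URL at a day offset drawn from the configured
  ALD (defaults m = 0, scale 10 days, κ = 1.5, i.e. ~69% lead mass,
  emulating strong non-native lead).  Offsets are `floor()` of the
  continuous draw: floor preserves the sign mass exactly
  (P(⌊X⌋ < 0) = P(X < 0)), so the configured lead mass survives day-level
  discretization; the ~0.5-day location shift it induces is small against
  the 10-day default scale.  Adoption events may fall outside the nominal
  month range; the timeline simply extends.

Identical config and seed give byte-identical corpora, which the fixture
writer (events JSONL + ground-truth CSVs + config + manifest with config
hash) asserts by file hash in tests.

What the generator does **not** emulate: real text (tokens are drawn from a
small fixed vocabulary per language — keyword counting is exercised, corpus
linguistics is not), bursty news-driven event clustering, account churn and
suspension, users active in both streams, retweet cascades with internal
structure (every retweet points directly at an influencer), or URL language
detection errors (generated hosts encode the language exactly).  Passing
tests therefore show the *estimators* are correct under the stated
generative assumptions, not that real corpora satisfy those assumptions.

## Problem sizes

Validation runs use corpora of a few thousand users over 12 months
(≈ 50–120k events) and URL pools of 0.5–3k with high cross-adoption, sizes
at which sampling error on the recovered quantities (stance accuracy, lead
mass within ±3 points, ALD parameters within ±5%) is comfortably below the
tolerances being asserted while a full run completes in seconds.

## Known limitations

* Stance propagation is one-pass with frozen labels; an evidence-weighted or
  iterative relabelling scheme could use later information but would lose
  order-independence.
* The degree measure ignores retweet volume entirely; a user retweeted 1,000
  times by one account has degree 1.
* The ALD is fitted to integer day differences with a continuous density;
  for very small timing scales (≲ 2 days) discretization biases the fit and
  a discretized likelihood would be preferable.
* URL language heuristics only see the URL string; content-based detection
  must come through the detector plug-in or override table.
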