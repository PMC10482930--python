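# xldiff

Cross-lingual misinformation-diffusion analysis for bilingual retweet
corpora.

When a piece of health misinformation — say, a news article claiming an
unproven drug treats Covid-19 — circulates on social media in two language
communities at once, several questions arise that single-language analyses
cannot answer: who are the influential spreaders in each community and how
stable is that group over time; which users endorse the claim and which push
back; and when a link is shared in both languages, *which community finds it
first*?  `xldiff` implements that analysis pipeline for retweet event
streams collected from two language communities (English and Japanese),
together with a synthetic bilingual corpus generator so every stage can be
validated against known ground truth.

## What it computes

**Influence.**  For each calendar month and language, users are ranked by
unique-retweeter degree: the number of *distinct* users who retweeted them
that month (duplicate retweets collapse; self-retweets count for nothing).

**Rank churn.**  Month-over-month stability of the top-10 influencer lists is
measured with Rank Biased Overlap.  For rankings *S*, *T* and a persistence
parameter *p* ∈ (0, 1),

    RBO(S, T, p) = (1 − p) Σ_d  p^(d−1) · A_d,    A_d = |S[:d] ∩ T[:d]| / d,

a geometrically weighted average of prefix-overlap proportions that penalizes
disagreement at the top of the list most heavily.  Both the truncated variant
(identical lists score 1 − p^depth) and the extrapolated variant (identical
lists score 1) are available; defaults are p = 0.9 at depth 10.

**Stance.**  Pro-use/anti-use labels spread outward from a seed set of tagged
influencers through the retweet graph: a user who retweeted pro-use-labelled
users more times than anti-use-labelled ones is tagged pro-use, and vice
versa; an exact tie gives `undetermined`.  Labels freeze once assigned,
undetermined users do not transmit, and the frontier advances a configurable
number of hops (default 6 in English, 5 in Japanese).  Coverage statistics
report the share of the population that received a stance.

**Cross-lingual diffusion timing.**  URLs shared by pro-use users of both
communities are canonicalized (tracking parameters stripped), tagged with a
language (override table → pluggable detector → deterministic heuristic), and
reduced to daily retweet series per community.  For each shared URL, day 0 is
its first post in the community matching the URL's language; the day
difference to the other community's first post (and to its peak-retweet day)
is the timing observation.  Negative day differences mean the non-native
community led.  The day-difference distribution is fitted by maximum
likelihood with an asymmetric Laplace distribution

    f(x) = λ/(κ + 1/κ) · exp(−λκ(x−m))     x ≥ m
    f(x) = λ/(κ + 1/κ) · exp(−(λ/κ)(m−x))  x < m

whose mass below the location, κ²/(1+κ²), quantifies the lead phenomenon.
The MLE is exact: the location is profiled over sample points with κ and λ at
closed-form conditional optima.  YouTube links can be excluded (their
language follows the viewer's location, not the content).

## Worked example

```python
from xldiff import (SyntheticConfig, generate_corpus, seed_labels_by_degree,
                    propagate_stance, coverage_stats, assign_native_language,
                    build_url_records, timing_observations,
                    fit_asymmetric_laplace, negative_mass)

cfg = SyntheticConfig(n_users_en=300, n_users_ja=200, n_months=6,
                      n_urls=150, crosslingual_share_prob=0.7, rng_seed=11)
events, truth = generate_corpus(cfg)
print(f"{len(events)} retweet events")

language_map = assign_native_language(events)
seeds = seed_labels_by_degree(events, truth, n_per_stance=20)
labels = {}
for lang, hops in (("en", 6), ("ja", 5)):
    stream = [e for e in events if e.stream_language == lang]
    lang_labels = propagate_stance(stream, seeds[lang], max_hops=hops)
    population = {u for e in stream for u in (e.retweeter_id, e.source_user_id)}
    stats = coverage_stats(lang_labels, total_users=len(population))
    print(f"{lang}: coverage {stats.coverage_pct:.1f}%, pro share {stats.pro_share_pct:.1f}%")
    labels.update(lang_labels)

records = build_url_records(events, labels, language_map)
obs = timing_observations(records, youtube_excluded=True)
params = fit_asymmetric_laplace([o.day_diff_first for o in obs])
mass = negative_mass(obs, params)
print(f"{sum(r.shared for r in records)} shared URLs, {len(obs)} timing observations")
print(f"ALD fit: m={params.location:.1f}, lambda={params.rate:.3f}, kappa={params.asymmetry:.2f}")
print(f"lead mass: empirical {mass.empirical:.3f}, model {mass.model:.3f}")
```

Output:

```
8271 retweet events
en: coverage 100.0%, pro share 63.0%
ja: coverage 100.0%, pro share 67.5%
111 shared URLs, 105 timing observations
ALD fit: m=-2.0, lambda=0.085, kappa=1.38
lead mass: empirical 0.714, model 0.726
```

The generator was configured with asymmetry κ = 1.5, i.e. a true lead mass of
κ²/(1+κ²) ≈ 0.69: most shared URLs reach the other community *before* their
own — and the fitted model recovers that (0.726) from day-level data alone.
The coverage lines show the propagation labelling essentially the whole
population from 40 seeds per language, with the pro share near the generated
60% pro fraction.

## Command line

The same pipeline runs from a shell, stage by stage or end to end:

```sh
xldiff synth --seed 7 --out run/            # synthetic fixture + seeds
xldiff run-all --config config.yaml --out run/
```

`run-all` writes `degrees.csv`, `rankings.csv`, `keywords.csv`, `rbo.csv`,
`stance_labels.csv`, `coverage.json`, `url_records.csv`,
`timing_observations.csv`, `ald_fit.json`, `nonnative_ranking.csv` and a
`run_manifest.json` (config hash, seed, row counts).  Reruns with the same
config and seed are byte-identical.  Real data enters through
`mode: files` with an events file (JSONL/CSV) and a seed-stance CSV.

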