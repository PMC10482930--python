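"""Synthetic bilingual retweet-corpus generator with known ground truth.

The generator emulates the structure of a two-stream retweet collection:

* two language communities of unequal size (English larger than Japanese);
* heavy-tailed influencer attractiveness (Pareto weights), so a small core of
  users receives most retweets and monthly top-10 rankings have a persistent
  core;
* stance homophily — each user holds a latent pro-use or anti-use stance and
  retweets a same-stance source with probability ``homophily``;
* a shared URL pool with a per-URL language; URL-bearing retweets come from
  pro-use users (misinformation links travel through the pro-use population);
* cross-lingual adoption: with probability ``crosslingual_share_prob`` a URL
  is also picked up by the other community at a day offset drawn from an
  asymmetric Laplace distribution, so the lead/lag mass is configurable in
  closed form.  Day offsets are the floor of the continuous draw, which
  preserves the sign mass exactly: P(floor(X) < 0) = P(X < 0);
* daily retweet counts that decay geometrically after each community's first
  post, so the peak day coincides with (or lands just after) the first post.

Identical config and seed produce a byte-identical corpus.
"""

from __future__ import annotations

import calendar
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import ald
from .events import RetweetEvent, write_events
from .influence import build_degree_table, influence_ranking
from .stance import ANTI, PRO, StanceLabel

START = datetime(2020, 2, 1, tzinfo=timezone.utc)

_VOCAB = {
    "en": [
        "treatment", "study", "doctor", "zinc", "trial", "horse", "doxycycline",
        "hydroxychloroquine", "vaccine", "india", "ivermectin", "covid", "coronavirus",
    ],
    "ja": [
        "chiryou", "kusuri", "kitasato", "fukusayou", "igaku", "kaigai", "rinshou",
        "shoujou", "kenkyuu", "kowa", "ivermectin", "covid", "coronavirus",
    ],
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults are the bundled study conditions.

    Sizes are scaled so a full corpus generates in seconds: two communities of
    2,000 and 1,000 users observed for 12 months.  ``degree_exponent`` is the
    Pareto tail index of the influencer-attractiveness weights;
    ``ald_location``/``ald_scale``/``ald_asymmetry`` parameterize the
    cross-lingual first-post offset in days (location m, scale 1/λ, asymmetry
    κ; mass below m is κ²/(1+κ²), so the default κ=1.5 yields the substantial
    lead mass seen in cross-community diffusion).
    """

    n_users_en: int = 2000
    n_users_ja: int = 1000
    n_months: int = 12
    degree_exponent: float = 1.1
    n_seed_influencers_per_month: int = 10
    pro_fraction: float = 0.6
    homophily: float = 0.9
    n_urls: int = 500
    url_lang_en_fraction: float = 0.7
    ald_location: float = 0.0
    ald_scale: float = 10.0
    ald_asymmetry: float = 1.5
    crosslingual_share_prob: float = 0.5
    events_per_user_per_month: float = 2.0
    youtube_fraction: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("pro_fraction", "homophily", "url_lang_en_fraction",
                     "crosslingual_share_prob", "youtube_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ald_scale <= 0 or self.ald_asymmetry <= 0:
            raise ValueError("ald_scale and ald_asymmetry must be > 0")
        if self.degree_exponent <= 0:
            raise ValueError("degree_exponent must be > 0")
        for name in ("n_users_en", "n_users_ja", "n_months", "n_urls",
                     "n_seed_influencers_per_month"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.events_per_user_per_month < 0:
            raise ValueError("events_per_user_per_month must be >= 0")
        if self.events_per_user_per_month > 0 and self.n_users_en + self.n_users_ja == 0:
            raise ValueError("zero users with a positive event rate")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


@dataclass
class GroundTruth:
    """Latent state the generator drew: recoverable targets for every stage."""

    stance: dict[str, str]
    user_language: dict[str, str]
    url_language: dict[str, str]
    url_native_first_day: dict[str, int]
    url_offset_days: dict[str, int]
    config: SyntheticConfig


class _Community:
    """Per-community user table with cumulative-weight sampling pools."""

    def __init__(self, lang: str, n: int, cfg: SyntheticConfig, rng: np.random.Generator):
        self.lang = lang
        self.users = np.array([f"{lang}_u{i:05d}" for i in range(n)])
        self.pro = rng.random(n) < cfg.pro_fraction
        self.attract = rng.pareto(cfg.degree_exponent, n) + 1.0 if n else np.array([])
        self.pools = {
            "pro": self._pool(self.pro),
            "anti": self._pool(~self.pro),
            "all": self._pool(np.ones(n, dtype=bool)),
        }

    def _pool(self, mask: np.ndarray):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return None
        cum = np.cumsum(self.attract[idx])
        return idx, cum

    def draw(self, pool: str, k: int, rng: np.random.Generator) -> np.ndarray:
        """k attractiveness-weighted user indices from a stance pool."""
        entry = self.pools[pool] or self.pools["all"]
        idx, cum = entry
        return idx[np.searchsorted(cum, rng.random(k) * cum[-1], side="right").clip(max=idx.size - 1)]

    def draw_sources(self, retweeter_pro: np.ndarray, homophily: float, rng: np.random.Generator) -> np.ndarray:
        """Sources for retweeters with the given stances, honouring homophily."""
        k = retweeter_pro.size
        out = np.empty(k, dtype=np.int64)
        same = rng.random(k) < homophily
        for mask, pool in (
            (same & retweeter_pro, "pro"),
            (same & ~retweeter_pro, "anti"),
            (~same, "all"),
        ):
            m = int(mask.sum())
            if m:
                out[mask] = self.draw(pool, m, rng)
        return out


def _month_spans(n_months: int) -> list[tuple[int, int]]:
    """(start_day_index, length) for each month of the timeline."""
    spans = []
    day = 0
    year, month = START.year, START.month
    for _ in range(n_months):
        length = calendar.monthrange(year, month)[1]
        spans.append((day, length))
        day += length
        month += 1
        if month > 12:
            month, year = 1, year + 1
    return spans


def _texts(lang: str, k: int, rng: np.random.Generator) -> list[str]:
    vocab = _VOCAB[lang]
    weights = 1.0 / np.arange(1, len(vocab) + 1)
    cum = np.cumsum(weights / weights.sum())
    picks = np.searchsorted(cum, rng.random((k, 3)), side="right").clip(max=len(vocab) - 1)
    return [" ".join(vocab[j] for j in row) for row in picks]


def _geometric_series(peak: int, ratio: float = 0.5, max_days: int = 8) -> list[int]:
    counts = []
    for t in range(max_days):
        c = int(peak * ratio**t + 0.5)
        if c < 1:
            break
        counts.append(c)
    return counts or [1]


def generate_corpus(config: SyntheticConfig) -> tuple[list[RetweetEvent], GroundTruth]:
    """Generate a bilingual retweet corpus and its ground truth.

    Events are returned sorted by (timestamp, event id); the same config and
    seed always yield an identical corpus.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    communities = {
        "en": _Community("en", config.n_users_en, config, rng),
        "ja": _Community("ja", config.n_users_ja, config, rng),
    }
    spans = _month_spans(config.n_months)
    total_days = sum(length for _, length in spans) if spans else 0

    events: list[RetweetEvent] = []

    def emit(lang: str, eid: str, day: int, sec: int, retweeter: str, source: str,
             text: str, urls: tuple[str, ...] = ()) -> None:
        ts = START + timedelta(days=int(day), seconds=int(sec))
        events.append(RetweetEvent(eid, ts, str(retweeter), str(source), lang, text, urls))

    # --- background retweets: homophilous, attractiveness-weighted ---
    for lang, com in communities.items():
        n = com.users.size
        if n == 0 or config.events_per_user_per_month == 0:
            continue
        for mi, (day0, length) in enumerate(spans):
            counts = rng.poisson(config.events_per_user_per_month, n)
            total = int(counts.sum())
            if total == 0:
                continue
            retweeters = np.repeat(np.arange(n), counts)
            sources = com.draw_sources(com.pro[retweeters], config.homophily, rng)
            days = day0 + rng.integers(0, length, total)
            secs = rng.integers(0, 86400, total)
            texts = _texts(lang, total, rng)
            for i in range(total):
                emit(lang, f"{lang}-m{mi:02d}-{i:06d}", days[i], secs[i],
                     com.users[retweeters[i]], com.users[sources[i]], texts[i])

    # --- URL diffusion events: pro-use users share misinformation links ---
    url_language: dict[str, str] = {}
    url_native_first_day: dict[str, int] = {}
    url_offset_days: dict[str, int] = {}

    def emit_url_series(com: _Community, url: str, first_day: int, peak: int, tag: str) -> None:
        if com.pools["pro"] is None:
            return
        pro_idx = com.pools["pro"][0]
        counter = 0
        for t, count in enumerate(_geometric_series(peak)):
            retweeters = pro_idx[rng.integers(0, pro_idx.size, count)]
            sources = com.draw("pro", count, rng)
            secs = rng.integers(0, 86400, count)
            for i in range(count):
                raw = url
                decoration = rng.random()
                if decoration < 0.3:
                    raw = url + "?utm_source=twitter&utm_medium=social"
                elif decoration < 0.4:
                    raw = url + "#share"
                emit(com.lang, f"{tag}-{com.lang}-{counter:04d}", first_day + t, secs[i],
                     com.users[retweeters[i]], com.users[sources[i]],
                     f"link {_VOCAB[com.lang][0]}", (raw,))
                counter += 1

    for j in range(config.n_urls):
        lang = "en" if rng.random() < config.url_lang_en_fraction else "ja"
        if rng.random() < config.youtube_fraction:
            url = f"https://youtu.be/vid{j:05d}"
        elif lang == "en":
            url = f"https://news-site-{j % 50:02d}.com/story/{j:05d}"
        else:
            url = f"https://news-site-{j % 50:02d}.jp/kiji/{j:05d}"
        url_language[url] = lang
        native_day = int(rng.integers(0, max(total_days, 1)))
        url_native_first_day[url] = native_day
        native_peak = 3 + int(rng.poisson(2.0))
        emit_url_series(communities[lang], url, native_day, native_peak, f"url{j:05d}")
        if rng.random() < config.crosslingual_share_prob:
            offset = int(np.floor(ald.ald_sample(
                1, config.ald_location, 1.0 / config.ald_scale, config.ald_asymmetry, rng,
            )[0]))
            url_offset_days[url] = offset
            other = communities["ja" if lang == "en" else "en"]
            other_peak = 2 + int(rng.poisson(2.0))
            emit_url_series(other, url, native_day + offset, other_peak, f"url{j:05d}x")

    events.sort(key=lambda e: (e.timestamp, e.event_id))
    truth = GroundTruth(
        stance={
            str(u): (PRO if p else ANTI)
            for com in communities.values()
            for u, p in zip(com.users, com.pro)
        },
        user_language={
            str(u): com.lang for com in communities.values() for u in com.users
        },
        url_language=url_language,
        url_native_first_day=url_native_first_day,
        url_offset_days=url_offset_days,
        config=config,
    )
    return events, truth


def seed_labels_by_degree(
    events: Iterable[RetweetEvent],
    truth: GroundTruth,
    n_per_stance: int = 20,
) -> dict[str, list[StanceLabel]]:
    """Per language: the most influential true-pro and true-anti users as seeds.

    Emulates manual tagging of the most influential accounts: users are ranked
    by full-period unique-retweeter degree and the top ``n_per_stance`` of
    each true stance become hop-0 seeds carrying their true label.
    """
    events = list(events)
    out: dict[str, list[StanceLabel]] = {}
    for lang in ("en", "ja"):
        table = build_degree_table([e for e in events if e.stream_language == lang])
        ranked = sorted(table.degrees.items(), key=lambda kv: (-kv[1], kv[0]))
        seeds: list[StanceLabel] = []
        taken = {PRO: 0, ANTI: 0}
        for user, _ in ranked:
            stance = truth.stance.get(user)
            if stance in taken and taken[stance] < n_per_stance:
                taken[stance] += 1
                seeds.append(StanceLabel(user, stance, hop=0, is_seed=True))
            if all(v >= n_per_stance for v in taken.values()):
                break
        out[lang] = seeds
    return out


def monthly_topk_seed_labels(
    events: Iterable[RetweetEvent],
    truth: GroundTruth,
    k: int | None = None,
) -> dict[str, list[StanceLabel]]:
    """Union of monthly top-k influencers per language, tagged with true stance.

    Mirrors the study design where each month's top influencers are manually
    reviewed; ``k`` defaults to the config's seed-influencer count.
    """
    from .events import partition_by_month

    if k is None:
        k = truth.config.n_seed_influencers_per_month
    events = list(events)
    out: dict[str, list[StanceLabel]] = {}
    for lang in ("en", "ja"):
        seen: dict[str, StanceLabel] = {}
        stream = [e for e in events if e.stream_language == lang]
        for month, bucket in partition_by_month(stream).items():
            ranking = influence_ranking(build_degree_table(bucket, month), k)
            for user in ranking.users:
                if user not in seen:
                    stance = truth.stance.get(user)
                    if stance is not None:
                        seen[user] = StanceLabel(user, stance, hop=0, is_seed=True)
        out[lang] = list(seen.values())
    return out


def write_fixture(
    events: list[RetweetEvent],
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a re-readable fixture: events, ground-truth CSVs, config, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out_dir / "events.jsonl",
        "users": out_dir / "truth_users.csv",
        "urls": out_dir / "truth_urls.csv",
        "config": out_dir / "config.json",
        "manifest": out_dir / "manifest.json",
    }
    write_events(events, paths["events"])
    with paths["users"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("user,language,stance\n")
        for user in sorted(truth.stance):
            fh.write(f"{user},{truth.user_language[user]},{truth.stance[user]}\n")
    with paths["urls"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("url,language,native_first_day,offset_days\n")
        for url in sorted(truth.url_language):
            offset = truth.url_offset_days.get(url)
            fh.write(
                f"{url},{truth.url_language[url]},{truth.url_native_first_day[url]},"
                f"{'' if offset is None else offset}\n"
            )
    paths["config"].write_text(truth.config.to_json() + "\n", encoding="utf-8")
    manifest = {
        "seed": truth.config.rng_seed,
        "config_sha256": truth.config.digest(),
        "n_events": len(events),
        "n_users": len(truth.stance),
        "n_urls": len(truth.url_language),
        "n_crosslingual_urls": len(truth.url_offset_days),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return paths
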