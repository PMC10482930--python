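"""Cross-lingual URL diffusion among pro-use users.

Given stance labels and a native-language map, this module builds per-URL
diffusion records (per-community retweet counts and daily series, restricted
to pro-use users), ranks users by how many distinct non-native-language URLs
they shared, extracts diffusion-timing observations (first-post and peak-day
differences between the URL's own language community and the other one), and
fits the asymmetric Laplace distribution to the day differences.

Day 0 for a URL is its first-post day in the community matching the URL's
language; negative day differences mean the *non-native* community posted (or
peaked) first — the lead phenomenon of interest.  All days are UTC calendar
days.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timezone
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .ald import ALDParams, fit_asymmetric_laplace
from .events import CanonicalUrl, InvalidUrlError, RetweetEvent, normalize_url
from .stance import PRO, StanceLabel

logger = logging.getLogger(__name__)

EN_URL_ADOPTED_BY_JA = "en_url_adopted_by_ja"
JA_URL_ADOPTED_BY_EN = "ja_url_adopted_by_en"

#: Unicode ranges whose presence marks a URL string as Japanese.
_JA_RANGES = (
    (0x3040, 0x30FF),  # hiragana + katakana
    (0x4E00, 0x9FFF),  # CJK unified ideographs
    (0xFF66, 0xFF9D),  # half-width katakana
)

Detector = Callable[[str], str]


def _heuristic_language(url: CanonicalUrl) -> str:
    if url.host.endswith(".jp"):
        return "ja"
    for ch in url.canonical:
        cp = ord(ch)
        if any(lo <= cp <= hi for lo, hi in _JA_RANGES):
            return "ja"
    return "en"


def detect_url_language(
    url: CanonicalUrl,
    detector: Detector | None = None,
    overrides: Mapping[str, str] | None = None,
) -> str:
    """Language of a URL: override table wins, then the pluggable detector,
    then a deterministic heuristic (Japanese codepoints or a ``.jp`` host →
    ``ja``, else ``en``).  A detector result other than en/ja → ``other``.
    """
    if overrides and url.canonical in overrides:
        return overrides[url.canonical]
    if detector is not None:
        code = detector(url.canonical)
        return code if code in ("en", "ja") else "other"
    return _heuristic_language(url)


def build_url_language_table(
    urls: Iterable[CanonicalUrl],
    detector: Detector | None = None,
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Cache of canonical URL → language, applying the precedence rules once."""
    table: dict[str, str] = {}
    for url in urls:
        if url.canonical not in table:
            table[url.canonical] = detect_url_language(url, detector, overrides)
    return table


@dataclass(slots=True)
class UrlDiffusionRecord:
    """Per-URL diffusion summary among pro-use users of each community."""

    url: CanonicalUrl
    url_language: str
    daily_series_en: dict[date, int] = field(default_factory=dict)
    daily_series_ja: dict[date, int] = field(default_factory=dict)

    def series(self, community: str) -> dict[date, int]:
        return self.daily_series_en if community == "en" else self.daily_series_ja

    @property
    def retweets_en(self) -> int:
        return sum(self.daily_series_en.values())

    @property
    def retweets_ja(self) -> int:
        return sum(self.daily_series_ja.values())

    @property
    def first_post_day_en(self) -> date | None:
        return min(self.daily_series_en) if self.daily_series_en else None

    @property
    def first_post_day_ja(self) -> date | None:
        return min(self.daily_series_ja) if self.daily_series_ja else None

    @property
    def shared(self) -> bool:
        return bool(self.daily_series_en) and bool(self.daily_series_ja)


@dataclass(frozen=True, slots=True)
class TimingObservation:
    """Day differences for one URL posted by pro-use users of both communities.

    Negative values mean the non-native community posted (peaked) before the
    URL's own language community first posted it.
    """

    url: str
    direction: str
    day_diff_first: int
    day_diff_peak: int
    is_youtube: bool = False


def build_url_records(
    events: Iterable[RetweetEvent],
    labels: Mapping[str, StanceLabel],
    language_map: Mapping[str, str],
    url_languages: Mapping[str, str] | None = None,
    detector: Detector | None = None,
    overrides: Mapping[str, str] | None = None,
) -> list[UrlDiffusionRecord]:
    """Per-URL per-community daily retweet series among pro-use users.

    Only events whose retweeter is labelled pro-use are counted; the community
    is the retweeter's native language.  Unparseable URLs are logged and
    skipped.  Records are returned sorted by canonical URL.  If
    ``url_languages`` is not given, languages are resolved via the detector /
    override / heuristic precedence of :func:`detect_url_language`.
    """
    records: dict[str, UrlDiffusionRecord] = {}
    for e in events:
        lab = labels.get(e.retweeter_id)
        if lab is None or lab.stance != PRO:
            continue
        community = language_map.get(e.retweeter_id)
        if community not in ("en", "ja"):
            continue
        day = e.timestamp.astimezone(timezone.utc).date()
        for raw in e.urls:
            try:
                cu = normalize_url(raw)
            except InvalidUrlError:
                logger.info("skipping unparseable URL %r in event %s", raw, e.event_id)
                continue
            rec = records.get(cu.canonical)
            if rec is None:
                rec = UrlDiffusionRecord(url=cu, url_language="")
                records[cu.canonical] = rec
            series = rec.series(community)
            series[day] = series.get(day, 0) + 1
    for canonical, rec in records.items():
        if url_languages is not None and canonical in url_languages:
            rec.url_language = url_languages[canonical]
        else:
            rec.url_language = detect_url_language(rec.url, detector, overrides)
    return [records[c] for c in sorted(records)]


def nonnative_share_ranking(
    events: Iterable[RetweetEvent],
    labels: Mapping[str, StanceLabel],
    language_map: Mapping[str, str],
    url_languages: Mapping[str, str],
    degrees: Mapping[str, int],
    top_n: int = 200,
) -> pd.DataFrame:
    """Pro-use users ranked by distinct non-native-language URLs shared.

    A non-native URL is one whose language is en/ja and differs from the
    user's native language; URLs of language ``other`` are ignored.  The
    full-period unique-retweeter ``degrees`` table supplies each user's
    influence and degree rank.  Ties in URL count break lexicographically.
    """
    user_urls: dict[str, set[str]] = {}
    for e in events:
        lab = labels.get(e.retweeter_id)
        if lab is None or lab.stance != PRO:
            continue
        native = language_map.get(e.retweeter_id)
        if native not in ("en", "ja"):
            continue
        for raw in e.urls:
            try:
                cu = normalize_url(raw)
            except InvalidUrlError:
                continue
            lang = url_languages.get(cu.canonical)
            if lang in ("en", "ja") and lang != native:
                user_urls.setdefault(e.retweeter_id, set()).add(cu.canonical)

    degree_rank = {
        u: i + 1
        for i, (u, _) in enumerate(sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0])))
    }
    rows = sorted(
        ((u, len(urls)) for u, urls in user_urls.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )[:top_n]
    return pd.DataFrame(
        {
            "user": [u for u, _ in rows],
            "native_language": [language_map[u] for u, _ in rows],
            "n_nonnative_urls": [n for _, n in rows],
            "degree": [degrees.get(u, 0) for u, _ in rows],
            "degree_rank": [degree_rank.get(u) for u, _ in rows],
        }
    )


def smooth_series(values: Sequence[float], smoothing: float = 0.0) -> np.ndarray:
    """Cubic smoothing spline evaluated at the input positions.

    ``smoothing`` is scipy's residual-sum-of-squares budget ``s``; 0 gives an
    interpolating spline that reproduces the input.  Fewer than 4 points are
    returned unchanged with a warning.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 4:
        warnings.warn("smooth_series needs >= 4 points; returning input unchanged")
        return y.copy()
    x = np.arange(y.size, dtype=float)
    spline = UnivariateSpline(x, y, k=3, s=float(smoothing))
    return spline(x)


def timing_observations(
    records: Iterable[UrlDiffusionRecord],
    youtube_excluded: bool = True,
) -> list[TimingObservation]:
    """Diffusion-timing day differences for URLs shared by both communities.

    Day 0 is the first-post day in the URL's own language community.
    ``day_diff_first`` is the other community's first-post day minus day 0;
    ``day_diff_peak`` uses the earliest day attaining the maximum of the other
    community's daily series.  URLs of language ``other`` or present in only
    one community are skipped; YouTube URLs are dropped first when
    ``youtube_excluded`` (their apparent language follows the viewer's
    location, not the content).
    """
    out: list[TimingObservation] = []
    for rec in records:
        if rec.url_language not in ("en", "ja") or not rec.shared:
            continue
        if youtube_excluded and rec.url.is_youtube:
            continue
        native = rec.url_language
        nonnative = "ja" if native == "en" else "en"
        day0 = min(rec.series(native))
        nn_series = rec.series(nonnative)
        nn_first = min(nn_series)
        peak_count = max(nn_series.values())
        nn_peak = min(d for d, c in nn_series.items() if c == peak_count)
        out.append(
            TimingObservation(
                url=rec.url.canonical,
                direction=EN_URL_ADOPTED_BY_JA if native == "en" else JA_URL_ADOPTED_BY_EN,
                day_diff_first=(nn_first - day0).days,
                day_diff_peak=(nn_peak - day0).days,
                is_youtube=rec.url.is_youtube,
            )
        )
    return out


@dataclass(frozen=True, slots=True)
class NegativeMass:
    """Empirical share of negative day differences, with the model-implied mass."""

    empirical: float
    model: float | None = None


def negative_mass(
    observations: Sequence[int] | Sequence[TimingObservation],
    params: ALDParams | None = None,
    which: str = "day_diff_first",
) -> NegativeMass:
    """Fraction of day differences below zero, plus the fitted model's F(0)."""
    values = [
        getattr(o, which) if isinstance(o, TimingObservation) else o for o in observations
    ]
    if not values:
        raise ValueError("need at least one observation")
    empirical = sum(1 for v in values if v < 0) / len(values)
    model = params.negative_mass() if params is not None else None
    return NegativeMass(empirical=empirical, model=model)


def fit_timing_distribution(observations: Sequence[TimingObservation], which: str = "day_diff_first") -> ALDParams:
    """Asymmetric Laplace MLE on one timing series (first-post or peak)."""
    return fit_asymmetric_laplace([getattr(o, which) for o in observations])
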