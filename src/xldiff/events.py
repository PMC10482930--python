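"""Retweet event data model, file I/O, URL canonicalization, and partitioning.

A corpus is a flat sequence of :class:`RetweetEvent` records, one per retweet,
collected from two language streams (English and Japanese).  This module owns
everything that happens before analysis: reading/writing event files (JSONL or
CSV), normalizing shared URLs so that the same article posted with different
tracking parameters collides to one canonical form, assigning each user a
native language from the streams they appear in, and splitting the corpus into
UTC calendar months.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import parse_qsl, urlencode, urlsplit, urlunsplit

logger = logging.getLogger(__name__)

#: The two collection streams / language communities.
LANGUAGES = ("en", "ja")

#: Hosts treated as YouTube for the exclusion flag in the timing analysis.
YOUTUBE_HOSTS = frozenset({"youtube.com", "www.youtube.com", "m.youtube.com", "youtu.be"})

#: Tracking query parameters stripped during URL canonicalization, in addition
#: to any parameter whose name starts with ``utm_``.
TRACKING_PARAMS = frozenset({"fbclid", "gclid"})

_REQUIRED_FIELDS = ("event_id", "timestamp", "retweeter_id", "source_user_id", "stream_language")

# bare host like "example.com/path" without a scheme
_BARE_HOST_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9.-]*\.[A-Za-z]{2,}([/?#]|$)")


class EventParseError(ValueError):
    """A malformed row in an event file; message names the field and line."""


class InvalidUrlError(ValueError):
    """A raw URL string with no parseable host; excluded from URL analyses."""


@dataclass(frozen=True, slots=True)
class RetweetEvent:
    """One retweet: who retweeted whom, when, in which stream, with which URLs.

    Self-retweets (``retweeter_id == source_user_id``) are kept in the event
    stream but contribute nothing to unique-retweeter degree.
    """

    event_id: str
    timestamp: datetime
    retweeter_id: str
    source_user_id: str
    stream_language: str
    text: str = ""
    urls: tuple[str, ...] = ()


@dataclass(frozen=True, slots=True)
class CanonicalUrl:
    """A normalized URL; ``canonical`` is idempotent under :func:`normalize_url`."""

    canonical: str
    host: str
    is_youtube: bool


def _parse_timestamp(value: str, line: int | None = None) -> datetime:
    try:
        ts = datetime.fromisoformat(str(value))
    except (TypeError, ValueError) as exc:
        raise EventParseError(f"unparseable timestamp {value!r}" + _at(line)) from exc
    if ts.tzinfo is None:
        # naive timestamps are taken to be UTC (the collection API's clock)
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _at(line: int | None) -> str:
    return f" at line {line}" if line is not None else ""


def _event_from_record(rec: Mapping[str, object], line: int) -> RetweetEvent:
    for field in _REQUIRED_FIELDS:
        if field not in rec or rec[field] in (None, ""):
            raise EventParseError(f"missing required field {field!r}{_at(line)}")
    lang = str(rec["stream_language"])
    if lang not in LANGUAGES:
        raise EventParseError(f"unknown stream_language {lang!r}{_at(line)}")
    urls = rec.get("urls") or ()
    if isinstance(urls, str):
        urls = tuple(u for u in urls.split("|") if u)
    else:
        urls = tuple(str(u) for u in urls)
    return RetweetEvent(
        event_id=str(rec["event_id"]),
        timestamp=_parse_timestamp(str(rec["timestamp"]), line),
        retweeter_id=str(rec["retweeter_id"]),
        source_user_id=str(rec["source_user_id"]),
        stream_language=lang,
        text=str(rec.get("text") or ""),
        urls=urls,
    )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"unknown event file format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".json", ".ndjson"):
        return "jsonl"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer event file format from {path.name!r}; pass format=")


def read_events(path: str | Path, format: str | None = None) -> list[RetweetEvent]:
    """Read retweet events from a JSONL or CSV file, preserving file order.

    Raises :class:`EventParseError` naming the offending field and line for
    malformed rows; an empty file yields an empty list.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    events: list[RetweetEvent] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise EventParseError(f"invalid JSON{_at(line_no)}") from exc
                events.append(_event_from_record(rec, line_no))
        else:
            reader = csv.DictReader(fh)
            # data rows start after the header
            for line_no, rec in enumerate(reader, start=2):
                events.append(_event_from_record(rec, line_no))
    return events


def write_events(events: Iterable[RetweetEvent], path: str | Path, format: str | None = None) -> Path:
    """Write events to JSONL (URLs as a JSON array) or CSV (pipe-delimited URLs)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for e in events:
                rec = {
                    "event_id": e.event_id,
                    "timestamp": e.timestamp.astimezone(timezone.utc).isoformat(),
                    "retweeter_id": e.retweeter_id,
                    "source_user_id": e.source_user_id,
                    "stream_language": e.stream_language,
                    "text": e.text,
                    "urls": list(e.urls),
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        else:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(list(_REQUIRED_FIELDS) + ["text", "urls"])
            for e in events:
                writer.writerow(
                    [
                        e.event_id,
                        e.timestamp.astimezone(timezone.utc).isoformat(),
                        e.retweeter_id,
                        e.source_user_id,
                        e.stream_language,
                        e.text,
                        "|".join(e.urls),
                    ]
                )
    return path


def normalize_url(raw: str) -> CanonicalUrl:
    """Canonicalize a raw URL string.

    Rules: scheme and host lowercased; fragment removed; tracking parameters
    (``utm_*``, ``fbclid``, ``gclid``) removed while other query parameters
    keep their original order; trailing slashes on a bare path (one with no
    remaining query) removed.  Scheme-less strings that start with a plausible
    host ("example.com/a") are accepted with an ``https`` scheme.

    Raises :class:`InvalidUrlError` if no host can be parsed.
    """
    s = (raw or "").strip()
    if not s:
        raise InvalidUrlError("empty URL")
    parts = urlsplit(s)
    if not parts.netloc and _BARE_HOST_RE.match(s):
        parts = urlsplit("https://" + s)
    try:
        host = parts.hostname
    except ValueError as exc:  # e.g. invalid port
        raise InvalidUrlError(f"unparseable host in {raw!r}") from exc
    if not parts.netloc or not host:
        raise InvalidUrlError(f"no parseable host in {raw!r}")
    scheme = (parts.scheme or "https").lower()
    netloc = parts.netloc.lower()
    pairs = [
        (k, v)
        for k, v in parse_qsl(parts.query, keep_blank_values=True)
        if not k.lower().startswith("utm_") and k.lower() not in TRACKING_PARAMS
    ]
    query = urlencode(pairs)
    path = parts.path
    if not query and path.endswith("/"):
        path = path.rstrip("/")
    canonical = urlunsplit((scheme, netloc, path, query, ""))
    return CanonicalUrl(canonical=canonical, host=host, is_youtube=host in YOUTUBE_HOSTS)


def assign_native_language(events: Iterable[RetweetEvent]) -> dict[str, str]:
    """Assign every user appearing in any event exactly one native language.

    A user seen in only one stream gets that stream's language.  A user seen
    in both gets the language of the majority of their events; an exact tie is
    broken by the language of their earliest event, and a tie on timestamp
    resolves to English.  Deterministic.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    earliest: dict[str, tuple[datetime, int]] = {}
    for e in events:
        lang_rank = LANGUAGES.index(e.stream_language)
        key = (e.timestamp, lang_rank)
        for uid in {e.retweeter_id, e.source_user_id}:
            counts[uid][e.stream_language] += 1
            if uid not in earliest or key < earliest[uid]:
                earliest[uid] = key
    out: dict[str, str] = {}
    for uid, c in counts.items():
        if c["en"] != c["ja"]:
            out[uid] = "en" if c["en"] > c["ja"] else "ja"
        else:
            out[uid] = LANGUAGES[earliest[uid][1]]
    return out


def month_key(ts: datetime) -> str:
    """UTC calendar year-month key, e.g. ``"2021-08"``."""
    t = ts.astimezone(timezone.utc)
    return f"{t.year:04d}-{t.month:02d}"


def partition_by_month(events: Iterable[RetweetEvent]) -> dict[str, list[RetweetEvent]]:
    """Bucket events by UTC calendar month; keys sorted, buckets in input order."""
    buckets: dict[str, list[RetweetEvent]] = defaultdict(list)
    for e in events:
        buckets[month_key(e.timestamp)].append(e)
    return dict(sorted(buckets.items()))
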