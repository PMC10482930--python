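"""Event I/O, URL canonicalization, native-language assignment, partitioning."""

from datetime import datetime, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xldiff import (
    EventParseError,
    InvalidUrlError,
    assign_native_language,
    normalize_url,
    partition_by_month,
    read_events,
    write_events,
)

from conftest import ev


class TestReadWrite:
    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_round_trip_preserves_all_fields_and_order(self, tmp_path, fmt):
        events = [
            ev("e1", "2021-03-01T10:00:00+00:00", "u1", "u2", "en", "zinc study", ["https://a.com/x"]),
            ev("e2", "2021-03-01T11:00:00+00:00", "u3", "u2", "ja", "薬の話", ["https://b.jp/y", "https://c.com"]),
            ev("e3", "2021-03-02T09:00:00+00:00", "u1", "u1", "en", "", []),
        ]
        path = tmp_path / f"events.{fmt}"
        write_events(events, path)
        assert read_events(path) == events

    def test_empty_file_yields_empty_sequence(self, tmp_path):
        path = tmp_path / "events.jsonl"
        path.write_text("")
        assert read_events(path) == []

    def test_missing_field_names_field_and_line(self, tmp_path):
        path = tmp_path / "events.jsonl"
        path.write_text(
            '{"event_id":"e1","timestamp":"2021-01-01T00:00:00","retweeter_id":"a","source_user_id":"b","stream_language":"en"}\n'
            '{"event_id":"e2","timestamp":"2021-01-01T00:00:00","retweeter_id":"a","stream_language":"en"}\n'
        )
        with pytest.raises(EventParseError, match="source_user_id.*line 2"):
            read_events(path)

    def test_unparseable_timestamp_is_hard_error(self, tmp_path):
        path = tmp_path / "events.jsonl"
        path.write_text(
            '{"event_id":"e1","timestamp":"not-a-date","retweeter_id":"a","source_user_id":"b","stream_language":"en"}\n'
        )
        with pytest.raises(EventParseError, match="timestamp"):
            read_events(path)

    def test_unknown_stream_language_is_hard_error(self, tmp_path):
        path = tmp_path / "events.jsonl"
        path.write_text(
            '{"event_id":"e1","timestamp":"2021-01-01T00:00:00","retweeter_id":"a","source_user_id":"b","stream_language":"de"}\n'
        )
        with pytest.raises(EventParseError, match="stream_language"):
            read_events(path)


class TestNormalizeUrl:
    def test_lowercases_strips_tracking_and_fragment_and_trailing_slash(self):
        cu = normalize_url("HTTPS://Example.com/a/?utm_source=x#frag")
        assert cu.canonical == "https://example.com/a"
        assert cu.host == "example.com"
        assert not cu.is_youtube

    @pytest.mark.parametrize(
        "raw", ["https://youtu.be/abc", "https://www.youtube.com/watch?v=abc", "https://m.youtube.com/x"]
    )
    def test_youtube_hosts_flagged(self, raw):
        assert normalize_url(raw).is_youtube

    def test_non_tracking_query_preserved_in_order(self):
        cu = normalize_url("https://example.com/a?page=2")
        assert cu.canonical == "https://example.com/a?page=2"
        cu2 = normalize_url("https://example.com/a?b=1&a=2&utm_campaign=x&fbclid=zz")
        assert cu2.canonical == "https://example.com/a?b=1&a=2"

    def test_scheme_less_host_accepted(self):
        cu = normalize_url("starpolitical.com/some-report/")
        assert cu.canonical == "https://starpolitical.com/some-report"

    @pytest.mark.parametrize("raw", ["", "   ", "not a url", "http://", "???"])
    def test_no_parseable_host_raises(self, raw):
        with pytest.raises(InvalidUrlError):
            normalize_url(raw)

    @given(
        scheme=st.sampled_from(["http", "HTTPS", "https"]),
        host=st.from_regex(r"[a-zA-Z][a-zA-Z0-9\-]{0,10}\.(com|jp|org|co\.uk)", fullmatch=True),
        path=st.lists(st.from_regex(r"[a-zA-Z0-9\-._~%]{0,8}", fullmatch=True), max_size=4),
        params=st.lists(
            st.tuples(
                st.from_regex(r"[a-zA-Z][a-zA-Z0-9_]{0,6}", fullmatch=True),
                st.from_regex(r"[a-zA-Z0-9 +/=\-]{0,8}", fullmatch=True),
            ),
            max_size=4,
        ),
        fragment=st.sampled_from(["", "frag", "x=1"]),
        slash=st.booleans(),
    )
    @settings(max_examples=1000, derandomize=True, deadline=None)
    def test_idempotent_on_fuzzed_urls(self, scheme, host, path, params, fragment, slash):
        from urllib.parse import urlencode

        raw = f"{scheme}://{host}/" + "/".join(path)
        if slash:
            raw += "/"
        if params:
            raw += "?" + urlencode(params)
        if fragment:
            raw += "#" + fragment
        once = normalize_url(raw)
        twice = normalize_url(once.canonical)
        assert twice == once


class TestNativeLanguage:
    def test_single_stream_user_gets_that_language(self):
        events = [ev(f"e{i}", f"2021-01-0{i+1}T00:00:00", "u1", "v", "ja") for i in range(5)]
        assert assign_native_language(events)["u1"] == "ja"

    def test_majority_wins(self):
        events = [ev(f"e{i}", f"2021-01-0{i+1}T00:00:00", "u1", "v", "en") for i in range(3)]
        events.append(ev("e9", "2021-02-01T00:00:00", "u1", "w", "ja"))
        assert assign_native_language(events)["u1"] == "en"

    def test_exact_tie_takes_earliest_events_language(self):
        events = [
            ev("e1", "2021-01-01T00:00:00", "u1", "v", "ja"),
            ev("e2", "2021-01-02T00:00:00", "u1", "v", "en"),
            ev("e3", "2021-01-03T00:00:00", "u1", "v", "ja"),
            ev("e4", "2021-01-04T00:00:00", "u1", "v", "en"),
        ]
        assert assign_native_language(events)["u1"] == "ja"

    def test_tie_on_timestamp_resolves_to_english(self):
        events = [
            ev("e1", "2021-01-01T00:00:00", "u1", "v", "ja"),
            ev("e2", "2021-01-01T00:00:00", "u1", "w", "en"),
        ]
        assert assign_native_language(events)["u1"] == "en"

    def test_sources_are_assigned_too(self):
        events = [ev("e1", "2021-01-01T00:00:00", "u1", "v", "en")]
        assert assign_native_language(events) == {"u1": "en", "v": "en"}

    def test_empty_input_gives_empty_map(self):
        assert assign_native_language([]) == {}


class TestPartitionByMonth:
    def test_utc_month_boundary_splits_buckets(self):
        a = ev("e1", "2021-08-31T23:59:00+00:00", "u", "v")
        b = ev("e2", "2021-09-01T00:00:00+00:00", "u", "v")
        buckets = partition_by_month([a, b])
        assert list(buckets) == ["2021-08", "2021-09"]
        assert buckets["2021-08"] == [a] and buckets["2021-09"] == [b]

    def test_non_utc_timestamps_bucket_by_utc(self):
        # 09:00+09:00 on Sep 1 is still August in UTC
        a = ev("e1", datetime(2021, 9, 1, 8, 59, tzinfo=timezone.utc).astimezone(), "u", "v")
        e = ev("e2", "2021-09-01T08:59:00+09:00", "u", "v")
        assert list(partition_by_month([e])) == ["2021-08"]

    def test_partition_conserves_events(self, small_corpus):
        events, _ = small_corpus
        buckets = partition_by_month(events)
        assert sum(len(b) for b in buckets.values()) == len(events)
        assert sorted(e for b in buckets.values() for e in (x.event_id for x in b)) == sorted(
            e.event_id for e in events
        )
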