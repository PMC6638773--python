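"""Corpus parsing, URL tokenisation, cleaning and location filtering."""

import json
from datetime import datetime, timezone

import numpy as np
import pytest

from symptweet.corpus_io import (
    BotRuleSet,
    RegionSpec,
    Tweet,
    clean_corpus,
    filter_location,
    load_corpus,
    parse_timestamp,
    replace_urls,
)


def _write_jsonl(path, records):
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


class TestLoadCorpus:
    def test_identity_parse(self, tmp_path):
        recs = [
            {"id": "1", "text": "wheezing again", "timestamp": "2016-06-15T10:00:00Z"},
            {"id": "2", "text": "lovely day", "timestamp": "2016-06-15T11:00:00Z"},
            {"id": "3", "text": "chest hurts", "timestamp": "2016-06-15T12:00:00Z"},
        ]
        path = tmp_path / "c.jsonl"
        _write_jsonl(path, recs)
        tweets = load_corpus(path)
        assert [t.id for t in tweets] == ["1", "2", "3"]
        assert tweets[0].text == "wheezing again"

    def test_missing_text_skipped(self, tmp_path):
        recs = [
            {"id": "1", "text": "ok", "timestamp": "2016-06-15T10:00:00Z"},
            {"id": "2", "timestamp": "2016-06-15T11:00:00Z"},
        ]
        path = tmp_path / "c.jsonl"
        _write_jsonl(path, recs)
        assert len(load_corpus(path)) == 1

    def test_timestamp_formats_normalised_utc(self, tmp_path):
        # ISO with offset and epoch seconds must agree with independent parsing
        iso = "2016-06-15T12:30:00+02:00"
        epoch = 1466000000
        path = tmp_path / "c.jsonl"
        _write_jsonl(
            path,
            [
                {"id": "1", "text": "a", "timestamp": iso},
                {"id": "2", "text": "b", "timestamp": epoch},
            ],
        )
        tweets = load_corpus(path)
        expect_iso = datetime.fromisoformat(iso).astimezone(timezone.utc)
        expect_epoch = datetime.fromtimestamp(epoch, tz=timezone.utc)
        assert tweets[0].timestamp == expect_iso
        assert tweets[1].timestamp == expect_epoch
        assert all(t.timestamp.tzinfo is not None for t in tweets)

    def test_twitter_created_at_format(self):
        dt = parse_timestamp("Wed Sep 23 20:06:35 +0000 2015")
        assert (dt.year, dt.month, dt.hour) == (2015, 9, 20)

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,text,timestamp\n1,hello,2016-06-15T10:00:00Z\n")
        tweets = load_corpus(path)
        assert tweets[0].text == "hello"


class TestReplaceUrls:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("wheezing all day http://t.co/abc", "wheezing all day <URL>"),
            ("no links here", "no links here"),
            ("see https://example.org/x and t.co/yz too", "see <URL> and <URL> too"),
        ],
    )
    def test_examples(self, text, expected):
        assert replace_urls(text) == expected

    def test_url_variants_collapse_to_equal_strings(self):
        # Two texts differing only in their URLs become identical.
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b = (f"http://t.co/{rng.integers(10**8)}" for _ in range(2))
            assert replace_urls(f"chest tight {a}") == replace_urls(f"chest tight {b}")


def _tweet(i, text, user=None, ts="2016-06-15T10:00:00Z", source=None):
    return Tweet(
        id=str(i), text=text, timestamp=parse_timestamp(ts), user_id=user, source=source
    )


class TestCleanCorpus:
    def test_retweet_removed(self):
        a = _tweet(1, "my asthma is bad today")
        rt = _tweet(2, "RT my asthma is bad today")
        cleaned, report = clean_corpus([a, rt])
        assert [t.id for t in cleaned] == ["1"]
        assert report.n_retweets_removed == 1

    def test_same_text_different_urls_deduplicated(self):
        a = _tweet(1, "wheezy http://t.co/aaa")
        b = _tweet(2, "wheezy http://t.co/bbb")
        cleaned, report = clean_corpus([a, b])
        assert [t.id for t in cleaned] == ["1"]
        assert report.n_duplicates_removed == 1
        assert cleaned[0].text == "wheezy <URL>"

    def test_first_occurrence_survives(self):
        tweets = [_tweet(i, "same text") for i in range(5)]
        cleaned, _ = clean_corpus(tweets)
        assert [t.id for t in cleaned] == ["0"]

    def test_per_user_same_day_keeps_first(self):
        a = _tweet(1, "one", user="u", ts="2016-06-15T08:00:00Z")
        b = _tweet(2, "two", user="u", ts="2016-06-15T20:00:00Z")
        c = _tweet(3, "three", user="u", ts="2016-06-16T08:00:00Z")
        cleaned, report = clean_corpus([a, b, c])
        assert [t.id for t in cleaned] == ["1", "3"]
        assert report.n_user_day_removed == 1

    def test_source_blocklist_bot_removed(self):
        a = _tweet(1, "air quality report http://x.com/1", source="twitterfeed")
        b = _tweet(2, "my chest hurts", user="u1")
        cleaned, report = clean_corpus([a, b])
        assert [t.id for t in cleaned] == ["2"]
        assert report.n_bots_removed == 1

    def test_high_volume_user_removed(self):
        flood = [
            _tweet(i, f"spam {i}", user="bot", ts=f"2016-06-15T{i:02d}:00:00Z")
            for i in range(12)
        ]
        keeper = _tweet(99, "real post", user="human")
        cleaned, report = clean_corpus(flood + [keeper])
        assert [t.id for t in cleaned] == ["99"]
        # 11 fall to the same-day rule, the remaining one to the volume rule
        assert report.n_user_day_removed + report.n_bots_removed == 12

    def test_report_matches_injections(self, small_corpus):
        tweets, ann = small_corpus
        cleaned, report = clean_corpus(tweets)
        assert report.n_retweets_removed == len(ann["retweets"])
        assert report.n_duplicates_removed == len(ann["duplicates"])
        assert report.n_bots_removed == len(ann["bots"])
        assert {t.id for t in cleaned} == set(ann["base_ids"])

    def test_idempotent(self, small_corpus):
        tweets, _ = small_corpus
        once, _ = clean_corpus(tweets)
        twice, report2 = clean_corpus(once)
        assert [t.id for t in twice] == [t.id for t in once]
        assert [t.text for t in twice] == [t.text for t in once]
        assert report2.n_output == report2.n_input

    def test_counts_reconcile_and_shrink(self, small_corpus):
        tweets, _ = small_corpus
        cleaned, report = clean_corpus(tweets)
        assert len(cleaned) <= len(tweets)
        report.check()

    def test_empty_input(self):
        cleaned, report = clean_corpus([])
        assert cleaned == [] and report.n_input == report.n_output == 0


class TestFilterLocation:
    uk = RegionSpec.uk_default()

    def test_uk_timezone_retained(self):
        t = _tweet(1, "x")
        t = Tweet(**{**t.__dict__, "timezone_name": "London"})
        assert filter_location([t], self.uk) == [t]

    def test_foreign_coordinates_dropped(self):
        t = Tweet(
            id="1", text="x", timestamp=parse_timestamp("2016-06-15T10:00:00Z"),
            coordinates=(48.85, 2.35),
        )
        assert filter_location([t], self.uk) == []

    def test_no_geo_fields_respects_switch(self):
        t = _tweet(1, "x")
        assert filter_location([t], self.uk) == [t]
        strict = RegionSpec.uk_default(keep_missing=False)
        assert filter_location([t], strict) == []

    def test_random_geo_assignment_matches_rule_oracle(self):
        # 1000 posts with random geo fields; retention must equal a direct
        # re-application of the "any populated field matches" rule.
        rng = np.random.default_rng(42)
        region = self.uk
        tweets, expected = [], []
        for i in range(1000):
            tz = rng.choice([None, "London", "Paris", "Eastern Time"])
            country = rng.choice([None, "GB", "FR"])
            coords = None
            if rng.random() < 0.3:
                coords = (float(rng.uniform(40, 65)), float(rng.uniform(-10, 5)))
            t = Tweet(
                id=str(i), text="x", timestamp=parse_timestamp("2016-06-15T10:00:00Z"),
                timezone_name=tz, place_country=country, coordinates=coords,
            )
            tweets.append(t)
            fields = []
            if tz is not None:
                fields.append(tz.lower() in region.timezones)
            if country is not None:
                fields.append(country.lower() in region.countries)
            if coords is not None:
                la, lo = coords
                b = region.bbox
                fields.append(b[0] <= la <= b[1] and b[2] <= lo <= b[3])
            expected.append(any(fields) if fields else region.keep_missing)
        kept = set(t.id for t in filter_location(tweets, region))
        assert kept == {t.id for t, e in zip(tweets, expected) if e}
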