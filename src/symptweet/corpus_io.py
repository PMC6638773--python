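"""Corpus input/output and stream cleaning.

Short-post corpora arrive as line-delimited JSON or CSV with at least
``id``, ``text`` and ``timestamp`` per record.  Before any classification the
raw stream is cleaned: URLs are collapsed to a ``<URL>`` token, retweets and
exact-text duplicates are dropped, repeated same-day posts by one user are
reduced to the first, and bot/news accounts are removed by configurable
heuristics.  Duplication removal matters for surveillance because repeated
text would otherwise register as a false signal.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

URL_TOKEN = "<URL>"

# http(s) URLs, or bare domain-with-path (e.g. "t.co/abc", "bbc.co.uk/news/1").
_URL_RE = re.compile(
    r"""(?:https?://\S+)|(?:\bwww\.\S+)|(?:\b[a-z0-9-]+(?:\.[a-z0-9-]+)+/\S+)""",
    re.IGNORECASE,
)

_FIRST_PERSON = frozenset({"i", "me", "my", "mine", "we", "us", "our", "i'm", "im", "i've"})


@dataclass
class Tweet:
    """One post with the attributes the pipeline consumes."""

    id: str
    text: str
    timestamp: datetime
    user_id: str | None = None
    timezone_name: str | None = None
    place_country: str | None = None
    coordinates: tuple[float, float] | None = None  # (lat, lon)
    source: str | None = None
    is_retweet: bool = False
    label: str | None = None  # optional attached label ("relevant"/"irrelevant")

    def with_text(self, text: str) -> "Tweet":
        return replace(self, text=text)


@dataclass
class CleanReport:
    """Accounting of what cleaning removed; counts reconcile exactly."""

    n_input: int = 0
    n_retweets_removed: int = 0
    n_duplicates_removed: int = 0
    n_user_day_removed: int = 0
    n_bots_removed: int = 0
    n_location_removed: int = 0
    n_output: int = 0

    def check(self) -> None:
        removed = (
            self.n_retweets_removed
            + self.n_duplicates_removed
            + self.n_user_day_removed
            + self.n_bots_removed
            + self.n_location_removed
        )
        assert self.n_output == self.n_input - removed, "clean report does not reconcile"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class BotRuleSet:
    """Heuristics for bot/news accounts.

    ``source_blocklist``: posts whose client/source matches are dropped.
    ``max_posts_per_day``: users exceeding this many posts in a UTC calendar
    day have all their posts dropped.
    ``url_without_first_person``: optionally drop posts that carry a URL but
    no first-person pronoun (typical of headline feeds).  Off by default:
    genuine symptomatic posts can share links too.
    """

    source_blocklist: frozenset[str] = frozenset({"twitterfeed", "dlvr.it", "ifttt"})
    max_posts_per_day: int = 10
    url_without_first_person: bool = False


@dataclass
class RegionSpec:
    """Coarse geographic filter: accepted timezones, countries and a
    lat/lon bounding box (lat_min, lat_max, lon_min, lon_max)."""

    timezones: frozenset[str] = frozenset()
    countries: frozenset[str] = frozenset()
    bbox: tuple[float, float, float, float] | None = None
    keep_missing: bool = True  # retain posts with no geo fields at all

    @classmethod
    def uk_default(cls, keep_missing: bool = True) -> "RegionSpec":
        return cls(
            timezones=frozenset({"london", "edinburgh", "europe/london", "dublin", "casablanca"}),
            countries=frozenset({"gb", "uk", "united kingdom", "great britain"}),
            bbox=(49.8, 60.9, -8.7, 1.8),
            keep_missing=keep_missing,
        )


def parse_timestamp(value) -> datetime:
    """Parse ISO-8601 strings, Twitter's ``created_at`` format or epoch
    seconds into a timezone-aware UTC datetime."""
    if isinstance(value, datetime):
        dt = value
    elif isinstance(value, (int, float)):
        dt = datetime.fromtimestamp(float(value), tz=timezone.utc)
    elif isinstance(value, str):
        s = value.strip()
        if re.fullmatch(r"\d{9,13}(\.\d+)?", s):
            num = float(s)
            if num > 1e12:  # epoch milliseconds
                num /= 1000.0
            dt = datetime.fromtimestamp(num, tz=timezone.utc)
        else:
            try:
                dt = datetime.fromisoformat(s.replace("Z", "+00:00"))
            except ValueError:
                # Twitter classic: "Wed Sep 23 20:06:35 +0000 2015"
                dt = datetime.strptime(s, "%a %b %d %H:%M:%S %z %Y")
    else:
        raise ValueError(f"unparseable timestamp: {value!r}")
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def _record_to_tweet(rec: dict) -> Tweet:
    coords = rec.get("coordinates")
    if coords is not None:
        try:
            lat, lon = float(coords[0]), float(coords[1])
            coords = (lat, lon)
        except (TypeError, ValueError, IndexError):
            logger.warning("malformed coordinates %r treated as absent", coords)
            coords = None
    return Tweet(
        id=str(rec["id"]),
        text=str(rec["text"]),
        timestamp=parse_timestamp(rec["timestamp"]),
        user_id=None if rec.get("user_id") in (None, "") else str(rec["user_id"]),
        timezone_name=rec.get("timezone") or None,
        place_country=rec.get("place_country") or None,
        coordinates=coords,
        source=rec.get("source") or None,
        is_retweet=bool(rec.get("is_retweet", False)),
        label=rec.get("label") or None,
    )


def load_corpus(path: str | Path, format: str | None = None) -> list[Tweet]:
    """Read a corpus from JSONL or CSV.  Records missing a mandatory field
    (id, text, timestamp) are skipped with a warning; input order is kept."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format: {format}")

    tweets: list[Tweet] = []
    n_malformed = 0
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    if not all(k in rec and rec[k] not in (None, "") for k in ("id", "text", "timestamp")):
                        raise KeyError("missing mandatory field")
                    tweets.append(_record_to_tweet(rec))
                except Exception as exc:  # malformed record: skip, keep going
                    n_malformed += 1
                    logger.warning("skipping malformed record at line %d: %s", lineno, exc)
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            for lineno, rec in enumerate(csv.DictReader(fh), 1):
                try:
                    if not all(rec.get(k) for k in ("id", "text", "timestamp")):
                        raise KeyError("missing mandatory field")
                    if rec.get("coordinates"):
                        rec = dict(rec)
                        rec["coordinates"] = rec["coordinates"].split()
                    else:
                        rec = {k: v for k, v in rec.items() if k != "coordinates"}
                    tweets.append(_record_to_tweet(rec))
                except Exception as exc:
                    n_malformed += 1
                    logger.warning("skipping malformed CSV record %d: %s", lineno, exc)
    if n_malformed:
        logger.warning("%d malformed records skipped from %s", n_malformed, path)
    return tweets


def save_corpus(tweets: Iterable[Tweet], path: str | Path) -> None:
    """Write tweets as JSONL (ISO timestamps, only populated fields)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            rec = {"id": t.id, "text": t.text, "timestamp": t.timestamp.isoformat()}
            for key, val in (
                ("user_id", t.user_id),
                ("timezone", t.timezone_name),
                ("place_country", t.place_country),
                ("source", t.source),
                ("label", t.label),
            ):
                if val is not None:
                    rec[key] = val
            if t.coordinates is not None:
                rec["coordinates"] = list(t.coordinates)
            if t.is_retweet:
                rec["is_retweet"] = True
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def load_labels(path: str | Path) -> dict[str, str]:
    """Read an ``id,label`` CSV into a mapping."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            labels[str(rec["id"])] = rec["label"].strip().lower()
    return labels


def replace_urls(text: str) -> str:
    """Replace every URL substring with the literal token ``<URL>``."""
    return _URL_RE.sub(URL_TOKEN, text)


def _dup_key(text: str) -> str:
    """Duplicate key: lowercased, URL-tokenised, whitespace-collapsed text."""
    return " ".join(replace_urls(text).lower().split())


def clean_corpus(
    tweets: Sequence[Tweet],
    bot_rules: BotRuleSet | None = None,
) -> tuple[list[Tweet], CleanReport]:
    """Clean a parsed stream.

    Removes, in order: retweets ("RT " prefix or retweet marker), exact-text
    duplicates computed after URL tokenisation (first occurrence survives),
    repeated same-day posts per user beyond the first, and bot/news posts
    per ``bot_rules``.  All surviving texts have URLs tokenised.  Idempotent.
    """
    if bot_rules is None:
        bot_rules = BotRuleSet()
    report = CleanReport(n_input=len(tweets))

    # Pass 1: retweets.
    survivors: list[Tweet] = []
    for t in tweets:
        if t.is_retweet or t.text.startswith("RT ") or t.text.startswith("RT@"):
            report.n_retweets_removed += 1
        else:
            survivors.append(t)

    # Pass 2: exact-text duplicates on the URL-tokenised key.
    seen: set[str] = set()
    deduped: list[Tweet] = []
    for t in survivors:
        key = _dup_key(t.text)
        if key in seen:
            report.n_duplicates_removed += 1
        else:
            seen.add(key)
            deduped.append(t)

    # Pass 3: per-user same-calendar-day repeats (UTC date); keep the first.
    seen_user_day: set[tuple[str, str]] = set()
    user_day_kept: list[Tweet] = []
    for t in deduped:
        if t.user_id is None:
            user_day_kept.append(t)
            continue
        key = (t.user_id, t.timestamp.date().isoformat())
        if key in seen_user_day:
            report.n_user_day_removed += 1
        else:
            seen_user_day.add(key)
            user_day_kept.append(t)

    # Pass 4: bot/news heuristics.
    posts_per_user_day: dict[tuple[str, str], int] = {}
    for t in tweets:
        if t.user_id is not None:
            k = (t.user_id, t.timestamp.date().isoformat())
            posts_per_user_day[k] = posts_per_user_day.get(k, 0) + 1

    cleaned: list[Tweet] = []
    for t in user_day_kept:
        drop = False
        if t.source is not None and t.source.lower() in bot_rules.source_blocklist:
            drop = True
        elif (
            t.user_id is not None
            and posts_per_user_day.get((t.user_id, t.timestamp.date().isoformat()), 0)
            > bot_rules.max_posts_per_day
        ):
            drop = True
        elif bot_rules.url_without_first_person:
            tokenised = replace_urls(t.text)
            if URL_TOKEN in tokenised:
                words = {w.strip(".,!?:;\"'").lower() for w in tokenised.split()}
                if not (words & _FIRST_PERSON):
                    drop = True
        if drop:
            report.n_bots_removed += 1
        else:
            cleaned.append(t.with_text(replace_urls(t.text)))

    report.n_output = len(cleaned)
    report.check()
    return cleaned, report


def filter_location(tweets: Sequence[Tweet], region: RegionSpec) -> list[Tweet]:
    """Retain a tweet iff at least one populated geo field (timezone,
    country, coordinates) matches the region; tweets with no geo fields are
    kept or dropped per ``region.keep_missing``."""
    kept: list[Tweet] = []
    for t in tweets:
        has_any = False
        match = False
        if t.timezone_name:
            has_any = True
            if t.timezone_name.strip().lower() in region.timezones:
                match = True
        if t.place_country:
            has_any = True
            if t.place_country.strip().lower() in region.countries:
                match = True
        if t.coordinates is not None:
            has_any = True
            if region.bbox is not None:
                lat, lon = t.coordinates
                lat_min, lat_max, lon_min, lon_max = region.bbox
                if lat_min <= lat <= lat_max and lon_min <= lon <= lon_max:
                    match = True
        if (has_any and match) or (not has_any and region.keep_missing):
            kept.append(t)
    return kept
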