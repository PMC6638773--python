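"""Synthetic corpora and paired tweet-stream/health-series fixtures.

No real social-media or health-service data ships with this package, so
every downstream module is exercised on generated data with recorded ground
truth.  The generator emulates the study conditions this package
operationalises: a ~23% relevant class prior, laughter present in ~3.9% of
posts and negative emojis in ~5.5% (with the negative-emoji posts heavily
relevant), duplicate/retweet/bot/URL contamination for the cleaner, and a
paired daily stream whose relevant-post counts share a controllable
correlation with a reference health-indicator series.

Posts are bag-of-words token sequences (8-25 tokens), not grammatical
English: relevant posts over-draw from a symptomatic vocabulary rich in
first-person and negative-sentiment words; irrelevant posts are a mixture
of casual chatter and "awareness" posts that mention symptom words next to
news vocabulary — the hard case for relevance filtering.  Because the
emission model is known, the Bayes-optimal posterior is computable in
closed form and bounds every learner from above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import Tweet, save_corpus
from .learners import IRRELEVANT, RELEVANT

# Class-conditional token-list defaults.  Relevant posts use symptomatic,
# first-person, negative-toned words; irrelevant class-specific words skew
# news/awareness.  Shared words are class-neutral filler.
RELEVANT_VOCAB = (
    "asthma attack chest tight wheeze wheezing cough inhaler breathe cant "
    "sick ill awful terrible bad hate my have feel awake bed night hospital cold"
).split()
IRRELEVANT_VOCAB = (
    "pollution health air quality news report study research awareness campaign "
    "forecast article government levels city smog charity week children schools"
).split()
SHARED_VOCAB = (
    "the a to and of in is it on for with this that so at be im just today day "
    "out up all get go now really about"
).split()

_LAUGHTER_INJECT = ("lol", "haha", "😂", "lmao")
_NEGEMOJI_INJECT = ("😷", "😭", "😢", ":'(")


@dataclass(frozen=True)
class CorpusSpec:
    """Generating conditions for a labelled corpus.

    The emoji/laughter rates are class-conditional presence probabilities
    chosen so the marginal prevalences echo the observed distributions
    (negative emojis in ~5.5% of posts, ~75% of those relevant; laughter in
    ~3.9%) at a 23% relevant prior.
    """

    n_tweets: int = 1000
    relevant_fraction: float = 0.23
    vocab_relevant: tuple[str, ...] = tuple(RELEVANT_VOCAB)
    vocab_irrelevant: tuple[str, ...] = tuple(IRRELEVANT_VOCAB)
    vocab_shared: tuple[str, ...] = tuple(SHARED_VOCAB)
    class_token_rate: float = 0.4  # P(token from class vocab | casual post)
    awareness_rate: float = 0.35   # P(awareness subtype | irrelevant)
    awareness_symptom_rate: float = 0.2  # P(token from relevant vocab | awareness)
    awareness_news_rate: float = 0.3     # P(token from irrelevant vocab | awareness)
    laughter_rate_by_class: tuple[float, float] = (0.054, 0.035)  # (relevant, irrelevant)
    negemoji_rate_by_class: tuple[float, float] = (0.179, 0.018)
    dup_rate: float = 0.05
    rt_rate: float = 0.05
    bot_rate: float = 0.02
    url_rate: float = 0.15
    n_days: int = 30
    start_date: str = "2016-06-15"
    seed: int = 0

    def __post_init__(self):
        for p in (
            self.relevant_fraction, self.class_token_rate, self.awareness_rate,
            self.awareness_symptom_rate, self.awareness_news_rate,
            *self.laughter_rate_by_class, *self.negemoji_rate_by_class,
            self.dup_rate, self.rt_rate, self.bot_rate, self.url_rate,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.relevant_fraction > 0 and not self.vocab_relevant:
            raise ValueError("relevant posts requested but relevant vocabulary is empty")
        if self.relevant_fraction < 1 and not self.vocab_irrelevant:
            raise ValueError("irrelevant posts requested but irrelevant vocabulary is empty")


@dataclass(frozen=True)
class PairedStreamSpec:
    """Generating conditions for a paired (post stream, health series).

    ``rho`` is the construction correlation between the daily relevant-post
    count and the health indicator: the indicator is built as an affine
    combination of the standardised realised relevant counts (weight rho)
    and independent noise (weight sqrt(1-rho^2)), plus measurement noise of
    ``noise_sd``.  Irrelevant chatter is overlaid with its own independent
    day-to-day fluctuation, which is what relevance filtering removes.
    """

    n_days: int = 77
    baseline_rate: float = 120.0     # mean relevant posts/day
    irrelevant_rate: float = 500.0   # mean irrelevant posts/day
    rate_fluctuation: float = 0.35   # day-to-day relative sd of the relevant rate
    chatter_fluctuation: float = 0.5 # day-to-day relative sd of irrelevant volume
    trend: float = 1.0               # per-day multiplicative drift of both rates
    rho: float = 0.4
    health_baseline: float = 50.0
    health_scale: float = 12.0
    noise_sd: float = 1.0
    start_date: str = "2016-06-15"
    seed: int = 0

    def __post_init__(self):
        if not (-1 <= self.rho <= 1):
            raise ValueError("rho must lie in [-1, 1]")
        if self.baseline_rate <= 0 or self.irrelevant_rate < 0:
            raise ValueError("rates must be positive")


# ---------------------------------------------------------------------------
# Corpus generation.
# ---------------------------------------------------------------------------


def _draw_tokens(rng: np.random.Generator, spec: CorpusSpec, label: str, aware: bool) -> list[str]:
    length = int(rng.integers(8, 26))
    tokens = []
    for _ in range(length):
        u = rng.random()
        if label == RELEVANT:
            pool = spec.vocab_relevant if u < spec.class_token_rate else spec.vocab_shared
        elif aware:
            if u < spec.awareness_symptom_rate:
                pool = spec.vocab_relevant
            elif u < spec.awareness_symptom_rate + spec.awareness_news_rate:
                pool = spec.vocab_irrelevant
            else:
                pool = spec.vocab_shared
        else:
            pool = spec.vocab_irrelevant if u < spec.class_token_rate else spec.vocab_shared
        tokens.append(pool[int(rng.integers(len(pool)))])
    return tokens


def generate_corpus(spec: CorpusSpec) -> tuple[list[Tweet], dict]:
    """Generate a labelled corpus plus ground-truth annotations.

    Annotations record every injection so downstream modules can be scored
    without re-deriving truth: ``labels`` (id -> class), ``duplicates``,
    ``retweets``, ``bots`` (ids the cleaner should remove), ``has_url``,
    ``has_laughter``, ``has_negemoji`` id lists, and the spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    start = datetime.fromisoformat(spec.start_date).replace(tzinfo=timezone.utc)

    tweets: list[Tweet] = []
    ann: dict = {
        "labels": {}, "duplicates": [], "retweets": [], "bots": [],
        "has_url": [], "has_laughter": [], "has_negemoji": [], "base_ids": [],
    }

    def stamp() -> datetime:
        day = int(rng.integers(spec.n_days))
        sec = int(rng.integers(86400))
        return start + timedelta(days=day, seconds=sec)

    for i in range(spec.n_tweets):
        label = RELEVANT if rng.random() < spec.relevant_fraction else IRRELEVANT
        aware = label == IRRELEVANT and rng.random() < spec.awareness_rate
        tokens = _draw_tokens(rng, spec, label, aware)
        cls_idx = 0 if label == RELEVANT else 1
        tid = f"t{i:06d}"
        if rng.random() < spec.laughter_rate_by_class[cls_idx]:
            tokens.append(_LAUGHTER_INJECT[int(rng.integers(len(_LAUGHTER_INJECT)))])
            ann["has_laughter"].append(tid)
        if rng.random() < spec.negemoji_rate_by_class[cls_idx]:
            tokens.append(_NEGEMOJI_INJECT[int(rng.integers(len(_NEGEMOJI_INJECT)))])
            ann["has_negemoji"].append(tid)
        if rng.random() < spec.url_rate:
            tokens.append(f"http://t.co/{rng.integers(10**8):08d}")
            ann["has_url"].append(tid)
        tweets.append(
            Tweet(id=tid, text=" ".join(tokens), timestamp=stamp(), user_id=f"u{i:06d}", label=label)
        )
        ann["labels"][tid] = label
        ann["base_ids"].append(tid)

    n_base = len(tweets)

    # Duplicate injections: same text, any URL swapped for a fresh one.
    for k in range(int(round(spec.dup_rate * spec.n_tweets))):
        src = tweets[int(rng.integers(n_base))]
        text = src.text
        if "http://t.co/" in text:
            head, _, _ = text.rpartition("http://t.co/")
            text = f"{head}http://t.co/{rng.integers(10**8):08d}"
        tid = f"dup{k:05d}"
        tweets.append(
            Tweet(id=tid, text=text, timestamp=src.timestamp + timedelta(hours=1),
                  user_id=f"ud{k:05d}", label=src.label)
        )
        ann["duplicates"].append(tid)
        ann["labels"][tid] = src.label

    # Retweet injections.
    for k in range(int(round(spec.rt_rate * spec.n_tweets))):
        src = tweets[int(rng.integers(n_base))]
        tid = f"rt{k:05d}"
        tweets.append(
            Tweet(id=tid, text="RT " + src.text, timestamp=src.timestamp + timedelta(hours=2),
                  user_id=f"ur{k:05d}", label=src.label)
        )
        ann["retweets"].append(tid)
        ann["labels"][tid] = src.label

    # Bot injections: headline-feed posts flagged by their source client,
    # one per bot user-day so only the source heuristic removes them.
    for k in range(int(round(spec.bot_rate * spec.n_tweets))):
        tokens = _draw_tokens(rng, spec, IRRELEVANT, aware=True)
        tokens.append(f"http://t.co/{rng.integers(10**8):08d}")
        tid = f"bot{k:05d}"
        tweets.append(
            Tweet(id=tid, text=" ".join(tokens), timestamp=stamp(),
                  user_id=f"ub{k:05d}", source="twitterfeed", label=IRRELEVANT)
        )
        ann["bots"].append(tid)
        ann["labels"][tid] = IRRELEVANT

    ann["spec"] = spec
    return tweets, ann


# ---------------------------------------------------------------------------
# Closed-form Bayes-optimal classification under the generating model.
# ---------------------------------------------------------------------------


def _log_multinomial(tokens: Sequence[str], spec: CorpusSpec, weights: dict[str, float]) -> float:
    """Sum of per-token log emission probabilities for one mixture
    component.  Tokens outside all three vocabularies (e.g. URLs) carry no
    information and are skipped; a vocabulary token the component cannot
    emit makes the component impossible (-inf)."""
    union = set(spec.vocab_relevant) | set(spec.vocab_irrelevant) | set(spec.vocab_shared)
    probs: dict[str, float] = {}
    for pool_name, w in weights.items():
        pool = getattr(spec, pool_name)
        for tok in pool:
            probs[tok] = probs.get(tok, 0.0) + w / len(pool)
    ll = 0.0
    for tok in tokens:
        if tok not in union:
            continue
        p = probs.get(tok, 0.0)
        if p <= 0:
            return -math.inf
        ll += math.log(p)
    return ll


def bayes_posterior_relevant(text: str, spec: CorpusSpec) -> float:
    """P(relevant | text) under the exact generating model (token emission
    mixture plus the two class-conditional binary injections)."""
    tokens = text.split()
    has_laugh = any(t in _LAUGHTER_INJECT for t in tokens)
    has_neg = any(t in _NEGEMOJI_INJECT for t in tokens)
    word_tokens = [t for t in tokens if t not in _LAUGHTER_INJECT and t not in _NEGEMOJI_INJECT]

    ll_rel = _log_multinomial(
        word_tokens, spec,
        {"vocab_relevant": spec.class_token_rate, "vocab_shared": 1 - spec.class_token_rate},
    )
    ll_casual = _log_multinomial(
        word_tokens, spec,
        {"vocab_irrelevant": spec.class_token_rate, "vocab_shared": 1 - spec.class_token_rate},
    )
    ll_aware = _log_multinomial(
        word_tokens, spec,
        {
            "vocab_relevant": spec.awareness_symptom_rate,
            "vocab_irrelevant": spec.awareness_news_rate,
            "vocab_shared": 1 - spec.awareness_symptom_rate - spec.awareness_news_rate,
        },
    )
    a = spec.awareness_rate
    ll_irr = np.logaddexp(
        math.log(a) + ll_aware if a > 0 else -np.inf,
        math.log(1 - a) + ll_casual if a < 1 else -np.inf,
    )

    def bern(p: float, present: bool) -> float:
        p = min(max(p, 1e-12), 1 - 1e-12)
        return math.log(p) if present else math.log(1 - p)

    ll_rel += bern(spec.laughter_rate_by_class[0], has_laugh)
    ll_rel += bern(spec.negemoji_rate_by_class[0], has_neg)
    ll_irr += bern(spec.laughter_rate_by_class[1], has_laugh)
    ll_irr += bern(spec.negemoji_rate_by_class[1], has_neg)

    pi = spec.relevant_fraction
    if pi <= 0:
        return 0.0
    if pi >= 1:
        return 1.0
    log_odds = (math.log(pi) + ll_rel) - (math.log(1 - pi) + ll_irr)
    if log_odds > 700:
        return 1.0
    if log_odds < -700:
        return 0.0
    return float(1.0 / (1.0 + math.exp(-log_odds)))


def bayes_optimal_labels(texts: Sequence[str], spec: CorpusSpec) -> list[str]:
    return [
        RELEVANT if bayes_posterior_relevant(t, spec) >= 0.5 else IRRELEVANT for t in texts
    ]


# ---------------------------------------------------------------------------
# Paired stream / health-indicator generation.
# ---------------------------------------------------------------------------


def generate_paired_stream(spec: PairedStreamSpec) -> tuple[list[Tweet], pd.Series, dict]:
    """Generate a labelled daily post stream and a correlated health series.

    Returns (tweets, health series, truth).  Truth holds the daily relevant
    and total counts and the latent relevant rate, keyed by date.
    """
    rng = np.random.default_rng(spec.seed)
    start = datetime.fromisoformat(spec.start_date).replace(tzinfo=timezone.utc)
    dates = pd.date_range(start.date(), periods=spec.n_days, freq="D")

    drift = spec.trend ** np.arange(spec.n_days)
    rel_rate = spec.baseline_rate * drift * np.maximum(
        0.05, 1 + spec.rate_fluctuation * rng.standard_normal(spec.n_days)
    )
    irr_rate = spec.irrelevant_rate * drift * np.maximum(
        0.05, 1 + spec.chatter_fluctuation * rng.standard_normal(spec.n_days)
    )
    n_rel = rng.poisson(rel_rate)
    n_irr = rng.poisson(irr_rate)

    z = (n_rel - n_rel.mean()) / max(n_rel.std(), 1e-9)
    g = rng.standard_normal(spec.n_days)
    e = rng.standard_normal(spec.n_days)
    health = (
        spec.health_baseline
        + spec.health_scale * (spec.rho * z + math.sqrt(max(0.0, 1 - spec.rho**2)) * g)
        + spec.noise_sd * e
    )
    health_series = pd.Series(health, index=dates, name="health")

    tweets: list[Tweet] = []
    counter = 0
    for d in range(spec.n_days):
        for label, count in ((RELEVANT, int(n_rel[d])), (IRRELEVANT, int(n_irr[d]))):
            pool = RELEVANT_VOCAB if label == RELEVANT else IRRELEVANT_VOCAB
            for _ in range(count):
                ts = start + timedelta(days=d, seconds=int(rng.integers(86400)))
                word = pool[int(rng.integers(len(pool)))]
                tweets.append(
                    Tweet(
                        id=f"s{counter:07d}",
                        text=f"{word} {SHARED_VOCAB[int(rng.integers(len(SHARED_VOCAB)))]}",
                        timestamp=ts,
                        user_id=f"su{counter:07d}",
                        label=label,
                    )
                )
                counter += 1

    truth = {
        "dates": [d.date().isoformat() for d in dates],
        "n_relevant": n_rel.tolist(),
        "n_total": (n_rel + n_irr).tolist(),
        "relevant_rate": rel_rate.tolist(),
        "spec": spec,
    }
    return tweets, health_series, truth


# ---------------------------------------------------------------------------
# Packaged deterministic fixtures.
# ---------------------------------------------------------------------------

FIXTURE_SPECS: dict[str, object] = {
    # 200 posts with all contamination types, for unit tests of the cleaner.
    "small_labelled": CorpusSpec(n_tweets=200, seed=20150923),
    # 500 labelled + 8000 unlabelled posts emulating the semi-supervised
    # working set (the study assimilated ~8000 previously unlabelled posts).
    "semisup_benchmark": (
        CorpusSpec(n_tweets=500, dup_rate=0, rt_rate=0, bot_rate=0, seed=20160615),
        CorpusSpec(n_tweets=8000, dup_rate=0, rt_rate=0, bot_rate=0, seed=20160616),
    ),
    # June-August-length paired stream at the reference correlation 0.4.
    "stream_77d": PairedStreamSpec(n_days=77, rho=0.4, seed=20160630),
}


def get_fixture(name: str):
    """Deterministic in-memory fixture.

    ``small_labelled`` -> (tweets, annotations);
    ``semisup_benchmark`` -> (labelled tweets, labelled ann, unlabelled
    tweets, unlabelled ann); ``stream_77d`` -> (tweets, health, truth).
    """
    if name not in FIXTURE_SPECS:
        raise KeyError(f"unknown fixture: {name!r}")
    spec = FIXTURE_SPECS[name]
    if name == "small_labelled":
        return generate_corpus(spec)
    if name == "semisup_benchmark":
        lab_spec, unlab_spec = spec
        lab, lab_ann = generate_corpus(lab_spec)
        unlab, unlab_ann = generate_corpus(unlab_spec)
        return lab, lab_ann, unlab, unlab_ann
    return generate_paired_stream(spec)


def packaged_fixture(name: str, out_dir: str | Path) -> list[Path]:
    """Write a fixture to disk (JSONL corpora, CSV labels/series); returns
    the paths.  Same name twice -> byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def write_labels(tweets: Sequence[Tweet], path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id,label\n")
            for t in tweets:
                fh.write(f"{t.id},{t.label}\n")

    if name == "small_labelled":
        tweets, _ = get_fixture(name)
        save_corpus(tweets, out / "small_labelled.jsonl")
        write_labels(tweets, out / "small_labelled_labels.csv")
        paths = [out / "small_labelled.jsonl", out / "small_labelled_labels.csv"]
    elif name == "semisup_benchmark":
        lab, _, unlab, _ = get_fixture(name)
        save_corpus(lab, out / "benchmark_labelled.jsonl")
        write_labels(lab, out / "benchmark_labels.csv")
        unlab_hidden = [
            Tweet(id=t.id, text=t.text, timestamp=t.timestamp, user_id=t.user_id)
            for t in unlab
        ]
        save_corpus(unlab_hidden, out / "benchmark_unlabelled.jsonl")
        paths = [
            out / "benchmark_labelled.jsonl",
            out / "benchmark_labels.csv",
            out / "benchmark_unlabelled.jsonl",
        ]
    elif name == "stream_77d":
        tweets, health, _ = get_fixture(name)
        save_corpus(tweets, out / "stream_77d.jsonl")
        from .signals import save_series

        save_series(health, out / "stream_77d_health.csv", value_name="health")
        paths = [out / "stream_77d.jsonl", out / "stream_77d_health.csv"]
    else:
        raise KeyError(f"unknown fixture: {name!r}")
    return paths
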