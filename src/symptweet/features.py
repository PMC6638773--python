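"""Compound feature extraction.

Each post is represented by a dictionary-backed feature vector: the union of
word-level n-gram weights over a training-set vocabulary and four custom
feature groups — per-class word-class counts, positive/negative word counts,
a binary laughter indicator and a binary negative-emoji/emoticon indicator.
Two overlapping projections of that vector form the co-training views:
the "taxonomical" view (n-grams + word classes + the two binaries) and the
"sentimental" view (n-grams + pos/neg counts + the two binaries).

Feature names are prefixed by group so views and ablation can select blocks:
``ng:`` n-grams, ``wc:`` word classes, ``sent:`` sentiment counts and
``tone:`` the two binaries.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus_io import URL_TOKEN
from .lexicons import Lexicons, lemmatize

logger = logging.getLogger(__name__)

FeatureVector = dict[str, float]

NGRAM_PREFIX = "ng:"
WORDCLASS_PREFIX = "wc:"
POS_COUNT = "sent:pos"
NEG_COUNT = "sent:neg"
LAUGHTER = "tone:laughter"
NEG_EMOJI = "tone:negemoji"

CUSTOM_BLOCKS = {
    "word_classes": lambda name: name.startswith(WORDCLASS_PREFIX),
    "posneg_counts": lambda name: name in (POS_COUNT, NEG_COUNT),
    "denotes_laughter": lambda name: name == LAUGHTER,
    "negative_emoji": lambda name: name == NEG_EMOJI,
    "ngrams": lambda name: name.startswith(NGRAM_PREFIX),
}

# ---------------------------------------------------------------------------
# Tokenisation: emoticons and emojis survive as standalone tokens, words are
# lowercased and lemmatised, the <URL> token is preserved, and punctuation
# that is not part of an emoticon is dropped.
# ---------------------------------------------------------------------------

# Western emoticons (:-) :'( ;p D: etc.) plus a small kaomoji set.  Emoticons
# whose "eyes" are letters or digits (xD, 8), D:) only match on their own so
# that ordinary words ("expo") are never split.
_EMOTICON_PATTERN = (
    r"(?:"
    r"[:;=][-'^o\*]?[)(\]\[dDpP/\\|oO3cC*]"          # punctuation eyes
    r"|(?<![A-Za-z0-9])[8xX][-'^o\*]?[)(\]\[dDpP|oO3cC*]"  # letter/digit eyes
    r"|(?:(?<![A-Za-z0-9])[dD]|[)(\]\[])[-'^o\*]?[:;=8]"   # reversed faces
    r"|\([To;wn\^_oO0]+[_.o][To;wn\^_oO0]+\)"        # (T_T) (;_;) (ToT)
    r"|\^_\^"
    r"|<3(?![0-9])"
    r")(?![A-Za-z])"
)
_EMOTICON_RE = re.compile(_EMOTICON_PATTERN)

# Unicode emoji blocks (pictographs, transport, supplemental, flags, misc
# symbols) plus the variation selector handled separately.
_EMOJI_RE = re.compile(
    "["
    "\U0001F300-\U0001F5FF"
    "\U0001F600-\U0001F64F"
    "\U0001F680-\U0001F6FF"
    "\U0001F700-\U0001F77F"
    "\U0001F900-\U0001FAFF"
    "\U00002600-\U000027BF"
    "\U0001F1E6-\U0001F1FF"
    "\U00002B00-\U00002BFF"
    "\U0001F000-\U0001F0FF"
    "]️?"
)

_WORD_RE = re.compile(r"[a-zA-Z][a-zA-Z']*")

_SPLIT_RE = re.compile(
    "(?:{})|(?:{})|(?:{})".format(re.escape(URL_TOKEN), _EMOJI_RE.pattern, _EMOTICON_PATTERN)
)


def extract_emoticons(text: str) -> list[str]:
    """All emoticon substrings, in order (regex inventory, not exhaustive)."""
    return _EMOTICON_RE.findall(text)


def extract_emojis(text: str) -> list[str]:
    """All emoji code points in the text, in order."""
    return _EMOJI_RE.findall(text)


def tokenize(text: str, lexicons: Lexicons | None = None) -> list[str]:
    """Split cleaned text into lemmatised word tokens, keeping emojis,
    emoticons and the ``<URL>`` token as standalone tokens."""
    known = lexicons.known_lemmas if lexicons is not None else None
    tokens: list[str] = []
    pos = 0
    for m in _SPLIT_RE.finditer(text):
        chunk = text[pos : m.start()]
        tokens.extend(lemmatize(w, known) for w in _WORD_RE.findall(chunk))
        tokens.append(m.group(0))
        pos = m.end()
    tokens.extend(lemmatize(w, known) for w in _WORD_RE.findall(text[pos:]))
    return tokens


# ---------------------------------------------------------------------------
# Vocabulary of n-grams over the training texts.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Vocabulary:
    """Ordered n-gram vocabulary built from training texts only."""

    terms: tuple[str, ...]
    n_range: tuple[int, int] = (1, 2)
    min_doc_freq: int = 2

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._term_set

    @property
    def _term_set(self) -> frozenset[str]:
        # cached lazily on the instance
        s = self.__dict__.get("_terms_cache")
        if s is None:
            s = frozenset(self.terms)
            object.__setattr__(self, "_terms_cache", s)
        return s


def iter_ngrams(tokens: Sequence[str], n_range: tuple[int, int]) -> Iterable[str]:
    lo, hi = n_range
    for n in range(lo, hi + 1):
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i : i + n])


def build_vocabulary(
    token_lists: Sequence[Sequence[str]],
    n_range: tuple[int, int] = (1, 2),
    min_doc_freq: int = 2,
) -> Vocabulary:
    """All n-grams whose document frequency meets ``min_doc_freq``, in
    deterministic (sorted) order."""
    if not token_lists:
        logger.warning("building vocabulary from an empty corpus")
        return Vocabulary(terms=(), n_range=n_range, min_doc_freq=min_doc_freq)
    df: Counter[str] = Counter()
    for tokens in token_lists:
        df.update(set(iter_ngrams(tokens, n_range)))
    terms = tuple(sorted(t for t, c in df.items() if c >= min_doc_freq))
    return Vocabulary(terms=terms, n_range=n_range, min_doc_freq=min_doc_freq)


# ---------------------------------------------------------------------------
# Custom features.
# ---------------------------------------------------------------------------


def word_class_counts(tokens: Sequence[str], lexicons: Lexicons) -> dict[str, int]:
    """Occurrences per word class.  Multi-word members (e.g. "runny nose")
    are matched on token bigrams."""
    bigrams = [" ".join(tokens[i : i + 2]) for i in range(len(tokens) - 1)]
    counts: dict[str, int] = {}
    for name, members in lexicons.word_classes.items():
        c = sum(1 for t in tokens if t in members)
        c += sum(1 for b in bigrams if b in members)
        counts[name] = c
    return counts


def posneg_counts(tokens: Sequence[str], lexicons: Lexicons) -> tuple[int, int]:
    """Counts of positive- and negative-dictionary tokens; words in neither
    dictionary are not counted."""
    pos = sum(1 for t in tokens if t in lexicons.positive_words)
    neg = sum(1 for t in tokens if t in lexicons.negative_words)
    return pos, neg


def denotes_laughter(text: str, tokens: Sequence[str], lexicons: Lexicons) -> int:
    """1 iff the post contains a laughter emoji/emoticon or laughter slang
    (lol, lmao, ...), matched case-insensitively on token boundaries."""
    lowered = [t.lower() for t in tokens]
    if any(t in lexicons.laughter_tokens for t in lowered):
        return 1
    for emo in extract_emoticons(text) + extract_emojis(text):
        if emo.lower() in lexicons.laughter_tokens:
            return 1
    return 0


def negative_emoji(text: str, lexicons: Lexicons) -> int:
    """1 iff the post contains a negative (ill/sad/angry) emoji or emoticon."""
    for emo in extract_emoticons(text) + extract_emojis(text):
        if emo.lower() in lexicons.negative_emoticons:
            return 1
    # direct scan catches list members the regex inventory may miss
    lowered = text.lower()
    return int(any(tok in lowered for tok in lexicons.negative_emoticons if len(tok) > 1))


# ---------------------------------------------------------------------------
# Compound vector and views.
# ---------------------------------------------------------------------------


def build_vector(
    text: str,
    vocabulary: Vocabulary,
    lexicons: Lexicons,
    tokens: Sequence[str] | None = None,
    binary_ngrams: bool = False,
) -> FeatureVector:
    """The full compound feature vector for one post (zero-valued n-gram
    entries are omitted from the mapping; custom features always present)."""
    if tokens is None:
        tokens = tokenize(text, lexicons)
    vec: FeatureVector = {}
    gram_counts = Counter(g for g in iter_ngrams(tokens, vocabulary.n_range) if g in vocabulary)
    for g, c in gram_counts.items():
        vec[NGRAM_PREFIX + g] = 1.0 if binary_ngrams else float(c)
    for name, c in word_class_counts(tokens, lexicons).items():
        vec[WORDCLASS_PREFIX + name] = float(c)
    pos, neg = posneg_counts(tokens, lexicons)
    vec[POS_COUNT] = float(pos)
    vec[NEG_COUNT] = float(neg)
    vec[LAUGHTER] = float(denotes_laughter(text, tokens, lexicons))
    vec[NEG_EMOJI] = float(negative_emoji(text, lexicons))
    return vec


def featurize_corpus(
    texts: Sequence[str],
    vocabulary: Vocabulary,
    lexicons: Lexicons,
    binary_ngrams: bool = False,
) -> list[FeatureVector]:
    return [build_vector(t, vocabulary, lexicons, binary_ngrams=binary_ngrams) for t in texts]


def build_views(vec: FeatureVector) -> tuple[FeatureVector, FeatureVector]:
    """Project the compound vector onto the two co-training views.

    View 1 (taxonomical) keeps n-grams, word classes and the two tone
    binaries; view 2 (sentimental) keeps n-grams, pos/neg counts and the two
    tone binaries.  Their union is the full vector.
    """
    x1 = {
        k: v
        for k, v in vec.items()
        if not (k == POS_COUNT or k == NEG_COUNT)
    }
    x2 = {k: v for k, v in vec.items() if not k.startswith(WORDCLASS_PREFIX)}
    return x1, x2


def drop_block(vec: FeatureVector, block: str) -> FeatureVector:
    """Remove one named feature block (for ablation)."""
    pred = CUSTOM_BLOCKS[block]
    return {k: v for k, v in vec.items() if not pred(k)}
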