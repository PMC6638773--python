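"""Lexicons backing the compound features.

Five word classes (Infection, Possession, Concern, Humour, Symptomatic),
positive/negative sentiment dictionaries, laughter tokens (slang, emojis,
smiling emoticons) and negative emojis/emoticons (ill/sad/angry faces).
The word lists ship as editable plain-text data files; the two emoji lists
are curated stand-ins, since no authoritative inventory exists.

Entries and corpus tokens go through the same small rule-based lemmatiser so
inflections collapse consistently on both sides of every membership test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

# ---------------------------------------------------------------------------
# Lemmatisation.  A compact rule engine: irregular map, then suffix rules
# with candidate restoration checked against a set of known lemmas so that
# e.g. "injured" -> "injure" when "injure" is a dictionary word.
# ---------------------------------------------------------------------------

_IRREGULAR = {
    "is": "be", "am": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "worse": "bad", "worst": "bad",
    "felt": "feel", "feeling": "feel",
    "does": "do", "did": "do", "done": "do",
    "got": "get", "gotten": "get",
    "went": "go", "gone": "go", "goes": "go",
    "men": "man", "women": "woman", "children": "child", "people": "person",
}

_VOWELS = set("aeiou")


def _strip_candidates(token: str) -> list[str]:
    """Possible lemmas for an inflected token, most specific first."""
    cands: list[str] = []
    if len(token) > 4 and token.endswith("ies"):
        cands.append(token[:-3] + "y")
    if len(token) > 4 and token.endswith("es") and token[-3] in "sxz":
        cands.append(token[:-2])
    if len(token) > 5 and (token.endswith("ches") or token.endswith("shes")):
        cands.append(token[:-2])
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss") and not token.endswith("us"):
        cands.append(token[:-1])
    for suffix in ("ing", "ed"):
        if len(token) > len(suffix) + 2 and token.endswith(suffix):
            stem = token[: -len(suffix)]
            cands.append(stem + "e")       # wheez+e, injur+e
            if len(stem) > 2 and stem[-1] == stem[-2]:
                cands.append(stem[:-1])    # runn -> run
            cands.append(stem)
    if len(token) > 4 and token.endswith("ied"):
        cands.append(token[:-3] + "y")     # worried -> worry
    return cands


def lemmatize(token: str, known: frozenset[str] | None = None) -> str:
    """Lowercase and collapse common English inflections.

    If ``known`` is given, the first candidate stem found in it wins;
    otherwise a bare suffix strip is used only for plural/-ies forms (verbal
    suffixes are too ambiguous to strip blindly).
    """
    token = token.lower()
    if known is not None and token in known:
        return token
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    cands = _strip_candidates(token)
    if known is not None:
        for c in cands:
            if c in known:
                return c
    # conservative fallback: plural stripping only
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss") and not token.endswith("us"):
        return token[:-1]
    return token


# ---------------------------------------------------------------------------
# Lexicon container and loading.
# ---------------------------------------------------------------------------

WORD_CLASS_NAMES = ("Infection", "Possession", "Concern", "Humour", "Symptomatic")


@dataclass(frozen=True)
class Lexicons:
    """All curated token lists, lemmatised and ready for membership tests."""

    word_classes: dict[str, frozenset[str]]
    positive_words: frozenset[str]
    negative_words: frozenset[str]
    laughter_tokens: frozenset[str]
    negative_emoticons: frozenset[str]
    known_lemmas: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.laughter_tokens & self.negative_emoticons:
            raise ValueError("laughter and negative emoji/emoticon lists must be disjoint")
        for name, words in self.word_classes.items():
            if not words:
                raise ValueError(f"word class {name!r} is empty")


def _read_token_file(path) -> list[str]:
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def load_lexicons(directory: str | Path | None = None) -> Lexicons:
    """Load lexicons from a directory, or the packaged defaults.

    Expects ``word_classes.json``, ``positive_words.txt``,
    ``negative_words.txt``, ``laughter_tokens.txt`` and
    ``negative_emoticons.txt``.
    """
    if directory is None:
        root = resources.files("symptweet") / "data"
    else:
        root = Path(directory)

    raw_classes = json.loads((root / "word_classes.json").read_text(encoding="utf-8"))
    raw_pos = _read_token_file(root / "positive_words.txt")
    raw_neg = _read_token_file(root / "negative_words.txt")
    laughter = _read_token_file(root / "laughter_tokens.txt")
    neg_emo = _read_token_file(root / "negative_emoticons.txt")

    # The lexicon's own word forms define the known-lemma reference set, so
    # corpus tokens collapse onto exactly these forms.
    known_words: set[str] = set()
    for words in raw_classes.values():
        for w in words:
            known_words.update(w.lower().split())
    known_words.update(w.lower() for w in raw_pos)
    known_words.update(w.lower() for w in raw_neg)
    known = frozenset(known_words)

    def lemma_phrase(phrase: str) -> str:
        return " ".join(lemmatize(w, known) for w in phrase.lower().split())

    word_classes = {
        name: frozenset(lemma_phrase(w) for w in words)
        for name, words in raw_classes.items()
    }
    positive = frozenset(lemmatize(w, known) for w in (w.lower() for w in raw_pos))
    negative = frozenset(lemmatize(w, known) for w in (w.lower() for w in raw_neg))

    return Lexicons(
        word_classes=word_classes,
        positive_words=positive,
        negative_words=negative,
        laughter_tokens=frozenset(t.lower() for t in laughter),
        negative_emoticons=frozenset(t.lower() for t in neg_emo),
        known_lemmas=known,
    )
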