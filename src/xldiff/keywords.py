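"""Monthly keyword counts over retweet text with stopword removal.

Tokenization is pluggable: the default is Unicode word segmentation plus
lowercasing, adequate for English.  Japanese text needs a morphological
analyzer; supply one as the ``tokenizer`` argument (any callable mapping text
to an iterable of lowercase tokens) or pre-tokenize the text upstream.
"""

from __future__ import annotations

import re
from collections import Counter
from pathlib import Path
from typing import Callable, Iterable

from .events import RetweetEvent

#: Common and expected terms removed by default: every retweet in the corpus
#: mentions the drug, so these carry no signal.
DEFAULT_STOPLIST = frozenset({"ivermectin", "covid", "coronavirus"})

_WORD_RE = re.compile(r"\w+", re.UNICODE)

Tokenizer = Callable[[str], Iterable[str]]


def default_tokenizer(text: str) -> list[str]:
    """Unicode word segmentation, lowercased."""
    return [m.group(0).lower() for m in _WORD_RE.finditer(text)]


def load_stoplist(path: str | Path) -> frozenset[str]:
    """Read a stoplist file: one lowercase token per line, blanks ignored."""
    tokens = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.strip().lower()
        if token:
            tokens.add(token)
    return frozenset(tokens)


def count_keywords(
    events: Iterable[RetweetEvent],
    tokenizer: Tokenizer = default_tokenizer,
    stoplist: frozenset[str] = DEFAULT_STOPLIST,
    k: int = 10,
) -> list[tuple[str, int]]:
    """Top-k (token, count) pairs across all event texts, stoplist removed.

    Each retweet's text is counted once per event (no deduplication).  Ties
    in count order lexicographically.
    """
    counts: Counter[str] = Counter()
    for e in events:
        for token in tokenizer(e.text):
            if token not in stoplist:
                counts[token] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
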