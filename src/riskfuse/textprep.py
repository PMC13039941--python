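"""Text normalization and n-gram tokenization for clinical notes.

Notes are lowercased, split into alphanumeric tokens, and filtered against an
English stopword list; unigrams and adjacent bigrams are formed over the
surviving sequence. Clinical acronyms ("SI", "SA", ...) are deliberately kept
as ordinary tokens — no expansion, stemming or lemmatization is applied.

The raw (pre-stopword) token sequence is retained on each
:class:`TokenStream`, because negation cues such as "not" belong to most
stopword lists yet must stay visible to the lexicon scorer's negation
lookback.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

#: Default stopword inventory (scikit-learn's English list).
DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass
class TokenStream:
    """Tokenized note.

    ``tokens`` is the stopword-removed sequence used for featurization;
    ``raw_tokens`` the full lowercase sequence; ``kept_idx[i]`` gives the
    position of ``tokens[i]`` within ``raw_tokens``.
    """

    note_id: object = None
    tokens: list = field(default_factory=list)
    raw_tokens: list = field(default_factory=list)
    kept_idx: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, stopwords=None, note_id=None) -> TokenStream:
    """Lowercase, split on non-alphanumeric boundaries, drop stopwords.

    Apostrophes and every other non-alphanumeric character act as token
    separators; digits are retained (clinical notes carry meaningful
    numerics). Empty or whitespace-only text yields an empty stream.
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    raw = _TOKEN_RE.findall(text.lower())
    kept, kept_idx = [], []
    for i, tok in enumerate(raw):
        if tok not in stopwords:
            kept.append(tok)
            kept_idx.append(i)
    return TokenStream(note_id=note_id, tokens=kept, raw_tokens=raw, kept_idx=kept_idx)


def build_ngrams(stream, orders=frozenset({1, 2})) -> list:
    """Emit unigram and/or adjacent-bigram strings over the kept tokens.

    Bigrams join two adjacent (post-stopword) tokens with a single space, so
    "alcohol and suicide" yields the bigram "alcohol suicide".
    """
    tokens = stream.tokens if isinstance(stream, TokenStream) else list(stream)
    orders = set(orders)
    bad = orders - {1, 2}
    if bad:
        raise ValueError(f"unsupported n-gram orders: {sorted(bad)}")
    out = []
    if 1 in orders:
        out.extend(tokens)
    if 2 in orders:
        out.extend(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return out


def load_stopwords(path) -> frozenset:
    """Read a stopword list: plain text, one token per line, '#' comments."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip().lower()
            if tok and not tok.startswith("#"):
                words.add(tok)
    return frozenset(words)
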