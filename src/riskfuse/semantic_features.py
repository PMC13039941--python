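"""Closed-vocabulary featurization: lexicon-category scores per note.

Each lexicon category is a curated set of unigrams tied to a psychosocial
construct (kinship, pleasure, valence, ...). A note's score for a category is
the proportion of its (stopword-removed) tokens that belong to the category's
term set. Every category may additionally emit negation-controlled variants:
for window size ``k``, a term match is suppressed whenever a negation cue
("no", "not", "denies", ...) occurs among the ``k`` raw tokens immediately
preceding it — "denies suicidal ideation" should not score as suicidal
content. Such variants are named ``<category>_neg_<k>``.

Negation lookback deliberately scans the *raw* (pre-stopword) sequence:
cues like "not" sit on most stopword lists and would otherwise vanish before
the scorer could see them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import FeatureMatrix
from .textprep import TokenStream

#: Default negation cue tokens.
DEFAULT_NEGATORS = frozenset({"no", "not", "never", "denies", "denied", "without", "n't"})

POLARITIES = ("positive", "negative", "neutral")


@dataclass
class LexiconCategory:
    """One named term list with its negation-variant windows."""

    category_id: str
    terms: frozenset
    polarity: str = "neutral"
    negation_variants: tuple = ()

    def __post_init__(self):
        self.terms = frozenset(self.terms)
        self.negation_variants = tuple(int(k) for k in self.negation_variants)
        if not self.terms:
            raise ValueError(f"category {self.category_id!r} has an empty term list")
        if any(t != t.lower() or " " in t for t in self.terms):
            raise ValueError(f"category {self.category_id!r}: terms must be lowercase unigrams")
        if self.polarity not in POLARITIES:
            raise ValueError(f"category {self.category_id!r}: unknown polarity {self.polarity!r}")
        if any(k < 1 for k in self.negation_variants):
            raise ValueError(f"category {self.category_id!r}: negation windows must be >= 1")


@dataclass
class Lexicon:
    name: str
    categories: list = field(default_factory=list)


def load_lexicon(path) -> Lexicon:
    """Parse a lexicon file (TSV with header, or a JSON equivalent).

    TSV columns: ``lexicon, category_id, polarity, negation_variants, terms``
    where ``negation_variants`` is a comma-separated integer list (may be
    empty) and ``terms`` a semicolon-separated token list. Duplicate terms
    within a category are deduplicated with a warning; an empty term list or
    a malformed row is an error naming the line.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        cats = [
            _make_category(c["category_id"], c["terms"], c.get("polarity", "neutral"),
                           c.get("negation_variants", []), where=path)
            for c in obj["categories"]
        ]
        return Lexicon(name=obj["name"], categories=cats)

    cats, name = [], None
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["lexicon", "category_id", "polarity", "negation_variants", "terms"]
        if header != expected:
            raise ValueError(f"{path}:1: header must be {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}")
            lex, cat_id, polarity, variants, terms = parts
            if name is None:
                name = lex
            elif lex != name:
                raise ValueError(f"{path}:{lineno}: multiple lexicon names in one file ({name!r}, {lex!r})")
            ks = [int(v) for v in variants.split(",") if v.strip()]
            term_list = [t.strip() for t in terms.split(";") if t.strip()]
            cats.append(_make_category(cat_id, term_list, polarity, ks, where=f"{path}:{lineno}"))
    if name is None:
        raise ValueError(f"{path}: no categories found")
    return Lexicon(name=name, categories=cats)


def _make_category(cat_id, term_list, polarity, variants, where) -> LexiconCategory:
    term_list = list(term_list)
    unique = set(term_list)
    if len(unique) < len(term_list):
        warnings.warn(f"{where}: duplicate terms in category {cat_id!r} deduplicated")
    try:
        return LexiconCategory(
            category_id=cat_id, terms=frozenset(unique),
            polarity=polarity, negation_variants=tuple(variants),
        )
    except ValueError as err:
        raise ValueError(f"{where}: {err}") from None


def score_document(
    stream: TokenStream,
    category: LexiconCategory,
    negation_k: int | None = None,
    negators=DEFAULT_NEGATORS,
) -> float:
    """Proportion of kept tokens matching the category, in [0, 1].

    With ``negation_k = k``, a match at raw position ``r`` is suppressed when
    any negator occurs among ``raw_tokens[r-k : r]``. Empty documents score 0.
    """
    n = len(stream.tokens)
    if n == 0:
        return 0.0
    hits = 0
    for i, tok in enumerate(stream.tokens):
        if tok not in category.terms:
            continue
        if negation_k is not None:
            r = stream.kept_idx[i]
            window = stream.raw_tokens[max(0, r - negation_k):r]
            if any(w in negators for w in window):
                continue
        hits += 1
    return hits / n


def featurize_semantic(corpus, lexicons, negators=DEFAULT_NEGATORS) -> FeatureMatrix:
    """Score every note against every (category × negation-variant) column.

    Columns are named ``<lexicon>.<category_id>`` for the base score and
    ``<lexicon>.<category_id>_neg_<k>`` per variant window, tagged
    ``semantic``; rows follow the corpus order.
    """
    corpus = list(corpus)
    cols: list[tuple[str, LexiconCategory, int | None]] = []
    for lex in lexicons:
        for cat in lex.categories:
            cols.append((f"{lex.name}.{cat.category_id}", cat, None))
            for k in cat.negation_variants:
                cols.append((f"{lex.name}.{cat.category_id}_neg_{k}", cat, k))
    values = np.zeros((len(corpus), len(cols)), dtype=float)
    row_ids = []
    for di, stream in enumerate(corpus):
        row_ids.append(stream.note_id if stream.note_id is not None else di)
        for j, (_, cat, k) in enumerate(cols):
            values[di, j] = score_document(stream, cat, negation_k=k, negators=negators)
    return FeatureMatrix(
        row_ids=np.asarray(row_ids, dtype=object),
        col_names=np.asarray([name for name, _, _ in cols], dtype=object),
        values=values,
        col_tags=np.full(len(cols), "semantic", dtype=object),
    )
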