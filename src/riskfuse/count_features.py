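"""Open-vocabulary featurization: document-term counts with df filtering.

A vocabulary is fitted on a (training) corpus of token streams: every unigram
or bigram is kept iff it occurs in at least ``min_df`` documents and in no
more than ``max_df`` (a proportion) of them — exceedingly rare and
exceedingly common terms carry little discriminative value and blow up the
matrix. The fitted vocabulary is then applied frozen to any corpus, yielding
sparse count matrices; a smoothed-idf TF-IDF re-weighting is available as an
alternative (off by default — plain counts performed slightly better in the
regime this package targets).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .matrix import FeatureMatrix
from .textprep import build_ngrams

DEFAULT_MIN_DF = 100
DEFAULT_MAX_DF = 0.9


@dataclass
class Vocabulary:
    """Fitted term inventory with fit-time document frequencies.

    ``terms`` is lexicographically ordered and fixes the column order of
    every matrix produced under this vocabulary. ``doc_freq`` aligns with
    ``terms`` and counts presence (a term occurring five times in one
    document contributes one).
    """

    terms: tuple
    doc_freq: np.ndarray
    n_docs_fit: int
    min_df: int
    max_df: float
    ngram_orders: frozenset = frozenset({1, 2})
    _index: dict = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.terms = tuple(self.terms)
        self.doc_freq = np.asarray(self.doc_freq, dtype=np.int64)
        if self._index is None:
            self._index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def index(self) -> dict:
        return self._index


def fit_vocabulary(
    corpus,
    min_df: int = DEFAULT_MIN_DF,
    max_df: float = DEFAULT_MAX_DF,
    ngram_orders=frozenset({1, 2}),
) -> Vocabulary:
    """Fit the df-filtered n-gram vocabulary on a corpus of token streams.

    A term survives iff ``min_df <= df(term) <= floor(max_df * n_docs)``;
    "occurs in more than max_df of documents" is read strictly, so at
    ``max_df=0.9`` a term present in exactly 90% of documents is retained.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    if min_df < 1:
        raise ValueError(f"min_df must be >= 1, got {min_df}")
    if not 0 < max_df <= 1:
        raise ValueError(f"max_df must lie in (0, 1], got {max_df}")
    ngram_orders = frozenset(ngram_orders)
    df: Counter = Counter()
    for stream in corpus:
        df.update(set(build_ngrams(stream, ngram_orders)))
    n = len(corpus)
    ceiling = math.floor(max_df * n + 1e-9)
    terms = sorted(t for t, d in df.items() if min_df <= d <= ceiling)
    if not terms:
        warnings.warn("document-frequency filter removed every term; vocabulary is empty")
    return Vocabulary(
        terms=tuple(terms),
        doc_freq=np.array([df[t] for t in terms], dtype=np.int64),
        n_docs_fit=n,
        min_df=min_df,
        max_df=max_df,
        ngram_orders=ngram_orders,
    )


def transform_counts(corpus, vocab: Vocabulary) -> FeatureMatrix:
    """Count in-vocabulary term occurrences per document (CSR, int64).

    Out-of-vocabulary terms are ignored; a document with no in-vocabulary
    term is an all-zero row.
    """
    corpus = list(corpus)
    indptr, indices, data = [0], [], []
    row_ids = []
    for di, stream in enumerate(corpus):
        row_ids.append(stream.note_id if stream.note_id is not None else di)
        counts = Counter(build_ngrams(stream, vocab.ngram_orders))
        for term, c in counts.items():
            j = vocab.index.get(term)
            if j is not None:
                indices.append(j)
                data.append(c)
        indptr.append(len(indices))
    values = sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices, dtype=np.int64), np.array(indptr)),
        shape=(len(corpus), len(vocab)),
    )
    values.sum_duplicates()
    return FeatureMatrix(
        row_ids=np.asarray(row_ids, dtype=object),
        col_names=np.asarray(vocab.terms, dtype=object),
        values=values,
        col_tags=np.full(len(vocab), "count", dtype=object),
    )


def tfidf_transform(counts: FeatureMatrix, vocab: Vocabulary) -> FeatureMatrix:
    """TF-IDF re-weighting of a count matrix under its fitting vocabulary.

    ``idf(t) = ln((1 + n_docs_fit) / (1 + df(t))) + 1`` (smoothed), applied
    multiplicatively to the counts, then each row is L2-normalized. All-zero
    rows stay zero. The idf uses the *fit-time* document frequencies, so the
    weighting of held-out corpora is frozen with the vocabulary.
    """
    if counts.shape[1] != len(vocab):
        raise ValueError(
            f"count matrix has {counts.shape[1]} columns but vocabulary {len(vocab)} terms"
        )
    idf = np.log((1.0 + vocab.n_docs_fit) / (1.0 + vocab.doc_freq)) + 1.0
    x = counts.values.tocsr().astype(float) if sp.issparse(counts.values) else sp.csr_matrix(
        np.asarray(counts.values, dtype=float)
    )
    x = x.multiply(idf[np.newaxis, :]).tocsr()
    norms = np.sqrt(np.asarray(x.multiply(x).sum(axis=1)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    x = sp.diags(inv) @ x
    return FeatureMatrix(
        row_ids=counts.row_ids.copy(),
        col_names=counts.col_names.copy(),
        values=x.tocsr(),
        col_tags=counts.col_tags.copy(),
    )
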