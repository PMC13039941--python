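import numpy as np
import pandas as pd
import pytest

from riskfuse.semantic_features import Lexicon, LexiconCategory
from riskfuse.textprep import TokenStream, tokenize


def stream_from_tokens(tokens, note_id=None):
    """A TokenStream with no stopword removal (kept == raw)."""
    tokens = list(tokens)
    return TokenStream(
        note_id=note_id, tokens=tokens, raw_tokens=list(tokens),
        kept_idx=list(range(len(tokens))),
    )


@pytest.fixture
def toy_lexicon():
    return Lexicon(
        name="toylex",
        categories=[
            LexiconCategory("mood", frozenset({"happy", "sad", "tearful"}), "negative", (3,)),
            LexiconCategory("kin", frozenset({"mother", "father", "wife"}), "neutral", (3,)),
        ],
    )


@pytest.fixture
def tiny_cohort():
    """Two match groups (1 case + 2 controls each), distinct tiers."""
    rows = []
    for gi, (perc, date) in enumerate([(1, "2017-03-01"), (40, "2017-06-01")]):
        for j, status in enumerate(["case", "control", "control"]):
            rows.append({
                "patient_id": f"p{gi}{j}", "status": status,
                "index_date": pd.Timestamp(date), "percentile": perc,
                "match_group": f"g{gi}", "facility": "facA",
            })
    return pd.DataFrame(rows)


def random_streams(rng, n_docs, vocab, doc_len=12):
    return [
        stream_from_tokens(rng.choice(vocab, size=rng.integers(0, doc_len + 1)), note_id=f"d{i}")
        for i in range(n_docs)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
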