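import numpy as np
import pytest

from riskfuse.semantic_features import (
    DEFAULT_NEGATORS,
    LexiconCategory,
    featurize_semantic,
    load_lexicon,
    score_document,
)
from riskfuse.textprep import tokenize
from conftest import stream_from_tokens


def oracle_score(stream, terms, negation_k, negators):
    """Independent oracle: explicit position scan with raw-sequence lookback."""
    if not stream.tokens:
        return 0.0
    hits = 0
    for pos in range(len(stream.tokens)):
        if stream.tokens[pos] not in terms:
            continue
        suppressed = False
        if negation_k is not None:
            raw_pos = stream.kept_idx[pos]
            for back in range(1, negation_k + 1):
                if raw_pos - back >= 0 and stream.raw_tokens[raw_pos - back] in negators:
                    suppressed = True
                    break
        if not suppressed:
            hits += 1
    return hits / len(stream.tokens)


LEXICON_TSV = """lexicon\tcategory_id\tpolarity\tnegation_variants\tterms
fixlex\tmood\tnegative\t3\thappy;sad;tearful
fixlex\tkin\tneutral\t\tmother;father;wife
"""


class TestLoadLexicon:
    def test_parses_tsv_fixture(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(LEXICON_TSV)
        lex = load_lexicon(path)
        assert lex.name == "fixlex"
        assert [c.category_id for c in lex.categories] == ["mood", "kin"]
        assert lex.categories[0].negation_variants == (3,)
        assert len(lex.categories[0].terms) == 3

    def test_duplicate_terms_deduplicated_with_warning(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(LEXICON_TSV.replace("happy;sad", "happy;happy;sad"))
        with pytest.warns(UserWarning, match="duplicate"):
            lex = load_lexicon(path)
        assert len(lex.categories[0].terms) == 3

    def test_empty_term_list_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(LEXICON_TSV.replace("mother;father;wife", ""))
        with pytest.raises(ValueError, match=":3"):
            load_lexicon(path)

    def test_malformed_row_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(LEXICON_TSV + "fixlex\tonly_two_fields\n")
        with pytest.raises(ValueError, match=":4"):
            load_lexicon(path)

    def test_json_equivalent(self, tmp_path):
        path = tmp_path / "lex.json"
        path.write_text(
            '{"name": "fixlex", "categories": [{"category_id": "mood",'
            ' "terms": ["happy", "sad"], "polarity": "negative",'
            ' "negation_variants": [3]}]}'
        )
        lex = load_lexicon(path)
        assert lex.categories[0].terms == frozenset({"happy", "sad"})


class TestScoreDocument:
    def test_proportion_of_matching_tokens(self):
        cat = LexiconCategory("c", {"happy"})
        assert score_document(stream_from_tokens(["happy", "sad", "table"]), cat) == pytest.approx(1 / 3)

    def test_negation_suppresses_match(self):
        cat = LexiconCategory("c", {"happy"})
        stream = stream_from_tokens(["not", "happy"])
        assert score_document(stream, cat, negation_k=3) == 0.0
        assert score_document(stream, cat) == pytest.approx(0.5)

    def test_negator_outside_window_does_not_suppress(self):
        cat = LexiconCategory("c", {"happy"})
        stream = stream_from_tokens(["not", "a", "b", "c", "happy"])
        assert score_document(stream, cat, negation_k=3) == pytest.approx(1 / 5)
        assert score_document(stream, cat, negation_k=4) == 0.0

    def test_lookback_scans_raw_sequence_denominator_uses_kept(self):
        # "was not happy": "was"/"not" are stopwords, so tokens == ["happy"],
        # but the raw-position lookback still sees "not".
        stream = tokenize("was not happy")
        cat = LexiconCategory("c", {"happy"})
        assert score_document(stream, cat) == pytest.approx(1.0)
        assert score_document(stream, cat, negation_k=3) == 0.0

    def test_empty_document_scores_zero(self):
        assert score_document(stream_from_tokens([]), LexiconCategory("c", {"x"})) == 0.0

    def test_matches_position_scanning_oracle(self, rng):
        pool = ["happy", "sad", "calm", "not", "no", "w1", "w2", "w3"]
        cat = LexiconCategory("c", {"happy", "sad"})
        for _ in range(20):
            tokens = list(rng.choice(pool, size=int(rng.integers(1, 21))))
            stream = stream_from_tokens(tokens)
            for k in (None, 1, 3):
                assert score_document(stream, cat, negation_k=k) == pytest.approx(
                    oracle_score(stream, cat.terms, k, DEFAULT_NEGATORS)
                )

    def test_monotone_suppression_in_window_size(self, rng):
        pool = ["happy", "not", "x", "y"]
        cat = LexiconCategory("c", {"happy"})
        for _ in range(10):
            stream = stream_from_tokens(rng.choice(pool, size=15))
            scores = [score_document(stream, cat, negation_k=k) for k in (1, 2, 4, 8)]
            assert scores == sorted(scores, reverse=True)

    def test_empty_negator_set_equals_base_score(self, rng):
        pool = ["happy", "not", "x"]
        cat = LexiconCategory("c", {"happy"})
        stream = stream_from_tokens(rng.choice(pool, size=20))
        base = score_document(stream, cat)
        for k in (1, 3, 9):
            assert score_document(stream, cat, negation_k=k, negators=frozenset()) == base


class TestFeaturizeSemantic:
    def test_column_layout(self, toy_lexicon):
        fm = featurize_semantic([stream_from_tokens(["happy"])], [toy_lexicon])
        assert list(fm.col_names) == [
            "toylex.mood", "toylex.mood_neg_3", "toylex.kin", "toylex.kin_neg_3",
        ]
        assert set(fm.col_tags) == {"semantic"}

    def test_empty_corpus_gives_zero_matrix(self, toy_lexicon):
        fm = featurize_semantic([stream_from_tokens([]) for _ in range(3)], [toy_lexicon])
        assert fm.toarray().sum() == 0

    def test_cells_match_per_document_scores(self, toy_lexicon, rng):
        pool = ["happy", "mother", "not", "x", "sad", "denies"]
        corpus = [stream_from_tokens(rng.choice(pool, size=12), note_id=f"d{i}") for i in range(6)]
        fm = featurize_semantic(corpus, [toy_lexicon])
        arr = fm.toarray()
        for i, stream in enumerate(corpus):
            for j, (cat, k) in enumerate(
                [(toy_lexicon.categories[0], None), (toy_lexicon.categories[0], 3),
                 (toy_lexicon.categories[1], None), (toy_lexicon.categories[1], 3)]
            ):
                assert arr[i, j] == pytest.approx(score_document(stream, cat, negation_k=k))

    def test_duplicated_document_scores_identically(self, toy_lexicon):
        s = stream_from_tokens(["happy", "mother", "x"], note_id="a")
        t = stream_from_tokens(["happy", "mother", "x"], note_id="b")
        fm = featurize_semantic([s, t], [toy_lexicon])
        np.testing.assert_array_equal(fm.toarray()[0], fm.toarray()[1])

    def test_disjoint_category_scores_sum_below_one(self, toy_lexicon, rng):
        pool = ["happy", "mother", "x", "y"]
        corpus = [stream_from_tokens(rng.choice(pool, size=10)) for _ in range(8)]
        fm = featurize_semantic(corpus, [toy_lexicon])
        arr = fm.toarray()
        base_cols = [0, 2]  # mood, kin (disjoint term sets)
        assert (arr[:, base_cols].sum(axis=1) <= 1 + 1e-12).all()
        assert (arr >= 0).all() and (arr <= 1).all()
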