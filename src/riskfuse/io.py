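"""File formats: cohort CSV, notes JSON-Lines, vocabulary TSV, matrix export.

All formats are plain text. Dates are ISO-8601; matrices go out as
MatrixMarket with sidecar row/column name files so they round-trip through
standard sparse tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .cohort import NOTE_COLUMNS, validate_cohort
from .count_features import Vocabulary
from .matrix import FeatureMatrix


def save_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, parse_dates=["index_date"]))


def save_notes(notes: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in notes.iterrows():
            fh.write(json.dumps({
                "note_id": row["note_id"],
                "patient_id": row["patient_id"],
                "note_date": pd.Timestamp(row["note_date"]).strftime("%Y-%m-%d"),
                "text": row["text"],
            }) + "\n")


def load_notes(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            missing = [k for k in NOTE_COLUMNS if k not in obj]
            if missing:
                raise ValueError(f"{path}:{lineno}: note record missing keys {missing}")
            rows.append(obj)
    notes = pd.DataFrame(rows, columns=list(NOTE_COLUMNS))
    notes["note_date"] = pd.to_datetime(notes["note_date"])
    if notes["note_id"].duplicated().any():
        raise ValueError("duplicate note_id in notes file")
    return notes


def save_vocabulary(vocab: Vocabulary, path) -> None:
    """TSV: header then one (term, doc_freq) row per retained term."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_docs_fit={vocab.n_docs_fit}\tmin_df={vocab.min_df}\t"
                 f"max_df={vocab.max_df}\torders={sorted(vocab.ngram_orders)}\n")
        fh.write("term\tdoc_freq\n")
        for t, d in zip(vocab.terms, vocab.doc_freq):
            fh.write(f"{t}\t{int(d)}\n")


def save_matrix(matrix: FeatureMatrix, stem) -> None:
    """Write <stem>.mtx plus <stem>.rows / <stem>.cols sidecars.

    The cols sidecar is TSV ``name<TAB>tag``.
    """
    stem = Path(stem)
    values = matrix.values if sp.issparse(matrix.values) else sp.csr_matrix(matrix.values)
    mmwrite(str(stem.with_suffix(".mtx")), values)
    stem.with_suffix(".rows").write_text("\n".join(map(str, matrix.row_ids)) + "\n")
    with open(stem.with_suffix(".cols"), "w", encoding="utf-8") as fh:
        for name, tag in zip(matrix.col_names, matrix.col_tags):
            fh.write(f"{name}\t{tag}\n")


def load_matrix(stem) -> FeatureMatrix:
    stem = Path(stem)
    values = sp.csr_matrix(mmread(str(stem.with_suffix(".mtx"))))
    row_ids = stem.with_suffix(".rows").read_text().splitlines()
    names, tags = [], []
    for line in stem.with_suffix(".cols").read_text().splitlines():
        name, tag = line.split("\t")
        names.append(name)
        tags.append(tag)
    return FeatureMatrix(
        row_ids=np.asarray(row_ids, dtype=object),
        col_names=np.asarray(names, dtype=object),
        values=values,
        col_tags=np.asarray(tags, dtype=object),
    )


def save_lexicon(lexicon, path) -> None:
    """Write a lexicon in the TSV interchange format (see load_lexicon)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lexicon\tcategory_id\tpolarity\tnegation_variants\tterms\n")
        for cat in lexicon.categories:
            variants = ",".join(str(k) for k in cat.negation_variants)
            terms = ";".join(sorted(cat.terms))
            fh.write(f"{lexicon.name}\t{cat.category_id}\t{cat.polarity}\t{variants}\t{terms}\n")


def save_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
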