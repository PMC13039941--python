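"""Shared feature-matrix container.

Rows are clinical notes, columns are features. Every featurizer in the
package emits a :class:`FeatureMatrix`; the fusion step concatenates them.
Values are kept sparse where the producer is sparse (token counts) and dense
otherwise (lexicon scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: Allowed per-column feature-set tags.
TAGS = ("count", "semantic")


@dataclass
class FeatureMatrix:
    """Documents-by-features matrix with named rows and tagged columns.

    Parameters
    ----------
    row_ids
        Note identifiers, one per row, unique.
    col_names
        Feature names, one per column, unique.
    values
        ``(n_rows, n_cols)`` array or scipy sparse matrix.
    col_tags
        Per-column feature-set tag, each one of :data:`TAGS`.
    """

    row_ids: np.ndarray
    col_names: np.ndarray
    values: sp.spmatrix | np.ndarray
    col_tags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.row_ids = np.asarray(self.row_ids, dtype=object)
        self.col_names = np.asarray(self.col_names, dtype=object)
        if self.col_tags is None:
            self.col_tags = np.full(len(self.col_names), "count", dtype=object)
        self.col_tags = np.asarray(self.col_tags, dtype=object)
        n_rows, n_cols = self.values.shape
        if len(self.row_ids) != n_rows:
            raise ValueError(
                f"{len(self.row_ids)} row ids for {n_rows} rows"
            )
        if len(self.col_names) != n_cols or len(self.col_tags) != n_cols:
            raise ValueError(
                f"{len(self.col_names)} names / {len(self.col_tags)} tags "
                f"for {n_cols} columns"
            )
        if len(set(self.row_ids)) != n_rows:
            raise ValueError("duplicate row ids")
        if len(set(self.col_names)) != n_cols:
            raise ValueError("duplicate column names")
        bad = set(self.col_tags) - set(TAGS)
        if bad:
            raise ValueError(f"unknown column tags: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def row_index(self) -> dict:
        return {rid: i for i, rid in enumerate(self.row_ids)}

    def take_rows(self, row_ids) -> "FeatureMatrix":
        """Subset/reorder rows by note id (all ids must be present)."""
        idx = self.row_index()
        missing = [r for r in row_ids if r not in idx]
        if missing:
            raise KeyError(f"unknown row ids: {missing[:5]}")
        pos = np.array([idx[r] for r in row_ids])
        vals = self.values[pos] if not sp.issparse(self.values) else self.values.tocsr()[pos]
        return FeatureMatrix(
            row_ids=np.asarray(list(row_ids), dtype=object),
            col_names=self.col_names.copy(),
            values=vals,
            col_tags=self.col_tags.copy(),
        )
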