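"""Joint-matrix fusion and the α/β feature-selection weighting scheme.

Count features vastly outnumber semantic features in a merged matrix, so
under uniform split-candidate sampling a boosted tree almost never considers
a semantic column. The scheme rebalances sampling propensities: count
features keep weight 1 and every semantic feature receives

    w_semantic = (n_count / n_semantic) * alpha

so that at ``alpha = 1`` the two *feature sets* are sampled equally often.
The reporting axis is ``beta = alpha / (alpha + 1)``, the probability that a
given split candidate drawn from the two balanced sets is semantic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import scipy.sparse as sp

from .matrix import FeatureMatrix

#: The α grid swept by default, and its β axis rounded to two decimals.
DEFAULT_ALPHA_GRID = (0.01, 0.03, 0.06, 0.10, 0.30, 0.60, 1.00, 2.50, 5.00)


def beta_from_alpha(alpha: float) -> float:
    """β = α / (α + 1): relative probability of sampling a semantic feature."""
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    return alpha / (alpha + 1.0)


def beta_table(alphas=DEFAULT_ALPHA_GRID, ndigits: int = 2) -> list:
    """β for each α, rounded half-up in decimal arithmetic.

    Reporting runs on the β axis rounded to ``ndigits``. Binary floats
    misround exact halves (0.60/1.60 is exactly 0.375, but its float64 image
    is fractionally below it and would round to 0.37), so the table is
    computed with :mod:`decimal` and conventional half-up rounding.
    """
    out = []
    q = Decimal(1).scaleb(-ndigits)
    for a in alphas:
        if a < 0:
            raise ValueError(f"alpha must be non-negative, got {a}")
        d = Decimal(str(a))
        out.append(float((d / (d + 1)).quantize(q, rounding=ROUND_HALF_UP)))
    return out


@dataclass
class WeightingScheme:
    """Per-feature-set selection weights for a given α."""

    alpha: float
    beta: float
    n_count: int
    n_semantic: int
    semantic_weight: float
    count_weight: float = 1.0


def compute_weights(n_count: int, n_semantic: int, alpha: float) -> WeightingScheme:
    """Build the weighting scheme ``w_semantic = (n_count/n_semantic)·α``."""
    if n_count < 1 or n_semantic < 1:
        raise ValueError(f"feature tallies must be >= 1, got n_count={n_count}, n_semantic={n_semantic}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return WeightingScheme(
        alpha=alpha,
        beta=beta_from_alpha(alpha),
        n_count=int(n_count),
        n_semantic=int(n_semantic),
        semantic_weight=(n_count / n_semantic) * alpha,
        count_weight=1.0,
    )


def merge_matrices(count_m: FeatureMatrix, semantic_m: FeatureMatrix) -> FeatureMatrix:
    """Horizontally merge count and semantic matrices aligned by note id.

    Both matrices must cover the same note set; rows of the semantic matrix
    are reordered to the count matrix's order. Column names are prefixed with
    their set tag (``count:`` / ``semantic:``) so names stay unique after the
    merge. Every input cell appears unchanged in the result.
    """
    left = set(count_m.row_ids)
    right = set(semantic_m.row_ids)
    if left != right:
        orphans = sorted(map(str, left ^ right))
        raise ValueError(f"row sets differ; orphan note ids: {orphans[:10]}")
    semantic_m = semantic_m.take_rows(count_m.row_ids)
    values = sp.hstack(
        [sp.csr_matrix(count_m.values, dtype=float), sp.csr_matrix(semantic_m.values, dtype=float)],
        format="csr",
    )
    names = np.concatenate([
        np.asarray([f"count:{n}" for n in count_m.col_names], dtype=object),
        np.asarray([f"semantic:{n}" for n in semantic_m.col_names], dtype=object),
    ])
    tags = np.concatenate([
        np.full(count_m.shape[1], "count", dtype=object),
        np.full(semantic_m.shape[1], "semantic", dtype=object),
    ])
    return FeatureMatrix(row_ids=count_m.row_ids.copy(), col_names=names, values=values, col_tags=tags)


def selection_weights(matrix: FeatureMatrix, scheme: WeightingScheme) -> np.ndarray:
    """Per-column selection-weight vector aligned to the matrix columns.

    Weights are relative sampling propensities handed to the learner, which
    normalizes them internally; they are not normalized here.
    """
    n_count = int(np.sum(matrix.col_tags == "count"))
    n_semantic = int(np.sum(matrix.col_tags == "semantic"))
    if (n_count, n_semantic) != (scheme.n_count, scheme.n_semantic):
        raise ValueError(
            f"scheme tallies ({scheme.n_count}, {scheme.n_semantic}) do not match "
            f"matrix tags ({n_count}, {n_semantic})"
        )
    return np.where(matrix.col_tags == "semantic", scheme.semantic_weight, scheme.count_weight).astype(float)
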