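"""Boosted-tree harness: grouped splits, training, randomized search.

Training rows are individual notes (far more numerous than patients), but the
outcome is per patient, so partitioning must happen at the patient level —
all of a patient's notes land in the same partition, and cross-validation
folds are likewise patient-grouped. The learner is XGBoost; the fusion
module's per-feature selection weights are passed through as feature weights,
which bias which columns are drawn as split candidates whenever column
subsampling is active (the default here: ``colsample_bynode=0.8``).

Missing values are left missing and nothing is normalized — gradient-boosted
trees handle both natively, and sparse count matrices rely on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.model_selection import GroupKFold
from xgboost import XGBClassifier

from . import evaluate
from .fusion import WeightingScheme, selection_weights
from .matrix import FeatureMatrix

PARTITIONS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)

#: Baseline learner configuration (overridable per call).
DEFAULT_PARAMS = dict(
    n_estimators=100,
    max_depth=6,
    learning_rate=0.3,
    subsample=1.0,
    colsample_bynode=0.8,
    min_child_weight=1,
)


@dataclass
class SplitPlan:
    fractions: tuple
    assignment: dict  # patient_id -> partition
    seed: int

    def patients(self, partition: str) -> list:
        return [p for p, part in self.assignment.items() if part == partition]


def grouped_split(
    cohort: pd.DataFrame,
    fractions: tuple = DEFAULT_FRACTIONS,
    seed: int = 0,
    unit: str | None = None,
) -> SplitPlan:
    """Randomly partition patients into train/validation/test.

    Notes inherit their patient's partition downstream, which is what keeps
    information from leaking across partitions. By default the sampling unit
    is the match group when the cohort carries one (``unit="auto"``): a case
    and its matched controls share an exact percentile, so scattering a
    matched set across partitions would let a model anti-learn test status
    from per-percentile training composition whenever a percentile hosts few
    groups. ``unit="patient"`` forces independent per-patient assignment.
    Patient counts per partition track the fractions either way.
    Reproducible under ``seed``. Warns when a partition ends up single-class.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be three positive numbers summing to 1, got {fractions}")
    if unit is None:
        unit = "match_group" if "match_group" in cohort.columns else "patient"
    rng = np.random.default_rng(seed)
    n = len(cohort)
    if unit == "match_group":
        blocks = [grp["patient_id"].to_list() for _, grp in cohort.groupby("match_group")]
    elif unit == "patient":
        blocks = [[p] for p in cohort["patient_id"]]
    else:
        raise ValueError(f"unknown split unit {unit!r}")
    order = rng.permutation(len(blocks))
    n_train = n * fractions[0]
    n_val = n * fractions[1]
    assignment = {}
    placed = 0
    for i in order:
        part = "train" if placed < round(n_train) else (
            "validation" if placed < round(n_train + n_val) else "test")
        for pid in blocks[i]:
            assignment[pid] = part
            placed += 1
    status = cohort.set_index("patient_id")["status"]
    for part in PARTITIONS:
        members = status.loc[[p for p, a in assignment.items() if a == part]]
        if len(set(members)) < 2:
            warnings.warn(f"partition {part!r} lacks both classes; downstream metrics undefined")
    return SplitPlan(fractions=fractions, assignment=assignment, seed=seed)


@dataclass
class FittedModel:
    """A trained note-level classifier plus its provenance."""

    estimator: XGBClassifier
    feature_names: np.ndarray
    params: dict
    seed: int
    scheme: WeightingScheme | None = None
    tier: str | None = None

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        return predict_notes(self, matrix)


def _as_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return labels == "case"
    return labels.astype(bool)


def _as_xgb_input(matrix: FeatureMatrix):
    return matrix.values.tocsr() if sp.issparse(matrix.values) else np.asarray(matrix.values, float)


def train_classifier(
    matrix: FeatureMatrix,
    labels,
    scheme: WeightingScheme | None = None,
    params: dict | None = None,
    seed: int = 0,
    class_weighting: bool = True,
) -> FittedModel:
    """Fit the boosted-tree note classifier.

    ``labels`` is per-note case/control, aligned to the matrix rows. When a
    :class:`WeightingScheme` is given, its per-column selection weights steer
    split-candidate sampling. With matched 1:k cohorts the classes are
    imbalanced; ``class_weighting`` sets the positive-class weight to
    n_control/n_case (disable to leave it at 1). Deterministic for fixed
    seed: single-threaded, exact histogram method.
    """
    y = _as_labels(labels)
    if y.shape[0] != matrix.shape[0]:
        raise ValueError("labels are not aligned to matrix rows")
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    merged = dict(DEFAULT_PARAMS)
    merged.update(params or {})
    spw = float((~y).sum() / y.sum()) if class_weighting else 1.0
    fw = selection_weights(matrix, scheme) if scheme is not None else None
    est = XGBClassifier(
        **merged,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        scale_pos_weight=spw,
        feature_weights=fw,
    )
    est.fit(_as_xgb_input(matrix), y.astype(int))
    return FittedModel(
        estimator=est,
        feature_names=matrix.col_names.copy(),
        params=merged,
        seed=seed,
        scheme=scheme,
    )


def predict_notes(model: FittedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Note-level case probabilities; matrix columns must match training."""
    if len(matrix.col_names) != len(model.feature_names) or not np.array_equal(
        matrix.col_names, model.feature_names
    ):
        missing = sorted(set(model.feature_names) - set(matrix.col_names))
        extra = sorted(set(matrix.col_names) - set(model.feature_names))
        raise ValueError(
            "matrix columns do not match training columns "
            f"(missing={missing[:5]}, extra={extra[:5]}, order must also match)"
        )
    return model.estimator.predict_proba(_as_xgb_input(matrix))[:, 1]


@dataclass
class SearchSpec:
    """Randomized hyperparameter-search configuration."""

    n_iterations: int = 100
    cv_folds: int = 5
    parameter_distributions: dict = field(default_factory=dict)
    seed: int = 0
    top_k: int = 5

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _default_distributions(rng: np.random.Generator) -> dict:
    return {
        "max_depth": lambda: int(rng.integers(2, 11)),
        "learning_rate": lambda: float(np.exp(rng.uniform(np.log(0.01), np.log(0.3)))),
        "n_estimators": lambda: int(rng.integers(50, 501)),
        "subsample": lambda: float(rng.uniform(0.5, 1.0)),
        "colsample_bynode": lambda: float(rng.uniform(0.5, 1.0)),
        "min_child_weight": lambda: int(rng.integers(1, 11)),
    }


def _patient_auc(probs, patient_ids, labels) -> float:
    frame = pd.DataFrame({
        "patient_id": np.asarray(patient_ids, dtype=object),
        "probability": np.asarray(probs, float),
        "case": _as_labels(labels),
    })
    grouped = frame.groupby("patient_id").agg(probability=("probability", "mean"), case=("case", "first"))
    return evaluate.auc((grouped["probability"].to_numpy(), grouped["case"].to_numpy()))


def search_hyperparameters(
    train_matrix: FeatureMatrix,
    train_labels,
    train_patient_ids,
    val_matrix: FeatureMatrix,
    val_labels,
    val_patient_ids,
    scheme: WeightingScheme | None = None,
    spec: SearchSpec | None = None,
) -> tuple[FittedModel, dict]:
    """Randomized search: patient-grouped CV for coarse ranking, then final
    selection on the withheld validation partition.

    Samples ``n_iterations`` configurations, scores each by mean patient-level
    AUC over patient-grouped ``cv_folds``-fold CV on the training data, refits
    the ``top_k`` best on the full training partition, and returns the refit
    whose validation patient-level AUC is highest, together with its
    configuration. Deterministic under ``spec.seed``.
    """
    spec = spec or SearchSpec()
    val_y = _as_labels(val_labels)
    if val_y.all() or not val_y.any():
        raise ValueError("validation partition lacks both classes")
    rng = np.random.default_rng(spec.seed)
    samplers = dict(_default_distributions(rng))
    samplers.update(spec.parameter_distributions)
    configs = [{k: draw() for k, draw in samplers.items()} for _ in range(spec.n_iterations)]

    groups = np.asarray(train_patient_ids, dtype=object)
    y = _as_labels(train_labels)
    n_folds = min(spec.cv_folds, len(set(groups)))
    cv = GroupKFold(n_splits=n_folds)
    cv_scores = []
    for cfg in configs:
        fold_scores = []
        for tr, te in cv.split(np.zeros(len(y)), y, groups):
            if y[tr].all() or not y[tr].any() or y[te].all() or not y[te].any():
                continue
            sub = FeatureMatrix(
                row_ids=train_matrix.row_ids[tr],
                col_names=train_matrix.col_names,
                values=train_matrix.values[tr] if not sp.issparse(train_matrix.values)
                else train_matrix.values.tocsr()[tr],
                col_tags=train_matrix.col_tags,
            )
            m = train_classifier(sub, y[tr], scheme=scheme, params=cfg, seed=spec.seed)
            held = train_matrix.values[te] if not sp.issparse(train_matrix.values) \
                else train_matrix.values.tocsr()[te]
            probs = m.estimator.predict_proba(held if not sp.issparse(held) else held.tocsr())[:, 1]
            fold_scores.append(_patient_auc(probs, groups[te], y[te]))
        cv_scores.append(float(np.mean(fold_scores)) if fold_scores else -np.inf)

    order = np.argsort(cv_scores)[::-1][: spec.top_k]
    best_model, best_cfg, best_val = None, None, -np.inf
    for i in order:
        m = train_classifier(train_matrix, y, scheme=scheme, params=configs[i], seed=spec.seed)
        val_auc = _patient_auc(predict_notes(m, val_matrix), val_patient_ids, val_y)
        if val_auc > best_val:
            best_model, best_cfg, best_val = m, dict(configs[i]), val_auc
    best_cfg["validation_patient_auc"] = float(best_val)
    return best_model, best_cfg
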