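"""End-to-end tier-stratified experiment.

For every risk tier present in the cohort and every requested feature mode
(semantic / count / joint), the experiment: filters notes to the analysis
window, tokenizes, fits the df-filtered vocabulary on the tier's *training*
notes only, builds the feature matrices, trains a note-level boosted-tree
classifier (for the joint mode, sweeping the α grid and selecting by
validation patient-level AUC), and evaluates on the withheld test partition
with bootstrap CIs — emitting a per-tier comparison table (AUC [95% CI] per
mode, best β for joint) plus the document/patient metric batteries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import cohort as cohort_mod
from . import count_features, evaluate, fusion, model, semantic_features, textprep
from .matrix import FeatureMatrix

FEATURE_MODES = ("semantic", "count", "joint")


@dataclass
class RunConfig:
    """Everything a full experiment run needs besides the data."""

    window_min_days: int = 5
    window_max_days: int = 30
    min_df: int = count_features.DEFAULT_MIN_DF
    max_df: float = count_features.DEFAULT_MAX_DF
    ngram_orders: frozenset = frozenset({1, 2})
    weighting: str = "count"  # count | tfidf
    alpha_grid: tuple = fusion.DEFAULT_ALPHA_GRID
    fractions: tuple = model.DEFAULT_FRACTIONS
    split_seed: int = 0
    model_seed: int = 0
    model_params: dict = field(default_factory=dict)
    class_weighting: bool = True
    search_iterations: int = 0  # 0 = fixed default hyperparameters
    search_cv_folds: int = 5
    search_seed: int = 0
    n_boot: int = 1000
    threshold: float = 0.5
    eval_seed: int = 0
    feature_modes: tuple = FEATURE_MODES
    stopwords: frozenset | None = None


def _partition_ids(notes: pd.DataFrame, plan: model.SplitPlan) -> pd.Series:
    return notes["patient_id"].map(plan.assignment)


def _rows(matrix: FeatureMatrix, note_ids) -> FeatureMatrix:
    return matrix.take_rows(list(note_ids))


def _fit_mode(
    matrix: FeatureMatrix,
    notes: pd.DataFrame,
    parts: pd.Series,
    labels: pd.Series,
    scheme,
    config: RunConfig,
):
    """Train on the train partition (optionally via randomized search)."""
    train_ids = notes.loc[parts == "train", "note_id"]
    val_ids = notes.loc[parts == "validation", "note_id"]
    train_m = _rows(matrix, train_ids)
    y_train = labels.loc[parts == "train"].to_numpy()
    if config.search_iterations > 0:
        val_m = _rows(matrix, val_ids)
        spec = model.SearchSpec(
            n_iterations=config.search_iterations,
            cv_folds=config.search_cv_folds,
            seed=config.search_seed,
        )
        fitted, chosen = model.search_hyperparameters(
            train_m, y_train, notes.loc[parts == "train", "patient_id"].to_numpy(),
            val_m, labels.loc[parts == "validation"].to_numpy(),
            notes.loc[parts == "validation", "patient_id"].to_numpy(),
            scheme=scheme, spec=spec,
        )
        return fitted, chosen
    fitted = model.train_classifier(
        train_m, y_train, scheme=scheme, params=config.model_params,
        seed=config.model_seed, class_weighting=config.class_weighting,
    )
    return fitted, dict(fitted.params)


def _val_patient_auc(fitted, matrix, notes, parts):
    val_notes = notes.loc[parts == "validation"]
    probs = model.predict_notes(fitted, _rows(matrix, val_notes["note_id"]))
    return model._patient_auc(probs, val_notes["patient_id"].to_numpy(),
                              val_notes["status"].to_numpy())


def _report_dict(rep: evaluate.EvaluationReport) -> dict:
    return {
        "auc": rep.auc, "ci_low": rep.ci_low, "ci_high": rep.ci_high,
        "n_boot": rep.n_boot, "threshold": rep.threshold, "metrics": rep.metrics,
    }


def run_experiment(
    cohort: pd.DataFrame,
    notes: pd.DataFrame,
    lexicons,
    config: RunConfig | None = None,
) -> dict:
    """Run the tier × feature-mode comparison; returns the report mapping.

    Report layout: ``report["tiers"][tier][mode]`` holds test-set document and
    patient evaluations plus the selected α/β and hyperparameters for joint
    models; ``report["comparison"]`` is the flat tier × mode AUC table.
    """
    config = config or RunConfig()
    cohort = cohort_mod.validate_cohort(cohort)
    notes = cohort_mod.filter_window(
        notes, cohort, min_days=config.window_min_days, max_days=config.window_max_days
    )
    report: dict = {"tiers": {}, "comparison": []}

    for tier in cohort_mod.TIERS:
        tier_cohort = cohort.loc[cohort["tier"] == tier].reset_index(drop=True)
        if tier_cohort.empty:
            continue
        entry: dict = {}
        report["tiers"][tier] = entry
        tier_notes = notes.loc[notes["patient_id"].isin(set(tier_cohort["patient_id"]))].reset_index(drop=True)
        status = tier_cohort.set_index("patient_id")["status"]
        tier_notes = tier_notes.assign(status=tier_notes["patient_id"].map(status))

        plan = model.grouped_split(tier_cohort, fractions=config.fractions, seed=config.split_seed)
        parts = _partition_ids(tier_notes, plan)
        ok = True
        for part in model.PARTITIONS:
            sub = tier_notes.loc[parts == part, "status"]
            if (sub == "case").sum() < 2 or (sub == "control").sum() < 2:
                entry["skipped"] = f"partition {part!r} lacks at least 2 case and 2 control notes"
                ok = False
                break
        if not ok:
            continue

        streams = [
            textprep.tokenize(t, stopwords=config.stopwords, note_id=nid)
            for nid, t in zip(tier_notes["note_id"], tier_notes["text"])
        ]
        train_streams = [s for s, p in zip(streams, parts) if p == "train"]
        vocab = count_features.fit_vocabulary(
            train_streams, min_df=config.min_df, max_df=config.max_df,
            ngram_orders=config.ngram_orders,
        )
        entry["vocab_size"] = len(vocab)
        entry["n_notes"] = int(len(tier_notes))
        entry["n_patients"] = int(len(tier_cohort))

        count_m = count_features.transform_counts(streams, vocab)
        if config.weighting == "tfidf":
            count_m = count_features.tfidf_transform(count_m, vocab)
        sem_m = semantic_features.featurize_semantic(streams, lexicons)
        labels = tier_notes["status"]
        test_notes = tier_notes.loc[parts == "test"]

        for mode in config.feature_modes:
            try:
                if mode == "count":
                    if len(vocab) == 0:
                        entry[mode] = {"skipped": "empty vocabulary after df filtering"}
                        continue
                    fitted, chosen = _fit_mode(count_m, tier_notes, parts, labels, None, config)
                    matrix, alpha = count_m, None
                elif mode == "semantic":
                    fitted, chosen = _fit_mode(sem_m, tier_notes, parts, labels, None, config)
                    matrix, alpha = sem_m, None
                elif mode == "joint":
                    if len(vocab) == 0:
                        entry[mode] = {"skipped": "empty vocabulary after df filtering"}
                        continue
                    joint = fusion.merge_matrices(count_m, sem_m)
                    best = None
                    for a in config.alpha_grid:
                        scheme = fusion.compute_weights(count_m.shape[1], sem_m.shape[1], a)
                        f, ch = _fit_mode(joint, tier_notes, parts, labels, scheme, config)
                        va = _val_patient_auc(f, joint, tier_notes, parts)
                        if best is None or va > best[0]:
                            best = (va, a, f, ch)
                    _, alpha, fitted, chosen = best
                    matrix = joint
                else:
                    raise ValueError(f"unknown feature mode {mode!r}")
            except ValueError as err:
                warnings.warn(f"tier {tier!r} mode {mode!r} failed: {err}")
                entry[mode] = {"skipped": str(err)}
                continue

            probs = model.predict_notes(fitted, _rows(matrix, test_notes["note_id"]))
            test_cohort = tier_cohort.loc[
                tier_cohort["patient_id"].isin(set(test_notes["patient_id"]))
            ]
            reports = evaluate.evaluate_predictions(
                probs, test_notes["patient_id"].to_numpy(), test_cohort,
                n_boot=config.n_boot, threshold=config.threshold, seed=config.eval_seed,
            )
            entry[mode] = {
                "document": _report_dict(reports["document"]),
                "patient": _report_dict(reports["patient"]),
                "alpha": alpha,
                "beta": None if alpha is None else fusion.beta_from_alpha(alpha),
                "chosen_params": {k: v for k, v in chosen.items()},
                "n_features": int(matrix.shape[1]),
            }
            pat = reports["patient"]
            report["comparison"].append({
                "tier": tier, "mode": mode, "auc": pat.auc,
                "ci_low": pat.ci_low, "ci_high": pat.ci_high,
                "beta": None if alpha is None else fusion.beta_table([alpha])[0],
            })

        pairs = [(a, b) for i, a in enumerate(config.feature_modes)
                 for b in config.feature_modes[i + 1:]]
        sig = {}
        for a, b in pairs:
            ra, rb = entry.get(a), entry.get(b)
            if ra and rb and "patient" in ra and "patient" in rb:
                sig[f"{a}_vs_{b}"] = evaluate.significance_by_overlap(
                    (ra["patient"]["ci_low"], ra["patient"]["ci_high"]),
                    (rb["patient"]["ci_low"], rb["patient"]["ci_high"]),
                )
        entry["significance"] = sig

    return report


def comparison_frame(report: dict) -> pd.DataFrame:
    """The tier × mode comparison as a DataFrame (one row per model)."""
    return pd.DataFrame(report["comparison"])
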