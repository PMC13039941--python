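"""Patient-level evaluation: aggregation, concordance AUC, bootstrap CIs.

Classifiers in this package score individual notes, but the outcome lives at
the patient level, so a patient's score is the arithmetic mean of their note
probabilities. Because controls are matched to cases on the baseline risk
percentile, an AUC above 0.50 measures discrimination *beyond* the baseline
model. AUC is computed as the Wilcoxon–Mann–Whitney concordance — over all
case-control pairs, (wins + 0.5·ties) / pairs — which equals the trapezoidal
area under the ROC curve. Uncertainty comes from a status-stratified
non-parametric bootstrap over patients (default 1000 resamples, 95%
percentile interval), and two models are called significantly different iff
their intervals do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def aggregate_patients(
    note_probs,
    note_patient_ids,
    cohort: pd.DataFrame,
) -> pd.DataFrame:
    """Average note-level probabilities per patient.

    Returns a frame with ``patient_id, probability, n_notes, status`` —
    one row per patient holding at least one scored note. Cohort patients
    with no scored notes are omitted with a warning.
    """
    probs = np.asarray(note_probs, dtype=float)
    pids = np.asarray(note_patient_ids, dtype=object)
    if probs.shape[0] != pids.shape[0]:
        raise ValueError("note_probs and note_patient_ids differ in length")
    status = cohort.set_index("patient_id")["status"]
    unknown = sorted(set(pids) - set(status.index))
    if unknown:
        raise ValueError(f"scored notes reference unknown patients: {unknown[:5]}")
    grouped = pd.DataFrame({"patient_id": pids, "probability": probs}).groupby(
        "patient_id", sort=True
    )["probability"].agg(["mean", "size"])
    missing = len(status) - len(grouped)
    if missing:
        warnings.warn(f"{missing} cohort patients have no scored notes and are omitted")
    out = grouped.reset_index().rename(columns={"mean": "probability", "size": "n_notes"})
    out["status"] = out["patient_id"].map(status).to_numpy()
    return out


def _scores_labels(scores) -> tuple[np.ndarray, np.ndarray]:
    """Accepts the aggregate_patients frame or (probs, labels)."""
    if isinstance(scores, pd.DataFrame):
        return scores["probability"].to_numpy(float), (scores["status"] == "case").to_numpy()
    probs, labels = scores
    return np.asarray(probs, dtype=float), np.asarray(labels, dtype=bool)


def auc(scores) -> float:
    """Probability-of-concordance AUC with ties counted 0.5.

    ``scores`` is either the frame from :func:`aggregate_patients` or a
    ``(probabilities, case_indicator)`` pair. Midranks make this the exact
    Mann–Whitney estimator, identical to trapezoidal ROC integration.
    """
    probs, is_case = _scores_labels(scores)
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one case and one control")
    ranks = rankdata(probs)
    return (ranks[is_case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_ci(
    scores,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the patient-level AUC.

    Patients are resampled with replacement, stratified by status so every
    replicate contains both classes. Reproducible under ``seed``.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    probs, is_case = _scores_labels(scores)
    case_p, ctrl_p = probs[is_case], probs[~is_case]
    if len(case_p) < 1 or len(ctrl_p) < 1:
        raise ValueError("bootstrap requires both classes")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        cp = case_p[rng.integers(0, len(case_p), len(case_p))]
        np_ = ctrl_p[rng.integers(0, len(ctrl_p), len(ctrl_p))]
        pooled = np.concatenate([cp, np_])
        mask = np.zeros(len(pooled), dtype=bool)
        mask[: len(cp)] = True
        stats[b] = auc((pooled, mask))
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


@dataclass
class EvaluationReport:
    """One evaluation at one level (document or patient)."""

    level: str
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int = 1000
    metrics: dict = field(default_factory=dict)
    threshold: float = 0.5


def significance_by_overlap(report_a, report_b) -> bool:
    """True iff the two 95% CIs are disjoint (the CI-overlap rule)."""
    a_lo, a_hi = (report_a.ci_low, report_a.ci_high) if isinstance(report_a, EvaluationReport) else report_a
    b_lo, b_hi = (report_b.ci_low, report_b.ci_high) if isinstance(report_b, EvaluationReport) else report_b
    return a_hi < b_lo or b_hi < a_lo


def metric_battery(probs, labels, threshold: float = 0.5) -> dict:
    """Brier score plus the thresholded confusion-matrix battery.

    ``labels`` is a case indicator (bool / 0-1 / 'case'-'control'). Ratios
    with empty denominators (e.g. precision with no predicted positives) are
    reported as 0.0 and listed under ``degenerate``.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    y = (labels == "case") if labels.dtype.kind in "OUS" else labels.astype(bool)
    pred = probs >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    npv = ratio(tn, tn + fn, "npv")
    f1 = ratio(2 * precision * recall, precision + recall, "f1") if (precision + recall) > 0 else (
        degenerate.append("f1") or 0.0
    )
    return {
        "brier": float(np.mean((probs - y.astype(float)) ** 2)),
        "accuracy": (tp + tn) / len(y) if len(y) else 0.0,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "ppv": precision,
        "npv": npv,
        "f1": f1,
        "degenerate": degenerate,
    }


def evaluate_predictions(
    note_probs,
    note_patient_ids,
    cohort: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Full two-level report: document-level and patient-level batteries.

    Returns ``{"document": EvaluationReport, "patient": EvaluationReport}``.
    """
    status = cohort.set_index("patient_id")["status"]
    note_labels = pd.Series(list(note_patient_ids)).map(status).to_numpy()
    doc_scores = (np.asarray(note_probs, float), note_labels == "case")
    doc_ci = bootstrap_ci(doc_scores, n_boot=n_boot, level=level, seed=seed)
    doc = EvaluationReport(
        level="document", auc=auc(doc_scores), ci_low=doc_ci[0], ci_high=doc_ci[1],
        n_boot=n_boot, threshold=threshold,
        metrics=metric_battery(doc_scores[0], doc_scores[1], threshold),
    )
    pat_frame = aggregate_patients(note_probs, note_patient_ids, cohort)
    pat_ci = bootstrap_ci(pat_frame, n_boot=n_boot, level=level, seed=seed + 1)
    pat = EvaluationReport(
        level="patient", auc=auc(pat_frame), ci_low=pat_ci[0], ci_high=pat_ci[1],
        n_boot=n_boot, threshold=threshold,
        metrics=metric_battery(
            pat_frame["probability"].to_numpy(), (pat_frame["status"] == "case").to_numpy(), threshold
        ),
    )
    return {"document": doc, "patient": pat}
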