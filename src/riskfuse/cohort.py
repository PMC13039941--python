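"""Cohort construction: risk tiers, matched controls, note-window filtering.

Patients carry a baseline risk percentile (1..100, 1 = riskiest) produced by
an upstream structured-data model. The percentile does double duty here: it
assigns each patient to a risk tier (high / moderate / low) and it is the
matching variable — each case is paired with ``k`` controls sharing its exact
percentile (and facility, when known), so any discrimination the downstream
text models achieve is *beyond* the baseline score, not beyond chance.

A cohort is a :class:`pandas.DataFrame` with at least the columns
``patient_id, status, index_date, percentile, tier, match_group``; notes are a
DataFrame with ``note_id, patient_id, note_date, text``.
"""

from __future__ import annotations

import math
import warnings
from numbers import Integral

import numpy as np
import pandas as pd

TIERS = ("high", "moderate", "low")

#: Columns every cohort table must carry.
COHORT_COLUMNS = ("patient_id", "status", "index_date", "percentile", "tier", "match_group")
NOTE_COLUMNS = ("note_id", "patient_id", "note_date", "text")


def assign_tier(percentile) -> str:
    """Map a risk percentile to its tier.

    Percentile 1 is the highest-risk stratum; 2–24 is moderate; 25–100 low.
    """
    if isinstance(percentile, bool) or not isinstance(percentile, (Integral, np.integer)):
        raise ValueError(f"percentile must be an integer, got {percentile!r}")
    p = int(percentile)
    if not 1 <= p <= 100:
        raise ValueError(f"percentile must lie in [1, 100], got {p}")
    if p == 1:
        return "high"
    if p <= 24:
        return "moderate"
    return "low"


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check cohort invariants; returns the frame with tier filled in."""
    missing = [c for c in COHORT_COLUMNS if c != "tier" and c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    cohort = cohort.copy()
    cohort["index_date"] = pd.to_datetime(cohort["index_date"]).dt.normalize()
    cohort["tier"] = [assign_tier(int(p)) for p in cohort["percentile"]]
    if cohort["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in cohort")
    bad_status = set(cohort["status"]) - {"case", "control"}
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    for mg, grp in cohort.groupby("match_group"):
        if (grp["status"] == "case").sum() != 1:
            raise ValueError(f"match group {mg!r} does not contain exactly one case")
        if grp["percentile"].nunique() != 1 or grp["index_date"].nunique() != 1:
            raise ValueError(f"match group {mg!r} is not percentile/index-date homogeneous")
    return cohort


def filter_window(
    notes: pd.DataFrame,
    cohort: pd.DataFrame,
    min_days: int = 5,
    max_days: int = 30,
) -> pd.DataFrame:
    """Retain notes dated ``min_days``..``max_days`` whole days before the
    patient's index date (both bounds inclusive).

    Notes closer to the index date than ``min_days`` are discarded — records
    entered just before (or misdated just after) the index event can leak
    outcome information. Notes after the index date or beyond ``max_days``
    are likewise dropped. Dropping is silent; an unknown ``patient_id`` is an
    error.
    """
    if not min_days < max_days:
        raise ValueError(f"require min_days < max_days, got {min_days} >= {max_days}")
    known = set(cohort["patient_id"])
    unknown = sorted(set(notes["patient_id"]) - known)
    if unknown:
        raise ValueError(f"notes reference unknown patients: {unknown[:5]}")
    index_dates = cohort.set_index("patient_id")["index_date"]
    note_dates = pd.to_datetime(notes["note_date"]).dt.normalize()
    idx = pd.to_datetime(notes["patient_id"].map(index_dates)).dt.normalize()
    days_before = (idx - note_dates).dt.days
    keep = (days_before >= min_days) & (days_before <= max_days)
    return notes.loc[keep.to_numpy()].reset_index(drop=True)


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair each case with up to ``k`` exact-percentile controls.

    Matching is greedy over a randomized case order (controlled by ``seed``):
    for each case, ``k`` controls sharing its percentile — and its facility,
    when both tables carry a ``facility`` column — are drawn at random from
    the still-unused pool. Controls are used at most once. Controls inherit
    the case's index date (equal "follow-up" time by construction). Cases with
    fewer than ``k`` eligible controls keep whatever was found and are marked
    ``short_group=True``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rng = np.random.default_rng(seed)
    use_facility = "facility" in cases.columns and "facility" in pool.columns

    pool = pool.reset_index(drop=True)
    used = np.zeros(len(pool), dtype=bool)
    by_key: dict = {}
    for i, row in pool.iterrows():
        key = (int(row["percentile"]), row["facility"]) if use_facility else int(row["percentile"])
        by_key.setdefault(key, []).append(i)

    order = rng.permutation(len(cases))
    rows = []
    for gi, ci in enumerate(order):
        case = cases.iloc[ci]
        key = (int(case["percentile"]), case["facility"]) if use_facility else int(case["percentile"])
        eligible = [i for i in by_key.get(key, []) if not used[i]]
        if len(pool) == 0:
            warnings.warn(f"empty control pool; case {case['patient_id']} unmatched")
        take = rng.choice(eligible, size=min(k, len(eligible)), replace=False) if eligible else []
        short = len(take) < k
        mg = f"mg{gi:06d}"
        crow = case.to_dict()
        crow.update(status="case", match_group=mg, short_group=short)
        rows.append(crow)
        for i in take:
            used[i] = True
            ctl = pool.iloc[i].to_dict()
            ctl.update(
                status="control",
                match_group=mg,
                short_group=short,
                index_date=case["index_date"],
                percentile=int(case["percentile"]),
            )
            rows.append(ctl)

    out = pd.DataFrame(rows).reset_index(drop=True)
    return validate_cohort(out)


def compute_smd(cohort: pd.DataFrame, covariate: str) -> tuple[float, str]:
    """Standardized mean difference of a covariate between cases and controls.

    ``|mean_case − mean_control| / sqrt((var_case + var_control) / 2)``.
    A covariate whose observed values are all 0/1 is treated as binary and
    uses the proportion variance ``p(1 − p)``. Returns ``(value, label)``
    with label thresholds 0.2 / 0.5 / 0.8 (negligible / small / medium /
    large).
    """
    vals = cohort[[covariate, "status"]].dropna()
    case = vals.loc[vals["status"] == "case", covariate].astype(float)
    ctrl = vals.loc[vals["status"] == "control", covariate].astype(float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(f"covariate {covariate!r} present for <2 patients in an arm")
    binary = set(np.unique(vals[covariate].astype(float))) <= {0.0, 1.0}
    if binary:
        p1, p0 = case.mean(), ctrl.mean()
        var1, var0 = p1 * (1 - p1), p0 * (1 - p0)
        diff = abs(p1 - p0)
    else:
        diff = abs(case.mean() - ctrl.mean())
        var1, var0 = case.var(ddof=1), ctrl.var(ddof=1)
    pooled = math.sqrt((var1 + var0) / 2.0)
    if pooled == 0.0:
        if diff == 0.0:
            smd = 0.0
        else:
            warnings.warn(f"zero pooled SD with unequal means for {covariate!r}")
            smd = math.inf
    else:
        smd = diff / pooled
    if smd < 0.2:
        label = "negligible"
    elif smd < 0.5:
        label = "small"
    elif smd < 0.8:
        label = "medium"
    else:
        label = "large"
    return smd, label
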