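import numpy as np
import pandas as pd
import pytest

from riskfuse.evaluate import auc
from riskfuse.fusion import compute_weights, merge_matrices
from riskfuse.matrix import FeatureMatrix
from riskfuse.model import (
    SearchSpec,
    grouped_split,
    predict_notes,
    search_hyperparameters,
    train_classifier,
)
from riskfuse.synthdata import GeneratorSpec, generate_cohort


def _plain_cohort(n, n_cases):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "status": ["case"] * n_cases + ["control"] * (n - n_cases),
    })


def _fm(values, tag="count", prefix="f", row_prefix="n"):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        row_ids=np.asarray([f"{row_prefix}{i}" for i in range(values.shape[0])], dtype=object),
        col_names=np.asarray([f"{prefix}{j}" for j in range(values.shape[1])], dtype=object),
        values=values,
        col_tags=np.full(values.shape[1], tag, dtype=object),
    )


def _signal_data(rng, n_notes=400, n_noise=40, n_signal=5, flip=0.02):
    """Count-style matrix where a handful of columns carry the label."""
    y = rng.random(n_notes) < 0.3
    noise = rng.poisson(1.0, size=(n_notes, n_noise))
    signal = rng.poisson(0.2, size=(n_notes, n_signal)) + rng.poisson(
        3.0, size=(n_notes, n_signal)
    ) * y[:, None]
    keep = rng.random(n_notes) > flip
    y = np.where(keep, y, ~y)  # small label noise keeps it non-degenerate
    return _fm(np.hstack([noise, signal])), y


class TestGroupedSplit:
    def test_fraction_targets_at_scale(self):
        cohort = generate_cohort(GeneratorSpec(n_cases=167, seed=5))  # 1002 patients
        plan = grouped_split(cohort, seed=9)
        counts = pd.Series(plan.assignment).value_counts(normalize=True)
        for part, frac in zip(("train", "validation", "test"), (0.64, 0.16, 0.20)):
            assert abs(counts[part] - frac) < 0.02
        assert len(plan.assignment) == len(cohort)

    def test_match_groups_stay_intact_by_default(self):
        cohort = generate_cohort(GeneratorSpec(n_cases=40, seed=2))
        plan = grouped_split(cohort, seed=1)
        parts = cohort["patient_id"].map(plan.assignment)
        assert (cohort.assign(part=parts).groupby("match_group")["part"].nunique() == 1).all()

    def test_patient_unit_hits_exact_sizes(self):
        cohort = _plain_cohort(100, 20)
        plan = grouped_split(cohort, seed=0, unit="patient")
        counts = pd.Series(plan.assignment).value_counts()
        assert (counts["train"], counts["validation"], counts["test"]) == (64, 16, 20)

    def test_deterministic_under_seed(self):
        cohort = _plain_cohort(60, 10)
        a = grouped_split(cohort, seed=7, unit="patient").assignment
        b = grouped_split(cohort, seed=7, unit="patient").assignment
        c = grouped_split(cohort, seed=8, unit="patient").assignment
        assert a == b
        assert a != c

    def test_every_patient_in_exactly_one_partition(self):
        cohort = generate_cohort(GeneratorSpec(n_cases=30, seed=3))
        plan = grouped_split(cohort, seed=0)
        assert set(plan.assignment) == set(cohort["patient_id"])
        assert set(plan.assignment.values()) <= {"train", "validation", "test"}

    def test_single_class_partition_warns(self):
        with pytest.warns(UserWarning, match="lacks both classes"):
            grouped_split(_plain_cohort(5, 1), seed=0, unit="patient")

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            grouped_split(_plain_cohort(10, 5), fractions=(0.5, 0.5, 0.5))


class TestTrainClassifier:
    def test_separates_planted_count_signal(self, rng):
        fm, y = _signal_data(rng)
        model = train_classifier(fm, y, seed=0)
        train_auc = auc((predict_notes(model, fm), y))
        assert train_auc > 0.9

    def test_single_class_labels_rejected(self, rng):
        fm, _ = _signal_data(rng, n_notes=20)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(fm, np.ones(20, dtype=bool))

    def test_deterministic_predictions(self, rng):
        fm, y = _signal_data(rng)
        p1 = predict_notes(train_classifier(fm, y, seed=4), fm)
        p2 = predict_notes(train_classifier(fm, y, seed=4), fm)
        np.testing.assert_array_equal(p1, p2)

    def test_vanishing_semantic_weight_suppresses_semantic_only_signal(self, rng):
        # signal lives exclusively in 2 semantic columns; counts are noise
        n = 500
        y = np.repeat([True, False], [150, 350])
        counts = _fm(rng.poisson(1.0, size=(n, 60)), tag="count")
        sem_vals = 0.05 * rng.random((n, 2)) + 0.1 * y[:, None]
        sem = _fm(sem_vals, tag="semantic", prefix="s")
        joint = merge_matrices(counts, sem)
        tr = rng.random(n) < 0.7
        jtr = joint.take_rows(joint.row_ids[tr])
        jte = joint.take_rows(joint.row_ids[~tr])
        params = {"colsample_bynode": 0.5}

        def test_auc(alpha):
            scheme = compute_weights(60, 2, alpha)
            m = train_classifier(jtr, y[tr], scheme=scheme, params=params, seed=0)
            return auc((predict_notes(m, jte), y[~tr]))

        assert test_auc(1e-6) < 0.58        # semantic set never sampled
        assert test_auc(5.0) > 0.9          # semantic set dominant

    def test_labels_accepted_as_strings(self, rng):
        fm, y = _signal_data(rng, n_notes=60)
        labels = np.where(y, "case", "control")
        model = train_classifier(fm, labels, seed=1)
        assert predict_notes(model, fm).shape == (60,)


class TestPredictNotes:
    def test_probability_codomain(self, rng):
        fm, y = _signal_data(rng, n_notes=80)
        probs = predict_notes(train_classifier(fm, y, seed=0), fm)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_column_mismatch_rejected(self, rng):
        fm, y = _signal_data(rng, n_notes=60)
        model = train_classifier(fm, y, seed=0)
        shuffled = FeatureMatrix(
            row_ids=fm.row_ids,
            col_names=fm.col_names[::-1].copy(),
            values=fm.toarray()[:, ::-1],
            col_tags=fm.col_tags,
        )
        with pytest.raises(ValueError, match="columns"):
            predict_notes(model, shuffled)

    def test_all_zero_row_scores_a_valid_probability(self, rng):
        fm, y = _signal_data(rng, n_notes=60)
        model = train_classifier(fm, y, seed=0)
        zero = FeatureMatrix(
            row_ids=np.array(["z"], dtype=object),
            col_names=fm.col_names,
            values=np.zeros((1, fm.shape[1])),
            col_tags=fm.col_tags,
        )
        assert 0.0 <= predict_notes(model, zero)[0] <= 1.0


class TestSearch:
    @staticmethod
    def _split_data(rng):
        fm, y = _signal_data(rng, n_notes=300, n_noise=20)
        pids = np.array([f"p{i // 3}" for i in range(300)], dtype=object)
        # patient-coherent labels: overwrite y so notes share patient label
        y = np.repeat(rng.random(100) < 0.3, 3)
        sig = fm.toarray()
        sig[:, -3:] = rng.poisson(0.2, size=(300, 3)) + 3.0 * y[:, None]
        fm = FeatureMatrix(fm.row_ids, fm.col_names, sig, fm.col_tags)
        val = rng.random(100) < 0.25
        val_mask = np.repeat(val, 3)
        take = lambda m: fm.take_rows(fm.row_ids[m])
        return (take(~val_mask), y[~val_mask], pids[~val_mask],
                take(val_mask), y[val_mask], pids[val_mask])

    def test_single_iteration_returns_that_configuration(self, rng):
        tr_m, tr_y, tr_p, va_m, va_y, va_p = self._split_data(rng)
        spec = SearchSpec(n_iterations=1, cv_folds=2, seed=0)
        model, chosen = search_hyperparameters(tr_m, tr_y, tr_p, va_m, va_y, va_p, spec=spec)
        assert model.params["max_depth"] == chosen["max_depth"]
        assert "validation_patient_auc" in chosen

    def test_dominant_configuration_wins(self, rng):
        tr_m, tr_y, tr_p, va_m, va_y, va_p = self._split_data(rng)
        draws = iter([1, 60])
        weak_strong = {"n_estimators": lambda: next(draws)}
        spec = SearchSpec(n_iterations=2, cv_folds=2, seed=0,
                          parameter_distributions=weak_strong)
        model, chosen = search_hyperparameters(tr_m, tr_y, tr_p, va_m, va_y, va_p, spec=spec)
        assert chosen["n_estimators"] == 60

    def test_deterministic_choice(self, rng):
        tr_m, tr_y, tr_p, va_m, va_y, va_p = self._split_data(rng)
        spec = SearchSpec(n_iterations=3, cv_folds=2, seed=5)
        _, a = search_hyperparameters(tr_m, tr_y, tr_p, va_m, va_y, va_p, spec=spec)
        _, b = search_hyperparameters(tr_m, tr_y, tr_p, va_m, va_y, va_p, spec=spec)
        assert a == b

    def test_single_class_validation_rejected(self, rng):
        tr_m, tr_y, tr_p, va_m, va_y, va_p = self._split_data(rng)
        with pytest.raises(ValueError, match="validation"):
            search_hyperparameters(
                tr_m, tr_y, tr_p, va_m, np.ones_like(va_y, dtype=bool), va_p,
                spec=SearchSpec(n_iterations=1, cv_folds=2),
            )
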