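"""Threshold model: labelling, fitting, CV, transfer and triage."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tff3quant as tq
from tests.conftest import make_records


class TestLabelRule:
    @pytest.mark.parametrize(
        "C, M, expected",
        [
            (1.0, 2.0, tq.RELEVANT),   # C cut-off alone
            (0.0, 3.0, tq.RELEVANT),   # M cut-off alone
            (0.0, 0.0, tq.FOCAL),
            (0.9, 2.9, tq.FOCAL),
            (5.0, 12.0, tq.RELEVANT),
        ],
    )
    def test_cutoffs(self, C, M, expected):
        assert tq.label_clinical_relevance(C, M) == expected

    def test_invalid_lengths(self):
        with pytest.raises(ValueError, match="non-negative"):
            tq.label_clinical_relevance(-1, 2)
        with pytest.raises(ValueError, match="C <= M"):
            tq.label_clinical_relevance(4, 2)


class TestFitCountModel:
    def test_separated_classes_threshold_in_gap(self):
        recs = make_records(
            [0, 1, 2, 30, 40, 50],
            [tq.FOCAL] * 3 + [tq.RELEVANT] * 3,
        )
        with pytest.warns(UserWarning, match="separation"):
            model = tq.fit_count_model(recs)
        assert 2 < model.tile_threshold < 30
        assert model.separated

    def test_constructed_model_threshold_inversion(self):
        model = tq.FittedCountModel(-16.6, 1.0, "identity", 16.6)
        assert model.tile_threshold == pytest.approx(-(-16.6) / 1.0)
        assert model.discrete_threshold == 16

    def test_log1p_threshold_inversion_consistency(self, best2_cohort):
        model = tq.fit_count_model(best2_cohort)
        assert model.slope > 0
        eta_at_threshold = model.intercept + model.slope * np.log1p(model.tile_threshold)
        assert eta_at_threshold == pytest.approx(0.0, abs=1e-9)

    def test_threshold_recovery_against_grid_search(self):
        """Logistic cut-off tracks the balanced-accuracy argmax (median <= 2).

        Near-balanced classes keep the balanced-accuracy optimum at the
        generative boundary; the grid argmax is itself noisy per cohort, so
        the comparison is a median over replicates.
        """
        diffs = []
        for seed in range(10):
            recs = tq.simulate_threshold_cohort(
                n_patients=529, seed=seed, relevant_length_fraction=0.9
            )
            model = tq.fit_count_model(recs)
            counts = np.array([r.tile_count for r in recs])
            y = np.array([r.class_label == tq.RELEVANT for r in recs])
            grid = np.arange(counts.max() + 1) + 0.5
            bal = []
            for t in grid:
                pred = counts >= t
                bal.append((pred[y].mean() + (~pred[~y]).mean()) / 2)
            best = grid[int(np.argmax(bal))]
            diffs.append(abs(model.tile_threshold - best))
        assert np.median(diffs) <= 2

    def test_single_class_rejected(self):
        recs = make_records([1, 2, 3], [tq.FOCAL] * 3)
        with pytest.raises(ValueError, match="both classes"):
            tq.fit_count_model(recs)

    def test_identical_counts_rejected(self):
        recs = make_records([5, 5, 5, 5], [tq.FOCAL, tq.FOCAL, tq.RELEVANT, tq.RELEVANT])
        with pytest.raises(ValueError, match="identical"):
            tq.fit_count_model(recs)

    def test_qc_failures_excluded_from_fit(self):
        good = make_records([1, 2, 3, 20, 30, 40], [tq.FOCAL] * 3 + [tq.RELEVANT] * 3)
        bad = make_records([1000], [tq.FOCAL], qc_pass=False)
        with pytest.warns(UserWarning, match="separation"):
            model = tq.fit_count_model(good + bad)
        assert 3 < model.tile_threshold < 20  # the QC-failed outlier did not enter


class TestPredict:
    def test_threshold_consistency(self, best2_cohort):
        model = tq.fit_count_model(best2_cohort)
        counts = list(range(0, 200))
        preds = tq.predict(model, counts)
        for c, p in zip(counts, preds):
            expected = tq.RELEVANT if c >= model.tile_threshold else tq.FOCAL
            assert p == expected

    def test_prediction_flips_exactly_once(self, best2_cohort):
        model = tq.fit_count_model(best2_cohort)
        preds = tq.predict(model, range(0, 300))
        flips = sum(a != b for a, b in zip(preds, preds[1:]))
        assert flips == 1
        assert preds[0] == tq.FOCAL and preds[-1] == tq.RELEVANT

    @given(st.sampled_from(["identity", "log1p"]))
    def test_transform_invariance_of_decision_rule(self, transform):
        recs = tq.simulate_threshold_cohort(n_patients=400, seed=3)
        model = tq.fit_count_model(recs, feature_transform=transform)
        counts = [0, 5, 10, 15, 16, 17, 25, 100]
        preds = tq.predict(model, counts)
        for c, p in zip(counts, preds):
            assert p == (tq.RELEVANT if c >= model.tile_threshold else tq.FOCAL)


class TestComputeMetrics:
    def test_hand_worked_confusion(self):
        y_true = [tq.RELEVANT, tq.RELEVANT, tq.FOCAL, tq.FOCAL]
        y_pred = [tq.RELEVANT, tq.FOCAL, tq.FOCAL, tq.FOCAL]
        m = tq.compute_metrics(y_true, y_pred)
        assert m.recall_relevant == 0.5
        assert m.recall_focal == 1.0
        assert m.balanced_accuracy == 0.75

    def test_perfect_prediction(self):
        y = [tq.RELEVANT, tq.FOCAL, tq.RELEVANT]
        m = tq.compute_metrics(y, y)
        for v in (m.accuracy, m.balanced_accuracy, m.precision_relevant, m.f1_focal):
            assert v == 1.0

    def test_printed_fold_recall_recomposition(self):
        # recalls 0.74 and 0.92 average to balanced accuracy 0.83
        m = tq.compute_metrics(
            [tq.RELEVANT] * 50 + [tq.FOCAL] * 50,
            [tq.RELEVANT] * 37 + [tq.FOCAL] * 13 + [tq.FOCAL] * 46 + [tq.RELEVANT] * 4,
        )
        assert m.recall_relevant == pytest.approx(0.74)
        assert m.recall_focal == pytest.approx(0.92)
        assert m.balanced_accuracy == pytest.approx(0.83)

    def test_constant_classifier_balanced_half(self):
        y_true = [tq.RELEVANT] * 7 + [tq.FOCAL] * 3
        m = tq.compute_metrics(y_true, [tq.RELEVANT] * 10)
        assert m.balanced_accuracy == 0.5

    def test_single_class_truth_gives_nan_metrics(self):
        m = tq.compute_metrics([tq.FOCAL, tq.FOCAL], [tq.FOCAL, tq.RELEVANT])
        assert math.isnan(m.recall_relevant)
        assert math.isnan(m.precision_focal) or m.precision_focal <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tq.compute_metrics([], [])


class TestCrossValidate:
    def test_deterministic_under_seed(self, best2_cohort):
        a = tq.cross_validate(best2_cohort, k=5, seed=4)
        b = tq.cross_validate(best2_cohort, k=5, seed=4)
        assert a.fold_thresholds == b.fold_thresholds
        assert a.fold_metrics == b.fold_metrics

    def test_mean_sd_recompute_from_folds(self, best2_cohort):
        cv = tq.cross_validate(best2_cohort, k=5, seed=4)
        assert cv.mean_threshold == pytest.approx(np.mean(cv.fold_thresholds))
        assert cv.sd_threshold == pytest.approx(np.std(cv.fold_thresholds, ddof=1))
        mean_row = cv.mean_row()
        assert mean_row["balanced_accuracy"] == pytest.approx(
            np.mean([m["balanced_accuracy"] for m in cv.fold_metrics])
        )

    def test_small_cohort_mechanics(self):
        recs = make_records(
            [0, 1, 2, 3, 4, 30, 35, 40, 45, 50],
            [tq.FOCAL] * 5 + [tq.RELEVANT] * 5,
        )
        with pytest.warns(UserWarning, match="separation"):
            cv = tq.cross_validate(recs, k=5, seed=0)
        assert len(cv.fold_thresholds) == 5

    def test_k_exceeding_n_rejected(self):
        recs = make_records([1, 20], [tq.FOCAL, tq.RELEVANT])
        with pytest.raises(ValueError, match="k=5"):
            tq.cross_validate(recs, k=5)


class TestTransferAndTriage:
    def test_self_transfer_equals_resubstitution(self, best2_cohort):
        model, metrics, _ = tq.train_and_transfer(best2_cohort, best2_cohort)
        kept = [r for r in best2_cohort if r.qc_pass]
        resub = tq.compute_metrics(
            [r.class_label for r in kept], tq.predict(model, kept)
        )
        assert metrics == resub

    def test_transfer_threshold_stability_across_prevalence(self):
        train = tq.simulate_threshold_cohort(529, seed=31, cohort_tag="train_like")
        cv = tq.cross_validate(train, k=5, seed=31)
        model, _, _ = tq.train_and_transfer(
            train,
            tq.simulate_threshold_cohort(
                158, seed=32, relevant_length_fraction=0.296, cohort_tag="test_like"
            ),
        )
        assert abs(cv.mean_threshold - model.tile_threshold) <= 1.0

    def test_all_below_threshold_recall_zero(self):
        train = make_records(
            [0, 1, 2, 50, 60, 70], [tq.FOCAL] * 3 + [tq.RELEVANT] * 3
        )
        test = make_records([1, 2, 3], [tq.FOCAL, tq.RELEVANT, tq.RELEVANT])
        with pytest.warns(UserWarning, match="separation"):
            _, metrics, triage = tq.train_and_transfer(train, test)
        assert metrics.recall_relevant == 0.0
        assert triage.pct_avoid_gastroscopy == 100.0

    def test_triage_extremes(self, best2_cohort):
        always_relevant = tq.FittedCountModel(1.0, 1.0, "identity", -1.0)
        t = tq.triage_summary(always_relevant, best2_cohort)
        assert t.pct_avoid_gastroscopy == 0.0 and t.pct_missed == 0.0

        never_relevant = tq.FittedCountModel(-(10**9), 1.0, "identity", 10**9)
        t = tq.triage_summary(never_relevant, best2_cohort)
        prevalence = np.mean([r.class_label == tq.RELEVANT for r in best2_cohort])
        assert t.pct_avoid_gastroscopy == 100.0
        assert t.pct_missed == pytest.approx(100 * prevalence)

    def test_empty_cohort_rejected(self):
        model = tq.FittedCountModel(0.0, 1.0, "identity", 5.0)
        with pytest.raises(ValueError, match="empty"):
            tq.triage_summary(model, [])

    def test_threshold_recovery_median_error(self):
        """Median |recovered - 16| over 20 replicates stays within 2 tiles."""
        errs = []
        for seed in range(20):
            recs = tq.simulate_threshold_cohort(n_patients=529, seed=seed)
            errs.append(abs(tq.fit_count_model(recs).tile_threshold - 16.0))
        assert np.median(errs) <= 2.0
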