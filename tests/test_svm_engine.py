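"""RBF SVM training, grid search, jackknife evaluation and prediction."""

import numpy as np
import pytest

from ggapsvm.sequence_io import ACIDIC, ALKALINE, ProteinRecord
from ggapsvm.svm_engine import (
    SVMGridSpec,
    TrainedClassifier,
    grid_search,
    jackknife_evaluate,
    predict,
    train,
)


def make_clouds(rng, n_per_class=20, offset=2.0, n_features=10):
    """Two Gaussian point clouds separated along every axis."""
    X = np.vstack(
        [rng.normal(0.0, 0.3, size=(n_per_class, n_features)),
         rng.normal(offset, 0.3, size=(n_per_class, n_features))]
    )
    labels = np.array([ACIDIC] * n_per_class + [ALKALINE] * n_per_class)
    return X, labels


class TestGridSpec:
    def test_default_grid_has_231_points(self):
        spec = SVMGridSpec()
        assert len(spec.c_values) == 21
        assert len(spec.gamma_values) == 11
        assert spec.n_points == 231
        assert max(spec.c_values) == 2.0**15
        assert min(spec.c_values) == 2.0**-5
        assert max(spec.gamma_values) == 2.0**-5
        assert min(spec.gamma_values) == 2.0**-15

    def test_coarse_gamma_step_override(self):
        spec = SVMGridSpec(gamma_exp_step=2)
        assert len(spec.gamma_values) == 6

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            SVMGridSpec(c_exp_min=5, c_exp_max=0)


class TestJackknife:
    def test_separated_clouds_reach_perfect_accuracy(self, rng):
        X, labels = make_clouds(rng)
        counts = jackknife_evaluate(X, labels, 1.0, 2.0**-5)
        assert counts.accuracy == 1.0
        assert counts.tp == counts.tn == 20

    def test_permuted_labels_score_near_chance(self, rng):
        # a localizing bandwidth is needed: a near-constant kernel makes
        # balanced LOO anti-predict (majority-vote artifact), not guess
        from ggapsvm.svm_engine import median_heuristic_gamma

        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.random((40, 10))
            labels = np.array([ACIDIC, ALKALINE] * 20)
            r.shuffle(labels)
            accs.append(jackknife_evaluate(X, labels, 32.0, median_heuristic_gamma(X)).accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_row_order_invariance(self, rng):
        X, labels = make_clouds(rng, offset=0.8)
        counts = jackknife_evaluate(X, labels, 2.0, 2.0**-7)
        perm = rng.permutation(len(labels))
        counts_shuffled = jackknife_evaluate(X[perm], labels[perm], 2.0, 2.0**-7)
        assert counts == counts_shuffled

    def test_fast_path_matches_public_svc_loop(self, rng):
        # dual-route check: low-level LibSVM loop vs per-fold SVC refits
        X, labels = make_clouds(rng, n_per_class=15, offset=0.7)
        fast = jackknife_evaluate(X, labels, 4.0, 2.0**-6, use_lowlevel=True)
        slow = jackknife_evaluate(X, labels, 4.0, 2.0**-6, use_lowlevel=False)
        assert fast == slow

    def test_scores_orientation_matches_labels(self, rng):
        X, labels = make_clouds(rng)
        counts, scores = jackknife_evaluate(X, labels, 1.0, 2.0**-5, return_scores=True)
        assert scores[labels == ALKALINE].min() > scores[labels == ACIDIC].max()

    def test_single_member_class_is_degenerate(self, rng):
        X = rng.random((5, 3))
        labels = [ACIDIC] * 4 + [ALKALINE]
        with pytest.raises(ValueError, match="degenerate"):
            jackknife_evaluate(X, labels, 1.0, 0.1)

    def test_nonpositive_hyperparameters_rejected(self, rng):
        X, labels = make_clouds(rng, n_per_class=3)
        with pytest.raises(ValueError):
            jackknife_evaluate(X, labels, 0.0, 0.1)


class TestGridSearch:
    def test_separable_data_finds_perfect_point(self, rng):
        X, labels = make_clouds(rng)
        spec = SVMGridSpec(c_exp_min=-2, c_exp_max=4, gamma_exp_min=-8, gamma_exp_max=-4)
        c, gamma, acc = grid_search(X, labels, spec)
        assert acc == 1.0
        assert c in spec.c_values and gamma in spec.gamma_values

    def test_single_point_grid_returned_unchanged(self, rng):
        X, labels = make_clouds(rng, n_per_class=5)
        spec = SVMGridSpec(c_exp_min=3, c_exp_max=3, gamma_exp_min=-6, gamma_exp_max=-6)
        c, gamma, _ = grid_search(X, labels, spec)
        assert (c, gamma) == (8.0, 2.0**-6)

    def test_tie_break_prefers_smaller_c_larger_gamma(self, rng):
        # fully separable: many grid points hit accuracy 1.0
        X, labels = make_clouds(rng, offset=4.0)
        spec = SVMGridSpec(c_exp_min=0, c_exp_max=2, gamma_exp_min=-6, gamma_exp_max=-5)
        c, gamma, acc = grid_search(X, labels, spec)
        accs = {
            (ci, gi): jackknife_evaluate(X, labels, ci, gi).accuracy
            for ci in spec.c_values
            for gi in spec.gamma_values
        }
        best = max(accs.values())
        winners = [k for k, v in accs.items() if v == best]
        expected = min(winners, key=lambda k: (k[0], -k[1]))
        assert (c, gamma) == expected


class TestTrainPredict:
    @pytest.fixture()
    def model_and_records(self, small_signal_dataset):
        from ggapsvm.anova_ifs import rank_features
        from ggapsvm.ggap_features import encode_dataset

        matrix = encode_dataset(small_signal_dataset, 2)
        ranking = rank_features(matrix)
        subset = ranking.order[:20]
        spec = SVMGridSpec(
            c_exp_min=0, c_exp_max=10, c_exp_step=5,
            gamma_exp_min=-10, gamma_exp_max=-5, gamma_exp_step=5,
        )
        c0, gamma0, _ = grid_search(matrix.values[:, subset], matrix.labels, spec)
        model = train(matrix.values, matrix.labels, subset, c0, gamma0, gap=2)
        return model, small_signal_dataset.records

    def test_probabilities_sum_to_one_and_label_rule(self, model_and_records):
        model, records = model_and_records
        results = predict(model, records[:10])
        for res in results:
            assert res.error is None
            assert res.probability_acidic + res.probability_alkaline == pytest.approx(1.0, abs=1e-9)
            expected = ACIDIC if res.probability_acidic > 0.5 else ALKALINE
            assert res.predicted_label == expected

    def test_training_set_accuracy_on_separable_signal(self, model_and_records, small_signal_dataset):
        model, records = model_and_records
        results = predict(model, records)
        correct = sum(
            res.predicted_label == lab
            for res, lab in zip(results, small_signal_dataset.labels)
        )
        assert correct / len(results) >= 0.95

    def test_save_load_round_trip_is_bit_identical(self, model_and_records, tmp_path):
        model, records = model_and_records
        before = predict(model, records[:5])
        path = tmp_path / "model.joblib"
        model.save(path)
        restored = TrainedClassifier.load(path)
        after = predict(restored, records[:5])
        assert before == after
        assert restored.feature_indices == model.feature_indices
        assert restored.dipeptide_order == model.dipeptide_order

    def test_version_mismatch_refused(self, model_and_records, tmp_path):
        import joblib

        model, _ = model_and_records
        path = tmp_path / "model.joblib"
        model.save(path)
        payload = joblib.load(path)
        payload["format_version"] = 99
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="version"):
            TrainedClassifier.load(path)

    def test_duplicate_records_get_identical_results(self, model_and_records):
        model, records = model_and_records
        rec = records[0]
        twin = ProteinRecord("copy", rec.description, rec.sequence)
        r1, r2 = predict(model, [rec, twin])
        assert (r1.probability_acidic, r1.predicted_label) == (
            r2.probability_acidic,
            r2.predicted_label,
        )

    def test_too_short_record_yields_error_entry_not_abort(self, model_and_records):
        model, records = model_and_records
        bad = ProteinRecord("tiny", "", "ACD")
        results = predict(model, [records[0], bad, records[1]])
        assert results[0].error is None and results[2].error is None
        assert results[1].error is not None and "too short" in results[1].error
        assert results[1].predicted_label is None

    def test_single_class_training_rejected(self, rng):
        X = rng.random((6, 400))
        with pytest.raises(ValueError):
            train(X, [ACIDIC] * 6, range(10), 1.0, 0.1, gap=0)


class TestDeterminism:
    def test_repeated_evaluation_is_identical(self, rng):
        X, labels = make_clouds(rng, offset=0.6)
        a = jackknife_evaluate(X, labels, 2.0, 2.0**-6, return_scores=True)
        b = jackknife_evaluate(X, labels, 2.0, 2.0**-6, return_scores=True)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_accuracy_monotone_in_class_separation(self, rng):
        accs = []
        for offset in (0.2, 0.8, 3.0):
            X, labels = make_clouds(np.random.default_rng(3), offset=offset)
            accs.append(jackknife_evaluate(X, labels, 1.0, 2.0**-5).accuracy)
        assert accs[0] <= accs[1] + 0.1 and accs[1] <= accs[2] + 0.1
        assert accs[2] == 1.0
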