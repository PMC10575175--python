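"""Metrics against an independent reference, splits, CV structure, and
experiment assembly."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

import skelact as sk
from skelact.skeleton import ValidationError


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = sk.confusion([0, 1, 2, 1], [0, 1, 2, 1], 3)
        np.testing.assert_array_equal(
            cm.counts, np.diag([1, 2, 1])
        )

    def test_direct_count_example(self):
        cm = sk.confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_column_sums_are_predicted_counts(self, rng):
        t = rng.integers(0, 4, 50)
        p = rng.integers(0, 4, 50)
        cm = sk.confusion(t, p, 4)
        np.testing.assert_array_equal(
            cm.counts.sum(axis=0), np.bincount(p, minlength=4)
        )
        assert cm.total == 50

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sk.confusion([0, 3], [0, 1], 3)


class TestMetrics:
    def test_binary_fixture(self):
        # TP=8, FP=2, FN=2, TN=8 for the positive class
        cm = sk.ConfusionMatrix(np.array([[8, 2], [2, 8]]))
        rep = sk.metrics_from_confusion(cm)
        assert rep.macro_precision == pytest.approx(0.8)
        assert rep.macro_recall == pytest.approx(0.8)
        assert rep.macro_f1 == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.8)

    def test_diagonal_matrix_all_ones(self):
        rep = sk.metrics_from_confusion(sk.ConfusionMatrix(np.diag([3, 5, 2])))
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0
        assert rep.accuracy == 1.0

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(5, 60))
            t = rng.integers(0, k, n)
            p = rng.integers(0, k, n)
            rep = sk.evaluate_predictions(t, p, k)
            prec, rec, f1, _ = precision_recall_fscore_support(
                t, p, labels=range(k), average="macro", zero_division=0
            )
            assert abs(rep.macro_precision - prec) < 1e-12
            assert abs(rep.macro_recall - rec) < 1e-12
            assert abs(rep.macro_f1 - f1) < 1e-12
            assert abs(rep.accuracy - accuracy_score(t, p)) < 1e-12

    def test_absent_class_flagged_with_zero_metrics(self):
        rep = sk.evaluate_predictions([0, 0, 1], [0, 0, 0], 3)
        assert rep.per_class_precision[2] == 0.0
        assert 2 in rep.undefined_precision_classes
        assert 2 in rep.undefined_recall_classes

    def test_accuracy_is_mean_recall_when_balanced(self, rng):
        k, per = 4, 10
        t = np.repeat(np.arange(k), per)
        p = rng.integers(0, k, k * per)
        rep = sk.evaluate_predictions(t, p, k)
        assert rep.accuracy == pytest.approx(rep.macro_recall)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            sk.metrics_from_confusion(sk.ConfusionMatrix(np.zeros((2, 2))))


class TestSubjectSplit:
    def test_partition_is_subject_disjoint(self, tiny_dataset):
        train, test = sk.subject_split(tiny_dataset, 1, seed=0)
        train_subj = {s.subject_id for s in train}
        test_subj = {s.subject_id for s in test}
        assert not train_subj & test_subj
        assert len(train) + len(test) == len(tiny_dataset)

    def test_same_seed_same_split(self, tiny_dataset):
        a = sk.subject_split(tiny_dataset, 1, seed=4)
        b = sk.subject_split(tiny_dataset, 1, seed=4)
        assert [s.subject_id for s in a[1]] == [s.subject_id for s in b[1]]

    def test_too_many_test_subjects_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError):
            sk.subject_split(tiny_dataset, 2, seed=0)  # only 2 subjects

    def test_folds_partition_subjects(self):
        subjects = [f"S{i}" for i in range(30)]
        folds = sk.subject_folds(subjects, 5, seed=1)
        assert len(folds) == 5
        assert all(len(f) == 6 for f in folds)
        assert sorted(sum(folds, [])) == sorted(subjects)
        assert folds == sk.subject_folds(subjects, 5, seed=1)


class TestAssembly:
    def test_output_size_is_clips_times_angles(self, tiny_dataset, topology,
                                               desk_heatmap_config):
        clips = tiny_dataset[:5]
        vols, labels, subjects = sk.assemble_training_set(
            clips, sk.CameraIntrinsics(), sk.OrbitConfig(),
            [0.0, 90.0, 180.0, 270.0], desk_heatmap_config, topology,
        )
        assert vols.shape[0] == 20
        assert vols.shape[1:] == (8, 24, 24)
        np.testing.assert_array_equal(
            labels, np.repeat([c.action_label for c in clips], 4)
        )
        np.testing.assert_array_equal(
            subjects, np.repeat([c.subject_id for c in clips], 4)
        )


class TestCrossValidateStructure:
    def test_fold_reports_and_subject_disjointness(self, tiny_dataset, topology,
                                                   desk_heatmap_config):
        # 3 classes x 2 subjects: 2-fold leave-one-subject-out
        vols, labels, subjects = sk.assemble_training_set(
            tiny_dataset, sk.CameraIntrinsics(), sk.OrbitConfig(), [0.0],
            desk_heatmap_config, topology,
        )
        cfg = sk.ModelConfig(num_classes=3, base_channels=4, stage_depths=[1])
        reports, pooled = sk.cross_validate(
            vols, labels, subjects, cfg,
            sk.TrainConfig(max_epochs=2, batch_size=6, seed=0),
            folds=2, seed=0,
        )
        assert len(reports) == 2
        assert pooled.confusion.total == len(vols)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            sk.subject_folds(["S0", "S1"], 5, seed=0)


class TestExperimentStructure:
    def test_report_per_model_spec(self, topology):
        data = sk.generate_dataset(
            sk.GeneratorConfig(num_subjects=3, num_actions=3,
                               num_repetitions=1, frames_per_clip=16,
                               noise_std=0.0, seed=1),
            topology,
        )
        exp = sk.ViewpointExperimentConfig(
            model_specs={"narrow": [0.0], "wide": 120.0},
            test_spacing_deg=90.0, num_test_subjects=1, seed=0,
        )
        hm = sk.HeatmapConfig(out_height=16, out_width=16, num_frames_out=4)
        mc = sk.ModelConfig(num_classes=3, base_channels=4, stage_depths=[1])
        tc = sk.TrainConfig(max_epochs=3, max_updates=10, batch_size=8, seed=0)
        report = sk.run_viewpoint_experiment(
            data, exp, topology, heatmap_config=hm, model_config=mc,
            train_config=tc,
        )
        assert set(report.reports) == {"narrow", "wide"}
        assert report.train_sizes == {"narrow": 6, "wide": 18}
        assert report.test_size == 3 * 4  # 1 subject x 3 clips x 4 test angles
        assert set(report.accuracy_ranking) == {"narrow", "wide"}
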