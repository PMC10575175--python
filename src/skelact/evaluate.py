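"""Metrics, subject-disjoint splits, cross-validation, and the
viewpoint-generalization experiment.

Per-class precision, recall and F1 come from a one-vs-rest reduction of
the confusion matrix; aggregate precision/recall/F1 are macro averages
(unweighted per-class means) and accuracy is micro (correct / total).
Splits and cross-validation folds are subject-disjoint throughout: a
subject's clips never straddle train and test, which is what a claim of
generalization to unseen performers requires.

The viewpoint experiment trains one classifier per viewpoint
configuration — A: {0°, 90°}; B: {0°, 90°, 180°, 270°}; C: the 45° grid
(8 views); D: the 10° grid (36 views) — on projections of the training
subjects' clips, then evaluates every model on held-out subjects
projected across the full 10° test grid, exposing how accuracy under
unseen viewpoints grows with training-viewpoint diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .camera import CameraIntrinsics, OrbitConfig, project_sequence, viewpoint_angles
from .heatmap import HeatmapConfig, build_volume
from .model import ModelConfig, TrainConfig, build_model, predict, train
from .skeleton import JointTopology, Skeleton3DSequence, ValidationError


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValidationError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]


@dataclass
class EvalReport:
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    confusion: ConfusionMatrix
    undefined_precision_classes: list[int] = field(default_factory=list)
    undefined_recall_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "confusion": self.confusion.counts.tolist(),
        }


def confusion(true_labels, predicted_labels, num_classes: int) -> ConfusionMatrix:
    t = np.asarray(true_labels, int)
    p = np.asarray(predicted_labels, int)
    if t.shape != p.shape:
        raise ValidationError("label lists must have equal length")
    if t.size and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValidationError(f"labels out of range [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> EvalReport:
    """Precision/recall/F1/accuracy from a confusion matrix.

    precision_c = TP/(TP+FP), recall_c = TP/(TP+FN), F1 the harmonic
    mean; accuracy = trace/total.  Zero denominators give 0 and the class
    is flagged in ``undefined_*_classes``.
    """
    c = cm.counts
    if cm.total < 1:
        raise ValidationError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    col = c.sum(axis=0).astype(float)  # TP + FP
    row = c.sum(axis=1).astype(float)  # TP + FN
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    return EvalReport(
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(tp.sum() / cm.total),
        confusion=cm,
        undefined_precision_classes=np.flatnonzero(col == 0).tolist(),
        undefined_recall_classes=np.flatnonzero(row == 0).tolist(),
    )


def evaluate_predictions(true_labels, predicted_labels, num_classes: int
                         ) -> EvalReport:
    return metrics_from_confusion(
        confusion(true_labels, predicted_labels, num_classes)
    )


def subject_split(
    dataset: list[Skeleton3DSequence], num_test_subjects: int, seed: int = 0
) -> tuple[list[Skeleton3DSequence], list[Skeleton3DSequence]]:
    """Random subject-disjoint train/test partition."""
    subjects = sorted({s.subject_id for s in dataset})
    if num_test_subjects < 1 or num_test_subjects >= len(subjects):
        raise ValidationError(
            f"num_test_subjects must be in [1, {len(subjects)})"
        )
    rng = np.random.default_rng(seed)
    test_subjects = set(
        rng.choice(subjects, size=num_test_subjects, replace=False).tolist()
    )
    train_set = [s for s in dataset if s.subject_id not in test_subjects]
    test_set = [s for s in dataset if s.subject_id in test_subjects]
    return train_set, test_set


def subject_folds(subjects: list[str], folds: int, seed: int = 0
                  ) -> list[list[str]]:
    """Partition subjects into ``folds`` near-equal groups."""
    subjects = sorted(set(subjects))
    if folds < 2 or folds > len(subjects):
        raise ValidationError(
            f"folds must be in [2, {len(subjects)}] for {len(subjects)} subjects"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    return [sorted(order[i::folds].tolist()) for i in range(folds)]


def assemble_training_set(
    train3d: list[Skeleton3DSequence],
    intrinsics: CameraIntrinsics,
    orbit: OrbitConfig,
    angles: list[float],
    heatmap_config: HeatmapConfig,
    topology: JointTopology,
    seed: int | None = None,
):
    """Project every clip at every angle and build heatmap volumes.

    Returns ``(volumes (N, T, H, W), labels (N,), subjects (N,))`` with
    N = len(train3d) * len(angles).
    """
    if not train3d or not angles:
        raise ValidationError("need at least one clip and one angle")
    vols, labels, subjects = [], [], []
    for clip in train3d:
        for theta in angles:
            seq2d = project_sequence(clip, intrinsics, orbit, theta)
            vol = build_volume(seq2d, topology, heatmap_config, seed)
            vols.append(vol.values.astype(np.float32))
            labels.append(clip.action_label)
            subjects.append(clip.subject_id)
    return (
        np.stack(vols).astype(np.float64),
        np.asarray(labels, int),
        np.asarray(subjects),
    )


def cross_validate(
    volumes: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[EvalReport], EvalReport]:
    """Subject-disjoint k-fold cross-validation.

    Each fold holds out one subject group for validation and trains on
    the rest; returns the per-fold reports and a pooled report computed
    from the union of all validation predictions.
    """
    groups = subject_folds(list(subjects), folds, seed)
    reports: list[EvalReport] = []
    all_true: list[int] = []
    all_pred: list[int] = []
    for k, held in enumerate(groups):
        held_set = set(held)
        val_mask = np.array([s in held_set for s in subjects])
        model = build_model(
            model_config.model_copy(update={"seed": model_config.seed + k})
        )
        train(model, volumes[~val_mask], labels[~val_mask], train_config)
        preds = [o.predicted_label for o in predict(model, volumes[val_mask])]
        truth = labels[val_mask].tolist()
        reports.append(
            evaluate_predictions(truth, preds, model_config.num_classes)
        )
        all_true += truth
        all_pred += preds
    pooled = evaluate_predictions(all_true, all_pred, model_config.num_classes)
    return reports, pooled


class ViewpointExperimentConfig(BaseModel):
    """The four training-viewpoint configurations and the shared test
    protocol.  ``model_specs`` maps a name to either an explicit angle
    list or a grid spacing in degrees."""

    model_config = ConfigDict(extra="forbid")

    model_specs: dict[str, list[float] | float] = {
        "A": [0.0, 90.0],
        "B": [0.0, 90.0, 180.0, 270.0],
        "C": 45.0,
        "D": 10.0,
    }
    test_spacing_deg: float = 10.0
    num_test_subjects: int = 2
    map_type: str = "joint"
    folds: int = 5
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ViewpointExperimentConfig":
        if not self.model_specs:
            raise ValueError("model_specs must be non-empty")
        for name, spec in self.model_specs.items():
            if isinstance(spec, list) and not spec:
                raise ValueError(f"model {name!r} has an empty angle list")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.map_type not in ("joint", "bone"):
            raise ValueError(f"unknown map_type {self.map_type!r}")
        return self

    def angles_for(self, name: str) -> list[float]:
        spec = self.model_specs[name]
        return viewpoint_angles(spec) if isinstance(spec, float) else list(spec)


@dataclass
class ViewpointExperimentReport:
    reports: dict[str, EvalReport]
    train_sizes: dict[str, int]
    test_size: int
    accuracy_ranking: list[str]  # best first

    def to_dict(self) -> dict:
        return {
            "accuracy_ranking": self.accuracy_ranking,
            "test_size": self.test_size,
            "models": {
                name: {"train_size": self.train_sizes[name], **rep.to_dict()}
                for name, rep in self.reports.items()
            },
        }


def run_viewpoint_experiment(
    dataset: list[Skeleton3DSequence],
    experiment: ViewpointExperimentConfig,
    topology: JointTopology,
    intrinsics: CameraIntrinsics | None = None,
    orbit: OrbitConfig | None = None,
    heatmap_config: HeatmapConfig | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> ViewpointExperimentReport:
    """Train one classifier per viewpoint configuration and evaluate all of
    them on held-out subjects projected at the dense test grid."""
    intrinsics = intrinsics or CameraIntrinsics()
    orbit = orbit or OrbitConfig()
    # desk-scale rendering default: 8 frames of 24x24 keeps the full
    # four-model experiment within minutes on one CPU core
    heatmap_config = heatmap_config or HeatmapConfig(
        out_height=24, out_width=24, num_frames_out=8
    )
    num_classes = len({s.action_label for s in dataset})
    model_config = model_config or ModelConfig(num_classes=num_classes)
    train_config = train_config or TrainConfig(
        max_epochs=30, max_updates=500, seed=experiment.seed
    )
    train3d, test3d = subject_split(
        dataset, experiment.num_test_subjects, experiment.seed
    )
    test_angles = viewpoint_angles(experiment.test_spacing_deg)
    test_vols, test_labels, _ = assemble_training_set(
        test3d, intrinsics, orbit, test_angles, heatmap_config, topology
    )
    reports: dict[str, EvalReport] = {}
    train_sizes: dict[str, int] = {}
    for name in experiment.model_specs:
        angles = experiment.angles_for(name)
        vols, labels, _ = assemble_training_set(
            train3d, intrinsics, orbit, angles, heatmap_config, topology
        )
        model = build_model(
            model_config.model_copy(update={"seed": experiment.seed})
        )
        train(model, vols, labels, train_config)
        preds = [o.predicted_label for o in predict(model, test_vols)]
        reports[name] = evaluate_predictions(
            test_labels.tolist(), preds, model_config.num_classes
        )
        train_sizes[name] = len(vols)
    ranking = sorted(reports, key=lambda n: reports[n].accuracy, reverse=True)
    return ViewpointExperimentReport(reports, train_sizes, len(test_vols), ranking)
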