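"""Linear-SVM classification of per-track features with consensus aggregation.

Tracks from a treated experiment are labelled positive, untreated negative. A
linear support-vector machine (C = 1, default settings) is trained on
per-image descriptors under a two-fold, video-exclusive protocol: videos are
split into two partitions so that no video contributes rows to both training
and testing; each partition takes a turn as test set. Feature selection is
refit on the training partition of each turn and its mask applied unchanged
to the test rows, so no test information leaks into the model.

Per-track decisions are then aggregated by majority voting at two consensus
levels — the biological group (tumor-cell neighborhood or cancer-cell
cluster) and the whole video — under the "wisdom of crowds" rationale that
the dominant motility response of a population is more reliable than any
single cell's. Balanced accuracy (mean of per-class recalls) is reported at
all three levels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import VarianceFeatureSelector

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "FoldSpec",
    "ConsensusReport",
    "MotilityStyleClassifier",
    "make_video_folds",
    "train_and_predict",
    "majority_vote",
    "balanced_accuracy",
    "evaluate_pipeline",
]

POSITIVE = "treated"
NEGATIVE = "untreated"


@dataclass(frozen=True)
class FoldSpec:
    """Two-fold, video-exclusive partition: video_id -> fold index (0 or 1)."""

    assignment: dict[str, int]

    def videos(self, fold: int) -> list[str]:
        return sorted(v for v, f in self.assignment.items() if f == fold)

    def row_folds(self, video_ids) -> np.ndarray:
        return np.array([self.assignment[v] for v in video_ids])


def make_video_folds(
    manifest: pd.DataFrame, experiment_ids: dict[str, int] | None = None
) -> FoldSpec:
    """Deterministic two-fold split of videos, stratified by class.

    With ``experiment_ids`` (video -> experiment, exactly two experiments),
    folds are the experiments — the replicated-experiment design. Otherwise
    videos are sorted within each class and assigned alternately, so both
    folds contain both classes whenever each class has >= 2 videos.
    """
    vids = manifest[["video_id", "label"]].drop_duplicates()
    labels = dict(zip(vids["video_id"], vids["label"]))
    if len(labels) < 2:
        raise ValueError("need at least 2 videos for two-fold testing")
    if experiment_ids is not None:
        exps = sorted(set(experiment_ids.values()))
        if len(exps) != 2:
            raise ValueError("experiment-wise folding needs exactly 2 experiments")
        assignment = {v: exps.index(e) for v, e in experiment_ids.items()}
    else:
        assignment = {}
        for lab in sorted(set(labels.values())):
            for i, v in enumerate(sorted(v for v, l in labels.items() if l == lab)):
                assignment[v] = i % 2
    for fold in (0, 1):
        fold_labels = {labels[v] for v, f in assignment.items() if f == fold}
        if len(fold_labels) < 2:
            raise ValueError(
                f"fold {fold} contains classes {sorted(fold_labels)} only; "
                "stratification impossible"
            )
    return FoldSpec(assignment)


class MotilityStyleClassifier(BaseEstimator, ClassifierMixin):
    """Variance-based feature selection followed by a linear SVM.

    The selector is fit on the training rows only; ``decision_function``
    returns the signed margin (positive = treated side).
    """

    def __init__(self, C: float = 1.0, selection_mode: str = "quantile",
                 selection_quantile: float = 0.5, selection_threshold: float = 0.0):
        self.C = C
        self.selection_mode = selection_mode
        self.selection_quantile = selection_quantile
        self.selection_threshold = selection_threshold

    def fit(self, X, y) -> "MotilityStyleClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold contains a single class")
        self.selector_ = VarianceFeatureSelector(
            mode=self.selection_mode,
            quantile=self.selection_quantile,
            threshold=self.selection_threshold,
        ).fit(X)
        Xs = self.selector_.transform(np.asarray(X))
        self.svc_ = SVC(kernel="linear", C=self.C)
        self.svc_.fit(Xs, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        margins = self.svc_.decision_function(self.selector_.transform(np.asarray(X)))
        # sklearn orients the margin toward classes_[1]; flip so positive = POSITIVE
        if list(self.classes_) == [POSITIVE, NEGATIVE]:
            margins = -margins
        return margins

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.svc_.predict(self.selector_.transform(np.asarray(X)))


def train_and_predict(
    features: np.ndarray,
    labels: np.ndarray,
    video_ids,
    folds: FoldSpec,
    clf: MotilityStyleClassifier | None = None,
    return_models: bool = False,
):
    """Two-fold video-exclusive training/prediction.

    Returns one row per feature row with columns ``turn`` (which fold was the
    test set), ``pred`` and ``margin``. Each turn refits feature selection
    and the SVM on the training fold only. With ``return_models`` the two
    fitted models are returned alongside, for inspection of the
    training-only artifacts (selection mask, support vectors).
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    video_ids = np.asarray(video_ids)
    row_fold = folds.row_folds(video_ids)
    out = pd.DataFrame(
        {"row": np.arange(len(labels)), "turn": -1, "pred": "", "margin": 0.0}
    )
    models = []
    for test_fold in (0, 1):
        train = row_fold != test_fold
        test = ~train
        model = (clf or MotilityStyleClassifier()).__class__(
            **(clf.get_params() if clf else {})
        )
        model.fit(features[train], labels[train])
        models.append(model)
        out.loc[test, "pred"] = model.predict(features[test])
        out.loc[test, "margin"] = model.decision_function(features[test])
        out.loc[test, "turn"] = test_fold
    return (out, models) if return_models else out


def majority_vote(member_labels, member_margins=None) -> str:
    """Consensus label of a group: strict majority, margin-sum tie-break.

    A tied vote is decided by the sign of the summed margins; a zero sum
    falls back to the negative (untreated) label with a warning.
    """
    member_labels = list(member_labels)
    if not member_labels:
        raise ValueError("empty group")
    pos = sum(1 for l in member_labels if l == POSITIVE)
    neg = len(member_labels) - pos
    if pos != neg:
        return POSITIVE if pos > neg else NEGATIVE
    s = float(np.sum(member_margins)) if member_margins is not None else 0.0
    if s == 0.0:
        warnings.warn("tied vote with zero summed margin; defaulting to negative")
        return NEGATIVE
    return POSITIVE if s > 0 else NEGATIVE


def balanced_accuracy(true_labels, predicted_labels) -> float:
    """Mean of per-class recalls, in percent."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    classes = np.unique(t)
    if len(classes) < 2:
        raise ValueError("balanced accuracy needs both classes in the truth")
    recalls = [np.mean(p[t == c] == c) for c in classes]
    return float(np.mean(recalls) * 100.0)


@dataclass
class ConsensusReport:
    """Balanced accuracy at track, group, and video level, per fold-turn and averaged."""

    case_study: str
    folds: list[dict]
    averages: dict
    confusion: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConsensusReport":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _confusion(t: np.ndarray, p: np.ndarray) -> dict:
    return {
        "tp": int(np.sum((t == POSITIVE) & (p == POSITIVE))),
        "fn": int(np.sum((t == POSITIVE) & (p == NEGATIVE))),
        "tn": int(np.sum((t == NEGATIVE) & (p == NEGATIVE))),
        "fp": int(np.sum((t == NEGATIVE) & (p == POSITIVE))),
    }


def evaluate_pipeline(
    manifest: pd.DataFrame,
    features: np.ndarray,
    folds: FoldSpec | None = None,
    clf: MotilityStyleClassifier | None = None,
    case_study: str = "synthetic",
) -> ConsensusReport:
    """Full two-fold evaluation with three consensus levels.

    ``manifest`` needs columns video_id, group_id, track_id, label, aligned
    row-by-row with ``features``.
    """
    folds = folds or make_video_folds(manifest)
    preds = train_and_predict(
        features, manifest["label"].to_numpy(), manifest["video_id"].to_numpy(), folds, clf
    )
    df = manifest.reset_index(drop=True).copy()
    df["pred"] = preds["pred"].to_numpy()
    df["margin"] = preds["margin"].to_numpy()
    df["turn"] = preds["turn"].to_numpy()

    fold_rows = []
    conf = {}
    for turn in (0, 1):
        sub = df[df["turn"] == turn]
        track_acc = balanced_accuracy(sub["label"], sub["pred"])
        g = sub.groupby(["video_id", "group_id"], sort=True)
        g_true = g["label"].first()
        g_pred = g.apply(
            lambda s: majority_vote(s["pred"], s["margin"]), include_groups=False
        )
        group_acc = balanced_accuracy(g_true, g_pred)
        v = sub.groupby("video_id", sort=True)
        v_true = v["label"].first()
        v_pred = v.apply(
            lambda s: majority_vote(s["pred"], s["margin"]), include_groups=False
        )
        video_acc = balanced_accuracy(v_true, v_pred)
        fold_rows.append(
            {
                "turn": turn,
                "track_acc": track_acc,
                "group_acc": group_acc,
                "video_acc": video_acc,
            }
        )
        conf[f"turn{turn}_track"] = _confusion(
            sub["label"].to_numpy(), sub["pred"].to_numpy()
        )
    averages = {
        k: float(np.mean([fr[k] for fr in fold_rows]))
        for k in ("track_acc", "group_acc", "video_acc")
    }
    return ConsensusReport(case_study, fold_rows, averages, conf)
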