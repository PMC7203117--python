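"""End-to-end orchestration: tracks -> atlas -> features -> consensus report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import BlankTrajectoryError, default_region_radius, track_to_image
from .classify import ConsensusReport, MotilityStyleClassifier, evaluate_pipeline, make_video_folds
from .features import ConvFeatureExtractor
from .simulate import ExperimentDesign, SyntheticDataset, simulate_experiment
from .track import Track

__all__ = ["atlas_images", "run_synthetic_experiment", "cap_group_members"]


def cap_group_members(
    tracks: list[Track],
    references: dict[tuple[str, int], tuple[float, float]],
    cap: int,
) -> list[Track]:
    """Keep at most ``cap`` tracks per group, nearest-first by start distance."""
    by_group: dict[tuple[str, int], list[Track]] = {}
    for tr in tracks:
        by_group.setdefault((tr.video_id, tr.group_id), []).append(tr)
    kept: list[Track] = []
    for key, members in sorted(by_group.items()):
        ref = np.asarray(references[key])
        members.sort(
            key=lambda tr: (float(np.hypot(tr.xs[0] - ref[0], tr.ys[0] - ref[1])), tr.track_id)
        )
        kept.extend(members[:cap])
    kept.sort(key=lambda tr: tr.track_id)
    return kept


def atlas_images(
    tracks: list[Track],
    references: dict[tuple[str, int], tuple[float, float]],
    labels: dict[str, str],
    R: int | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame, int]:
    """In-memory atlas: binary images + manifest, skipping blank-region tracks."""
    R = R or default_region_radius(tracks, references)
    images, rows = [], []
    for tr in sorted(tracks, key=lambda t: (t.video_id, t.group_id or 0, t.track_id)):
        try:
            ti = track_to_image(tr, references[(tr.video_id, tr.group_id)], R)
        except BlankTrajectoryError:
            continue
        images.append(ti.pixels)
        rows.append((tr.video_id, tr.group_id, tr.track_id, labels[tr.video_id]))
    manifest = pd.DataFrame(rows, columns=["video_id", "group_id", "track_id", "label"])
    return images, manifest, R


def run_synthetic_experiment(
    design: ExperimentDesign | None = None,
    weight_seed: int = 0,
    clf: MotilityStyleClassifier | None = None,
    track_cap: int | None = None,
    dataset: SyntheticDataset | None = None,
) -> tuple[ConsensusReport, pd.DataFrame]:
    """Simulate (or take) a dataset and evaluate the full deep pipeline on it."""
    if dataset is None:
        dataset = simulate_experiment(design or ExperimentDesign())
    tracks = dataset.tracks
    if track_cap:
        tracks = cap_group_members(tracks, dataset.references, track_cap)
    images, manifest, R = atlas_images(tracks, dataset.references, dataset.labels)
    feats = (
        ConvFeatureExtractor(weights="fixed_seed_random", weight_seed=weight_seed)
        .fit()
        .transform(images)
    )
    folds = make_video_folds(manifest)
    report = evaluate_pipeline(manifest, feats, folds, clf)
    return report, manifest
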