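"""File formats and configuration.

Tracks CSV: ``video_id,group_id,track_id,frame,x,y`` (frame 0-based integer;
x = column, y = row, float px). Detections CSV:
``video_id,frame,x,y,r,score``. Videos are multi-page grayscale 8-bit TIFF;
atlas images 8-bit PNG (background 0, trajectory 255). Every artifact written
by the CLI gets a ``.meta.json`` sidecar recording the config hash, seed and
package version, so outputs are reproducible from their metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .track import Track

__all__ = [
    "TRACK_COLUMNS",
    "DETECTION_COLUMNS",
    "PipelineConfig",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_detections_csv",
    "write_detections_csv",
    "read_tiff",
    "write_tiff",
    "read_png",
    "save_features",
    "load_features",
    "load_config",
    "config_hash",
    "write_sidecar",
]

TRACK_COLUMNS = ["video_id", "group_id", "track_id", "frame", "x", "y"]
DETECTION_COLUMNS = ["video_id", "frame", "x", "y", "r", "score"]


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for f, x, y in zip(tr.frames, tr.xs, tr.ys):
            gid = tr.group_id if tr.group_id is not None else -1
            rows.append((tr.video_id, gid, tr.track_id, int(f), x, y))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_tracks_csv(path: str | Path) -> list[Track]:
    """Read and validate a tracks table; frames of each track must be contiguous."""
    df = pd.read_csv(path)
    if list(df.columns) != TRACK_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(TRACK_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df[["frame", "x", "y"]].isna().any().any():
        bad = int(df[df[["frame", "x", "y"]].isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"{path}: malformed row at line {bad}")
    tracks = []
    for (vid, gid, tid), sub in df.groupby(["video_id", "group_id", "track_id"], sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        gaps = np.flatnonzero(np.diff(frames) != 1)
        if gaps.size:
            line = int(sub.index[gaps[0] + 1]) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: track {tid} (video {vid}) has a frame gap at line {line}; "
                "tracks must be contiguous"
            )
        tracks.append(
            Track(
                int(tid),
                frames,
                sub["x"].to_numpy(),
                sub["y"].to_numpy(),
                video_id=str(vid),
                group_id=None if gid == -1 else int(gid),
            )
        )
    return tracks


def write_detections_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f", columns=DETECTION_COLUMNS)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != DETECTION_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(DETECTION_COLUMNS)}, got {','.join(df.columns)}"
        )
    return df


def write_tiff(stack: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint8), photometric="minisblack")


def read_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def read_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(path)


def save_features(
    path: str | Path, features: np.ndarray, mask: np.ndarray | None,
    spec: dict, manifest_hash: str = ""
) -> None:
    """Feature matrix as compressed .npz plus a JSON sidecar (spec, mask, hash)."""
    path = Path(path)
    np.savez_compressed(
        path, features=features,
        mask=mask if mask is not None else np.ones(features.shape[1], bool),
    )
    meta = {"spec": spec, "manifest_hash": manifest_hash,
            "n_rows": int(features.shape[0]), "n_cols": int(features.shape[1])}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        features, mask = z["features"], z["mask"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return features, mask, meta


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, loadable from one JSON file."""

    frame_interval_min: float = 2.0
    pixel_size_um: float = 0.65
    # detector
    radius_range: tuple[int, int] = (3, 8)
    sensitivity: float = 0.5
    # tracker
    window_T: int = 10
    sigma_floor: float = 0.5
    coldstart_sigma: float = 2.0
    gate_mahalanobis: float = 4.0
    # atlas
    region_radius: int | None = None  # None = dataset-driven percentile
    grouping_mode: str = "tumor_neighborhood"
    neighborhood_radius: float = 80.0
    linkage_distance: float = 30.0
    track_cap: int = 200
    # backbone + selection
    backbone_weights: str = "fixed_seed_random"
    backbone_weight_seed: int = 0
    selection_mode: str = "quantile"
    selection_quantile: float = 0.5
    selection_threshold: float = 0.0
    # classifier
    svm_C: float = 1.0
    # experiment design (simulate stage); None uses package defaults
    design: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_interval_min", "pixel_size_um", "sensitivity",
                     "neighborhood_radius", "linkage_distance", "svm_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.grouping_mode not in ("tumor_neighborhood", "cluster", "self"):
            raise ValueError("grouping_mode must be tumor_neighborhood|cluster|self")

    def tracker_config(self):
        from .track import TrackerConfig

        return TrackerConfig(
            window_T=self.window_T, sigma_floor=self.sigma_floor,
            coldstart_sigma=self.coldstart_sigma,
            gate_mahalanobis=self.gate_mahalanobis,
        )


def load_config(path: str | Path) -> PipelineConfig:
    d = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "radius_range" in d:
        d["radius_range"] = tuple(d["radius_range"])
    return PipelineConfig(**d)


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_sidecar(artifact: str | Path, cfg: PipelineConfig, seed: int) -> None:
    from . import __version__

    meta = {"config_hash": config_hash(cfg), "seed": seed, "version": __version__}
    Path(str(artifact) + ".meta.json").write_text(json.dumps(meta, indent=2))
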