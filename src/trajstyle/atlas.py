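"""Binary trajectory images ("visual atlas") and the grouping structures for consensus.

Each track is projected into a (2R+1) x (2R+1) binary image by marking, for
every time point, the pixel at the track position relative to a reference
point (tumor-cell center, cluster center, or the track's own geometric
center). A stopped cell appears as a single white pixel; pure drift appears
as a straight line; diffusive motion as a scribbled cloud. The image is a
length-free encoding: tracks of any duration map to the same canvas.

Coordinate convention: x = column increasing rightward, y = row increasing
downward, 0-based; offsets are rounded to the nearest pixel, halves away
from zero. The reference point maps to the center pixel (R, R).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .track import Track

__all__ = [
    "TrajectoryImage",
    "GroupAssignment",
    "BlankTrajectoryError",
    "track_to_image",
    "default_region_radius",
    "assign_tumor_neighborhoods",
    "cluster_tracks",
    "build_atlas",
]


class BlankTrajectoryError(ValueError):
    """Raised when every point of a track falls outside the atlas region."""


@dataclass
class TrajectoryImage:
    pixels: np.ndarray  # (2R+1, 2R+1) uint8 in {0, 1}
    region_radius: int
    reference: tuple[float, float]
    track_id: int = 0
    video_id: str = ""
    group_id: int | None = None


@dataclass
class GroupAssignment:
    """A consensus group: its reference point and member tracks."""

    group_id: int
    reference: tuple[float, float]
    member_track_ids: list[int]
    group_kind: str = "tumor_neighborhood"  # or "cluster", "self"


def _round_half_away(v: np.ndarray) -> np.ndarray:
    return np.trunc(v + np.copysign(0.5, v)).astype(int)


def track_to_image(track: Track, reference: tuple[float, float], R: int) -> TrajectoryImage:
    """Rasterize one track relative to ``reference`` on a (2R+1)^2 binary canvas.

    Points whose offset falls outside [-R, R]^2 are dropped; if ALL points
    fall outside, a :class:`BlankTrajectoryError` is raised instead of
    producing a blank image.
    """
    if R < 1:
        raise ValueError("region radius R must be >= 1")
    dx = _round_half_away(track.xs - reference[0])
    dy = _round_half_away(track.ys - reference[1])
    keep = (np.abs(dx) <= R) & (np.abs(dy) <= R)
    if not keep.any():
        raise BlankTrajectoryError(
            f"track {track.track_id} lies entirely outside the region (R={R})"
        )
    img = np.zeros((2 * R + 1, 2 * R + 1), dtype=np.uint8)
    img[dy[keep] + R, dx[keep] + R] = 1
    return TrajectoryImage(
        img, R, (float(reference[0]), float(reference[1])),
        track.track_id, track.video_id, track.group_id,
    )


def default_region_radius(
    tracks: list[Track],
    references: dict[tuple[str, int], tuple[float, float]],
    percentile: float = 98.5,
) -> int:
    """Dataset-driven region radius: the given percentile of Chebyshev offsets, rounded up.

    Keeps nearly all trajectory points on the canvas while letting rare long
    excursions be clipped rather than inflating every image.
    """
    offs = []
    for tr in tracks:
        ref = references[(tr.video_id, tr.group_id)]
        offs.append(np.maximum(np.abs(tr.xs - ref[0]), np.abs(tr.ys - ref[1])))
    allo = np.concatenate(offs)
    return max(1, int(np.ceil(np.percentile(allo, percentile))))


def assign_tumor_neighborhoods(
    tracks: list[Track],
    tumor_centers: list[tuple[float, float]],
    radius: float,
) -> list[GroupAssignment]:
    """Assign each track to the nearest tumor center within ``radius`` of its start.

    Ties go to the lower-indexed center; tracks farther than ``radius`` from
    every center are excluded. Centers with no member yield no group.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not tumor_centers:
        return []
    centers = np.asarray(tumor_centers, dtype=float)
    members: dict[int, list[int]] = {}
    for tr in tracks:
        start = np.array([tr.xs[0], tr.ys[0]])
        d = np.hypot(*(centers - start).T)
        k = int(np.argmin(d))  # argmin takes the first (lowest-index) minimum
        if d[k] <= radius:
            members.setdefault(k, []).append(tr.track_id)
    return [
        GroupAssignment(k, tuple(centers[k]), sorted(ids), "tumor_neighborhood")
        for k, ids in sorted(members.items())
    ]


def cluster_tracks(tracks: list[Track], linkage_distance: float) -> list[GroupAssignment]:
    """Group tracks by single-linkage clustering of their geometric centers.

    Clusters are cut at ``linkage_distance``; each group's reference is the
    mean of its member track centers. Group ids are assigned in order of the
    lowest member track index, so the result is independent of input order.
    """
    if linkage_distance <= 0:
        raise ValueError("linkage_distance must be > 0")
    if not tracks:
        return []
    order = np.argsort([tr.track_id for tr in tracks])
    tracks = [tracks[i] for i in order]
    centers = np.array([tr.geometric_center() for tr in tracks])
    if len(tracks) == 1:
        labels = np.array([1])
    else:
        Z = linkage(centers, method="single")
        labels = fcluster(Z, t=linkage_distance, criterion="distance")
    groups: list[GroupAssignment] = []
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(groups)
            groups.append(GroupAssignment(len(groups), (0.0, 0.0), [], "cluster"))
        groups[seen[lab]].member_track_ids.append(tracks[i].track_id)
    for g in groups:
        idx = [i for i, tr in enumerate(tracks) if tr.track_id in set(g.member_track_ids)]
        g.reference = tuple(centers[idx].mean(axis=0))
        g.member_track_ids.sort()
    return groups


def build_atlas(
    tracks: list[Track],
    groups: dict[tuple[str, int], GroupAssignment] | None,
    R: int,
    out_dir: str | Path,
    labels: dict[str, str] | None = None,
    references: dict[tuple[str, int], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Write one PNG per track plus a manifest CSV; return the manifest.

    The reference for each track comes from ``references[(video_id, group_id)]``
    (or from ``groups``). Tracks that raise :class:`BlankTrajectoryError` are
    recorded in the manifest with an empty image_path and skipped with a warning.
    Deterministic file naming: ``{video_id}_g{group_id}_t{track_id}.png``.
    """
    import warnings

    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = references or {
        k: g.reference for k, g in (groups or {}).items()
    }
    rows = []
    for tr in sorted(tracks, key=lambda t: (t.video_id, t.group_id or 0, t.track_id)):
        ref = refs[(tr.video_id, tr.group_id)]
        label = labels.get(tr.video_id, "") if labels else ""
        name = f"{tr.video_id}_g{tr.group_id}_t{tr.track_id}.png"
        try:
            ti = track_to_image(tr, ref, R)
        except BlankTrajectoryError as e:
            warnings.warn(str(e))
            rows.append(("", tr.video_id, tr.group_id, tr.track_id, label))
            continue
        iio.imwrite(out_dir / name, ti.pixels * np.uint8(255))
        rows.append((name, tr.video_id, tr.group_id, tr.track_id, label))
    return pd.DataFrame(
        rows, columns=["image_path", "video_id", "group_id", "track_id", "label"]
    )
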