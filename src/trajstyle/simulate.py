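"""Synthetic cell-motility data with the statistical structure the pipeline assumes.

Tracks follow a 2D random walk with time-varying drift and volatility,

    x(t+1) - x(t) = mu_x(t) + sigma_x(t) * w(t)

with ``w`` zero-mean unit-variance white noise (Gaussian by default),
independent across axes and time. Drift may be a constant vector or a
magnitude directed toward a group reference point, which models the
"attractiveness" of a tumor cell for surrounding immune cells: an untreated
experiment is emulated with stronger attraction toward the reference than a
treated one (or vice versa, per design).

Track lengths are drawn from a truncated lognormal to emulate the strongly
right-skewed length heterogeneity of long live-cell experiments, where
cells enter/exit the field of view and tracks are much shorter than the
observation window on average.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .track import Track

__all__ = [
    "MotilityParams",
    "TrackLengthSpec",
    "FrameGeometry",
    "ExperimentDesign",
    "SyntheticDataset",
    "simulate_track",
    "sample_track_lengths",
    "simulate_experiment",
    "render_video",
    "case_study_design",
]

_NOISE_MODELS = {
    "gaussian": lambda rng, size: rng.standard_normal(size),
    # zero-mean, unit-variance alternatives
    "uniform": lambda rng, size: rng.uniform(-np.sqrt(3), np.sqrt(3), size),
    "laplace": lambda rng, size: rng.laplace(0.0, 1.0 / np.sqrt(2), size),
}


@dataclass(frozen=True)
class MotilityParams:
    """Random-walk parameters for one experimental condition.

    drift_x/drift_y: constant drift (px/frame); ignored when ``attraction``
    is non-zero, in which case the drift at each step has magnitude
    ``attraction`` (px/frame) and points from the current position toward
    the reference point.
    volatility_x/volatility_y: per-frame displacement std (px/frame).
    """

    drift_x: float = 0.0
    drift_y: float = 0.0
    attraction: float = 0.0
    volatility_x: float = 1.0
    volatility_y: float = 1.0
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.volatility_x < 0 or self.volatility_y < 0:
            raise ValueError("volatility must be non-negative")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class TrackLengthSpec:
    """Lognormal track-length model, truncated to [2, max_frames].

    ``mean``/``std`` are the target moments (in frames) of the untruncated
    lognormal; ``std == 0`` degenerates to constant length ``mean``.
    """

    mean: float = 50.0
    std: float = 35.0

    def __post_init__(self) -> None:
        if self.mean < 2:
            raise ValueError("mean track length must be >= 2 frames")
        if self.std < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass(frozen=True)
class FrameGeometry:
    height: int = 512
    width: int = 512
    cell_radius: float = 4.0

    def __post_init__(self) -> None:
        if min(self.height, self.width) < 4 * self.cell_radius:
            raise ValueError("frame too small for the configured cell radius")


@dataclass(frozen=True)
class ExperimentDesign:
    """A two-condition synthetic experiment layout.

    Each video contains ``n_groups_per_video`` reference points (tumor cells
    or cluster centers) with ``n_tracks_per_group`` tracks born around each.
    """

    n_videos_per_condition: int = 4
    n_groups_per_video: int = 5
    n_tracks_per_group: int = 40
    observation_frames: int = 150
    track_length: TrackLengthSpec = field(default_factory=TrackLengthSpec)
    condition_params: dict[str, MotilityParams] = field(
        default_factory=lambda: {
            "untreated": MotilityParams(attraction=0.45),
            "treated": MotilityParams(attraction=0.08),
        }
    )
    frame_geometry: FrameGeometry = field(default_factory=FrameGeometry)
    start_radius: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_videos_per_condition", "n_groups_per_video", "n_tracks_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.observation_frames < 2:
            raise ValueError("observation_frames must be >= 2")
        if set(self.condition_params) != {"treated", "untreated"}:
            raise ValueError("conditions must be exactly {treated, untreated}")


@dataclass
class SyntheticDataset:
    """Tracks plus the ground truth that generated them."""

    tracks: list[Track]
    references: dict[tuple[str, int], tuple[float, float]]
    labels: dict[str, str]
    design: ExperimentDesign

    def video_ids(self) -> list[str]:
        return sorted(self.labels)

    def tracks_of(self, video_id: str) -> list[Track]:
        return [t for t in self.tracks if t.video_id == video_id]

    def ground_truth_links(self, video_id: str) -> dict[int, dict[int, tuple[float, float]]]:
        """frame -> {track_id -> (x, y)} identity correspondences for one video."""
        links: dict[int, dict[int, tuple[float, float]]] = {}
        for tr in self.tracks_of(video_id):
            for f, x, y in zip(tr.frames, tr.xs, tr.ys):
                links.setdefault(int(f), {})[tr.track_id] = (float(x), float(y))
        return links


def simulate_track(
    params: MotilityParams,
    start: tuple[float, float],
    n_steps: int,
    rng: np.random.Generator,
    reference: tuple[float, float] | None = None,
    birth_frame: int = 0,
    track_id: int = 0,
    video_id: str = "",
    group_id: int | None = None,
) -> Track:
    """Simulate one random-walk track of ``n_steps`` displacements (n_steps+1 positions)."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if params.attraction != 0.0 and reference is None:
        raise ValueError("attraction drift requires a reference point")
    noise = _NOISE_MODELS[params.noise_model]
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    sig = np.array([params.volatility_x, params.volatility_y])
    ref = np.asarray(reference, dtype=float) if reference is not None else None
    w = noise(rng, (n_steps, 2))
    for t in range(n_steps):
        if params.attraction != 0.0:
            v = ref - pos[t]
            d = np.hypot(*v)
            mu = params.attraction * v / d if d > 1e-9 else np.zeros(2)
        else:
            mu = np.array([params.drift_x, params.drift_y])
        pos[t + 1] = pos[t] + mu + sig * w[t]
    frames = birth_frame + np.arange(n_steps + 1)
    return Track(track_id, frames, pos[:, 0], pos[:, 1], video_id=video_id, group_id=group_id)


def sample_track_lengths(
    spec: TrackLengthSpec,
    n: int,
    rng: np.random.Generator,
    max_frames: int = 150,
) -> np.ndarray:
    """Draw ``n`` integer track lengths in [2, max_frames] from the truncated lognormal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if max_frames < 2:
        raise ValueError("truncation bound must be >= 2")
    if spec.std == 0:
        return np.full(n, int(np.clip(round(spec.mean), 2, max_frames)))
    s2 = np.log1p((spec.std / spec.mean) ** 2)
    mu = np.log(spec.mean) - s2 / 2
    out = np.empty(n, dtype=int)
    filled = 0
    for _ in range(200):  # rejection sampling, then clip any stragglers
        draw = np.rint(rng.lognormal(mu, np.sqrt(s2), n - filled)).astype(int)
        ok = draw[(draw >= 2) & (draw <= max_frames)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
        if filled == n:
            break
    if filled < n:
        draw = np.rint(rng.lognormal(mu, np.sqrt(s2), n - filled)).astype(int)
        out[filled:] = np.clip(draw, 2, max_frames)
    return out


def _group_references(
    n_groups: int, geom: FrameGeometry, margin: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Jittered grid of group reference points, kept ``margin`` px from the border."""
    k = int(np.ceil(np.sqrt(n_groups)))
    margin = min(margin, (min(geom.width, geom.height) - 1) / 2)
    gx = np.linspace(margin, geom.width - margin, k)
    gy = np.linspace(margin, geom.height - margin, k)
    cells = [(x, y) for y in gy for x in gx][:n_groups]
    jitter = max(
        min(
            (gx[1] - gx[0]) if k > 1 else geom.width - 2 * margin,
            (gy[1] - gy[0]) if k > 1 else geom.height - 2 * margin,
        ) * 0.1,
        0.0,
    )
    return [
        (float(x + rng.uniform(-jitter, jitter)), float(y + rng.uniform(-jitter, jitter)))
        for x, y in cells
    ]


def simulate_experiment(design: ExperimentDesign) -> SyntheticDataset:
    """Generate the full two-condition dataset described by ``design``.

    Deterministic given ``design`` (including its seed). Tracks are born at a
    uniformly random frame such that they fit inside the observation window,
    and start uniformly inside a disc of radius ``start_radius`` around their
    group's reference point.
    """
    rng = np.random.default_rng(design.seed)
    geom = design.frame_geometry
    margin = design.start_radius + 40.0
    tracks: list[Track] = []
    references: dict[tuple[str, int], tuple[float, float]] = {}
    labels: dict[str, str] = {}
    tid = 0
    for cond in sorted(design.condition_params):
        params = design.condition_params[cond]
        for v in range(design.n_videos_per_condition):
            video_id = f"{cond}-{v + 1:02d}"
            labels[video_id] = cond
            refs = _group_references(design.n_groups_per_video, geom, margin, rng)
            for g, ref in enumerate(refs):
                references[(video_id, g)] = ref
                lengths = sample_track_lengths(
                    design.track_length,
                    design.n_tracks_per_group,
                    rng,
                    design.observation_frames,
                )
                for L in lengths:
                    n_steps = int(L) - 1
                    birth = int(rng.integers(0, design.observation_frames - n_steps))
                    theta = rng.uniform(0, 2 * np.pi)
                    rad = design.start_radius * np.sqrt(rng.uniform())
                    start = (ref[0] + rad * np.cos(theta), ref[1] + rad * np.sin(theta))
                    tracks.append(
                        simulate_track(
                            params,
                            start,
                            n_steps,
                            rng,
                            reference=ref,
                            birth_frame=birth,
                            track_id=tid,
                            video_id=video_id,
                            group_id=g,
                        )
                    )
                    tid += 1
    return SyntheticDataset(tracks, references, labels, design)


def render_video(
    dataset: SyntheticDataset,
    video_id: str,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
    foreground: int = 200,
    background: int = 30,
) -> np.ndarray:
    """Rasterize one video as a (T, H, W) uint8 stack: filled disks + additive noise.

    Positions outside the frame are clipped to the border. Writable as a
    multi-page grayscale TIFF.
    """
    from skimage.draw import disk

    geom = dataset.design.frame_geometry
    T = dataset.design.observation_frames
    stack = np.full((T, geom.height, geom.width), float(background))
    for tr in dataset.tracks_of(video_id):
        for f, x, y in zip(tr.frames, tr.xs, tr.ys):
            cy = float(np.clip(y, 0, geom.height - 1))
            cx = float(np.clip(x, 0, geom.width - 1))
            rr, cc = disk((cy, cx), geom.cell_radius, shape=(geom.height, geom.width))
            stack[int(f), rr, cc] = foreground
    if noise_level > 0:
        rng = rng or np.random.default_rng(0)
        stack += rng.normal(0.0, noise_level, stack.shape)
    return np.clip(stack, 0, 255).astype(np.uint8)


def case_study_design(seed: int = 0) -> ExperimentDesign:
    """The default synthetic analogue of a two-condition drug-response experiment."""
    return ExperimentDesign(seed=seed)
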