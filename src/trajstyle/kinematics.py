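"""The 28-descriptor kinematic baseline for trajectory classification.

Eight low-level features are computed per track: tangential speed magnitude
(f1), track curvature (f2), angular speed magnitude (f3), turning angle (f4),
distance to the track centre (f5) — all series along the track — plus three
scalars: average distance from the cancer/cluster centre (f6), diffusion
coefficient (f7), and directional persistence (f8). For each of the five
series, the mean, variance, skewness, kurtosis and Shannon entropy summarize
the variability along time (25 values); with f6–f8 appended the descriptor
vector has exactly 28 entries, independent of track length.

Conventions (the source literature does not pin them down): curvature is the
turning angle divided by the local mean segment length; the diffusion
coefficient is 1/4 of the OLS slope of MSD(tau) over the first quartile of
lags; persistence is net displacement over total path length (in [0, 1]);
entropy uses 16 equal-width bins over the series' own range, in bits;
kurtosis is excess kurtosis, and skewness/kurtosis/entropy of a constant
series are 0 by convention. The frame interval is 1 internally; physical
units are applied at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .track import Track

__all__ = [
    "DESCRIPTOR_NAMES",
    "low_level_series",
    "descriptor_vector",
    "KinematicFeaturizer",
]

_MOMENTS = ("mean", "var", "skew", "kurt", "entropy")
_SERIES = ("speed", "curvature", "angular_speed", "turning_angle", "dist_center")
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    f"{s}_{m}" for s in _SERIES for m in _MOMENTS
) + ("dist_group_center", "diffusion_coeff", "persistence")

MIN_TRACK_LENGTH = 3


def low_level_series(track: Track, group_center: tuple[float, float]) -> dict:
    """Compute f1..f5 series and the f6, f7, f8 scalars for one track."""
    L = len(track)
    if L < MIN_TRACK_LENGTH:
        raise ValueError(
            f"track {track.track_id} has {L} points; kinematic descriptors "
            f"need at least {MIN_TRACK_LENGTH}"
        )
    pos = track.positions
    disp = np.diff(pos, axis=0)
    seg = np.hypot(disp[:, 0], disp[:, 1])  # segment lengths
    speed = seg.copy()  # f1, dt = 1 frame

    # turning angle between consecutive displacement vectors (absolute), f4
    cross = disp[:-1, 0] * disp[1:, 1] - disp[:-1, 1] * disp[1:, 0]
    dot = (disp[:-1] * disp[1:]).sum(axis=1)
    turning = np.abs(np.arctan2(cross, dot))
    degenerate = (seg[:-1] < 1e-12) | (seg[1:] < 1e-12)
    turning[degenerate] = 0.0
    angular_speed = turning.copy()  # f3 = f4 / dt
    # discrete curvature, f2: turning angle per unit arc length
    arc = 0.5 * (seg[:-1] + seg[1:])
    curvature = np.where(arc > 1e-12, turning / np.maximum(arc, 1e-12), 0.0)

    center = pos.mean(axis=0)
    dist_center = np.hypot(*(pos - center).T)  # f5

    gc = np.asarray(group_center, dtype=float)
    f6 = float(np.hypot(*(pos - gc).T).mean())
    f7 = _diffusion_coefficient(pos)
    path = seg.sum()
    net = float(np.hypot(*(pos[-1] - pos[0])))
    f8 = float(np.clip(net / path, 0.0, 1.0)) if path > 1e-12 else 0.0
    return {
        "speed": speed,
        "curvature": curvature,
        "angular_speed": angular_speed,
        "turning_angle": turning,
        "dist_center": dist_center,
        "f6": f6,
        "f7": f7,
        "f8": f8,
    }


def _diffusion_coefficient(pos: np.ndarray) -> float:
    """D = slope/4 of an OLS line fit to MSD(tau) over the first quartile of lags."""
    L = len(pos)
    max_lag = min(L - 1, max(2, (L - 1) // 4))
    lags = np.arange(1, max_lag + 1)
    msd = np.array(
        [float((((pos[k:] - pos[:-k]) ** 2).sum(axis=1)).mean()) for k in lags]
    )
    if len(lags) == 1:
        slope = msd[0] / lags[0]
    else:
        slope = np.polyfit(lags, msd, 1)[0]
    return float(max(slope, 0.0)) / 4.0


def shannon_entropy(series: np.ndarray, bins: int = 16) -> float:
    """Entropy (bits) of the series histogram over ``bins`` equal-width bins.

    A constant series occupies a single bin and has entropy 0.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = series.min(), series.max()
    if hi - lo < 1e-12:
        return 0.0
    counts, _ = np.histogram(series, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _moments(series: np.ndarray, entropy_bins: int) -> list[float]:
    m = float(series.mean())
    v = float(series.var())
    if v < 1e-24:  # degenerate (constant) series convention
        return [m, v, 0.0, 0.0, 0.0]
    return [
        m,
        v,
        float(stats.skew(series)),
        float(stats.kurtosis(series)),  # excess kurtosis
        shannon_entropy(series, entropy_bins),
    ]


def descriptor_vector(
    track: Track, group_center: tuple[float, float], entropy_bins: int = 16
) -> np.ndarray:
    """The 28-element kinematic descriptor vector, in DESCRIPTOR_NAMES order."""
    ll = low_level_series(track, group_center)
    out: list[float] = []
    for name in _SERIES:
        out.extend(_moments(np.asarray(ll[name]), entropy_bins))
    out.extend([ll["f6"], ll["f7"], ll["f8"]])
    vec = np.array(out, dtype=float)
    assert vec.shape == (28,) and np.all(np.isfinite(vec))
    return vec


class KinematicFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn transformer: list of (Track, group_center) pairs -> (n, 28) matrix."""

    def __init__(self, entropy_bins: int = 16):
        self.entropy_bins = entropy_bins

    def fit(self, X=None, y=None) -> "KinematicFeaturizer":
        self.n_features_out_ = 28
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack(
            [descriptor_vector(tr, gc, self.entropy_bins) for tr, gc in X]
        )
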