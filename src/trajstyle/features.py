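"""Transfer-learning style descriptors for trajectory images.

Each binary trajectory image is pushed through the convolutional front end of
an AlexNet-geometry network (original 96/256-channel variant) and the output
of the second max-pooling stage ("pool2", 13 x 13 x 256 for a 227 x 227
input) is flattened into a 43264-dimensional descriptor. The network is used
purely as a fixed feature extractor — it is never fine-tuned.

Two weight sources are supported. ``fixed_seed_random`` draws He-scaled
Gaussian filters from a seeded generator: random convolutional features are a
well-studied fixed embedding that preserves local image geometry (edges,
orientation, density), which is exactly what distinguishes trajectory shapes.
``pretrained`` requests ImageNet weights and falls back to the fixed-seed
random filters with a warning when no weight source is importable, so the
pipeline always runs offline.

Dimensionality is then reduced by an unsupervised variance criterion: columns
whose variance over the (training) images is low carry little information and
are rejected. Class labels are never consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BackboneSpec",
    "ConvFeatureExtractor",
    "VarianceFeatureSelector",
    "preprocess_image",
    "extract_features",
    "select_features",
    "POOL2_DIM",
]

POOL2_DIM = 13 * 13 * 256  # flattened second-pooling output for 227x227 input


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture + tap-layer description of the fixed feature extractor."""

    architecture: str = "alexnet"
    tap_layer: str = "pool2"
    input_size: tuple[int, int, int] = (227, 227, 3)
    weights: str = "pretrained"  # or "fixed_seed_random"
    weight_seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture != "alexnet":
            raise ValueError("only the alexnet-geometry backbone is available")
        if self.tap_layer != "pool2":
            raise ValueError("only the pool2 tap layer is available")
        if self.weights not in ("pretrained", "fixed_seed_random"):
            raise ValueError("weights must be 'pretrained' or 'fixed_seed_random'")
        if self.input_size != (227, 227, 3):
            raise ValueError("alexnet expects 227x227x3 input")


def preprocess_image(img: np.ndarray, spec: BackboneSpec | None = None) -> np.ndarray:
    """Resize a binary trajectory image to the network input geometry.

    Bilinear resize to 227x227, values scaled to [0, 1] then centered to
    [-1, 1]. The single gray channel is replicated to the three input
    channels at convolution time, so the returned array is 2D. Deterministic.
    """
    from skimage.transform import resize

    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("zero-size image")
    spec = spec or BackboneSpec()
    h, w, _ = spec.input_size
    x = resize(img.astype(np.float32), (h, w), order=1, anti_aliasing=False,
               preserve_range=True)
    return (2.0 * x - 1.0).astype(np.float32)


def _pool(x: np.ndarray, k: int = 3, s: int = 2) -> np.ndarray:
    # x: (C, H, W) -> max pool
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
    return win.max(axis=(-2, -1))


class _NumpyAlexnetFront:
    """conv1(11x11/4) -> relu -> pool -> conv2(5x5, pad 2) -> relu -> pool2.

    Original-geometry channel counts (96, 256). Because the input channels
    are replications of one gray image, conv1 is applied with its filters
    summed over input channels — mathematically identical and ~3x cheaper.
    """

    def __init__(self, rng: np.random.Generator):
        w1 = rng.normal(0.0, np.sqrt(2.0 / (11 * 11 * 3)), (96, 3, 11, 11))
        self.w1g = w1.sum(axis=1).reshape(96, -1).astype(np.float32).T  # (121, 96)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / (5 * 5 * 96)), (256, 96, 5, 5))
        self.w2 = self.w2.reshape(256, -1).astype(np.float32).T  # (2400, 256)

    def forward(self, img: np.ndarray) -> np.ndarray:
        # conv1: 227 -> 55 (stride 4), via im2col on the single gray channel
        patches = sliding_window_view(img, (11, 11))[::4, ::4]  # (55, 55, 11, 11)
        c1 = patches.reshape(55 * 55, 121) @ self.w1g  # (3025, 96)
        c1 = np.maximum(c1, 0.0).reshape(55, 55, 96).transpose(2, 0, 1)
        p1 = _pool(c1)  # (96, 27, 27)
        # conv2: pad 2, 27 -> 27
        pad = np.pad(p1, ((0, 0), (2, 2), (2, 2)))
        win = sliding_window_view(pad, (5, 5), axis=(1, 2))  # (96, 27, 27, 5, 5)
        cols = win.transpose(1, 2, 0, 3, 4).reshape(27 * 27, 96 * 25)
        c2 = np.maximum(cols @ self.w2, 0.0)  # (729, 256)
        c2 = c2.reshape(27, 27, 256).transpose(2, 0, 1)
        return _pool(c2).ravel()  # (256*13*13,) = 43264


def _build_backbone(spec: BackboneSpec) -> _NumpyAlexnetFront:
    weights = spec.weights
    if weights == "pretrained":
        try:  # pragma: no cover - exercised only where torchvision exists
            import torchvision  # noqa: F401

            raise ImportError(
                "no pretrained weight source with original AlexNet geometry"
            )
        except ImportError:
            warnings.warn(
                "pretrained backbone weights unavailable; falling back to "
                "fixed_seed_random filters (seed "
                f"{spec.weight_seed})",
                stacklevel=3,
            )
            weights = "fixed_seed_random"
    rng = np.random.default_rng(spec.weight_seed)
    return _NumpyAlexnetFront(rng)


class ConvFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn transformer: trajectory images -> flattened pool2 descriptors.

    ``X`` may be a list of 2D arrays of heterogeneous sizes (each image is
    resized independently). Output is (n_images, 43264) float32, rows in
    input order.
    """

    def __init__(self, weights: str = "fixed_seed_random", weight_seed: int = 0):
        self.weights = weights
        self.weight_seed = weight_seed

    @property
    def spec(self) -> BackboneSpec:
        return BackboneSpec(weights=self.weights, weight_seed=self.weight_seed)

    def fit(self, X=None, y=None) -> "ConvFeatureExtractor":
        self.backbone_ = _build_backbone(self.spec)
        self.n_features_out_ = POOL2_DIM
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "backbone_")
        out = np.empty((len(X), POOL2_DIM), dtype=np.float32)
        for i, img in enumerate(X):
            out[i] = self.backbone_.forward(preprocess_image(img, self.spec))
        return out


def extract_features(images, spec: BackboneSpec | None = None) -> np.ndarray:
    """One pool2 descriptor row per image (manifest order)."""
    spec = spec or BackboneSpec()
    ext = ConvFeatureExtractor(weights=spec.weights, weight_seed=spec.weight_seed)
    return ext.fit().transform(images)


class VarianceFeatureSelector(BaseEstimator, SelectorMixin):
    """Unsupervised variance-criterion feature selection.

    mode="quantile" (default): reject the lowest ``quantile`` fraction of
    columns by variance (ties at the cutoff are rejected). mode="absolute":
    reject columns with variance <= ``threshold``. Labels are never an input;
    fit on training rows only and apply the same mask to test rows.
    """

    def __init__(self, mode: str = "quantile", quantile: float = 0.5,
                 threshold: float = 0.0):
        self.mode = mode
        self.quantile = quantile
        self.threshold = threshold

    def fit(self, X, y=None) -> "VarianceFeatureSelector":
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2D matrix with at least 2 rows")
        self.variances_ = X.var(axis=0)
        if self.mode == "quantile":
            if not 0.0 <= self.quantile < 1.0:
                raise ValueError("quantile must be in [0, 1)")
            cutoff = np.quantile(self.variances_, self.quantile)
            mask = self.variances_ > cutoff
            if not mask.any():  # all-equal variances: quantile rejects everything
                mask = self.variances_ > 0
        elif self.mode == "absolute":
            mask = self.variances_ > self.threshold
        else:
            raise ValueError("mode must be 'quantile' or 'absolute'")
        if not mask.any():
            raise ValueError("variance threshold rejected every feature")
        self.retained_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "retained_mask_")
        return self.retained_mask_


def select_features(fm: np.ndarray, variance_threshold: float = 0.0,
                    mode: str = "absolute", quantile: float = 0.5):
    """Functional wrapper: returns (reduced matrix, retained mask)."""
    sel = VarianceFeatureSelector(mode=mode, quantile=quantile,
                                  threshold=variance_threshold).fit(fm)
    return sel.transform(np.asarray(fm)), sel.retained_mask_
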