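"""Frozen feature extraction and the trainable softmax classifier head.

The transfer-learning design keeps the feature extractor frozen and
federates only the parameters of a linear softmax head, which makes the
local objective convex and the federated/centralized comparison exact.

Two backends are provided:

``texture_descriptor`` (default)
    A deterministic handcrafted descriptor: per-channel intensity
    histograms, multiscale gradient-magnitude statistics, a
    gradient-weighted axial orientation histogram with a coherence
    summary, difference-of-Gaussians blob statistics, band-energy ratios
    and green-channel moments, normalized by frozen reference constants.
    74 dimensions, no downloaded weights, fully reproducible.

``pretrained_cnn``
    A frozen ImageNet-pretrained EfficientNet-B0 truncated before its
    classification head, followed by global average pooling (d = 1280).
    Requires a deep-learning runtime with the pretrained weights; when
    unavailable an informative error points at ``texture_descriptor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .simulate import LabeledImage

__all__ = [
    "FeatureVector",
    "ModelParams",
    "HeadTrainConfig",
    "extract_features",
    "feature_names",
    "global_average_pool",
    "predict",
    "head_loss",
    "head_gradient",
    "train_head",
    "BACKENDS",
]

TEXTURE_BACKEND = "texture_descriptor"
CNN_BACKEND = "pretrained_cnn"
BACKENDS = (TEXTURE_BACKEND, CNN_BACKEND)

_NORM_CACHE: dict[str, np.ndarray] = {}


def _descriptor_norm() -> tuple[np.ndarray, np.ndarray]:
    """Frozen per-feature (center, scale) normalization constants.

    Computed once from a fixed-seed reference batch of the packaged
    scenario (see ``scripts/calibrate_descriptor.py``) and shipped as
    package data, in the same spirit as ImageNet channel statistics:
    stateless, identical on every node, never fit to a user's data.
    Gradient-magnitude features have zero center so a constant image still
    maps to exactly zero.
    """
    if not _NORM_CACHE:
        import json
        from importlib import resources

        raw = json.loads(
            resources.files("col6fl.data").joinpath("descriptor_norm.json").read_text()
        )
        _NORM_CACHE["center"] = np.asarray(raw["center"], dtype=float)
        _NORM_CACHE["scale"] = np.asarray(raw["scale"], dtype=float)
    return _NORM_CACHE["center"], _NORM_CACHE["scale"]

_HIST_BINS = 16
_GRAD_SIGMAS = (1.0, 2.0, 4.0)
_ORIENT_BINS = 8


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    backend_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return self.values.size


def feature_names(backend_id: str = TEXTURE_BACKEND) -> list[str]:
    """Names of the descriptor components, in output order."""
    if backend_id != TEXTURE_BACKEND:
        raise ValueError(f"feature names only defined for {TEXTURE_BACKEND!r}")
    names = [
        f"hist_{ch}_{b}" for ch in "rgb" for b in range(_HIST_BINS)
    ]
    for s in _GRAD_SIGMAS:
        names += [f"grad_s{s:g}_mean", f"grad_s{s:g}_std", f"grad_s{s:g}_p90"]
    names += [f"orient_bin{b}" for b in range(_ORIENT_BINS)]
    names += ["orient_coherence", "blob_mean", "blob_p99", "blob_area",
              "band_ratio_fine", "band_ratio_coarse",
              "int_mean", "int_std", "int_m3"]
    return names


def global_average_pool(feature_map: np.ndarray) -> np.ndarray:
    """Average an H x W x C feature map over its spatial axes."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3:
        raise ValueError(f"expected H x W x C feature map, got shape {fm.shape}")
    return fm.mean(axis=(0, 1))


def _texture_descriptor(img: np.ndarray) -> np.ndarray:
    # float32 throughout: halves filter cost, far above the head's needs
    g = np.ascontiguousarray(img[:, :, 1], dtype=np.float32)
    npix = img.shape[0] * img.shape[1]
    feats: list[np.ndarray] = []

    # per-channel intensity histograms, Hellinger-mapped (sqrt of the bin
    # proportion): evens out the dominant background bin, which markedly
    # improves the conditioning of the downstream linear head
    q = np.minimum((img * _HIST_BINS).astype(np.intp), _HIST_BINS - 1)
    for ch in range(3):
        h = np.bincount(q[:, :, ch].ravel(), minlength=_HIST_BINS)
        feats.append(np.sqrt(h / npix))

    # multiscale gradient-magnitude statistics (exactly 0 on constant input);
    # coarser scales are built incrementally from the finer blurs
    smooth, prev = {}, g
    prev_s = 0.0
    for s in _GRAD_SIGMAS:
        prev = gaussian_filter(prev, np.sqrt(s**2 - prev_s**2), truncate=3.0)
        smooth[s] = prev
        prev_s = s
    grads = {}
    for s in _GRAD_SIGMAS:
        gy, gx = np.gradient(smooth[s])
        m = np.hypot(gy, gx)
        grads[s] = (gy, gx, m)
        feats.append(10.0 * np.array([m.mean(), m.std(), np.percentile(m, 90)]))

    # gradient-weighted axial orientation histogram + coherence (sigma = 2)
    gy, gx, m = grads[2.0]
    wsum = m.sum()
    if wsum > 0:
        theta = np.arctan2(gy, gx).ravel()
        theta = np.where(theta < 0, theta + np.pi, theta)  # axial, [0, pi)
        bins = np.minimum(
            (theta * (_ORIENT_BINS / np.pi)).astype(np.intp), _ORIENT_BINS - 1
        )
        oh = np.bincount(bins, weights=m.ravel(), minlength=_ORIENT_BINS) / wsum
        # resultant length of the doubled angles: cos2t=(gx^2-gy^2)/m^2 etc.
        with np.errstate(invalid="ignore", divide="ignore"):
            c2 = np.where(m > 0, (gx**2 - gy**2) / np.where(m > 0, m, 1), 0.0)
            s2 = np.where(m > 0, 2 * gx * gy / np.where(m > 0, m, 1), 0.0)
        coherence = float(np.hypot(c2.sum(), s2.sum()) / wsum)
    else:
        oh = np.zeros(_ORIENT_BINS)
        coherence = 0.0
    feats.append(2.0 * oh)
    feats.append(np.array([coherence]))

    # punctate (blob) response: positive difference-of-Gaussians, sigma 1->2
    dog = np.clip(smooth[1.0] - smooth[2.0], 0.0, None)
    feats.append(
        np.array([
            50.0 * dog.mean(),
            10.0 * np.percentile(dog, 99),
            20.0 * np.mean(dog > 0.05),
        ])
    )

    # band-energy ratios: fine-scale modulation (bead periodicity, puncta)
    # relative to overall fibril contrast; gain-insensitive by construction
    m1, m2, m4 = (grads[s][2].mean() for s in _GRAD_SIGMAS)
    feats.append(
        np.array([
            2.0 * dog.mean() / (m1 + 0.01),
            2.0 * m4 / (m1 + 0.01),
        ])
    )

    # green-channel moments (third moment unnormalised: defined for flat input)
    mu = g.mean()
    feats.append(np.array([mu, 3.0 * g.std(), 30.0 * np.mean((g - mu) ** 3)]))
    return np.concatenate(feats)


def extract_features(image, backend_id: str = TEXTURE_BACKEND) -> FeatureVector:
    """Map one preprocessed 256 x 256 x 3 image to a fixed-length vector."""
    if isinstance(image, LabeledImage):
        image = image.pixels
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if backend_id == TEXTURE_BACKEND:
        center, scale = _descriptor_norm()
        return FeatureVector((_texture_descriptor(img) - center) / scale, backend_id)
    if backend_id == CNN_BACKEND:
        try:
            return FeatureVector(_efficientnet_features(img), backend_id)
        except ImportError as exc:
            raise RuntimeError(
                "the pretrained_cnn backend needs a deep-learning runtime with "
                "ImageNet EfficientNet-B0 weights; use "
                "backend_id='texture_descriptor' instead"
            ) from exc
    raise ValueError(f"unknown backend {backend_id!r}; expected one of {BACKENDS}")


def _efficientnet_features(img: np.ndarray) -> np.ndarray:
    from tensorflow.keras.applications import EfficientNetB0  # pragma: no cover
    from tensorflow.keras.applications.efficientnet import (  # pragma: no cover
        preprocess_input,
    )

    model = EfficientNetB0(include_top=False, weights="imagenet", pooling="avg")
    x = preprocess_input(img[None, ...] * 255.0)
    return np.asarray(model.predict(x, verbose=0))[0]


def extract_feature_matrix(
    images: list, backend_id: str = TEXTURE_BACKEND
) -> np.ndarray:
    """Stack per-image feature vectors into an (n, d) matrix."""
    return np.stack([extract_features(im, backend_id).values for im in images])


# ---------------------------------------------------------------------------
# softmax head


@dataclass
class ModelParams:
    """The trainable (and federated) parameters: a d x K linear softmax head."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float).ravel()
        if self.weights.ndim != 2:
            raise ValueError("weights must be a d x K matrix")
        if self.bias.shape[0] != self.weights.shape[1]:
            raise ValueError(
                f"bias length {self.bias.shape[0]} does not match K="
                f"{self.weights.shape[1]}"
            )
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("parameters must be finite")

    @property
    def d(self) -> int:
        return self.weights.shape[0]

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(self.weights.copy(), self.bias.copy())

    @classmethod
    def zeros(cls, d: int, n_classes: int) -> "ModelParams":
        return cls(np.zeros((d, n_classes)), np.zeros(n_classes))


@dataclass(frozen=True)
class HeadTrainConfig:
    """Optimizer settings for the head: plain (mini-batch) gradient descent
    on mean cross-entropy + l2 * ||W||^2 (bias unpenalised)."""

    learning_rate: float = 0.15
    epochs: int = 20
    l2: float = 1e-3
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = features
    else:
        X = np.stack(
            [f.values if isinstance(f, FeatureVector) else np.asarray(f, float)
             for f in features]
        )
    if X.ndim == 1:
        X = X[None, :]
    return np.asarray(X, dtype=float)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict(params: ModelParams, f) -> np.ndarray:
    """Class probabilities softmax(W^T f + b); accepts one vector or a batch."""
    if isinstance(f, FeatureVector):
        single, X = True, f.values[None, :]
    elif isinstance(f, np.ndarray) or (
        isinstance(f, (list, tuple)) and f and np.isscalar(f[0])
    ):
        arr = np.asarray(f, dtype=float)
        single = arr.ndim == 1
        X = arr[None, :] if single else arr
    else:
        single, X = False, _as_matrix(f)
    if X.shape[1] != params.d:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match head d={params.d}"
        )
    P = _softmax(X @ params.weights + params.bias)
    return P[0] if single else P


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"labels must be 0-based indices in [0, {k})")
    out = np.zeros((y.size, k))
    out[np.arange(y.size), y] = 1.0
    return out


def head_loss(params: ModelParams, X: np.ndarray, y: np.ndarray, l2: float) -> float:
    """Mean cross-entropy over (X, y) plus l2 * ||W||^2."""
    P = _softmax(X @ params.weights + params.bias)
    n = X.shape[0]
    ce = -np.log(np.clip(P[np.arange(n), np.asarray(y, int)], 1e-300, None)).mean()
    return float(ce + l2 * np.sum(params.weights**2))


def head_gradient(
    params: ModelParams, X: np.ndarray, y: np.ndarray, l2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`head_loss` w.r.t. (weights, bias)."""
    n = X.shape[0]
    P = _softmax(X @ params.weights + params.bias)
    R = P - _one_hot(y, params.n_classes)
    gw = X.T @ R / n + 2.0 * l2 * params.weights
    gb = R.mean(axis=0)
    return gw, gb


def train_head(
    features,
    labels,
    params0: ModelParams,
    hyper: HeadTrainConfig | None = None,
) -> ModelParams:
    """Gradient-descent training of the softmax head from ``params0``.

    ``labels`` are 0-based class-column indices.  Full-batch by default
    (deterministic); with a batch size, the per-epoch shuffle is seeded.
    """
    hyper = hyper or HeadTrainConfig()
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=int).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != y.size:
        raise ValueError("features and labels length mismatch")
    if X.shape[1] != params0.d:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match head d={params0.d}"
        )
    params = params0.copy()
    rng = np.random.default_rng(hyper.seed)
    n = X.shape[0]
    for _ in range(hyper.epochs):
        if hyper.batch_size is None or hyper.batch_size >= n:
            gw, gb = head_gradient(params, X, y, hyper.l2)
            params.weights = params.weights - hyper.learning_rate * gw
            params.bias = params.bias - hyper.learning_rate * gb
        else:
            idx = rng.permutation(n)
            for start in range(0, n, hyper.batch_size):
                b = idx[start: start + hyper.batch_size]
                gw, gb = head_gradient(params, X[b], y[b], hyper.l2)
                params.weights = params.weights - hyper.learning_rate * gw
                params.bias = params.bias - hyper.learning_rate * gb
    return params
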