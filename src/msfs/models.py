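"""Feature-layer model contract, branch utilities, and a compact backbone.

Any classifier usable with the position regularizer must expose, for a batch
of trials, both its logits and the activations of the layer feeding the final
dense classifier (the "feature layer").  The contract here is deliberately
minimal so the training code never touches architecture internals:

* ``forward(X)`` returns ``(logits, features, cache)``;
* ``backward(cache, dlogits, dfeatures)`` returns parameter gradients for
  the upstream gradients of both heads (``dfeatures`` may be ``None``);
* ``params`` is an ordered name -> array mapping updated in place.

Models are plain NumPy with hand-written backpropagation; gradients are
checked against finite differences in the test suite.

:class:`ReferenceBackbone` is a small band-power-style network (temporal
convolution over all channels jointly, squared activations averaged over
time, log compression, then two dense layers).  It mimics the inductive bias
of shallow EEG decoders — learnable band-pass filtering plus spatial mixing
feeding log-power features — at desk scale; it makes no claim of fidelity to
any published EEG architecture.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .losses import position_loss

__all__ = [
    "FeatureModel",
    "FeatureModelOutput",
    "ReferenceBackbone",
    "LinearFeatureModel",
    "Adam",
    "branch_average",
    "branch_position_loss",
    "clone_model",
    "save_model",
    "load_model",
    "BACKBONE_REGISTRY",
]

_LOG_EPS = 1e-6


@dataclass(frozen=True)
class FeatureModelOutput:
    """Logits ``(N x K)`` plus feature-layer activations ``(N x F)``."""

    logits: np.ndarray
    features: np.ndarray

    def __post_init__(self) -> None:
        if self.logits.shape[0] != self.features.shape[0]:
            raise ValueError("logits and features disagree on batch size")
        if not (np.all(np.isfinite(self.logits))
                and np.all(np.isfinite(self.features))):
            raise ValueError("non-finite model output")


class FeatureModel(Protocol):
    params: dict[str, np.ndarray]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]: ...

    def backward(self, cache: dict, dlogits: np.ndarray,
                 dfeatures: np.ndarray | None) -> dict[str, np.ndarray]: ...


def branch_average(branch_logits: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-branch logits (multi-branch decision rule)."""
    if len(branch_logits) == 0:
        raise ValueError("need at least one branch")
    shapes = {b.shape for b in branch_logits}
    if len(shapes) != 1:
        raise ValueError(f"branches disagree on logit shape: {shapes}")
    return np.mean(branch_logits, axis=0)


def branch_position_loss(branch_features: list[np.ndarray], target_fn) -> float:
    """Mean over branches of the position loss with per-branch targets.

    Each branch has its own feature layer, so targets are recomputed
    independently per branch via ``target_fn(features) -> targets`` and the
    per-branch losses are averaged, mirroring the symmetric treatment of
    branches in the logit average.
    """
    if len(branch_features) == 0:
        raise ValueError("need at least one branch")
    return float(np.mean(
        [position_loss(Z, target_fn(Z)) for Z in branch_features]
    ))


class ReferenceBackbone:
    """Temporal-conv + log-power + dense network mapping ``C x T`` to logits.

    Pipeline per trial: a bank of ``n_filters`` temporal convolution kernels
    spanning all channels (joint spectral-spatial filtering), squared and
    averaged over time (band-power estimate), log-compressed, then a dense
    layer with ELU producing the ``feature_dim`` feature layer, and a final
    dense layer producing the class logits.

    Parameters
    ----------
    n_channels, n_samples : input trial geometry (``T >= kernel``).
    n_classes : number of classes K.
    feature_dim : width F of the feature layer the regularizer acts on.
    n_filters : temporal filter bank size.
    kernel : temporal kernel length in samples.
    seed : initialization seed; equal seeds give identical parameters.
    """

    def __init__(self, n_channels: int, n_samples: int, n_classes: int,
                 feature_dim: int = 16, n_filters: int = 8, kernel: int = 49,
                 seed: int = 0):
        if n_channels < 1 or n_samples < 16:
            raise ValueError("need C >= 1 and T >= 16")
        if kernel > n_samples:
            raise ValueError("kernel longer than trial")
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.n_classes = n_classes
        self.feature_dim = feature_dim
        self.n_filters = n_filters
        self.kernel = kernel
        rng = np.random.default_rng(seed)
        # He-style scaling for the conv/dense stack
        self.params: dict[str, np.ndarray] = {
            "W0": rng.normal(0, np.sqrt(2.0 / (n_channels * kernel)),
                             (n_filters, n_channels, kernel)),
            "b0": np.zeros(n_filters),
            "W1": rng.normal(0, np.sqrt(2.0 / n_filters),
                             (n_filters, feature_dim)),
            "b1": np.zeros(feature_dim),
            "W2": rng.normal(0, np.sqrt(2.0 / feature_dim),
                             (feature_dim, n_classes)),
            "b2": np.zeros(n_classes),
        }

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (self.n_channels, self.n_samples):
            raise ValueError(
                f"expected N x {self.n_channels} x {self.n_samples}, "
                f"got {X.shape}")
        p = self.params
        Xw = sliding_window_view(X, self.kernel, axis=2)  # (N, C, T1, k)
        conv = np.einsum("nctk,fck->nft", Xw, p["W0"]) + p["b0"][None, :, None]
        power = np.mean(conv ** 2, axis=2)  # (N, n_filters)
        h = np.log(power + _LOG_EPS)
        pre = h @ p["W1"] + p["b1"]
        feat = np.where(pre > 0, pre, np.expm1(pre))  # ELU
        logits = feat @ p["W2"] + p["b2"]
        cache = {"Xw": Xw, "conv": conv, "power": power, "h": h,
                 "pre": pre, "feat": feat}
        return logits, feat, cache

    def backward(self, cache: dict, dlogits: np.ndarray,
                 dfeatures: np.ndarray | None = None) -> dict[str, np.ndarray]:
        p = self.params
        feat, pre, h = cache["feat"], cache["pre"], cache["h"]
        power, conv, Xw = cache["power"], cache["conv"], cache["Xw"]
        grads = {
            "W2": feat.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ p["W2"].T
        if dfeatures is not None:
            dfeat = dfeat + dfeatures
        dpre = dfeat * np.where(pre > 0, 1.0, np.exp(pre))
        grads["W1"] = h.T @ dpre
        grads["b1"] = dpre.sum(axis=0)
        dh = dpre @ p["W1"].T
        dpower = dh / (power + _LOG_EPS)
        T1 = conv.shape[2]
        dconv = dpower[:, :, None] * (2.0 * conv / T1)
        grads["W0"] = np.einsum("nft,nctk->fck", dconv, Xw)
        grads["b0"] = dconv.sum(axis=(0, 2))
        return grads


class LinearFeatureModel:
    """Flatten-then-affine model honoring the same (logits, features) contract.

    Exists to demonstrate (and test) that the training code is
    backbone-agnostic: features are an affine map of the flattened trial,
    logits an affine map of the features.
    """

    def __init__(self, n_channels: int, n_samples: int, n_classes: int,
                 feature_dim: int = 8, seed: int = 0):
        self.n_channels = n_channels
        self.n_samples = n_samples
        d = n_channels * n_samples
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": rng.normal(0, 1.0 / np.sqrt(d), (d, feature_dim)),
            "b1": np.zeros(feature_dim),
            "W2": rng.normal(0, 1.0 / np.sqrt(feature_dim),
                             (feature_dim, n_classes)),
            "b2": np.zeros(n_classes),
        }

    def forward(self, X):
        X = np.asarray(X, dtype=float)
        Xf = X.reshape(X.shape[0], -1)
        feat = Xf @ self.params["W1"] + self.params["b1"]
        logits = feat @ self.params["W2"] + self.params["b2"]
        return logits, feat, {"Xf": Xf, "feat": feat}

    def backward(self, cache, dlogits, dfeatures=None):
        feat = cache["feat"]
        grads = {"W2": feat.T @ dlogits, "b2": dlogits.sum(axis=0)}
        dfeat = dlogits @ self.params["W2"].T
        if dfeatures is not None:
            dfeat = dfeat + dfeatures
        grads["W1"] = cache["Xf"].T @ dfeat
        grads["b1"] = dfeat.sum(axis=0)
        return grads


class Adam:
    """Adam with coupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clone_model(model):
    """Deep copy of a model (parameters included)."""
    return copy.deepcopy(model)


def save_model(model, path) -> None:
    """Serialize parameters and constructor metadata to an .npz file."""
    meta = {k: v for k, v in vars(model).items()
            if isinstance(v, (int, float)) and not k.startswith("_")}
    np.savez(path, __class__=type(model).__name__,
             __meta__=np.array([f"{k}={v}" for k, v in meta.items()]),
             **model.params)


def load_model(path):
    data = np.load(path, allow_pickle=False)
    cls_name = str(data["__class__"])
    meta = dict(item.split("=", 1) for item in data["__meta__"])
    kwargs = {k: int(float(v)) for k, v in meta.items()}
    cls = BACKBONE_REGISTRY[cls_name]
    # constructor kwargs are the intersection of metadata and signature
    import inspect
    sig = inspect.signature(cls.__init__)
    model = cls(**{k: v for k, v in kwargs.items() if k in sig.parameters})
    for k in model.params:
        model.params[k] = data[k]
    return model


BACKBONE_REGISTRY: dict[str, type] = {
    "ReferenceBackbone": ReferenceBackbone,
    "reference": ReferenceBackbone,
    "LinearFeatureModel": LinearFeatureModel,
    "linear": LinearFeatureModel,
}
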