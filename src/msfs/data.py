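"""Trial epoching, an HDF5 epoched-trial container, and synthetic generators.

The synthetic generator emulates the structure that makes motor-imagery EEG
decodable across subjects: a rhythmic (mu-band, 10 Hz) oscillation whose
post-cue amplitude is attenuated on a class-specific channel group
(event-related desynchronization), superimposed on 1/f-shaped background
noise, with per-subject multiplicative channel gains and additive offsets
standing in for anatomy/electrode-placement variability.  It deliberately
omits many properties of real recordings — no artifacts, no non-stationarity
within a session, no beta-band or phase structure — so results on it speak
to the mechanics of the transfer pipeline, not to real-EEG performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "EpochedDataset",
    "SynthSpec",
    "epoch_trials",
    "save_epoched",
    "load_epoched",
    "pool_datasets",
    "split_train_test",
    "generate_feature_batch",
    "generate_synthetic_subjects",
    "read_raw_continuous",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochedDataset:
    """Per-subject epoched trials: ``X (n_trials x C x T)``, labels, metadata."""

    X: np.ndarray
    y: np.ndarray
    fs: float
    subject: str = "unknown"
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3:
            raise ValueError(f"X must be n_trials x C x T, got {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match n_trials")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.X.shape[1])]
        if len(self.channels) != self.X.shape[1]:
            raise ValueError("channel names must match channel count")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def n_samples(self) -> int:
        return self.X.shape[2]

    def subset(self, idx: np.ndarray) -> "EpochedDataset":
        return EpochedDataset(self.X[idx], self.y[idx], self.fs,
                              self.subject, list(self.channels))


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the synthetic multi-subject benchmark.

    ``effect_size`` is the fractional post-cue attenuation of the class
    channel group's oscillation (0 = no class signal); ``subject_shift``
    scales the per-subject channel gain spread (std of the multiplicative
    gain) and offset spread (std ``10 * subject_shift`` uV); ``noise_uv`` is
    the background 1/f noise standard deviation in microvolts.
    """

    n_subjects: int = 4
    trials_per_class: int = 24
    n_classes: int = 2
    n_channels: int = 6
    n_samples: int = 128
    fs: float = 128.0
    effect_size: float = 0.4
    subject_shift: float = 0.25
    noise_uv: float = 10.0
    osc_uv: float = 8.0
    cue_sample: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must be in [0, 1)")
        for name in ("n_subjects", "trials_per_class", "n_classes",
                     "n_channels", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def epoch_trials(continuous: np.ndarray, cue_samples, fs: float,
                 pre_s: float, post_s: float, labels=None,
                 channels: list[str] | None = None,
                 subject: str = "unknown") -> EpochedDataset:
    """Crop cue-aligned trials out of a continuous ``C x S`` recording.

    Each trial is the half-open sample window
    ``[cue - round(pre_s * fs), cue + round(post_s * fs))`` — length
    ``round((pre_s + post_s) * fs)`` samples, so 0.5 s before and 4 s after
    the cue at 250 Hz give the standard 1125-sample motor-imagery trial.
    Out-of-bounds windows are rejected per trial with a warning; rejecting
    every cue is an error.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous must be C x S")
    S = continuous.shape[1]
    pre = int(round(pre_s * fs))
    T = int(round((pre_s + post_s) * fs))
    cues = np.asarray(cue_samples, dtype=int)
    labels = (np.ones(len(cues), dtype=int) if labels is None
              else np.asarray(labels, dtype=int))
    kept_X, kept_y = [], []
    for cue, lab in zip(cues, labels):
        start = cue - pre
        if start < 0 or start + T > S:
            logger.warning("rejecting cue at sample %d: window [%d, %d) "
                           "outside recording of %d samples",
                           cue, start, start + T, S)
            continue
        kept_X.append(continuous[:, start:start + T])
        kept_y.append(lab)
    if not kept_X:
        raise ValueError("all cue windows fall outside the recording")
    return EpochedDataset(np.stack(kept_X), np.array(kept_y), fs,
                          subject=subject, channels=channels or [])


def save_epoched(ds: EpochedDataset, path) -> None:
    """Write the dataset to HDF5 (datasets X, y; attrs fs, subject, channels)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ds.X)
        f.create_dataset("y", data=ds.y)
        f.attrs["fs"] = ds.fs
        f.attrs["subject"] = ds.subject
        f.attrs["channels"] = [str(c) for c in ds.channels]


def load_epoched(path) -> EpochedDataset:
    with h5py.File(path, "r") as f:
        for key in ("X", "y"):
            if key not in f:
                raise KeyError(f"container missing dataset '{key}'")
        for attr in ("fs", "subject", "channels"):
            if attr not in f.attrs:
                raise KeyError(f"container missing attribute '{attr}'")
        return EpochedDataset(
            X=f["X"][()], y=f["y"][()], fs=float(f.attrs["fs"]),
            subject=str(f.attrs["subject"]),
            channels=[str(c) for c in f.attrs["channels"]],
        )


def pool_datasets(datasets: list[EpochedDataset]) -> EpochedDataset:
    """Concatenate trials from several subjects into one training pool."""
    if not datasets:
        raise ValueError("nothing to pool")
    return EpochedDataset(
        np.concatenate([d.X for d in datasets]),
        np.concatenate([d.y for d in datasets]),
        datasets[0].fs, subject="pool",
        channels=list(datasets[0].channels),
    )


def split_train_test(ds: EpochedDataset, n_train_per_class: int,
                     seed: int) -> tuple[EpochedDataset, EpochedDataset]:
    """Seeded stratified split into a training and a held-out test set."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(ds.y):
        idx = rng.permutation(np.flatnonzero(ds.y == c))
        if len(idx) <= n_train_per_class:
            raise ValueError(
                f"class {c} has {len(idx)} trials, cannot keep a test split "
                f"with {n_train_per_class} training trials")
        train_idx.extend(idx[:n_train_per_class])
        test_idx.extend(idx[n_train_per_class:])
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def generate_feature_batch(n_per_class: int, K: int, F: int,
                           informative: int, separation: float,
                           rng: np.random.Generator):
    """Gaussian feature-batch fixture for the silhouette machinery.

    Informative features get class means spaced ``separation`` apart with
    unit variance; the rest are class-independent standard Gaussians.
    Returns a :class:`~msfs.silhouette.FeatureBatch` with balanced labels.
    """
    from .silhouette import FeatureBatch

    if informative > F:
        raise ValueError("informative must be <= F")
    y = np.repeat(np.arange(1, K + 1), n_per_class)
    N = len(y)
    Z = rng.normal(size=(N, F))
    means = (np.arange(K) - (K - 1) / 2) * separation
    Z[:, :informative] += means[y - 1][:, None]
    return FeatureBatch(Z, y)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance, last axis = time."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True)
    return pink


def generate_synthetic_subjects(spec: SynthSpec) -> list[EpochedDataset]:
    """Multi-subject ERD-like synthetic benchmark.

    Every trial carries a 10 Hz oscillation (random phase per trial and
    channel group) on each class's channel group on top of pink noise; the
    trial's own class group is attenuated by ``effect_size`` from the cue
    sample onward, so class identity is encoded in post-cue band power.
    Subjects differ by fixed per-channel gains and offsets.  Fully
    reproducible from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    C, T, K = spec.n_channels, spec.n_samples, spec.n_classes
    if C < K:
        raise ValueError("need at least one channel per class group")
    # class c owns a contiguous channel group
    group_size = max(1, C // (K + 1))
    groups = [np.arange(c * group_size, (c + 1) * group_size) for c in range(K)]
    tgrid = np.arange(T) / spec.fs
    post = (np.arange(T) >= spec.cue_sample).astype(float)
    datasets = []
    for s, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        gain = 1.0 + spec.subject_shift * rng.standard_normal(C)
        offset = 10.0 * spec.subject_shift * rng.standard_normal(C)
        n = spec.trials_per_class * K
        y = np.repeat(np.arange(1, K + 1), spec.trials_per_class)
        y = rng.permutation(y)
        X = spec.noise_uv * _pink_noise(rng, (n, C), T, spec.fs)
        for i in range(n):
            for c, grp in enumerate(groups, start=1):
                phase = rng.uniform(0, 2 * np.pi)
                osc = np.sin(2 * np.pi * 10.0 * tgrid + phase)
                amp = np.full(T, spec.osc_uv)
                if c == y[i]:
                    amp *= 1.0 - spec.effect_size * post
                X[i, grp, :] += amp * osc
        X = gain[None, :, None] * X + offset[None, :, None]
        datasets.append(EpochedDataset(X, y, spec.fs, subject=f"S{s + 1:02d}"))
    return datasets


def read_raw_continuous(path, picks: list[str] | None = None):
    """Optional raw-file ingestion (EDF/GDF) via MNE; returns (data, fs, names).

    Requires the ``mne`` extra; every test and synthetic pathway works
    without it.
    """
    try:
        import mne  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover
        raise ImportError("raw-file ingestion requires mne") from exc
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    if picks:
        raw = raw.pick(picks)
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
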