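"""One-dimensional silhouette machinery for batch-wise target-position search.

The regularizer treats each feature dimension of a batch feature matrix
``Z (N x F)`` independently: distances are absolute differences of scalar
feature values, and the silhouette coefficient

    s_i = (b_i - a_i) / max(a_i, b_i)

measures how well sample ``i`` sits inside its own class along that feature
(``a_i``: mean distance to own-class members excluding itself; ``b_i``:
minimum over other classes of the mean distance to that class).  For every
sample and feature, the search relocates the sample to each candidate value
already present in the batch (the sample's own value included), scores the
relocation with the silhouette of the relocated sample while all other
samples stay fixed, and returns the argmax candidate value as the regression
target.  Everything is vectorized so a batch costs O(F * N^2) distance
entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureBatch",
    "SilhouetteTensor",
    "batch_is_msfs_eligible",
    "pairwise_abs_distance",
    "silhouette_1d",
    "relocated_silhouette",
    "opt_pos_sil",
    "opt_pos_brute",
    "opt_pos_sil_subsampled",
    "rand_pos",
    "topk_feature_mask",
    "export_feature_silhouettes",
]

#: absolute tolerance on silhouette scores when detecting argmax ties;
#: scores live in [-1, 1], so ties below this scale are numerically
#: indistinguishable between equivalent evaluation orders
TIE_ATOL = 1e-9


class EligibilityError(ValueError):
    """Batch composition does not support the silhouette computation."""


@dataclass(frozen=True)
class FeatureBatch:
    """A batch feature matrix ``Z (N x F)`` with integer class labels ``y``.

    Labels follow the ``{1..K}`` convention but any integer coding is
    accepted; classes are whatever distinct values appear in ``y``.
    """

    Z: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        y = np.asarray(self.y)
        if Z.ndim != 2:
            raise ValueError(f"Z must be 2-D (N x F), got shape {Z.shape}")
        if Z.shape[0] < 2 or Z.shape[1] < 1:
            raise ValueError(f"need N >= 2 and F >= 1, got {Z.shape}")
        if not np.all(np.isfinite(Z)):
            raise ValueError("Z contains non-finite entries")
        if y.ndim != 1 or y.shape[0] != Z.shape[0]:
            raise ValueError("y must be a length-N label vector")
        if not np.issubdtype(y.dtype, np.integer):
            raise ValueError("labels must be integers")
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "y", y.astype(np.int64))

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_features(self) -> int:
        return self.Z.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)


@dataclass(frozen=True)
class SilhouetteTensor:
    """Relocation silhouettes ``s (N x F x N)`` with their ``a`` and ``b`` parts.

    Entry ``[i, f, j]`` refers to sample ``i`` relocated, along feature ``f``,
    to the value of batch member ``j`` (all other samples fixed).
    """

    s: np.ndarray
    a: np.ndarray
    b: np.ndarray


def batch_is_msfs_eligible(y: np.ndarray) -> bool:
    """True iff >= 2 classes are present and every present class has >= 2 samples.

    Batches failing this test are optimized with cross-entropy only: with a
    singleton class the intra-class mean distance is undefined, and with one
    class the nearest-other-class term is a minimum over an empty set.
    """
    y = np.asarray(y)
    if y.size == 0:
        return False
    _, counts = np.unique(y, return_counts=True)
    return len(counts) >= 2 and bool(np.all(counts >= 2))


def _require_eligible(batch: FeatureBatch) -> None:
    if not batch_is_msfs_eligible(batch.y):
        raise EligibilityError(
            "batch needs >= 2 classes with >= 2 samples each for the "
            "silhouette computation (skip this batch and use CE only)"
        )


def pairwise_abs_distance(batch: FeatureBatch) -> np.ndarray:
    """Per-feature pairwise absolute distances ``D (F x N x N)``.

    ``D[f, j, k] = |Z[j, f] - Z[k, f]|``.
    """
    Z = batch.Z
    return np.abs(Z.T[:, :, None] - Z.T[:, None, :])


def silhouette_1d(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Silhouette coefficient of each sample along a single feature.

    ``a_i`` is the mean absolute distance to own-class members excluding the
    sample itself, ``b_i`` the minimum over other classes of the mean distance
    to that class, and ``s_i = (b_i - a_i) / max(a_i, b_i)`` with the
    convention ``s_i = 0`` where ``max(a_i, b_i) = 0``.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y)
    if values.ndim != 1 or values.shape != y.shape:
        raise ValueError("values and y must be equal-length 1-D arrays")
    if not batch_is_msfs_eligible(y):
        raise EligibilityError(
            "silhouette needs >= 2 classes with >= 2 samples each"
        )
    D = np.abs(values[:, None] - values[None, :])  # (N, N)
    classes, counts = np.unique(y, return_counts=True)
    onehot = (y[:, None] == classes[None, :]).astype(float)  # (N, K)
    class_sums = D @ onehot  # (N, K): sum of distances from i to class q
    own = y[:, None] == classes[None, :]
    a = (class_sums[own] - 0.0) / (counts[np.searchsorted(classes, y)] - 1)
    means = class_sums / counts[None, :]
    b = np.min(np.where(own, np.inf, means), axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    return s


def relocated_silhouette(batch: FeatureBatch) -> SilhouetteTensor:
    """Silhouette of every (sample, feature, candidate) relocation.

    For sample ``i`` moved to the value of batch member ``j`` along feature
    ``f`` (all other samples fixed at their own values):

    * ``a[i,f,j]`` = mean of ``D[f,j,k]`` over own-class members ``k != i``;
    * ``b[i,f,j]`` = min over other classes ``q`` of the mean of ``D[f,j,k]``
      over ``k`` in class ``q`` — including ``k = j`` itself when ``j``
      belongs to ``q``, since sample ``j`` keeps sitting at its own value;
    * ``s = (b - a) / max(a, b)``, 0 where both vanish.
    """
    _require_eligible(batch)
    Z, y = batch.Z, batch.y
    N, F = Z.shape
    classes, counts = np.unique(y, return_counts=True)
    K = len(classes)
    D = pairwise_abs_distance(batch)  # (F, N, N)

    onehot = (y[:, None] == classes[None, :]).astype(float)  # (N, K)
    # class_sums[f, j, q] = sum_{k in C_q} D[f, j, k]
    class_sums = D @ onehot  # (F, N, K)
    class_means = class_sums / counts[None, None, :]

    ci = np.searchsorted(classes, y)  # class index per sample
    # a[i, f, j]: drop sample i's own distance from its class sum
    own_sums = class_sums[:, :, ci]  # (F, N_j, N_i)
    a = (own_sums - D) / (counts[ci] - 1)[None, None, :]  # (F, j, i)
    a = np.ascontiguousarray(np.transpose(a, (2, 0, 1)))  # (i, f, j)

    # b[i, f, j]: min over classes other than y_i of class_means[f, j, q]
    masked = np.where(
        (np.arange(K)[None, :] == ci[:, None])[:, None, None, :],
        np.inf,
        class_means[None, :, :, :],
    )  # (i, f, j, q)
    b = masked.min(axis=3)

    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    return SilhouetteTensor(s=s, a=a, b=b)


def _argmax_with_ties(s_if: np.ndarray, Z: np.ndarray, i: int, f: int,
                      candidates: np.ndarray) -> float:
    """Tie-aware argmax over candidate positions for one (sample, feature).

    Candidates within ``TIE_ATOL`` of the best score are tied; among them the
    value closest to the sample's current value wins, then the lowest index.
    """
    smax = s_if[candidates].max()
    tied = candidates[s_if[candidates] >= smax - TIE_ATOL]
    dist = np.abs(Z[tied, f] - Z[i, f])
    best = tied[dist == dist.min()]
    return float(Z[best.min(), f])


def opt_pos_sil(batch: FeatureBatch) -> np.ndarray:
    """Silhouette-maximizing target positions ``t (N x F)``.

    ``t[i, f]`` is the batch value of feature ``f`` whose relocation
    silhouette for sample ``i`` is maximal.  The sample's own value is always
    a candidate, so the selected score never falls below the current one.
    """
    _require_eligible(batch)
    sil = relocated_silhouette(batch)
    return _select_targets(sil.s, batch)


def _select_targets(s: np.ndarray, batch: FeatureBatch,
                    candidate_mask: np.ndarray | None = None) -> np.ndarray:
    """Vectorized tie-aware selection of the argmax candidate value.

    ``candidate_mask (N x F x N)``, when given, restricts the candidate set
    per (sample, feature); the sample itself must be included by the caller.
    """
    Z = batch.Z
    N, F = Z.shape
    if candidate_mask is None:
        s_eff = s
    else:
        s_eff = np.where(candidate_mask, s, -np.inf)
    smax = s_eff.max(axis=2, keepdims=True)  # (N, F, 1)
    tied = s_eff >= smax - TIE_ATOL  # (N, F, j)
    # among tied candidates prefer the value closest to the current one
    value_dist = np.abs(Z.T[None, :, :] - Z[:, :, None])  # (i, f, j)
    value_dist = np.where(tied, value_dist, np.inf)
    dmin = value_dist.min(axis=2, keepdims=True)
    closest = value_dist <= dmin  # exact: |.| values of equal floats coincide
    jstar = np.argmax(closest, axis=2)  # first (lowest index) winner
    return Z[jstar, np.arange(F)[None, :]]


def opt_pos_brute(batch: FeatureBatch) -> np.ndarray:
    """Brute-force target-position search (independent oracle).

    For every (sample, feature, candidate) this literally copies the feature
    column, overwrites the sample's entry with the candidate value, and
    recomputes that sample's silhouette from the definitions.  Intended for
    small batches; must agree elementwise with :func:`opt_pos_sil`.
    """
    _require_eligible(batch)
    Z, y = batch.Z, batch.y
    N, F = Z.shape
    classes = np.unique(y)
    t = np.empty((N, F))
    s_all = np.empty((N, F, N))
    for f in range(F):
        col = Z[:, f]
        for i in range(N):
            for j in range(N):
                moved = col.copy()
                moved[i] = col[j]
                d = np.abs(moved[i] - moved)
                own = (y == y[i]) & (np.arange(N) != i)
                a = d[own].mean()
                b = min(d[y == q].mean() for q in classes if q != y[i])
                m = max(a, b)
                s_all[i, f, j] = (b - a) / m if m > 0 else 0.0
            t[i, f] = _argmax_with_ties(s_all[i, f], Z, i, f, np.arange(N))
    return t


def opt_pos_sil_subsampled(batch: FeatureBatch, m: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Approximate target search over a per-class candidate subsample.

    For each feature, ``min(m, class size)`` candidate indices are drawn
    without replacement from every class; each sample's own position is
    always added to its candidate set.  With ``m`` at least the largest
    class size the result equals :func:`opt_pos_sil` exactly.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    _require_eligible(batch)
    Z, y = batch.Z, batch.y
    N, F = Z.shape
    classes, counts = np.unique(y, return_counts=True)
    if m >= counts.max():
        return opt_pos_sil(batch)
    sil = relocated_silhouette(batch)
    mask = np.zeros((N, F, N), dtype=bool)
    for f in range(F):
        chosen: list[np.ndarray] = []
        for q, c in zip(classes, counts):
            idx = np.flatnonzero(y == q)
            chosen.append(rng.choice(idx, size=min(m, c), replace=False))
        cols = np.concatenate(chosen)
        mask[:, f, cols] = True
    mask[np.arange(N), :, np.arange(N)] = True  # own position always in
    return _select_targets(sil.s, batch, candidate_mask=mask)


def rand_pos(batch: FeatureBatch, rng: np.random.Generator) -> np.ndarray:
    """Random-target ablation: uniform draws within each feature's batch range."""
    Z = batch.Z
    lo = Z.min(axis=0)
    hi = Z.max(axis=0)
    return rng.uniform(lo, hi, size=Z.shape)


def topk_feature_mask(batch: FeatureBatch, k: int) -> np.ndarray:
    """Indices of the k features with highest mean current silhouette.

    The per-feature statistic is the mean over samples of the 1-D silhouette
    at the current (un-relocated) positions; ties resolve to the lowest
    feature index.  Returned sorted ascending.
    """
    _require_eligible(batch)
    F = batch.n_features
    if not 1 <= k <= F:
        raise ValueError(f"k must be in [1, {F}], got {k}")
    means = np.array(
        [silhouette_1d(batch.Z[:, f], batch.y).mean() for f in range(F)]
    )
    # stable sort on negated scores -> ties keep ascending feature order
    order = np.argsort(-means, kind="stable")
    return np.sort(order[:k])


def export_feature_silhouettes(batch: FeatureBatch, path) -> None:
    """Write per-feature mean silhouettes as delimited text (index, mean)."""
    means = [silhouette_1d(batch.Z[:, f], batch.y).mean()
             for f in range(batch.n_features)]
    with open(path, "w") as fh:
        fh.write("feature\tmean_silhouette\n")
        for f, v in enumerate(means):
            fh.write(f"{f}\t{v:.10g}\n")
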