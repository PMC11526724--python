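"""Homogeneous ensemble feature selection with Relief as the base learner.

A single filter run can latch onto peculiarities of one training sample.  The
ensemble scheme implemented here draws ``M`` bootstrap subsets of the training
rows, computes a ReliefF importance vector v^(j) on each, and fuses the M
vectors by vote-based rank aggregation: each base learner votes for its
``top_t`` features, features are ranked by descending vote count (ties broken
by ascending mean within-learner rank, then lexicographically), and the top
``k_final`` names are selected.

ReliefF rewards features whose values agree with nearest same-class neighbours
(hits) and differ from nearest other-class neighbours (misses): for each
anchor instance the weight of feature f is increased by the mean |difference|
to the k nearest misses and decreased by the mean |difference| to the k
nearest hits, on features min-max scaled to [0, 1].  All instances serve as
anchors, so the weights are deterministic given the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError


@dataclass(frozen=True)
class BootstrapConfig:
    """Ensemble resampling parameters.

    ``n_boot=None`` uses the training-set size.  ``stratified`` draws each
    bootstrap subset within class (preserving class counts); plain uniform
    resampling is available by switching it off.
    """

    M: int = 100
    n_boot: int | None = None
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.M < 1:
            raise ValidationError("M: must be >= 1")
        if self.n_boot is not None and self.n_boot < 2:
            raise ValidationError("n_boot: must be >= 2")


@dataclass
class ImportanceMatrix:
    """Per-bootstrap Relief importance vectors, rows j = v^(j)."""

    weights: np.ndarray  # (M, D)
    feature_names: list[str]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValidationError("weights: expected an (M, D) matrix")
        if self.weights.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names: length must equal weight columns")
        if not np.isfinite(self.weights).all():
            raise ValidationError("weights: must be finite")


@dataclass
class AggregatedRanking:
    """Vote-fused ranking: per-feature vote counts, final order, selection."""

    feature_names: list[str]
    votes: np.ndarray          # integer votes in [0, M], aligned to feature_names
    mean_ranks: np.ndarray     # mean within-learner rank, aligned to feature_names
    ranking: list[str]         # all features, best first
    selected: list[str] = field(default_factory=list)


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    scaled = np.zeros_like(X, dtype=float)
    nz = rng > 0
    scaled[:, nz] = (X[:, nz] - lo[nz]) / rng[nz]
    return scaled


def relief_weights(X, y, k_neighbors: int = 10, seed: int | None = None) -> np.ndarray:
    """ReliefF feature weights, one per column of ``X``.

    Every instance is used as an anchor; distances are Manhattan on features
    min-max scaled to [0, 1].  ``seed`` is accepted for interface uniformity
    but the computation is deterministic (no instance subsampling).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, D = X.shape
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("y: Relief requires both classes present")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValidationError("y: each class needs >= 2 samples")

    Xs = _minmax_scale(X)
    dist = cdist(Xs, Xs, metric="cityblock")
    np.fill_diagonal(dist, np.inf)

    W = np.zeros(D)
    for anchor in range(n):
        same = y == y[anchor]
        hit_idx = np.flatnonzero(same)
        hit_idx = hit_idx[hit_idx != anchor]
        miss_idx = np.flatnonzero(~same)
        k_h = min(k_neighbors, len(hit_idx))
        k_m = min(k_neighbors, len(miss_idx))
        hits = hit_idx[np.argsort(dist[anchor, hit_idx], kind="stable")[:k_h]]
        misses = miss_idx[np.argsort(dist[anchor, miss_idx], kind="stable")[:k_m]]
        W += np.abs(Xs[misses] - Xs[anchor]).mean(axis=0)
        W -= np.abs(Xs[hits] - Xs[anchor]).mean(axis=0)
    return W / n


def bootstrap_subsets(n: int, config: BootstrapConfig, y=None) -> list[np.ndarray]:
    """M index multisets of size n_boot, i.i.d. uniform with replacement.

    With ``config.stratified`` and labels ``y`` given, indices are drawn
    within class, preserving the class counts of the original sample.
    """
    if n < 2:
        raise ValidationError("n: must be >= 2")
    rng = np.random.default_rng(config.seed)
    size = config.n_boot if config.n_boot is not None else n
    subsets = []
    for _ in range(config.M):
        if config.stratified and y is not None:
            y = np.asarray(y)
            parts = []
            for c in np.unique(y):
                idx = np.flatnonzero(y == c)
                n_c = max(1, round(size * len(idx) / n))
                parts.append(rng.choice(idx, size=n_c, replace=True))
            subsets.append(np.concatenate(parts))
        else:
            subsets.append(rng.integers(0, n, size=size))
    return subsets


def aggregate_votes(importance: ImportanceMatrix, top_t: int) -> AggregatedRanking:
    """Fuse importance vectors by voting.

    Each base learner votes for its ``top_t`` features by weight (within-learner
    ties broken by column order).  Features are ranked by descending votes,
    then ascending mean within-learner rank, then name.
    """
    Wm = importance.weights
    M, D = Wm.shape
    if not 1 <= top_t <= D:
        raise ValidationError("top_t: must lie in [1, D]")
    names = importance.feature_names

    # within-learner ranks (0 = best); stable sort -> column-order tie-break
    order = np.argsort(-Wm, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(M)[:, None]
    ranks[rows, order] = np.arange(D)[None, :]

    votes = (ranks < top_t).sum(axis=0)
    mean_ranks = ranks.mean(axis=0)

    final = sorted(range(D), key=lambda f: (-votes[f], mean_ranks[f], names[f]))
    return AggregatedRanking(
        feature_names=list(names),
        votes=votes.astype(int),
        mean_ranks=mean_ranks,
        ranking=[names[f] for f in final],
    )


def ensemble_select(X, y, config: BootstrapConfig | None = None,
                    top_t: int | None = None, k_final: int = 35,
                    k_neighbors: int = 10,
                    feature_names: list[str] | None = None
                    ) -> tuple[list[str], AggregatedRanking]:
    """Relief on M bootstrap subsets, vote aggregation, top-``k_final`` names.

    ``top_t`` defaults to ceil(0.25 * D).  ``k_final=35`` matches the scale
    used for image-feature tables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, D = X.shape
    config = config or BootstrapConfig()
    if k_final > D:
        raise ValidationError("k_final: must be <= number of features")
    if top_t is None:
        top_t = math.ceil(0.25 * D)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(D)]

    subsets = bootstrap_subsets(n, config, y=y)
    rows = []
    for idx in subsets:
        rows.append(relief_weights(X[idx], y[idx], k_neighbors=k_neighbors))
    importance = ImportanceMatrix(np.vstack(rows), list(feature_names))
    ranking = aggregate_votes(importance, top_t)
    ranking.selected = ranking.ranking[:k_final]
    return ranking.selected, ranking
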