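"""Mutual-information relevance and JMIM redundancy-aware feature ranking.

Relevance of each continuous feature to the 6 discrete severity classes is
estimated with the k-nearest-neighbor estimator for mixed continuous/discrete
variables (neighbor distances within the same class, Chebyshev metric),
reported in nats.  Joint MI of a feature pair with the classes uses the same
estimator over the 2-D max-norm distance, which makes marginal and joint
estimates directly comparable.

JMIM (joint mutual information maximization) first picks the feature with
maximal marginal MI and then greedily adds the candidate whose *minimum*
joint MI with any already-selected feature is maximal — rewarding relevance
while penalizing redundancy.  Ties break by input order.

Percentile features contain many exactly tied values, which break kNN
distance ranks; a tiny seeded jitter (default 1e-10 of each dimension's
range) is added before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

DEFAULT_K_NEIGHBORS = 6
_JITTER_SCALE = 1e-10


class EstimationError(ValueError):
    """MI estimation impossible (e.g. a class with too few samples)."""


@dataclass(frozen=True)
class MIResult:
    feature_name: str
    mi: float  # nats, clipped at 0
    k_neighbors: int


@dataclass(frozen=True)
class JmimRanking:
    """Greedy JMIM selection order with the criterion value at each step.

    The first score is the winning marginal MI; subsequent scores are the
    winning min-joint-MI criterion values."""

    order: tuple[str, ...]
    scores: tuple[float, ...]


def _prepare(x: np.ndarray, y: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("feature values and class labels must have equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature values must be finite")
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < k + 1]
    if thin.size:
        raise EstimationError(
            f"class {thin[0]!r} has fewer than k+1={k + 1} samples"
        )
    rng = np.random.default_rng(seed)
    span = np.ptp(x, axis=0)
    span[span == 0] = 1.0
    x = x + rng.normal(0.0, _JITTER_SCALE, size=x.shape) * span
    return x, y


def _knn_mi_nats(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """kNN MI between continuous x (n, d) and discrete y, in nats.

    For each sample, the radius is the Chebyshev distance to its k-th nearest
    neighbor within the same class; m counts all samples (any class) strictly
    inside that radius, including the point itself."""
    n = x.shape[0]
    full_tree = cKDTree(x)
    radius = np.empty(n)
    label_count = np.empty(n)
    for cls in np.unique(y):
        mask = y == cls
        pts = x[mask]
        tree = cKDTree(pts)
        # k+1 because the query point is its own nearest neighbor
        dist, _ = tree.query(pts, k=k + 1, p=np.inf)
        radius[mask] = dist[:, -1]
        label_count[mask] = pts.shape[0]
    shrunk = np.nextafter(radius, 0)
    m = np.array(
        [
            len(full_tree.query_ball_point(x[i], shrunk[i], p=np.inf))
            for i in range(n)
        ],
        dtype=float,
    )
    mi = (
        digamma(n)
        + digamma(k)
        - np.mean(digamma(label_count))
        - np.mean(digamma(m))
    )
    return max(0.0, float(mi))


def mi_continuous_discrete(
    feature_values: np.ndarray,
    class_labels: np.ndarray,
    k: int = DEFAULT_K_NEIGHBORS,
    feature_name: str = "feature",
    seed: int = 0,
) -> MIResult:
    """MI (nats) between one continuous feature and the discrete class labels."""
    x, y = _prepare(feature_values, class_labels, k, seed)
    return MIResult(feature_name, _knn_mi_nats(x, y, k), k)


def joint_mi(
    feature_pair: np.ndarray,
    class_labels: np.ndarray,
    k: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> float:
    """MI (nats) between a 2-D continuous feature and the class labels,
    with max-norm neighbor distances."""
    pair = np.asarray(feature_pair, dtype=float)
    if pair.ndim != 2 or pair.shape[1] != 2:
        raise ValueError("feature_pair must have shape (n, 2)")
    x, y = _prepare(pair, class_labels, k, seed)
    return _knn_mi_nats(x, y, k)


def jmim_rank(
    candidate_features: dict[str, np.ndarray],
    class_labels: np.ndarray,
    k: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> JmimRanking:
    """Greedy JMIM ordering of the candidate features.

    Deterministic given the data: ties break by the input (insertion) order
    of ``candidate_features``.
    """
    names = list(candidate_features)
    if len(names) < 2:
        raise ValueError("need at least two candidate features")
    marginal = {
        name: mi_continuous_discrete(
            candidate_features[name], class_labels, k, name, seed
        ).mi
        for name in names
    }
    first = max(names, key=lambda nm: (marginal[nm], -names.index(nm)))
    order = [first]
    scores = [marginal[first]]
    remaining = [nm for nm in names if nm != first]
    joint_cache: dict[tuple[str, str], float] = {}

    def jmi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in joint_cache:
            pair = np.column_stack(
                [candidate_features[key[0]], candidate_features[key[1]]]
            )
            joint_cache[key] = joint_mi(pair, class_labels, k, seed)
        return joint_cache[key]

    while remaining:
        crit = {
            cand: min(jmi(cand, sel) for sel in order) for cand in remaining
        }
        best = max(remaining, key=lambda nm: (crit[nm], -remaining.index(nm)))
        order.append(best)
        scores.append(crit[best])
        remaining.remove(best)
    return JmimRanking(tuple(order), tuple(scores))
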