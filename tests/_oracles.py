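"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — explicit sorts, O(n^2) pair counts,
direct curve enumeration, quadrature — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def weighted_percentile_oracle(values, weights, q: float) -> float:
    """Smallest value whose normalized cumulative weight (ascending sort)
    reaches q/100; NaN values carry no weight; empty -> NaN."""
    vals = np.asarray(values, dtype=float)
    wts = np.asarray(weights, dtype=float).copy()
    wts[np.isnan(vals)] = 0.0
    pairs = sorted(
        (v, w) for v, w in zip(vals, wts) if not np.isnan(v) and w > 0
    )
    total = sum(w for _, w in pairs)
    if total == 0:
        return float("nan")
    target = (q / 100.0) * total - 1e-9 * total
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc >= target:
            return float(v)
    return float(pairs[-1][0])


def moving_percentile_oracle(series, window: int, q: float, weights=None) -> np.ndarray:
    """Per-position recomputation of the (weighted) moving percentile."""
    series = np.asarray(series, dtype=float)
    if weights is None:
        weights = np.ones(window)
    half = window // 2
    out = np.empty(series.size)
    for i in range(series.size):
        vals, wts = [], []
        for j in range(-half, half + 1):
            if 0 <= i + j < series.size:
                vals.append(series[i + j])
                wts.append(weights[j + half])
        out[i] = weighted_percentile_oracle(vals, wts, q)
    return out


def roc_auc_pairs_oracle(scores, labels) -> float:
    """Pairwise concordance probability, ties counted one-half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_oracle(scores, labels) -> float:
    """Step-wise precision-recall integration over descending unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    ap = 0.0
    prev_recall = 0.0
    for threshold in sorted(set(scores), reverse=True):
        predicted = scores >= threshold
        tp = int((predicted & (labels == 1)).sum())
        precision = tp / int(predicted.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def pr_auc_oracle(scores, labels) -> float:
    """Class-averaged PR AUC: mean AP of (class 1, scores) and
    (class 0, negated scores)."""
    labels = np.asarray(labels, dtype=int)
    return 0.5 * (
        average_precision_oracle(scores, labels)
        + average_precision_oracle(-np.asarray(scores, dtype=float), 1 - labels)
    )


def discrete_mi_plugin_oracle(x, y, n_bins: int = 200) -> float:
    """Plug-in MI (nats) after fine binning of the continuous variable."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    x_bins = np.digitize(x, np.linspace(x.min(), x.max(), n_bins))
    classes = np.unique(y)
    n = x.size
    mi = 0.0
    for xb in np.unique(x_bins):
        px = (x_bins == xb).sum() / n
        for c in classes:
            joint = ((x_bins == xb) & (y == c)).sum() / n
            if joint > 0:
                py = (y == c).sum() / n
                mi += joint * np.log(joint / (px * py))
    return mi


def gaussian_location_mi_oracle(delta: float) -> float:
    """Analytic MI (nats) of a balanced 2-class Gaussian location model:
    X | Y=y ~ N(+-delta/2, 1).  MI = H(X) - H(X|Y) with H(X) by quadrature."""

    def mixture_pdf(x):
        return 0.5 * (norm.pdf(x, -delta / 2.0, 1.0) + norm.pdf(x, delta / 2.0, 1.0))

    def integrand(x):
        f = mixture_pdf(x)
        return -f * np.log(f) if f > 0 else 0.0

    h_x, _ = quad(integrand, -12 - delta, 12 + delta, limit=200)
    h_x_given_y = 0.5 * np.log(2.0 * np.pi * np.e)
    return h_x - h_x_given_y
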