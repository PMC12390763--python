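"""Evaluation suite: RMSE, clustering agreement (ARI, purity) and
per-spot distributional agreement (Jensen-Shannon divergence, Pearson).

RMSE is taken over all spot x type entries.  For ARI/purity the predicted
proportions are k-means-clustered into as many clusters as cell types and
compared against reference layer labels via the contingency table; ARI is
evaluated directly from the pair-counting formula, purity as the mean
majority fraction.  JS divergence uses the natural logarithm (so its
maximum is ln 2); a base-2 variant is available.  Per-spot metrics are
averaged over spatial locations, with zero-variance Pearson rows excluded
and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from sklearn.cluster import KMeans

from .io_formats import ProportionMatrix, ValidationError

__all__ = [
    "ClusteringComparison",
    "rmse",
    "cluster_proportions",
    "adjusted_rand_index",
    "purity",
    "js_divergence",
    "pearson",
    "evaluate_dataset",
]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, ProportionMatrix) else np.asarray(x, dtype=np.float64)


def rmse(pred, truth) -> float:
    """Root mean squared difference over all spot x type entries."""
    p, q = _values(pred), _values(truth)
    if p.shape != q.shape:
        raise ValidationError("rmse requires matching shapes")
    return float(np.sqrt(np.mean((p - q) ** 2)))


def cluster_proportions(pred, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels of proportion rows (k = number of cell types)."""
    p = _values(pred)
    if k < 1:
        raise ValidationError("k must be at least 1")
    if k > p.shape[0]:
        raise ValidationError("more clusters than spots")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
    return km.fit_predict(p)


@dataclass
class ClusteringComparison:
    """Contingency table between a true labelling and a clustering."""

    true_labels: np.ndarray
    pred_labels: np.ndarray
    contingency: np.ndarray
    n: int

    @classmethod
    def from_labels(cls, true_labels, pred_labels) -> "ClusteringComparison":
        t = np.asarray(true_labels)
        p = np.asarray(pred_labels)
        if t.shape != p.shape or t.ndim != 1:
            raise ValidationError("labelings must be 1-D and cover the same spots")
        _, ti = np.unique(t, return_inverse=True)
        _, pi = np.unique(p, return_inverse=True)
        table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
        np.add.at(table, (ti, pi), 1)
        return cls(t, p, table, t.size)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(cmp: ClusteringComparison) -> float:
    """Chance-corrected partition agreement from the contingency table."""
    if cmp.n < 2:
        raise ValidationError("ARI needs at least 2 samples")
    nij = cmp.contingency
    a = nij.sum(axis=1)
    b = nij.sum(axis=0)
    index = _comb2(nij).sum()
    expected = _comb2(a).sum() * _comb2(b).sum() / _comb2(np.array(cmp.n))
    max_index = 0.5 * (_comb2(a).sum() + _comb2(b).sum())
    if max_index == expected:  # both partitions trivial -> perfect by convention
        return 1.0
    return float((index - expected) / (max_index - expected))


def purity(cmp: ClusteringComparison) -> float:
    """Mean over spots of the majority-class fraction of their cluster."""
    if cmp.n == 0:
        raise ValidationError("purity needs at least 1 sample")
    return float(cmp.contingency.max(axis=0).sum() / cmp.n)


def js_divergence(p, q, base2: bool = False) -> float:
    """Jensen-Shannon divergence between two proportion vectors.

    Natural log by default (maximum ln 2); base2=True rescales to [0, 1].
    Vectors are renormalized, with a warning when a sum is off by more
    than 1e-6.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 1:
        raise ValidationError("js_divergence requires equal-length vectors")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("negative entries in proportion vector")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-6:
            warnings.warn("proportion vector renormalized for JS divergence", stacklevel=2)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    js = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    js = float(max(js, 0.0))
    return js / np.log(2.0) if base2 else js


def pearson(p, q) -> float:
    """Pearson correlation; NaN when either vector has zero variance."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.size < 2:
        raise ValidationError("pearson requires equal-length vectors of length >= 2")
    sp = p - p.mean()
    sq = q - q.mean()
    denom = np.sqrt((sp**2).sum() * (sq**2).sum())
    if denom == 0:
        return float("nan")
    return float((sp * sq).sum() / denom)


def evaluate_dataset(
    pred: ProportionMatrix,
    truth: ProportionMatrix,
    true_layer_labels=None,
    seed: int = 0,
) -> dict:
    """One-row metrics report.

    Always: global RMSE, mean per-spot JS, mean per-spot Pearson (with a
    count of zero-variance rows excluded).  With layer labels: k-means
    clustering of the predictions into k = n cell types, then ARI and
    purity against the labels.
    """
    p, q = _values(pred), _values(truth)
    if p.shape != q.shape:
        raise ValidationError("prediction and truth must align")
    js_vals = [js_divergence(pi, qi) for pi, qi in zip(p, q)]
    pr_vals = np.array([pearson(pi, qi) for pi, qi in zip(p, q)])
    defined = np.isfinite(pr_vals)
    report = {
        "rmse": rmse(p, q),
        "mean_js": float(np.mean(js_vals)),
        "mean_pearson": float(pr_vals[defined].mean()) if defined.any() else float("nan"),
        "n_pearson_excluded": int((~defined).sum()),
    }
    if true_layer_labels is not None:
        labels = cluster_proportions(p, k=p.shape[1], seed=seed)
        cmp = ClusteringComparison.from_labels(np.asarray(true_layer_labels), labels)
        report["ari"] = adjusted_rand_index(cmp)
        report["purity"] = purity(cmp)
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    return pd.DataFrame([report])
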