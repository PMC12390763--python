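"""Training objectives and diagnostics.

* dynamic contrastive loss over spatial positive/negative zones: for an
  anchor i, the positive term averages -log softmax(-d_ij) over j in P_i
  (softmax normalized within P_i), the negative term the same with +d_ij
  over N_i; the total is the mean over anchors of the two terms.
* squared maximum mean discrepancy with a Gaussian kernel
  k(x, y) = exp(-||x-y||^2 / (2 sigma^2)), sigma = 1.0 by default, as the
  biased V-statistic with diagonal terms included (an unbiased U-statistic
  variant is available behind a flag).
* mean absolute (L1) proportion loss and binary cross-entropy for the
  domain classifier.

Every function accepts either plain numpy arrays (returning a float) or
autodiff Tensors (returning a Tensor), so the same code path is used for
evaluation and for gradient-based training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, logsumexp
from .contrastive_zones import ZoneIndex
from .io_formats import ProportionMatrix, ValidationError

__all__ = [
    "MMDConfig",
    "contrastive_loss",
    "gaussian_kernel",
    "mmd2",
    "l1_proportion_loss",
    "domain_bce",
]

_DIST_EPS = 1e-12  # keeps sqrt differentiable when embeddings coincide
_BCE_CLAMP = 1e-7


@dataclass(frozen=True)
class MMDConfig:
    """Gaussian kernel bandwidth for the MMD diagnostic/loss."""

    sigma: float = 1.0
    unbiased: bool = False

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


def _as_tensor(x) -> tuple[Tensor, bool]:
    """Lift input to a Tensor; second element says whether to return a float."""
    if isinstance(x, Tensor):
        return x, False
    if isinstance(x, ProportionMatrix):
        return Tensor(x.values), True
    return Tensor(np.asarray(x, dtype=np.float64)), True


def contrastive_loss(E, zones: ZoneIndex, anchor_subset=None):
    """Mean over anchors of positive-pull and negative-push softmax terms.

    An anchor with an empty positive (negative) set contributes 0 for that
    term; a singleton set also yields exactly 0 (the softmax over one
    element is 1).  Distances are Euclidean between embedding rows.
    """
    E_t, plain = _as_tensor(E)
    if not np.all(np.isfinite(E_t.data)):
        raise ValidationError("non-finite embedding entries")
    anchors = range(zones.n_spots) if anchor_subset is None else anchor_subset
    anchors = list(anchors)
    if not anchors:
        return 0.0 if plain else Tensor(0.0)
    total = Tensor(0.0)
    for i in anchors:
        if not (0 <= i < zones.n_spots):
            raise ValidationError(f"anchor index {i} out of range")
        for partners, sign in ((zones.positives[i], -1.0), (zones.negatives[i], 1.0)):
            if len(partners) == 0:
                continue
            diffs = E_t.take([i] * len(partners)) - E_t.take(partners)
            d = ((diffs * diffs).sum(axis=1) + _DIST_EPS) ** 0.5
            logits = d * sign
            log_probs = logits - logsumexp(logits)
            total = total - log_probs.mean()
    loss = total / len(anchors)
    return loss.item() if plain else loss


def gaussian_kernel(x, y, sigma: float = 1.0):
    """exp(-||x - y||^2 / (2 sigma^2)) between two vectors."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    x_t, px = _as_tensor(x)
    y_t, py = _as_tensor(y)
    if x_t.data.shape != y_t.data.shape:
        raise ValidationError("gaussian_kernel requires equal dimensions")
    diff = x_t - y_t
    k = (-(diff * diff).sum() / (2.0 * sigma**2)).exp()
    return k.item() if (px and py) else k


def _pairwise_sq_dists(A: Tensor, B: Tensor) -> Tensor:
    sa = (A * A).sum(axis=1, keepdims=True)          # n x 1
    sb = (B * B).sum(axis=1, keepdims=True).T        # 1 x m
    return sa + sb - 2.0 * (A @ B.T)


def mmd2(X, Y, cfg: MMDConfig | None = None):
    """Squared MMD between two samples under the Gaussian kernel.

    Biased V-statistic by default (diagonals included):
    mean k(x,x') + mean k(y,y') - 2 mean k(x,y).  With cfg.unbiased the
    within-sample diagonals are excluded (requires n, m >= 2).
    """
    cfg = cfg or MMDConfig()
    X_t, px = _as_tensor(X)
    Y_t, py = _as_tensor(Y)
    if X_t.data.ndim != 2 or Y_t.data.ndim != 2 or X_t.data.shape[1] != Y_t.data.shape[1]:
        raise ValidationError("mmd2 requires n x d and m x d inputs with matching d")
    n, m = X_t.data.shape[0], Y_t.data.shape[0]
    if n < 1 or m < 1:
        raise ValidationError("mmd2 requires at least one sample per side")
    denom = 2.0 * cfg.sigma**2
    k_xx = (-_pairwise_sq_dists(X_t, X_t) / denom).exp()
    k_yy = (-_pairwise_sq_dists(Y_t, Y_t) / denom).exp()
    k_xy = (-_pairwise_sq_dists(X_t, Y_t) / denom).exp()
    if cfg.unbiased:
        if n < 2 or m < 2:
            raise ValidationError("unbiased mmd2 requires n, m >= 2")
        off_xx = (k_xx.sum() - n) / (n * (n - 1))  # diagonal of k_xx is exactly 1
        off_yy = (k_yy.sum() - m) / (m * (m - 1))
        val = off_xx + off_yy - 2.0 * k_xy.mean()
    else:
        val = k_xx.mean() + k_yy.mean() - 2.0 * k_xy.mean()
    return val.item() if (px and py) else val


def l1_proportion_loss(pred, truth):
    """Mean absolute difference over all spot x type entries."""
    p_t, pp = _as_tensor(pred)
    q_t, pq = _as_tensor(truth)
    if p_t.data.shape != q_t.data.shape:
        raise ValidationError("l1_proportion_loss requires matching shapes")
    loss = (p_t - q_t).abs().mean()
    return loss.item() if (pp and pq) else loss


def domain_bce(p, labels):
    """Mean binary cross-entropy of predicted domain probabilities.

    Probabilities at exactly 0 or 1 are clamped to 1e-7 with a warning.
    """
    p_t, pp = _as_tensor(p)
    y = np.asarray(labels, dtype=np.float64)
    if p_t.data.shape != y.shape:
        raise ValidationError("domain_bce requires matching shapes")
    if np.any((p_t.data <= 0.0) | (p_t.data >= 1.0)):
        warnings.warn("domain probabilities at 0/1 clamped to 1e-7", stacklevel=2)
    q = p_t.clamp(_BCE_CLAMP, 1.0 - _BCE_CLAMP)
    loss = -(y * q.log() + (1.0 - y) * (1.0 - q).log()).mean()
    return loss.item() if pp else loss
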