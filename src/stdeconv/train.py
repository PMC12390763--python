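"""Alternating adversarial training and k-fold cross-validation.

One round = Phase A then Phase B.  Phase A updates encoder + predictor
jointly with Adam on

    lambda_cl * contrastive + lambda_l1 * L1(proportions)
    + lambda_adv * BCE(domain, flipped labels)  [classifier frozen]
    + lambda_mmd * MMD^2(sim emb, real emb),

where flipping the domain labels inside the encoder step is the
alternating-phase equivalent of a gradient-reversal layer.  Phase B (only
with the domain-adversarial switch on) updates the classifier alone on
BCE with true domain labels, using eval-mode (frozen) encoder features.
The squared MMD between batch embeddings is always logged as a domain-
alignment diagnostic, whether or not it enters the gradient.

Real-domain spots carry no proportion labels; they enter Phase A batches
1:1 with simulated spots for the adversarial and MMD terms only.  10% of
simulated spots are held out for per-round validation RMSE.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, cat
from .contrastive_zones import ZoneIndex, build_zones, suggest_zone_config
from .io_formats import ProportionMatrix, SpotDataset, ValidationError
from .losses import MMDConfig, contrastive_loss, domain_bce, l1_proportion_loss, mmd2
from .metrics import js_divergence, pearson, rmse
from .model import (
    CLASSIFIER_KEYS,
    ENCODER_KEYS,
    PREDICTOR_KEYS,
    ModelState,
    NetworkSpec,
    classify_domain,
    encoder_forward,
    init_model_state,
    predict_proportions,
)
from .preprocess import build_model_input

__all__ = ["TrainConfig", "Adam", "run_training", "run_cross_validation", "uniform_baseline_rmse"]


@dataclass
class TrainConfig:
    """Optimization schedule and loss weights."""

    learning_rate: float = 0.0003
    batch_size: int = 32
    rounds: int = 50
    epochs_per_phase: int = 1
    lambda_cl: float = 0.1
    lambda_l1: float = 1.0
    lambda_adv: float = 0.1
    lambda_mmd: float = 0.0
    mmd_sigma: float = 1.0
    use_dann: bool = True
    seed: int = 0
    folds: int = 5
    val_fraction: float = 0.1
    normalize_expr: bool = True
    coord_mode: str = "minmax"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size < 1 or self.rounds < 1 or self.epochs_per_phase < 1:
            raise ValidationError("batch_size, rounds, epochs_per_phase must be >= 1")
        for lam in (self.lambda_cl, self.lambda_l1, self.lambda_adv, self.lambda_mmd):
            if lam < 0:
                raise ValidationError("loss weights must be non-negative")
        if self.folds < 1:
            raise ValidationError("folds must be positive")


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def uniform_baseline_rmse(truth: ProportionMatrix) -> float:
    """RMSE of the constant uniform (1/K per type) predictor."""
    k = truth.values.shape[1]
    return rmse(np.full_like(truth.values, 1.0 / k), truth.values)


def _param_digest(state: ModelState, keys) -> str:
    h = hashlib.sha256()
    for k in keys:
        h.update(np.ascontiguousarray(state.params[k].data).tobytes())
    return h.hexdigest()


def run_training(
    sim: SpotDataset,
    sim_props: ProportionMatrix,
    real: SpotDataset | None = None,
    zones: ZoneIndex | None = None,
    spec: NetworkSpec | None = None,
    cfg: TrainConfig | None = None,
    init_state: ModelState | None = None,
) -> tuple[ModelState, pd.DataFrame]:
    """Train on labelled pseudo-spots (optionally against a real domain).

    Returns the final model state and the per-(round, phase) training
    history including validation RMSE.  Deterministic given cfg.seed.
    """
    cfg = cfg or TrainConfig()
    if sim.n_spots != sim_props.n_spots:
        raise ValidationError("simulated spots and labels must align")
    if cfg.use_dann and real is None:
        raise ValidationError(
            "domain-adversarial training needs a real dataset; pass use_dann=False (--no-dann)"
        )
    rng = np.random.default_rng(cfg.seed)
    X_sim = build_model_input(sim, cfg.normalize_expr, cfg.coord_mode)
    X_real = build_model_input(real, cfg.normalize_expr, cfg.coord_mode) if real is not None else None
    n_types = sim_props.values.shape[1]
    if spec is None:
        spec = NetworkSpec(d_input=X_sim.shape[1], n_types=n_types, seed=cfg.seed)
    if spec.d_input != X_sim.shape[1]:
        raise ValidationError("spec.d_input does not match assembled input width")
    if zones is None and cfg.lambda_cl > 0:
        zones = build_zones(sim.coords, suggest_zone_config(sim.coords, "structured"))

    state = init_state.copy() if init_state is not None else init_model_state(spec)
    opt_encpred = Adam(state.parameters(ENCODER_KEYS + PREDICTOR_KEYS), cfg.learning_rate)
    opt_cls = Adam(state.parameters(CLASSIFIER_KEYS), cfg.learning_rate)
    mmd_cfg = MMDConfig(sigma=cfg.mmd_sigma)

    # held-out validation split over simulated spots
    n = sim.n_spots
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    zones_train = zones.restrict(train_idx) if zones is not None else None
    labels_train = sim_props.values[train_idx]
    X_train = X_sim[train_idx]

    history: list[dict] = []
    for rnd in range(1, cfg.rounds + 1):
        # ---- Phase A: encoder + predictor -----------------------------
        cl_sum = l1_sum = adv_sum = mmd_sum = 0.0
        n_batches = 0
        for _ in range(cfg.epochs_per_phase):
            order = rng.permutation(len(train_idx))
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss = Tensor(0.0)
                # supervised L1 on simulated labels
                needed, anchor_pos, batch_zones = _collect_partners(batch, zones_train)
                emb = encoder_forward(Tensor(X_train[needed]), state, "train", rng)
                emb_batch = emb.take(anchor_pos)
                pred = predict_proportions(emb_batch, state, "train", rng)
                l1 = l1_proportion_loss(pred, Tensor(labels_train[batch]))
                loss = loss + cfg.lambda_l1 * l1
                l1_sum += l1.item()
                # contrastive pull/push over precomputed zones
                if cfg.lambda_cl > 0 and batch_zones is not None:
                    cl = contrastive_loss(emb, batch_zones, anchor_pos)
                    loss = loss + cfg.lambda_cl * cl
                    cl_sum += cl.item()
                # adversarial + MMD terms against the real domain
                if X_real is not None and (cfg.lambda_adv > 0 or cfg.lambda_mmd > 0 or cfg.use_dann):
                    rb = rng.choice(X_real.shape[0], size=len(batch), replace=X_real.shape[0] < len(batch))
                    emb_real = encoder_forward(Tensor(X_real[rb]), state, "train", rng)
                    if cfg.lambda_adv > 0 and cfg.use_dann:
                        p_dom = classify_domain(cat([emb_batch, emb_real]), state, "train", rng)
                        flipped = np.concatenate([np.zeros(len(batch)), np.ones(len(rb))])
                        adv = domain_bce(p_dom, flipped)
                        loss = loss + cfg.lambda_adv * adv
                        adv_sum += adv.item()
                    mmd_val = mmd2(emb_batch, emb_real, mmd_cfg)
                    if cfg.lambda_mmd > 0:
                        loss = loss + cfg.lambda_mmd * mmd_val
                    mmd_sum += mmd_val.item()
                opt_encpred.zero_grad()
                opt_cls.zero_grad()
                loss.backward()
                opt_encpred.step()
                n_batches += 1
        val_rmse = _validation_rmse(state, X_sim, sim_props, val_idx)
        history.append(
            {
                "round": rnd,
                "phase": "encoder",
                "cl_loss": cl_sum / max(n_batches, 1),
                "l1_loss": l1_sum / max(n_batches, 1),
                "adv_loss": adv_sum / max(n_batches, 1),
                "mmd_diag": mmd_sum / max(n_batches, 1),
                "classifier_bce": np.nan,
                "val_rmse": val_rmse,
            }
        )
        # ---- Phase B: domain classifier, encoder frozen ----------------
        if cfg.use_dann and X_real is not None:
            bce_sum = 0.0
            nb = 0
            X_all = np.vstack([X_train, X_real])
            y_all = np.concatenate([np.ones(len(X_train)), np.zeros(len(X_real))])
            for _ in range(cfg.epochs_per_phase):
                order = rng.permutation(len(X_all))
                for start in range(0, len(order), cfg.batch_size):
                    batch = order[start : start + cfg.batch_size]
                    emb_frozen = encoder_forward(X_all[batch], state, "eval")  # plain array
                    p_dom = classify_domain(Tensor(emb_frozen), state, "train", rng)
                    bce = domain_bce(p_dom, y_all[batch])
                    opt_cls.zero_grad()
                    bce.backward()
                    opt_cls.step()
                    bce_sum += bce.item()
                    nb += 1
            history.append(
                {
                    "round": rnd,
                    "phase": "classifier",
                    "cl_loss": np.nan,
                    "l1_loss": np.nan,
                    "adv_loss": np.nan,
                    "mmd_diag": np.nan,
                    "classifier_bce": bce_sum / max(nb, 1),
                    "val_rmse": val_rmse,
                }
            )
    hist = pd.DataFrame(history)
    hist.attrs["val_idx"] = val_idx
    hist.attrs["train_idx"] = train_idx
    return state, hist


def _collect_partners(batch: np.ndarray, zones: ZoneIndex | None):
    """Rows to embed for a batch: the batch plus all its zone partners.

    Returns (needed global indices, anchor positions within `needed`, and
    a remapped ZoneIndex over the needed rows; None when zones are off).
    """
    if zones is None:
        return np.asarray(batch), np.arange(len(batch)), None
    partner_sets = [zones.positives[i] for i in batch] + [zones.negatives[i] for i in batch]
    allidx = np.concatenate([np.asarray(batch)] + partner_sets) if partner_sets else np.asarray(batch)
    needed = np.unique(allidx)
    pos_of = {int(g): j for j, g in enumerate(needed)}
    anchor_pos = np.array([pos_of[int(i)] for i in batch])
    positives = [np.empty(0, dtype=np.int64)] * len(needed)
    negatives = [np.empty(0, dtype=np.int64)] * len(needed)
    for i, a in zip(batch, anchor_pos):
        positives[a] = np.array([pos_of[int(j)] for j in zones.positives[i]], dtype=np.int64)
        negatives[a] = np.array([pos_of[int(j)] for j in zones.negatives[i]], dtype=np.int64)
    return needed, anchor_pos, ZoneIndex(positives, negatives)


def _validation_rmse(state, X_sim, sim_props, val_idx) -> float:
    if len(val_idx) == 0:
        return float("nan")
    emb = encoder_forward(X_sim[val_idx], state, "eval")
    pred = predict_proportions(emb, state, "eval")
    return rmse(pred.values, sim_props.values[val_idx])


def run_cross_validation(
    sim: SpotDataset,
    sim_props: ProportionMatrix,
    real: SpotDataset | None = None,
    cfg: TrainConfig | None = None,
    spec: NetworkSpec | None = None,
) -> pd.DataFrame:
    """k-fold cross-validation over simulated spots.

    Spots are split into cfg.folds disjoint folds by seeded shuffle; each
    fold's model trains on the remainder (zones rebuilt on the training
    coordinates) and is scored on the held-out fold with RMSE, mean
    per-spot JS divergence and mean per-spot Pearson correlation.  The
    returned table has one row per fold plus a mean row.
    """
    cfg = cfg or TrainConfig()
    if cfg.folds < 2:
        raise ValidationError("cross-validation needs folds >= 2")
    n = sim.n_spots
    if n < cfg.folds:
        raise ValidationError("fewer spots than folds")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cfg.folds)
    rows = []
    for f, test_idx in enumerate(folds):
        test_idx = np.sort(test_idx)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        ds_train, pm_train = sim.subset(train_idx), sim_props.subset(train_idx)
        state, _ = run_training(ds_train, pm_train, real=real, cfg=cfg, spec=spec)
        ds_test, pm_test = sim.subset(test_idx), sim_props.subset(test_idx)
        X_test = build_model_input(ds_test, cfg.normalize_expr, cfg.coord_mode)
        pred = predict_proportions(encoder_forward(X_test, state, "eval"), state, "eval")
        js_vals = [js_divergence(p, q) for p, q in zip(pred.values, pm_test.values)]
        pr_vals = [pearson(p, q) for p, q in zip(pred.values, pm_test.values)]
        pr_vals = [v for v in pr_vals if np.isfinite(v)]
        rows.append(
            {
                "fold": f"fold{f}",
                "n_test": len(test_idx),
                "rmse": rmse(pred.values, pm_test.values),
                "mean_js": float(np.mean(js_vals)),
                "mean_pearson": float(np.mean(pr_vals)) if pr_vals else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    mean_row = table.drop(columns=["fold"]).mean(numeric_only=True)
    mean_row["fold"] = "mean"
    return pd.concat([table, mean_row.to_frame().T], ignore_index=True)[table.columns]
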