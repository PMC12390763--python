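"""The three networks: encoder, proportion predictor, domain classifier.

Encoder: input (selected genes + 2 coordinates) -> 512 -> 256 -> d_emb,
each layer affine -> ReLU -> dropout with rates 0 / 0.5 / 0.3.  Predictor:
d_emb -> 128 (leaky ReLU, slope 0.01, dropout 0.5 in training) -> n_types
with a row-wise softmax, so outputs live on the probability simplex.
Domain classifier: d_emb -> 64 (ReLU) -> 1 with a logistic output,
convention 1 = simulated, 0 = real.

Dropout is inverted (masks scaled by 1/(1-p) in train mode) so evaluation
needs no rescaling; all dropout masks derive from an explicit generator,
making training runs reproducible.  Forward functions accept numpy arrays
(returning arrays) or autodiff Tensors (returning Tensors, for training).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor
from .io_formats import ProportionMatrix, ValidationError

__all__ = [
    "NetworkSpec",
    "ModelState",
    "init_model_state",
    "encoder_forward",
    "predict_proportions",
    "classify_domain",
    "save_checkpoint",
    "load_checkpoint",
]

LEAKY_SLOPE = 0.01


@dataclass
class NetworkSpec:
    """Layer dimensions and dropout schedule of the three networks."""

    d_input: int
    n_types: int
    d_hidden1: int = 512
    d_hidden2: int = 256
    d_emb: int = 128
    dropout1: float = 0.0
    dropout2: float = 0.5
    dropout3: float = 0.3
    predictor_hidden: int = 128
    predictor_dropout: float = 0.5
    classifier_hidden: int = 64
    seed: int = 0

    def __post_init__(self):
        dims = (
            self.d_input,
            self.n_types,
            self.d_hidden1,
            self.d_hidden2,
            self.d_emb,
            self.predictor_hidden,
            self.classifier_hidden,
        )
        if any(d < 1 for d in dims):
            raise ValidationError("all network dimensions must be >= 1")
        for p in (self.dropout1, self.dropout2, self.dropout3, self.predictor_dropout):
            if not (0 <= p < 1):
                raise ValidationError("dropout rates must lie in [0, 1)")

    def n_parameters(self) -> int:
        """Closed-form total parameter count (weights + biases)."""

        def affine(a, b):
            return a * b + b

        return (
            affine(self.d_input, self.d_hidden1)
            + affine(self.d_hidden1, self.d_hidden2)
            + affine(self.d_hidden2, self.d_emb)
            + affine(self.d_emb, self.predictor_hidden)
            + affine(self.predictor_hidden, self.n_types)
            + affine(self.d_emb, self.classifier_hidden)
            + affine(self.classifier_hidden, 1)
        )


_LAYERS = [
    ("enc1", "d_input", "d_hidden1"),
    ("enc2", "d_hidden1", "d_hidden2"),
    ("enc3", "d_hidden2", "d_emb"),
    ("pred1", "d_emb", "predictor_hidden"),
    ("pred2", "predictor_hidden", "n_types"),
    ("dom1", "d_emb", "classifier_hidden"),
    ("dom2", "classifier_hidden", "1"),
]

ENCODER_KEYS = ["enc1.W", "enc1.b", "enc2.W", "enc2.b", "enc3.W", "enc3.b"]
PREDICTOR_KEYS = ["pred1.W", "pred1.b", "pred2.W", "pred2.b"]
CLASSIFIER_KEYS = ["dom1.W", "dom1.b", "dom2.W", "dom2.b"]


@dataclass
class ModelState:
    """All affine parameters of the three networks, as named Tensors."""

    spec: NetworkSpec
    params: dict[str, Tensor]

    def parameters(self, keys=None) -> list[Tensor]:
        keys = keys if keys is not None else list(self.params)
        return [self.params[k] for k in keys]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def copy(self) -> "ModelState":
        return ModelState(
            self.spec, {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()}
        )


def init_model_state(spec: NetworkSpec) -> ModelState:
    """Kaiming-style uniform fan-in initialization from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    params: dict[str, Tensor] = {}
    for name, a, b in _LAYERS:
        fan_in = getattr(spec, a) if a != "1" else 1
        fan_out = getattr(spec, b) if b != "1" else 1
        w_bound = 1.0 / np.sqrt(fan_in)
        b_bound = 1.0 / np.sqrt(fan_in)
        params[f"{name}.W"] = Tensor(
            rng.uniform(-w_bound, w_bound, size=(fan_in, fan_out)), requires_grad=True
        )
        params[f"{name}.b"] = Tensor(
            rng.uniform(-b_bound, b_bound, size=(fan_out,)), requires_grad=True
        )
    return ModelState(spec, params)


def _lift(x):
    if isinstance(x, Tensor):
        return x, False
    return Tensor(np.asarray(x, dtype=np.float64)), True


def _dropout(h: Tensor, rate: float, mode: str, rng) -> Tensor:
    if mode != "train" or rate == 0.0:
        return h
    if rng is None:
        raise ValidationError("train-mode dropout needs a random generator")
    mask = (rng.random(h.data.shape) >= rate) / (1.0 - rate)
    return h * mask


def _check_mode(mode: str):
    if mode not in ("train", "eval"):
        raise ValidationError(f"mode must be 'train' or 'eval', got {mode!r}")


def encoder_forward(x, state: ModelState, mode: str = "eval", rng=None):
    """Embed spots: three affine->ReLU->dropout layers (rates 0/0.5/0.3)."""
    _check_mode(mode)
    x_t, plain = _lift(x)
    if x_t.data.shape[1] != state.spec.d_input:
        raise ValidationError(
            f"encoder expects {state.spec.d_input} input columns, got {x_t.data.shape[1]}"
        )
    p = state.params
    h = _dropout((x_t @ p["enc1.W"] + p["enc1.b"]).relu(), state.spec.dropout1, mode, rng)
    h = _dropout((h @ p["enc2.W"] + p["enc2.b"]).relu(), state.spec.dropout2, mode, rng)
    h = _dropout((h @ p["enc3.W"] + p["enc3.b"]).relu(), state.spec.dropout3, mode, rng)
    return h.data if plain else h


def _softmax_rows(z: Tensor) -> Tensor:
    shifted = z - z.data.max(axis=1, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


def predict_proportions(E, state: ModelState, mode: str = "eval", rng=None):
    """Per-spot cell-type proportions: affine -> leaky ReLU -> dropout ->
    affine -> row softmax.  Plain-array input returns a ProportionMatrix."""
    _check_mode(mode)
    e_t, plain = _lift(E)
    if e_t.data.shape[1] != state.spec.d_emb:
        raise ValidationError(
            f"predictor expects {state.spec.d_emb} embedding columns, got {e_t.data.shape[1]}"
        )
    p = state.params
    h = (e_t @ p["pred1.W"] + p["pred1.b"]).leaky_relu(LEAKY_SLOPE)
    h = _dropout(h, state.spec.predictor_dropout, mode, rng)
    y = _softmax_rows(h @ p["pred2.W"] + p["pred2.b"])
    if plain:
        names = [f"type{t}" for t in range(state.spec.n_types)]
        return ProportionMatrix(y.data, names)
    return y


def classify_domain(E, state: ModelState, mode: str = "eval", rng=None):
    """Probability that each spot is simulated (1 = simulated, 0 = real)."""
    _check_mode(mode)
    e_t, plain = _lift(E)
    if e_t.data.shape[1] != state.spec.d_emb:
        raise ValidationError("classifier input must have d_emb columns")
    p = state.params
    h = (e_t @ p["dom1.W"] + p["dom1.b"]).relu()
    out = (h @ p["dom2.W"] + p["dom2.b"]).sigmoid().reshape(e_t.data.shape[0])
    return out.data if plain else out


def save_checkpoint(state: ModelState, path) -> None:
    """Single portable file: named arrays plus the NetworkSpec as JSON."""
    arrays = {k.replace(".", "__"): v.data for k, v in state.params.items()}
    np.savez(path, __spec__=np.frombuffer(json.dumps(asdict(state.spec)).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as archive:
        spec = NetworkSpec(**json.loads(bytes(archive["__spec__"]).decode()))
        params = {
            k.replace("__", "."): Tensor(archive[k].copy(), requires_grad=True)
            for k in archive.files
            if k != "__spec__"
        }
    return ModelState(spec, params)
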