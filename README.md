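# stdeconv

Cell-type deconvolution for spatial transcriptomics with spatially
informed contrastive learning and domain-adversarial training.

## The problem

Spot-based spatial transcriptomics assays (e.g. the classic ST platform
or Visium) measure gene expression at spatially indexed capture spots,
each containing a mixture of several cells. Deconvolution estimates, for
every spot *s*, a vector of cell-type proportions **y**<sub>s</sub> on
the probability simplex, using a single-cell RNA-seq reference that
carries cell-type labels but no spatial context. `stdeconv` is for
computational biologists who want a reference-based deconvolution method
that exploits the spatial coherence of tissue — nearby spots tend to
share composition — and that transfers from simulated training data to
real target data.

## The method

1. **Pseudo-spot simulation.** Labelled training spots are built from
   the reference: per-spot type proportions are drawn Dirichlet over a
   random type subset, an integer number of cells is allocated to types
   by largest-remainder rounding, sampled cells' counts are summed, and
   spatial coordinates are assigned by k-means clustering of the
   proportion vectors (cluster anchor + Gaussian jitter), so
   compositionally similar spots are spatial neighbours.
2. **Gene filtering.** A per-type one-vs-rest Welch *t*-test on the
   reference keeps genes with any p < 0.005; simulated and real data are
   aligned on the shared gene space.
3. **Embedding.** An encoder (input → 512 → 256 → d, ReLU, dropout
   0/0.5/0.3) maps each spot's expression-plus-coordinates vector to an
   embedding **e**<sub>s</sub>.
4. **Spatial contrastive loss.** Around each anchor spot three
   concentric bands define positive partners (d < t_pos), a drop zone,
   and negative partners (t_neg < d < t_radius). The loss averages
   −log softmax(−‖**e**_i − **e**_j‖) over positives and
   −log softmax(+‖**e**_i − **e**_j‖) over negatives.
5. **Domain-adversarial alignment.** A domain classifier is trained to
   distinguish simulated from real embeddings (binary cross-entropy);
   in alternating phases the encoder is trained with flipped domain
   labels so the two domains become indistinguishable. The squared
   maximum mean discrepancy MMD²(P, Q) under a Gaussian kernel
   (σ = 1.0) is logged as an alignment diagnostic and can optionally
   join the objective.
6. **Prediction.** A predictor head (d → 128, leaky ReLU, dropout 0.5
   → softmax) outputs proportions, trained with mean-absolute (L1) loss
   against the realized simulated proportions, jointly with the other
   terms under Adam (lr 0.0003, batch 32, 50 alternating rounds by
   default).

Evaluation follows the field's clustering-plus-distribution protocol:
global RMSE; per-spot Jensen–Shannon divergence and Pearson correlation
averaged over spots; and, after k-means clustering of the predictions
into k = number of cell types, adjusted Rand index and purity against
reference layer labels.

## Worked example

```python
import numpy as np
from stdeconv import (
    ReferenceSpec, SpotSimSpec, TrainConfig, generate_reference, simulate_spots,
    run_training, encoder_forward, predict_proportions, evaluate_dataset,
)
from stdeconv.preprocess import build_model_input

ref = generate_reference(ReferenceSpec(n_types=4, n_genes=120, cells_per_type=100, seed=0))
sim, props, _ = simulate_spots(ref, SpotSimSpec(n_spots=600, seed=0))
state, history = run_training(sim, props, cfg=TrainConfig(rounds=10, use_dann=False, seed=0))

X = build_model_input(sim)
pred = predict_proportions(encoder_forward(X, state, "eval"), state, "eval")
report = evaluate_dataset(pred, props, true_layer_labels=np.argmax(props.values, axis=1))
for k, v in report.items():
    print(f"{k}: {v:.4f}" if isinstance(v, float) else f"{k}: {v}")
```

prints

```
rmse: 0.0797
mean_js: 0.0345
mean_pearson: 0.9666
n_pearson_excluded: 0
ari: 0.8918
purity: 0.9583
```

RMSE 0.08 means the average per-entry error of the estimated
proportions is 8 percentage points (the constant uniform predictor
scores 0.34 on the same data); per-spot Pearson 0.97 says the shape of
each spot's composition is recovered almost perfectly; ARI 0.89 and
purity 0.96 say that clustering the predictions reproduces the
dominant-type spatial domains.

The same pipeline is scriptable from the shell:

```bash
stdeconv run --config src/stdeconv/demo_config.yaml --output-dir demo_out
```

which writes every intermediate artifact (reference, pseudo-spots,
gene-selection report, checkpoint, predictions, metrics) plus a
`manifest.json` of sha256 checksums; rerunning with the same config
reproduces the deterministic artifacts bit-exactly. Individual stages
are exposed as `simulate-reference`, `simulate-spots`, `preprocess`,
`train` (with `--no-dann`), `predict`, `evaluate` and `cross-validate`.

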