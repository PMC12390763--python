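"""Synthetic type-structured single-cell reference.

Generates a cells x genes count matrix in which each cell type owns a
disjoint block of marker genes whose expected expression is `marker_fold`
times the background.  Counts are negative-binomial (gamma-Poisson) to
mimic scRNA-seq overdispersion: mean mu, variance mu + mu^2 / dispersion.

This is a fixture generator: no batch effects, doublets or ambient RNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CellReference, ValidationError

__all__ = ["ReferenceSpec", "generate_reference"]


@dataclass
class ReferenceSpec:
    """Parameters of the synthetic reference.

    base_mean is the expected background count per gene; markers of a
    cell's own type have mean base_mean * marker_fold.  dispersion is the
    negative-binomial size parameter (larger = closer to Poisson).
    """

    n_types: int = 4
    n_genes: int = 120
    cells_per_type: int = 100
    n_markers_per_type: int = 10
    base_mean: float = 2.0
    marker_fold: float = 5.0
    dispersion: float = 2.0
    seed: int = 0
    permute_genes: bool = False

    def validate(self) -> None:
        if self.n_types < 1 or self.n_genes < 1 or self.cells_per_type < 1:
            raise ValidationError("n_types, n_genes, cells_per_type must be positive")
        if self.n_markers_per_type < 0:
            raise ValidationError("n_markers_per_type must be non-negative")
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValidationError(
                "marker budget exceeded: n_markers_per_type * n_types > n_genes"
            )
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("base_mean and dispersion must be positive")
        if self.marker_fold <= 1:
            raise ValidationError("marker_fold must exceed 1")


def marker_blocks(spec: ReferenceSpec) -> list[np.ndarray]:
    """Disjoint marker gene indices per type (contiguous blocks)."""
    m = spec.n_markers_per_type
    return [np.arange(t * m, (t + 1) * m) for t in range(spec.n_types)]


def generate_reference(spec: ReferenceSpec) -> CellReference:
    """Draw a synthetic reference; deterministic given spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_types * spec.cells_per_type
    mean = np.full((n_cells, spec.n_genes), spec.base_mean)
    blocks = marker_blocks(spec)
    for t, block in enumerate(blocks):
        rows = slice(t * spec.cells_per_type, (t + 1) * spec.cells_per_type)
        mean[rows, block] = spec.base_mean * spec.marker_fold
    # NB(mean mu, size r): p = r / (r + mu)
    r = spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.float64)
    gene_ids = [f"gene{j:04d}" for j in range(spec.n_genes)]
    if spec.permute_genes:
        order = rng.permutation(spec.n_genes)
        counts = counts[:, order]
        gene_ids = [gene_ids[j] for j in order]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    cell_types = [f"type{t}" for t in range(spec.n_types) for _ in range(spec.cells_per_type)]
    return CellReference(counts, gene_ids, cell_ids, cell_types)
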