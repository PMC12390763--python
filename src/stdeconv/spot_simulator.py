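"""Labelled pseudo-spot simulation from a single-cell reference.

Each pseudo-spot mixes a random number of reference cells: per-spot type
proportions are drawn Dirichlet over a random subset of types, cells are
allocated to types by largest-remainder rounding, sampled with
replacement, and their count vectors summed exactly.  Coordinates come
from k-means clustering of the proportion vectors: every cluster gets a
distinct lattice anchor and spots scatter around their anchor with
Gaussian jitter, so nearby spots share composition — the spatial signal
the contrastive stage later exploits.

No post-hoc noise is added to spot expression; all stochasticity enters
through proportion sampling and cell resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io_formats import CellReference, ProportionMatrix, SpotDataset, ValidationError

__all__ = [
    "SpotSimSpec",
    "sample_proportions",
    "largest_remainder_allocation",
    "mix_spots",
    "assign_coordinates",
    "simulate_spots",
]


@dataclass
class SpotSimSpec:
    """Pseudo-spot simulation parameters.

    cells_min..cells_max bound the uniform draw of cells per spot;
    dirichlet_alpha is the symmetric concentration over the chosen type
    subset; n_spatial_clusters and jitter_sd set the spatial structure
    (few clusters + small jitter = high spatial correlation).
    """

    n_spots: int = 600
    cells_min: int = 8
    cells_max: int = 12
    dirichlet_alpha: float = 1.0
    max_types_per_spot: int = 3
    n_spatial_clusters: int = 4
    grid_side: float = 100.0
    jitter_sd: float = 3.0
    seed: int = 0

    def validate(self, n_types: int | None = None) -> None:
        if self.n_spots < 1:
            raise ValidationError("n_spots must be positive")
        if not (1 <= self.cells_min <= self.cells_max):
            raise ValidationError("need 1 <= cells_min <= cells_max")
        if self.dirichlet_alpha <= 0:
            raise ValidationError("dirichlet_alpha must be positive")
        if self.max_types_per_spot < 1:
            raise ValidationError("max_types_per_spot must be positive")
        if self.n_spatial_clusters < 1:
            raise ValidationError("n_spatial_clusters must be positive")
        if self.n_spatial_clusters > self.n_spots:
            raise ValidationError("n_spatial_clusters cannot exceed n_spots")
        if n_types is not None and self.max_types_per_spot > n_types:
            raise ValidationError("max_types_per_spot exceeds number of reference types")
        if self.jitter_sd < 0 or self.grid_side <= 0:
            raise ValidationError("grid_side must be positive, jitter_sd non-negative")


def sample_proportions(
    spec: SpotSimSpec, n_types: int, type_names: list[str] | None = None
) -> ProportionMatrix:
    """Random per-spot type proportions.

    For each spot a subset of at most max_types_per_spot types is chosen
    uniformly (subset size uniform on 1..max), weights on the subset are
    symmetric Dirichlet(alpha), remaining types get 0.
    """
    if n_types < 1:
        raise ValidationError("n_types must be at least 1")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    kmax = min(spec.max_types_per_spot, n_types)
    values = np.zeros((spec.n_spots, n_types))
    for i in range(spec.n_spots):
        k = int(rng.integers(1, kmax + 1))
        chosen = rng.choice(n_types, size=k, replace=False)
        values[i, chosen] = rng.dirichlet(np.full(k, spec.dirichlet_alpha))
    names = type_names if type_names is not None else [f"type{t}" for t in range(n_types)]
    return ProportionMatrix(values, names)


def largest_remainder_allocation(c: int, proportions: np.ndarray) -> np.ndarray:
    """Allocate c integer cells to types by largest-remainder rounding.

    Floors c*p, then hands the remaining units to the largest fractional
    parts; ties break to the lowest type index (deterministic).
    """
    exact = c * np.asarray(proportions, dtype=np.float64)
    alloc = np.floor(exact).astype(np.int64)
    leftover = int(round(c - alloc.sum()))
    if leftover > 0:
        frac = exact - alloc
        # stable sort descending by fraction; ties keep index order
        order = np.argsort(-frac, kind="stable")
        alloc[order[:leftover]] += 1
    return alloc


def mix_spots(
    ref: CellReference, props: ProportionMatrix, spec: SpotSimSpec
) -> tuple[SpotDataset, ProportionMatrix, list[np.ndarray]]:
    """Sum sampled reference cells into pseudo-spots.

    Returns the spot dataset (coordinates zeroed until assigned), the
    realized proportions (allocated cell counts / total cells, the actual
    training labels) and a per-spot log of the sampled cell row indices.
    """
    spec.validate()
    type_names = ref.type_names
    missing = [t for t in props.cell_type_names if t not in type_names]
    if missing:
        raise ValidationError(f"reference lacks required cell type {missing[0]!r}")
    cells_of_type = {
        t: np.flatnonzero(np.asarray(ref.cell_types, dtype=object) == t)
        for t in props.cell_type_names
    }
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n_spots, n_types = props.values.shape
    expr = np.zeros((n_spots, ref.n_genes))
    realized = np.zeros_like(props.values)
    cell_log: list[np.ndarray] = []
    for i in range(n_spots):
        c = int(rng.integers(spec.cells_min, spec.cells_max + 1))
        alloc = largest_remainder_allocation(c, props.values[i])
        picked: list[np.ndarray] = []
        for t_idx, t_name in enumerate(props.cell_type_names):
            if alloc[t_idx] == 0:
                continue
            pool = cells_of_type[t_name]
            picked.append(rng.choice(pool, size=alloc[t_idx], replace=True))
        chosen = np.concatenate(picked) if picked else np.empty(0, dtype=np.int64)
        expr[i] = ref.counts[chosen].sum(axis=0)
        realized[i] = alloc / c
        cell_log.append(chosen)
    spot_ids = [f"spot{i:05d}" for i in range(n_spots)]
    ds = SpotDataset(expr, list(ref.gene_ids), spot_ids, np.zeros((n_spots, 2)), "simulated")
    realized_pm = ProportionMatrix(realized, list(props.cell_type_names), spot_ids)
    return ds, realized_pm, cell_log


def assign_coordinates(props: ProportionMatrix, spec: SpotSimSpec) -> np.ndarray:
    """Spatial coordinates from k-means on proportion vectors.

    Clusters of compositionally similar spots get distinct anchors on a
    sqrt(k) x sqrt(k) lattice scaled to grid_side; each spot sits at its
    cluster anchor plus isotropic Gaussian jitter.
    """
    spec.validate()
    k = spec.n_spatial_clusters
    if k > props.n_spots:
        raise ValidationError("more spatial clusters than spots")
    km = KMeans(n_clusters=k, n_init=10, random_state=spec.seed % (2**31))
    labels = km.fit_predict(props.values)
    side = int(np.ceil(np.sqrt(k)))
    spacing = spec.grid_side / side
    anchors = np.array(
        [((c % side + 0.5) * spacing, (c // side + 0.5) * spacing) for c in range(k)]
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    jitter = rng.normal(0.0, spec.jitter_sd, size=(props.n_spots, 2))
    return anchors[labels] + jitter


def simulate_spots(
    ref: CellReference, spec: SpotSimSpec
) -> tuple[SpotDataset, ProportionMatrix, list[np.ndarray]]:
    """Full pseudo-spot simulation: proportions -> mixing -> coordinates.

    Returns (spot dataset with coordinates, realized proportions, cell log).
    """
    spec.validate(n_types=len(ref.type_names))
    props = sample_proportions(spec, len(ref.type_names), ref.type_names)
    ds, realized, log = mix_spots(ref, props, spec)
    ds.coords = assign_coordinates(realized, spec)
    return ds, realized, log
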