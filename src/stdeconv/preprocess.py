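"""Gene selection, gene-space alignment and network input assembly.

Informative genes are picked on the labelled single-cell reference with a
per-type one-vs-rest Welch t-test; a gene is kept when any type's
two-sided p-value falls below the threshold (default 0.005, applied raw;
a Benjamini-Hochberg option is available).  Simulated and real spot
datasets are then re-indexed onto a shared, string-sorted gene space, and
assembled into the network input matrix: optionally normalized expression
(per-spot scaling to the dataset median total, then log1p) with the two
min-max-scaled coordinate columns appended last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CellReference, SpotDataset, ValidationError

__all__ = [
    "GeneSelection",
    "select_genes_ttest",
    "align_gene_space",
    "build_model_input",
]


@dataclass
class GeneSelection:
    """Outcome of the differential-expression filter."""

    kept_gene_ids: list[str]
    p_values: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.005

    def report(self) -> pd.DataFrame:
        kept = set(self.kept_gene_ids)
        return pd.DataFrame(
            {
                "gene": list(self.p_values),
                "min_p": [self.p_values[g] for g in self.p_values],
                "kept": [g in kept for g in self.p_values],
            }
        )


def select_genes_ttest(
    ref: CellReference, threshold: float = 0.005, bh_correct: bool = False
) -> GeneSelection:
    """One-vs-rest Welch t-test per gene and cell type.

    A gene is kept if its smallest two-sided p-value over types is below
    `threshold`.  Genes whose test is undefined (zero variance in both
    groups with equal means) are never kept.  With `bh_correct`, the
    per-type p-values are Benjamini-Hochberg adjusted across genes first.
    """
    types = ref.type_names
    if len(types) < 2:
        raise ValidationError("gene selection needs at least 2 cell types")
    labels = np.asarray(ref.cell_types, dtype=object)
    min_p = np.full(ref.n_genes, np.inf)
    for t in types:
        in_group = labels == t
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ValidationError(f"cell type {t!r} needs at least 2 cells in each group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(
                ref.counts[in_group], ref.counts[~in_group], equal_var=False, axis=0
            )
        p = np.asarray(p, dtype=np.float64)
        if bh_correct:
            p = _benjamini_hochberg(p)
        p = np.where(np.isnan(p), np.inf, p)  # undefined test -> never significant
        min_p = np.minimum(min_p, p)
    kept = [g for g, pv in zip(ref.gene_ids, min_p) if pv < threshold]
    p_map = {g: (float(pv) if np.isfinite(pv) else float("nan")) for g, pv in zip(ref.gene_ids, min_p)}
    return GeneSelection(kept, p_map, threshold)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    if ok.sum():
        pv = p[ok]
        m = pv.size
        order = np.argsort(pv)
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.clip(ranked, 0, 1)
        adj[ok] = out
    return adj


def align_gene_space(
    sim: SpotDataset, real: SpotDataset, selection: GeneSelection | None = None
) -> tuple[SpotDataset, SpotDataset]:
    """Re-index both datasets onto the union of their genes (kept genes only).

    Genes absent from one dataset are zero-filled there; the column order
    of the two outputs is identical (string-sorted).  Idempotent.
    """
    union = set(sim.gene_ids) | set(real.gene_ids)
    if selection is not None:
        union &= set(selection.kept_gene_ids)
    if not union:
        raise ValidationError("gene alignment produced an empty gene set")
    order = sorted(union)

    def reindex(ds: SpotDataset) -> SpotDataset:
        col = {g: j for j, g in enumerate(ds.gene_ids)}
        expr = np.zeros((ds.n_spots, len(order)))
        for j, g in enumerate(order):
            if g in col:
                expr[:, j] = ds.expr[:, col[g]]
        return SpotDataset(expr, order, list(ds.spot_ids), ds.coords.copy(), ds.domain_tag)

    return reindex(sim), reindex(real)


def build_model_input(
    ds: SpotDataset, normalize_expr: bool = True, coord_mode: str = "minmax"
) -> np.ndarray:
    """Assemble the spots x (genes + 2) network input matrix.

    Expression is optionally library-size normalized (per-spot totals
    scaled to the dataset median total, then log1p).  Coordinates are
    min-max scaled to [0, 1] per axis (`coord_mode="minmax"`) or replaced
    by zeros (`coord_mode="zeros"`, the coordinate-free ablation); they
    form the last two columns.
    """
    if coord_mode not in ("minmax", "zeros"):
        raise ValidationError(f"unknown coord_mode {coord_mode!r}")
    expr = ds.expr.astype(np.float64, copy=True)
    if normalize_expr:
        totals = expr.sum(axis=1)
        median = np.median(totals[totals > 0]) if np.any(totals > 0) else 0.0
        scale = np.where(totals > 0, median / np.where(totals > 0, totals, 1.0), 0.0)
        expr = np.log1p(expr * scale[:, None])
    if coord_mode == "zeros":
        coords = np.zeros((ds.n_spots, 2))
    else:
        lo = ds.coords.min(axis=0)
        rng_ = ds.coords.max(axis=0) - lo
        coords = np.zeros((ds.n_spots, 2))
        for axis in range(2):
            if rng_[axis] > 0:
                coords[:, axis] = (ds.coords[:, axis] - lo[axis]) / rng_[axis]
            else:
                warnings.warn(
                    f"degenerate coordinate range on axis {axis}; using zeros",
                    stacklevel=2,
                )
    return np.hstack([expr, coords])
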