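"""Expression-side spatial analyses.

Normalization (median-total scaling + log1p), control-matched gene-module
scores, distance-binned expression profiles with Spearman statistics on
the unbinned per-cell pairs, score-vs-distance correlations, and a thin
BH-adjusted rank-sum utility for group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .datatypes import CellMap, ExpressionMatrix, GeneSet
from .errors import ValidationError
from .geometry import DistanceField

__all__ = [
    "ModuleScoreConfig",
    "DistanceProfile",
    "normalize_expression",
    "module_score",
    "binned_distance_profile",
    "correlate_score_distance",
    "spatial_gene_set_score_map",
    "rank_sum_groups",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleScoreConfig:
    n_bins: int = 25
    n_ctrl_per_gene: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.n_ctrl_per_gene < 1:
            raise ValidationError("n_ctrl_per_gene must be >= 1")


def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell's total to the median per-cell total, then log1p.

    Refuses to run twice (the ``normalized`` flag guards idempotence).
    All-zero cells are retained unchanged, with a warning.
    """
    if expr.normalized:
        raise ValidationError("expression matrix is already normalized")
    X = sp.csr_matrix(expr.X, dtype=float, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    nz = totals > 0
    if not nz.all():
        log.warning("%d all-zero cells left unscaled", int((~nz).sum()))
    median_total = float(np.median(totals[nz])) if nz.any() else 1.0
    scale = np.ones_like(totals)
    scale[nz] = median_total / totals[nz]
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return ExpressionMatrix(
        cell_ids=list(expr.cell_ids),
        genes=list(expr.genes),
        X=sp.csr_matrix(X),
        normalized=True,
    )


def module_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    config: ModuleScoreConfig | None = None,
) -> np.ndarray:
    """Per-cell module score: mean expression of the set genes minus the
    mean of expression-matched control genes.

    Controls are drawn per set gene from its average-expression bin among
    ``n_bins`` equal-frequency bins (seeded, without replacement up to the
    bin size, set genes excluded from the pool when possible).
    """
    config = config or ModuleScoreConfig()
    gidx = expr.gene_index()
    present = [g for g in gene_set.genes if g in gidx]
    missing = sorted(gene_set.genes - set(present))
    if missing:
        log.info("gene set %s: %d genes absent from matrix: %s",
                 gene_set.name, len(missing), missing[:10])
    if not present:
        raise ValidationError(
            f"no gene of set {gene_set.name!r} present in the matrix"
        )
    set_cols = np.array(sorted(gidx[g] for g in present))

    avg = np.asarray(expr.X.mean(axis=0)).ravel()
    n_bins = max(1, min(config.n_bins, len(avg) // 2))
    ranks = pd.Series(avg).rank(method="first").to_numpy()
    bins = np.minimum(
        (ranks - 1) * n_bins // len(avg), n_bins - 1
    ).astype(int)

    rng = np.random.default_rng(config.seed)
    set_mask = np.zeros(len(avg), dtype=bool)
    set_mask[set_cols] = True
    ctrl: set[int] = set()
    for col in set_cols:
        pool = np.flatnonzero((bins == bins[col]) & ~set_mask)
        if len(pool) == 0:
            pool = np.flatnonzero(bins == bins[col])
            pool = pool[pool != col]
        if len(pool) == 0:
            continue
        take = min(config.n_ctrl_per_gene, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ValidationError("no control genes available")
    ctrl_cols = np.array(sorted(ctrl))

    set_mean = np.asarray(expr.X[:, set_cols].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(expr.X[:, ctrl_cols].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


@dataclass
class DistanceProfile:
    """Binned distance profile plus unbinned Spearman statistics.

    ``bin_table``: one row per (bin, column) with the bin interval, mean
    value and cell count; ``correlations``: per column rho/p/n/note from
    the unbinned per-cell (distance, value) pairs.
    """

    bin_edges: np.ndarray
    bin_table: pd.DataFrame
    correlations: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.bin_table


def _spearman_or_na(d: np.ndarray, v: np.ndarray):
    if len(d) < 2 or np.std(v) == 0 or np.std(d) == 0:
        return np.nan, np.nan, "zero variance"
    rho, p = spearmanr(d, v)
    return float(rho), float(p), ""


def binned_distance_profile(
    values: pd.DataFrame,
    distance: DistanceField,
    bin_width: float = 10.0,
    max_dist: float = 300.0,
    min_cells: int = 10,
) -> DistanceProfile:
    """Bin per-cell values by distance and report per-bin means.

    ``values`` holds one column per gene/score, aligned row-for-row with
    the cell map the distance field was computed on.  Spearman statistics
    are computed on the *unbinned* per-cell pairs; bins are display-level
    summaries.  Cells beyond ``max_dist`` or at infinite distance are
    excluded.  Empty bins get an NA mean.
    """
    d = np.asarray(distance.values, dtype=float)
    in_range = np.isfinite(d) & (d < max_dist)
    if in_range.sum() < min_cells:
        raise ValidationError(
            f"only {int(in_range.sum())} cells with finite distance "
            f"< {max_dist} (need >= {min_cells})"
        )
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    edges = edges[edges <= max_dist + 1e-9]
    which = np.digitize(d[in_range], edges[1:-1], right=False)
    n_bins = len(edges) - 1

    rows, corr_rows = [], []
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)[in_range]
        for b in range(n_bins):
            sel = which == b
            rows.append(
                {
                    "column": col,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "mean": float(np.mean(v[sel])) if sel.any() else np.nan,
                    "n_cells": int(sel.sum()),
                }
            )
        rho, p, note = _spearman_or_na(d[in_range], v)
        corr_rows.append({"column": col, "spearman_rho": rho,
                          "spearman_p": p, "n": int(in_range.sum()),
                          "note": note})
    bin_table = pd.DataFrame(rows).sort_values(
        ["column", "bin_lo"], kind="mergesort"
    ).reset_index(drop=True)
    correlations = pd.DataFrame(corr_rows).sort_values(
        "column", kind="mergesort"
    ).reset_index(drop=True)
    return DistanceProfile(bin_edges=edges, bin_table=bin_table,
                           correlations=correlations)


def correlate_score_distance(
    score: np.ndarray,
    distance: DistanceField,
    subset: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Spearman rho and two-sided p between a per-cell score and the
    distance field, over an optional boolean cell subset."""
    d = np.asarray(distance.values, dtype=float)
    s = np.asarray(score, dtype=float)
    mask = np.isfinite(d) & np.isfinite(s)
    if subset is not None:
        mask &= np.asarray(subset, dtype=bool)
    if mask.sum() < 10:
        raise ValidationError(
            f"subset yields {int(mask.sum())} usable cells (need >= 10)"
        )
    rho, p, note = _spearman_or_na(d[mask], s[mask])
    return rho, p, int(mask.sum())


def spatial_gene_set_score_map(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    cells: CellMap,
    config: ModuleScoreConfig | None = None,
) -> pd.DataFrame:
    """Module score attached to spatial coordinates for map rendering.

    Numerically identical to :func:`module_score`; rows align cell-by-cell
    with the cell map (matched on cell_id).
    """
    scores = module_score(expr, gene_set, config)
    lut = dict(zip(expr.cell_ids, scores))
    t = cells.table
    mapped = np.array([lut.get(cid, np.nan) for cid in t["cell_id"]])
    return pd.DataFrame(
        {
            "cell_id": t["cell_id"].to_numpy(),
            "sample_id": t["sample_id"].to_numpy(),
            "x": t["x"].to_numpy(),
            "y": t["y"].to_numpy(),
            "score": mapped,
        }
    )


def rank_sum_groups(
    score: np.ndarray, groups: np.ndarray, reference: str | None = None
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of a score across groups, BH-adjusted.

    With ``reference`` set, each group is compared against it; otherwise
    all unordered group pairs are compared.
    """
    score = np.asarray(score, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups))
    pairs = (
        [(g, reference) for g in names if g != reference]
        if reference is not None
        else [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    )
    rows = []
    for a, b in pairs:
        va, vb = score[groups == a], score[groups == b]
        if len(va) == 0 or len(vb) == 0:
            continue
        stat, p = mannwhitneyu(va, vb, alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "n_a": len(va),
                     "n_b": len(vb), "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        _, p_adj, _, _ = multipletests(out["p"], method="fdr_bh")
        out["p_adj"] = p_adj
    return out
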