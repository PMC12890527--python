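"""Single-spot colocalization scoring.

For an (anchor, target) type pair the per-cell score is the product of
kernel-weighted local masses of the two types within a short radius:

    f_T(i)  = sum over type-T cells j with d_ij <= r of w(d_ij)
    score_i = f_anchor(i) * f_target(i)

so the score is zero unless both types contribute mass simultaneously,
symmetric in the pair, and high exactly where the two types coexist
closely.  Kernels: uniform w=1, linear w = 1 - d/r (default), gaussian
w = exp(-d^2 / (2 (r/2)^2)) truncated at r; w(0) = 1 for all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .datatypes import CellMap
from .errors import ValidationError

__all__ = [
    "ColocConfig",
    "ColocScoreField",
    "coloc_score",
    "coloc_significance",
    "correlate_signal_with_coloc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocConfig:
    radius_um: float = 10.0
    kernel: str = "linear"  # uniform | linear | gaussian
    include_self: bool = True
    evaluate_at: str = "all_cells"  # all_cells | anchor_cells

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValidationError("radius_um must be > 0")
        if self.kernel not in {"uniform", "linear", "gaussian"}:
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.evaluate_at not in {"all_cells", "anchor_cells"}:
            raise ValidationError(
                f"unknown evaluate_at {self.evaluate_at!r}"
            )


@dataclass
class ColocScoreField:
    """Per-cell nonnegative colocalization score for one type pair.

    ``cell_index`` holds the evaluated cells' row positions in the cell
    map; ``scores`` aligns with it.
    """

    anchor_type: str
    target_type: str
    config: ColocConfig
    cell_index: np.ndarray
    scores: np.ndarray
    cells: CellMap = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """cell_id, sample_id, x, y, score — sorted by (sample_id, cell_id)."""
        t = self.cells.table.iloc[self.cell_index]
        out = pd.DataFrame(
            {
                "cell_id": t["cell_id"].to_numpy(),
                "sample_id": t["sample_id"].to_numpy(),
                "x": t["x"].to_numpy(),
                "y": t["y"].to_numpy(),
                "score": self.scores,
            }
        )
        return out.sort_values(["sample_id", "cell_id"],
                               kind="mergesort").reset_index(drop=True)


def _kernel_weights(d: np.ndarray, config: ColocConfig) -> np.ndarray:
    r = config.radius_um
    if config.kernel == "uniform":
        return np.ones_like(d)
    if config.kernel == "linear":
        return 1.0 - d / r
    sigma = r / 2.0
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def _radius_weight_matrix(cells: CellMap, config: ColocConfig) -> sp.csr_matrix:
    """Sparse (n × n) within-sample kernel-weight matrix at the config
    radius, diagonal included iff ``include_self``."""
    n = cells.n_cells
    coords = cells.coords
    rows_out, cols_out, w_out = [], [], []
    for sid, rows in cells.sample_index().items():
        xy = coords[rows]
        tree = cKDTree(xy)
        pairs = tree.query_ball_point(xy, config.radius_um)
        for local, nbrs in enumerate(pairs):
            nb = np.asarray(nbrs, dtype=np.intp)
            if not config.include_self:
                nb = nb[nb != local]
            d = np.hypot(*(xy[nb] - xy[local]).T)
            keep = d <= config.radius_um
            nb, d = nb[keep], d[keep]
            rows_out.append(np.full(len(nb), rows[local], dtype=np.intp))
            cols_out.append(rows[nb])
            w_out.append(_kernel_weights(d, config))
    if rows_out:
        rows_cat = np.concatenate(rows_out)
        cols_cat = np.concatenate(cols_out)
        w_cat = np.concatenate(w_out)
    else:  # pragma: no cover - single-cell-per-sample edge
        rows_cat = cols_cat = np.empty(0, dtype=np.intp)
        w_cat = np.empty(0)
    return sp.csr_matrix((w_cat, (rows_cat, cols_cat)), shape=(n, n))


def _check_types(cells: CellMap, anchor_type: str, target_type: str) -> None:
    labels = set(cells.table["cell_type"])
    for t in (anchor_type, target_type):
        if t not in labels:
            raise ValidationError(f"cell type {t!r} absent from input")
    for sid, rows in cells.sample_index().items():
        present = set(cells.table["cell_type"].to_numpy()[rows])
        for t in (anchor_type, target_type):
            if t not in present:
                log.warning(
                    "sample %s lacks %r cells; its scores are zero", sid, t
                )


def coloc_score(
    cells: CellMap,
    anchor_type: str,
    target_type: str,
    config: ColocConfig | None = None,
) -> ColocScoreField:
    """Compute the colocalization score field for one type pair."""
    config = config or ColocConfig()
    _check_types(cells, anchor_type, target_type)
    W = _radius_weight_matrix(cells, config)
    labels = cells.table["cell_type"].to_numpy()
    f_anchor = W @ (labels == anchor_type).astype(float)
    f_target = W @ (labels == target_type).astype(float)
    scores = f_anchor * f_target
    if config.evaluate_at == "anchor_cells":
        idx = np.flatnonzero(labels == anchor_type)
    else:
        idx = np.arange(cells.n_cells)
    return ColocScoreField(
        anchor_type=anchor_type,
        target_type=target_type,
        config=config,
        cell_index=idx,
        scores=scores[idx],
        cells=cells,
    )


def coloc_significance(
    cells: CellMap,
    fld: ColocScoreField,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell empirical p-values against a within-sample label-shuffle
    null: p_i = (1 + #{null score_i >= observed_i}) / (n_perm + 1)."""
    if n_perm < 20:
        log.warning(
            "n_perm=%d gives a p-value floor of %.3g; consider more "
            "permutations", n_perm, 1.0 / (n_perm + 1),
        )
    W = _radius_weight_matrix(cells, fld.config)
    labels = cells.table["cell_type"].to_numpy()
    obs = fld.scores
    idx = fld.cell_index
    sample_rows = list(cells.sample_index().values())
    seeds = np.random.SeedSequence(seed).spawn(n_perm)
    ge = np.zeros(len(idx))
    for i in range(n_perm):
        rng = np.random.default_rng(seeds[i])
        lab = labels.copy()
        for rows in sample_rows:
            lab[rows] = lab[rows[rng.permutation(len(rows))]]
        fa = W @ (lab == fld.anchor_type).astype(float)
        ft = W @ (lab == fld.target_type).astype(float)
        ge += (fa * ft)[idx] >= obs - 1e-12
    return (1.0 + ge) / (n_perm + 1.0)


def correlate_signal_with_coloc(
    signal: pd.DataFrame, fld: ColocScoreField
) -> pd.DataFrame:
    """Spearman correlation of each ligand-receptor signal column with the
    score field over overlapping cells.

    ``signal``: first column ``cell_id``, remaining columns one per LR
    pair.  Returns a table (lr_pair, rho, p, p_adj, n, note) sorted by
    descending rho (NA correlations last).
    """
    if "cell_id" not in signal.columns:
        signal = signal.rename(columns={signal.columns[0]: "cell_id"})
    field_frame = pd.DataFrame(
        {
            "cell_id": self_ids(fld),
            "score": fld.scores,
        }
    )
    merged = field_frame.merge(
        signal.assign(cell_id=signal["cell_id"].astype(str)), on="cell_id"
    )
    if len(merged) < 10:
        raise ValidationError(
            f"only {len(merged)} overlapping cells between signal table "
            "and score field (need >= 10)"
        )
    score = merged["score"].to_numpy(dtype=float)
    rows = []
    for col in signal.columns:
        if col == "cell_id":
            continue
        v = merged[col].to_numpy(dtype=float)
        if np.nanstd(v) == 0 or np.nanstd(score) == 0:
            rows.append({"lr_pair": col, "rho": np.nan, "p": np.nan,
                         "n": len(v), "note": "zero variance"})
            continue
        rho, p = spearmanr(v, score)
        rows.append({"lr_pair": col, "rho": rho, "p": p, "n": len(v),
                     "note": ""})
    out = pd.DataFrame(rows)
    valid = out["rho"].notna()
    out["p_adj"] = np.nan
    if valid.any():
        _, p_adj, _, _ = multipletests(out.loc[valid, "p"], method="fdr_bh")
        out.loc[valid, "p_adj"] = p_adj
    out = out.sort_values("rho", ascending=False, na_position="last",
                          kind="mergesort").reset_index(drop=True)
    return out[["lr_pair", "rho", "p", "p_adj", "n", "note"]]


def self_ids(fld: ColocScoreField) -> np.ndarray:
    return fld.cells.table["cell_id"].to_numpy()[fld.cell_index]
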