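"""Core domain types shared across the toolkit.

``CellMap`` is the central object: one row per segmented cell with 2D
centroid coordinates in micrometers, a sample identifier, a cell-type label
and an optional lineage label.  All spatial analyses operate strictly
within a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

__all__ = ["CellMap", "ExpressionMatrix", "GeneSet"]

_CELL_COLUMNS = ["cell_id", "sample_id", "x", "y", "cell_type"]


@dataclass
class CellMap:
    """Per-cell coordinates (μm), sample id, type and optional lineage labels.

    Parameters
    ----------
    table
        DataFrame with columns ``cell_id``, ``sample_id``, ``x``, ``y``,
        ``cell_type`` and optionally ``lineage``.  Row order is preserved
        and is the canonical cell ordering used by every per-cell array in
        the package.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CELL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"cell table missing columns: {missing}")
        if len(self.table) == 0:
            raise ValidationError("cell map must contain at least one cell")
        t = self.table.reset_index(drop=True).copy()
        t["cell_id"] = t["cell_id"].astype(str)
        t["sample_id"] = t["sample_id"].astype(str)
        t["cell_type"] = t["cell_type"].astype(str)
        xy = t[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("cell coordinates must be finite")
        if (t["cell_type"].str.len() == 0).any():
            raise ValidationError("every cell must carry a non-empty cell_type")
        dup = t.duplicated(subset=["sample_id", "cell_id"])
        if dup.any():
            bad = t.loc[dup, "cell_id"].iloc[0]
            raise ValidationError(
                f"duplicate cell_id within a sample (e.g. {bad!r})"
            )
        self.table = t

    # -- convenience accessors -------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) float array of x/y centroids in μm, in table row order."""
        return self.table[["x", "y"]].to_numpy(dtype=float)

    @property
    def cell_types(self) -> list[str]:
        """Sorted unique cell-type labels."""
        return sorted(self.table["cell_type"].unique())

    @property
    def sample_ids(self) -> list[str]:
        """Sorted unique sample identifiers."""
        return sorted(self.table["sample_id"].unique())

    def sample_index(self) -> dict[str, np.ndarray]:
        """Row positions per sample, in table row order."""
        return {
            s: np.flatnonzero((self.table["sample_id"] == s).to_numpy())
            for s in self.sample_ids
        }

    def type_codes(self, types: list[str] | None = None) -> np.ndarray:
        """Integer codes of ``cell_type`` against ``types`` (default sorted)."""
        types = self.cell_types if types is None else types
        lut = {t: i for i, t in enumerate(types)}
        return np.array(
            [lut.get(t, -1) for t in self.table["cell_type"]], dtype=np.intp
        )

    def subset(self, mask: np.ndarray) -> "CellMap":
        return CellMap(self.table.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class ExpressionMatrix:
    """Sparse cell × gene matrix with aligned id lists.

    ``normalized`` records whether :func:`normalize_expression` has been
    applied; raw counts carry ``False``.
    """

    cell_ids: list[str]
    genes: list[str]
    X: sp.csr_matrix
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.cell_ids), len(self.genes)):
            raise ValidationError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.genes)} genes"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise ValidationError("expression values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def gene_index(self) -> dict[str, int]:
        return {g.upper(): i for i, g in enumerate(self.genes)}


@dataclass
class GeneSet:
    """A named set of gene symbols, uppercase-normalized."""

    name: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = {g.upper() for g in self.genes if g}
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
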