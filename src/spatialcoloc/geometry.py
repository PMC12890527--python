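"""Spatial queries: kNN / fixed-radius neighbor graphs and nearest-distance
fields, always computed strictly within a sample.

Distances are 2D Euclidean in μm.  Ties at equal distance are broken by
ascending row index so downstream permutation tests are reproducible
bit-for-bit.  Neighbor candidate sets come from a kd-tree, but the reported
distances are recomputed with plain numpy arithmetic so that results match
a brute-force oracle exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import CellMap
from .errors import ValidationError

__all__ = [
    "NeighborQuery",
    "NeighborGraph",
    "DistanceField",
    "build_neighbor_graph",
    "nearest_distance_to_type",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborQuery:
    """Neighborhood descriptor: ``mode`` is ``"knn"`` or ``"radius"``."""

    mode: str
    k: int | None = None
    radius_um: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "knn":
            if self.k is None or self.k < 1:
                raise ValidationError("knn query requires k >= 1")
        elif self.mode == "radius":
            if self.radius_um is None or not self.radius_um > 0:
                raise ValidationError("radius query requires radius_um > 0")
        else:
            raise ValidationError(f"unknown query mode {self.mode!r}")


@dataclass
class NeighborGraph:
    """CSR-style neighbor lists over the cells of a :class:`CellMap`.

    ``indptr``/``indices``/``distances`` follow the usual compressed-row
    layout; the neighbor list of cell ``i`` is
    ``indices[indptr[i]:indptr[i+1]]`` with matching distances, sorted by
    (distance, index).  Indices are global row positions into the cell map.
    """

    query: NeighborQuery
    n_cells: int
    indptr: np.ndarray
    indices: np.ndarray
    distances: np.ndarray
    truncated: bool = False

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return self.indices[sl], self.distances[sl]

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)


@dataclass
class DistanceField:
    """Per-cell Euclidean distance (μm) to the nearest cell of one type.

    ``np.inf`` marks cells in samples that contain no target cell.
    """

    target_type: str
    exclude_self_type: bool
    values: np.ndarray


def _sorted_by_distance(
    d: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    order = np.lexsort((idx, d))
    return d[order], idx[order]


def build_neighbor_graph(cells: CellMap, query: NeighborQuery) -> NeighborGraph:
    """Per-sample kd-tree neighbor graph under ``query``.

    For kNN queries, ``k`` is truncated to ``n_sample - 1`` with a warning
    when a sample is too small.
    """
    n = cells.n_cells
    coords = cells.coords
    nbr_idx: list[np.ndarray] = [np.empty(0, dtype=np.intp)] * n
    nbr_d: list[np.ndarray] = [np.empty(0, dtype=float)] * n
    truncated = False

    for sid, rows in cells.sample_index().items():
        m = len(rows)
        xy = coords[rows]
        if m == 1:
            continue
        tree = cKDTree(xy)
        if query.mode == "knn":
            k = query.k
            if k > m - 1:
                log.warning(
                    "sample %s has %d cells; truncating k=%d to %d",
                    sid, m, k, m - 1,
                )
                k = m - 1
                truncated = True
            kth_d, _ = tree.query(xy, k=k + 1)
            kth_d = np.atleast_2d(kth_d)[:, -1]
            for local, row in enumerate(rows):
                r = kth_d[local] * (1 + 1e-9) + 1e-12
                cand = np.array(tree.query_ball_point(xy[local], r), dtype=np.intp)
                cand = cand[cand != local]
                d = np.hypot(*(xy[cand] - xy[local]).T)
                d, cand = _sorted_by_distance(d, rows[cand])
                nbr_idx[row] = cand[:k]
                nbr_d[row] = d[:k]
        else:
            r = float(query.radius_um)
            balls = tree.query_ball_point(xy, r)
            for local, row in enumerate(rows):
                cand = np.array(balls[local], dtype=np.intp)
                cand = cand[cand != local]
                d = np.hypot(*(xy[cand] - xy[local]).T)
                keep = d <= r
                d, cand = _sorted_by_distance(d[keep], rows[cand[keep]])
                nbr_idx[row] = cand
                nbr_d[row] = d

    counts = np.array([len(a) for a in nbr_idx])
    indptr = np.zeros(n + 1, dtype=np.intp)
    np.cumsum(counts, out=indptr[1:])
    indices = (
        np.concatenate(nbr_idx) if indptr[-1] else np.empty(0, dtype=np.intp)
    )
    dists = np.concatenate(nbr_d) if indptr[-1] else np.empty(0, dtype=float)
    return NeighborGraph(
        query=query,
        n_cells=n,
        indptr=indptr,
        indices=indices.astype(np.intp),
        distances=dists.astype(float),
        truncated=truncated,
    )


def nearest_distance_to_type(
    cells: CellMap, target_type: str, exclude_self_type: bool = False
) -> DistanceField:
    """Distance from every cell to the closest target-type cell in the same
    sample.

    Target cells get 0 unless ``exclude_self_type``, in which case they get
    the distance to the nearest *other* target cell.  Samples with no target
    cell yield ``inf`` with a logged warning.
    """
    labels = cells.table["cell_type"].to_numpy()
    if target_type not in labels:
        raise ValidationError(
            f"target type {target_type!r} absent from every sample"
        )
    coords = cells.coords
    out = np.full(cells.n_cells, np.inf)

    for sid, rows in cells.sample_index().items():
        is_t = labels[rows] == target_type
        t_rows = rows[is_t]
        if len(t_rows) == 0:
            log.warning(
                "sample %s contains no %r cells; distances set to inf",
                sid, target_type,
            )
            continue
        tree = cKDTree(coords[t_rows])
        d, j = tree.query(coords[rows], k=1)
        d = np.hypot(*(coords[t_rows[j]] - coords[rows]).T)  # exact re-eval
        out[rows] = d
        if not exclude_self_type:
            out[t_rows] = 0.0
        else:
            if len(t_rows) == 1:
                out[t_rows] = np.inf
            else:
                d2, j2 = tree.query(coords[t_rows], k=2)
                other = t_rows[j2[:, 1]]
                out[t_rows] = np.hypot(*(coords[other] - coords[t_rows]).T)
    return DistanceField(
        target_type=target_type,
        exclude_self_type=exclude_self_type,
        values=out,
    )
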