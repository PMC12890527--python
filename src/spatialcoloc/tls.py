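"""TLS detection and characterization.

Regions are detected from a T vs B/plasma colocalization score field:
cells scoring above a per-sample quantile of the nonzero scores are linked
by single linkage at a fixed radius, and connected components with enough
members become regions.  Characterization quantifies cell-type composition
against binned distance to the nearest region B cell, 10 μm proximity
shares, and linear decay slopes with 95% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import t as t_dist
from shapely.geometry import MultiPoint, Point

from .colocalization import ColocScoreField
from .datatypes import CellMap
from .errors import ValidationError

__all__ = [
    "TLSConfig",
    "TLSRegion",
    "TLSRegionSet",
    "detect_tls",
    "tls_distance_composition",
    "tls_proximity_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TLSConfig:
    score_quantile: float = 0.90  # over nonzero scores, per sample
    linkage_radius_um: float = 30.0
    min_cells: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.score_quantile < 1:
            raise ValidationError("score_quantile must be in (0, 1)")
        if not self.linkage_radius_um > 0:
            raise ValidationError("linkage_radius_um must be > 0")
        if self.min_cells < 1:
            raise ValidationError("min_cells must be >= 1")


@dataclass
class TLSRegion:
    region_id: int
    sample_id: str
    member_rows: np.ndarray        # row positions into the cell map
    member_cells: list[str]        # cell ids
    hull: object                   # shapely polygon (or line/point)
    type_counts: dict[str, int]


@dataclass
class TLSRegionSet:
    regions: list[TLSRegion] = field(default_factory=list)
    cells: CellMap | None = None
    config: TLSConfig | None = None

    def __len__(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        """One row per member cell: region_id, cell_id, sample_id, x, y,
        cell_type — sorted by (region_id, sample_id, cell_id)."""
        rows = []
        for r in self.regions:
            t = self.cells.table.iloc[r.member_rows]
            for cid, sid, x, y, ct in zip(
                t["cell_id"], t["sample_id"], t["x"], t["y"], t["cell_type"]
            ):
                rows.append({"region_id": r.region_id, "cell_id": cid,
                             "sample_id": sid, "x": x, "y": y,
                             "cell_type": ct})
        cols = ["region_id", "cell_id", "sample_id", "x", "y", "cell_type"]
        if not rows:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(rows).sort_values(
            ["region_id", "sample_id", "cell_id"], kind="mergesort"
        ).reset_index(drop=True)[cols]


def _single_linkage_components(xy: np.ndarray, radius: float) -> np.ndarray:
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(xy)
    adj = sp.csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def detect_tls(
    fld: ColocScoreField,
    cells: CellMap,
    config: TLSConfig | None = None,
) -> TLSRegionSet:
    """Detect TLS candidate regions from a colocalization score field.

    Per sample, cells whose (nonzero) score reaches the configured
    quantile of that sample's nonzero scores are single-linkage clustered
    at the linkage radius; components with at least ``min_cells`` members
    become regions, ordered by descending size.  No cell above threshold
    yields an empty set, not an error.
    """
    config = config or TLSConfig()
    scores = np.zeros(cells.n_cells)
    scores[fld.cell_index] = fld.scores
    labels = cells.table["cell_type"].to_numpy()
    coords = cells.coords

    components: list[tuple[str, np.ndarray]] = []
    for sid, rows in cells.sample_index().items():
        s = scores[rows]
        nonzero = s > 0
        if not nonzero.any():
            continue
        thr = np.quantile(s[nonzero], config.score_quantile)
        selected = rows[(s >= thr) & nonzero]
        if len(selected) == 0:
            continue
        comp = _single_linkage_components(
            coords[selected], config.linkage_radius_um
        )
        for c in np.unique(comp):
            members = selected[comp == c]
            if len(members) >= config.min_cells:
                components.append((sid, members))

    # deterministic ordering: descending size, then sample id, then first
    # member row
    components.sort(key=lambda sc: (-len(sc[1]), sc[0], int(sc[1][0])))
    regions = []
    for rid, (sid, members) in enumerate(components):
        pts = MultiPoint([tuple(p) for p in coords[members]])
        counts = pd.Series(labels[members]).value_counts().to_dict()
        regions.append(
            TLSRegion(
                region_id=rid,
                sample_id=sid,
                member_rows=members,
                member_cells=list(
                    cells.table["cell_id"].to_numpy()[members]
                ),
                hull=pts.convex_hull,
                type_counts={str(k): int(v) for k, v in counts.items()},
            )
        )
    return TLSRegionSet(regions=regions, cells=cells, config=config)


def _region_b_distance(
    cells: CellMap, regions: TLSRegionSet, b_label: str
) -> np.ndarray:
    """Per-cell distance to the nearest region-member B cell in the same
    sample (inf where the sample has none)."""
    labels = cells.table["cell_type"].to_numpy()
    coords = cells.coords
    b_rows_by_sample: dict[str, list[int]] = {}
    for r in regions.regions:
        b = r.member_rows[labels[r.member_rows] == b_label]
        b_rows_by_sample.setdefault(r.sample_id, []).extend(b.tolist())
    out = np.full(cells.n_cells, np.inf)
    for sid, rows in cells.sample_index().items():
        b_rows = np.array(sorted(set(b_rows_by_sample.get(sid, []))),
                          dtype=np.intp)
        if len(b_rows) == 0:
            continue
        tree = cKDTree(coords[b_rows])
        d, j = tree.query(coords[rows], k=1)
        out[rows] = np.hypot(*(coords[b_rows[j]] - coords[rows]).T)
    return out


def _neighborhood_mask(
    cells: CellMap, regions: TLSRegionSet, max_dist: float
) -> np.ndarray:
    """Members plus cells within ``max_dist`` of any region hull (same
    sample)."""
    mask = np.zeros(cells.n_cells, dtype=bool)
    sids = cells.table["sample_id"].to_numpy()
    coords = cells.coords
    for r in regions.regions:
        mask[r.member_rows] = True
        in_sample = np.flatnonzero(sids == r.sample_id)
        for row in in_sample:
            if not mask[row] and r.hull.distance(
                Point(coords[row])
            ) <= max_dist:
                mask[row] = True
    return mask


def tls_distance_composition(
    cells: CellMap,
    regions: TLSRegionSet,
    b_label: str = "B/plasma",
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-type distribution of distance to the nearest region B cell.

    Restricted to the TLS neighborhood (region members plus cells within
    the largest bin edge of any region hull).  For each cell type the
    fraction of that type's cells falling in each distance bin is
    reported; every type's curve sums to 1 over bins.  Bins are half-open
    ``[lo, hi)`` and linear in μm (default 5 μm up to 50).
    """
    if len(regions) == 0:
        raise ValidationError("no TLS regions detected")
    bins = np.arange(0.0, 55.0, 5.0) if bins is None else np.asarray(bins)
    max_dist = float(bins[-1])
    dist = _region_b_distance(cells, regions, b_label)
    if not np.isfinite(dist).any():
        raise ValidationError(
            f"no region member carries the B label {b_label!r}"
        )
    mask = _neighborhood_mask(cells, regions, max_dist)
    mask &= np.isfinite(dist) & (dist < max_dist)

    labels = cells.table["cell_type"].to_numpy()
    rows = []
    for ct in sorted(set(labels[mask])):
        sel = mask & (labels == ct)
        n_t = int(sel.sum())
        if n_t == 0:  # pragma: no cover
            continue
        which = np.digitize(dist[sel], bins[1:-1], right=False)
        for b in range(len(bins) - 1):
            rows.append(
                {
                    "cell_type": ct,
                    "bin_lo": bins[b],
                    "bin_hi": bins[b + 1],
                    "proportion": float((which == b).sum()) / n_t,
                    "n_cells": int((which == b).sum()),
                }
            )
    present = {r["cell_type"] for r in rows}
    absent = sorted(set(labels[_neighborhood_mask(cells, regions,
                                                  max_dist)]) - present)
    if absent:
        log.info("types absent from the TLS distance range: %s", absent)
    return pd.DataFrame(rows).sort_values(
        ["cell_type", "bin_lo"], kind="mergesort"
    ).reset_index(drop=True)


def _ols_slope_ci(x: np.ndarray, y: np.ndarray):
    """Closed-form OLS slope with 95% CI from the standard slope error."""
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    if n > 2:
        resid = y - (intercept + slope * x)
        se = np.sqrt((resid ** 2).sum() / (n - 2) / sxx)
        half = t_dist.ppf(0.975, n - 2) * se
        return slope, slope - half, slope + half
    return slope, np.nan, np.nan


def tls_proximity_summary(
    cells: CellMap,
    regions: TLSRegionSet,
    b_label: str = "B/plasma",
    near_radius: float = 10.0,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-type proximity share and spatial decay slope.

    For each cell type in the TLS neighborhood: the share of its cells
    within ``near_radius`` of a region B cell, and the OLS slope (per μm,
    with 95% CI) of its per-bin proportion against bin midpoints.  Types
    with fewer than 3 nonempty bins get an NA slope.
    """
    comp = tls_distance_composition(cells, regions, b_label, bins)
    dist = _region_b_distance(cells, regions, b_label)
    max_dist = comp["bin_hi"].max()
    mask = _neighborhood_mask(cells, regions, float(max_dist))
    mask &= np.isfinite(dist) & (dist < max_dist)
    labels = cells.table["cell_type"].to_numpy()

    rows = []
    for ct, grp in comp.groupby("cell_type", sort=True):
        sel = mask & (labels == ct)
        n_t = int(sel.sum())
        share = float((dist[sel] < near_radius).sum()) / n_t * 100.0
        nonempty = grp[grp["n_cells"] > 0]
        if len(nonempty) >= 3:
            mids = ((nonempty["bin_lo"] + nonempty["bin_hi"]) / 2.0
                    ).to_numpy(dtype=float)
            slope, lo, hi = _ols_slope_ci(
                mids, nonempty["proportion"].to_numpy(dtype=float)
            )
        else:
            slope = lo = hi = np.nan
        rows.append(
            {
                "cell_type": ct,
                "n_cells": n_t,
                "pct_within_near_radius": share,
                "slope_per_um": slope,
                "slope_ci_lo": lo,
                "slope_ci_hi": hi,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "cell_type", kind="mergesort"
    ).reset_index(drop=True)
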