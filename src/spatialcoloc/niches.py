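"""Spatial niche construction: k-nearest-neighbor composition vectors,
k-means clustering into niches, and lineage-based niche-class annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datatypes import CellMap
from .errors import ValidationError
from .geometry import NeighborQuery, build_neighbor_graph

__all__ = [
    "NicheConfig",
    "NicheAssignment",
    "niche_composition",
    "cluster_niches",
    "annotate_niche_classes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NicheConfig:
    k_neighbors: int = 30
    n_niches: int = 30
    seed: int = 0
    restarts: int = 10
    class_z_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.n_niches < 2:
            raise ValidationError("n_niches must be >= 2")


@dataclass
class NicheAssignment:
    """Per-cell niche ids plus the niche × cell-type profile matrix."""

    niche_id: np.ndarray            # per cell, aligned with the cell map
    niche_profiles: pd.DataFrame    # niche × cell type, rows sum to 1
    inertia: float
    config: NicheConfig
    class_label: dict[int, str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"niche_id": self.niche_id})


def niche_composition(
    cells: CellMap, k_neighbors: int = 30
) -> tuple[pd.DataFrame, bool]:
    """Per-cell cell-type fractions among the k nearest within-sample
    neighbors (self excluded).

    Returns (composition frame with one column per type, truncated flag
    set when any sample had fewer than k+1 cells).
    """
    graph = build_neighbor_graph(
        cells, NeighborQuery(mode="knn", k=k_neighbors)
    )
    types = cells.cell_types
    codes = cells.type_codes(types)
    n, T = cells.n_cells, len(types)
    deg = graph.degrees
    src = np.repeat(np.arange(n), deg)
    counts = np.zeros((n, T))
    np.add.at(counts, (src, codes[graph.indices]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / np.maximum(deg, 1)[:, None]
    return pd.DataFrame(frac, columns=types), graph.truncated


def cluster_niches(
    composition: pd.DataFrame,
    config: NicheConfig | None = None,
    cells: CellMap | None = None,
) -> NicheAssignment:
    """K-means over composition vectors with k-means++ seeding and
    ``restarts`` independent starts; deterministic given the seed.

    When ``cells`` is provided, rows are canonically ordered by
    (sample_id, cell_id) before fitting so that assignments are invariant
    to the input row order.
    """
    config = config or NicheConfig()
    X = composition.to_numpy(dtype=float)
    if len(X) < config.n_niches:
        raise ValidationError(
            f"{len(X)} composition rows < n_niches={config.n_niches}"
        )
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < config.n_niches:
        raise ValidationError(
            f"only {n_distinct} distinct composition vectors for "
            f"n_niches={config.n_niches}"
        )

    if cells is not None:
        order = np.lexsort(
            (cells.table["cell_id"].to_numpy(),
             cells.table["sample_id"].to_numpy())
        )
    else:
        order = np.arange(len(X))
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))

    km = KMeans(
        n_clusters=config.n_niches,
        init="k-means++",
        n_init=config.restarts,
        random_state=config.seed,
    ).fit(X[order])
    labels = km.labels_[inverse]

    profiles = np.zeros((config.n_niches, X.shape[1]))
    for k in range(config.n_niches):
        members = labels == k
        if members.any():
            profiles[k] = X[members].mean(axis=0)
            s = profiles[k].sum()
            if s > 0:
                profiles[k] /= s
        else:  # pragma: no cover - sklearn repairs empty clusters
            log.warning("niche %d is empty", k)
    prof = pd.DataFrame(profiles, columns=list(composition.columns))
    prof.index.name = "niche_id"
    return NicheAssignment(
        niche_id=labels,
        niche_profiles=prof,
        inertia=float(km.inertia_),
        config=config,
    )


def annotate_niche_classes(
    assignment: NicheAssignment,
    lineage_map: dict[str, str],
    class_z_threshold: float | None = None,
) -> dict[int, str]:
    """Annotate each niche by its relative lineage enrichment.

    Lineage shares per niche are z-scored across niches per lineage; the
    label is the top-z lineage, with the runner-up appended ("A+B") when
    its z reaches the threshold.  If every lineage has zero variance
    across niches, labels fall back to the globally most abundant lineage
    and ``assignment.class_fallback`` is set.
    """
    config = assignment.config
    thr = config.class_z_threshold if class_z_threshold is None \
        else class_z_threshold
    prof = assignment.niche_profiles
    unmapped = [t for t in prof.columns if t not in lineage_map]
    if unmapped:
        raise ValidationError(f"cell types missing from lineage_map: "
                              f"{unmapped}")
    lineages = sorted(set(lineage_map.values()))
    shares = pd.DataFrame(0.0, index=prof.index, columns=lineages)
    for t in prof.columns:
        shares[lineage_map[t]] += prof[t]

    mu = shares.mean(axis=0)
    sd = shares.std(axis=0, ddof=0)
    z = (shares - mu) / sd.replace(0.0, np.nan)
    z = z.fillna(0.0)

    labels: dict[int, str] = {}
    assignment.class_fallback = False
    if (sd == 0).all():
        sizes = np.bincount(assignment.niche_id,
                            minlength=len(prof)).astype(float)
        weights = shares.mul(sizes, axis=0).sum(axis=0)
        top = weights.idxmax()
        log.warning("all niches share one lineage composition; labels "
                    "fall back to %r", top)
        assignment.class_fallback = True
        for k in prof.index:
            labels[int(k)] = str(top)
    else:
        for k in prof.index:
            zk = z.loc[k].sort_values(ascending=False, kind="mergesort")
            label = str(zk.index[0])
            if len(zk) > 1 and zk.iloc[1] >= thr:
                label = f"{label}+{zk.index[1]}"
            labels[int(k)] = label
    assignment.class_label = labels
    return labels
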