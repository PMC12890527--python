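"""Cell-type neighborhood enrichment against a label-permutation null.

The directed statistic for a type pair (A, B) is the mean, over A-cells
with at least one spatial neighbor, of the fraction of B cells among those
neighbors.  The null is built by shuffling cell-type labels (within each
sample by default) with coordinates fixed, recomputing the statistic for
every permutation, and summarizing as a z-score with a permutation p-value

    p = (1 + #{null >= observed}) / (n_perm + 1)

for the one-sided enrichment alternative (mirrored for depletion, doubled
minimum for two-sided).  Benjamini-Hochberg correction is applied jointly
across all tested directed pairs.

``exhaustive_null`` provides the exact small-instance analogue in which the
null enumerates every distinct label assignment.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import CellMap
from .errors import ValidationError
from .geometry import NeighborGraph, NeighborQuery, build_neighbor_graph

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "neighborhood_composition",
    "enrichment_test",
    "exhaustive_null",
]

log = logging.getLogger(__name__)

_TOL = 1e-12  # float tolerance for >=/<= comparisons against the observed


@dataclass(frozen=True)
class EnrichmentConfig:
    query: NeighborQuery = field(
        default_factory=lambda: NeighborQuery(mode="radius", radius_um=30.0)
    )
    n_perm: int = 1000
    seed: int = 0
    min_cells_per_type: int = 10
    alternative: str = "enrichment"  # enrichment | depletion | two-sided
    within_sample_permutation: bool = True
    threads: int = 1

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.alternative not in {"enrichment", "depletion", "two-sided"}:
            raise ValidationError(
                f"unknown alternative {self.alternative!r}"
            )


@dataclass
class EnrichmentResult:
    """Directed type-pair table plus the config that produced it.

    ``table`` columns: anchor_type, target_type, observed_stat, perm_mean,
    perm_sd, z, p_perm, p_adj, n_anchor_cells, status.  Sorted by
    (anchor_type, target_type).
    """

    table: pd.DataFrame
    config: EnrichmentConfig
    n_labelings: int | None = None  # set by exhaustive_null

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def pair(self, anchor: str, target: str) -> pd.Series:
        t = self.table
        row = t[(t.anchor_type == anchor) & (t.target_type == target)]
        if row.empty:
            raise KeyError((anchor, target))
        return row.iloc[0]


def neighborhood_composition(
    cells: CellMap, graph: NeighborGraph
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell fraction of each cell type among its neighbors.

    Returns (composition DataFrame indexed like the cell table with one
    column per type, boolean flag array marking zero-neighbor cells whose
    rows are all-zero).
    """
    types = cells.cell_types
    codes = cells.type_codes(types)
    n, T = cells.n_cells, len(types)
    deg = graph.degrees
    src = np.repeat(np.arange(n), deg)
    counts = np.zeros((n, T))
    np.add.at(counts, (src, codes[graph.indices]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / deg[:, None]
    isolated = deg == 0
    frac[isolated] = 0.0
    return pd.DataFrame(frac, columns=types), isolated


class _StatEngine:
    """Precomputed arrays for fast repeated evaluation of the pair statistic
    under relabelings.  Geometry (the graph) is fixed; only labels move."""

    def __init__(self, cells: CellMap, graph: NeighborGraph,
                 types: list[str]):
        self.types = types
        self.T = len(types)
        self.n = cells.n_cells
        deg = graph.degrees
        src = np.repeat(np.arange(self.n), deg)
        self.tgt = graph.indices
        with np.errstate(divide="ignore"):
            w = 1.0 / deg[src]
        self.src = src
        self.w = w
        self.has_nbrs = deg > 0
        self.codes = cells.type_codes(types)

    def stat(self, codes: np.ndarray) -> np.ndarray:
        """(T, T) matrix of mean neighbor fractions for one labeling.

        Anchor cells with zero neighbors are excluded from the mean; an
        anchor type with no contributing cells yields 0 (the degenerate
        all-isolated contract).
        """
        T = self.T
        flat = codes[self.src] * T + codes[self.tgt]
        S = np.bincount(flat, weights=self.w, minlength=T * T)
        S = S.reshape(T, T)
        denom = np.bincount(codes[self.has_nbrs], minlength=T).astype(float)
        out = np.zeros((T, T))
        ok = denom > 0
        out[ok] = S[ok] / denom[ok, None]
        return out


def _perm_codes(codes, sample_rows, rng, within_sample):
    p = codes.copy()
    if within_sample:
        for rows in sample_rows:
            p[rows] = p[rows[rng.permutation(len(rows))]]
    else:
        p = p[rng.permutation(len(p))]
    return p


def _pvalues(obs, null, alternative, n_eff):
    """Permutation p per pair from a stack of null matrices."""
    ge = (null >= obs[None] - _TOL).sum(axis=0)
    le = (null <= obs[None] + _TOL).sum(axis=0)
    p_enr = (1.0 + ge) / (n_eff + 1.0)
    p_dep = (1.0 + le) / (n_eff + 1.0)
    if alternative == "enrichment":
        return p_enr
    if alternative == "depletion":
        return p_dep
    return np.minimum(1.0, 2.0 * np.minimum(p_enr, p_dep))


def _assemble(types, obs, null, p_perm, tested_mask, n_anchor, config,
              n_labelings=None):
    perm_mean = null.mean(axis=0)
    perm_sd = null.std(axis=0, ddof=1) if null.shape[0] > 1 else \
        np.zeros_like(obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - perm_mean) / perm_sd
    z[perm_sd == 0] = np.nan

    rows = []
    for i, a in enumerate(types):
        for j, b in enumerate(types):
            tested = bool(tested_mask[i] and tested_mask[j])
            rows.append(
                {
                    "anchor_type": a,
                    "target_type": b,
                    "observed_stat": obs[i, j] if tested else np.nan,
                    "perm_mean": perm_mean[i, j] if tested else np.nan,
                    "perm_sd": perm_sd[i, j] if tested else np.nan,
                    "z": z[i, j] if tested else np.nan,
                    "p_perm": p_perm[i, j] if tested else np.nan,
                    "n_anchor_cells": int(n_anchor[i]),
                    "status": "tested" if tested else "skipped_low_count",
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["anchor_type", "target_type"], kind="mergesort"
    ).reset_index(drop=True)

    table["p_adj"] = np.nan
    tested_rows = table["status"] == "tested"
    if tested_rows.any():
        _, p_adj, _, _ = multipletests(
            table.loc[tested_rows, "p_perm"], method="fdr_bh"
        )
        table.loc[tested_rows, "p_adj"] = p_adj
    table = table[
        ["anchor_type", "target_type", "observed_stat", "perm_mean",
         "perm_sd", "z", "p_perm", "p_adj", "n_anchor_cells", "status"]
    ]
    return EnrichmentResult(table=table, config=config,
                            n_labelings=n_labelings)


def _prepare(cells: CellMap, config: EnrichmentConfig):
    types = cells.cell_types
    graph = build_neighbor_graph(cells, config.query)
    eng = _StatEngine(cells, graph, types)

    # a type is tested unless it is below the minimum count in every sample
    per_sample = cells.table.groupby(
        ["sample_id", "cell_type"], observed=True
    ).size().unstack(fill_value=0)
    max_count = per_sample.max(axis=0).reindex(types, fill_value=0)
    tested_mask = (max_count >= config.min_cells_per_type).to_numpy()
    if tested_mask.sum() < 2:
        raise ValidationError(
            "fewer than 2 cell types pass min_cells_per_type="
            f"{config.min_cells_per_type}"
        )
    n_anchor = np.bincount(eng.codes[eng.has_nbrs], minlength=eng.T)
    return types, eng, tested_mask, n_anchor


def enrichment_test(
    cells: CellMap, config: EnrichmentConfig | None = None
) -> EnrichmentResult:
    """Monte-Carlo neighborhood enrichment test (label-shuffling null).

    Per-permutation sub-seeds derive deterministically from ``config.seed``
    by counter, so results are identical for any thread count.
    """
    config = config or EnrichmentConfig()
    types, eng, tested_mask, n_anchor = _prepare(cells, config)
    obs = eng.stat(eng.codes)

    sample_rows = list(cells.sample_index().values())
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_perm)

    def one_perm(i):
        rng = np.random.default_rng(seeds[i])
        codes = _perm_codes(eng.codes, sample_rows, rng,
                            config.within_sample_permutation)
        return eng.stat(codes)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            null = np.stack(list(pool.map(one_perm, range(config.n_perm))))
    else:
        null = np.stack([one_perm(i) for i in range(config.n_perm)])

    p_perm = _pvalues(obs, null, config.alternative, config.n_perm)
    return _assemble(types, obs, null, p_perm, tested_mask, n_anchor, config)


def _count_labelings(counts_per_sample: list[np.ndarray]) -> int:
    total = 1
    for counts in counts_per_sample:
        n = int(counts.sum())
        c = math.factorial(n)
        for k in counts:
            c //= math.factorial(int(k))
        total *= c
    return total


def _multiset_perms(codes: np.ndarray):
    """Yield all distinct arrangements of a label-code multiset, in
    lexicographic order (iterative next-permutation)."""
    a = np.sort(codes).tolist()
    n = len(a)
    while True:
        yield np.array(a, dtype=np.intp)
        i = n - 2
        while i >= 0 and a[i] >= a[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while a[j] <= a[i]:
            j -= 1
        a[i], a[j] = a[j], a[i]
        a[i + 1:] = reversed(a[i + 1:])


def exhaustive_null(
    cells: CellMap,
    config: EnrichmentConfig | None = None,
    max_labelings: int = 10 ** 6,
) -> EnrichmentResult:
    """Exact enrichment test enumerating every distinct label assignment.

    Within-sample structure is respected: the enumeration is the Cartesian
    product of per-sample multiset permutations.  The exact p-value is the
    fraction of labelings whose statistic is at least (at most, for
    depletion) the observed one; the observed labeling is always a member
    of the enumeration, so p >= 1/n_labelings.
    """
    config = config or EnrichmentConfig()
    types, eng, tested_mask, n_anchor = _prepare(cells, config)
    obs = eng.stat(eng.codes)

    sample_rows = list(cells.sample_index().values())
    counts = [np.bincount(eng.codes[rows], minlength=eng.T)
              for rows in sample_rows]
    n_labelings = _count_labelings(counts)
    if n_labelings > max_labelings:
        raise ValidationError(
            f"{n_labelings} distinct labelings exceed the exhaustive "
            f"bound of {max_labelings}"
        )

    null = np.empty((n_labelings, eng.T, eng.T))
    base = eng.codes.copy()
    for idx, combo in enumerate(
        product(*[_multiset_perms(eng.codes[rows]) for rows in sample_rows])
    ):
        for rows, arrangement in zip(sample_rows, combo):
            base[rows] = arrangement
        null[idx] = eng.stat(base)

    ge = (null >= obs[None] - _TOL).sum(axis=0)
    le = (null <= obs[None] + _TOL).sum(axis=0)
    p_enr = ge / n_labelings
    p_dep = le / n_labelings
    if config.alternative == "enrichment":
        p = p_enr
    elif config.alternative == "depletion":
        p = p_dep
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_enr, p_dep))
    return _assemble(types, obs, null, p, tested_mask, n_anchor, config,
                     n_labelings=n_labelings)
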