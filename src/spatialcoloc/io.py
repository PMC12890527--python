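"""Readers and writers for the standard on-disk formats.

Supported inputs: delimited cell tables (Xenium ``cells.csv`` dialect),
10x-style MatrixMarket triplet directories, GMT gene sets and plain gene
lists.  Outputs are TSV tables (floats at 6 significant digits, ``inf`` /
``NA`` spelled out) and GeoJSON polygons for TLS hulls.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CellMap, ExpressionMatrix, GeneSet
from .errors import FormatError

__all__ = [
    "read_cell_table",
    "read_expression_mtx",
    "read_gene_sets_gmt",
    "read_gene_list",
    "write_result_table",
    "write_geojson",
    "DEFAULT_COLUMN_MAP",
]

log = logging.getLogger(__name__)

#: Xenium ``cells.csv`` dialect.
DEFAULT_COLUMN_MAP = {
    "cell_id": "cell_id",
    "x": "x_centroid",
    "y": "y_centroid",
    "cell_type": "cell_type",
    "sample_id": "sample_id",
    "lineage": "lineage",
}

_OPTIONAL_COLUMNS = ("sample_id", "lineage")


def read_cell_table(
    path: str | os.PathLike,
    column_map: dict[str, str] | None = None,
    unit_scale: float = 1.0,
) -> CellMap:
    """Read a delimited cell table into a :class:`CellMap`.

    ``column_map`` maps canonical names (``cell_id``, ``x``, ``y``,
    ``cell_type``, optionally ``sample_id`` and ``lineage``) to the file's
    column names; unmapped optional columns fall back to defaults.
    Coordinates are multiplied by ``unit_scale`` (μm per coordinate unit).
    Rows with a missing or empty cell-type label are dropped with a logged
    count; output row order equals input row order after that filter.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cell table not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype={0: str})

    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    for key in ("cell_id", "x", "y", "cell_type"):
        col = cmap[key]
        if col not in raw.columns:
            raise FormatError(
                f"required column {col!r} (mapped from {key!r}) "
                f"missing from {path.name}"
            )

    out = pd.DataFrame(
        {
            "cell_id": raw[cmap["cell_id"]].astype(str),
            "x": raw[cmap["x"]].astype(float) * unit_scale,
            "y": raw[cmap["y"]].astype(float) * unit_scale,
            "cell_type": raw[cmap["cell_type"]],
        }
    )
    if cmap["sample_id"] in raw.columns:
        out["sample_id"] = raw[cmap["sample_id"]].astype(str)
    else:
        out["sample_id"] = "sample0"
    if cmap["lineage"] in raw.columns:
        out["lineage"] = raw[cmap["lineage"]]
    out = out[["cell_id", "sample_id", "x", "y", "cell_type"]
              + (["lineage"] if "lineage" in out.columns else [])]

    label = out["cell_type"]
    keep = label.notna() & (label.astype(str).str.strip() != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d cells with missing cell_type label", n_dropped)
        out = out.loc[keep]
    out["cell_type"] = out["cell_type"].astype(str)
    cm = CellMap(out.reset_index(drop=True))
    cm.n_dropped_unlabeled = n_dropped
    return cm


def _open_maybe_gz(base: Path):
    for cand in (base, base.with_name(base.name + ".gz")):
        if cand.exists():
            if cand.suffix == ".gz":
                return gzip.open(cand, "rt")
            return open(cand, "rt")
    raise FormatError(f"file not found: {base} (or {base.name}.gz)")


def read_expression_mtx(mtx_dir: str | os.PathLike) -> ExpressionMatrix:
    """Read a 10x MatrixMarket triplet directory into cells × genes.

    Expects ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``, each optionally gzipped.  The on-disk matrix may be
    oriented either way; orientation is resolved against the id-file
    lengths, and genes-as-rows input is transposed.
    """
    d = Path(mtx_dir)
    with _open_maybe_gz(d / "matrix.mtx") as fh:
        mat = scipy.io.mmread(fh)
    feat_base = d / "features.tsv"
    if not feat_base.exists() and not feat_base.with_suffix(".tsv.gz").exists():
        if (d / "genes.tsv").exists() or (d / "genes.tsv.gz").exists():
            feat_base = d / "genes.tsv"
    with _open_maybe_gz(feat_base) as fh:
        feats = pd.read_csv(fh, sep="\t", header=None)
    with _open_maybe_gz(d / "barcodes.tsv") as fh:
        barcodes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    # 10x features files carry (id, symbol, type); use the symbol column
    # when present, else the first column.
    genes = list(feats[1] if feats.shape[1] > 1 else feats[0])
    genes = [str(g) for g in genes]

    mat = sp.csr_matrix(mat)
    n_genes, n_cells = len(genes), len(barcodes)
    if mat.shape == (n_cells, n_genes) and mat.shape != (n_genes, n_cells):
        pass  # already cells × genes
    elif mat.shape == (n_genes, n_cells):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"{n_genes} features × {n_cells} barcodes nor its transpose"
        )
    return ExpressionMatrix(cell_ids=barcodes, genes=genes, X=mat)


def write_expression_mtx(expr: ExpressionMatrix,
                         mtx_dir: str | os.PathLike) -> None:
    """Write a 10x-style uncompressed MTX triplet (genes × cells on disk)."""
    d = Path(mtx_dir)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(expr.X.T))
    with open(d / "features.tsv", "w") as fh:
        for g in expr.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(d / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(expr.cell_ids) + "\n")


def read_gene_sets_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Parse a GMT file (name, description, genes...) into gene sets."""
    sets = []
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], genes=set(parts[2:])))
    if not sets:
        raise FormatError(f"no gene sets parsed from {path}")
    return sets


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        genes = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    if not genes:
        raise FormatError(f"no genes parsed from {path}")
    return genes


def write_result_table(result, path: str | os.PathLike) -> None:
    """Write any tabular result as TSV.

    Results expose ``to_frame()`` (or already are DataFrames).  Floats are
    written at 6 significant digits, missing values as ``NA`` and infinities
    as ``inf``.  Row order is the result type's documented sort order, which
    ``to_frame`` implementations guarantee.
    """
    if result is None:
        raise ValueError("result is None")
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(result).__name__}")
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g",
                 na_rep="NA")


def write_geojson(regions, path: str | os.PathLike) -> None:
    """Write TLS hull polygons as a GeoJSON FeatureCollection."""
    from shapely.geometry import mapping

    features = []
    for r in regions.regions:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.hull),
                "properties": {
                    "region_id": int(r.region_id),
                    "sample_id": r.sample_id,
                    "n_cells": len(r.member_cells),
                    "type_counts": {k: int(v)
                                    for k, v in r.type_counts.items()},
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
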