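"""Readers and writers for the plain-text formats the pipeline touches.

Expression tables are delimited text with a header row; sparse cell/spot
matrices arrive as a MatrixMarket triplet plus feature/barcode lists (the
10x-style export); gene sets are GMT lines; networks go out as an edge-list
TSV or GraphML (Cytoscape-ready) and round-trip losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    ValidationError,
    WeightedNetwork,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(
    path, unit: str, genes_in_rows: bool = True, sep: str = "\t"
) -> ExpressionMatrix:
    """Read a delimited gene x sample table (first column = gene ids).

    Set ``genes_in_rows=False`` for a transposed (samples-in-rows) layout.
    Duplicate identifiers and non-numeric cells are rejected with an error
    naming the offender.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if not genes_in_rows:
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate gene id {dup[0]!r}")
    dup = df.columns[df.columns.duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate sample id {dup[0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any() and not df[col].isna().any():
                row = df.index[bad.isna().argmax()]
                raise ValidationError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(list(df.index), list(df.columns), values, unit)


def write_expression_table(m: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write a matrix as delimited text with full float precision."""
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_sparse_counts(matrix_path, features_path, barcodes_path) -> ExpressionMatrix:
    """Read a MatrixMarket triplet with companion feature/barcode lists.

    Indices on disk are 1-based per the MatrixMarket convention; the list
    files carry one identifier per line (extra tab-separated columns, as in
    10x feature files, are ignored beyond the first).
    """
    mat = scipy.io.mmread(matrix_path)
    mat = scipy.sparse.coo_matrix(mat)
    features = _read_id_list(features_path)
    barcodes = _read_id_list(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise ValidationError(
            f"{matrix_path}: declared shape {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    dense = np.asarray(mat.todense(), dtype=float)
    return ExpressionMatrix(features, barcodes, dense, "counts")


def write_sparse_counts(m: ExpressionMatrix, matrix_path, features_path,
                        barcodes_path) -> None:
    sparse = scipy.sparse.coo_matrix(m.values)
    scipy.io.mmwrite(str(matrix_path), sparse)
    Path(features_path).write_text("".join(f"{g}\n" for g in m.gene_ids))
    Path(barcodes_path).write_text("".join(f"{s}\n" for s in m.sample_ids))


def _read_id_list(path) -> list[str]:
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            ids.append(line.split("\t")[0])
    return ids


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_annotation(path, sep: str = "\t") -> SampleAnnotation:
    """Read a sample annotation table (sample_id, patient_id, site[, x, y])."""
    return SampleAnnotation(pd.read_csv(path, sep=sep))


def write_annotation(ann: SampleAnnotation, path, sep: str = "\t") -> None:
    ann.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, category: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``name <tab> description <tab> member...`` per line.

    Duplicate members within a line are collapsed; duplicate set names and
    lines with fewer than three fields are errors.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs name, description and "
                f"at least one member (got {len(fields)} fields)"
            )
        name = fields[0].strip()
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = frozenset(m.strip() for m in fields[2:] if m.strip())
        if not members:
            raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
    return GeneSetCollection(category or Path(path).stem, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, collection.category, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(net: WeightedNetwork, path, fmt: str = "edgelist") -> None:
    """Export a network as an edge-list TSV or GraphML.

    The edge list carries ``source, target, weight, sign`` (isolated nodes
    in a companion node section are not represented; use GraphML to preserve
    them together with module labels and site overlays).
    """
    path = Path(path)
    if fmt == "edgelist":
        rows = [
            {"source": u, "target": v, "weight": d["weight"],
             "sign": int(d.get("sign", 1))}
            for u, v, d in net.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> WeightedNetwork:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        clean = nx.Graph()
        for n, d in g.nodes(data=True):
            attrs = {"module": int(d.get("module", 0))}
            attrs.update({k: float(v) for k, v in d.items()
                          if k.startswith("overlay_")})
            clean.add_node(str(n), **attrs)
        for u, v, d in g.edges(data=True):
            clean.add_edge(str(u), str(v), weight=float(d["weight"]),
                           sign=int(d.get("sign", 1)))
        return WeightedNetwork(clean)
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(str(row.source), str(row.target),
                       weight=float(row.weight), sign=int(row.sign))
        return WeightedNetwork(g)
    raise ValueError(f"unknown network format {fmt!r}")
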