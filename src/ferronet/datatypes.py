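"""Core data containers shared by every pipeline stage.

The pipeline moves gene x sample abundance tables (bulk cohorts, cell and
spot matrices), sample metadata, gene-set collections and weighted gene
networks between stages.  Each container validates its invariants on
construction so that format errors surface at the boundary, naming the
offending record, rather than deep inside a computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

#: abundance units the pipeline understands; ``log2p1`` marks values that
#: have already been through ``log2(x + 1)``.
VALID_UNITS = ("TPM", "FPKM", "counts", "log2p1")

#: bulk anatomical sites: matched adjacent normal, inner tumor core,
#: invasive front, metastasis.
BULK_SITES = ("N", "IC", "IF", "M")

TUMOR_SITES = ("IC", "IF", "M")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with a unit tag.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered unique identifiers (case-sensitive, whitespace-stripped).
    values
        ``(n_genes, n_samples)`` float array.  Non-negative unless
        ``unit == "log2p1"`` (a log ratio overlay never lives here).
    unit
        One of :data:`VALID_UNITS`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in VALID_UNITS:
            raise ValidationError(
                f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}"
            )
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D gene x sample array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.unit != "log2p1" and np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r} (unit {self.unit})"
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), unit)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, cols], self.unit)


@dataclass
class SampleAnnotation:
    """Per-column metadata: patient, site/cluster label, optional coordinates.

    For bulk cohorts ``site`` is one of N/IC/IF/M; for cell or spot matrices
    it holds the cluster or region label.  ``x``/``y`` columns are spot
    lattice coordinates when present.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "site")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        t = t.copy()
        for col in self.REQUIRED:
            t[col] = t[col].astype(str).str.strip()
        _check_unique(list(t["sample_id"]), "sample")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["site"]))

    def patient_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["patient_id"]))

    def check_against(self, m: ExpressionMatrix) -> None:
        """Every annotated sample must exist in the companion matrix."""
        missing = sorted(set(self.sample_ids) - set(m.sample_ids))
        if missing:
            raise ValidationError(
                f"annotated samples absent from matrix: {missing[:5]}"
            )

    def check_matched_normals(self) -> None:
        """Gradient analysis requires a site-N sample for every tumor patient."""
        t = self.table
        normals = set(t.loc[t["site"] == "N", "patient_id"])
        tumors = t[t["site"].isin(TUMOR_SITES)]
        orphans = sorted(set(tumors["patient_id"]) - normals)
        if orphans:
            raise ValidationError(
                f"tumor samples without a matched normal for patients: {orphans[:5]}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets grouped under one annotation category.

    ``category`` is e.g. ``ferroptosis``/``inflammation``/``GO-BP``/``KEGG``;
    set membership is deduplicated and order-free.
    """

    category: str
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            name = str(name).strip()
            if name in clean:
                raise ValidationError(
                    f"duplicate set name {name!r} in category {self.category!r}"
                )
            fs = frozenset(str(m).strip() for m in members)
            if not fs:
                raise ValidationError(
                    f"empty gene set {name!r} in category {self.category!r}"
                )
            clean[name] = fs
        self.sets = clean

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


class WeightedNetwork:
    """Undirected weighted gene graph with module labels and site overlays.

    Backed by a :class:`networkx.Graph`; edge attributes are ``weight``
    (in ``(0, 1]``) and ``sign`` (+1/-1, the sign of the underlying
    correlation), node attributes are ``module`` (int, 0 = unassigned) and
    one ``overlay_<site>`` float per overlay key.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self.validate()

    @classmethod
    def build(
        cls,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str, float, int]],
        modules: Mapping[str, int] | None = None,
        overlays: Mapping[str, Mapping[str, float]] | None = None,
    ) -> "WeightedNetwork":
        """Assemble from explicit parts; ``edges`` yields (u, v, weight, sign)."""
        g = nx.Graph()
        for n in nodes:
            g.add_node(str(n), module=int(modules.get(n, 0)) if modules else 0)
        for u, v, w, s in edges:
            g.add_edge(str(u), str(v), weight=float(w), sign=int(s))
        if overlays:
            for site, values in overlays.items():
                for n, val in values.items():
                    if n in g:
                        g.nodes[n][f"overlay_{site}"] = float(val)
        return cls(g)

    def validate(self) -> None:
        g = self.graph
        for u, v, data in g.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = data.get("weight")
            if w is None or not (0 < w <= 1):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) weight {w} outside (0, 1]"
                )
        for n, data in g.nodes(data=True):
            data.setdefault("module", 0)

    # -- views -------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def module_of(self) -> dict[str, int]:
        return {n: int(d.get("module", 0)) for n, d in self.graph.nodes(data=True)}

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def subgraph(self, nodes: Iterable[str]) -> "WeightedNetwork":
        return WeightedNetwork(self.graph.subgraph(list(nodes)).copy())

    def structurally_equal(self, other: "WeightedNetwork", tol: float = 1e-12) -> bool:
        """Same node set, module labels and edge multiset (weights to ``tol``)."""
        if set(self.nodes) != set(other.nodes):
            return False
        if self.module_of() != other.module_of():
            return False
        if self.n_edges != other.n_edges:
            return False
        for u, v, d in self.graph.edges(data=True):
            if not other.graph.has_edge(u, v):
                return False
            od = other.graph.edges[u, v]
            if abs(d["weight"] - od["weight"]) > tol:
                return False
            if int(d.get("sign", 1)) != int(od.get("sign", 1)):
                return False
        return True


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the published defaults.

    Switch-style fields expose the choices the method leaves open:
    correlation estimator, adjacency signedness, tree-cut variant, which
    quantity an edge "weight" refers to during trimming, score aggregation
    and top-N ranking key.
    """

    # network construction
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_cut: float = 0.7
    deep_split: int = 2
    min_module_size: int = 5
    correlation: str = "pearson"          # pearson | spearman
    signed: bool = False                  # unsigned |cor|^beta by default
    treecut_variant: str = "hybrid"       # hybrid | tree
    # annotation + trimming
    q_cut: float = 0.05
    top_terms: int = 20
    edge_floor: float = 0.01
    max_edges_per_node: int = 50
    edge_weight_kind: str = "tom"         # tom | adjacency | correlation
    # scoring / stratification / intersection
    high_cut: float = 5.0
    low_cut: float = 3.0
    fc_cut: float = 1.5
    top_n: int = 1500
    score_agg: str = "mean"               # mean | sum
    rank_by: str = "fc"                   # fc | p
    patient_summary: str = "median"       # median | pooled
    seed: int = 0

    def __post_init__(self) -> None:
        if self.high_cut <= self.low_cut:
            raise ValidationError("high_cut must exceed low_cut")
        for name in ("min_module_size", "top_terms", "max_edges_per_node", "top_n"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        for name in ("scale_free_cut", "q_cut", "edge_floor", "fc_cut"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not (0 < self.q_cut < 1):
            raise ValidationError("q_cut must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "candidate_powers" in raw:
            raw["candidate_powers"] = tuple(int(p) for p in raw["candidate_powers"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["candidate_powers"] = list(self.candidate_powers)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
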