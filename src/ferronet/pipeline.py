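"""End-to-end orchestration of the cohort analysis.

Chains the stages: sparse-gene filter and log2 transform, correlation,
soft-threshold selection, adjacency, TOM, average linkage, dynamic cut,
hypergeometric module annotation, network trimming, signature-subnetwork
extraction and the gradient decision.  Each stage remains individually
callable; this module only wires them with a shared config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import gradient as grad_mod
from . import network as net_mod
from . import preprocess, treecut
from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    PipelineConfig,
    SampleAnnotation,
    WeightedNetwork,
)

log = logging.getLogger(__name__)

#: a module's mean within-similarity must exceed this multiple of the
#: 99.9th-percentile permutation-null TOM similarity of the same data
NOISE_FLOOR_MULTIPLIER = 2.0


@dataclass
class NetworkResult:
    """Everything the network stage produces, on one gene universe."""

    gene_ids: list[str]
    scan: net_mod.SoftThresholdScan
    cor: np.ndarray
    tom: np.ndarray
    labels: np.ndarray            # module label per gene, 0 = unassigned

    def module_of(self) -> dict[str, int]:
        return {g: int(m) for g, m in zip(self.gene_ids, self.labels)}

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "module": self.labels})


def build_network(m: ExpressionMatrix,
                  config: PipelineConfig | None = None) -> NetworkResult:
    """Run the full network stage on an abundance matrix.

    Accepts TPM/FPKM/counts (filtered for sparse genes, then log2(x+1)
    transformed) or an already-transformed log2p1 matrix.  Zero-variance
    genes are removed with a logged warning before correlation.
    """
    config = config or PipelineConfig()
    if m.unit != "log2p1":
        m = preprocess.filter_sparse_genes(m)
        m = preprocess.log2_transform(m)
    sd = m.values.std(axis=1)
    if np.any(sd == 0):
        dropped = [g for g, s in zip(m.gene_ids, sd) if s == 0]
        log.warning("dropping %d zero-variance genes before correlation",
                    len(dropped))
        keep = [g for g, s in zip(m.gene_ids, sd) if s > 0]
        m = m.subset_genes(keep)
    cor = net_mod.correlation_matrix(m.values, m.gene_ids,
                                     method=config.correlation)
    scan = net_mod.select_power(cor, config.candidate_powers,
                                config.scale_free_cut, signed=config.signed)
    adj = net_mod.adjacency(cor, scan.selected, signed=config.signed)
    tom = net_mod.tom_similarity(adj)
    linkage = net_mod.average_linkage(1.0 - tom)
    floor = NOISE_FLOOR_MULTIPLIER * net_mod.permutation_noise_floor(
        m.values, scan.selected, signed=config.signed)
    labels = treecut.cut_dynamic(
        linkage, 1.0 - tom,
        deep_split=config.deep_split,
        min_module_size=config.min_module_size,
        variant=config.treecut_variant,
        min_within_sim=floor,
    )
    n_mod = int(labels.max())
    log.info("network stage: beta=%d, %d modules, %d/%d genes assigned",
             scan.selected, n_mod, int((labels > 0).sum()), len(m.gene_ids))
    return NetworkResult(list(m.gene_ids), scan, cor, tom, labels)


@dataclass
class CohortResult:
    """Full cohort analysis: network, annotation, subnetworks, gradients."""

    network: NetworkResult
    records: list = field(default_factory=list)
    representative: dict = field(default_factory=dict)
    trimmed: WeightedNetwork | None = None
    subnetworks: dict = field(default_factory=dict)   # signature -> node set
    gradient_table: pd.DataFrame | None = None
    verdicts: dict = field(default_factory=dict)      # signature -> verdict


def run_cohort(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    collections: list[GeneSetCollection],
    config: PipelineConfig | None = None,
    signature_category: str = "signatures",
) -> CohortResult:
    """Cohort pipeline from abundances to per-signature gradient verdicts.

    ``collections`` must include one category named ``signature_category``
    holding the named signature sets; any further collections (GO/KEGG
    style) contribute representative terms for trimming only.
    """
    config = config or PipelineConfig()
    net = build_network(matrix, config)
    background = net.gene_ids
    module_of = net.module_of()

    records = ann_mod.annotate_modules(module_of, collections, background)
    representative = ann_mod.representative_terms(
        records, top=config.top_terms, q_cut=config.q_cut)
    keep = ann_mod.representative_gene_union(representative, collections,
                                             background)
    result = CohortResult(net, records, representative)
    if not keep:
        log.warning("no representative terms at q <= %g; nothing to trim",
                    config.q_cut)
        return result

    weights = {"tom": net.tom,
               "adjacency": np.abs(net.cor) ** scan_power(net),
               "correlation": net.cor}[config.edge_weight_kind]
    result.trimmed = ann_mod.trim_network(
        net.cor, weights, net.gene_ids, keep, module_of,
        edge_floor=config.edge_floor,
        max_edges_per_node=config.max_edges_per_node,
    )

    sigs = next((c for c in collections if c.category == signature_category),
                None)
    if sigs is None:
        log.warning("no %r collection supplied; skipping subnetworks",
                    signature_category)
        return result

    table = grad_mod.tn_log_ratio(matrix, annotation,
                                  summary=config.patient_summary)
    result.gradient_table = table
    sig_records = [r for r in records if r.collection == signature_category]
    for name, genes in sigs:
        nodes, _sub = ann_mod.signature_subnetwork(
            result.trimmed, sig_records, name, genes, q_cut=config.q_cut)
        result.subnetworks[name] = nodes
        if nodes:
            sub_table = table[table["gene_id"].isin(nodes)]
            try:
                result.verdicts[name] = grad_mod.classify_gradient(
                    sub_table, name=name)
            except Exception as exc:  # a site can be empty on tiny inputs
                log.warning("gradient verdict for %r failed: %s", name, exc)
    return result


def scan_power(net: NetworkResult) -> int:
    return net.scan.selected
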