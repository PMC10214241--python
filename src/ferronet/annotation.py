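"""Module annotation against gene-set collections and network reduction.

Modules from the tree cut are characterized by upper-tail hypergeometric
enrichment against each gene-set collection (GO-BP, GO-CC, KEGG and the
named signature sets), with Benjamini-Hochberg adjustment per collection.
The full network is then trimmed to the genes of representatively enriched
terms with a positive-sign, weight-floor, per-node top-k edge filter, and a
signature-related subnetwork is the union of every enriched,
signature-containing module with its direct neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datatypes import GeneSetCollection, ValidationError, WeightedNetwork

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------

def hypergeom_pval(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value, computed in log space.

    Probability of drawing at least ``k`` set members in a sample of ``n``
    genes from a background of ``N`` genes of which ``K`` are in the set:
    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n).
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= min(n, K) and K <= N and n <= N and n >= 0 and K >= 0):
        raise ValidationError(
            f"invalid hypergeometric counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0  # the full tail is certain
    upper = min(n, K)
    i = np.arange(k, upper + 1)
    log_terms = (
        _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    )
    # stable log-sum-exp, then clip the inevitable rounding excursion
    m = log_terms.max()
    p = float(np.exp(m) * np.exp(log_terms - m).sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j) over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# module annotation
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    """One module x gene-set hypergeometric result."""

    module: int
    collection: str
    set_name: str
    k: int       # overlap
    n: int       # module size (within background)
    K: int       # set size within background
    N: int       # background size
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.K <= self.N
                and self.n <= self.N):
            raise ValidationError(f"inconsistent enrichment counts: {self}")


def annotate_modules(
    module_of: dict[str, int],
    collections: list[GeneSetCollection],
    background: list[str],
) -> list[EnrichmentRecord]:
    """Hypergeometric annotation of every module against every collection.

    The background is the gene universe that entered network construction;
    sets are intersected with it before counting, and a set entirely
    outside the background is skipped with a warning.  BH adjustment is
    applied within each collection (one family per annotation category).
    """
    bg = set(background)
    if not bg:
        raise ValidationError("empty enrichment background")
    outside = set(module_of) - bg
    if outside:
        raise ValidationError(
            f"module genes missing from background: {sorted(outside)[:5]}"
        )
    N = len(bg)
    modules = sorted({m for m in module_of.values() if m != 0})
    members = {m: {g for g, lab in module_of.items() if lab == m}
               for m in modules}

    records: list[EnrichmentRecord] = []
    for coll in collections:
        family: list[EnrichmentRecord] = []
        for set_name, genes in coll:
            in_bg = genes & bg
            if not in_bg:
                log.warning("set %r (%s) has no genes in background; skipped",
                            set_name, coll.category)
                continue
            for m in modules:
                mod = members[m]
                rec = EnrichmentRecord(
                    module=m, collection=coll.category, set_name=set_name,
                    k=len(mod & in_bg), n=len(mod), K=len(in_bg), N=N,
                    p=hypergeom_pval(len(mod & in_bg), len(mod), len(in_bg), N),
                )
                family.append(rec)
        if family:
            qs = bh_adjust([r.p for r in family])
            for rec, q in zip(family, qs):
                rec.q = float(q)
        records.extend(family)
    return records


def representative_terms(
    records: list[EnrichmentRecord],
    top: int = 20,
    q_cut: float = 0.05,
) -> dict[str, list[str]]:
    """Representatively enriched terms per annotation category.

    Within each collection, unique terms are ranked by their best q
    (ties by ascending p, then name), truncated to the top ``top``, and
    filtered to q <= ``q_cut``.
    """
    by_cat: dict[str, dict[str, tuple[float, float]]] = {}
    for r in records:
        best = by_cat.setdefault(r.collection, {})
        cur = best.get(r.set_name)
        if cur is None or (r.q, r.p) < cur:
            best[r.set_name] = (r.q, r.p)
    out: dict[str, list[str]] = {}
    for cat, terms in by_cat.items():
        ranked = sorted(terms, key=lambda t: (terms[t][0], terms[t][1], t))
        out[cat] = [t for t in ranked[:top] if terms[t][0] <= q_cut]
    return out


def representative_gene_union(
    terms_per_category: dict[str, list[str]],
    collections: list[GeneSetCollection],
    background: set[str] | list[str],
) -> set[str]:
    """Union of the member genes of all representative terms, within background."""
    bg = set(background)
    by_cat = {c.category: c for c in collections}
    keep: set[str] = set()
    for cat, terms in terms_per_category.items():
        coll = by_cat.get(cat)
        if coll is None:
            continue
        for t in terms:
            keep |= coll[t] & bg
    return keep


# ---------------------------------------------------------------------------
# trimming and subnetworks
# ---------------------------------------------------------------------------

def trim_network(
    cor: np.ndarray,
    weights: np.ndarray,
    gene_ids: list[str],
    keep_genes: set[str] | list[str],
    module_of: dict[str, int],
    edge_floor: float = 0.01,
    max_edges_per_node: int = 50,
    positive_only: bool = True,
) -> WeightedNetwork:
    """Reduce the network to ``keep_genes`` with the published edge rules.

    Candidate edges are pairs of kept genes whose weight exceeds
    ``edge_floor`` and (with ``positive_only``) whose underlying Pearson
    correlation is positive.  Each node ranks its candidate incident edges
    by descending weight (ties by lexicographic pair) and keeps its top
    ``max_edges_per_node``; an edge survives if either endpoint keeps it.
    Module labels are carried onto the nodes.  Deterministic and
    idempotent for fixed matrices.
    """
    keep = [g for g in gene_ids if g in set(keep_genes)]
    if not keep:
        raise ValidationError("no genes to keep in trimmed network")
    index = {g: i for i, g in enumerate(gene_ids)}
    rows = np.array([index[g] for g in keep])
    w = np.asarray(weights, dtype=float)[np.ix_(rows, rows)]
    c = np.asarray(cor, dtype=float)[np.ix_(rows, rows)]

    nk = len(keep)
    cand = w > edge_floor
    if positive_only:
        cand &= c > 0
    np.fill_diagonal(cand, False)
    cand = np.triu(cand)

    ii, jj = np.nonzero(cand)
    # per-node ranking with union survival
    incident: dict[int, list[tuple[float, str, str, int]]] = {}
    for e, (i, j) in enumerate(zip(ii, jj)):
        u, v = keep[i], keep[j]
        key = (-w[i, j], min(u, v), max(u, v), e)
        incident.setdefault(i, []).append(key)
        incident.setdefault(j, []).append(key)
    survive: set[int] = set()
    for node, edges in incident.items():
        edges.sort()
        survive.update(e for *_, e in edges[:max_edges_per_node])

    def edge_iter():
        for e in sorted(survive):
            i, j = int(ii[e]), int(jj[e])
            sign = 1 if c[i, j] > 0 else -1
            yield keep[i], keep[j], float(w[i, j]), sign

    return WeightedNetwork.build(
        nodes=keep, edges=edge_iter(),
        modules={g: module_of.get(g, 0) for g in keep},
    )


def signature_subnetwork(
    net: WeightedNetwork,
    records: list[EnrichmentRecord],
    signature_name: str,
    signature_genes: set[str] | frozenset[str],
    q_cut: float = 0.05,
) -> tuple[set[str], WeightedNetwork]:
    """Extract the subnetwork related to one signature.

    Seed modules are those with an enrichment record for the signature at
    q <= ``q_cut`` that also contain at least one signature gene among their
    in-network members.  The node set is the seed modules' genes together
    with all their direct neighbours; the induced subnetwork is returned.
    """
    module_of = net.module_of()
    seeds = set()
    for r in records:
        if r.set_name != signature_name or r.q > q_cut or r.module == 0:
            continue
        members = {g for g, m in module_of.items() if m == r.module}
        if members & set(signature_genes):
            seeds.add(r.module)
    if not seeds:
        log.warning("no module qualifies for signature %r at q <= %g",
                    signature_name, q_cut)
        return set(), WeightedNetwork.build(nodes=[], edges=[])
    nodes = {g for g, m in module_of.items() if m in seeds}
    for g in list(nodes):
        nodes |= net.neighbors(g)
    return nodes, net.subgraph(nodes)
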