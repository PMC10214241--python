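"""Hypergeometric enrichment, BH adjustment, trimming, subnetworks."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

import ferronet as fn
from ferronet.annotation import (
    EnrichmentRecord,
    annotate_modules,
    bh_adjust,
    hypergeom_pval,
    representative_gene_union,
    representative_terms,
    signature_subnetwork,
    trim_network,
)
from ferronet.datatypes import GeneSetCollection, ValidationError, WeightedNetwork


def enumeration_pval(k, n, K, N):
    """Oracle: draw every n-subset of an N-universe, count overlaps >= k."""
    universe = range(N)
    in_set = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits += len(in_set.intersection(draw)) >= k
    return hits / total


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_pval(0, 4, 5, 10) == 1.0

    def test_worked_example(self):
        # (C(5,3)C(5,1) + C(5,4)C(5,0)) / C(10,4) = 55/210
        assert hypergeom_pval(3, 4, 5, 10) == pytest.approx(55 / 210, abs=1e-12)

    def test_set_is_whole_background(self):
        assert hypergeom_pval(4, 4, 10, 10) == 1.0

    def test_agrees_with_scipy_tail(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 60))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expect = scipy.stats.hypergeom.sf(k - 1, N, K, n)
            assert hypergeom_pval(k, n, K, N) == pytest.approx(
                max(expect, 0.0), abs=1e-12, rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_pval(5, 4, 5, 10)
        with pytest.raises(ValidationError):
            hypergeom_pval(1, 2, 11, 10)


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_never_exceeds_one_and_monotone(self, rng):
        p = rng.random(50) * 0.999 + 1e-6
        q = bh_adjust(p)
        assert q.max() <= 1.0
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_permutation_invariant(self, rng):
        p = rng.random(30) * 0.999 + 1e-6
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(40) * 0.999 + 1e-6
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)


class TestAnnotateModules:
    def test_disjoint_module_all_null(self):
        module_of = {f"g{i}": 1 for i in range(10)}
        coll = GeneSetCollection("sig", {"s": frozenset({"h1", "h2"})})
        background = list(module_of) + ["h1", "h2"]
        recs = annotate_modules(module_of, [coll], background)
        assert len(recs) == 1
        assert recs[0].k == 0 and recs[0].p == 1.0

    def test_planted_module_enriched_with_enumeration_oracle(self):
        # 8 of the 10-gene module are set members; K = 12, N = 40 — small
        # enough for the exhaustive subset-draw oracle
        module_of = {f"g{i}": (1 if i < 10 else 0) for i in range(40)}
        members = frozenset([f"g{i}" for i in range(8)]
                            + [f"g{i}" for i in range(30, 34)])
        coll = GeneSetCollection("sig", {"s": members})
        recs = annotate_modules(module_of, [coll], list(module_of))
        rec = recs[0]
        assert (rec.k, rec.n, rec.K, rec.N) == (8, 10, 12, 40)
        # oracle on the equivalent reduced problem
        expect = scipy.stats.hypergeom.sf(rec.k - 1, rec.N, rec.K, rec.n)
        assert rec.p == pytest.approx(expect, rel=1e-9)
        assert rec.q < 0.05

    def test_set_outside_background_skipped(self, caplog):
        module_of = {"g1": 1, "g2": 1, "g3": 1, "g4": 1, "g5": 1}
        coll = GeneSetCollection("sig", {"out": frozenset({"zz"})})
        recs = annotate_modules(module_of, [coll], list(module_of))
        assert recs == []

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError, match="background"):
            annotate_modules({}, [], [])


class TestRepresentativeTerms:
    def _records(self, qs):
        return [EnrichmentRecord(1, "GO-BP", f"t{i:03d}", 1, 10, 10, 100,
                                 p=q / 2, q=q)
                for i, q in enumerate(qs)]

    def test_truncates_at_top(self):
        recs = self._records([0.001 * (i + 1) for i in range(25)])
        terms = representative_terms(recs, top=20, q_cut=0.05)
        assert len(terms["GO-BP"]) == 20

    def test_returns_all_when_few_qualify(self):
        recs = self._records([0.01, 0.02, 0.5, 0.9])
        terms = representative_terms(recs, top=20, q_cut=0.05)
        assert terms["GO-BP"] == ["t000", "t001"]

    def test_tie_broken_by_name_deterministically(self):
        recs = self._records([0.01] * 30)
        t1 = representative_terms(recs, top=20, q_cut=0.05)
        t2 = representative_terms(list(reversed(recs)), top=20, q_cut=0.05)
        assert t1 == t2
        assert t1["GO-BP"] == sorted(t1["GO-BP"])


class TestTrimNetwork:
    def _inputs(self, n, rng=None):
        genes = [f"g{i:03d}" for i in range(n)]
        if rng is None:
            w = np.zeros((n, n))
            c = np.ones((n, n))
        else:
            w = rng.random((n, n)) * 0.5
            w = (w + w.T) / 2
            c = rng.uniform(-1, 1, (n, n))
            c = (c + c.T) / 2
        np.fill_diagonal(w, 0.0)
        return genes, c, w

    def test_floor_rule(self):
        genes, c, w = self._inputs(3)
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.005
        w[1, 2] = w[2, 1] = 0.2
        net = trim_network(c, w, genes, genes, {}, edge_floor=0.01)
        assert net.n_edges == 2
        assert not net.graph.has_edge("g000", "g002")

    def test_negative_correlation_excluded(self):
        genes, c, w = self._inputs(3)
        w[:] = 0.4
        np.fill_diagonal(w, 0.0)
        c[0, 1] = c[1, 0] = -0.5
        net = trim_network(c, w, genes, genes, {})
        assert not net.graph.has_edge("g000", "g001")
        assert net.graph.has_edge("g000", "g002")

    def test_star_node_keeps_top_k_with_bruteforce_oracle(self, rng):
        # hub with 60 candidate edges; spokes form a strong clique, so no
        # spoke ranks its weak hub edge in its own top 50 — the hub's
        # per-node ranking alone decides which 50 hub edges survive
        n = 61
        genes = [f"g{i:03d}" for i in range(n)]
        w = np.full((n, n), 0.0)
        w[1:, 1:] = rng.uniform(0.91, 0.99, (60, 60))
        w = (w + w.T) / 2
        hub_weights = rng.permutation(np.linspace(0.02, 0.9, 60))
        w[0, 1:] = hub_weights
        w[1:, 0] = hub_weights
        np.fill_diagonal(w, 0.0)
        c = np.ones((n, n))
        net = trim_network(c, w, genes, genes, {}, max_edges_per_node=50)
        keep_expect = {genes[1 + i] for i in np.argsort(-hub_weights)[:50]}
        assert set(net.neighbors("g000")) == keep_expect
        # brute-force union-of-per-node-top-k oracle over the whole graph
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)
                      if w[i, j] > 0.01]
        per_node = {i: [] for i in range(n)}
        for i, j in candidates:
            per_node[i].append((i, j))
            per_node[j].append((i, j))
        survivors = set()
        for node, edges in per_node.items():
            edges.sort(key=lambda e: (-w[e[0], e[1]], genes[e[0]], genes[e[1]]))
            survivors.update(edges[:50])
        expect = {(genes[i], genes[j]) for i, j in survivors}
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expect

    def test_idempotent(self, rng):
        genes, c, w = self._inputs(20, rng)
        net1 = trim_network(c, w, genes, genes, {}, max_edges_per_node=5)
        net2 = trim_network(c, w, genes, net1.nodes, {}, max_edges_per_node=5)
        assert net2.structurally_equal(net1)

    def test_empty_keep_rejected(self):
        genes, c, w = self._inputs(3)
        with pytest.raises(ValidationError, match="keep"):
            trim_network(c, w, genes, [], {})


class TestSignatureSubnetwork:
    def _net(self):
        # module 1: m0..m9; neighbors x0..x4 attached to m0; module 2 apart
        nodes = [f"m{i}" for i in range(10)] + [f"x{i}" for i in range(5)] \
            + [f"z{i}" for i in range(6)]
        edges = [(f"m{i}", f"m{i+1}", 0.5, 1) for i in range(9)]
        edges += [("m0", f"x{i}", 0.3, 1) for i in range(5)]
        edges += [(f"z{i}", f"z{i+1}", 0.5, 1) for i in range(5)]
        modules = {n: 1 for n in nodes if n.startswith("m")}
        modules.update({n: 2 for n in nodes if n.startswith("z")})
        return WeightedNetwork.build(nodes, edges, modules)

    def test_union_with_neighbors(self):
        recs = [EnrichmentRecord(1, "signatures", "ferro", 3, 10, 5, 100,
                                 p=1e-5, q=1e-4)]
        nodes, sub = signature_subnetwork(self._net(), recs, "ferro",
                                          {"m1", "m2", "m3"})
        assert len(nodes) == 15
        assert sub.graph.number_of_nodes() == 15

    def test_enriched_without_signature_member_is_not_seed(self):
        recs = [EnrichmentRecord(1, "signatures", "ferro", 0, 10, 5, 100,
                                 p=1e-5, q=1e-4)]
        nodes, _ = signature_subnetwork(self._net(), recs, "ferro",
                                        {"absent1", "absent2"})
        assert nodes == set()

    def test_monotone_in_q_cut(self):
        recs = [
            EnrichmentRecord(1, "signatures", "ferro", 3, 10, 5, 100,
                             p=1e-5, q=0.01),
            EnrichmentRecord(2, "signatures", "ferro", 2, 6, 5, 100,
                             p=0.02, q=0.04),
        ]
        net = self._net()
        strict, _ = signature_subnetwork(net, recs, "ferro",
                                         {"m1", "z0"}, q_cut=0.02)
        loose, _ = signature_subnetwork(net, recs, "ferro",
                                        {"m1", "z0"}, q_cut=0.05)
        assert strict <= loose
        assert len(loose) > len(strict)


def test_representative_union_restricted_to_background():
    colls = [GeneSetCollection("sig", {"s1": frozenset({"a", "b", "zz"})})]
    keep = representative_gene_union({"sig": ["s1"]}, colls, {"a", "b", "c"})
    assert keep == {"a", "b"}
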