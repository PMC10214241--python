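"""Signature scoring, stratification, group DE, intersection."""

import numpy as np
import pandas as pd
import pytest

import ferronet as fn
from ferronet.datatypes import ValidationError
from ferronet.scoring import (
    epithelial_call,
    fc_filter,
    group_de,
    intersect_platforms,
    signature_score,
    stratify,
    top_n_genes,
)


def _matrix(values, unit="log2p1", prefix="g"):
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"c{j}" for j in range(values.shape[1])]
    return fn.ExpressionMatrix(genes, cols, values, unit)


class TestSignatureScore:
    def test_all_zero_column_scores_zero(self):
        m = _matrix([[0.0, 2.0], [0.0, 4.0]])
        s = signature_score(m, {"g0", "g1"})
        assert s.score.tolist() == [0.0, 3.0]

    def test_mean_of_present_genes(self):
        m = _matrix([[2.0], [4.0], [9.0]])
        s = signature_score(m, {"g0", "g1", "absent"})
        assert s.score[0] == pytest.approx(3.0)
        assert s.coverage[0] == pytest.approx(2 / 3)

    def test_matches_loop_oracle(self, rng):
        m = _matrix(rng.normal(5, 2, size=(20, 8)))
        genes = {f"g{i}" for i in range(0, 20, 3)}
        s = signature_score(m, genes)
        for j, col in enumerate(m.sample_ids):
            expect = np.mean([m.values[i, j] for i in range(20)
                              if f"g{i}" in genes])
            assert s.score[j] == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_row_and_column_order(self, rng):
        m = _matrix(rng.normal(size=(10, 6)))
        gperm = list(rng.permutation(m.gene_ids))
        cperm = list(rng.permutation(m.sample_ids))
        m2 = m.subset_genes(gperm).subset_samples(cperm)
        genes = {"g1", "g4", "g7"}
        s1 = signature_score(m, genes).set_index("column_id").score
        s2 = signature_score(m2, genes).set_index("column_id").score
        np.testing.assert_allclose(s1[s2.index], s2, atol=1e-12)

    def test_zero_overlap_names_signature(self):
        m = _matrix([[1.0]])
        with pytest.raises(ValidationError, match="mySig"):
            signature_score(m, {"nope"}, name="mySig")

    def test_sum_aggregation(self):
        m = _matrix([[2.0], [4.0]])
        s = signature_score(m, {"g0", "g1"}, agg="sum")
        assert s.score[0] == pytest.approx(6.0)


class TestStratify:
    @pytest.mark.parametrize("score,expect", [
        (5.0, "intermediate"),   # strict > for high
        (3.0, "low"),            # inclusive <= for low
        (7.2, "high"),
        (4.0, "intermediate"),
    ])
    def test_boundaries(self, score, expect):
        s = pd.DataFrame({"column_id": ["c"], "score": [score]})
        assert stratify(s).stratum[0] == expect

    def test_partitions_every_column(self, rng):
        s = pd.DataFrame({"column_id": [f"c{i}" for i in range(100)],
                          "score": rng.uniform(0, 8, 100)})
        lab = stratify(s)
        assert len(lab) == 100
        assert set(lab.stratum) <= {"high", "low", "intermediate"}

    def test_inverted_cuts_rejected(self):
        s = pd.DataFrame({"column_id": ["c"], "score": [1.0]})
        with pytest.raises(ValidationError):
            stratify(s, high_cut=2, low_cut=3)


class TestGroupDE:
    def _labels(self, m, n_high, n_low):
        strata = ["high"] * n_high + ["low"] * n_low \
            + ["intermediate"] * (m.n_samples - n_high - n_low)
        return pd.DataFrame({"column_id": m.sample_ids, "stratum": strata})

    def test_flat_gene_null(self):
        m = _matrix(np.ones((1, 8)))
        de = group_de(m, self._labels(m, 4, 4))
        assert de.p[0] == 1.0 and de.log2_fc[0] == 0.0

    def test_separated_5v5_exact_p(self):
        m = _matrix([list(range(10, 15)) + list(range(5))])
        de = group_de(m, self._labels(m, 5, 5))
        assert de.p[0] == pytest.approx(2 / 252, rel=1e-9)
        assert de.log2_fc[0] == pytest.approx(10.0)

    def test_planted_spots_recovered(self):
        spots, ann, truth = fn.simulate_spots(seed=5, n_spots=200,
                                              effect=1.0)
        m = fn.log2_transform(spots)
        labels = pd.DataFrame({
            "column_id": ann.table.sample_id,
            "stratum": ann.table.site.map({"front": "high", "core": "low"}),
        })
        de = group_de(m, labels)
        planted = de[de.gene_id.isin(truth.de_genes)]
        assert (planted.q <= 0.05).mean() >= 0.9

    def test_null_calibration(self, rng):
        m = _matrix(rng.normal(size=(2000, 60)))
        de = group_de(m, self._labels(m, 30, 30))
        frac = (de.p <= 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_small_stratum_rejected(self):
        m = _matrix(np.ones((1, 4)))
        with pytest.raises(ValidationError, match="high"):
            group_de(m, self._labels(m, 1, 3))


class TestEpithelialCall:
    def test_zero_cells_are_non_tumor(self):
        m = _matrix(np.zeros((3, 4)))
        calls = epithelial_call(m, {"g0", "g1"},
                                {f"c{j}": "k0" for j in range(4)}, cut=0.5)
        assert not calls.tumor.any()

    def test_threshold_separates_clusters(self):
        m = _matrix([[1.2, 1.2, 4.8, 4.8]])
        clusters = {"c0": "A", "c1": "A", "c2": "B", "c3": "B"}
        calls = epithelial_call(m, {"g0"}, clusters, cut=3.0)
        assert calls.set_index("cluster").tumor.to_dict() == {
            "A": False, "B": True}

    def test_uncovered_column_rejected(self):
        m = _matrix(np.ones((1, 2)))
        with pytest.raises(ValidationError, match="c1"):
            epithelial_call(m, {"g0"}, {"c0": "A"}, cut=0.5)


class TestTopN:
    def _de(self, fcs, ps=None):
        n = len(fcs)
        return pd.DataFrame({
            "gene_id": [f"g{i:02d}" for i in range(n)],
            "log2_fc": fcs,
            "p": ps if ps is not None else [0.01] * n,
        })

    def test_fewer_than_n_returns_all(self, caplog):
        out = top_n_genes(self._de([2.0, 1.0, 0.5, -1.0]), n=1500)
        assert out == ["g00", "g01", "g02"]

    def test_single_top_gene(self):
        assert top_n_genes(self._de([0.5, 3.0, 1.0]), n=1) == ["g01"]

    def test_tie_broken_by_p_then_name(self):
        de = self._de([1.0, 1.0, 1.0], ps=[0.5, 0.01, 0.5])
        out1 = top_n_genes(de, n=3)
        out2 = top_n_genes(de.sample(frac=1, random_state=0), n=3)
        assert out1 == out2 == ["g01", "g00", "g02"]

    def test_p_ranking_mode(self):
        de = self._de([0.5, 2.0], ps=[0.001, 0.5])
        assert top_n_genes(de, n=1, rank_by="p") == ["g00"]


class TestFcFilter:
    def _pair(self, treated, control):
        return (_matrix(np.array(treated)[:, None], unit="FPKM"),
                _matrix(np.array(control)[:, None], unit="FPKM"))

    def test_inclusive_boundary(self):
        t, c = self._pair([2.0], [1.0])   # (2+1)/(1+1) = 1.5 exactly
        assert fc_filter(t, c).gene_id.tolist() == ["g0"]

    def test_equal_means_excluded(self):
        t, c = self._pair([5.0], [5.0])
        assert fc_filter(t, c).empty

    def test_matches_direct_ratio_oracle(self, rng):
        tv = rng.gamma(2, 10, 10)
        cv = rng.gamma(2, 10, 10)
        t, c = self._pair(tv, cv)
        out = fc_filter(t, c, ratio_cut=1.2)
        expect = {f"g{i}": (tv[i] + 1) / (cv[i] + 1) for i in range(10)
                  if (tv[i] + 1) / (cv[i] + 1) >= 1.2}
        assert dict(zip(out.gene_id, out.ratio)) == pytest.approx(expect)
        assert out.ratio.is_monotonic_decreasing

    def test_mismatched_universe_rejected(self):
        t = _matrix([[1.0]], unit="FPKM")
        c = _matrix([[1.0]], unit="FPKM", prefix="other")
        with pytest.raises(ValidationError, match="universes"):
            fc_filter(t, c)


class TestIntersectPlatforms:
    def test_disjoint_lists_empty(self):
        assert intersect_platforms(["a", "b"], ["c", "d"]).empty

    def test_self_intersection_deduplicates(self):
        out = intersect_platforms(["b", "a", "b"], ["b", "a", "b"])
        assert out.gene_id.tolist() == ["a", "b"]

    def test_commutative_on_gene_set(self):
        a, b = ["x", "y", "z"], ["y", "w", "x"]
        fwd = intersect_platforms(a, b)
        rev = intersect_platforms(b, a)
        assert fwd.gene_id.tolist() == rev.gene_id.tolist() == ["x", "y"]

    def test_provenance_ranks(self):
        out = intersect_platforms(["p", "q", "r"], ["r", "s"])
        assert out.iloc[0].rank_a == 3 and out.iloc[0].rank_b == 1

    def test_synthetic_platform_lists_have_planted_overlap(self):
        a, b = fn.platform_gene_lists(seed=9)
        assert len(a) == 1500 and len(b) == 539
        assert len(intersect_platforms(a, b)) == 42
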