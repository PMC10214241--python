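"""Gene-set scoring, stratification and cross-platform gene comparison.

A signature score is the unweighted mean of log2(x+1) expression over the
signature genes present in the matrix, per column (sample, cell or spot).
Columns are stratified into high/intermediate/low groups against printed
cuts (score > 5 high, <= 3 low by default), and high-vs-low differential
expression is a per-gene two-sided rank-sum test with BH adjustment.
Spatially up-regulated genes (top-N by fold change) are intersected with
fold-change-filtered bulk genes to find genes co-upregulated on both
platforms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .annotation import bh_adjust
from .datatypes import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def signature_score(m: ExpressionMatrix, genes, name: str = "signature",
                    agg: str = "mean") -> pd.DataFrame:
    """Score each column by its aggregate log2p1 expression over a gene set.

    Returns a frame with columns ``column_id, signature, score, coverage``
    where coverage is the fraction of signature genes present in the
    matrix.  Zero overlap is an error naming the signature.
    """
    if m.unit != "log2p1":
        raise ValidationError("signature_score expects log2(x+1) values")
    if agg not in ("mean", "sum"):
        raise ValidationError(f"unknown aggregation {agg!r}")
    genes = set(genes)
    present = [g for g in m.gene_ids if g in genes]
    if not present:
        raise ValidationError(f"no gene of signature {name!r} is in the matrix")
    idx = [m.gene_ids.index(g) for g in present]
    block = m.values[idx]
    scores = block.mean(axis=0) if agg == "mean" else block.sum(axis=0)
    return pd.DataFrame({
        "column_id": m.sample_ids,
        "signature": name,
        "score": scores,
        "coverage": len(present) / len(genes),
    })


def stratify(scores: pd.DataFrame, high_cut: float = 5.0,
             low_cut: float = 3.0) -> pd.DataFrame:
    """Label columns high (score > high_cut), low (score <= low_cut) or
    intermediate.  Boundary behaviour is strict above, inclusive below,
    matching the printed definition of the groups.
    """
    if high_cut <= low_cut:
        raise ValidationError("high_cut must exceed low_cut")
    s = scores["score"].to_numpy()
    stratum = np.where(s > high_cut, "high",
                       np.where(s <= low_cut, "low", "intermediate"))
    return pd.DataFrame({"column_id": scores["column_id"],
                         "stratum": stratum})


def group_de(m: ExpressionMatrix, labels: pd.DataFrame) -> pd.DataFrame:
    """High-vs-low differential expression per gene.

    Two-sided Mann-Whitney rank-sum p (exact for small tie-free groups,
    tie-corrected normal otherwise), log2 fold change as mean(high) -
    mean(low) on the log2p1 scale, and BH q over all genes tested.
    Intermediate columns are excluded.  Each stratum needs >= 2 columns.
    """
    if m.unit == "counts":
        values = np.log2(m.values + 1.0)
    elif m.unit == "log2p1":
        values = m.values
    else:
        raise ValidationError("group_de expects log2p1 or counts values")
    lab = dict(zip(labels["column_id"], labels["stratum"]))
    hi = [i for i, s in enumerate(m.sample_ids) if lab.get(s) == "high"]
    lo = [i for i, s in enumerate(m.sample_ids) if lab.get(s) == "low"]
    for name, cols in (("high", hi), ("low", lo)):
        if len(cols) < 2:
            raise ValidationError(
                f"stratum {name!r} has {len(cols)} column(s); need >= 2"
            )
    high, low = values[:, hi], values[:, lo]
    if max(len(hi), len(lo)) <= 8:
        # small groups: decide exact vs asymptotic per gene, so a tie in
        # one gene does not demote every other gene's test
        p = np.array([
            scipy.stats.mannwhitneyu(h, l, alternative="two-sided",
                                     method="auto").pvalue
            for h, l in zip(high, low)
        ])
    else:
        res = scipy.stats.mannwhitneyu(high, low, axis=1,
                                       alternative="two-sided",
                                       method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    p = np.minimum(p, 1.0)
    fc = high.mean(axis=1) - low.mean(axis=1)
    # identical gene across every column: no information, p = 1 by convention
    flat = np.ptp(values[:, hi + lo], axis=1) == 0
    p[flat] = 1.0
    return pd.DataFrame({
        "gene_id": m.gene_ids,
        "mean_high": high.mean(axis=1),
        "mean_low": low.mean(axis=1),
        "log2_fc": fc,
        "p": p,
        "q": bh_adjust(p),
    })


def epithelial_call(m: ExpressionMatrix, epithelial_genes, clusters,
                    cut: float) -> pd.DataFrame:
    """Call tumor (epithelial) versus non-tumor cell clusters.

    ``clusters`` maps column id -> cluster label and must cover every
    column.  A cluster is called tumor when the mean epithelial score of
    its member columns exceeds ``cut``.
    """
    clusters = dict(clusters)
    missing = [s for s in m.sample_ids if s not in clusters]
    if missing:
        raise ValidationError(f"columns without cluster label: {missing[:5]}")
    scores = signature_score(m, epithelial_genes, name="epithelial")
    scores["cluster"] = [clusters[c] for c in scores["column_id"]]
    rows = []
    for cluster, grp in scores.groupby("cluster", sort=True):
        if grp.empty:
            raise ValidationError(f"cluster {cluster!r} is empty")
        mean = float(grp["score"].mean())
        rows.append({"cluster": cluster, "mean_score": mean,
                     "tumor": mean > cut})
    return pd.DataFrame(rows)


def top_n_genes(de: pd.DataFrame, n: int = 1500, rank_by: str = "fc") -> list[str]:
    """Top up-regulated genes of a high-vs-low DE table.

    Only genes with positive fold change qualify; ranking is by descending
    fold change (ties by ascending p, then name) or, with
    ``rank_by="p"``, by ascending p (ties by descending fold change, then
    name).  Fewer than ``n`` qualifying genes returns them all with a
    warning.
    """
    up = de[de["log2_fc"] > 0].copy()
    if rank_by == "fc":
        up = up.sort_values(["log2_fc", "p", "gene_id"],
                            ascending=[False, True, True], kind="stable")
    elif rank_by == "p":
        up = up.sort_values(["p", "log2_fc", "gene_id"],
                            ascending=[True, False, True], kind="stable")
    else:
        raise ValidationError(f"unknown ranking key {rank_by!r}")
    if len(up) < n:
        log.warning("only %d up-regulated genes available (requested %d)",
                    len(up), n)
    return list(up["gene_id"].head(n))


def fc_filter(treated: ExpressionMatrix, control: ExpressionMatrix,
              ratio_cut: float = 1.5) -> pd.DataFrame:
    """Genes up-regulated in treated vs control by mean fold change.

    Both matrices must share one gene universe.  The ratio is
    (mean treated + 1)/(mean control + 1); genes at or above ``ratio_cut``
    are returned sorted by descending ratio (ties by name).
    """
    if treated.gene_ids != control.gene_ids:
        mism = sorted(set(treated.gene_ids) ^ set(control.gene_ids))
        raise ValidationError(
            f"gene universes differ between conditions: {mism[:5]}"
            if mism else "gene order differs between conditions"
        )
    ratio = (treated.values.mean(axis=1) + 1.0) / (control.values.mean(axis=1) + 1.0)
    df = pd.DataFrame({"gene_id": treated.gene_ids, "ratio": ratio})
    df = df[df["ratio"] >= ratio_cut]
    return df.sort_values(["ratio", "gene_id"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)


def intersect_platforms(list_a, list_b) -> pd.DataFrame:
    """Genes common to two platform lists, lexicographically sorted.

    Provenance columns record each gene's rank in list A (1-based) and its
    position-derived rank in list B.  Commutative on the gene set and
    idempotent (a list intersected with itself is its deduplicated self).
    """
    rank_a: dict[str, int] = {}
    for i, g in enumerate(list_a, start=1):
        rank_a.setdefault(str(g).strip(), i)
    rank_b: dict[str, int] = {}
    for i, g in enumerate(list_b, start=1):
        rank_b.setdefault(str(g).strip(), i)
    common = sorted(set(rank_a) & set(rank_b))
    return pd.DataFrame({
        "gene_id": common,
        "rank_a": [rank_a[g] for g in common],
        "rank_b": [rank_b[g] for g in common],
    })
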