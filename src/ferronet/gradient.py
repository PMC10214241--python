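"""Tumor/normal gradient analysis across matched anatomical sites.

For every gene, tumor samples from the inner core (IC), invasive front (IF)
and metastasis (M) are compared with the same patient's adjacent normal
tissue (N) as log2((TPM_T + 1)/(TPM_N + 1)), summarized across patients.
A subnetwork shows the "gradual increase" differential pattern when the
per-gene medians rise strictly from IC to IF to M and two paired two-sided
Wilcoxon signed-rank tests (IC vs IF, IC vs M; pairing by gene) both reach
p <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import (
    ExpressionMatrix,
    SampleAnnotation,
    TUMOR_SITES,
    ValidationError,
)

log = logging.getLogger(__name__)

#: sample size above which the signed-rank test switches from the exact
#: null distribution to the tie- and continuity-corrected normal one
EXACT_LIMIT = 25


def tn_log_ratio(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    summary: str = "median",
) -> pd.DataFrame:
    """Per-gene, per-site summarized log2 tumor/normal ratios.

    For each patient and tumor site, log2((T + 1)/(N + 1)) is computed
    per gene against that patient's normal sample (normals averaged if a
    patient has several).  ``summary="median"`` takes the median across
    patients per (gene, site); ``"pooled"`` takes the median across all
    contributing samples without patient collapsing first.

    Returns a tidy frame with columns ``gene_id, site, log2_tn, n``.
    Antisymmetric in T and N: swapping the roles negates every value.
    """
    if m.unit not in ("TPM", "FPKM", "counts"):
        raise ValidationError("tn_log_ratio expects an abundance unit")
    if summary not in ("median", "pooled"):
        raise ValidationError(f"unknown summary mode {summary!r}")
    ann.check_against(m)
    ann.check_matched_normals()
    t = ann.table
    col = {s: i for i, s in enumerate(m.sample_ids)}

    normal_log: dict[str, np.ndarray] = {}
    for patient, grp in t[t["site"] == "N"].groupby("patient_id"):
        cols = [col[s] for s in grp["sample_id"]]
        normal_log[patient] = np.log2(m.values[:, cols] + 1.0).mean(axis=1)

    rows = []
    for site in TUMOR_SITES:
        site_samples = t[t["site"] == site]
        if site_samples.empty:
            continue
        per_patient = []
        for patient, grp in site_samples.groupby("patient_id"):
            cols = [col[s] for s in grp["sample_id"]]
            tumor_log = np.log2(m.values[:, cols] + 1.0)
            ratios = tumor_log - normal_log[patient][:, None]
            if summary == "median":
                per_patient.append(ratios.mean(axis=1, keepdims=True))
            else:
                per_patient.append(ratios)
        stacked = np.hstack(per_patient)
        summarized = np.median(stacked, axis=1)
        rows.append(pd.DataFrame({
            "gene_id": m.gene_ids,
            "site": site,
            "log2_tn": summarized,
            "n": stacked.shape[1],
        }))
    if not rows:
        raise ValidationError("no tumor samples found in annotation")
    return pd.concat(rows, ignore_index=True)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Differences d = y - x; zero differences are dropped, |d| is ranked with
    midranks for ties, and W is the sum of positive-difference ranks.  The
    two-sided p is exact (full sign-assignment null distribution, computed
    by convolution) for n <= 25 remaining pairs and a tie- and
    continuity-corrected normal approximation above.  All differences zero
    yields (0, 1) with a log message.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("wilcoxon_signed_rank needs equal-length 1-D pairs")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        log.info("wilcoxon_signed_rank: all differences zero; p = 1")
        return 0.0, 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        return w, _exact_two_sided_p(ranks, w)
    return w, _approx_two_sided_p(ranks, w, n)


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """Exact p over all 2^n equally likely sign assignments.

    Midranks are multiples of 1/2, so doubled ranks are integers and the
    null distribution of 2W is built by convolution in O(n * total).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts += shifted
    denom = counts.sum()  # 2^n
    w2 = int(np.rint(2 * w))
    p_ge = counts[w2:].sum() / denom
    p_le = counts[:w2 + 1].sum() / denom
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def _approx_two_sided_p(ranks: np.ndarray, w: float, n: int) -> float:
    """Normal approximation with tie variance correction and continuity."""
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0
    dev = abs(w - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * scipy.stats.norm.sf(z)))


@dataclass
class GradientVerdict:
    """Outcome of the three-criterion gradual-increase decision."""

    name: str
    medians: dict = field(default_factory=dict)   # site -> median log2 T/N
    p_ic_if: float = float("nan")
    p_ic_m: float = float("nan")
    gradual_increase: bool = False


def classify_gradient(table: pd.DataFrame, name: str = "subnetwork",
                      alpha: float = 0.05) -> GradientVerdict:
    """Apply the gradual-increase criteria to a subnetwork's gradient table.

    ``table`` is the tidy (gene_id, site, log2_tn) frame restricted to the
    subnetwork's genes.  The flag is the conjunction of (i) strictly
    increasing medians IC < IF < M, (ii) p(IC vs IF) <= alpha, and
    (iii) p(IC vs M) <= alpha, with pairing by gene.
    """
    missing = [s for s in TUMOR_SITES if s not in set(table["site"])]
    if missing:
        raise ValidationError(f"gradient table lacks site(s): {missing}")
    wide = table.pivot_table(index="gene_id", columns="site",
                             values="log2_tn", aggfunc="first")
    wide = wide.dropna(subset=list(TUMOR_SITES))
    if wide.empty:
        raise ValidationError("no gene has values at all three tumor sites")
    medians = {s: float(np.median(wide[s])) for s in TUMOR_SITES}
    _, p_ic_if = wilcoxon_signed_rank(wide["IC"], wide["IF"])
    _, p_ic_m = wilcoxon_signed_rank(wide["IC"], wide["M"])
    increasing = medians["IC"] < medians["IF"] < medians["M"]
    flag = increasing and p_ic_if <= alpha and p_ic_m <= alpha
    return GradientVerdict(name, medians, p_ic_if, p_ic_m, flag)
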