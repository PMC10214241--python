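"""Weighted coexpression network construction.

The chain is the classic one: Pearson correlation across samples, a soft
threshold power chosen to approximate scale-free topology, power adjacency
a_ij = |cor_ij|^beta, topological overlap TOM_ij combining direct adjacency
with shared-neighbour structure, average-linkage clustering of 1 - TOM, and
an adaptive (dynamic) cut of the dendrogram into modules.

Everything here is deterministic: no RNG is used at any step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .datatypes import ValidationError

log = logging.getLogger(__name__)


def correlation_matrix(values: np.ndarray, gene_ids: list[str] | None = None,
                       method: str = "pearson") -> np.ndarray:
    """Gene-gene correlation across samples for a (genes x samples) array.

    Requires at least 3 samples and nonzero variance for every gene
    (zero-variance genes must be removed upstream).  The result has an
    exact unit diagonal and is symmetric to machine precision.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValidationError("correlation needs a 2-D matrix with >= 3 samples")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        i = int(np.argmax(sd == 0))
        name = gene_ids[i] if gene_ids else f"row {i}"
        raise ValidationError(f"zero-variance gene reached correlation: {name}")
    if method == "spearman":
        values = scipy.stats.rankdata(values, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    cor = (cor + cor.T) / 2.0
    np.fill_diagonal(cor, 1.0)
    return cor


def adjacency(cor: np.ndarray, beta: int, signed: bool = False) -> np.ndarray:
    """Power adjacency a_ij = |cor_ij|^beta (unsigned, the default) or
    ((1 + cor_ij)/2)^beta (signed).  The diagonal is set to 0 so that
    connectivity sums k_i = sum_j a_ij exclude the self term.
    """
    if beta < 1:
        raise ValidationError("soft-threshold power must be >= 1")
    base = (1.0 + cor) / 2.0 if signed else np.abs(cor)
    a = base ** float(beta)
    np.fill_diagonal(a, 0.0)
    return a


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Per-node connectivity k_i (adjacency row sums, self excluded)."""
    return adj.sum(axis=1)


def scale_free_fit(k: np.ndarray, nbins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity distribution.

    Nodes are binned into ``nbins`` equal-width bins of k; log10(frequency)
    is regressed on log10(mean k) over non-empty bins.  Returns R^2 when the
    slope is negative (the scale-free direction) and -R^2 otherwise.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValidationError("connectivities must be non-negative")
    distinct_pos = np.unique(k[k > 0])
    if distinct_pos.size < nbins:
        raise ValidationError(
            f"scale-free fit needs >= {nbins} distinct positive connectivities "
            f"(got {distinct_pos.size})"
        )
    if np.allclose(k, k[0]):
        raise ValidationError("all connectivities identical; fit undefined")
    edges = np.linspace(k.min(), k.max(), nbins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, nbins - 1)
    log_freq, log_k = [], []
    for b in range(nbins):
        members = k[idx == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        log_freq.append(np.log10(members.size / k.size))
        log_k.append(np.log10(members.mean()))
    if len(log_k) < 2:
        raise ValidationError("too few non-empty bins for the scale-free fit")
    slope, _, r, _, _ = scipy.stats.linregress(log_k, log_freq)
    r2 = float(r ** 2)
    return r2 if slope < 0 else -r2


@dataclass
class SoftThresholdScan:
    """Result of the soft-threshold scan over candidate powers."""

    powers: list[int]
    fit_index: list[float]          # NaN where the fit was undefined
    mean_connectivity: list[float]
    selected: int

    def __post_init__(self) -> None:
        if not (len(self.powers) == len(self.fit_index)
                == len(self.mean_connectivity)):
            raise ValidationError("scan columns must have equal length")
        if self.selected not in self.powers:
            raise ValidationError("selected power must be a candidate")


def select_power(cor: np.ndarray,
                 candidates: tuple[int, ...] = tuple(range(1, 21)),
                 cut: float = 0.7,
                 signed: bool = False,
                 nbins: int = 10) -> SoftThresholdScan:
    """Scan candidate powers and pick the smallest with fit index >= cut.

    If no candidate reaches the cut, the power of maximal fit is selected
    with a logged warning.
    """
    fits, mean_k = [], []
    for beta in candidates:
        adj = adjacency(cor, beta, signed=signed)
        k = connectivity(adj)
        mean_k.append(float(k.mean()))
        try:
            fits.append(scale_free_fit(k, nbins=nbins))
        except ValidationError as exc:
            log.warning("power %d: scale-free fit undefined (%s)", beta, exc)
            fits.append(float("nan"))
    eligible = [b for b, f in zip(candidates, fits) if np.isfinite(f) and f >= cut]
    if eligible:
        selected = eligible[0]
    else:
        finite = [(f, b) for b, f in zip(candidates, fits) if np.isfinite(f)]
        if not finite:
            raise ValidationError("scale-free fit undefined for every candidate")
        selected = max(finite)[1]
        log.warning(
            "no candidate power reached fit cut %.2f; falling back to "
            "beta=%d (max fit %.3f)", cut, selected, max(finite)[0]
        )
    return SoftThresholdScan(list(candidates), fits, mean_k, selected)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu; TOM_ii = 1.  An exactly
    zero denominator (isolated node pair) yields TOM_ij = 0.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, (l + a) / denom, 0.0)
    if np.any(denom <= 0):
        log.info("tom_similarity: %d degenerate zero denominators set to 0",
                 int((denom <= 0).sum()))
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def permutation_noise_floor(
    values: np.ndarray,
    beta: int,
    signed: bool = False,
    quantile: float = 0.999,
) -> float:
    """Upper quantile of the TOM similarity expected from sampling noise.

    Each gene's sample values are independently permuted (fixed internal
    seed, so the result is a deterministic function of the input), which
    preserves every marginal distribution while destroying all gene-gene
    correlation; the permuted data is pushed through the same
    adjacency/TOM chain and the ``quantile`` of its off-diagonal
    similarities is returned.  Used to anchor the dynamic tree cut's
    coherence criterion on the similarity scale that pure noise attains
    under the selected power.
    """
    rng = np.random.default_rng(0)
    perm = np.array([rng.permutation(row) for row in np.asarray(values)])
    cor0 = correlation_matrix(perm)
    tom0 = tom_similarity(adjacency(cor0, beta, signed=signed))
    off = tom0[np.triu_indices(tom0.shape[0], k=1)]
    return float(np.quantile(off, quantile))


def average_linkage(diss: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a symmetric dissimilarity.

    Returns a scipy linkage matrix; merge heights are invariant to leaf
    permutation.
    """
    d = np.asarray(diss, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValidationError("dissimilarities must be finite")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("dissimilarity must be square symmetric")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return sch.linkage(ssd.squareform(d, checks=False), method="average")
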