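"""Shared filtering and transform primitives applied before network building."""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def filter_sparse_genes(m: ExpressionMatrix,
                        zero_fraction_cut: float = 0.9) -> ExpressionMatrix:
    """Drop genes whose fraction of zero values reaches ``zero_fraction_cut``.

    The removal is inclusive (zero fraction >= cut removes the gene), the
    conservative reading of "genes with 90% of zero values were excluded".
    Survivor order is preserved and the operation is idempotent.
    """
    if m.unit == "log2p1":
        raise ValidationError("filter_sparse_genes expects an abundance unit, "
                              "not log2p1")
    zero_frac = (m.values == 0).mean(axis=1)
    keep = zero_frac < zero_fraction_cut
    if not keep.any():
        raise ValidationError(
            f"no genes survive zero-fraction cut {zero_fraction_cut}; "
            "lower the cut"
        )
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_sparse_genes: removed %d/%d genes at cut %.3g",
                 dropped, m.n_genes, zero_fraction_cut)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(m.sample_ids), m.values[keep], m.unit)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``x -> log2(x + 1)`` and retag the unit as ``log2p1``."""
    if m.unit == "log2p1":
        raise ValidationError("matrix is already log2(x+1)-transformed")
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids),
                            np.log2(m.values + 1.0), "log2p1")
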