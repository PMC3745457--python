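"""Two-group differential expression and signature set algebra.

Differential expression on log2 values uses Welch's two-sample t-test
(unequal variances).  Signatures are derived by joint thresholding on
the absolute log2 fold change and the negative log10 p-value (NLP), the
filtering style common for two-colour/oligo array contrasts where a
handful of replicates per genotype precludes FDR-based selection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .iodata import Direction, ExpressionMatrix, GeneSignature, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = ["welch_de", "filter_signature", "signature_overlap"]


def welch_de(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene Welch t-test of ``group_a`` against ``group_b``.

    Returns a DataFrame indexed by gene id with columns

    ``log2_fc``
        mean(log2 A) - mean(log2 B);
    ``p``
        two-sided Welch p-value, set to 1 for genes constant across the
        pooled samples (no evidence either way);
    ``nlp``
        -log10(p).

    Both groups need at least two samples.
    """
    samples_a = annot.samples_in(group_a)
    samples_b = annot.samples_in(group_b)
    for label in (group_a, group_b):
        if label not in annot.distinct_groups():
            raise ValueError(f"unknown group label {label!r}")
    for label, members in ((group_a, samples_a), (group_b, samples_b)):
        if len(members) < 2:
            raise ValueError(f"group {label!r} has {len(members)} samples; need >=2")
    sidx = matrix.sample_index()
    missing = [s for s in samples_a + samples_b if s not in sidx]
    if missing:
        raise ValueError(f"annotated samples absent from matrix: {missing}")
    a = matrix.values[:, [sidx[s] for s in samples_a]]
    b = matrix.values[:, [sidx[s] for s in samples_b]]

    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # constant-across-both genes produce nan (0/0); no signal -> p = 1
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    nlp = -np.log10(p)
    return pd.DataFrame(
        {"log2_fc": log2_fc, "p": p, "nlp": nlp}, index=pd.Index(matrix.gene_ids, name="gene_id")
    )


def filter_signature(
    table: pd.DataFrame,
    min_abs_log2_fc: float,
    min_nlp: float,
    name: str,
) -> GeneSignature | None:
    """Threshold a DE table into an oriented signature.

    Keeps genes with ``|log2_fc| > min_abs_log2_fc`` AND ``nlp > min_nlp``
    (strict inequalities); direction is ``up`` for positive fold change.
    Returns ``None`` when no gene passes (logged), since a signature may
    not be empty.
    """
    if min_abs_log2_fc < 0 or min_nlp < 0:
        raise ValueError("thresholds must be >= 0")
    keep = (table["log2_fc"].abs() > min_abs_log2_fc) & (table["nlp"] > min_nlp)
    entries: list[tuple[str, Direction]] = [
        (str(g), "up" if lfc > 0 else "down")
        for g, lfc in table.loc[keep, "log2_fc"].items()
    ]
    if not entries:
        logger.warning("filter_signature: no gene passed (%g, %g) for %r", min_abs_log2_fc, min_nlp, name)
        return None
    return GeneSignature(name, entries)


def signature_overlap(a: GeneSignature, b: GeneSignature) -> list[str]:
    """Sorted intersection of two signatures' gene sets (direction ignored)."""
    return sorted(set(a.genes) & set(b.genes))
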