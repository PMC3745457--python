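"""Cross-species signature projection, scoring, and the permutation
separation test.

The central question this module answers: does a gene signature derived
in one system (e.g. mouse tumor fibroblasts) separate tumor stroma from
normal stroma in an independent human cohort better than random gene
sets of the same size?

The per-sample summary is the *oriented mean z-score*: rows of the
expression matrix are standardized, each signature gene contributes its
z-value with weight +1 (direction ``up``) or -1 (``down``), and the mean
over signature genes is the sample's score.  Scores of the tumor group
are compared to the normal group with a one-sided Wilcoxon rank-sum
statistic, and significance comes from re-drawing the signature as a
random gene set from the full matrix universe ``n_perm`` times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iodata import Direction, ExpressionMatrix, GeneSignature, OrthologMap, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationTestResult",
    "map_orthologs",
    "pca_project",
    "row_standardize",
    "separation_test",
    "signature_score",
    "variance_filter",
    "wilcoxon_rank_sum",
]


# ---------------------------------------------------------------------------
# projection and filtering
# ---------------------------------------------------------------------------

def map_orthologs(
    sig: GeneSignature,
    ortho: OrthologMap,
    platform_genes: set[str] | None = None,
) -> GeneSignature | None:
    """Project a signature across species via an ortholog table.

    Each source gene is replaced by its ortholog; genes without a mapping
    are dropped, as are mapped genes absent from ``platform_genes`` when a
    platform universe is supplied (both logged).  A source gene with
    several listed orthologs keeps the first listed target only.
    Directions carry over unchanged.  Returns ``None`` if nothing maps.
    """
    target_of = ortho.first_target()
    entries: list[tuple[str, Direction]] = []
    seen: set[str] = set()
    n_unmapped = n_off_platform = 0
    for gene, direction in sig.entries:
        target = target_of.get(gene)
        if target is None:
            n_unmapped += 1
            continue
        if platform_genes is not None and target not in platform_genes:
            n_off_platform += 1
            continue
        if target in seen:  # two sources converging on one target
            continue
        seen.add(target)
        entries.append((target, direction))
    if n_unmapped or n_off_platform:
        logger.info(
            "map_orthologs(%s): %d unmapped, %d off-platform of %d genes",
            sig.name, n_unmapped, n_off_platform, len(sig),
        )
    if not entries:
        logger.warning("map_orthologs(%s): no gene survived projection", sig.name)
        return None
    return GeneSignature(sig.name, entries)


def variance_filter(
    matrix: ExpressionMatrix, sig: GeneSignature, cutoff: float
) -> GeneSignature | None:
    """Keep signature genes whose expression variance across all samples
    exceeds ``cutoff`` (unbiased n-1 variance, strict inequality).

    Signature genes absent from the matrix are dropped first (logged).
    """
    if matrix.n_samples < 2:
        raise ValueError("variance undefined with fewer than 2 samples")
    gidx = matrix.gene_index()
    present = [(g, d) for g, d in sig.entries if g in gidx]
    n_absent = len(sig) - len(present)
    if n_absent:
        logger.info("variance_filter(%s): %d genes absent from matrix", sig.name, n_absent)
    entries = [
        (g, d)
        for g, d in present
        if matrix.values[gidx[g]].var(ddof=1) > cutoff
    ]
    if not entries:
        logger.warning("variance_filter(%s): no gene passed cutoff %g", sig.name, cutoff)
        return None
    return GeneSignature(sig.name, entries)


def row_standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row to mean 0 and unbiased variance 1.

    Zero-variance rows carry no between-sample information and are
    dropped with a logged warning; an all-constant matrix is an error.
    """
    if matrix.n_samples < 2:
        raise ValueError("standardization undefined with fewer than 2 samples")
    sd = matrix.values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all rows are constant; nothing to standardize")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("row_standardize: dropped %d zero-variance rows", n_dropped)
    vals = matrix.values[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep, None]
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(matrix.sample_ids), z)


# ---------------------------------------------------------------------------
# scoring and testing
# ---------------------------------------------------------------------------

def signature_score(z: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Oriented mean z-score per sample.

    ``score(s) = (1/|G|) * sum_g w_g * z[g, s]`` with ``w_g = +1`` for
    ``up`` genes and ``-1`` for ``down`` genes, over the signature genes
    ``G`` present in ``z``.
    """
    gidx = z.gene_index()
    rows = [(gidx[g], 1.0 if d == "up" else -1.0) for g, d in sig.entries if g in gidx]
    if not rows:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    idx, w = zip(*rows)
    scores = np.asarray(w) @ z.values[list(idx)] / len(rows)
    return pd.Series(scores, index=z.sample_ids, name=sig.name)


def wilcoxon_rank_sum(x, y, alternative: str = "greater") -> tuple[float, float]:
    """One-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Returns ``(u, p)`` where ``u`` is the Mann-Whitney U statistic of
    ``x`` (mid-ranks for ties).  The p-value is exact (full enumeration)
    for tie-free samples with ``len(x) + len(y) <= 12``, otherwise a
    normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _u_statistics(scores: np.ndarray, tumor_cols: np.ndarray, normal_cols: np.ndarray) -> np.ndarray:
    """Mann-Whitney U of the tumor columns for each row of ``scores``."""
    n_t = tumor_cols.size
    ranks = stats.rankdata(scores, axis=-1)
    r_t = ranks[..., tumor_cols].sum(axis=-1)
    return r_t - n_t * (n_t + 1) / 2.0


@dataclass
class PermutationTestResult:
    """Outcome of the random-gene-set separation test."""

    observed_u: float
    n_perm: int
    n_ge: int
    p: float
    seed: int
    n_genes_used: int
    dropped_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "observed_u": self.observed_u,
            "n_perm": self.n_perm,
            "n_ge": self.n_ge,
            "p": self.p,
            "seed": self.seed,
            "n_genes_used": self.n_genes_used,
            "dropped_genes": list(self.dropped_genes),
        }


def separation_test(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    sig: GeneSignature,
    n_perm: int = 10_000,
    seed: int = 0,
    tumor_group: str | None = None,
    flip: bool = False,
) -> PermutationTestResult:
    """Test whether a signature separates tumor from normal samples
    better than random gene sets of equal size.

    The observed statistic is the one-sided Wilcoxon U of tumor-group
    oriented-mean scores against normal-group scores (tumor expected
    higher; pass ``flip=True`` to reverse the orientation).  The null is
    built from ``n_perm`` signatures of the same size drawn uniformly
    without replacement from all genes of the (standardized) matrix,
    with direction labels permuted from the observed signature.  The
    empirical p-value uses the add-one rule ``(n_ge + 1)/(n_perm + 1)``.

    ``tumor_group`` defaults to the first of the two annotation groups;
    the other group plays the normal-stroma role.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = annot.distinct_groups()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if tumor_group is None:
        tumor_group = groups[0]
    if tumor_group not in groups:
        raise ValueError(f"unknown tumor group {tumor_group!r}")
    normal_group = next(g for g in groups if g != tumor_group)

    z = row_standardize(matrix)
    gidx = z.gene_index()
    used = [(g, d) for g, d in sig.entries if g in gidx]
    dropped = [g for g, _ in sig.entries if g not in gidx]
    if dropped:
        logger.info("separation_test(%s): %d signature genes not in matrix", sig.name, len(dropped))
    if not used:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    m = len(used)
    if m > z.n_genes:
        raise ValueError("signature larger than the matrix gene universe")

    sidx = z.sample_index()
    tumor_cols = np.array([sidx[s] for s in annot.samples_in(tumor_group) if s in sidx])
    normal_cols = np.array([sidx[s] for s in annot.samples_in(normal_group) if s in sidx])
    if tumor_cols.size == 0 or normal_cols.size == 0:
        raise ValueError("both groups must have samples present in the matrix")
    if flip:
        tumor_cols, normal_cols = normal_cols, tumor_cols

    signs = np.array([1.0 if d == "up" else -1.0 for _, d in used])
    rows = np.array([gidx[g] for g, _ in used])
    obs_scores = signs @ z.values[rows] / m
    observed_u = float(_u_statistics(obs_scores, tumor_cols, normal_cols))

    rng = np.random.default_rng(seed)
    null_u = np.empty(n_perm)
    # chunked so memory stays flat for the 10,000-draw default
    chunk = max(1, min(n_perm, 2_000_000 // max(1, m * z.n_samples)))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        k = stop - start
        draw = np.empty((k, m), dtype=np.intp)
        perm_signs = np.empty((k, m))
        for i in range(k):
            draw[i] = rng.choice(z.n_genes, size=m, replace=False)
            perm_signs[i] = rng.permutation(signs)
        null_scores = np.einsum("km,kms->ks", perm_signs, z.values[draw]) / m
        null_u[start:stop] = _u_statistics(null_scores, tumor_cols, normal_cols)

    n_ge = int((null_u >= observed_u).sum())
    p = (n_ge + 1) / (n_perm + 1)
    return PermutationTestResult(
        observed_u=observed_u,
        n_perm=n_perm,
        n_ge=n_ge,
        p=p,
        seed=seed,
        n_genes_used=m,
        dropped_genes=dropped,
    )


# ---------------------------------------------------------------------------
# PCA export
# ---------------------------------------------------------------------------

def pca_project(matrix: ExpressionMatrix, sig: GeneSignature) -> pd.DataFrame:
    """Project samples on the first two principal components of the
    standardized signature-gene submatrix.

    Sign convention: each component's loading on the alphabetically
    first signature gene is made non-negative, so coordinates are
    reproducible across eigensolvers.  Returns a DataFrame indexed by
    sample id with columns ``pc1``/``pc2``; the fraction of variance
    explained is attached as ``.attrs['explained_variance_ratio']``.
    """
    if matrix.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    gidx = matrix.gene_index()
    genes = [g for g in sig.genes if g in gidx]
    if not genes:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    z = row_standardize(matrix.subset_genes(genes))
    # rows are mean 0, so the sample cloud is already centered in gene space
    u_mat, s, vt = np.linalg.svd(z.values, full_matrices=False)
    if s.size < 2 or s[1] <= 1e-12 * s[0]:
        raise ValueError("fewer than 2 non-degenerate principal components")
    first = z.gene_ids.index(min(z.gene_ids))
    coords = np.empty((z.n_samples, 2))
    for k in range(2):
        sign = -1.0 if u_mat[first, k] < 0 else 1.0
        coords[:, k] = sign * s[k] * vt[k]
    out = pd.DataFrame(coords, index=z.sample_ids, columns=["pc1", "pc2"])
    total = float((s**2).sum())
    out.attrs["explained_variance_ratio"] = [float(s[0] ** 2 / total), float(s[1] ** 2 / total)]
    return out
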