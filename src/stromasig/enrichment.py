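"""Preranked enrichment scoring with gene-set resampling significance.

Implements the classic weighted Kolmogorov-Smirnov running-sum
enrichment score on a ranked gene list: walking the list from top to
bottom, the sum rises by ``|metric|^exponent`` (normalized over the
set's hits) at each set member and falls by ``1/(N - n_set)`` at each
miss; the enrichment score (ES) is the signed extremum of the walk.
Significance per set comes from random same-size gene sets drawn from
the ranked universe; the normalized enrichment score (NES) divides ES
by the mean magnitude of null scores sharing its sign.  The leading
edge is the subset of the gene set at or before (after, for negative
ES) the running-sum peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "gsea",
    "leading_edge",
    "leading_edge_overlap",
    "rank_genes",
]


def rank_genes(table: pd.DataFrame, metric: str = "log2_fc") -> pd.Series:
    """Order genes by a DE-table column, descending.

    ``metric`` is ``log2_fc`` or ``signed_nlp`` (NLP carrying the fold
    change's sign).  Ties are broken by gene id ascending so the ranking
    is deterministic.  Returns a Series (index gene id, values metric).
    """
    if len(table) == 0:
        raise ValueError("DE table is empty")
    if metric == "log2_fc":
        values = table["log2_fc"]
    elif metric == "signed_nlp":
        values = np.sign(table["log2_fc"]) * table["nlp"]
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    df = pd.DataFrame({"metric": values, "gene": table.index.astype(str)})
    df = df.sort_values(["metric", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["metric"].to_numpy(), index=pd.Index(df["gene"], name="gene_id"))


def _validate_ranked(ranked: pd.Series) -> None:
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    vals = ranked.to_numpy(dtype=float)
    if np.any(np.diff(vals) > 1e-12):
        raise ValueError("ranked list metric must be non-increasing")


def _running_sum(metric: np.ndarray, hit: np.ndarray, exponent: float) -> np.ndarray:
    """Running enrichment sum for one 0/1 hit indicator."""
    n = metric.size
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hits == n:
        miss_step = 0.0
    else:
        miss_step = 1.0 / (n - n_hits)
    weights = np.abs(metric) ** exponent
    total = weights[hit.astype(bool)].sum()
    steps = np.where(hit.astype(bool), (weights / total) if total > 0 else (1.0 / n_hits), -miss_step)
    return np.cumsum(steps)


def enrichment_score(
    ranked: pd.Series, set_genes: Iterable[str], exponent: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score and its peak position.

    Returns ``(es, peak_index)`` where ``es`` is the running-sum value of
    largest magnitude (sign preserved) and ``peak_index`` the 0-based
    list position of that extremum (first occurrence on ties).
    """
    _validate_ranked(ranked)
    genes = ranked.index.to_numpy(dtype=object)
    hit = np.isin(genes, list(set(set_genes))).astype(float)
    walk = _running_sum(ranked.to_numpy(dtype=float), hit, exponent)
    peak = int(np.argmax(np.abs(walk)))
    # cumsum round-off can push the extremum past +/-1 by ~1e-16
    return float(np.clip(walk[peak], -1.0, 1.0)), peak


def leading_edge(ranked: pd.Series, set_genes: Iterable[str], exponent: float = 1.0) -> list[str]:
    """Set members driving the enrichment peak, in ranked order.

    For a non-negative ES these are the set genes at positions up to and
    including the peak; for a negative ES, from the peak to the list
    end.
    """
    set_genes = set(set_genes)
    es, peak = enrichment_score(ranked, set_genes, exponent)
    genes = list(ranked.index)
    if es >= 0:
        span = genes[: peak + 1]
    else:
        span = genes[peak:]
    return [g for g in span if g in set_genes]


@dataclass
class EnrichmentResult:
    """Per-set outcome of the preranked enrichment analysis."""

    set_name: str
    es: float
    nes: float
    nominal_p: float
    leading_edge: list[str]
    n_perm: int
    seed: int
    n_genes_in_list: int

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "es": self.es,
            "nes": self.nes,
            "nominal_p": self.nominal_p,
            "leading_edge": list(self.leading_edge),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_genes_in_list": self.n_genes_in_list,
        }


def _null_es(
    metric: np.ndarray, n: int, m: int, n_perm: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """ES for ``n_perm`` random m-gene sets drawn from an n-gene list."""
    null = np.empty(n_perm)
    weights = np.abs(metric) ** exponent
    miss_step = 1.0 / (n - m) if m < n else 0.0
    chunk = max(1, min(n_perm, 4_000_000 // n))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        k = stop - start
        hits = np.empty((k, m), dtype=np.intp)
        for i in range(k):
            hits[i] = rng.choice(n, size=m, replace=False)
        steps = np.full((k, n), -miss_step)
        hit_w = weights[hits]
        totals = hit_w.sum(axis=1, keepdims=True)
        safe = np.where(totals > 0, totals, 1.0)
        np.put_along_axis(steps, hits, np.where(totals > 0, hit_w / safe, 1.0 / m), axis=1)
        walk = np.cumsum(steps, axis=1)
        idx = np.argmax(np.abs(walk), axis=1)
        null[start:stop] = np.clip(walk[np.arange(k), idx], -1.0, 1.0)
    return null


def gsea(
    ranked: pd.Series,
    sets: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Score each gene set against a ranked list with a random-set null.

    ``sets`` may contain :class:`~stromasig.iodata.GeneSignature` objects
    or ``(name, genes)`` pairs.  Set members absent from the ranked list
    are ignored; per set, the null is ``n_perm`` uniform draws of the
    same effective size from the ranked universe.  The nominal p-value
    uses the add-one rule over null scores at least as extreme and of
    the same sign as the observed ES.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _validate_ranked(ranked)
    metric = ranked.to_numpy(dtype=float)
    universe = set(ranked.index)
    n = len(universe)
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for s in sets:
        if hasattr(s, "genes"):
            name, genes = s.name, set(s.genes)
        else:
            name, genes = s[0], set(s[1])
        present = genes & universe
        if len(genes) > n:
            raise ValueError(f"set {name!r} larger than the ranked universe")
        if not present:
            raise ValueError(f"no gene of set {name!r} present in the ranked list")
        es, _ = enrichment_score(ranked, present, exponent)
        ledge = leading_edge(ranked, present, exponent)
        null = _null_es(metric, n, len(present), n_perm, exponent, rng)
        same_sign = null >= 0 if es >= 0 else null < 0
        if same_sign.any():
            nes = es / np.abs(null[same_sign]).mean()
        else:  # degenerate: every null landed on the other side
            nes = es / np.abs(null).mean()
            logger.warning("gsea(%s): no same-sign null scores; NES uses all nulls", name)
        extreme = (null >= es) if es >= 0 else (null <= es)
        nominal_p = (1 + int((extreme & same_sign).sum())) / (1 + n_perm)
        results.append(
            EnrichmentResult(
                set_name=name,
                es=es,
                nes=float(nes),
                nominal_p=float(nominal_p),
                leading_edge=ledge,
                n_perm=n_perm,
                seed=seed,
                n_genes_in_list=len(present),
            )
        )
    return results


def leading_edge_overlap(a: EnrichmentResult, b: EnrichmentResult) -> tuple[list[str], float]:
    """Shared leading-edge genes and the shared fraction of ``a``'s edge."""
    if not a.leading_edge:
        raise ValueError(f"leading edge of {a.set_name!r} is empty; fraction undefined")
    shared = sorted(set(a.leading_edge) & set(b.leading_edge))
    return shared, len(shared) / len(a.leading_edge)
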