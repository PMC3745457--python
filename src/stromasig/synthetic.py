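"""Synthetic datasets with the statistical structure the pipeline assumes.

Three generators cover the three study designs the pipeline consumes:

* a two-group stroma cohort (tumor vs normal samples) with a planted,
  direction-oriented signature of configurable effect size;
* a four-genotype fibroblast study — control vs knockout fibroblasts in
  a normal and in a tumor context — with planted differential-expression
  genes partially shared between contexts;
* a survival cohort whose event times follow a Cox model with known
  coefficients and independent exponential censoring.

Background log2 intensities are i.i.d. Gaussian around 7, resembling
normalized oligo-array scales.  All generators are pure functions of
their parameters and seed.  They emulate planted mean shifts and
proportional hazards only: no probe effects, batch structure, or
correlated gene blocks beyond the planted signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .iodata import (
    Direction,
    ExpressionMatrix,
    GeneSignature,
    SampleAnnotation,
    SurvivalTable,
)

__all__ = [
    "MouseStudy",
    "SyntheticTruth",
    "gen_mouse_fibroblast_study",
    "gen_stroma_dataset",
    "gen_survival_cohort",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    planted_genes: list[tuple[str, Direction]]
    effect_size: float
    true_beta: np.ndarray
    censoring_rate: float
    seed: int
    extra: dict = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def gen_stroma_dataset(
    n_genes: int = 1000,
    n_per_group: int | tuple[int, int] = (49, 52),
    n_signature: int = 38,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    frac_up: float = 16 / 38,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleAnnotation, GeneSignature, SyntheticTruth]:
    """Two-group log2-expression cohort with a planted oriented signature.

    ``n_per_group`` is ``(n_tumor, n_normal)`` (an int means both).  The
    default cohort shape — 49 tumor and 52 normal samples scored with a
    38-gene signature, 16 genes up and 22 down — mirrors a laser-capture
    breast-stroma study.  Planted ``up`` genes are shifted ``+effect_size``
    and ``down`` genes ``-effect_size`` (log2 units; equal to within-group
    SD units when ``noise_sd`` is 1) in the tumor group only.
    """
    if isinstance(n_per_group, int):
        n_tumor = n_normal = n_per_group
    else:
        n_tumor, n_normal = n_per_group
    if not (0 < n_signature <= n_genes):
        raise ValueError("need 0 < n_signature <= n_genes")
    if effect_size < 0 or noise_sd <= 0:
        raise ValueError("effect_size must be >= 0 and noise_sd > 0")
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    tumor = [f"t{i:03d}" for i in range(n_tumor)]
    normal = [f"n{i:03d}" for i in range(n_normal)]
    values = rng.normal(7.0, noise_sd, size=(n_genes, n_tumor + n_normal))

    planted_idx = rng.choice(n_genes, size=n_signature, replace=False)
    n_up = int(round(frac_up * n_signature))
    dirs: list[Direction] = ["up"] * n_up + ["down"] * (n_signature - n_up)
    for row, d in zip(planted_idx, dirs):
        shift = effect_size if d == "up" else -effect_size
        values[row, :n_tumor] += shift

    matrix = ExpressionMatrix(genes, tumor + normal, values)
    annot = SampleAnnotation({s: "tumor" for s in tumor} | {s: "normal" for s in normal})
    entries: list[tuple[str, Direction]] = [(genes[i], d) for i, d in zip(planted_idx, dirs)]
    sig = GeneSignature("planted", entries)
    truth = SyntheticTruth(
        planted_genes=entries,
        effect_size=effect_size,
        true_beta=np.zeros(0),
        censoring_rate=0.0,
        seed=seed,
    )
    return matrix, annot, sig, truth


@dataclass
class MouseStudy:
    """Paired two-group comparisons in a normal and a tumor context."""

    normal_matrix: ExpressionMatrix
    normal_annot: SampleAnnotation
    tumor_matrix: ExpressionMatrix
    tumor_annot: SampleAnnotation
    truth: SyntheticTruth


def gen_mouse_fibroblast_study(
    n_genes: int = 2000,
    n_per_genotype: int = 5,
    n_de_tumor: int = 107,
    n_de_normal: int = 22,
    n_shared: int = 4,
    lfc: float = 3.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> MouseStudy:
    """Four-genotype fibroblast study: control vs knockout, with and
    without a tumor context.

    Plants ``n_de_normal`` differential genes in the normal-context
    comparison and ``n_de_tumor`` in the tumor-context comparison,
    sharing exactly ``n_shared`` genes (same direction in both), so that
    threshold filtering plus set intersection recovers the overlap.  The
    defaults mirror the printed list sizes of a conditional-knockout
    fibroblast study (107 tumor-context and 22 normal-context genes
    sharing 4).  Group labels are ``ctrl`` (gene intact) and ``ko``;
    planted genes are higher in ``ctrl`` for direction ``up``.
    """
    if n_shared > min(n_de_tumor, n_de_normal):
        raise ValueError("n_shared cannot exceed either planted list size")
    total_planted = n_de_tumor + n_de_normal - n_shared
    if total_planted > n_genes:
        raise ValueError("planted lists exceed the gene universe")
    if n_per_genotype < 2:
        raise ValueError("need at least 2 samples per genotype")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)

    chosen = rng.choice(n_genes, size=total_planted, replace=False)
    shared = chosen[:n_shared]
    tumor_only = chosen[n_shared:n_de_tumor]
    normal_only = chosen[n_de_tumor:]
    tumor_idx = np.concatenate([shared, tumor_only]).astype(int)
    normal_idx = np.concatenate([shared, normal_only]).astype(int)
    signs_all = rng.choice([1.0, -1.0], size=total_planted)
    sign_of = dict(zip(chosen.tolist(), signs_all.tolist()))

    def _context(planted: np.ndarray, tag: str) -> tuple[ExpressionMatrix, SampleAnnotation]:
        ctrl = [f"{tag}_ctrl_{i}" for i in range(n_per_genotype)]
        ko = [f"{tag}_ko_{i}" for i in range(n_per_genotype)]
        vals = rng.normal(7.0, noise_sd, size=(n_genes, 2 * n_per_genotype))
        for row in planted:
            vals[row, :n_per_genotype] += sign_of[int(row)] * lfc
        mat = ExpressionMatrix(genes, ctrl + ko, vals)
        annot = SampleAnnotation({s: "ctrl" for s in ctrl} | {s: "ko" for s in ko})
        return mat, annot

    normal_matrix, normal_annot = _context(normal_idx, "nf")
    tumor_matrix, tumor_annot = _context(tumor_idx, "tf")

    def _entries(idx: np.ndarray) -> list[tuple[str, Direction]]:
        return [(genes[i], "up" if sign_of[int(i)] > 0 else "down") for i in idx]

    truth = SyntheticTruth(
        planted_genes=_entries(tumor_idx),
        effect_size=lfc,
        true_beta=np.zeros(0),
        censoring_rate=0.0,
        seed=seed,
        extra={
            "normal_planted": _entries(normal_idx),
            "shared_genes": sorted(genes[int(i)] for i in shared),
        },
    )
    return MouseStudy(normal_matrix, normal_annot, tumor_matrix, tumor_annot, truth)


def gen_survival_cohort(
    n_patients: int = 200,
    n_genes: int = 30,
    true_beta=None,
    baseline_rate: float = 0.1,
    censoring_rate: float = 0.3,
    shape: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, SurvivalTable, SyntheticTruth]:
    """Survival cohort from a proportional-hazards model.

    Gene values are i.i.d. standard Gaussian; event times are Weibull
    with scale set by ``baseline_rate * exp(x @ beta)`` (``shape=1``,
    the default, gives exponential times).  Censoring times are drawn
    from an independent exponential whose rate is solved numerically so
    the expected censored fraction matches ``censoring_rate``.

    Returns ``(X, survival_table, truth)`` with ``X`` patients x genes.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if not (0 <= censoring_rate < 1):
        raise ValueError("censoring_rate must be in [0, 1)")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    if true_beta is None:
        true_beta = np.zeros(n_genes)
    true_beta = np.asarray(true_beta, dtype=float)
    if true_beta.shape != (n_genes,):
        raise ValueError(f"true_beta must have length {n_genes}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_patients, n_genes))
    rates = baseline_rate * np.exp(x @ true_beta)
    # T = (E / rate)^(1/shape) with E ~ Exp(1): Weibull via inverse hazard
    t_event = (rng.exponential(1.0, n_patients) / rates) ** (1.0 / shape)

    if censoring_rate == 0:
        observed, event = t_event, np.ones(n_patients, dtype=int)
    else:
        # P(censored) given the realized event times = mean(1 - exp(-c*T));
        # solve for the exponential censoring rate c
        def frac(log_c: float) -> float:
            return float(np.mean(1.0 - np.exp(-np.exp(log_c) * t_event))) - censoring_rate

        log_c = optimize.brentq(frac, -40.0, 40.0)
        t_cens = rng.exponential(1.0 / np.exp(log_c), n_patients)
        event = (t_event <= t_cens).astype(int)
        observed = np.minimum(t_event, t_cens)

    patients = [f"p{i:04d}" for i in range(n_patients)]
    surv = SurvivalTable(patients, observed, event)
    truth = SyntheticTruth(
        planted_genes=[],
        effect_size=float(np.max(np.abs(true_beta), initial=0.0)),
        true_beta=true_beta,
        censoring_rate=censoring_rate,
        seed=seed,
    )
    return x, surv, truth
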