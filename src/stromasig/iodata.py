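"""Domain types and tabular readers/writers shared by every pipeline stage.

All on-disk formats are plain tab-separated UTF-8 text (LF or CRLF):

* expression matrix — first row sample header, first column gene ids;
* gene sets — GMT (name, description, gene ids);
* sample annotation — columns ``sample_id``, ``group``;
* survival table — columns ``patient_id``, ``time``, ``event``;
* signature — columns ``gene_id``, ``direction``;
* ortholog / probe maps — two unnamed columns.

Readers validate invariants and raise :class:`FormatError` rather than
silently repairing malformed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]

__all__ = [
    "Direction",
    "ExpressionMatrix",
    "FormatError",
    "GeneSignature",
    "OrthologMap",
    "ProbeMap",
    "SampleAnnotation",
    "SurvivalTable",
    "collapse_probes",
    "read_expression_matrix",
    "read_gene_sets",
    "read_ortholog_map",
    "read_probe_map",
    "read_sample_annotation",
    "read_signature",
    "read_survival_table",
    "write_expression_matrix",
    "write_gene_sets",
    "write_signature",
    "write_survival_table",
]


class FormatError(ValueError):
    """Raised when a file or in-memory object violates a format invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 intensities.

    ``values[i, j]`` is the log2 expression of ``gene_ids[i]`` in
    ``sample_ids[j]``.  Identifiers are opaque case-sensitive strings and
    must be unique on each axis; every value must be finite (missing data
    is the caller's problem, upstream of this package).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must all be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset in the given gene order; unknown genes are an error."""
        idx = self.gene_index()
        genes = list(genes)
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Mapping of sample id to categorical group label."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.groups = {str(k): str(v) for k, v in self.groups.items()}

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def distinct_groups(self) -> list[str]:
        out: list[str] = []
        for g in self.groups.values():
            if g not in out:
                out.append(g)
        return out


@dataclass
class GeneSignature:
    """Named, direction-oriented gene list.

    ``direction`` is the sign of change in the reference comparison that
    defined the signature (``up`` = higher in the reference condition).
    """

    name: str
    entries: list[tuple[str, Direction]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise FormatError(f"signature {self.name!r} is empty")
        self.entries = [(str(g), d) for g, d in self.entries]
        for _, d in self.entries:
            if d not in ("up", "down"):
                raise FormatError(f"invalid direction {d!r} in signature {self.name!r}")
        _check_unique([g for g, _ in self.entries], f"gene in signature {self.name!r}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def directions(self) -> dict[str, Direction]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class OrthologMap:
    """Source-species to target-species gene pairs (may be many-to-many)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        _check_unique([f"{a}\t{b}" for a, b in self.pairs], "ortholog pair")

    def first_target(self) -> dict[str, str]:
        """First listed target per source gene (many-to-many resolution rule)."""
        out: dict[str, str] = {}
        for src, tgt in self.pairs:
            out.setdefault(src, tgt)
        return out


@dataclass
class ProbeMap:
    """Probe-to-gene mapping; each probe maps to at most one gene."""

    pairs: list[tuple[str, str]]
    _probe_to_gene: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pairs = [(str(p), str(g)) for p, g in self.pairs]
        self._probe_to_gene = {}
        for probe, gene in self.pairs:
            if probe in self._probe_to_gene and self._probe_to_gene[probe] != gene:
                raise FormatError(f"probe {probe!r} maps to multiple genes")
            self._probe_to_gene[probe] = gene

    def gene_of(self, probe: str) -> str | None:
        return self._probe_to_gene.get(probe)


@dataclass
class SurvivalTable:
    """Right-censored survival records: one (time, event) pair per patient."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.patient_ids, "patient id")
        n = len(self.patient_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise FormatError("time/event length must match patient count")
        if n == 0:
            raise FormatError("survival table is empty")
        for pid, t in zip(self.patient_ids, self.time):
            if not (np.isfinite(t) and t > 0):
                raise FormatError(f"non-positive or non-finite time for patient {pid!r}")
        for pid, e in zip(self.patient_ids, self.event):
            if e not in (0, 1):
                raise FormatError(f"event flag for patient {pid!r} must be 0 or 1")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, patient_ids: Sequence[str]) -> "SurvivalTable":
        idx = {p: i for i, p in enumerate(self.patient_ids)}
        rows = [idx[p] for p in patient_ids]
        return SurvivalTable(list(patient_ids), self.time[rows], self.event[rows])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return [ln for ln in text.replace("\r\n", "\n").split("\n") if ln != ""]


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse a genes x samples TSV; header row holds sample ids."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns in header")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        row: list[float] = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                ) from None
        rows.append(row)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Serialize with >=6 significant digits so read/write round-trips."""
    if matrix.n_samples == 0 or matrix.n_genes == 0:
        raise FormatError("refusing to serialize an empty expression matrix")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def read_gene_sets(path: str | Path) -> list[GeneSignature]:
    """Parse GMT: one set per line — name, description, then gene ids.

    Duplicate genes within a line are dropped with a logged warning;
    directions default to ``up`` (GMT carries no orientation).
    """
    signatures: list[GeneSignature] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
        name, genes = fields[0], fields[2:]
        uniq: list[str] = []
        for g in genes:
            if g in uniq:
                logger.warning("%s:%d: duplicate gene %r in set %r dropped", path, lineno, g, name)
            else:
                uniq.append(g)
        signatures.append(GeneSignature(name, [(g, "up") for g in uniq]))
    return signatures


def write_gene_sets(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Parse an oriented signature TSV (columns gene_id, direction)."""
    lines = _read_lines(path)
    entries: list[tuple[str, Direction]] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if lineno == 1 and fields[0] == "gene_id":
            continue
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected gene_id<TAB>direction")
        gene, direction = fields
        if direction not in ("up", "down"):
            raise FormatError(f"{path}:{lineno}: invalid direction {direction!r}")
        entries.append((gene, direction))  # type: ignore[arg-type]
    return GeneSignature(name or Path(path).stem, entries)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tdirection\n")
        for gene, direction in sig.entries:
            fh.write(f"{gene}\t{direction}\n")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty annotation file")
    groups: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if lineno == 1 and fields[0] == "sample_id":
            continue
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected sample_id<TAB>group")
        sample, group = fields
        if sample in groups:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        groups[sample] = group
    return SampleAnnotation(groups)


def write_sample_annotation(annot: SampleAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in annot.groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_survival_table(path: str | Path) -> SurvivalTable:
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty survival file")
    patients: list[str] = []
    times: list[float] = []
    events: list[int] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if lineno == 1 and fields[0] == "patient_id":
            continue
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected patient_id<TAB>time<TAB>event")
        pid, t_str, e_str = fields
        try:
            t = float(t_str)
            e = int(e_str)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric time/event for {pid!r}") from None
        patients.append(pid)
        times.append(t)
        events.append(e)
    return SurvivalTable(patients, np.array(times), np.array(events))


def write_survival_table(surv: SurvivalTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id\ttime\tevent\n")
        for pid, t, e in zip(surv.patient_ids, surv.time, surv.event):
            fh.write(f"{pid}\t{format(t, '.10g')}\t{int(e)}\n")


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
        pairs.append((fields[0], fields[1]))
    return pairs


def read_ortholog_map(path: str | Path) -> OrthologMap:
    return OrthologMap(_read_pairs(path))


def read_probe_map(path: str | Path) -> ProbeMap:
    return ProbeMap(_read_pairs(path))


# ---------------------------------------------------------------------------
# probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For genes measured by several probes the probe with maximal unbiased
    row variance is kept, so downstream variance filtering sees the most
    informative measurement.  Unmapped probes are dropped (count logged).
    Gene order follows first appearance of each gene among the probes.
    """
    if not probe_map.pairs:
        raise FormatError("probe map is empty")
    variances = matrix.values.var(axis=1, ddof=1) if matrix.n_samples > 1 else np.zeros(matrix.n_genes)
    best: dict[str, int] = {}
    order: list[str] = []
    n_unmapped = 0
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_map.gene_of(probe)
        if gene is None:
            n_unmapped += 1
            continue
        if gene not in best:
            best[gene] = i
            order.append(gene)
        elif variances[i] > variances[best[gene]]:
            best[gene] = i
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    if not order:
        raise FormatError("no probe of the matrix is covered by the probe map")
    rows = [best[g] for g in order]
    return ExpressionMatrix(order, list(matrix.sample_ids), matrix.values[rows])
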