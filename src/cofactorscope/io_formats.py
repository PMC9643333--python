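"""Readers and writers for the on-disk formats the pipeline touches.

Every parser validates strictly and raises :class:`FormatError` naming the
offending line (and motif id where available).  Coordinates are 0-based
half-open throughout, matching BED semantics.

Formats:

* JASPAR-style multi-motif text for PWMs (counts or probabilities; counts
  are normalised per column).
* BED3+ for ChIP-seq peaks.
* A four-column module TSV: ``module_id  cell_line  support  m1,m2,...``.
* A four-column PPI edge TSV: ``protein_a  protein_b  is_tf_a  is_tf_b``.
* Gene annotation TSV (``gene_id  chrom  tss  strand``) and a two-column
  gene-to-GO-term map.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = ("A", "C", "G", "T")

__all__ = [
    "ALPHABET",
    "FormatError",
    "PWM",
    "Peak",
    "MotifModule",
    "PPIEdgeList",
    "GeneAnnotation",
    "parse_pwm_file",
    "write_pwm_file",
    "parse_bed",
    "write_bed",
    "parse_modules",
    "write_modules",
    "parse_edge_list",
    "write_edge_list",
    "parse_annotation",
    "write_annotation",
    "parse_gene2go",
    "write_gene2go",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class PWM:
    """A position weight matrix: per-column nucleotide probabilities.

    ``matrix`` has shape ``(4, width)`` with rows ordered A, C, G, T.
    Every column must sum to 1 (within 1e-6) and the width must be >= 4.
    """

    motif_id: str
    matrix: np.ndarray
    tf_names: list[str] = field(default_factory=list)
    source: str = "predicted"  # {"predicted", "known"}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(
                f"PWM {self.motif_id!r}: matrix must have shape (4, w), "
                f"got {self.matrix.shape}"
            )
        if self.width < 4:
            raise ValueError(f"PWM {self.motif_id!r}: width {self.width} < 4")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError(f"PWM {self.motif_id!r}: entries outside [0, 1]")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"PWM {self.motif_id!r}: column {bad} sums to {sums[bad]:.8f}, not 1"
            )
        if self.source not in ("predicted", "known"):
            raise ValueError(f"PWM {self.motif_id!r}: bad source {self.source!r}")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        tf_names: list[str] | None = None,
        source: str = "predicted",
    ) -> "PWM":
        """Build a PWM from a count (or probability) matrix, normalising columns."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise FormatError(
                f"motif {motif_id!r}: expected 4 rows, got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise FormatError(f"motif {motif_id!r}: negative count")
        sums = counts.sum(axis=0)
        if np.any(sums <= 0):
            bad = int(np.argmax(sums <= 0))
            raise FormatError(f"motif {motif_id!r}: column {bad} sums to zero")
        return cls(motif_id, counts / sums, list(tf_names or []), source)

    def allclose(self, other: "PWM", atol: float = 1e-9) -> bool:
        return (
            self.motif_id == other.motif_id
            and self.tf_names == other.tf_names
            and self.source == other.source
            and self.matrix.shape == other.matrix.shape
            and bool(np.allclose(self.matrix, other.matrix, atol=atol))
        )


@dataclass(frozen=True)
class Peak:
    """A genomic interval (0-based half-open) called in one cell line."""

    chrom: str
    start: int
    end: int
    cell_line: str = ""
    peak_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak {self.peak_id!r}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.peak_id!r}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class MotifModule:
    """A set of >=2 motifs that co-occur in ``support`` input sequences."""

    module_id: str
    cell_line: str
    motif_ids: frozenset[str]
    support: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif_ids", frozenset(self.motif_ids))
        if len(self.motif_ids) < 2:
            raise ValueError(f"module {self.module_id!r}: fewer than 2 motifs")
        if self.support < 1:
            raise ValueError(f"module {self.module_id!r}: support {self.support} < 1")

    @property
    def size(self) -> int:
        return len(self.motif_ids)


@dataclass
class PPIEdgeList:
    """Undirected protein-protein interactions plus per-protein TF flags."""

    edges: set[frozenset[str]]
    tf_flags: dict[str, bool]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge {set(e)}")
            for p in e:
                if p not in self.tf_flags:
                    raise ValueError(f"edge endpoint {p!r} missing from tf_flags")

    @property
    def n_tfs(self) -> int:
        return sum(bool(v) for v in self.tf_flags.values())

    def tfs(self) -> set[str]:
        return {p for p, f in self.tf_flags.items() if f}


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene with a single transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# PWM (JASPAR-style) files
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^([ACGTacgt])\s*\[?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def parse_pwm_file(path: str | Path, source: str = "known") -> list[PWM]:
    """Parse a JASPAR-style multi-motif text file.

    Each block is a ``>`` header (motif id followed by optional TF names)
    and four rows ``A [counts...]`` ... ``T [counts...]``.  Counts or
    probabilities are accepted; columns are normalised to probabilities.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pwms: list[PWM] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path.name}:{i + 1}: expected '>' header, got {line!r}")
        tokens = line[1:].split()
        if not tokens:
            raise FormatError(f"{path.name}:{i + 1}: empty motif header")
        motif_id, tf_names = tokens[0], tokens[1:]
        rows: list[list[float]] = []
        for j, base in enumerate(ALPHABET):
            li = i + 1 + j
            if li >= n:
                raise FormatError(
                    f"{path.name}:{li + 1}: motif {motif_id!r} truncated before row {base}"
                )
            m = _ROW_RE.match(lines[li].strip())
            if m is None:
                raise FormatError(
                    f"{path.name}:{li + 1}: motif {motif_id!r}: malformed matrix row"
                )
            if m.group(1).upper() != base:
                raise FormatError(
                    f"{path.name}:{li + 1}: motif {motif_id!r}: expected row {base}, "
                    f"got {m.group(1).upper()}"
                )
            try:
                values = [float(x) for x in m.group(2).split()]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{li + 1}: motif {motif_id!r}: non-numeric entry"
                ) from exc
            rows.append(values)
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(
                f"{path.name}:{i + 2}: motif {motif_id!r}: rows have unequal widths "
                f"{sorted(len(r) for r in rows)}"
            )
        pwms.append(PWM.from_counts(motif_id, np.array(rows), tf_names, source))
        i += 5
    return pwms


def write_pwm_file(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write PWMs as JASPAR-style probability matrices."""
    with open(path, "w") as fh:
        for pwm in pwms:
            header = " ".join([pwm.motif_id, *pwm.tf_names])
            fh.write(f">{header}\n")
            for base, row in zip(ALPHABET, pwm.matrix):
                cells = " ".join(f"{v:.10f}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------


def parse_bed(path: str | Path, cell_line: str = "") -> list[Peak]:
    """Parse a BED3+ file into peaks tagged with ``cell_line``."""
    path = Path(path)
    peaks: list[Peak] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path.name}:{ln}: fewer than 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path.name}:{ln}: non-integer coordinate") from exc
        if start < 0:
            raise FormatError(f"{path.name}:{ln}: negative start {start}")
        if start >= end:
            raise FormatError(f"{path.name}:{ln}: start {start} >= end {end}")
        peak_id = fields[3] if len(fields) > 3 else f"{cell_line or 'peak'}_{ln}"
        peaks.append(Peak(chrom, start, end, cell_line, peak_id))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


# ---------------------------------------------------------------------------
# Motif-module TSV
# ---------------------------------------------------------------------------


def parse_modules(path: str | Path) -> list[MotifModule]:
    """Parse the module TSV: ``module_id  cell_line  support  m1,m2,...``."""
    path = Path(path)
    modules: list[MotifModule] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path.name}:{ln}: expected 4 columns, got {len(fields)}")
        module_id, cell_line, support_s, members_s = fields
        try:
            support = int(support_s)
        except ValueError as exc:
            raise FormatError(f"{path.name}:{ln}: non-integer support") from exc
        members = [m for m in members_s.split(",") if m]
        if len(members) != len(set(members)):
            raise FormatError(
                f"{path.name}:{ln}: module {module_id!r} has duplicate motif ids"
            )
        if len(members) < 2:
            raise FormatError(
                f"{path.name}:{ln}: module {module_id!r} has fewer than 2 motifs"
            )
        if support < 1:
            raise FormatError(f"{path.name}:{ln}: module {module_id!r} support < 1")
        modules.append(MotifModule(module_id, cell_line, frozenset(members), support))
    return modules


def write_modules(modules: Iterable[MotifModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in modules:
            members = ",".join(sorted(m.motif_ids))
            fh.write(f"{m.module_id}\t{m.cell_line}\t{m.support}\t{members}\n")


# ---------------------------------------------------------------------------
# PPI edge TSV
# ---------------------------------------------------------------------------


def parse_edge_list(path: str | Path) -> PPIEdgeList:
    """Parse ``protein_a  protein_b  is_tf_a  is_tf_b`` rows.

    Edges are deduplicated as unordered pairs; self-edges are dropped with a
    logged warning.  Conflicting TF flags for the same protein are an error.
    """
    path = Path(path)
    edges: set[frozenset[str]] = set()
    tf_flags: dict[str, bool] = {}
    n_self = 0
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path.name}:{ln}: expected 4 columns, got {len(fields)}")
        a, b, fa_s, fb_s = fields[:4]
        if fa_s not in ("0", "1") or fb_s not in ("0", "1"):
            raise FormatError(f"{path.name}:{ln}: TF flags must be 0 or 1")
        for prot, flag_s in ((a, fa_s), (b, fb_s)):
            flag = flag_s == "1"
            if prot in tf_flags and tf_flags[prot] != flag:
                raise FormatError(
                    f"{path.name}:{ln}: conflicting TF flag for protein {prot!r}"
                )
            tf_flags[prot] = flag
        if a == b:
            n_self += 1
            continue
        edges.add(frozenset((a, b)))
    if n_self:
        logger.warning("%s: dropped %d self-edge(s)", path.name, n_self)
    return PPIEdgeList(edges, tf_flags)


def write_edge_list(ppi: PPIEdgeList, path: str | Path) -> None:
    """Write edges; isolated proteins are emitted as self-rows so their TF
    flags survive a round trip (the parser drops self-edges but keeps flags)."""
    with open(path, "w") as fh:
        for e in sorted(tuple(sorted(e)) for e in ppi.edges):
            a, b = e
            fh.write(
                f"{a}\t{b}\t{int(ppi.tf_flags[a])}\t{int(ppi.tf_flags[b])}\n"
            )
        connected = {p for e in ppi.edges for p in e}
        for p in sorted(set(ppi.tf_flags) - connected):
            fh.write(f"{p}\t{p}\t{int(ppi.tf_flags[p])}\t{int(ppi.tf_flags[p])}\n")


# ---------------------------------------------------------------------------
# Gene annotation and gene->GO map
# ---------------------------------------------------------------------------


def parse_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Parse ``gene_id  chrom  tss  strand`` rows; one TSS per gene."""
    path = Path(path)
    seen: set[str] = set()
    genes: list[GeneAnnotation] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path.name}:{ln}: expected 4 columns, got {len(fields)}")
        gene_id, chrom, tss_s, strand = fields
        if gene_id in seen:
            raise FormatError(f"{path.name}:{ln}: duplicate gene {gene_id!r}")
        seen.add(gene_id)
        try:
            tss = int(tss_s)
        except ValueError as exc:
            raise FormatError(f"{path.name}:{ln}: non-integer TSS") from exc
        try:
            genes.append(GeneAnnotation(gene_id, chrom, tss, strand))
        except ValueError as exc:
            raise FormatError(f"{path.name}:{ln}: {exc}") from exc
    return genes


def write_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def parse_gene2go(path: str | Path) -> dict[str, set[str]]:
    """Parse a two-column ``gene_id  term_id`` map."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path.name}:{ln}: expected 2 columns, got {len(fields)}")
        out.setdefault(fields[0], set()).add(fields[1])
    return out


def write_gene2go(gene2go: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene2go):
            for term in sorted(gene2go[gene]):
                fh.write(f"{gene}\t{term}\n")
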