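"""Domain types and readers/writers for the formats the pipeline touches.

All genomic intervals are 0-based half-open (BED convention); GFF input is
converted at the boundary.  Read sequences are stored uppercase with ``U``
(T and U are treated as equivalent on input).  The genome itself is kept in
DNA alphabet as read from FASTA.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ELEMENT_CLASSES = frozenset(
    {
        "exon",
        "intron",
        "utr5",
        "utr3",
        "transposon_known",
        "transposon_unknown",
        "rRNA",
        "tRNA",
        "snoRNA",
        "known_miRNA",
        "gene_model",
    }
)

#: Class labels a cluster can carry after classification.
CLASS_LABELS = (
    "known_miRNA",
    "miRNA_candidate_HU",
    "tRNA",
    "snoRNA",
    "endo_siRNA",
    "piRNA",
    "mer25",
    "unclassified",
)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def to_rna(sequence: str) -> str:
    """Uppercase and convert T to U."""
    return sequence.upper().replace("T", "U")


def to_dna(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def reverse_complement_rna(sequence: str) -> str:
    return sequence.translate(_RNA_COMPLEMENT)[::-1]


def reverse_complement_dna(sequence: str) -> str:
    return sequence.translate(_DNA_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed input rows; message names the offending line."""


@dataclass(frozen=True)
class MappedRead:
    """One genomic alignment of a collapsed small-RNA sequence.

    ``count`` is the total abundance of the collapsed sequence in its library
    and ``n_mappings`` the number of genomic loci the sequence maps to; a
    sequence mapping to *k* loci appears as *k* MappedRead records sharing
    ``count`` and ``n_mappings``.
    """

    scaffold: str
    start: int
    end: int
    strand: str
    sequence: str
    count: int = 1
    n_mappings: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        if self.start < 0 or self.end < 0:
            raise ValueError(
                f"negative coordinate for read on {self.scaffold}: "
                f"{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"interval length {self.end - self.start} != sequence length "
                f"{len(self.sequence)} for read at "
                f"{self.scaffold}:{self.start}-{self.end}"
            )
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.n_mappings < 1:
            raise ValueError(f"n_mappings must be >= 1, got {self.n_mappings}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        """Distinctness key: (scaffold, start, end, strand, sequence)."""
        return (self.scaffold, self.start, self.end, self.strand, self.sequence)


@dataclass
class AnnotationTrack:
    """A set of genomic intervals of one element class.

    Intervals are ``(scaffold, start, end, strand, name)`` tuples, 0-based
    half-open.  Overlapping intervals are preserved as given, not merged.
    """

    element_class: str
    intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(
                f"unknown element class {self.element_class!r}; "
                f"expected one of {sorted(ELEMENT_CLASSES)}"
            )
        for iv in self.intervals:
            if iv[1] >= iv[2]:
                raise ValueError(f"empty or inverted interval {iv}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int, str, str]]:
        return iter(self.intervals)


@dataclass
class Library:
    """A small-RNA library: a named collection of mapped reads.

    ``depth`` counts each distinct collapsed sequence once, however many
    genomic loci it maps to.
    """

    name: str
    stage_label: str
    reads: list[MappedRead] = field(default_factory=list)

    @property
    def depth(self) -> int:
        seen: dict[str, int] = {}
        for r in self.reads:
            seen[r.sequence] = r.count
        return sum(seen.values())


# ---------------------------------------------------------------------------
# Mapped-read I/O
# ---------------------------------------------------------------------------

def _parse_read_row(fields: list[str], lineno: int, path: str) -> MappedRead:
    if len(fields) < 4:
        raise ParseError(f"{path}:{lineno}: expected >= 4 columns, got {len(fields)}")
    scaffold, start_s, end_s = fields[0], fields[1], fields[2]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    sequence = None
    count = 1
    n_mappings = 1
    strand = "+"
    for tok in fields[3:]:
        for sub in tok.split(";"):
            if sub in ("+", "-"):
                strand = sub
            elif sub.startswith("seq="):
                sequence = sub[4:]
            elif sub.startswith("count="):
                count = int(sub[6:])
            elif sub.startswith("nh="):
                n_mappings = int(sub[3:])
    if sequence is None:
        raise ParseError(f"{path}:{lineno}: missing seq= field")
    try:
        return MappedRead(scaffold, start, end, strand, sequence, count, n_mappings)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_mapped_reads(path: str | Path, format: str = "tsv") -> list[MappedRead]:
    """Read mapped reads from a BED-like TSV or a SAM/BAM file.

    The tabular dialect is one row per mapping::

        scaffold  start  end  seq=...;count=...;nh=...  strand

    with the key=value fields accepted in any order, joined by ``;`` or as
    separate columns.  For SAM/BAM, mapping multiplicity is taken from the
    ``NH`` tag and abundance from a trailing ``_xN`` in the query name
    (collapsed-read convention), defaulting to 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("sam", "bam"):
        return _read_sam(path)
    if format != "tsv":
        raise ValueError(f"unknown read format {format!r}")
    reads: list[MappedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            reads.append(_parse_read_row(line.split(), lineno, str(path)))
    return reads


def _read_sam(path: Path) -> list[MappedRead]:
    import pysam

    mode = "rb" if path.suffix == ".bam" else "r"
    reads = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence
            if aln.is_reverse:
                seq = reverse_complement_dna(seq)
                strand = "-"
            else:
                strand = "+"
            count = 1
            name = aln.query_name or ""
            if "_x" in name:
                tail = name.rsplit("_x", 1)[1]
                if tail.isdigit():
                    count = int(tail)
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            reads.append(
                MappedRead(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    strand,
                    seq,
                    count,
                    int(nh),
                )
            )
    return reads


def write_mapped_reads(reads: Iterable[MappedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\t"
                f"seq={r.sequence};count={r.count};nh={r.n_mappings}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path, format: Optional[str] = None, element_class: str = "exon"
) -> AnnotationTrack:
    """Read a BED or GFF/GTF file into an AnnotationTrack.

    GFF coordinates (1-based inclusive) are converted to 0-based half-open.
    ``format`` is inferred from the extension when omitted.
    """
    path = Path(path)
    if element_class not in ELEMENT_CLASSES:
        raise ValueError(f"unknown element class {element_class!r}")
    if format is None:
        suffix = path.suffix.lower()
        format = "gff" if suffix in (".gff", ".gff3", ".gtf") else "bed"
    intervals: list[tuple[str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            try:
                if format == "gff":
                    scaffold = f[0]
                    start, end = int(f[3]) - 1, int(f[4])
                    strand = f[6] if len(f) > 6 and f[6] in "+-" else "+"
                    name = f[8] if len(f) > 8 else ""
                else:
                    scaffold = f[0]
                    start, end = int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else ""
                    strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            intervals.append((scaffold, start, end, strand, name))
    return AnnotationTrack(element_class, intervals)


def write_annotation(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track as 6-column BED."""
    with open(path, "w") as fh:
        for scaffold, start, end, strand, name in track:
            fh.write(f"{scaffold}\t{start}\t{end}\t{name or '.'}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Genome I/O
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as {scaffold: uppercase DNA string}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def genome_lengths(genome: dict[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


# ---------------------------------------------------------------------------
# Cluster report
# ---------------------------------------------------------------------------

CLUSTER_REPORT_COLUMNS = [
    "scaffold",
    "start",
    "end",
    "class",
    "ui",
    "ui_normalized",
    "peak_length",
    "total_count",
    "distinct_reads",
    "context",
    "fold_mfe",
    "randfold_p",
]

_NA = "NA"


def _fmt(value, ndigits=None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return _NA
    if ndigits is not None and isinstance(value, float):
        return f"{value:.{ndigits}g}" if ndigits > 6 else f"{round(value, ndigits)}"
    return str(value)


def write_cluster_report(clusters, path: str | Path) -> None:
    """Write one row per classified cluster (TSV with header).

    Clusters without a fold result emit ``NA`` in the fold columns.
    """
    from .classification import peak_length  # local import avoids a cycle

    with open(path, "w") as fh:
        fh.write("\t".join(CLUSTER_REPORT_COLUMNS) + "\n")
        for c in clusters:
            fold_mfe = c.fold.mfe if c.fold is not None else None
            randfold_p = c.fold.randfold_p if c.fold is not None else None
            row = [
                c.scaffold,
                str(c.start),
                str(c.end),
                c.label or "unclassified",
                f"{c.ui:.2f}",
                _fmt(c.ui_normalized, 10),
                str(peak_length(c.length_histogram)),
                str(c.total_count),
                str(c.distinct_reads),
                c.context or _NA,
                _fmt(fold_mfe, 2),
                _fmt(randfold_p, 10),
            ]
            fh.write("\t".join(row) + "\n")


def read_cluster_report(path: str | Path):
    """Read a cluster report back as a pandas DataFrame (NA-aware)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=[_NA])
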