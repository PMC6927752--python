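"""Coordinate types, interval algebra, and file-format readers/writers.

All coordinates are 0-based half-open internally.  RepeatMasker ``.out``
files (1-based inclusive) and VCF positions (1-based) are converted at
parse time; BED files pass through unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-anchored 0-based half-open interval, optionally stranded."""

    contig: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (STRAND_PLUS, STRAND_MINUS, STRAND_NONE):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across contigs)."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class GenomeSequence:
    """An ordered mapping of contig id to uppercase sequence over {A,C,G,T,N}."""

    contigs: dict[str, str]
    total_size: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_size = sum(len(s) for s in self.contigs.values())

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


#: Things that can stand in for a genome when only contig sizes matter.
ContigSizes = Union[GenomeSequence, Mapping[str, int]]


def contig_lengths_of(genome: ContigSizes) -> dict[str, int]:
    if isinstance(genome, GenomeSequence):
        return genome.contig_lengths
    return dict(genome)


_NORMALIZE = str.maketrans("U", "T")
_NON_ACGTN = re.compile("[^ACGTN]")


def parse_fasta(path: Union[str, Path]) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased, U is mapped to T, and any character outside
    {A,C,G,T,N} is replaced by N with a logged warning.  Contig order is
    preserved; duplicate ids or an empty file raise :class:`FormatError`.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig id {record.id!r} in {path}")
        seq = str(record.seq).upper().translate(_NORMALIZE)
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            log.warning(
                "contig %s: %d characters outside {A,C,G,T,N} mapped to N",
                record.id, n_bad,
            )
            seq = _NON_ACGTN.sub("N", seq)
        contigs[record.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated repeat copy (e.g. a single Helitron fragment)."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str = "."

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise ValueError("repeat_name must be non-empty")


def _looks_like_rm_header(fields: Sequence[str]) -> bool:
    return not fields or fields[0] in ("SW", "score") or fields[0].startswith("#")


def parse_repeatmasker(
    path: Union[str, Path], keyword: str = ""
) -> list[RepeatAnnotation]:
    """Read repeat annotations from a RepeatMasker ``.out`` file or BED.

    ``keyword`` is matched case-insensitively as a substring against both
    the repeat name and class; an empty keyword keeps everything.  ``.out``
    coordinates (1-based inclusive) are converted to 0-based half-open.
    Records are returned in file order.
    """
    kw = keyword.lower()
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if _looks_like_rm_header(fields):
                continue
            try:
                if len(fields) >= 11 and fields[0].lstrip("-").isdigit():
                    # RepeatMasker .out row: score div del ins query begin end
                    # (left) strand repeat class ...
                    contig = fields[4]
                    start = int(fields[5]) - 1
                    end = int(fields[6])
                    strand = STRAND_MINUS if fields[8] in ("C", "-") else STRAND_PLUS
                    name, rclass = fields[9], fields[10]
                elif 3 <= len(fields) <= 6:
                    # BED3/BED6
                    contig = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    name = fields[3] if len(fields) > 3 else "."
                    rclass = "."
                    strand = fields[5] if len(fields) > 5 else STRAND_NONE
                else:
                    raise ValueError("unrecognized column layout")
                ann = RepeatAnnotation(
                    GenomicInterval(contig, start, end, strand), name, rclass
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: cannot parse line {lineno}: {exc}") from exc
            if not kw or kw in ann.repeat_name.lower() or kw in ann.repeat_class.lower():
                out.append(ann)
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping intervals into maximal runs.

    Output is sorted by (contig, start) and unstranded.  Abutting intervals
    ([a,b) followed by [b,c)) are *not* merged — only a >= 1 bp overlap
    joins two inputs — so covered-base totals are preserved exactly while
    interval counts stay deterministic.
    """
    items = sorted(intervals, key=lambda iv: (iv.contig, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if (
            merged
            and merged[-1].contig == iv.contig
            and iv.start < merged[-1].end
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.contig, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return merged


def genome_fraction(
    merged_intervals: Iterable[GenomicInterval], genome: ContigSizes
) -> float:
    """Fraction of the genome covered by an already-merged interval set."""
    sizes = contig_lengths_of(genome)
    total = sum(sizes.values())
    covered = 0
    for iv in merged_intervals:
        if iv.contig not in sizes:
            raise ValueError(f"interval on unknown contig {iv.contig!r}")
        covered += iv.length
    return covered / total


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcriptional start site."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        if self.strand == STRAND_PLUS:
            return self.interval.start
        return self.interval.end - 1


def read_gene_table(path: Union[str, Path]) -> list[GeneModel]:
    """Read genes from a TSV with columns gene_id, contig, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    required = {"gene_id", "contig", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneModel(
            row.gene_id,
            GenomicInterval(row.contig, int(row.start), int(row.end), row.strand),
            row.strand,
        )
        for row in df.itertuples(index=False)
    ]


def read_gff3_genes(path: Union[str, Path]) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 subset (9 tab-separated columns)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            if fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}: line {lineno}: gene has no ID attribute")
            start, end, strand = int(fields[3]) - 1, int(fields[4]), fields[6]
            genes.append(
                GeneModel(gene_id, GenomicInterval(fields[0], start, end, strand), strand)
            )
    return genes


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open, as on disk)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                strand = fields[5] if len(fields) > 5 else STRAND_NONE
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: cannot parse line {lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: Union[str, Path],
    names: Iterable[str] | None = None,
) -> None:
    """Write BED6 (name defaults to '.', score 0)."""
    name_iter = iter(names) if names is not None else None
    with open(path, "w") as fh:
        for iv in intervals:
            name = next(name_iter) if name_iter is not None else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def summit_positions(intervals: Iterable[GenomicInterval]) -> list[tuple[str, int]]:
    """Collapse BED records to single-bp summit positions (midpoint)."""
    return [(iv.contig, iv.start + (iv.length - 1) // 2) for iv in intervals]
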