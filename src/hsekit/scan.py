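"""Degenerate IUPAC motif scanning on both strands.

Every start position is tested independently, so overlapping and tandem
occurrences are all reported (a plain regex ``findall`` would skip them).
A window matching on both strands yields two records.  An N in the genome
never matches any pattern symbol, including N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .core import (
    STRAND_MINUS,
    STRAND_PLUS,
    GenomeSequence,
    GenomicInterval,
)

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: The default degenerate heat-shock element, two inverted nGAAn units
#: flanking a central nTTCn.
DEFAULT_HSE_MOTIF = "NGAANNTTCNNGAAN"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) IUPAC string."""
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif with per-position allowed-base sets."""

    motif_string: str
    forward_sets: tuple[frozenset[str], ...]
    reverse_sets: tuple[frozenset[str], ...]

    @property
    def length(self) -> int:
        return len(self.motif_string)

    @property
    def reverse_complement_string(self) -> str:
        return reverse_complement(self.motif_string)

    @property
    def n_fixed_positions(self) -> int:
        return sum(1 for s in self.forward_sets if len(s) == 1)


def compile_iupac_pattern(motif_string: str) -> MotifPattern:
    """Compile an IUPAC string into allowed-base sets for both strands."""
    motif = motif_string.upper()
    forward = []
    for pos, ch in enumerate(motif):
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"illegal IUPAC character {ch!r} at position {pos} of {motif_string!r}"
            )
        forward.append(IUPAC_SETS[ch])
    reverse = [IUPAC_SETS[ch] for ch in reverse_complement(motif)]
    return MotifPattern(motif, tuple(forward), tuple(reverse))


@dataclass(frozen=True, order=True)
class MotifMatch:
    """One motif occurrence; ``matched_seq`` is read on the + strand."""

    interval: GenomicInterval
    strand: str
    matched_seq: str


def _overlapping_regex(sets: Iterable[frozenset[str]]) -> re.Pattern[str]:
    # Lookahead with a capture group reports overlapping windows too.
    body = "".join("[" + "".join(sorted(s)) + "]" for s in sets)
    return re.compile(f"(?=({body}))")


def scan_genome(
    genome: GenomeSequence,
    pattern: MotifPattern,
    strands: str = "both",
    dedupe_spans: bool = False,
) -> list[MotifMatch]:
    """Report every position where the motif matches on the requested strands.

    A minus-strand match at [i, i+L) means the reverse complement of the
    genome window equals the motif, i.e. the window satisfies the pattern's
    reverse-complement allowed sets on the + strand text.  With
    ``dedupe_spans`` a window matching on both strands is collapsed to one
    record (kept strand: +).
    """
    if strands not in ("both", "plus", "minus"):
        raise ValueError(f"strands must be both/plus/minus, got {strands!r}")
    fwd_re = _overlapping_regex(pattern.forward_sets)
    rev_re = _overlapping_regex(pattern.reverse_sets)
    matches: list[MotifMatch] = []
    length = pattern.length
    for contig, seq in genome.contigs.items():
        if strands in ("both", "plus"):
            for m in fwd_re.finditer(seq):
                i = m.start()
                matches.append(
                    MotifMatch(
                        GenomicInterval(contig, i, i + length, STRAND_PLUS),
                        STRAND_PLUS,
                        m.group(1),
                    )
                )
        if strands in ("both", "minus"):
            for m in rev_re.finditer(seq):
                i = m.start()
                matches.append(
                    MotifMatch(
                        GenomicInterval(contig, i, i + length, STRAND_MINUS),
                        STRAND_MINUS,
                        m.group(1),
                    )
                )
    matches.sort(key=lambda m: (m.interval.contig, m.interval.start, m.strand))
    if dedupe_spans:
        seen: set[tuple[str, int]] = set()
        unique = []
        for m in matches:
            key = (m.interval.contig, m.interval.start)
            if key not in seen:
                seen.add(key)
                unique.append(m)
        matches = unique
    return matches


def write_matches_bed(matches: Iterable[MotifMatch], path) -> None:
    """BED6 with the matched + strand sequence in the name column."""
    with open(path, "w") as fh:
        for m in matches:
            iv = m.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{m.matched_seq}\t0\t{m.strand}\n"
            )


def read_matches_bed(path) -> list[MotifMatch]:
    matches = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, _score, strand = line.split()[:6]
            matches.append(
                MotifMatch(
                    GenomicInterval(contig, int(start), int(end), strand), strand, name
                )
            )
    return matches
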