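"""Partition motif matches into repeat-acquired vs repeat-independent,
call bound matches from peak summits, and per-genome overlap summaries."""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import (
    GenomeSequence,
    GenomicInterval,
    RepeatAnnotation,
    genome_fraction,
    merge_intervals,
    overlap_bp,
)
from .density import window_counts
from .scan import MotifMatch, MotifPattern, scan_genome
from .stats import binomial_overlap_test

log = logging.getLogger(__name__)

CATEGORY_ACQUIRED = "Hac"
CATEGORY_INDEPENDENT = "Hin"


@dataclass(frozen=True)
class HseClassification:
    match: MotifMatch
    category: str
    host_repeat: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.category == CATEGORY_ACQUIRED) != (self.host_repeat is not None):
            raise ValueError("host_repeat must be present exactly for Hac")


class _ContigIndex:
    """Sorted-start lookup of merged (disjoint) intervals on one contig."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.starts = [iv.start for iv in intervals]
        self.intervals = list(intervals)

    def containing(self, start: int, end: int) -> Optional[GenomicInterval]:
        i = bisect.bisect_right(self.starts, start) - 1
        if i >= 0:
            iv = self.intervals[i]
            if iv.start <= start and end <= iv.end:
                return iv
        return None


def classify_hses(
    matches: Iterable[MotifMatch],
    merged_repeats: Sequence[GenomicInterval],
    annotations: Optional[Sequence[RepeatAnnotation]] = None,
) -> list[HseClassification]:
    """Label each match Hac iff its interval lies entirely within one merged
    repeat interval; everything else is Hin.

    ``host_repeat`` is taken from the original (unmerged) annotation with
    maximal overlap, ties broken by file order; if no annotations are
    supplied the merged interval's coordinates are used as the host name.
    """
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in merged_repeats:
        by_contig.setdefault(iv.contig, []).append(iv)
    index = {c: _ContigIndex(sorted(ivs, key=lambda x: x.start)) for c, ivs in by_contig.items()}

    ann_by_contig: dict[str, list[RepeatAnnotation]] = {}
    if annotations:
        for ann in annotations:
            ann_by_contig.setdefault(ann.interval.contig, []).append(ann)

    out: list[HseClassification] = []
    for m in matches:
        iv = m.interval
        host = None
        idx = index.get(iv.contig)
        if idx is not None:
            host = idx.containing(iv.start, iv.end)
        if host is None:
            out.append(HseClassification(m, CATEGORY_INDEPENDENT))
            continue
        name = f"{host.contig}:{host.start}-{host.end}"
        if annotations:
            best_ov = 0
            for ann in ann_by_contig.get(iv.contig, ()):
                ov = overlap_bp(iv, ann.interval)
                if ov > best_ov:
                    best_ov, name = ov, ann.repeat_name
        out.append(HseClassification(m, CATEGORY_ACQUIRED, name))
    return out


def summit_windows(
    summits: Iterable[tuple[str, int]], window_bp: int = 101
) -> list[GenomicInterval]:
    """Center a fixed odd-width window on each single-bp summit position."""
    if window_bp % 2 == 0:
        raise ValueError("window_bp must be odd (no unique center)")
    half = window_bp // 2
    out = []
    for contig, pos in summits:
        out.append(GenomicInterval(contig, max(0, pos - half), pos + half + 1))
    return out


def bound_hses_from_summits(
    matches: Sequence[MotifMatch],
    summits: Iterable[tuple[str, int]],
    window_bp: int = 101,
    min_overlap_bp: int = 14,
) -> list[MotifMatch]:
    """Matches overlapping any single summit window by >= ``min_overlap_bp``.

    Each match is reported at most once, in input order.
    """
    windows = summit_windows(summits, window_bp)
    win_by_contig: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        win_by_contig.setdefault(w.contig, []).append(w)
    for ws in win_by_contig.values():
        ws.sort(key=lambda w: w.start)
    bound: list[MotifMatch] = []
    for m in matches:
        iv = m.interval
        ws = win_by_contig.get(iv.contig, ())
        starts = [w.start for w in ws]
        # only windows starting within window_bp of the match can overlap
        lo = bisect.bisect_left(starts, iv.start - window_bp)
        hi = bisect.bisect_right(starts, iv.end)
        if any(overlap_bp(iv, w) >= min_overlap_bp for w in ws[lo:hi]):
            bound.append(m)
    return bound


@dataclass
class SpeciesOverlapSummary:
    species: str
    n_hse_total: int
    n_hse_in_repeat: int
    repeat_fraction: float
    binomial_p: float
    n_windows_gt_threshold: int

    def __post_init__(self) -> None:
        if self.n_hse_in_repeat > self.n_hse_total:
            raise ValueError("n_hse_in_repeat exceeds n_hse_total")


def species_overlap_summary(
    genome: GenomeSequence,
    repeat_annotations: Sequence[RepeatAnnotation],
    pattern: MotifPattern,
    species: str = "unnamed",
    window_bp: int = 1000,
    density_threshold: int = 10,
) -> SpeciesOverlapSummary:
    """Scan, classify, test overlap enrichment, and count high-density windows.

    With no repeat annotations the repeat fraction is undefined; the
    binomial p is reported as 1 with a warning.
    """
    matches = scan_genome(genome, pattern)
    merged = merge_intervals([a.interval for a in repeat_annotations])
    classified = classify_hses(matches, merged)
    n_total = len(classified)
    n_in = sum(1 for c in classified if c.category == CATEGORY_ACQUIRED)
    fraction = genome_fraction(merged, genome) if merged else 0.0
    if not merged or not (0 < fraction < 1) or n_total == 0:
        log.warning(
            "species %s: degenerate overlap test (fraction=%s, n=%d); p set to 1",
            species, fraction, n_total,
        )
        p = 1.0
    else:
        p = binomial_overlap_test(n_in, n_total, fraction).p_value
    profile = window_counts(matches, genome, window_bp=window_bp, step_bp=window_bp)
    return SpeciesOverlapSummary(
        species=species,
        n_hse_total=n_total,
        n_hse_in_repeat=n_in,
        repeat_fraction=fraction,
        binomial_p=p,
        n_windows_gt_threshold=profile.n_high_windows(density_threshold),
    )
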