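"""Sliding-window Tajima's D from biallelic SNPs.

Implements the standard estimator: D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))
with the usual constants derived from the number of sampled haplotypes.
Sites with any missing genotype are dropped from both S and pi
(complete-case), and diploid genotypes are decomposed into haplotypes
ignoring phase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .core import GenomicInterval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Normalizing constants for a sample of ``n`` haplotypes (n >= 2)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(seg_sites: int, pi: float, n: int) -> Optional[float]:
    """D for one window; None when undefined (S = 0 or n < 3)."""
    if seg_sites == 0 or n < 3:
        return None
    k = tajima_constants(n)
    var = k.e1 * seg_sites + k.e2 * seg_sites * (seg_sites - 1)
    if var <= 0:  # degenerate, e.g. n = 3 with S = 1
        return None
    return (pi - seg_sites / k.a1) / math.sqrt(var)


@dataclass
class TajimaWindow:
    interval: GenomicInterval
    n_samples: int
    seg_sites: int
    pi: float
    d_value: Optional[float]

    @property
    def defined(self) -> bool:
        return self.d_value is not None


@dataclass
class SiteTable:
    """Biallelic SNPs as per-contig positions and derived-allele counts."""

    positions: dict[str, np.ndarray]  # 0-based
    alt_counts: dict[str, np.ndarray]
    n_haplotypes: int


def load_biallelic_sites(vcf_path) -> SiteTable:
    """Read CHROM/POS/REF/ALT/GT from a VCF, keeping complete-case
    biallelic SNPs only.  Non-biallelic or non-SNP records are skipped
    with a warning; any missing genotype drops the whole site."""
    vf = pysam.VariantFile(str(vcf_path))
    positions: dict[str, list[int]] = {}
    counts: dict[str, list[int]] = {}
    n_hap = None
    n_skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_skipped += 1
            continue
        alleles: list[int] = []
        complete = True
        for sample in rec.samples.values():
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                complete = False
                break
            alleles.extend(gt)
        if not complete:
            continue
        if n_hap is None:
            n_hap = len(alleles)
        elif len(alleles) != n_hap:
            raise ValueError(f"inconsistent ploidy at {rec.chrom}:{rec.pos}")
        positions.setdefault(rec.chrom, []).append(rec.pos - 1)
        counts.setdefault(rec.chrom, []).append(sum(alleles))
    if n_skipped:
        log.warning("skipped %d non-biallelic-SNP records", n_skipped)
    return SiteTable(
        positions={c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        alt_counts={c: np.array(v, dtype=np.int64) for c, v in counts.items()},
        n_haplotypes=n_hap or 0,
    )


def window_stats(alt_counts: np.ndarray, n: int) -> tuple[int, float]:
    """(S, pi) for a set of sites: S counts segregating sites and pi is the
    mean number of pairwise differences, summed over sites."""
    seg = (alt_counts > 0) & (alt_counts < n)
    c = alt_counts[seg].astype(float)
    pairs = n * (n - 1) / 2.0
    pi = float((c * (n - c)).sum() / pairs)
    return int(seg.sum()), pi


def sliding_tajima(
    sites: SiteTable,
    contig_lengths: Mapping[str, int],
    window_bp: int = 10_000,
    step_bp: int = 100,
) -> list[TajimaWindow]:
    """Tajima's D over sliding windows on every contig.

    Windows start at multiples of ``step_bp`` while the start lies on the
    contig; the trailing window is truncated at the contig end.  Windows
    with S = 0 or fewer than 3 haplotypes carry ``d_value = None``.
    """
    n = sites.n_haplotypes
    out: list[TajimaWindow] = []
    for contig, length in contig_lengths.items():
        pos = sites.positions.get(contig, np.empty(0, dtype=np.int64))
        alt = sites.alt_counts.get(contig, np.empty(0, dtype=np.int64))
        order = np.argsort(pos, kind="stable")
        pos, alt = pos[order], alt[order]
        for w_start in range(0, length, step_bp):
            w_end = min(w_start + window_bp, length)
            lo, hi = np.searchsorted(pos, [w_start, w_end])
            if n >= 2:
                s, pi = window_stats(alt[lo:hi], n)
            else:
                s, pi = 0, 0.0
            out.append(
                TajimaWindow(
                    GenomicInterval(contig, w_start, w_end),
                    n_samples=n,
                    seg_sites=s,
                    pi=pi,
                    d_value=tajima_d(s, pi, n),
                )
            )
    return out


def write_tajima_tsv(windows: Sequence[TajimaWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tS\tpi\tD\n")
        for w in windows:
            d = "NA" if w.d_value is None else f"{w.d_value:.6f}"
            fh.write(
                f"{w.interval.contig}\t{w.interval.start}\t{w.interval.end}"
                f"\t{w.seg_sites}\t{w.pi:.6f}\t{d}\n"
            )
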