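"""Heat-shock-responsive gene calling and strand-aware upstream proximity.

Distances are measured from the TSS to the nearest base of a site on the
gene's upstream side; a site straddling the TSS base counts as distance 0
and anything strictly downstream is ignored.  Genes are binned by their
*minimum* upstream distance, so each gene lands in at most one bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import STRAND_PLUS, GeneModel, GenomicInterval
from .scan import MotifMatch
from .stats import EnrichmentResult, chi2_proximity_test, hypergeometric_overlap_test

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fold_change: float
    padj: float

    @property
    def is_up(self) -> bool:
        return self.fold_change > 2.0 and self.padj < 0.01


def read_expression_table(
    path,
    gene_col: str = "gene_id",
    fc_col: str = "fold_change",
    padj_col: str = "padj",
) -> pd.DataFrame:
    """Read a DE table; column names are remappable for DESeq2-style exports."""
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, fc_col, padj_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df.rename(
        columns={gene_col: "gene_id", fc_col: "fold_change", padj_col: "padj"}
    )[["gene_id", "fold_change", "padj"]]


def call_up_genes(
    expression: pd.DataFrame,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.01,
) -> set[str]:
    """Genes passing strict fold-change and adjusted-p thresholds."""
    for col in ("gene_id", "fold_change", "padj"):
        if col not in expression.columns:
            raise ValueError(f"expression table missing column {col!r}")
    mask = (expression["fold_change"] > fc_threshold) & (
        expression["padj"] < padj_threshold
    )
    return set(expression.loc[mask, "gene_id"].astype(str))


SiteLike = Union[MotifMatch, GenomicInterval]


def _site_interval(site: SiteLike) -> GenomicInterval:
    return site.interval if isinstance(site, MotifMatch) else site


def upstream_distance(gene: GeneModel, site: SiteLike) -> Optional[int]:
    """TSS-to-nearest-base distance when the site is upstream, else None."""
    iv = _site_interval(site)
    if iv.contig != gene.interval.contig:
        return None
    tss = gene.tss
    if iv.start <= tss < iv.end:
        return 0
    if gene.strand == STRAND_PLUS:
        if iv.start > tss:  # strictly downstream
            return None
        return tss - (iv.end - 1)
    if iv.end - 1 < tss:  # strictly downstream for a - gene
        return None
    return iv.start - tss


def min_upstream_distances(
    genes: Sequence[GeneModel],
    sites: Sequence[SiteLike],
    max_bp: Optional[int] = None,
) -> np.ndarray:
    """Per-gene minimum upstream distance to any site (inf when none).

    Vectorized per contig; ``max_bp`` only limits the search radius.
    """
    out = np.full(len(genes), np.inf)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        iv = _site_interval(s)
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    arrays = {
        c: (np.array([p[0] for p in ps]), np.array([p[1] for p in ps]))
        for c, ps in by_contig.items()
    }
    for gi, gene in enumerate(genes):
        pair = arrays.get(gene.interval.contig)
        if pair is None:
            continue
        starts, ends = pair
        tss = gene.tss
        overlap = (starts <= tss) & (tss < ends)
        if gene.strand == STRAND_PLUS:
            upstream = ends - 1 <= tss
            dist = tss - (ends - 1)
        else:
            upstream = starts >= tss
            dist = starts - tss
        dist = np.where(overlap, 0, dist)
        ok = upstream | overlap
        if max_bp is not None:
            ok &= dist < max_bp
        if ok.any():
            out[gi] = dist[ok].min()
    return out


@dataclass
class ProximityProfile:
    bin_bp: int
    max_bp: int
    observed: np.ndarray
    background_mean: np.ndarray
    n_reps: int
    within_cutoff_bp: int
    observed_within: int
    expected_within: float
    enrichment: EnrichmentResult


def _bin_counts(distances: np.ndarray, bin_bp: int, n_bins: int) -> np.ndarray:
    finite = distances[np.isfinite(distances)]
    idx = (finite // bin_bp).astype(np.int64)
    idx = idx[idx < n_bins]
    return np.bincount(idx, minlength=n_bins)


def proximity_profile(
    up_genes: set[str],
    all_genes: Sequence[GeneModel],
    sites: Sequence[SiteLike],
    bin_bp: int = 500,
    max_bp: int = 10_000,
    cutoff_bp: int = 2500,
    n_reps: int = 100,
    seed: int = 0,
) -> ProximityProfile:
    """Observed vs sampled-background upstream-proximity profile.

    Each gene contributes to the 500-bp bin of its minimum upstream
    distance.  The background samples ``len(up_genes)`` genes without
    replacement from ``all_genes`` ``n_reps`` times and averages the bin
    counts; enrichment contrasts the within-cutoff observed count against
    the mean background with the two-cell chi-square test.
    """
    gene_ids = [g.gene_id for g in all_genes]
    unknown = up_genes - set(gene_ids)
    if unknown:
        raise ValueError(f"up genes absent from gene universe: {sorted(unknown)[:5]}")
    n_up = len(up_genes)
    if n_up == 0:
        raise ValueError("empty up-gene set")
    dists = min_upstream_distances(all_genes, sites, max_bp=max_bp)
    up_mask = np.array([gid in up_genes for gid in gene_ids])
    n_bins = max_bp // bin_bp
    observed = _bin_counts(dists[up_mask], bin_bp, n_bins)
    observed_within = int(np.count_nonzero(dists[up_mask] < cutoff_bp))

    rng = np.random.default_rng(seed)
    bg = np.zeros((n_reps, n_bins))
    bg_within = np.zeros(n_reps)
    for r in range(n_reps):
        pick = rng.choice(len(all_genes), size=n_up, replace=False)
        d = dists[pick]
        bg[r] = _bin_counts(d, bin_bp, n_bins)
        bg_within[r] = np.count_nonzero(d < cutoff_bp)
    expected_within = float(bg_within.mean())

    if 0 < expected_within < n_up:
        enrichment = chi2_proximity_test(observed_within, expected_within, n_up)
    else:
        log.warning("degenerate proximity background (expected=%s); p set to 1",
                    expected_within)
        enrichment = EnrichmentResult(
            observed=observed_within, expected=expected_within, total=n_up,
            statistic=0.0, p_value=1.0, test_name="chi2",
        )
    return ProximityProfile(
        bin_bp=bin_bp,
        max_bp=max_bp,
        observed=observed,
        background_mean=bg.mean(axis=0),
        n_reps=n_reps,
        within_cutoff_bp=cutoff_bp,
        observed_within=observed_within,
        expected_within=expected_within,
        enrichment=enrichment,
    )


def call_hsr_genes(
    genes: Sequence[GeneModel],
    up_genes: set[str],
    sites: Sequence[SiteLike],
    cutoff_bp: int = 2500,
) -> set[str]:
    """Up-regulated genes with a qualifying site strictly within the cutoff
    upstream of their TSS."""
    dists = min_upstream_distances(genes, sites, max_bp=cutoff_bp)
    return {
        g.gene_id
        for g, d in zip(genes, dists)
        if g.gene_id in up_genes and d < cutoff_bp
    }


def count_upstream_hses(
    gene: GeneModel, sites: Sequence[SiteLike], cutoff_bp: int = 2500
) -> int:
    """Number of sites with upstream distance strictly below the cutoff."""
    n = 0
    for s in sites:
        d = upstream_distance(gene, s)
        if d is not None and d < cutoff_bp:
            n += 1
    return n


@dataclass
class OrthologPartition:
    shared: set[tuple[str, str]]
    unique_a: set[tuple[str, str]]
    unique_b: set[tuple[str, str]]
    test: EnrichmentResult


def partition_orthologs(
    up_a: set[str],
    up_b: set[str],
    has_hse_a: set[str],
    has_hse_b: set[str],
    ortholog_pairs: Iterable[tuple[str, str]],
    known_a: Optional[set[str]] = None,
    known_b: Optional[set[str]] = None,
) -> OrthologPartition:
    """Partition ortholog pairs by which species has an up-regulated,
    HSE-qualified copy; test the shared overlap hypergeometrically.

    A pair qualifies in species A when its A gene is both up-regulated and
    HSE-flagged (analogously for B).  Pairs naming genes outside the
    optional ``known_*`` universes are skipped with a warning.
    """
    pairs = []
    for a, b in ortholog_pairs:
        if (known_a is not None and a not in known_a) or (
            known_b is not None and b not in known_b
        ):
            log.warning("skipping ortholog pair with unknown gene: (%s, %s)", a, b)
            continue
        pairs.append((a, b))
    qual_a = {(a, b) for a, b in pairs if a in up_a and a in has_hse_a}
    qual_b = {(a, b) for a, b in pairs if b in up_b and b in has_hse_b}
    shared = qual_a & qual_b
    test = hypergeometric_overlap_test(
        len(shared), len(qual_a), len(qual_b), len(pairs)
    )
    return OrthologPartition(
        shared=shared,
        unique_a=qual_a - shared,
        unique_b=qual_b - shared,
        test=test,
    )
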