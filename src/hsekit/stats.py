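"""The four significance tests used throughout the pipeline.

All upper-tail p-values go through survival functions rather than
``1 - cdf`` so that extreme enrichments (p far below 1e-15) do not lose
precision to cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.stats as sps


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    expected: float
    total: float
    statistic: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def binomial_overlap_test(
    n_inside: int, n_total: int, genome_fraction: float
) -> EnrichmentResult:
    """One-sided (enrichment) cumulative binomial: P(X >= n_inside).

    X ~ Binomial(n_total, genome_fraction); the fraction is the share of
    the genome covered by the feature class of interest.
    """
    if not 0 < genome_fraction < 1:
        raise ValueError(f"genome_fraction must be in (0, 1), got {genome_fraction}")
    if not 0 <= n_inside <= n_total:
        raise ValueError(f"require 0 <= n_inside <= n_total, got {n_inside}/{n_total}")
    p = float(sps.binom.sf(n_inside - 1, n_total, genome_fraction))
    return EnrichmentResult(
        observed=n_inside,
        expected=n_total * genome_fraction,
        total=n_total,
        statistic=float(n_inside),
        p_value=p,
        test_name="binomial",
    )


def chi2_proximity_test(
    observed: float, expected: float, total: float
) -> EnrichmentResult:
    """Two-cell goodness-of-fit chi-square (1 df, no continuity correction).

    Cells are (within, beyond): chi2 = (O-E)^2/E + ((T-O)-(T-E))^2/(T-E).
    """
    if not 0 < expected < total:
        raise ValueError(
            f"expected must lie strictly between 0 and total, got {expected}/{total}"
        )
    if observed > total:
        raise ValueError(f"observed {observed} exceeds total {total}")
    stat = (observed - expected) ** 2 / expected + (
        (total - observed) - (total - expected)
    ) ** 2 / (total - expected)
    p = float(sps.chi2.sf(stat, df=1))
    return EnrichmentResult(
        observed=observed,
        expected=expected,
        total=total,
        statistic=stat,
        p_value=p,
        test_name="chi2",
    )


def fisher_exact_2x2(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test (sum of tables at most as probable)."""
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError(f"table cells must be non-negative integers: {table}")
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero table is undefined")
    res = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    expected = (a + b) * (a + c) / total if total else 0.0
    return EnrichmentResult(
        observed=a,
        expected=expected,
        total=total,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="fisher_exact",
    )


def hypergeometric_overlap_test(
    k_overlap: int, set_a: int, set_b: int, universe: int
) -> EnrichmentResult:
    """Upper-tail hypergeometric: P(X >= k_overlap) for the set overlap."""
    if not (0 <= k_overlap <= min(set_a, set_b)):
        raise ValueError(f"k_overlap {k_overlap} exceeds min({set_a}, {set_b})")
    if set_a > universe or set_b > universe:
        raise ValueError("set sizes exceed universe")
    p = float(sps.hypergeom.sf(k_overlap - 1, universe, set_a, set_b))
    return EnrichmentResult(
        observed=k_overlap,
        expected=set_a * set_b / universe if universe else 0.0,
        total=universe,
        statistic=float(k_overlap),
        p_value=p,
        test_name="hypergeometric",
    )
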