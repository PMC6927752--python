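"""Windowed site density, cumulative-distribution curves, and the random
k-mer permutation clustering test.

Windows tile every contig strictly longer than the window size; the
trailing partial window is kept.  A site belongs to the window(s) whose
span contains its start position, so a site straddling a boundary is
counted exactly once when step == window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .core import ContigSizes, GenomicInterval, contig_lengths_of
from .scan import MotifMatch
from .stats import EnrichmentResult, fisher_exact_2x2

SiteLike = Union[MotifMatch, GenomicInterval, tuple]


def _site_start(site: SiteLike) -> tuple[str, int]:
    if isinstance(site, MotifMatch):
        return site.interval.contig, site.interval.start
    if isinstance(site, GenomicInterval):
        return site.contig, site.start
    contig, start = site[0], site[1]
    return contig, int(start)


@dataclass
class DensityProfile:
    window_bp: int
    step_bp: int
    counts: dict[tuple[str, int], int]
    windows_per_contig: dict[str, int]

    @property
    def n_windows(self) -> int:
        return sum(self.windows_per_contig.values())

    def count_values(self) -> np.ndarray:
        """Per-window counts including zeros, one entry per window."""
        vals = np.zeros(self.n_windows, dtype=np.int64)
        offsets: dict[str, int] = {}
        pos = 0
        for contig, n in self.windows_per_contig.items():
            offsets[contig] = pos
            pos += n
        for (contig, idx), c in self.counts.items():
            vals[offsets[contig] + idx] = c
        return vals

    def n_high_windows(self, threshold: int) -> int:
        """Windows with count strictly greater than ``threshold``."""
        return sum(1 for c in self.counts.values() if c > threshold)


def _n_windows(length: int, step_bp: int) -> int:
    # window starts at 0, step, 2*step, ... while start < length
    return (length + step_bp - 1) // step_bp


def window_counts(
    sites: Iterable[SiteLike],
    genome: ContigSizes,
    window_bp: int = 1000,
    step_bp: int = 1000,
) -> DensityProfile:
    """Count sites per window on all contigs longer than ``window_bp``.

    With overlapping windows (step < window) a site is counted once per
    covering window; with the default tiling each site lands in exactly
    one window, so counts sum to the number of sites on included contigs.
    """
    if step_bp > window_bp:
        raise ValueError("step_bp must be <= window_bp")
    lengths = contig_lengths_of(genome)
    included = {c: n for c, n in lengths.items() if n > window_bp}
    windows_per_contig = {c: _n_windows(n, step_bp) for c, n in included.items()}
    counts: dict[tuple[str, int], int] = {}
    for site in sites:
        contig, start = _site_start(site)
        if contig not in included:
            continue
        # windows with w_start <= start < w_start + window_bp
        hi = start // step_bp
        lo = max(0, (start - window_bp) // step_bp + 1)
        for idx in range(lo, hi + 1):
            if idx < windows_per_contig[contig]:
                key = (contig, idx)
                counts[key] = counts.get(key, 0) + 1
    return DensityProfile(window_bp, step_bp, counts, windows_per_contig)


def cumulative_bins(
    profile: DensityProfile, k_max: int = 100
) -> list[tuple[int, int]]:
    """For k = 1..k_max, the number of windows holding at least k sites."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    vals = np.fromiter(profile.counts.values(), dtype=np.int64, count=len(profile.counts))
    return [(k, int(np.count_nonzero(vals >= k))) for k in range(1, k_max + 1)]


def sample_site_starts(
    n_sites: int,
    site_len_bp: int,
    genome: ContigSizes,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Uniformly sample site start positions over all valid starts.

    Valid starts are positions where the full site fits on its contig;
    sampling is with replacement, pooled across contigs weighted by their
    numbers of valid starts.
    """
    lengths = contig_lengths_of(genome)
    contigs = [c for c, n in lengths.items() if n >= site_len_bp]
    valid = np.array([lengths[c] - site_len_bp + 1 for c in contigs], dtype=np.int64)
    if valid.sum() == 0:
        raise ValueError("no contig admits a full site")
    which = rng.choice(len(contigs), size=n_sites, p=valid / valid.sum())
    starts = rng.integers(0, valid[which])
    return [(contigs[i], int(s)) for i, s in zip(which, starts)]


def permutation_cluster_test(
    n_sites: int,
    site_len_bp: int,
    genome: ContigSizes,
    observed_high_bins: int,
    threshold: int = 10,
    window_bp: int = 1000,
    step_bp: int = 1000,
    seed: int = 0,
) -> tuple[EnrichmentResult, int]:
    """Compare observed high-density windows against a random-placement null.

    Draws ``n_sites`` start positions uniformly, counts windows holding
    strictly more than ``threshold`` sampled sites, and contrasts the
    observed and sampled high-window counts over the shared window
    universe with Fisher's exact test.  Returns the test result and the
    sampled high-window count.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    sampled = sample_site_starts(n_sites, site_len_bp, genome, rng)
    profile = window_counts(sampled, genome, window_bp, step_bp)
    sampled_high = profile.n_high_windows(threshold)
    universe = profile.n_windows
    result = fisher_exact_2x2(
        [
            [observed_high_bins, universe - observed_high_bins],
            [sampled_high, universe - sampled_high],
        ]
    )
    return result, sampled_high


def write_profile_tsv(profile: DensityProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\twindow_start\tcount\n")
        for contig in profile.windows_per_contig:
            for idx in range(profile.windows_per_contig[contig]):
                count = profile.counts.get((contig, idx), 0)
                fh.write(f"{contig}\t{idx * profile.step_bp}\t{count}\n")
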