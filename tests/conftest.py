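import numpy as np
import pytest

from hsekit.core import GenomeSequence, GenomicInterval
from hsekit.simulate import SimConfig, simulate_bundle


def random_genome(rng: np.random.Generator, sizes: dict[str, int]) -> GenomeSequence:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return GenomeSequence(
        {c: bases[rng.integers(0, 4, size=n)].tobytes().decode() for c, n in sizes.items()}
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact default-structure bundle shared by read-only tests."""
    cfg = SimConfig(seed=11, genome_bp=600_000, n_helitrons=50, n_genes=400,
                    n_hin_hses=60, n_variant_samples=12)
    return simulate_bundle(cfg, tmp_path_factory.mktemp("bundle"))


def brute_force_iupac_scan(seq: str, pattern) -> set[tuple[int, str]]:
    """Position-by-position allowed-set oracle, both strands."""
    hits = set()
    L = pattern.length
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if all(b in s for b, s in zip(window, pattern.forward_sets)):
            hits.add((i, "+"))
        if all(b in s for b, s in zip(window, pattern.reverse_sets)):
            hits.add((i, "-"))
    return hits


def coverage_mask_fraction(intervals, sizes: dict[str, int]) -> float:
    """Per-base boolean-mask union coverage oracle."""
    covered = 0
    for contig, n in sizes.items():
        mask = np.zeros(n, dtype=bool)
        for iv in intervals:
            if iv.contig == contig:
                mask[iv.start : iv.end] = True
        covered += int(mask.sum())
    return covered / sum(sizes.values())


def make_interval(contig, start, end, strand="."):
    return GenomicInterval(contig, start, end, strand)
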