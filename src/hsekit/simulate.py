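"""Ground-truth-labeled synthetic input bundles.

Generates a genome with planted repeat intervals, clustered embedded
motif instances plus scattered independent ones, peak summits at a subset
of instances, genes whose upstream proximity to bound instances drives
up-regulation, an expression table, and a biallelic SNP VCF — everything
the pipeline consumes, with truth tables for every planted feature.

Chance motif matches arising from the random background are expected and
deliberately retained; truth tables label only planted instances.
"""

from __future__ import annotations

import dataclasses
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    STRAND_MINUS,
    STRAND_PLUS,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    RepeatAnnotation,
)
from .scan import DEFAULT_HSE_MOTIF, compile_iupac_pattern, reverse_complement
from .tajima import tajima_constants

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_REPEAT_NAMES = (
    "SimHelitron1",
    "SimHelitronY1",
    "SimHelitronY2",
    "SimHelitronY4",
    "SimHelitron2",
)


@dataclass
class SimConfig:
    seed: int = 0
    genome_bp: int = 5_000_000
    n_contigs: int = 5
    gc: float = 0.36
    motif: str = DEFAULT_HSE_MOTIF
    n_helitrons: int = 300
    helitron_len_min: int = 200
    helitron_len_max: int = 3000
    frac_helitrons_with_hses: float = 0.19
    hses_per_helitron_mean: float = 5.0
    heavy_tail_prob: float = 0.02
    heavy_tail_min: int = 20
    heavy_tail_max: int = 120
    cluster_gap_min: int = 1
    cluster_gap_max: int = 30
    overlap_clusters: bool = False
    n_hin_hses: int = 150
    frac_hses_with_summit: float = 0.3
    n_genes: int = 2000
    gene_len_min: int = 500
    gene_len_max: int = 3000
    p_gene_per_summit_hse: float = 0.5
    proximity_cutoff_bp: int = 2500
    p_up_given_proximal_bound_hse: float = 0.7
    p_up_background: float = 0.05
    log2fc_signal_mean: float = 3.0
    log2fc_signal_sd: float = 1.0
    log2fc_null_sd: float = 0.5
    n_variant_samples: int = 20
    theta_per_bp: float = 0.001

    def validate(self) -> None:
        for name in (
            "gc",
            "frac_helitrons_with_hses",
            "frac_hses_with_summit",
            "p_up_given_proximal_bound_hse",
            "p_up_background",
            "heavy_tail_prob",
            "p_gene_per_summit_hse",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.helitron_len_min <= 0 or self.helitron_len_max < self.helitron_len_min:
            raise ValueError("bad helitron length range")
        mean_len = (self.helitron_len_min + self.helitron_len_max) / 2
        if self.n_helitrons * mean_len > 0.5 * self.genome_bp:
            raise ValueError(
                "infeasible packing: expected repeat length exceeds half the genome"
            )

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Flat key=value config file; '#' starts a comment."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(cls, key, None)
                default = cls.__dataclass_fields__[key].default
                if isinstance(default, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(value)
                elif isinstance(default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SimBundle:
    """In-memory view of a generated bundle plus the paths written."""

    config: SimConfig
    genome: GenomeSequence
    repeats: list[RepeatAnnotation]
    genes: list[GeneModel]
    summits: list[tuple[str, int]]
    truth_hse: pd.DataFrame
    truth_genes: pd.DataFrame
    expression: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


class _Occupancy:
    """Per-contig disjoint-interval bookkeeping for rejection placement."""

    def __init__(self) -> None:
        self._by_contig: dict[str, list[tuple[int, int]]] = {}

    def clashes(self, contig: str, start: int, end: int) -> bool:
        ivs = self._by_contig.get(contig, [])
        i = bisect_left(ivs, (start, end))
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if start < e and s < end:
                    return True
        return False

    def add(self, contig: str, start: int, end: int) -> None:
        insort(self._by_contig.setdefault(contig, []), (start, end))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _instantiate_motif(rng: np.random.Generator, motif: str) -> str:
    from .scan import IUPAC_SETS

    return "".join(
        sorted(IUPAC_SETS[ch])[rng.integers(0, len(IUPAC_SETS[ch]))] for ch in motif
    )


def _place_interval(
    rng: np.random.Generator,
    contigs: list[str],
    lengths: dict[str, int],
    size: int,
    occupancy: _Occupancy,
    max_tries: int = 1000,
) -> Optional[tuple[str, int]]:
    weights = np.array([max(lengths[c] - size, 0) for c in contigs], dtype=float)
    if weights.sum() == 0:
        return None
    p = weights / weights.sum()
    for _ in range(max_tries):
        contig = contigs[rng.choice(len(contigs), p=p)]
        start = int(rng.integers(0, lengths[contig] - size))
        if not occupancy.clashes(contig, start, start + size):
            return contig, start
    return None


def _hse_count(rng: np.random.Generator, cfg: SimConfig) -> int:
    if rng.random() < cfg.heavy_tail_prob:
        return int(rng.integers(cfg.heavy_tail_min, cfg.heavy_tail_max + 1))
    return int(rng.geometric(1.0 / cfg.hses_per_helitron_mean))


def _upstream_dist(tss: int, strand: str, s: int, e: int) -> Optional[int]:
    # generator-side arithmetic, kept separate from the pipeline's version
    if s <= tss < e:
        return 0
    if strand == STRAND_PLUS:
        return tss - (e - 1) if e - 1 < tss else None
    return s - tss if s > tss else None


def simulate_bundle(config: SimConfig, out_dir) -> SimBundle:
    """Generate the full bundle, write it under ``out_dir``, return truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- genome ---------------------------------------------------------
    per = config.genome_bp // config.n_contigs
    lengths = {
        f"sim{chr(ord('A') + i)}": per
        + (config.genome_bp - per * config.n_contigs if i == 0 else 0)
        for i in range(config.n_contigs)
    }
    contigs = list(lengths)
    seqs = {c: _random_bases(rng, n, config.gc) for c, n in lengths.items()}

    # --- repeats --------------------------------------------------------
    occupancy = _Occupancy()
    repeats: list[RepeatAnnotation] = []
    for i in range(config.n_helitrons):
        size = int(rng.integers(config.helitron_len_min, config.helitron_len_max + 1))
        placed = _place_interval(rng, contigs, lengths, size, occupancy)
        if placed is None:
            raise ValueError("infeasible packing: could not place repeat")
        contig, start = placed
        occupancy.add(contig, start, start + size)
        name = _REPEAT_NAMES[i % len(_REPEAT_NAMES)]
        repeats.append(
            RepeatAnnotation(
                GenomicInterval(contig, start, start + size, STRAND_PLUS),
                name,
                "DNA/Helitron",
            )
        )

    # --- planted motif instances ---------------------------------------
    motif_len = len(config.motif)
    hse_rows: list[dict] = []

    def plant(
        contig: str, start: int, host: Optional[str], strand: Optional[str] = None
    ) -> dict:
        concrete = _instantiate_motif(rng, config.motif)
        if strand is None:
            strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        written = concrete if strand == STRAND_PLUS else reverse_complement(concrete)
        seqs[contig][start : start + motif_len] = np.frombuffer(
            written.encode(), dtype="S1"
        )
        row = {
            "contig": contig,
            "start": start,
            "end": start + motif_len,
            "strand": strand,
            "category": "Hac" if host else "Hin",
            "host_repeat": host or ".",
        }
        hse_rows.append(row)
        return row

    period = 10  # offset preserving unit phase for tandem overlapping runs
    for rep in repeats:
        if rng.random() >= config.frac_helitrons_with_hses:
            continue
        want = _hse_count(rng, config)
        iv = rep.interval
        pos = iv.start + int(rng.integers(0, max(1, config.cluster_gap_max)))
        placed = 0
        # overlapping tandem runs must share one strand: a reverse-complement
        # write inside the overlap would destroy the previous instance
        run_strand = (
            (STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS)
            if config.overlap_clusters
            else None
        )
        while placed < want and pos + motif_len <= iv.end:
            plant(iv.contig, pos, rep.repeat_name, strand=run_strand)
            placed += 1
            if config.overlap_clusters:
                pos += period
            else:
                pos += motif_len + int(
                    rng.integers(config.cluster_gap_min, config.cluster_gap_max + 1)
                )

    for _ in range(config.n_hin_hses):
        placed = _place_interval(rng, contigs, lengths, motif_len, occupancy)
        if placed is None:
            break
        contig, start = placed
        occupancy.add(contig, start, start + motif_len)
        plant(contig, start, None)

    # --- summits and bound labels --------------------------------------
    summits: list[tuple[str, int]] = []
    for row in hse_rows:
        row["has_summit"] = int(rng.random() < config.frac_hses_with_summit)
        if row["has_summit"]:
            summits.append((row["contig"], row["start"] + motif_len // 2))
    # an instance is bound if any summit window [p-50, p+51) overlaps >= 14 bp
    for row in hse_rows:
        bound = 0
        for contig, p in summits:
            if contig != row["contig"]:
                continue
            ov = min(row["end"], p + 51) - max(row["start"], p - 50)
            if ov >= 14:
                bound = 1
                break
        row["is_bound"] = bound
    truth_hse = pd.DataFrame(
        hse_rows,
        columns=[
            "contig", "start", "end", "strand", "category",
            "host_repeat", "has_summit", "is_bound",
        ],
    )

    # --- genes ----------------------------------------------------------
    genes: list[GeneModel] = []
    gene_rows: list[dict] = []

    def add_gene(contig: str, tss: int, strand: str) -> None:
        glen = int(rng.integers(config.gene_len_min, config.gene_len_max + 1))
        if strand == STRAND_PLUS:
            start, end = tss, min(tss + glen, lengths[contig])
        else:
            start, end = max(tss - glen + 1, 0), tss + 1
        gid = f"simg{len(genes):05d}"
        genes.append(
            GeneModel(gid, GenomicInterval(contig, start, end, strand), strand)
        )
        gene_rows.append({"gene_id": gid, "contig": contig, "tss": tss, "strand": strand})

    bound_rows = [r for r in hse_rows if r["is_bound"]]
    for row in bound_rows:
        if len(genes) >= config.n_genes:
            break
        if rng.random() >= config.p_gene_per_summit_hse:
            continue
        d = int(rng.integers(100, config.proximity_cutoff_bp - 100))
        strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        if strand == STRAND_PLUS:
            tss = row["end"] - 1 + d
        else:
            tss = row["start"] - d
        if 0 <= tss < lengths[row["contig"]]:
            add_gene(row["contig"], tss, strand)
    while len(genes) < config.n_genes:
        contig = contigs[
            rng.choice(
                len(contigs),
                p=np.array([lengths[c] for c in contigs], dtype=float)
                / sum(lengths.values()),
            )
        ]
        tss = int(rng.integers(0, lengths[contig]))
        add_gene(contig, tss, STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS)

    bound_by_contig: dict[str, list[tuple[int, int]]] = {}
    for r in bound_rows:
        bound_by_contig.setdefault(r["contig"], []).append((r["start"], r["end"]))
    for grow in gene_rows:
        proximal = 0
        for s, e in bound_by_contig.get(grow["contig"], ()):
            d = _upstream_dist(grow["tss"], grow["strand"], s, e)
            if d is not None and d < config.proximity_cutoff_bp:
                proximal = 1
                break
        grow["proximal_bound_hse"] = proximal

    # --- expression ------------------------------------------------------
    expr_rows = []
    for grow in gene_rows:
        p_up = (
            config.p_up_given_proximal_bound_hse
            if grow["proximal_bound_hse"]
            else config.p_up_background
        )
        if rng.random() < p_up:
            log2fc = rng.normal(config.log2fc_signal_mean, config.log2fc_signal_sd)
            log2fc = max(log2fc, 1.05)  # keep intended signal above threshold
            padj = 1e-6
        else:
            log2fc = rng.normal(0.0, config.log2fc_null_sd)
            padj = rng.random()
        fc = 2.0**log2fc
        expr_rows.append(
            {"gene_id": grow["gene_id"], "fold_change": fc, "padj": padj}
        )
        grow["is_up"] = int(fc > 2.0 and padj < 0.01)
        grow["is_hsr"] = int(grow["is_up"] and grow["proximal_bound_hse"])
    expression = pd.DataFrame(expr_rows)
    truth_genes = pd.DataFrame(gene_rows)

    # --- variants --------------------------------------------------------
    n = config.n_variant_samples
    a1 = tajima_constants(n).a1 if n >= 2 else 1.0
    sfs_p = np.array([1.0 / i for i in range(1, n)]) if n >= 2 else None
    if sfs_p is not None:
        sfs_p = sfs_p / sfs_p.sum()
    variant_lines: list[str] = []
    for contig in contigs:
        length = lengths[contig]
        n_sites = int(round(config.theta_per_bp * length * a1))
        n_sites = min(n_sites, length)
        if n_sites == 0 or sfs_p is None:
            continue
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        derived = rng.choice(np.arange(1, n), size=n_sites, p=sfs_p)
        for p, c in zip(pos, derived):
            ref = seqs[contig][p].decode()
            if ref == "N":
                continue
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[rng.integers(0, 3)]
            carriers = set(rng.choice(n, size=int(c), replace=False).tolist())
            gts = "\t".join("1" if i in carriers else "0" for i in range(n))
            variant_lines.append(
                f"{contig}\t{p + 1}\tsim{len(variant_lines)}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{gts}"
            )

    # --- serialize -------------------------------------------------------
    genome = GenomeSequence({c: seqs[c].tobytes().decode() for c in contigs})
    paths = _write_bundle(
        out_dir, config, genome, repeats, summits, genes, gene_rows,
        expression, truth_hse, truth_genes, variant_lines,
    )
    return SimBundle(
        config=config,
        genome=genome,
        repeats=repeats,
        genes=genes,
        summits=summits,
        truth_hse=truth_hse,
        truth_genes=truth_genes,
        expression=expression,
        paths=paths,
    )


def _write_bundle(
    out_dir: Path,
    config: SimConfig,
    genome: GenomeSequence,
    repeats: list[RepeatAnnotation],
    summits: list[tuple[str, int]],
    genes: list[GeneModel],
    gene_rows: list[dict],
    expression: pd.DataFrame,
    truth_hse: pd.DataFrame,
    truth_genes: pd.DataFrame,
    variant_lines: list[str],
) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    p = paths["genome"] = out_dir / "genome.fa"
    with open(p, "w") as fh:
        for contig, seq in genome.contigs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    p = paths["repeats_out"] = out_dir / "helitrons.out"
    with open(p, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query         "
            "matching repeat       position in repeat\n"
            "score  div. del. ins.  sequence  begin end (left)  strand  "
            "repeat   class/family  begin end (left) ID\n\n"
        )
        for i, rep in enumerate(repeats, start=1):
            iv = rep.interval
            fh.write(
                f"1000 0.0 0.0 0.0 {iv.contig} {iv.start + 1} {iv.end} "
                f"(0) + {rep.repeat_name} {rep.repeat_class} 1 {iv.length} (0) {i}\n"
            )

    p = paths["repeats_bed"] = out_dir / "helitrons.bed"
    with open(p, "w") as fh:
        for rep in repeats:
            iv = rep.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{rep.repeat_name}\t0\t{iv.strand}\n"
            )

    p = paths["summits"] = out_dir / "summits.bed"
    with open(p, "w") as fh:
        for contig, pos in summits:
            fh.write(f"{contig}\t{pos}\t{pos + 1}\tsummit\t0\t.\n")

    p = paths["genes"] = out_dir / "genes.tsv"
    with open(p, "w") as fh:
        fh.write("gene_id\tcontig\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{iv.contig}\t{iv.start}\t{iv.end}\t{g.strand}\n")

    p = paths["expression"] = out_dir / "expression.tsv"
    expression.to_csv(p, sep="\t", index=False, float_format="%.8g")

    p = paths["variants"] = out_dir / "variants.vcf"
    with open(p, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in genome.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i:02d}" for i in range(config.n_variant_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for line in variant_lines:
            fh.write(line + "\n")

    p = paths["truth_hse"] = out_dir / "truth_hse.tsv"
    truth_hse.to_csv(p, sep="\t", index=False)

    p = paths["truth_genes"] = out_dir / "truth_genes.tsv"
    truth_genes.to_csv(p, sep="\t", index=False)

    return paths
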