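# hsekit

Analysis toolkit for degenerate transcription-factor motif scanning and
transposon/motif co-localization in small genomes. It was built around the
heat-shock element (HSE) / Helitron use case: scan a genome for a degenerate
IUPAC motif on both strands, partition occurrences into repeat-acquired
(Hac) vs repeat-independent (Hin), call bound occurrences from ChIP peak
summits, measure density clustering against a random-placement null, test
upstream-proximity enrichment of up-regulated genes, partition ortholog
pairs, and compute sliding-window Tajima's D — plus a synthetic-data
generator that produces fully ground-truth-labeled input bundles so every
stage can be validated without any external download.

## Layout

| module               | contents |
|----------------------|----------|
| `hsekit.core`        | coordinate types, interval merge/overlap/coverage, FASTA / RepeatMasker `.out` / BED / gene-table / GFF3 readers |
| `hsekit.scan`        | IUPAC pattern compilation and overlapping-occurrence genome scanning on both strands |
| `hsekit.stats`       | cumulative binomial, 2-cell χ², Fisher's exact, hypergeometric tests |
| `hsekit.classify`    | Hac/Hin containment classification, summit-window bound calls, per-species overlap summaries |
| `hsekit.density`     | 1-kb window counts, cumulative curves, random k-mer permutation clustering test |
| `hsekit.hsr`         | up-regulated gene calling, strand-aware upstream proximity profiles with sampled backgrounds, HSR-gene calls, ortholog partitioning |
| `hsekit.tajima`      | sliding-window Tajima's D from a minimal VCF subset |
| `hsekit.simulate`    | deterministic synthetic bundle generator with truth tables |

## CLI

```sh
hsekit simulate --seed 1 --out sim/                 # synthetic bundle
hsekit scan --genome sim/genome.fa --out hse.bed    # motif scan (BED6)
hsekit classify --hse hse.bed --repeats sim/helitrons.out \
    --summits sim/summits.bed --out classified.bed
hsekit density profile --hse hse.bed --genome sim/genome.fa --out profile.tsv
hsekit density permtest --genome sim/genome.fa --n 18766 --observed 310 --seed 1
hsekit enrich overlap --inside 11527 --total 18766 --fraction 0.016755
hsekit tajima --vcf sim/variants.vcf --genome sim/genome.fa --out tajima.tsv
```

The default motif is `NGAANNTTCNNGAAN`; any IUPAC string works via
`--motif`.

## Conventions

All coordinates are 0-based half-open internally; RepeatMasker `.out`
(1-based inclusive) and VCF (1-based) inputs are converted at parse time.
Upper-tail p-values are computed with survival functions, never `1 - cdf`.
All randomness flows through explicitly seeded `numpy` generators; the
simulator is byte-reproducible for a fixed seed.
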