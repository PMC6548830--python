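# hybscan

Characterization of interspecies hybrid yeast genomes from sequencing-derived
signals, plus a synthetic data generator to exercise every stage:

- **`hybscan.simulate`** — homoploid-hybridization + loss-of-heterozygosity
  simulator: two diverged parental genomes with shared ortholog coordinates,
  diploid hybrid mosaics (per-ORF origin CC / PP / CP, per-ORF or contiguous
  block modes), Poisson read counts with a cross-species misassignment rate,
  single-end reads, per-base depth profiles with tandem copy-number
  expansions, and a truth table for recovery experiments.
- **`hybscan.kmer_assign`** — competitive read assignment by diagnostic
  k-mer voting against both parents' ORFs (a desk-scale stand-in for
  competitive mapping to a combined multi-species reference).
- **`hybscan.orf_calls`** — foreign-ORF detection: per-ORF fold-coverage
  (reads × read length / ORF length), presence at ≥ ¼ of the median genome
  coverage, a 25% intra-group read filter, four-way origin calls
  (REF_ONLY / FOREIGN / HETEROZYGOUS / ABSENT) and cohort summaries
  (per-strain counts, union, shared core, heterozygous percentage).
- **`hybscan.divergence`** — 10 kb sliding-window divergence of an N-masked
  consensus against a reference with pairwise deletion, 10% threshold
  labeling (conspecific / heterospecific / no-data), block merging and the
  foreign genome fraction.
- **`hybscan.snp_matrix`** — SNP extraction with an inclusive ≥ 85%
  site-occupancy filter, foreign-region masking, concatenated alignments
  (FASTA/PHYLIP), pairwise mismatch distances and a neighbor-joining tree.
- **`hybscan.cnv`** — read-depth copy-number estimation with a control-gene
  calibration and flanking-gene sanity ratios; Kruskal–Wallis omnibus and
  pairwise Dunn tests (Bonferroni) across strain groups.
- **`hybscan.reporting`** — isolation-frequency and marker-presence
  arithmetic (half-up rounding at the printed precision) and a markdown
  cohort report.

## CLI

Every stage is a subcommand of `hybscan` (all formats are plain text:
FASTA, TSV, BED, YAML):

```sh
hybscan simulate   --config cfg.yaml --outdir cohort/ --reads
hybscan assign     --reads cohort/strain001.reads.fasta \
                   --parent-a cohort/parentA.fasta --parent-b cohort/parentB.fasta \
                   --annotations cohort/annotations.tsv \
                   --out-counts counts.tsv --out-depth depth.tsv
hybscan call-orfs  --counts counts.tsv --annotations cohort/annotations.tsv \
                   --depth depth.tsv --out-calls calls.tsv --out-summary summary.tsv
hybscan divergence --consensus cohort/strain001.consensus.fasta \
                   --reference cohort/parentA.fasta \
                   --out-windows windows.tsv --out-blocks blocks.bed
hybscan snps       --consensus a.fasta --consensus b.fasta --consensus c.fasta \
                   --mask beddir/ --out-alignment aln.fasta --out-tree tree.nwk
hybscan cnv        --depth depth.tsv --genes genes.bed --control control.bed --out cnv.tsv
hybscan report     --sources sources.tsv --markers markers.tsv --out report.md
```

## Notes

- All randomness derives from the single config seed; identical
  (config, seed) reproduces byte-identical FASTA/TSV outputs.
- Window labels use strict `>` at the divergence threshold; divergence
  exactly at the threshold is conspecific.
- Occupancy and read-fraction comparisons are inclusive (`>=`), pinned by
  boundary tests.
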