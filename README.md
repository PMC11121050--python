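# mutprof

Post-variant-calling analysis of mutagenized, resequenced plant lines.
Given per-line VCFs for mutant lines and their non-irradiated parental
(wild-type) lines, a reference FASTA and a GFF3 annotation, the pipeline:

- derives **induced mutations** by mutant-vs-wild-type subtraction after
  GATK-style hard filters (`QD < 2.0 || FS > 60.0 || MQ < 40.0`, sample
  `GQ < 20`), classifying records into SBS / insertion / deletion (InDels
  capped at 50 bp, MNVs logged and excluded);
- characterizes the **mutation spectrum**: Ti/Tv, the 12 directional
  substitution types, InDel length histograms, per-line and per-pond
  (per-wild-type background) aggregation;
- assigns each mutation one **genomic-context category** (exonic / UTR5 /
  UTR3 / intron / upstream / downstream / intergenic) and classifies coding
  mutations as synonymous / nonsynonymous / nonsense / frameshift /
  in-frame InDel with a strand-aware codon translation engine;
- scans windowed mutation frequencies (1 Mb / 100 kb by default), calls
  **high-frequency (HF) regions** against the chromosome-mean frequency
  (default fold 20), and quantifies SBS–InDel **colocalization** with a
  hypergeometric tail test;
- back-projects M*n* mutation counts to **M1 mutation counts and per-bp
  rates** under Mendelian selfing, and implements the trait-screening
  statistic `|mutant − mean(wt)| / sd(wt) ≥ 3`.

A first-class synthetic-data module generates toy genomes, gene models and
planted mutation sets (with truth tables and per-mutation effect oracles)
so the whole pipeline is testable offline. Bundled under `mutprof/data/`
are the published per-line summary counts of an eight-line carbon-ion-beam
rice mutagenesis dataset, used as desk-scale worked examples.

## CLI

```sh
# generate a synthetic fixture (FASTA, GFF3, per-line VCFs, truth TSV)
mutprof simulate --outdir fx --seed 1 --gene-count 8 --n-mutations 400 \
    --pond WT1=mutA,mutB --hotspot chr1:0-10000:50

# run the full pipeline
mutprof run --genome fx/genome.fasta --gff fx/annotation.gff3 \
    --vcf WT1=fx/WT1.vcf --vcf mutA=fx/mutA.vcf --vcf mutB=fx/mutB.vcf \
    --pond WT1=mutA,mutB --window-size 10000 --outdir out
```

Other subcommands (`derive`, `spectrum`, `effects`, `hotspots`, `rates`,
`screen`) run individual stages; `mutprof run --config file` reads a flat
`key=value` config (keys `vcf.<line>` and `pond.<wt>`), with flags taking
precedence. All reports are plain TSV/BED; coordinates are 1-based in
VCF/GFF3 interfaces and 0-based half-open in window/BED outputs.

## Notes on the back-projection modes

`mode="table"` uses the asymptotic retention probability 1/2 (every M1
estimate is exactly twice the Mn count); `mode="exact"` uses the
generation-specific probability `(1 − 2^−(n−1))/2` (e.g. 31/64 at M6, so
the factor is 64/31 ≈ 2.065); `mode="inclusive"` additionally counts
mutations still segregating as heterozygotes. The default is `table`.
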