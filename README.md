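# ednamix

Toolkit for extracting population-genetic and phylogenetic signal from
mixed-species ancient environmental DNA, exercised end-to-end on synthetic
data with known truth. Six stages:

- **`simdata`** — synthetic inputs with full provenance: diverged reference
  pairs, infinite-sites coalescent genotype panels (one or two populations
  with a clean split, plus a multi-population star generator), damaged
  ancient-DNA fragments, species mixtures, VCF/FASTQ/FASTA emission.
- **`readmap`** — desk-scale end-to-end mini-mapper (substitution-only,
  exhaustive-equivalent, optional damage-tolerant scoring), SAM ingest/emit,
  map-quality/length filters, and the competitive partition of reads into
  unique-to-reference-A / unique-to-B / shared sets (presence or
  least-edit-distance arbitration; generalises to k references).
- **`authenticate`** — terminal substitution profiles (5' C→T, 3' G→A) and
  an ancient-like verdict gated on both a terminal-rate threshold and a
  two-proportion z test against the read interior.
- **`mitoplace`** — biallelic transversion SNPs from a mitogenome MSA,
  plurality consensus (MSA or 66%/3× pileup rule), branch assignment on a
  rooted outgroup-polarised tree, per-read-set support/conflict tallies and
  greedy best-path placement, including the dual-path report for two-species
  mixtures.
- **`popgen`** — site filters (MQ > 20, AN > 150, biallelic), pseudo-haploid
  calling (random-read or single-read-only), flat-missing rescaled Hamming
  distances, neighbor joining, PCA with least-squares projection of sparse
  samples, and f4 statistics with a weighted 500-SNP block jackknife.
- **`divergence`** — heterozygosity-conditioned divergence: ML heterozygous
  transversion calls in a high-coverage sample (call quality > 20, depth
  15–40), the alternate-allele match fraction of single-read pseudo-haploid
  calls in a low-coverage sample, the coalescent same-population null of
  one-third, and a split-time scan run end-to-end through read simulation,
  mapping and filtering.

## Command line

Every stage is exposed under one entry point; stochastic commands require
`--seed`. All files are plain text (FASTA/FASTQ/SAM/VCF/TSV/Newick/JSON).

```sh
ednamix simdata species-pair --length 10000 --divergence 0.05 --seed 1 --out-prefix pair
ednamix simdata reads --source-fasta pair.refA.fa --n-reads 500 --seed 2 \
    --out-fastq a.fq --out-truth a.tsv
ednamix readmap map --fastq mix.fq --reference pair.refA.fa --out-sam a.sam
ednamix readmap filter --sam a.sam --out-sam a.filt.sam
ednamix readmap partition --sam a.filt.sam --sam b.filt.sam --fastq mix.fq \
    --mode edit --out partition.tsv
ednamix authenticate verdict --sam a.filt.sam --reference pair.refA.fa --out verdict.json
ednamix mitoplace assign --msa msa.fa --tree tree.nwk --outgroup OG \
    --reference-row A --out branches.tsv
ednamix popgen f4 --vcf panel.vcf --pops pops.tsv --quadruple A,B,C,D --out f4.json
ednamix divergence null --theta 600 --seed 1 --out null.json
ednamix divergence scan --split-times 0,0.25,0.5,1.0 --seed 1 --out scan.tsv
```

`ednamix <group> --help` lists every command.

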