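# panelpop

Population-genomic analysis of sparse sequence-based genotyping panels for
allotetraploid diversity panels (A/C subgenomes, A01–A10 + C01–C09
chromosome naming), from raw variant filtering through population
structure, differentiation, diversity, allele sharing, gene-set tests,
inversion-signature region scanning and NJ phylogenies. A first-class
synthetic-data generator makes every stage testable end-to-end without any
external data.

## Pipeline stages

| module | what it does |
| --- | --- |
| `panelpop.types` / `vcfio` / `annotation` / `newick` | domain types; VCF (GT:AD:DP) read/write; GFF3 gene annotation (genic/intergenic SNP flags); Newick trees |
| `panelpop.simulate` | Balding–Nichols subpopulations with tunable pairwise Fst, selfing-excess homozygosity (F_is), per-genotype read depth with dropout, non-recombining inversion regions, and raw-VCF emission with plantable filter violations |
| `panelpop.filtering` | filter cascade: non-biallelic/fixed-alt removal → DP < 4 genotype masking → imbalanced-het recoding → mismatch-locus masking → site call-rate (≥ 30 samples) → sample missingness (≤ 80%) filters, with a per-stage report |
| `panelpop.ppca` | probabilistic PCA by exact EM on the incomplete dosage matrix; top-loading SNP blocks; nearest-centroid label-discordance flags |
| `panelpop.fst` | Hudson Fst: per-SNP components, ratio-of-averages genome-wide estimates per subgenome, dual ascertainment, inbreeding-adjusted effective chromosome counts |
| `panelpop.sfs` | folded SFS by exact hypergeometric projection to 100 chromosomes; π, per-SNP Π, Tajima's D; heterozygosity/call-rate tracks |
| `panelpop.sharing` | pooled minor-allele Venn partition across subpopulations per subgenome, with size-matched downsampling replicates |
| `panelpop.permutation` | 40-SNP-per-gene representative sets; composition-matched (subgenome × genic) permutation test for mean Fst / mean Π |
| `panelpop.roi` | mean + 3 SD outlier SNPs → gap-merged regions → region-PCA band diagnosis (exact 1-D k-means + separation rule) for inversion signatures |
| `panelpop.nj` | weighted p-distances (het = 0.5) with pairwise deletion, neighbor joining, midpoint rooting, Felsenstein bootstrap supports |

## CLI

Every stage is a `panelpop` subcommand operating on plain-text inputs
(VCF, TSV matrix + sample metadata, GFF3):

```bash
panelpop simulate --config sim.yaml --seed 1 --out-prefix out/panel
panelpop filter   --vcf out/panel.vcf --samples out/panel.samples.tsv --out-prefix out/filtered
panelpop pca      --matrix out/panel.matrix.tsv --samples out/panel.samples.tsv -q 10 --out-prefix out/pca
panelpop fst      --matrix ... --samples ... --pair WE,SP --pair WA,SP --out-prefix out/fst
panelpop sfs      --matrix ... --samples ... --subpop WE --out-prefix out/sfs
panelpop diversity --matrix ... --samples ... --out-prefix out/div
panelpop sharing  --matrix ... --samples ... --downsample-to 185 --out-prefix out/share
panelpop geneperm --matrix ... --samples ... --genes genes.gff3 --focal-list focal.txt \
                  --statistic fst --pair WE,SP --iterations 1000 --direction greater --out perm.tsv
panelpop roiscan  --matrix ... --samples ... --pair WE,SP --out-prefix out/roi
panelpop njtree   --matrix ... --samples ... --subgenome A --bootstrap 1000 --out-prefix out/tree
```

`simulate --config` takes a YAML file with `SimulationConfig` fields, e.g.:

```yaml
subpop_sizes: {WE: 347, WA: 212, SP: 185}
n_snps: {A: 12000, C: 19000}
target_fst: 0.2          # or a mapping of pairs -> targets
f_is: 0.8
call_rate: 0.35
inversions:
  - {chrom: C02, start: 23325687, end: 32393406, freq: {WE: 0.02, WA: 0.02, SP: 0.5}}
```

## Conventions

- Coordinates are 1-based with inclusive ends throughout (VCF/GFF style).
- Dosages count alternate-allele copies ∈ {0, 1, 2}; missing is `NA` in
  TSV and `-1` internally.
- Subgenome is `A` iff the chromosome name starts with `A`.
- Genome order is A01..A10 then C01..C09.
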