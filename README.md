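# driftscan

Population-structure and selection-signature analysis for SNP-array genotype
panels, built around allele-frequency drift between populations:

- **genotype_io** — PLINK 1 binary (.bed/.bim/.fam) reader/writer, iterative
  QC filtering (SNP call rate, sample call rate, MAF), per-population allele
  frequencies.
- **drift_simulator** — pure-drift genotype simulator on a population tree
  (Beta / Balding–Nichols transition per branch, Hardy–Weinberg genotypes),
  with optional selected loci (inflated drift or deterministic shift) and a
  recorded ground truth, so every downstream statistic is testable without
  real data.
- **population_structure** — VanRaden genomic relationship matrix
  (G = ZZ'/k, k = 2·Σ p(1−p)) and its SVD for PC-style structure plots.
- **f_statistics** — bias-corrected f2 and outgroup-f3 with weighted
  block-jackknife standard errors, z-scores and a sorted outgroup-f3 table.
- **selection_scan** — per-SNP Weir–Cockerham FST (plus a plain
  variance-ratio option), centered sliding-window smoothing, 95th-quantile
  region calling, the kinship-corrected FLK test (NJ tree on Reynolds
  distances, rooted on an outgroup; chi-square with n−1 df) and Storey
  q-values with an FDR cut-off of 0.15 by default.
- **annotation_enrichment** — interval overlap of called regions with
  gene/QTL tables (BED 0-based half-open or TSV 1-based inclusive) and
  one-sided Fisher-exact category enrichment.
- **cli** — `driftscan` command with `simulate`, `qc`, `structure`,
  `fstats`, `scan`, `annotate` subcommands.

## Quick start

```bash
# simulate a 7-population dataset shaped like a typical outgroup design
driftscan simulate --n-snps 5000 --samples-per-pop 30 --seed 1 --out-prefix out/sim

# QC, structure, f3 table and a selection scan (D is the outgroup)
driftscan qc        --bfile out/sim --out-prefix out/qc
driftscan structure --bfile out/qc --out-dir out/structure
driftscan fstats    --bfile out/qc --outgroup D --out out/f3.tsv
driftscan scan      --bfile out/qc --outgroup D --out-dir out/scan

# overlap called regions with a feature table and test category enrichment
driftscan annotate --regions out/scan/scan_regions.tsv \
    --features genes.bed --categories categories.tsv \
    --background background_genes.txt --out-dir out/annotation
```

All outputs are TSV; each command writes a JSON run log recording the
parameter values in effect.

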