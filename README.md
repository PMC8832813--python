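# methlink

Integrative RRBS + RNA-seq analysis of diet effects on DNA methylation,
built as a tested, reusable pipeline with a first-class synthetic-data
module. It covers:

- **Region annotation** — an exclusive genome partition into exon,
  intron, three promoter tiers (P250 = 1–250 bp, P1K = 251–1000 bp,
  P5K = 1001–5000 bp upstream of the TSS), 10-kb mRNA flanks and the
  intergenic remainder, resolved by the fixed precedence
  exon > intron > P250 > P1K > P5K > flanks > IGR, with an Exon150
  (TSS to +149 bp) sub-label. Longest-isoform selection from GFF3.
- **Differential methylation** — coverage filtering (drop ≤ 10× and
  above the per-sample 99.9th percentile), per-CpG binomial
  logistic-regression likelihood-ratio tests (pairwise, or with a
  tissue covariate for the combined two-tissue design), BH or
  Storey-π₀ q-values, and DMC calling at q < 0.01 and |Δ| ≥ 25
  percentage points.
- **Differential expression** — median-of-ratios normalization, a
  negative-binomial Wald GLM per gene with trend-shrunk
  method-of-moments dispersions, DEGs at BH-adjusted p < 0.1, and a
  top-variance PCA.
- **Enrichment** — hypergeometric ORA, preranked GSEA (weighted
  running sum, gene-permutation NES, |NES| > 2 filter), cross-contrast
  common pathways, and a two-stage tissue-specificity filter on
  class/subclass-structured collections.
- **Integration** — DMGs by ten region groups (GB, exon, intron, P,
  P250, P1K, P5K, flanks, P+GB, RS+GB), direction-matched common-DMC
  merging (IGR excluded, Exon150 split), top-3 candidate ranking,
  DEG:DMC linkage over all dataset pairs, the OLS expectation model
  `n_link ~ n_deg + n_dmg` on max-normalized counts, dose-consistency
  correlations, and a canonical 13-table TSV export.
- **Synthetic data** — toy genomes and gene models (FASTA/GFF3),
  beta-binomial bisulfite counts around region-typical baselines
  (P250 ≈ 22 %, P1K ≈ 57 %, exon ≈ 76 %), negative-binomial expression
  counts, digestion-signature FASTQ reads, and a recorded truth table
  of planted DMCs/DEGs.
- **Read QC** — retain reads whose 5′ end carries an MspI/TaqI
  bisulfite-space digestion signature (CGG/TGG/CGA/TGA), trimmed to
  50 bp.

## Command line

```sh
methlink run-all --seed 0 --out out/            # full synthetic pipeline
methlink simulate --seed 1 --out sim/           # genome + gene models only
methlink filter-reads in.fastq out.fastq --max-len 50
methlink annotate-regions models.gff3 --chrom-sizes sizes.tsv --out-bed part.bed
methlink diffmeth --coverage-dir cov/ --metadata meta.tsv \
    --gff3 models.gff3 --chrom-sizes sizes.tsv --contrast L2:L1 --out dmcs.tsv
methlink diffexpr --counts counts.tsv --metadata meta.tsv \
    --contrast L3:L1 --out de.tsv
methlink enrich --method gsea --ranking ranked.tsv --gmt sets.gmt --out enr.tsv
methlink merge-common dmcs_L2L1.tsv dmcs_L3L1.tsv --out common.tsv
methlink link --links link_counts.tsv
```

`run-all` orchestrates simulate → annotate → diffmeth → diffexpr →
enrich → link → export from one YAML config (all thresholds
overridable; see `methlink.pipeline.DEFAULT_CONFIG`) and writes the 13
result tables under `<out>/tables/`, byte-deterministically for a fixed
seed.

## Layout

```
src/methlink/
  simulate.py     synthetic genomes, counts, reads, truth tables
  readqc.py       digestion-signature read filter
  regions.py      partition, site annotation, GFF3/BED interchange
  diffmeth.py     coverage filter, per-CpG tests, q-values, DMCs, PCA
  diffexpr.py     size factors, NB Wald GLM, DEGs, PCA
  enrichment.py   ORA, GSEA, common pathways, tissue-specificity filter
  integration.py  DMGs, common DMCs, linkage, expectation model, export
  datasets.py     packaged miniature gene-set collection
  pipeline.py     run-all orchestration
  cli.py          click CLI
```
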