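# meqtlkit

Cross-tissue **cis-meQTL** analysis in Python: methylation quantitative trait
locus mapping in several tissues, cross-tissue harmonization and concordance
statistics, MAF-matched permutation enrichment of SNP sets in annotation sets,
and consensus co-methylation network analysis with disease-association
statistics — plus a synthetic multi-tissue cohort generator so the whole
pipeline is testable end to end with known ground truth.

It is aimed at statistical geneticists and epigenomics researchers who want a
self-contained, reproducible implementation of this analysis style — for
method evaluation on simulated cohorts, or as a library of the individual
building blocks (QC, scan, harmonization, enrichment, networks) applied to
their own dosage/beta-value tables.

## The statistics implemented

**cis-meQTL scan.** For each SNP–CpG pair on the same chromosome with
|pos_SNP − pos_CpG| ≤ 20 kbp, methylation *m* is regressed on coding-allele
dosage *g* with covariates *C* (age, sex, diagnosis, cell proportions,
ancestry PCs):

    m = α + β·g + Cγ + ε

Pairs with two-sided p ≤ 1 × 10⁻⁵ are retained. The effect statistic carried
across tissues is the normalized coefficient **β̂ = β / std(β)** — the
standardized methylation change per coding allele. The scan residualizes *m*
and *g* on the covariates once and computes correlation-based t statistics,
which is algebraically identical to the per-pair multiple regression
(Frisch–Waugh–Lovell) and is verified against it to 1e-8 in the tests.

**Cross-tissue harmonization.** SNPs and CpGs are matched across tissues by
chromosome position; alleles are reconciled by strand complement and
coding/other swap (palindromic A/T and C/G SNPs are dropped as
strand-ambiguous). Concordance is summarized by the same-sign fraction and
the Spearman rank correlation of harmonized β̂ values.

**MAF-matched permutation enrichment.** The SNP universe is LD-pruned
(greedy, r² > 0.7, annotation SNPs kept with priority), the query set is
binned by MAF in 0.05-wide bins, and null SNP sets matching the per-bin
counts are drawn without replacement. P_perm is the fraction of null sets
with a strictly higher annotation-overlap proportion than observed; the same
2×2 table gives a Fisher exact p and a sample odds ratio with Wald CI.

**Consensus co-methylation networks.** Per tissue, unsigned adjacency
a_ij = |cor(m_i, m_j)|⁶ is converted to a topological overlap matrix (TOM);
the consensus TOM is the element-wise minimum across tissues. Modules are
average-linkage clusters of 1 − TOM under a static height cut. Module
eigengenes (first PC of the module's CpGs) are tested for diagnosis
association per tissue and combined across tissues (Fisher's method, with a
signed Stouffer alternative); per-CpG module membership (MM) and methylation
significance (MS) are cross-tissue combined Z-scores.

## Worked example

Run the full pipeline on a synthetic three-tissue cohort (200 subjects per
tissue, 300 SNPs, 300 CpGs on a 3 Mbp chromosome):

```bash
meqtlkit run-all --out demo_run --seed 7
```

The run directory contains per-stage TSVs and `report.txt`; with seed 7 the
report reads (abridged):

```
scan[brain]: 56 pairs at window=20000 pmax=1e-05
scan[blood]: 54 pairs at window=20000 pmax=1e-05
scan[saliva]: 52 pairs at window=20000 pmax=1e-05
compare:
  brain: 56 pairs (18.37% of SNPs are meQTLs, 19.18% of CpGs targeted); shared fraction 71.43%
  blood: 54 pairs (17.35% of SNPs are meQTLs, 18.49% of CpGs targeted); shared fraction 74.07%
  saliva: 51 pairs (16.33% of SNPs are meQTLs, 17.47% of CpGs targeted); shared fraction 78.43%
shared pairs: 40; same-sign 100.0%, Spearman rho 0.892
dropped during harmonization: palindromic=16
network: 1 modules (power=6, min_size=30, cut_height=0.995, combine=fisher)
  module 1: size=46 combined_p=0.00546128 mm_ms_r=0.622
```

Reading this: the scan found 51–56 significant cis pairs per tissue, of which
40 are shared by all three tissues (the cohort was simulated with 60% of
planted effects shared); every matched pair has the same effect sign across
tissues and the β̂ patterns rank-correlate at 0.89; 16 palindromic SNP pairs
were dropped during allele harmonization; and the consensus network recovers
one module (46 CpGs, overlapping the planted 50-CpG disease module) whose
eigengene–diagnosis association combines to p ≈ 0.005 across tissues, with
module membership correlating with per-CpG disease significance at 0.62.

Each stage is also a library call (`meqtlkit.scan_tissue`,
`meqtlkit.match_tables`, `meqtlkit.snp_set_enrichment`,
`meqtlkit.consensus_network`, ...) and a CLI subcommand (`simulate`, `qc`,
`scan`, `compare`, `enrich`, `network`) operating on plain TSV files.

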