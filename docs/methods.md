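# Methods

This note documents the models, defaults, and numerical choices behind
meqtlkit, and what the synthetic cohorts do and do not emulate.

## Synthetic cohort model

Genotypes are biallelic SNPs on one chromosome (1-based positions), dosage
drawn per subject as Binomial(2, p) with the coding-allele frequency p chosen
so the minor-allele frequency falls in `maf_range`. Hardy–Weinberg
proportions therefore hold by construction. Tissues share the SNP and CpG
universes (positions, alleles, allele frequencies, annotation) but have
disjoint subjects with independent dosage draws — mirroring a design where
different cohorts are measured per tissue.

Methylation is generated on the logit scale and mapped through the inverse
logit, which guarantees beta values in (0, 1) without truncation:

    logit(m_ij) = b_j + Σ_k β_k g_ik + age/sex terms + batch shift
                  + λ_j f_i + ε_ij,   ε_ij ~ N(0, noise_sd²)

* `b_j`: per-CpG baseline, uniform on (−1.5, 1.5) (beta baselines ~0.18–0.82).
* Planted cis effects `β_k`: magnitude uniform in `effect_size_range`, random
  sign, only for SNP–CpG pairs within the 20 kbp cis window. A fraction
  `frac_shared` of planted pairs is active in every tissue with the identical
  effect (size and sign); the rest are active in exactly one tissue. Equal
  shared effects make sign-concordance checks crisp.
* Disease module: `module_size` CpGs load on a latent factor `f_i` that is
  N(0, 1) shifted by `module_effect` for cases. Loadings λ_j are
  heterogeneous (uniform 0.4–1.6 times the base loading implied by
  `module_cor`), so CpGs closer to the module core carry larger case–control
  effects — this is what makes module membership (MM) and methylation
  significance (MS) genuinely correlated, as in real co-methylation modules,
  rather than differing only by noise.
* Batch structure: per-(batch, CpG) location shifts ~ N(0, `batch_shift_sd`).
* A detection-p channel marks a configurable fraction of entries as failed
  (p > 0.05) to exercise the missingness pipeline.

Annotation ("risk locus") SNP sets are planted against the meQTL truth set at
a target odds ratio by drawing the overlap count from Fisher's noncentral
hypergeometric distribution with odds equal to the target — the exact
conditional law of a 2×2 table given its margins — then sampling members
uniformly inside and outside the truth set.

Defaults (200 subjects × 3 tissues; 300 SNPs and 300 CpGs on 3 Mbp;
MAF 0.05–0.5; effects 0.3–0.8 logit units per allele; noise SD 0.5; 2 batches
with shift SD 0.3; 50-CpG module with shift 0.3) describe a deliberately
small but realistic regime: 200 is the smallest sample size among the study
designs the power restriction refers to, and the SNP/CpG density gives most
CpGs a handful of cis SNPs. Simulation sizes in the tests (e.g. a 20,000-SNP
universe with a 500-SNP query for permutation checks, 150-subject tissues for
network checks) are the package's chosen problem sizes for those properties.

What the generator does **not** emulate: linkage disequilibrium (available
only through an explicit `add_ld_partner` helper that copies a SNP with
redraws to a target r²; default cohorts are LD-free), realistic genome
annotation, probe chemistry artifacts, cell-composition effects on
methylation, or trans effects. Passing tests therefore demonstrate
correctness of the statistics under the stated generative model, not
robustness to the full messiness of array data.

## Preprocessing

Pipeline order is fixed: blacklist filter → detection-p masking (p > 0.05
treated as missing) → missingness filter (> 1% missing removed) → quantile
normalization → per-CpG mean imputation → empirical-Bayes batch adjustment.
Normalization precedes imputation so imputed values cannot distort the
quantile reference; the quantile step is missing-data-aware (subjects with
missing entries contribute their sorted observed values interpolated onto the
common order-statistic grid, and keep their missing entries missing).

* Genotype QC removes SNPs with missingness > `max_snp_missing` (default 1%),
  MAF < `min_maf` (default 0.05), or HWE p < 1e-6. The HWE test is a 1-df
  chi-square against expected genotype counts with Yates continuity
  correction when any expected count is below 5; an exact test would be
  preferable at very small counts but the chi-square matches the thresholding
  use here.
* Quantile normalization forces every subject's value vector to the
  across-subject mean of order statistics; ties get average ranks.
* Rank normalization (used by one source-study style) is the per-CpG
  inverse-normal transform at Blom positions (r − 3/8)/(n + 1/4).
* Batch adjustment is the standard parametric empirical-Bayes scheme:
  per-CpG batch locations shrunk under a normal prior, batch scales under an
  inverse-gamma prior (method-of-moments hyperparameters, fixed-point
  iteration to 1e-6), both removed after standardization by the pooled
  residual SD. Covariates passed as *protected* (by default the diagnosis
  label) sit in the design matrix, so their effects survive adjustment —
  verified on noise-free planted effects to within 10%. No Python
  implementation of this scheme was available as a dependency, so it is
  implemented here and tested against its defining behaviors.

One subtlety worth knowing: quantile normalization equalizes each subject's
whole-vector distribution, so a co-methylation module spanning a large
fraction of a small synthetic CpG universe is partially absorbed as a
"global" shift and its within-module correlation attenuates. On real arrays
(hundreds of thousands of CpGs) a 50-CpG module is far below that threshold.
Network tests therefore either use universes where the module is a small
fraction, or build the correlation structure directly.

## cis-meQTL scan

Window ≤ 20,000 bp, boundary inclusive, same chromosome; p ≤ 1e-5 retained.
Dosage counts the stated coding allele and every record carries that allele,
so downstream harmonization is well defined. β̂ = β/std(β) is the t statistic
of the slope — the only reading under which standardized effects are
comparable across studies with different scales. Missing dosages fall back to
pairwise-complete per-pair fits; the complete-data fast path residualizes
both matrices on the covariates once (QR) and is exactly the per-pair OLS.
Degenerate pairs (constant dosage, collinear design) are flagged and excluded
rather than raised.

Analytic detection power for the slope t-test uses the noncentral t with
noncentrality effect·sqrt(n·2·maf·(1−maf)) on n − 2 df — effect in
residual-SD units, dosage variance from HWE. This is a reconstruction of the
power analysis the pipeline needs (sample size, MAF, effect size in, power
out); the far-tail noncentral-t underflow in scipy is clamped to zero where
the contribution is negligible. Agreement with Monte-Carlo rejection rates is
within 2 percentage points over the tested grid.

## Cross-tissue comparison

Matching is by (chromosome, position) for both SNPs and CpGs — not by rsid.
Allele harmonization compares coding/other alleles directly and after strand
complement; a coding/other swap contributes a −1 multiplier applied to the
second record's β̂. Palindromic SNPs (A/T, C/G) cannot be disambiguated
without allele-frequency heuristics and are dropped, with per-reason drop
counts reported so the accounting is auditable. "Fraction shared"
denominators are each tissue's own significant set restricted to the common
universe. Restricted mode additionally requires cross-tissue MAF agreement
(|ΔMAF| < 0.1 by default) and analytic power ≥ 0.8 at a reference n for the
effect implied by each record's β̂.

## Enrichment

LD pruning is greedy in position order with annotation (priority) SNPs
processed first, so a priority SNP is never displaced by a non-priority one;
the kept set never contains two SNPs with r² > 0.7 within the window, and
every removed SNP conflicts with a kept one. MAF bins are [0, 0.05), ...,
[0.45, 0.50] with the last bin right-closed. Null sets match the query's
per-bin counts and are drawn without replacement within bins; the empirical
p-value uses the strict "greater than" convention, and p_perm = 0 is reported
as "< 1/n_sets".

Because the per-bin overlap of a without-replacement draw with the annotation
is exactly hypergeometric, the default implementation draws the per-bin
overlap counts directly from that distribution and sums them — the identical
null law at a fraction of the cost of materializing 10⁵ SNP sets. Explicit
set sampling remains available (`return_null_sets=True`) and the two routes
are tested for agreement. Under a planted null (OR = 1) the rejection rate at
p_perm < 0.05 sits inside the binomial band around 0.05; the strict-greater
convention makes ties non-rejecting, so calibration is slightly conservative
where the overlap distribution is coarse.

Fisher 2×2 tests are two-sided exact (hypergeometric tail summation, checked
against full enumeration); the sample odds ratio ad/bc gets a Haldane 0.5
correction when a cell is zero, and the 95% CI is Wald on the log odds ratio.
Whether an exact (conditional) CI would better match published practice is
not decidable from the outputs alone; Wald was chosen and is labeled in the
output. CpG-context enrichment applies the same 2×2 machinery per region flag
and island-context category between two CpG sets.

## Consensus networks

Unsigned adjacency |cor|^6 (soft power configurable, default 6), TOM
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), consensus =
element-wise minimum (an optional 95th-percentile quantile alignment before
the minimum is off by default). Module detection is average-linkage
clustering of 1 − TOM with a **static** cut at 0.995 of the maximum merge
height and a minimum module size of 30; clusters below the size floor are
labeled 0. This replaces the dynamic tree-cut family: the static cut is
self-contained, deterministic, and sufficient for well-separated modules,
but it will not resolve nested or partially overlapping modules the way
dynamic cutting can — a known limitation.

Module eigengenes are first-PC scores of the standardized module CpGs, unit
variance, sign-oriented so the mean eigengene–CpG correlation is positive.
Disease association is OLS of the eigengene on diagnosis plus covariates per
tissue; p-values combine across tissues by Fisher's method (−2Σln p on 2k
df). A signed Stouffer combination is available behind `combine="stouffer"`:
the two combiners can disagree noticeably (for per-tissue p-values 5.33e-3
and 2.87e-4, Fisher gives 2.2e-5 while signed Stouffer gives ≈ 5.8e-6), and
published combined values in this analysis style are sometimes consistent
only with the Stouffer reading — both are therefore implemented and the
choice is recorded in the output. MM combines Fisher r-to-z transformed
CpG–eigengene correlations as Z-scores across tissues (computing Z from the
correlation rather than from a correlation-test p-value; the two agree to
first order and the r-to-z route keeps the sign naturally); MS combines
signed per-CpG diagnosis-association Z-scores the same way.

## Pipeline and reproducibility

The orchestrator (`run_pipeline`, CLI `run-all`) holds no computation: every
stage is a library call, every artifact a plain TSV, and all stage parameters
are echoed in the report. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical config + seed reproduces
byte-identical outputs. `scripts/acceptance.py` derives all of its world
seeds from the single `--seed` argument.

## Known limitations

* Cell proportions are simulated covariates; no reference-based cell-type
  deconvolution is included.
* Genotype imputation, array-level signal preprocessing, and trans-meQTL
  scans are out of scope.
* The LD model is a single-proxy copy mechanism, not haplotype structure;
  supervised pruning is exercised on it but population LD patterns are not
  represented.
* The static module cut requires modules to be well separated from the
  background at the chosen height; `cut_height` and `min_size` deserve a
  sensitivity check on new data.
* FDR control beyond the fixed p ≤ 1e-5 threshold is intentionally absent;
  the threshold mirrors the cross-study comparability argument rather than a
  per-dataset error-rate guarantee.
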