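"""Synthetic multi-tissue cohort generator with known ground truth.

Emulates the study design that the downstream stages expect: biallelic SNPs in
Hardy-Weinberg proportions on a single chromosome, beta-valued methylation
generated on the logit scale with planted cis effects (partly shared across
three tissues, partly tissue-specific), covariate and batch structure,
case/control labels with one planted disease-associated co-methylation module,
and an annotation SNP set planted at a chosen odds ratio against the meQTL
truth set. Every random choice is driven by an explicit seed so an identical
spec reproduces a byte-identical cohort.

Generation happens on the logit scale and is mapped through the inverse logit,
which guarantees valid beta values in (0, 1) without truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import (
    BLACKLIST_FLAGS,
    CovariateTable,
    GenotypeMatrix,
    ISLAND_CONTEXTS,
    MethylationMatrix,
    REGION_FLAGS,
)

DEFAULT_TISSUES = ("brain", "blood", "saliva")

#: Marginal probabilities used when drawing CpG annotation flags. Region flags
#: are independent Bernoulli draws; island context is one categorical draw.
REGION_PROBS = {
    "gene_body": 0.35,
    "TSS200": 0.08,
    "TSS1500": 0.12,
    "UTR5": 0.06,
    "UTR3": 0.04,
    "first_exon": 0.05,
    "enhancer": 0.15,
}
ISLAND_PROBS = (0.30, 0.15, 0.15, 0.07, 0.07, 0.26)
BLACKLIST_PROBS = {"snp_coincident": 0.01, "cross_reactive": 0.01, "sex_chromosome": 0.005}


class SpecificationError(ValueError):
    """Raised when a cohort spec violates its own constraints."""


@dataclass
class CohortSpec:
    """Parameters of one synthetic multi-tissue cohort.

    Defaults describe a cohort of 200 subjects per tissue (the size of the
    smallest source study the power restriction refers to), 300 SNPs and 300
    CpGs on a 3 Mbp chromosome (dense enough that most CpGs have at least one
    SNP within the 20 kbp cis window), moderate per-allele effects on the
    logit scale, and a 50-CpG disease module shared by all tissues.
    """

    n_subjects_per_tissue: tuple[int, ...] = (200, 200, 200)
    n_snps: int = 300
    n_cpgs: int = 300
    chrom_length: int = 3_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_cis_pairs: float = 0.3
    frac_shared: float = 0.6
    effect_size_range: tuple[float, float] = (0.3, 0.8)
    noise_sd: float = 0.5
    covariate_effect_sd: float = 0.05
    n_batches: int = 2
    batch_shift_sd: float = 0.3
    case_fraction: float = 0.5
    module_size: int = 50
    module_effect: float = 0.3
    module_cor: float = 0.8
    annotation_size: int = 30
    annotation_or: float = 2.0
    detect_fail_fraction: float = 0.0
    cis_window: int = 20_000
    seed: int = 0
    tissues: tuple[str, ...] = DEFAULT_TISSUES

    def validate(self) -> None:
        if len(self.n_subjects_per_tissue) != len(self.tissues):
            raise SpecificationError("one subject count per tissue required")
        if any(n < 2 for n in self.n_subjects_per_tissue):
            raise SpecificationError("need at least 2 subjects per tissue")
        if self.n_snps < 1 or self.n_cpgs < 1:
            raise SpecificationError("n_snps and n_cpgs must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SpecificationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("frac_cis_pairs", "frac_shared", "case_fraction", "detect_fail_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecificationError(f"{name} must be in [0, 1], got {v}")
        if self.module_size > self.n_cpgs:
            raise SpecificationError("module_size exceeds n_cpgs")
        if not (0.0 <= self.module_cor < 1.0):
            raise SpecificationError("module_cor must be in [0, 1)")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise SpecificationError("SDs must be nonnegative")
        if self.n_batches < 1:
            raise SpecificationError("need at least one batch")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("n_subjects_per_tissue", "maf_range", "effect_size_range", "tissues"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth of one synthetic cohort.

    ``planted_pairs`` has columns snp_id, cpg_id, tissues (comma-joined subset
    of the simulated tissues), effect (logit scale, per coding allele).
    """

    planted_pairs: pd.DataFrame
    module_cpgs: tuple[str, ...]
    risk_snps: tuple[str, ...]
    annotation_or: float

    def pairs_for_tissue(self, tissue: str) -> pd.DataFrame:
        mask = self.planted_pairs["tissues"].str.split(",").apply(lambda ts: tissue in ts)
        return self.planted_pairs[mask]

    @property
    def meqtl_snps(self) -> set[str]:
        return set(self.planted_pairs["snp_id"])

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.planted_pairs.to_csv(directory / "planted_pairs.tsv", sep="\t", index=False)
        pd.DataFrame({"cpg_id": list(self.module_cpgs)}).to_csv(
            directory / "module_cpgs.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"snp_id": list(self.risk_snps), "target_or": self.annotation_or}
        ).to_csv(directory / "risk_snps.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "TruthTable":
        directory = Path(directory)
        pairs = pd.read_csv(directory / "planted_pairs.tsv", sep="\t")
        module = pd.read_csv(directory / "module_cpgs.tsv", sep="\t")
        risk = pd.read_csv(directory / "risk_snps.tsv", sep="\t")
        target_or = float(risk["target_or"].iloc[0]) if len(risk) else float("nan")
        return cls(
            planted_pairs=pairs,
            module_cpgs=tuple(module["cpg_id"].astype(str)),
            risk_snps=tuple(risk["snp_id"].astype(str)),
            annotation_or=target_or,
        )


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def _simulate_snp_universe(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Shared SNP metadata: positions, alleles, and population coding-allele freq."""
    pos = np.sort(rng.choice(np.arange(1, spec.chrom_length + 1), size=spec.n_snps, replace=False))
    lo, hi = spec.maf_range
    maf = rng.uniform(lo, hi, size=spec.n_snps)
    # coding allele may be either the minor or the major allele
    freq = np.where(rng.random(spec.n_snps) < 0.5, maf, 1.0 - maf)
    bases = np.array(list("ACGT"))
    coding_idx = rng.integers(0, 4, size=spec.n_snps)
    other_idx = (coding_idx + rng.integers(1, 4, size=spec.n_snps)) % 4
    ids = [f"snp{i:05d}" for i in range(spec.n_snps)]
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos.astype(int),
            "coding_allele": bases[coding_idx],
            "other_allele": bases[other_idx],
            "freq_coding": freq,
        },
        index=pd.Index(ids, name="snp_id"),
    )


def _draw_dosages(
    universe: pd.DataFrame, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    freq = universe["freq_coding"].to_numpy()
    dosages = rng.binomial(2, freq, size=(n, len(universe))).astype(float)
    subjects = pd.Index([f"s{i:04d}" for i in range(n)], name="subject")
    dos = pd.DataFrame(dosages, index=subjects, columns=universe.index)
    meta = universe[["chrom", "pos", "coding_allele", "other_allele"]].copy()
    emp_freq = dosages.mean(axis=0) / 2.0
    meta["maf"] = np.minimum(emp_freq, 1.0 - emp_freq)
    return GenotypeMatrix(dos, meta)


def simulate_genotypes(spec: CohortSpec, n: int, seed: int) -> GenotypeMatrix:
    """Draw ``n`` subjects of HWE genotypes: per SNP, dosage ~ Binomial(2, p).

    Coding-allele frequency p is sampled so the minor-allele frequency lies in
    ``spec.maf_range``; positions are strictly increasing on one chromosome;
    per-SNP empirical MAF is recorded in the metadata.
    """
    spec.validate()
    if n < 2:
        raise SpecificationError("need n >= 2 subjects")
    rng = np.random.default_rng(seed)
    universe = _simulate_snp_universe(spec, rng)
    return _draw_dosages(universe, n, rng)


def add_ld_partner(
    G: GenotypeMatrix, snp_id: str, target_r2: float, seed: int, new_id: str | None = None
) -> GenotypeMatrix:
    """Append a copy of ``snp_id`` with per-subject redraws to hit ``target_r2``.

    Copying a column and independently redrawing a fraction 1 - sqrt(r2) of
    entries from the SNP's HWE distribution gives expected dosage correlation
    about sqrt(r2), i.e. expected r^2 about ``target_r2``. Used to exercise LD
    pruning; default cohorts are LD-free.
    """
    if not (0.0 <= target_r2 <= 1.0):
        raise SpecificationError("target_r2 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = G.dosages[snp_id].to_numpy().copy()
    freq = g.mean() / 2.0
    keep = rng.random(len(g)) < np.sqrt(target_r2)
    redraw = rng.binomial(2, freq, size=len(g)).astype(float)
    g_new = np.where(keep, g, redraw)
    new_id = new_id or f"{snp_id}_ld"
    meta_row = G.snp_meta.loc[snp_id].copy()
    meta_row["pos"] = int(meta_row["pos"]) + 1
    meta_row["maf"] = min(g_new.mean() / 2.0, 1.0 - g_new.mean() / 2.0)
    dosages = G.dosages.copy()
    dosages[new_id] = g_new
    meta = pd.concat([G.snp_meta, meta_row.to_frame().T.set_axis([new_id])])
    meta["pos"] = meta["pos"].astype(int)
    return GenotypeMatrix(dosages, meta)


# --------------------------------------------------------------------------
# CpG universe and covariates
# --------------------------------------------------------------------------

def _simulate_cpg_universe(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    pos = np.sort(rng.choice(np.arange(1, spec.chrom_length + 1), size=spec.n_cpgs, replace=False))
    ids = [f"cg{i:05d}" for i in range(spec.n_cpgs)]
    meta = pd.DataFrame({"chrom": "1", "pos": pos.astype(int)}, index=pd.Index(ids, name="cpg_id"))
    for flag in REGION_FLAGS:
        meta[f"region_{flag}"] = rng.random(spec.n_cpgs) < REGION_PROBS[flag]
    meta["island_context"] = rng.choice(ISLAND_CONTEXTS, size=spec.n_cpgs, p=ISLAND_PROBS)
    for flag in BLACKLIST_FLAGS:
        meta[f"blacklist_{flag}"] = rng.random(spec.n_cpgs) < BLACKLIST_PROBS[flag]
    meta["baseline_logit"] = rng.uniform(-1.5, 1.5, size=spec.n_cpgs)
    return meta


def simulate_covariates(spec: CohortSpec, n: int, seed: int) -> CovariateTable:
    """Age, sex, diagnosis, batch label, 3 cell proportions, 3 ancestry PCs."""
    rng = np.random.default_rng(seed)
    subjects = pd.Index([f"s{i:04d}" for i in range(n)], name="subject")
    table = pd.DataFrame(index=subjects)
    table["age"] = np.clip(rng.normal(40.0, 12.0, size=n), 18.0, 65.0)
    table["sex"] = rng.integers(0, 2, size=n)
    table["diagnosis"] = (rng.random(n) < spec.case_fraction).astype(int)
    table["batch"] = [f"b{rng.integers(0, spec.n_batches)}" for _ in range(n)]
    cells = rng.dirichlet((5.0, 3.0, 2.0), size=n)
    for k in range(3):
        table[f"cell_{k}"] = cells[:, k]
    pcs = rng.normal(0.0, 1.0, size=(n, 3))
    for k in range(3):
        table[f"pc{k + 1}"] = pcs[:, k]
    return CovariateTable(table)


# --------------------------------------------------------------------------
# methylation
# --------------------------------------------------------------------------

def simulate_methylation(
    G: GenotypeMatrix,
    cpg_meta: pd.DataFrame,
    truth: TruthTable,
    covariates: CovariateTable,
    spec: CohortSpec,
    tissue: str,
    seed: int,
) -> MethylationMatrix:
    """Generate beta values for one tissue from the additive logit model.

    logit(m) = baseline + sum(effect * dosage) over planted pairs active in
    this tissue + covariate terms + batch shift + module latent factor +
    case/control module shift + Gaussian noise; beta = inverse logit.
    """
    rng = np.random.default_rng(seed)
    n = G.n_subjects
    cpg_ids = cpg_meta.index
    pos_snp = G.snp_meta["pos"]
    pos_cpg = cpg_meta["pos"]

    if "baseline_logit" in cpg_meta.columns:
        baseline = cpg_meta["baseline_logit"].to_numpy()
    else:
        baseline = rng.uniform(-1.5, 1.5, size=len(cpg_ids))
    logit = np.tile(baseline, (n, 1))

    cpg_index = {c: j for j, c in enumerate(cpg_ids)}
    for row in truth.pairs_for_tissue(tissue).itertuples(index=False):
        if row.snp_id not in G.snp_meta.index or row.cpg_id not in cpg_index:
            raise SpecificationError(f"planted pair {row.snp_id}-{row.cpg_id} not in universe")
        dist = abs(int(pos_snp[row.snp_id]) - int(pos_cpg[row.cpg_id]))
        if dist > spec.cis_window:
            raise SpecificationError(
                f"planted pair {row.snp_id}-{row.cpg_id} violates cis window ({dist} bp)"
            )
        logit[:, cpg_index[row.cpg_id]] += row.effect * G.dosages[row.snp_id].to_numpy()

    cov = covariates.table
    if spec.covariate_effect_sd > 0:
        age_z = (cov["age"].to_numpy() - 40.0) / 12.0
        sex = cov["sex"].to_numpy().astype(float)
        age_coef = rng.normal(0.0, spec.covariate_effect_sd, size=len(cpg_ids))
        sex_coef = rng.normal(0.0, spec.covariate_effect_sd, size=len(cpg_ids))
        logit += np.outer(age_z, age_coef) + np.outer(sex, sex_coef)

    if spec.n_batches > 1 and spec.batch_shift_sd > 0:
        batches = pd.unique(cov["batch"])
        shift = rng.normal(0.0, spec.batch_shift_sd, size=(len(batches), len(cpg_ids)))
        batch_idx = cov["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
        logit += shift[batch_idx, :]

    module_idx = [cpg_index[c] for c in truth.module_cpgs if c in cpg_index]
    if module_idx and spec.module_cor > 0:
        # A shared latent factor induces the co-methylation structure; the
        # disease shifts the factor itself, so per-CpG case/control effects
        # scale with each CpG's loading (its closeness to the module core).
        diagnosis = cov["diagnosis"].to_numpy().astype(float)
        base_loading = spec.noise_sd * np.sqrt(spec.module_cor / (1.0 - spec.module_cor))
        loadings = base_loading * rng.uniform(0.4, 1.6, size=len(module_idx))
        factor = rng.normal(0.0, 1.0, size=n) + spec.module_effect * diagnosis
        logit[:, module_idx] += np.outer(factor, loadings)

    if spec.noise_sd > 0:
        logit += rng.normal(0.0, spec.noise_sd, size=logit.shape)

    values = pd.DataFrame(special.expit(logit), index=G.dosages.index, columns=cpg_ids)

    det = rng.uniform(0.0, 0.04, size=logit.shape)
    if spec.detect_fail_fraction > 0:
        fail = rng.random(logit.shape) < spec.detect_fail_fraction
        det = np.where(fail, rng.uniform(0.051, 0.5, size=logit.shape), det)
    detection_p = pd.DataFrame(det, index=G.dosages.index, columns=cpg_ids)

    return MethylationMatrix(values, cpg_meta.copy(), detection_p)


# --------------------------------------------------------------------------
# annotation planting
# --------------------------------------------------------------------------

def plant_annotation_set(
    universe: Sequence[str],
    meqtl_truth: set[str] | Sequence[str],
    target_or: float,
    size: int,
    seed: int,
) -> set[str]:
    """Sample an annotation SNP set whose 2x2 odds ratio against the truth set
    has expectation ``target_or``.

    The overlap count with the truth set is drawn from Fisher's noncentral
    hypergeometric distribution with odds equal to ``target_or`` (the exact
    conditional law of the 2x2 table given its margins); members are then
    chosen uniformly inside and outside the truth set.
    """
    universe = list(universe)
    truth_set = set(meqtl_truth) & set(universe)
    if size > len(universe):
        raise SpecificationError("annotation size exceeds universe")
    if not (target_or > 0) and not np.isinf(target_or):
        raise SpecificationError("target_or must be positive")
    rng = np.random.default_rng(seed)
    in_truth = [s for s in universe if s in truth_set]
    out_truth = [s for s in universe if s not in truth_set]
    t, M = len(in_truth), len(universe)
    if np.isinf(target_or):
        if size > t:
            raise SpecificationError("target_or=inf infeasible: size exceeds truth set")
        a = size
    else:
        dist = stats.nchypergeom_fisher(M, t, size, target_or)
        a = int(dist.rvs(random_state=rng))
    chosen = set(rng.choice(in_truth, size=a, replace=False)) if a else set()
    b = size - a
    if b > len(out_truth):
        raise SpecificationError("annotation size infeasible outside truth set")
    if b:
        chosen |= set(rng.choice(out_truth, size=b, replace=False))
    return chosen


# --------------------------------------------------------------------------
# whole cohort
# --------------------------------------------------------------------------

def _plant_pairs(
    spec: CohortSpec,
    snp_universe: pd.DataFrame,
    cpg_meta: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose (SNP, CpG) cis pairs and effect sizes; assign tissue sets."""
    from .scan import cis_pairs

    pairs = cis_pairs(snp_universe, cpg_meta, spec.cis_window)
    if pairs.empty or spec.frac_cis_pairs == 0:
        return pd.DataFrame(columns=["snp_id", "cpg_id", "tissues", "effect"])
    by_cpg = pairs.groupby("cpg_id")["snp_id"].apply(list)
    eligible = list(by_cpg.index)
    n_target = int(round(spec.frac_cis_pairs * spec.n_cpgs))
    n_pairs = min(n_target, len(eligible))
    chosen_cpgs = rng.choice(eligible, size=n_pairs, replace=False)
    lo, hi = spec.effect_size_range
    rows = []
    n_shared = int(round(spec.frac_shared * n_pairs))
    for i, cpg in enumerate(chosen_cpgs):
        snp = by_cpg[cpg][int(rng.integers(0, len(by_cpg[cpg])))]
        effect = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        if i < n_shared:
            tissues = ",".join(spec.tissues)
        else:
            tissues = spec.tissues[int(rng.integers(0, len(spec.tissues)))]
        rows.append({"snp_id": snp, "cpg_id": cpg, "tissues": tissues, "effect": effect})
    return pd.DataFrame(rows)


def build_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, tuple[GenotypeMatrix, MethylationMatrix, CovariateTable]], TruthTable]:
    """Generate the full multi-tissue cohort plus its truth table.

    All tissues share the SNP and CpG universes (positions, alleles, allele
    frequencies, CpG annotation); subjects, dosage draws, covariates, and
    noise are tissue-specific. Shared planted pairs carry the identical effect
    (size and sign) in every tissue.
    """
    spec.validate()
    root = np.random.default_rng(spec.seed)
    snp_universe = _simulate_snp_universe(spec, root)
    cpg_meta = _simulate_cpg_universe(spec, root)
    planted = _plant_pairs(spec, snp_universe, cpg_meta, root)

    non_module = [c for c in cpg_meta.index]
    module_cpgs = tuple(root.choice(non_module, size=spec.module_size, replace=False))
    truth_partial = TruthTable(planted, module_cpgs, (), spec.annotation_or)

    risk = plant_annotation_set(
        list(snp_universe.index),
        truth_partial.meqtl_snps,
        spec.annotation_or,
        min(spec.annotation_size, len(snp_universe)),
        seed=int(root.integers(2**31)),
    )
    truth = TruthTable(planted, module_cpgs, tuple(sorted(risk)), spec.annotation_or)

    tissues: dict[str, tuple[GenotypeMatrix, MethylationMatrix, CovariateTable]] = {}
    for tissue, n in zip(spec.tissues, spec.n_subjects_per_tissue):
        g_seed = int(root.integers(2**31))
        c_seed = int(root.integers(2**31))
        m_seed = int(root.integers(2**31))
        rng_t = np.random.default_rng(g_seed)
        G = _draw_dosages(snp_universe, n, rng_t)
        C = simulate_covariates(spec, n, c_seed)
        M = simulate_methylation(G, cpg_meta, truth, C, spec, tissue, m_seed)
        tissues[tissue] = (G, M, C)
    return tissues, truth


def write_cohort(
    directory: str | Path,
    tissues: Mapping[str, tuple[GenotypeMatrix, MethylationMatrix, CovariateTable]],
    truth: TruthTable,
    spec: CohortSpec | None = None,
    vcf: bool = False,
) -> None:
    """Write a cohort as TSV (plus optional VCF) under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tissue, (G, M, C) in tissues.items():
        tdir = directory / tissue
        tdir.mkdir(exist_ok=True)
        G.to_tsv(tdir / "dosages.tsv", tdir / "snp_meta.tsv")
        if vcf:
            G.to_vcf(tdir / "genotypes.vcf")
        M.to_tsv(tdir / "methylation.tsv", tdir / "cpg_meta.tsv")
        C.to_tsv(tdir / "covariates.tsv")
    truth.to_dir(directory / "truth")
    if spec is not None:
        spec.to_yaml(directory / "cohort_spec.yaml")
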