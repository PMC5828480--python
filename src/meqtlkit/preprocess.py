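"""Genotype and methylation QC / normalization.

The methylation pipeline applies, in order: blacklist filter, detection-p
masking, missingness filter, quantile normalization, per-CpG mean imputation,
then empirical-Bayes batch adjustment. Normalization precedes imputation so
imputed values cannot distort the quantile reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CovariateTable, GenotypeMatrix, MethylationMatrix


@dataclass
class QcLog:
    """Per-rule removal counts from a QC pass."""

    counts: dict[str, int]

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.counts), "n_removed": list(self.counts.values())}
        )


# --------------------------------------------------------------------------
# genotype QC
# --------------------------------------------------------------------------

def hwe_test(counts: tuple[int, int, int]) -> float:
    """Two-sided goodness-of-fit p-value for Hardy-Weinberg proportions.

    1-df chi-square of observed genotype counts (n_AA, n_Aa, n_aa) against
    expectations from the estimated allele frequency, with Yates continuity
    correction when any expected count is below 5.
    """
    n_aa_hom, n_het, n_alt_hom = (float(c) for c in counts)
    if min(n_aa_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa_hom + n_het + n_alt_hom
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_aa_hom + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa_hom, n_het, n_alt_hom])
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: trivially consistent with HWE
    diff = np.abs(observed - expected)
    if expected.min() < 5:
        diff = np.maximum(diff - 0.5, 0.0)  # continuity correction
    chi2 = float(np.sum(diff**2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def genotype_qc(
    G: GenotypeMatrix,
    max_snp_missing: float = 0.01,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QcLog]:
    """Drop SNPs failing missingness, MAF, or Hardy-Weinberg rules.

    A SNP is removed when its missing fraction exceeds ``max_snp_missing``,
    its empirical MAF is below ``min_maf``, or its HWE test p-value falls
    below ``hwe_alpha``. Returns the filtered matrix and per-rule counts
    (a SNP failing several rules is counted under each).
    """
    for name, v in (("max_snp_missing", max_snp_missing), ("min_maf", min_maf), ("hwe_alpha", hwe_alpha)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    dos = G.dosages
    missing_frac = dos.isna().mean(axis=0)
    freq = dos.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    hwe_p = pd.Series(1.0, index=dos.columns)
    arr = dos.to_numpy()
    for j, snp in enumerate(dos.columns):
        col = arr[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            hwe_p[snp] = 1.0
            continue
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        hwe_p[snp] = hwe_test(counts)

    fail_missing = missing_frac > max_snp_missing
    fail_maf = maf < min_maf
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_missing | fail_maf | fail_hwe)
    log = QcLog(
        {
            "missingness": int(fail_missing.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        }
    )
    if keep.sum() == 0:
        warnings.warn("genotype_qc removed every SNP", stacklevel=2)
    kept_ids = dos.columns[keep]
    out = GenotypeMatrix(dos[kept_ids], G.snp_meta.loc[kept_ids].copy())
    emp_freq = out.dosages.mean(axis=0) / 2.0
    out.snp_meta["maf"] = np.minimum(emp_freq, 1.0 - emp_freq)
    return out, log


# --------------------------------------------------------------------------
# methylation QC
# --------------------------------------------------------------------------

def methylation_qc(
    M: MethylationMatrix,
    max_missing: float = 0.01,
    detection_alpha: float = 0.05,
) -> tuple[MethylationMatrix, QcLog]:
    """Blacklist filter, detection-p masking, and per-CpG missingness filter.

    CpGs carrying any blacklist flag (SNP-coincident, cross-reactive probe,
    sex chromosome) are removed outright. Entries whose detection p exceeds
    ``detection_alpha`` are set missing; CpGs whose missing fraction then
    exceeds ``max_missing`` are removed.
    """
    meta = M.cpg_meta
    flag_cols = [c for c in meta.columns if c.startswith("blacklist_")]
    blacklisted = (
        meta[flag_cols].any(axis=1) if flag_cols else pd.Series(False, index=meta.index)
    )
    values = M.values.copy()
    if M.detection_p is not None:
        values = values.mask(M.detection_p > detection_alpha)
    missing_frac = values.isna().mean(axis=0)
    fail_missing = missing_frac > max_missing
    keep = ~(blacklisted | fail_missing)
    log = QcLog(
        {"blacklist": int(blacklisted.sum()), "missingness": int((fail_missing & ~blacklisted).sum())}
    )
    kept = values.columns[keep]
    det = M.detection_p[kept] if M.detection_p is not None else None
    return MethylationMatrix(values[kept], meta.loc[kept].copy(), det), log


def quantile_normalize(M: MethylationMatrix) -> MethylationMatrix:
    """Force every subject's value vector to the mean empirical distribution.

    The reference distribution is the across-subject mean of order statistics;
    each subject's values are replaced by the reference at their (average,
    tie-aware) ranks. With a single subject this is the identity.
    """
    vals = M.values.to_numpy(dtype=float)
    n_subj, n_cpg = vals.shape
    if n_subj < 2:
        return M.copy()
    # Reference: mean of per-subject order statistics. Subjects with missing
    # entries contribute their sorted observed values interpolated onto the
    # common order-statistic grid, and keep their missing entries missing.
    grid = np.arange(n_cpg, dtype=float)
    contributions = np.empty((n_subj, n_cpg))
    for i in range(n_subj):
        obs = np.sort(vals[i][np.isfinite(vals[i])])
        m = obs.size
        if m < 2:
            raise ValueError("quantile_normalize needs >=2 observed values per subject")
        contributions[i] = np.interp(grid * (m - 1) / (n_cpg - 1), np.arange(m), obs)
    reference = contributions.mean(axis=0)
    out = np.full_like(vals, np.nan)
    for i in range(n_subj):
        mask = np.isfinite(vals[i])
        m = int(mask.sum())
        ranks = stats.rankdata(vals[i][mask], method="average")  # 1..m, ties averaged
        positions = (ranks - 1.0) * (n_cpg - 1) / (m - 1)
        out[i, mask] = np.interp(positions, grid, reference)
    values = pd.DataFrame(out, index=M.values.index, columns=M.values.columns)
    det = None if M.detection_p is None else M.detection_p.copy()
    return MethylationMatrix(values, M.cpg_meta.copy(), det)


def mean_impute(M: MethylationMatrix) -> MethylationMatrix:
    """Replace missing entries by the per-CpG mean of the observed entries."""
    values = M.values
    if values.isna().all(axis=0).any():
        bad = values.columns[values.isna().all(axis=0)].tolist()
        raise ValueError(f"fully-missing CpGs (remove in QC first): {bad}")
    filled = values.fillna(values.mean(axis=0))
    det = None if M.detection_p is None else M.detection_p.copy()
    return MethylationMatrix(filled, M.cpg_meta.copy(), det)


def rank_normalize(M: MethylationMatrix) -> MethylationMatrix:
    """Per-CpG inverse-normal transform of ranks with the Blom offset.

    Each CpG column is replaced by Phi^{-1}((r - 3/8) / (n + 1/4)) of its
    average ranks, yielding mean about 0 and variance about 1 per CpG and
    preserving the within-CpG ordering exactly.
    """
    vals = M.values.to_numpy(dtype=float)
    n = vals.shape[0]
    const = vals.std(axis=0) == 0
    if const.any():
        bad = M.values.columns[const].tolist()
        raise ValueError(f"rank_normalize undefined for constant CpGs: {bad[:5]}")
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)
    out = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    values = pd.DataFrame(out, index=M.values.index, columns=M.values.columns)
    det = None if M.detection_p is None else M.detection_p.copy()
    return MethylationMatrix(values, M.cpg_meta.copy(), det)


# --------------------------------------------------------------------------
# batch adjustment (parametric empirical Bayes, ComBat-style)
# --------------------------------------------------------------------------

def _eb_iterate(
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    n_b: int,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the parametric EB posterior for one batch's location/scale."""
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 1.0
    # method-of-moments inverse-gamma hyperparameters for the scale
    v = delta_hat.mean()
    s2 = delta_hat.var(ddof=1) if delta_hat.size > 1 else 1.0
    lam = (2 * s2 + v**2) / s2 if s2 > 0 else 2.0
    theta = (v * s2 + v**3) / s2 if s2 > 0 else v
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        if tau2 > 0:
            g_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n_b * tau2 + delta_star
            )
        else:
            g_new = np.full_like(gamma_hat, gamma_bar)
        sum2 = delta_hat * (n_b - 1) + n_b * (gamma_hat - g_new) ** 2
        d_new = (theta + 0.5 * sum2) / (n_b / 2.0 + lam - 1.0)
        d_new = np.maximum(d_new, 1e-12)
        change = max(
            np.abs(g_new - gamma_star).max(initial=0.0),
            np.abs(d_new - delta_star).max(initial=0.0),
        )
        gamma_star, delta_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star


def batch_adjust(
    M: MethylationMatrix,
    batch: pd.Series,
    protected: pd.DataFrame | None = None,
) -> MethylationMatrix:
    """Remove per-CpG batch location/scale effects by parametric empirical Bayes.

    Per CpG the model is value = alpha + X_protected beta + gamma_batch +
    delta_batch * eps. Batch parameters are estimated per batch, shrunk
    towards their across-CpG mean (normal prior for locations, inverse-gamma
    for scales), and removed. Covariates in ``protected`` (e.g. diagnosis)
    are part of the design so their effects survive adjustment.
    """
    batch = batch.loc[M.values.index]
    levels = pd.unique(batch)
    if len(levels) < 2:
        warnings.warn("single batch: batch_adjust is the identity", stacklevel=2)
        return M.copy()
    sizes = batch.value_counts()
    if (sizes < 2).any():
        raise ValueError("every batch needs at least 2 subjects")

    Y = M.values.to_numpy(dtype=float)
    n, p = Y.shape
    onehot = np.stack([(batch == b).to_numpy(float) for b in levels], axis=1)
    X_parts = [onehot]
    if protected is not None and protected.shape[1] > 0:
        Xp = protected.loc[M.values.index].to_numpy(dtype=float)
        Xp = Xp - Xp.mean(axis=0)  # centered so batch columns absorb the intercept
        X_parts.append(Xp)
    X = np.concatenate(X_parts, axis=1)

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_batches = len(levels)
    batch_means = beta[:n_batches]  # per-batch intercepts
    weights = sizes.loc[levels].to_numpy(float) / n
    grand = weights @ batch_means
    resid = Y - X @ beta
    pooled_var = (resid**2).sum(axis=0) / n
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))

    stand = (Y - onehot @ batch_means - (X[:, n_batches:] @ beta[n_batches:] if X.shape[1] > n_batches else 0.0))
    stand = (stand + onehot @ (batch_means - grand)) / pooled_sd

    adjusted = np.empty_like(stand)
    for bi, b in enumerate(levels):
        mask = (batch == b).to_numpy()
        Zb = stand[mask]
        n_b = Zb.shape[0]
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gamma_star, delta_star = _eb_iterate(gamma_hat, delta_hat, n_b)
        adjusted[mask] = (Zb - gamma_star) / np.sqrt(delta_star)

    out = adjusted * pooled_sd + grand
    if X.shape[1] > n_batches:
        out = out + X[:, n_batches:] @ beta[n_batches:]
    values = pd.DataFrame(out, index=M.values.index, columns=M.values.columns)
    det = None if M.detection_p is None else M.detection_p.copy()
    return MethylationMatrix(values, M.cpg_meta.copy(), det)


# --------------------------------------------------------------------------
# convenience pipeline
# --------------------------------------------------------------------------

def preprocess_methylation(
    M: MethylationMatrix,
    covariates: CovariateTable | None = None,
    max_missing: float = 0.01,
    detection_alpha: float = 0.05,
    adjust_batches: bool = True,
    protect_diagnosis: bool = True,
) -> tuple[MethylationMatrix, QcLog]:
    """Full methylation preprocessing in the fixed pipeline order."""
    M, log = methylation_qc(M, max_missing=max_missing, detection_alpha=detection_alpha)
    M = quantile_normalize(M)
    if M.values.isna().any().any():
        M = mean_impute(M)
    if adjust_batches and covariates is not None and "batch" in covariates.table.columns:
        protected = None
        if protect_diagnosis and "diagnosis" in covariates.table.columns:
            protected = covariates.table[["diagnosis"]].astype(float)
        if covariates.table["batch"].nunique() > 1:
            M = batch_adjust(M, covariates.table["batch"], protected)
    return M, log
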