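"""Covariate-adjusted cis-meQTL association scan.

For every same-chromosome SNP-CpG pair within the cis window (default
20 kbp, boundary inclusive) the methylation value is regressed on the coding
allele dosage plus covariates by ordinary least squares. The reported effect
statistics are the per-allele coefficient beta, its standard error, the
normalized coefficient beta_hat = beta / se (the quantity compared across
tissues), and the two-sided t-test p-value.

``scan_tissue`` uses a residualization fast path: methylation and dosage are
both residualized on the covariate design once, after which each pair's
statistics follow from the residual correlation. This is algebraically
identical to the per-pair multiple regression (Frisch-Waugh-Lovell) and is
checked against it in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CovariateTable,
    GenotypeMatrix,
    MeqtlTable,
    MethylationMatrix,
    empty_meqtl_records,
)

DEFAULT_WINDOW = 20_000
DEFAULT_P_THRESHOLD = 1e-5


def cis_pairs(
    snp_meta: pd.DataFrame, cpg_meta: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """All same-chromosome SNP-CpG pairs with |pos_snp - pos_cpg| <= window.

    Returns a DataFrame with columns snp_id, cpg_id, distance; each pair
    appears exactly once. The window boundary is inclusive.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = []
    for chrom, snps in snp_meta.groupby("chrom", sort=False):
        cpgs = cpg_meta[cpg_meta["chrom"] == chrom]
        if cpgs.empty:
            continue
        spos = snps["pos"].to_numpy()
        order = np.argsort(spos, kind="stable")
        spos_sorted = spos[order]
        snp_ids = snps.index.to_numpy()[order]
        for cpg_id, cpos in zip(cpgs.index, cpgs["pos"].to_numpy()):
            lo = np.searchsorted(spos_sorted, cpos - window, side="left")
            hi = np.searchsorted(spos_sorted, cpos + window, side="right")
            for k in range(lo, hi):
                out.append(
                    {
                        "snp_id": snp_ids[k],
                        "cpg_id": cpg_id,
                        "distance": int(abs(spos_sorted[k] - cpos)),
                    }
                )
    return pd.DataFrame(out, columns=["snp_id", "cpg_id", "distance"])


@dataclass
class AssociationFit:
    """OLS statistics for one SNP-CpG pair."""

    beta: float
    se: float
    beta_hat: float
    p: float
    n: int
    ok: bool = True
    reason: str = ""


def fit_cis_association(
    g: np.ndarray, m: np.ndarray, C: np.ndarray | None = None
) -> AssociationFit:
    """OLS of methylation on [1, dosage, covariates] for one pair.

    Subjects with a missing dosage or methylation value are dropped pairwise.
    Returns beta, its standard error, beta_hat = beta/se, and the two-sided
    t-test p-value on n - k residual degrees of freedom. A constant dosage or
    rank-deficient design yields a flagged, unusable fit instead of an error.
    """
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    mask = np.isfinite(g) & np.isfinite(m)
    if C is not None:
        C = np.asarray(C, dtype=float)
        mask &= np.isfinite(C).all(axis=1)
    g, m = g[mask], m[mask]
    n = g.size
    k = 2 + (0 if C is None else C.shape[1])
    if n < k + 1:
        return AssociationFit(np.nan, np.nan, np.nan, np.nan, n, ok=False, reason="too_few_subjects")
    if np.ptp(g) == 0:
        return AssociationFit(np.nan, np.nan, np.nan, np.nan, n, ok=False, reason="constant_dosage")
    X = np.column_stack([np.ones(n), g] + ([] if C is None else [C[mask]]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return AssociationFit(np.nan, np.nan, np.nan, np.nan, n, ok=False, reason="collinear_design")
    coef, _, _, _ = np.linalg.lstsq(X, m, rcond=None)
    resid = m - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    beta = float(coef[1])
    if se == 0.0:
        # perfect fit: p-value limit is 0 (reported as the smallest float)
        return AssociationFit(beta, 0.0, np.inf if beta > 0 else -np.inf, 0.0, n)
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    p = max(p, np.finfo(float).tiny)
    return AssociationFit(beta, se, float(t), p, n)


def _residualize(Y: np.ndarray, C: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Residualize columns of Y on [1, C]; returns residuals and rank used."""
    n = Y.shape[0]
    X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(X)
    return Y - Q @ (Q.T @ Y), X.shape[1]


def scan_tissue(
    G: GenotypeMatrix,
    M: MethylationMatrix,
    covariates: CovariateTable | None = None,
    window: int = DEFAULT_WINDOW,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    tissue: str = "tissue",
) -> MeqtlTable:
    """Scan all cis pairs of one tissue and keep associations with p <= threshold.

    Complete-data pairs go through the residualized fast path; pairs whose SNP
    or CpG has missing entries fall back to the per-pair fit (pairwise subject
    removal). Both routes produce identical statistics.
    """
    if not G.dosages.index.equals(M.values.index):
        raise ValueError("genotypes and methylation must be subject-aligned")
    C_df = None
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        C_df = covariates.design_matrix()
        C_df = C_df.loc[G.dosages.index]
        cov_names = tuple(C_df.columns)
    pairs = cis_pairs(G.snp_meta, M.cpg_meta, window)
    if pairs.empty:
        warnings.warn("no cis pairs within window", stacklevel=2)
        return MeqtlTable(tissue, empty_meqtl_records(), window, p_threshold, cov_names)

    C = None if C_df is None else C_df.to_numpy(dtype=float)
    Garr = G.dosages.to_numpy(dtype=float)
    Marr = M.values.to_numpy(dtype=float)
    snp_pos = {s: i for i, s in enumerate(G.dosages.columns)}
    cpg_pos = {c: i for i, c in enumerate(M.values.columns)}
    si = pairs["snp_id"].map(snp_pos).to_numpy()
    ci = pairs["cpg_id"].map(cpg_pos).to_numpy()

    n = Garr.shape[0]
    complete = (
        np.isfinite(Garr).all()
        and np.isfinite(Marr).all()
        and (C is None or np.isfinite(C).all())
    )
    rows = []
    if complete:
        Gres, k_cov = _residualize(Garr, C)
        Mres, _ = _residualize(Marr, C)
        df = n - k_cov - 1
        g_ss = (Gres**2).sum(axis=0)
        m_ss = (Mres**2).sum(axis=0)
        nonconst = np.ptp(Garr, axis=0) > 0
        for idx in range(len(pairs)):
            j, c = si[idx], ci[idx]
            if not nonconst[j] or g_ss[j] <= 0:
                continue
            cross = float(Gres[:, j] @ Mres[:, c])
            beta = cross / g_ss[j]
            rss = m_ss[c] - cross**2 / g_ss[j]
            rss = max(rss, 0.0)
            sigma2 = rss / df
            se = float(np.sqrt(sigma2 / g_ss[j]))
            if se == 0.0:
                t_stat, p = np.inf if beta > 0 else -np.inf, 0.0
            else:
                t_stat = beta / se
                p = float(2.0 * stats.t.sf(abs(t_stat), df))
                p = max(p, np.finfo(float).tiny)
            if p <= p_threshold:
                rows.append((idx, beta, se, t_stat, p, n))
    else:
        for idx in range(len(pairs)):
            j, c = si[idx], ci[idx]
            fit = fit_cis_association(Garr[:, j], Marr[:, c], C)
            if fit.ok and fit.p <= p_threshold:
                rows.append((idx, fit.beta, fit.se, fit.beta_hat, fit.p, fit.n))

    if not rows:
        return MeqtlTable(tissue, empty_meqtl_records(), window, p_threshold, cov_names)
    idxs = [r[0] for r in rows]
    sel = pairs.iloc[idxs]
    meta = G.snp_meta.loc[sel["snp_id"]]
    records = pd.DataFrame(
        {
            "snp_id": sel["snp_id"].to_numpy(),
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "coding_allele": meta["coding_allele"].to_numpy(),
            "other_allele": meta["other_allele"].to_numpy(),
            "maf": meta["maf"].to_numpy(),
            "cpg_id": sel["cpg_id"].to_numpy(),
            "cpg_pos": M.cpg_meta.loc[sel["cpg_id"], "pos"].to_numpy(),
            "beta": [r[1] for r in rows],
            "se": [r[2] for r in rows],
            "beta_hat": [r[3] for r in rows],
            "p": [r[4] for r in rows],
            "n": [r[5] for r in rows],
        }
    )
    return MeqtlTable(tissue, records.reset_index(drop=True), window, p_threshold, cov_names)


def analytic_power(
    n: int, maf: float, effect: float, alpha: float = DEFAULT_P_THRESHOLD
) -> float:
    """Power of the two-sided slope t-test for an additive cis effect.

    ``effect`` is the per-allele effect in residual-SD units. Under HWE the
    dosage variance is 2 maf (1 - maf), so the noncentrality parameter is
    effect * sqrt(n * 2 * maf * (1 - maf)); power integrates the noncentral t
    over both rejection tails with n - 2 degrees of freedom.
    """
    if n <= 2:
        raise ValueError("n must exceed 2")
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    df = n - 2
    nc = effect * np.sqrt(n * 2.0 * maf * (1.0 - maf))
    crit = stats.t.isf(alpha / 2.0, df)
    # far-tail noncentral-t probabilities can underflow to NaN; they are
    # negligible there, so treat NaN as 0
    upper = np.nan_to_num(stats.nct.sf(crit, df, nc), nan=0.0)
    lower = np.nan_to_num(stats.nct.cdf(-crit, df, nc), nan=0.0)
    return float(upper + lower)
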