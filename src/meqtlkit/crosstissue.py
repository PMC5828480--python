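"""Cross-tissue harmonization of meQTL tables and concordance statistics.

SNPs and CpGs are matched across tissues by chromosome position. Alleles are
harmonized per SNP: if the second table reports the same coding/other alleles
(directly or after strand complement) the sign multiplier is +1; if coding and
other are swapped the multiplier is -1 and is applied to the second table's
beta_hat before any comparison. Palindromic SNPs (A/T, C/G) are dropped as
strand-ambiguous, with per-reason drop accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MeqtlTable
from .scan import analytic_power

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize_alleles(
    coding_a: str, other_a: str, coding_b: str, other_b: str
) -> tuple[int, str]:
    """Sign multiplier aligning table B's coding allele with table A's.

    Returns (multiplier, reason): (+1, "match") when the coding alleles agree
    directly or after strand complement; (-1, "swap") when coding/other are
    swapped (directly or after complement); (0, reason) when the SNP must be
    dropped (palindromic and hence strand-ambiguous, or irreconcilable).
    """
    alleles = (coding_a, other_a, coding_b, other_b)
    if any(a not in COMPLEMENT for a in alleles):
        return 0, "invalid_allele"
    if _is_palindromic(coding_a, other_a) or _is_palindromic(coding_b, other_b):
        return 0, "palindromic"
    if (coding_b, other_b) == (coding_a, other_a):
        return 1, "match"
    if (coding_b, other_b) == (other_a, coding_a):
        return -1, "swap"
    comp_b = (COMPLEMENT[coding_b], COMPLEMENT[other_b])
    if comp_b == (coding_a, other_a):
        return 1, "match"
    if comp_b == (other_a, coding_a):
        return -1, "swap"
    return 0, "allele_mismatch"


@dataclass
class MatchedPairSet:
    """SNP-CpG pairs present in two tables with harmonized alleles.

    ``pairs`` columns: chrom, pos, cpg_pos, snp_id_a, cpg_id_a, beta_hat_a,
    beta_hat_b (already sign-corrected), sign_multiplier, maf_a, maf_b, n_a,
    n_b. ``dropped`` counts pairs removed per harmonization reason.
    """

    pairs: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def match_tables(tab_a: MeqtlTable, tab_b: MeqtlTable) -> MatchedPairSet:
    """Pairs significant in both tables, keyed by (chrom, SNP pos, CpG pos)."""
    key = ["chrom", "pos", "cpg_pos"]
    a = tab_a.records.add_suffix("_a").rename(
        columns={f"{k}_a": k for k in key}
    )
    b = tab_b.records.add_suffix("_b").rename(
        columns={f"{k}_b": k for k in key}
    )
    merged = a.merge(b, on=key, how="inner")
    if merged.empty:
        warnings.warn("no pairs shared between tables", stacklevel=2)
        empty = merged.assign(
            sign_multiplier=pd.Series(dtype=int),
            harmonize_reason=pd.Series(dtype=str),
            beta_hat_b_raw=pd.Series(dtype=float),
        )
        return MatchedPairSet(empty, {})
    mults, reasons = [], []
    for row in merged.itertuples(index=False):
        mult, reason = harmonize_alleles(
            row.coding_allele_a, row.other_allele_a, row.coding_allele_b, row.other_allele_b
        )
        mults.append(mult)
        reasons.append(reason)
    merged["sign_multiplier"] = mults
    merged["harmonize_reason"] = reasons
    dropped_mask = merged["sign_multiplier"] == 0
    dropped = merged.loc[dropped_mask, "harmonize_reason"].value_counts().to_dict()
    kept = merged[~dropped_mask].copy()
    kept["beta_hat_b_raw"] = kept["beta_hat_b"]
    kept["beta_hat_b"] = kept["beta_hat_b"] * kept["sign_multiplier"]
    kept["beta_b"] = kept["beta_b"] * kept["sign_multiplier"]
    return MatchedPairSet(kept.reset_index(drop=True), {str(k): int(v) for k, v in dropped.items()})


def concordance_stats(matched: MatchedPairSet) -> tuple[float, float]:
    """Same-sign fraction and Spearman rho of harmonized beta_hat values.

    A beta_hat of exactly zero counts as positive sign. Spearman uses average
    ranks for ties and needs at least two pairs; with fewer, rho is NaN.
    """
    if len(matched) == 0:
        return float("nan"), float("nan")
    a = matched.pairs["beta_hat_a"].to_numpy(dtype=float)
    b = matched.pairs["beta_hat_b"].to_numpy(dtype=float)
    sign_a = np.where(a >= 0, 1, -1)
    sign_b = np.where(b >= 0, 1, -1)
    same = float((sign_a == sign_b).mean())
    if len(matched) < 2:
        return same, float("nan")
    rho = float(stats.spearmanr(a, b).statistic)
    return same, rho


@dataclass
class OverlapSummary:
    """Per-tissue and shared meQTL/CpG/pair fractions plus concordance."""

    tissues: tuple[str, ...]
    n_common_snps: int
    n_common_cpgs: int
    per_tissue: pd.DataFrame  # index tissue: n_pairs, n_meqtls, n_cpgs, frac_snps_meqtl, frac_cpgs_targeted
    shared_pairs: int
    shared_fraction: pd.Series  # per tissue: shared pairs / tissue pairs
    shared_meqtl_fraction: pd.Series
    shared_cpg_fraction: pd.Series
    same_sign_fraction: float
    spearman_rho: float
    dropped: dict[str, int]
    restricted: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = self.per_tissue.copy()
        df["shared_pair_fraction"] = self.shared_fraction
        df["shared_meqtl_fraction"] = self.shared_meqtl_fraction
        df["shared_cpg_fraction"] = self.shared_cpg_fraction
        df["shared_pairs"] = self.shared_pairs
        df["same_sign_fraction"] = self.same_sign_fraction
        df["spearman_rho"] = self.spearman_rho
        return df

    def report(self) -> str:
        lines = [
            f"tissues: {', '.join(self.tissues)}"
            + ("  [restricted mode]" if self.restricted else ""),
            f"common universe: {self.n_common_snps} SNPs, {self.n_common_cpgs} CpGs",
        ]
        for t in self.tissues:
            row = self.per_tissue.loc[t]
            lines.append(
                f"  {t}: {int(row['n_pairs'])} pairs "
                f"({100 * row['frac_snps_meqtl']:.2f}% of SNPs are meQTLs, "
                f"{100 * row['frac_cpgs_targeted']:.2f}% of CpGs targeted); "
                f"shared fraction {100 * self.shared_fraction[t]:.2f}%"
            )
        lines.append(
            f"shared pairs: {self.shared_pairs}; same-sign "
            f"{100 * self.same_sign_fraction:.1f}%, Spearman rho {self.spearman_rho:.3f}"
        )
        if self.dropped:
            drops = ", ".join(f"{k}={v}" for k, v in sorted(self.dropped.items()))
            lines.append(f"dropped during harmonization: {drops}")
        return "\n".join(lines)


def _restrict_pairs(
    matched: MatchedPairSet,
    max_maf_diff: float,
    min_power: float,
    n_ref: int,
    alpha: float,
) -> MatchedPairSet:
    """Keep pairs with concordant MAF and detection power >= min_power at n_ref.

    The per-allele effect in residual-SD units implied by a record is
    beta_hat / sqrt(n * 2 maf (1 - maf)); power is evaluated at the reference
    sample size for both tissues and both must clear the threshold.
    """
    df = matched.pairs
    if df.empty:
        return matched
    keep = np.ones(len(df), dtype=bool)
    maf_a = df["maf_a"].to_numpy(float)
    maf_b = df["maf_b"].to_numpy(float)
    keep &= np.abs(maf_a - maf_b) < max_maf_diff
    for suffix, maf in (("a", maf_a), ("b", maf_b)):
        bh = df[f"beta_hat_{suffix}"].to_numpy(float)
        n_col = df[f"n_{suffix}"].to_numpy(float)
        implied = np.abs(bh) / np.sqrt(n_col * 2.0 * maf * (1.0 - maf))
        power = np.array(
            [
                analytic_power(n_ref, mf, eff, alpha) if 0 < mf <= 0.5 else 0.0
                for mf, eff in zip(maf, implied)
            ]
        )
        keep &= power >= min_power
    return MatchedPairSet(df[keep].reset_index(drop=True), dict(matched.dropped))


def overlap_summary(
    tables: dict[str, MeqtlTable],
    common_snps: pd.DataFrame,
    common_cpgs: pd.DataFrame,
    restricted: tuple[float, float, int] | None = None,
    alpha: float = 1e-5,
) -> OverlapSummary:
    """Overlap bookkeeping for two or three tissues on a common universe.

    ``common_snps`` / ``common_cpgs`` carry (chrom, pos) of the markers present
    in every tissue; tables are restricted to that universe before any
    fraction is computed. Fractions shared use each tissue's own significant
    set (within the universe) as denominator. With three tables the shared
    quantities refer to the three-way intersection; concordance statistics are
    reported for the first pair. ``restricted`` = (max_maf_diff, min_power,
    n_ref) additionally filters matched pairs by MAF concordance and implied
    detection power before the shared statistics.
    """
    names = tuple(tables)
    if len(names) < 2:
        raise ValueError("need at least two tables")
    snp_keys = set(zip(common_snps["chrom"].astype(str), common_snps["pos"].astype(int)))
    cpg_keys = set(zip(common_cpgs["chrom"].astype(str), common_cpgs["pos"].astype(int)))

    def in_universe(tab: MeqtlTable) -> MeqtlTable:
        rec = tab.records
        if rec.empty:
            return tab
        mask = [
            (str(c), int(p)) in snp_keys and (str(c), int(cp)) in cpg_keys
            for c, p, cp in zip(rec["chrom"], rec["pos"], rec["cpg_pos"])
        ]
        return MeqtlTable(tab.tissue, rec[mask].reset_index(drop=True), tab.window, tab.p_threshold, tab.covariates)

    restricted_tabs = {t: in_universe(tab) for t, tab in tables.items()}
    per_rows = {}
    pair_keys: dict[str, set] = {}
    meqtl_keys: dict[str, set] = {}
    cpg_keys_sig: dict[str, set] = {}
    for t, tab in restricted_tabs.items():
        rec = tab.records
        pk = set(zip(rec["chrom"].astype(str), rec["pos"].astype(int), rec["cpg_pos"].astype(int)))
        mk = set(zip(rec["chrom"].astype(str), rec["pos"].astype(int)))
        ck = set(zip(rec["chrom"].astype(str), rec["cpg_pos"].astype(int)))
        pair_keys[t], meqtl_keys[t], cpg_keys_sig[t] = pk, mk, ck
        per_rows[t] = {
            "n_pairs": len(pk),
            "n_meqtls": len(mk),
            "n_cpgs": len(ck),
            "frac_snps_meqtl": len(mk) / len(snp_keys) if snp_keys else np.nan,
            "frac_cpgs_targeted": len(ck) / len(cpg_keys) if cpg_keys else np.nan,
        }
    per_tissue = pd.DataFrame.from_dict(per_rows, orient="index").loc[list(names)]

    matched = match_tables(restricted_tabs[names[0]], restricted_tabs[names[1]])
    if restricted is not None:
        matched = _restrict_pairs(matched, restricted[0], restricted[1], restricted[2], alpha)

    shared_pair_keys = set.intersection(*pair_keys.values()) if pair_keys else set()
    shared_meqtl_keys = set.intersection(*meqtl_keys.values())
    shared_cpg_keys = set.intersection(*cpg_keys_sig.values())
    if restricted is not None and len(names) == 2:
        kept_keys = set(
            zip(
                matched.pairs["chrom"].astype(str),
                matched.pairs["pos"].astype(int),
                matched.pairs["cpg_pos"].astype(int),
            )
        )
        shared_pair_keys &= kept_keys
        shared_meqtl_keys &= {(c, p) for c, p, _ in kept_keys}
        shared_cpg_keys &= {(c, cp) for c, _, cp in kept_keys}

    def frac(shared: set, per: dict[str, set]) -> pd.Series:
        return pd.Series(
            {t: (len(shared) / len(per[t]) if per[t] else np.nan) for t in names}
        )

    same_sign, rho = concordance_stats(matched)
    return OverlapSummary(
        tissues=names,
        n_common_snps=len(snp_keys),
        n_common_cpgs=len(cpg_keys),
        per_tissue=per_tissue,
        shared_pairs=len(shared_pair_keys),
        shared_fraction=frac(shared_pair_keys, pair_keys),
        shared_meqtl_fraction=frac(shared_meqtl_keys, meqtl_keys),
        shared_cpg_fraction=frac(shared_cpg_keys, cpg_keys_sig),
        same_sign_fraction=same_sign,
        spearman_rho=rho,
        dropped=matched.dropped,
        restricted=restricted is not None,
    )
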