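"""Annotation enrichment: supervised LD pruning, MAF-matched permutation
null, and Fisher exact 2x2 tests.

The permutation test asks whether a query SNP set (e.g. cross-tissue meQTLs)
overlaps an annotation set (e.g. GWAS risk loci) more than random SNP sets of
the same size and MAF composition drawn from the pruned universe. Queries are
binned by MAF in 0.05-wide bins; each null set matches the query's per-bin
counts and is drawn without replacement within bins. The empirical p-value is
the fraction of null sets with a strictly higher overlap proportion than
observed, so p_perm = 0 means "< 1/n_sets".

Within one MAF bin, the overlap of a without-replacement draw with the
annotation is exactly hypergeometric, so by default the per-bin overlap
counts are drawn directly from that distribution — the same null law at a
fraction of the cost. Explicit null sets are available for auditing via
``return_null_sets``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

MAF_BIN_WIDTH = 0.05


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[mask], g2[mask]
    if g1.size < 2 or np.ptp(g1) == 0 or np.ptp(g2) == 0:
        warnings.warn("constant dosage vector: r2 undefined, treated as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def supervised_ld_prune(
    G: GenotypeMatrix,
    priority: set[str] | None = None,
    r2_max: float = 0.7,
    window: int = 1_000_000,
) -> set[str]:
    """Greedy LD pruning that keeps annotation (priority) SNPs first.

    Priority SNPs are processed in position order, then the remaining SNPs in
    position order; a SNP is kept iff its r^2 with every already-kept SNP
    within ``window`` bp (same chromosome) is <= ``r2_max``. Priority SNPs can
    therefore never be displaced by a non-priority SNP.
    """
    if not (0.0 < r2_max < 1.0):
        raise ValueError("r2_max must be in (0, 1)")
    priority = priority or set()
    meta = G.snp_meta
    order = meta.sort_values(["chrom", "pos"], kind="stable").index
    queue = [s for s in order if s in priority] + [s for s in order if s not in priority]
    dosages = G.dosages
    kept: list[str] = []
    kept_meta: list[tuple[str, int]] = []
    for snp in queue:
        chrom = str(meta.at[snp, "chrom"])
        pos = int(meta.at[snp, "pos"])
        ok = True
        for other, (ochrom, opos) in zip(kept, kept_meta):
            if ochrom != chrom or abs(opos - pos) > window:
                continue
            if genotype_r2(dosages[snp].to_numpy(), dosages[other].to_numpy()) > r2_max:
                ok = False
                break
        if ok:
            kept.append(snp)
            kept_meta.append((chrom, pos))
    return set(kept)


def maf_bins(maf: np.ndarray, bin_width: float = MAF_BIN_WIDTH) -> np.ndarray:
    """Bin index per SNP: [0,0.05), [0.05,0.10), ..., last bin right-closed."""
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    idx = np.digitize(maf, edges[1:-1], right=False)
    return idx


def maf_matched_permutation(
    query: set[str],
    annotation: set[str],
    universe_maf: pd.Series,
    bin_width: float = MAF_BIN_WIDTH,
    n_sets: int = 100_000,
    seed: int = 0,
    return_null_sets: bool = False,
) -> "PermutationResult":
    """MAF-matched permutation enrichment of ``query`` in ``annotation``.

    ``universe_maf`` maps every SNP of the (pruned) universe to its MAF;
    ``query`` must be a subset of the universe. Returns the observed overlap
    proportion, the null proportions, and p_perm = (# null > observed)/n_sets.
    """
    if n_sets < 100:
        raise ValueError("n_sets must be at least 100")
    universe = universe_maf.index
    query = set(query)
    if not query:
        raise ValueError("query set is empty")
    if not query <= set(universe):
        missing = sorted(query - set(universe))[:5]
        raise ValueError(f"query SNPs missing from universe, e.g. {missing}")
    annotation = set(annotation) & set(universe)

    maf = universe_maf.to_numpy(dtype=float)
    bins = maf_bins(maf, bin_width)
    in_query = universe.isin(query)
    in_ann = universe.isin(annotation)
    observed_overlap = int((in_query & in_ann).sum())
    observed = observed_overlap / len(query)

    rng = np.random.default_rng(seed)
    n_bins = bins.max() + 1
    null_overlap = np.zeros(n_sets, dtype=np.int64)
    null_sets: list[np.ndarray] | None = [] if return_null_sets else None
    if return_null_sets:
        sampled = [np.empty(0, dtype=object)] * n_sets

    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        k = int((in_query & (bins == b)).sum())
        if k == 0:
            continue
        if k > members.size:
            raise ValueError(
                f"MAF bin {b} ([{b * bin_width:.2f},{(b + 1) * bin_width:.2f})) "
                f"has {members.size} universe SNPs but query needs {k}"
            )
        n_ann_bin = int((in_ann & (bins == b)).sum())
        if return_null_sets:
            ann_members = set(np.flatnonzero(in_ann & (bins == b)))
            for s in range(n_sets):
                draw = rng.choice(members, size=k, replace=False)
                null_overlap[s] += np.intp(sum(1 for d in draw if d in ann_members))
                sampled[s] = np.concatenate([sampled[s], universe.to_numpy()[draw]])
        else:
            # overlap of a without-replacement draw with the annotated members
            # of the bin is exactly Hypergeometric(members, annotated, k)
            null_overlap += rng.hypergeometric(n_ann_bin, members.size - n_ann_bin, k, size=n_sets)

    null_prop = null_overlap / len(query)
    p_perm = float((null_prop > observed).mean())
    if return_null_sets:
        null_sets = sampled
    return PermutationResult(
        observed_proportion=float(observed),
        observed_overlap=observed_overlap,
        query_size=len(query),
        null_proportions=null_prop,
        p_perm=p_perm,
        n_sets=n_sets,
        null_sets=null_sets,
    )


@dataclass
class PermutationResult:
    observed_proportion: float
    observed_overlap: int
    query_size: int
    null_proportions: np.ndarray
    p_perm: float
    n_sets: int
    null_sets: list[np.ndarray] | None = None

    def p_perm_label(self) -> str:
        return f"< {1.0 / self.n_sets:g}" if self.p_perm == 0.0 else f"{self.p_perm:g}"


def fisher_2x2(table: np.ndarray | list) -> tuple[float, tuple[float, float], float]:
    """Two-sided Fisher exact test with sample OR and 95% Wald CI.

    The sample odds ratio is ad/bc with a Haldane 0.5 correction applied to
    every cell when any cell is zero; the CI is Wald on the log odds ratio;
    the p-value sums hypergeometric probabilities no larger than the observed
    table's. A zero margin is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds_ratio = (a2 * d2) / (b2 * c2)
    se_log = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    z = stats.norm.isf(0.025)
    lo = float(np.exp(np.log(odds_ratio) - z * se_log))
    hi = float(np.exp(np.log(odds_ratio) + z * se_log))
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds_ratio), (lo, hi), float(p)


@dataclass
class EnrichmentResult:
    """One annotation-enrichment comparison (permutation + Fisher)."""

    name: str
    observed_proportion: float
    p_perm: float | None
    n_sets: int | None
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    ci95: tuple[float, float]
    p_fisher: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "observed_proportion": self.observed_proportion,
            "p_perm": self.p_perm,
            "n_sets": self.n_sets,
            "a": self.table[0],
            "b": self.table[1],
            "c": self.table[2],
            "d": self.table[3],
            "odds_ratio": self.odds_ratio,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_fisher": self.p_fisher,
        }


def snp_set_enrichment(
    query: set[str],
    annotation: set[str],
    universe_maf: pd.Series,
    name: str = "annotation",
    bin_width: float = MAF_BIN_WIDTH,
    n_sets: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Combined permutation + Fisher enrichment of a query SNP set.

    The Fisher 2x2 contrasts annotation membership between the query and the
    rest of the universe: a = query & annotation, b = query only,
    c = annotation only, d = neither.
    """
    perm = maf_matched_permutation(
        query, annotation, universe_maf, bin_width=bin_width, n_sets=n_sets, seed=seed
    )
    uni = set(universe_maf.index)
    ann = set(annotation) & uni
    q = set(query)
    a = len(q & ann)
    b = len(q) - a
    c = len(ann - q)
    d = len(uni) - a - b - c
    odds, ci, p_f = fisher_2x2([[a, b], [c, d]])
    return EnrichmentResult(
        name=name,
        observed_proportion=perm.observed_proportion,
        p_perm=perm.p_perm,
        n_sets=n_sets,
        table=(a, b, c, d),
        odds_ratio=odds,
        ci95=ci,
        p_fisher=p_f,
    )


def cpg_context_enrichment(
    set_a: set[str], set_b: set[str], cpg_meta: pd.DataFrame
) -> pd.DataFrame:
    """Fisher enrichment of CpG set A vs set B per genomic context.

    For every region flag and island-context category the 2x2 table is
    (in context vs not) x (in set A vs set B). Contexts with an empty margin
    are skipped with a note column. Returns one row per context.
    """
    ids_a = [c for c in set_a if c in cpg_meta.index]
    ids_b = [c for c in set_b if c in cpg_meta.index]
    if not ids_a or not ids_b:
        raise ValueError("both CpG sets must intersect the metadata")
    contexts: list[tuple[str, pd.Series]] = []
    for col in cpg_meta.columns:
        if col.startswith("region_"):
            contexts.append((col.removeprefix("region_"), cpg_meta[col].astype(bool)))
    if "island_context" in cpg_meta.columns:
        for cat in pd.unique(cpg_meta["island_context"]):
            contexts.append((str(cat), cpg_meta["island_context"] == cat))
    rows = []
    for name, mask in contexts:
        a = int(mask.loc[ids_a].sum())
        b = len(ids_a) - a
        c = int(mask.loc[ids_b].sum())
        d = len(ids_b) - c
        if (a + c == 0) or (b + d == 0):
            rows.append(
                {"context": name, "a": a, "b": b, "c": c, "d": d, "odds_ratio": np.nan,
                 "ci95_low": np.nan, "ci95_high": np.nan, "p_fisher": np.nan,
                 "note": "empty context margin"}
            )
            continue
        odds, ci, p = fisher_2x2([[a, b], [c, d]])
        rows.append(
            {"context": name, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds,
             "ci95_low": ci[0], "ci95_high": ci[1], "p_fisher": p, "note": ""}
        )
    return pd.DataFrame(rows)
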