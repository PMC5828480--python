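"""Consensus weighted co-methylation network analysis.

Per tissue, an unsigned adjacency a_ij = |cor(m_i, m_j)|^power (soft power 6)
is turned into a topological overlap matrix (TOM); the consensus TOM is the
element-wise minimum across tissues, so only co-methylation present in every
tissue survives. Modules are average-linkage clusters of 1 - TOM under a
static height cut. Each module is summarized per tissue by its eigengene
(first principal component of the standardized module CpGs), tested for
disease association with covariate adjustment, and the per-tissue p-values
are combined across tissues (Fisher's method by default; Stouffer's weighted
Z available — the two can differ noticeably, see docs). Module membership
(MM) and methylation significance (MS) are cross-tissue combined Z-scores per
CpG, and their correlation measures whether the disease signal aligns with
the module's core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import CovariateTable, MethylationMatrix
from .scan import fit_cis_association

DEFAULT_POWER = 6
DEFAULT_MIN_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.995


@dataclass
class TomMatrix:
    """Square symmetric topological-overlap matrix with unit diagonal."""

    values: pd.DataFrame
    provenance: str = "tissue"

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def correlation_adjacency(M: MethylationMatrix | pd.DataFrame, power: int = DEFAULT_POWER) -> pd.DataFrame:
    """Unsigned adjacency |cor|^power with zero diagonal."""
    values = M.values if isinstance(M, MethylationMatrix) else M
    arr = values.to_numpy(dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 subjects for correlations")
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = values.columns[sd == 0].tolist()
        raise ValueError(f"constant CpGs have undefined correlation: {bad[:5]}")
    corr = np.corrcoef(arr, rowvar=False)
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=values.columns, columns=values.columns)


def tom_similarity(A: pd.DataFrame | np.ndarray, provenance: str = "tissue") -> TomMatrix:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    k is the row-sum connectivity; the diagonal is 1 by convention. Inputs
    must be symmetric with entries in [0, 1] and a zero diagonal.
    """
    if isinstance(A, pd.DataFrame):
        idx = A.index
        arr = A.to_numpy(dtype=float)
    else:
        arr = np.asarray(A, dtype=float)
        idx = pd.RangeIndex(arr.shape[0])
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(arr, arr.T):
        raise ValueError("adjacency must be symmetric")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = arr.sum(axis=1)
    shared = arr @ arr  # sum_u a_iu a_uj
    denom = np.minimum.outer(k, k) + 1.0 - arr
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + arr) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return TomMatrix(pd.DataFrame(tom, index=idx, columns=idx), provenance)


def consensus_tom(toms: list[TomMatrix], scale: bool = False) -> TomMatrix:
    """Element-wise minimum TOM across tissues.

    With ``scale`` enabled the inputs are first quantile-aligned at the 95th
    percentile of their off-diagonal entries (all matrices rescaled to the
    first one's reference), which compensates for tissue-specific overall
    connectivity; default off.
    """
    if len(toms) < 2:
        raise ValueError("need at least two TOM matrices")
    ref_ids = toms[0].cpg_ids
    for t in toms[1:]:
        if not t.cpg_ids.equals(ref_ids):
            raise ValueError("TOM matrices must share an identical CpG ordering")
    arrays = [t.to_numpy().copy() for t in toms]
    if scale:
        off = ~np.eye(len(ref_ids), dtype=bool)
        ref_q = np.quantile(arrays[0][off], 0.95)
        for arr in arrays[1:]:
            q = np.quantile(arr[off], 0.95)
            if q > 0:
                arr[off] = arr[off] * (ref_q / q)
                np.clip(arr, 0.0, 1.0, out=arr)
    cons = np.minimum.reduce(arrays)
    np.fill_diagonal(cons, 1.0)
    return TomMatrix(pd.DataFrame(cons, index=ref_ids, columns=ref_ids), "consensus")


def detect_modules(
    tom: TomMatrix,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The tree is cut at ``cut_height`` times the maximum merge height; clusters
    smaller than ``min_size`` get the unassigned label 0, the rest are
    relabeled 1, 2, ... by decreasing size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not (0.0 < cut_height <= 1.0):
        raise ValueError("cut_height must be in (0, 1]")
    ids = tom.cpg_ids
    n = len(ids)
    if n < 2 or min_size > n:
        return pd.Series(0, index=ids, name="module")
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    threshold = cut_height * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=threshold, criterion="distance")
    labels = pd.Series(raw, index=ids, name="module")
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size].index
    mapping = {old: new for new, old in enumerate(keep, start=1)}
    return labels.map(lambda x: mapping.get(x, 0)).rename("module")


def module_eigengene(M_module: pd.DataFrame) -> pd.Series:
    """First principal component scores of the standardized module CpGs.

    Scores have unit variance and are oriented so the mean correlation with
    the module CpGs is positive.
    """
    arr = M_module.to_numpy(dtype=float)
    n, p = arr.shape
    if p < 2 or n < 3:
        raise ValueError("need >= 2 CpGs and >= 3 subjects")
    sd = arr.std(axis=0, ddof=0)
    if (sd == 0).all():
        raise ValueError("module matrix has rank 0 after standardization")
    std = (arr - arr.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    u, s, _ = np.linalg.svd(std, full_matrices=False)
    scores = u[:, 0]
    scores = scores / scores.std(ddof=0)
    corr_mean = np.mean([np.corrcoef(scores, std[:, j])[0, 1] for j in range(p)])
    if corr_mean < 0:
        scores = -scores
    return pd.Series(scores, index=M_module.index, name="ME")


def fisher_combine(pvals: list[float] | np.ndarray) -> float:
    """Fisher's combined p: -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return float("nan")
    stat = -2.0 * np.log(np.clip(p, np.finfo(float).tiny, 1.0)).sum()
    return float(stats.chi2.sf(stat, df=2 * p.size))


def stouffer_combine(pvals: np.ndarray, signs: np.ndarray | None = None) -> tuple[float, float]:
    """Stouffer's combined Z (optionally signed) and its two-sided p."""
    p = np.asarray(pvals, dtype=float)
    keep = np.isfinite(p)
    p = np.clip(p[keep], np.finfo(float).tiny, 1.0 - 1e-16)
    if p.size == 0:
        return float("nan"), float("nan")
    z = stats.norm.isf(p / 2.0)
    if signs is not None:
        z = z * np.sign(np.asarray(signs, dtype=float)[keep])
    zc = z.sum() / np.sqrt(p.size)
    return float(zc), float(2.0 * stats.norm.sf(abs(zc)))


@dataclass
class ConsensusModule:
    """One consensus module with per-tissue and combined disease statistics."""

    label: int
    cpg_ids: tuple[str, ...]
    eigengenes: dict[str, pd.Series]
    tissue_stats: pd.DataFrame  # index tissue: t, p
    combined_p: float
    combined_method: str
    mm: pd.Series  # per-CpG combined module-membership Z
    ms: pd.Series  # per-CpG combined disease-association Z
    mm_ms_r: float

    @property
    def size(self) -> int:
        return len(self.cpg_ids)

    def summary_row(self) -> dict:
        row: dict = {"module": self.label, "size": self.size, "combined_p": self.combined_p,
                     "combined_method": self.combined_method, "mm_ms_r": self.mm_ms_r}
        for tissue, st in self.tissue_stats.iterrows():
            row[f"t_{tissue}"] = st["t"]
            row[f"p_{tissue}"] = st["p"]
        return row


def _diagnosis_association(
    y: np.ndarray, diagnosis: np.ndarray, C: np.ndarray | None
) -> tuple[float, float]:
    """t statistic and p for the diagnosis coefficient, covariate-adjusted."""
    fit = fit_cis_association(diagnosis, y, C)
    if not fit.ok:
        return float("nan"), float("nan")
    return fit.beta_hat, fit.p


def module_disease_stats(
    modules: pd.Series,
    tissue_data: dict[str, tuple[MethylationMatrix, CovariateTable]],
    combine: str = "fisher",
) -> list[ConsensusModule]:
    """Disease-association statistics for every detected consensus module.

    Per tissue: the module eigengene is regressed on diagnosis plus the
    numeric covariates; the diagnosis t-statistic and p-value are recorded
    and combined across tissues ("fisher": chi-square on -2 sum ln p;
    "stouffer": signed weighted Z). MM per CpG combines the Fisher r-to-z
    transformed CpG-eigengene correlations across tissues; MS per CpG
    combines the signed diagnosis-association Z-scores.
    """
    if combine not in ("fisher", "stouffer"):
        raise ValueError("combine must be 'fisher' or 'stouffer'")
    out: list[ConsensusModule] = []
    tissues = list(tissue_data)
    for label in sorted(l for l in modules.unique() if l != 0):
        cpgs = tuple(modules.index[modules == label])
        eigengenes: dict[str, pd.Series] = {}
        t_rows = {}
        mm_z = np.zeros(len(cpgs))
        ms_z = np.zeros(len(cpgs))
        n_mm = 0
        for tissue in tissues:
            M, cov = tissue_data[tissue]
            avail = [c for c in cpgs if c in M.values.columns]
            sub = M.values[avail]
            me = module_eigengene(sub)
            eigengenes[tissue] = me
            design = cov.design_matrix(include_diagnosis=False)
            design = design.loc[sub.index]
            diagnosis = cov.table.loc[sub.index, "diagnosis"].to_numpy(dtype=float)
            C = design.to_numpy(dtype=float) if design.shape[1] else None
            t_stat, p = _diagnosis_association(me.to_numpy(), diagnosis, C)
            t_rows[tissue] = {"t": t_stat, "p": p}
            if np.isfinite(t_stat):
                n = len(me)
                # MM: Fisher r-to-z of CpG-eigengene correlation, in Z units
                r = np.array([np.corrcoef(me, sub[c])[0, 1] for c in avail])
                r = np.clip(r, -0.999999, 0.999999)
                mm_z += np.arctanh(r) * np.sqrt(max(n - 3, 1))
                # MS: signed diagnosis-association Z per CpG
                for j, c in enumerate(avail):
                    t_c, p_c = _diagnosis_association(sub[c].to_numpy(), diagnosis, C)
                    if np.isfinite(t_c):
                        z = stats.norm.isf(np.clip(p_c / 2.0, np.finfo(float).tiny, 1.0))
                        ms_z[j] += np.sign(t_c) * z
                n_mm += 1
        if n_mm == 0:
            continue
        mm = pd.Series(mm_z / np.sqrt(n_mm), index=list(cpgs), name="MM")
        ms = pd.Series(ms_z / np.sqrt(n_mm), index=list(cpgs), name="MS")
        stats_df = pd.DataFrame.from_dict(t_rows, orient="index")
        pvals = stats_df["p"].to_numpy(dtype=float)
        if combine == "fisher":
            combined = fisher_combine(pvals[np.isfinite(pvals)])
        else:
            signs = np.sign(stats_df["t"].to_numpy(dtype=float))
            _, combined = stouffer_combine(pvals, signs)
        if mm.std(ddof=0) > 0 and ms.std(ddof=0) > 0:
            mm_ms_r = float(np.corrcoef(mm, ms)[0, 1])
        else:
            mm_ms_r = float("nan")
        out.append(
            ConsensusModule(
                label=int(label),
                cpg_ids=cpgs,
                eigengenes=eigengenes,
                tissue_stats=stats_df,
                combined_p=combined,
                combined_method=combine,
                mm=mm,
                ms=ms,
                mm_ms_r=mm_ms_r,
            )
        )
    return out


def consensus_network(
    tissue_data: dict[str, tuple[MethylationMatrix, CovariateTable]],
    power: int = DEFAULT_POWER,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    scale: bool = False,
    combine: str = "fisher",
) -> tuple[pd.Series, list[ConsensusModule], TomMatrix]:
    """End-to-end consensus network: adjacency -> TOM -> min -> modules -> stats.

    All tissues must carry the same CpG columns (the cross-tissue targeted
    CpG set); subjects may differ freely.
    """
    tissues = list(tissue_data)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues for a consensus network")
    ref_cols = tissue_data[tissues[0]][0].values.columns
    toms = []
    for t in tissues:
        M = tissue_data[t][0]
        if not M.values.columns.equals(ref_cols):
            raise ValueError("tissues must share an identical CpG set and order")
        adj = correlation_adjacency(M, power=power)
        toms.append(tom_similarity(adj, provenance=t))
    cons = consensus_tom(toms, scale=scale)
    modules = detect_modules(cons, min_size=min_size, cut_height=cut_height)
    stats_list = module_disease_stats(modules, tissue_data, combine=combine)
    return modules, stats_list, cons
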