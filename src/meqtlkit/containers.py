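"""Shared in-memory containers for genotype, methylation, and covariate data.

All containers are thin wrappers around pandas objects: subjects are rows,
markers (SNPs or CpGs) are columns, and marker metadata travels in a parallel
DataFrame indexed by marker id. Plain-text TSV is the interchange format so
every pipeline stage can be run and inspected in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

#: Gene-region annotation flags carried as boolean columns ``region_<name>``.
REGION_FLAGS = (
    "gene_body",
    "TSS200",
    "TSS1500",
    "UTR5",
    "UTR3",
    "first_exon",
    "enhancer",
)

#: Mutually exclusive CpG-island context categories.
ISLAND_CONTEXTS = ("island", "N_shore", "S_shore", "N_shelf", "S_shelf", "open_sea")

#: Probe-level exclusion flags carried as boolean columns ``blacklist_<name>``.
BLACKLIST_FLAGS = ("snp_coincident", "cross_reactive", "sex_chromosome")


@dataclass
class GenotypeMatrix:
    """Additive dosages (subjects x SNPs) plus per-SNP metadata.

    ``dosages`` holds counts of the coding allele in {0, 1, 2} (NaN = missing).
    ``snp_meta`` is indexed by SNP id with columns ``chrom``, ``pos`` (1-based),
    ``coding_allele``, ``other_allele``, ``maf``.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snp_meta.index):
            self.snp_meta = self.snp_meta.loc[self.dosages.columns]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = pd.Index(snp_ids)
        return GenotypeMatrix(self.dosages[ids], self.snp_meta.loc[ids])

    def empirical_maf(self) -> pd.Series:
        """Minor-allele frequency recomputed from the dosage matrix."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq).rename("maf")

    # --- I/O -------------------------------------------------------------
    def to_tsv(self, dosage_path: str | Path, meta_path: str | Path) -> None:
        self.dosages.rename_axis("subject").to_csv(dosage_path, sep="\t")
        self.snp_meta.rename_axis("snp_id").to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, dosage_path: str | Path, meta_path: str | Path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"chrom": str})
        return cls(dos, meta)

    def to_vcf(self, path: str | Path) -> None:
        """Write hard-call genotypes as a minimal single-sample-per-column VCF.

        Dosage d codes the GT as 0/0, 0/1, 1/1 with REF = other allele and
        ALT = coding allele, so the ALT count equals the stored dosage.
        """
        meta = self.snp_meta
        subjects = list(self.dosages.index.astype(str))
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            chroms = pd.unique(meta["chrom"].astype(str))
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(subjects) + "\n")
            dosage_arr = self.dosages.to_numpy()
            for j, snp in enumerate(meta.index):
                row = meta.iloc[j]
                calls = [
                    gt_codes[int(d)] if np.isfinite(d) else "./."
                    for d in dosage_arr[:, j]
                ]
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t"
                    f"{row['other_allele']}\t{row['coding_allele']}\t.\t.\t.\tGT\t"
                    + "\t".join(calls)
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read genotypes from a VCF; dosage = ALT allele count per subject."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        subjects = list(vcf.samples)
        ids, rows, meta_rows = [], [], []
        for var in vcf:
            # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
            gts = np.asarray(var.gt_types, dtype=float)
            gts[gts == 3] = np.nan
            snp_id = var.ID or f"{var.CHROM}:{var.POS}"
            ids.append(snp_id)
            rows.append(gts)
            meta_rows.append(
                {
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "coding_allele": var.ALT[0] if var.ALT else "N",
                    "other_allele": var.REF,
                }
            )
        dos = pd.DataFrame(np.asarray(rows).T, index=subjects, columns=ids)
        meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="snp_id"))
        freq = dos.mean(axis=0) / 2.0
        meta["maf"] = np.minimum(freq, 1.0 - freq)
        return cls(dos, meta)


@dataclass
class MethylationMatrix:
    """Methylation values (subjects x CpGs) plus per-CpG metadata.

    Values are beta fractions in [0, 1] until :func:`~meqtlkit.preprocess.rank_normalize`
    replaces them with normal scores. ``cpg_meta`` is indexed by CpG id with
    ``chrom``, ``pos``, boolean ``region_*`` and ``blacklist_*`` columns, and a
    categorical ``island_context``. ``detection_p`` is an optional same-shape
    channel of per-entry detection p-values.
    """

    values: pd.DataFrame
    cpg_meta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.cpg_meta.index):
            self.cpg_meta = self.cpg_meta.loc[self.values.columns]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    def subset_cpgs(self, cpg_ids: Iterable[str]) -> "MethylationMatrix":
        ids = pd.Index(cpg_ids)
        det = self.detection_p[ids] if self.detection_p is not None else None
        return MethylationMatrix(self.values[ids], self.cpg_meta.loc[ids], det)

    def copy(self) -> "MethylationMatrix":
        det = None if self.detection_p is None else self.detection_p.copy()
        return MethylationMatrix(self.values.copy(), self.cpg_meta.copy(), det)

    def to_tsv(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.rename_axis("subject").to_csv(values_path, sep="\t")
        self.cpg_meta.rename_axis("cpg_id").to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, values_path: str | Path, meta_path: str | Path
    ) -> "MethylationMatrix":
        vals = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"chrom": str})
        for col in meta.columns:
            if col.startswith(("region_", "blacklist_")):
                meta[col] = meta[col].astype(bool)
        return cls(vals, meta)


@dataclass
class CovariateTable:
    """Per-subject covariates: age, sex, diagnosis, batch, cell proportions, PCs."""

    table: pd.DataFrame

    NUMERIC_PREFIXES = ("age", "sex", "cell_", "pc")

    @property
    def subjects(self) -> pd.Index:
        return self.table.index

    def design_matrix(self, include_diagnosis: bool = True) -> pd.DataFrame:
        """Numeric design columns for association models (no intercept, no batch).

        When the cell proportions are compositionally complete (rows sum to a
        constant) the last cell column is dropped so the design stays full
        rank next to an intercept.
        """
        cols = [
            c
            for c in self.table.columns
            if c == "age"
            or c == "sex"
            or c.startswith("cell_")
            or c.startswith("pc")
        ]
        out = self.table[cols].astype(float).copy()
        cell_cols = [c for c in cols if c.startswith("cell_")]
        if len(cell_cols) > 1:
            sums = out[cell_cols].sum(axis=1)
            if float(sums.std()) < 1e-8:
                out = out.drop(columns=cell_cols[-1])
        if include_diagnosis and "diagnosis" in self.table.columns:
            out["diagnosis"] = self.table["diagnosis"].astype(float)
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("subject").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CovariateTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class MeqtlTable:
    """Significant cis SNP-CpG associations from one tissue's scan.

    ``records`` columns: snp_id, chrom, pos, coding_allele, other_allele, maf,
    cpg_id, cpg_pos, beta, se, beta_hat, p, n.
    """

    tissue: str
    records: pd.DataFrame
    window: int
    p_threshold: float
    covariates: tuple[str, ...] = field(default_factory=tuple)

    COLUMNS = (
        "snp_id",
        "chrom",
        "pos",
        "coding_allele",
        "other_allele",
        "maf",
        "cpg_id",
        "cpg_pos",
        "beta",
        "se",
        "beta_hat",
        "p",
        "n",
    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_positions(self) -> pd.DataFrame:
        return self.records[["chrom", "pos"]].drop_duplicates()

    def to_tsv(self, path: str | Path) -> None:
        header = (
            f"# tissue={self.tissue} window={self.window} "
            f"p_threshold={self.p_threshold:g} covariates={','.join(self.covariates)}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.records.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeqtlTable":
        with open(path) as fh:
            first = fh.readline()
        meta = {}
        if first.startswith("#"):
            for token in first[1:].split():
                k, _, v = token.partition("=")
                meta[k] = v
            records = pd.read_csv(path, sep="\t", skiprows=1, dtype={"chrom": str})
        else:
            records = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        covs = tuple(c for c in meta.get("covariates", "").split(",") if c)
        return cls(
            tissue=meta.get("tissue", "unknown"),
            records=records,
            window=int(meta.get("window", 20_000)),
            p_threshold=float(meta.get("p_threshold", 1e-5)),
            covariates=covs,
        )


def empty_meqtl_records() -> pd.DataFrame:
    return pd.DataFrame(columns=list(MeqtlTable.COLUMNS))
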