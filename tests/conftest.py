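import numpy as np
import pandas as pd
import pytest

from meqtlkit.containers import GenotypeMatrix, MethylationMatrix
from meqtlkit.synth import CohortSpec, build_cohort


def make_cpg_meta(cpg_ids, positions=None, chrom="1"):
    """Minimal CpG metadata frame for hand-built methylation matrices."""
    n = len(cpg_ids)
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions if positions is not None else np.arange(1, n + 1) * 1000,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    meta["island_context"] = "open_sea"
    return meta


def make_snp_meta(snp_ids, positions, coding="A", other="G", chrom="1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "coding_allele": coding,
            "other_allele": other,
            "maf": 0.3,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


def make_methylation(values, cpg_ids=None, detection_p=None):
    values = np.asarray(values, dtype=float)
    cpg_ids = cpg_ids or [f"cg{j:03d}" for j in range(values.shape[1])]
    subjects = [f"s{i:03d}" for i in range(values.shape[0])]
    vals = pd.DataFrame(values, index=subjects, columns=cpg_ids)
    det = None
    if detection_p is not None:
        det = pd.DataFrame(np.asarray(detection_p, float), index=subjects, columns=cpg_ids)
    return MethylationMatrix(vals, make_cpg_meta(cpg_ids), det)


def make_genotypes(dosages, positions=None, snp_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    snp_ids = snp_ids or [f"snp{j:03d}" for j in range(dosages.shape[1])]
    subjects = [f"s{i:03d}" for i in range(dosages.shape[0])]
    positions = positions if positions is not None else np.arange(1, dosages.shape[1] + 1) * 1000
    dos = pd.DataFrame(dosages, index=subjects, columns=snp_ids)
    return GenotypeMatrix(dos, make_snp_meta(snp_ids, positions))


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_subjects_per_tissue=(60, 60, 60),
        n_snps=80,
        n_cpgs=80,
        chrom_length=800_000,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return build_cohort(small_spec)
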