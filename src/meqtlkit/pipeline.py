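"""Pipeline orchestration: simulate -> qc -> scan -> compare -> enrich -> network.

The orchestrator holds no computation of its own: every stage is a call into
the corresponding module, every stage output is a plain TSV in the run
directory, and all stage parameters are echoed into ``report.txt`` so a run
is reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conetwork, crosstissue, enrich, preprocess, scan, synth
from .containers import MeqtlTable

logger = logging.getLogger("meqtlkit")


@dataclass
class RunConfig:
    """Parameters of one end-to-end synthetic run."""

    out_dir: str = "meqtlkit_run"
    cohort: synth.CohortSpec = field(default_factory=synth.CohortSpec)
    window: int = scan.DEFAULT_WINDOW
    p_threshold: float = scan.DEFAULT_P_THRESHOLD
    min_maf: float = 0.05
    max_snp_missing: float = 0.01
    hwe_alpha: float = 1e-6
    max_cpg_missing: float = 0.01
    detection_alpha: float = 0.05
    r2_max: float = 0.7
    prune_window: int = 1_000_000
    bin_width: float = enrich.MAF_BIN_WIDTH
    n_sets: int = 2_000
    network_power: int = conetwork.DEFAULT_POWER
    min_module_size: int = conetwork.DEFAULT_MIN_SIZE
    cut_height: float = conetwork.DEFAULT_CUT_HEIGHT
    combine: str = "fisher"
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if self.window <= 0 or self.prune_window <= 0:
            raise ValueError("windows must be positive")
        if not (0.0 <= self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in [0, 1]")
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError("r2_max must be in (0, 1)")
        if self.n_sets < 100:
            raise ValueError("n_sets must be at least 100")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cohort = data.pop("cohort", None)
        cfg = cls(**data)
        if cohort:
            for key in ("n_subjects_per_tissue", "maf_range", "effect_size_range", "tissues"):
                if key in cohort and isinstance(cohort[key], list):
                    cohort[key] = tuple(cohort[key])
            cfg.cohort = synth.CohortSpec(**cohort)
        return cfg


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage on a synthetic cohort; returns the run directory.

    Identical config (including seeds) reproduces identical output tables.
    Stage failures abort the run with the stage name in the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: list[str] = ["meqtlkit pipeline report", "=" * 30]
    try:
        stage = "simulate"
        logger.info("stage %s", stage)
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        tissues, truth = synth.build_cohort(spec)
        synth.write_cohort(out / "cohort", tissues, truth, spec)
        report.append(
            f"simulate: tissues={','.join(spec.tissues)} "
            f"n={spec.n_subjects_per_tissue} snps={spec.n_snps} cpgs={spec.n_cpgs} seed={config.seed}"
        )

        stage = "qc"
        logger.info("stage %s", stage)
        processed = {}
        for tissue, (G, M, C) in tissues.items():
            Gq, glog = preprocess.genotype_qc(
                G, config.max_snp_missing, config.min_maf, config.hwe_alpha
            )
            Mq, mlog = preprocess.preprocess_methylation(
                M, C, config.max_cpg_missing, config.detection_alpha
            )
            glog.to_frame().to_csv(out / f"qc_genotype_{tissue}.tsv", sep="\t", index=False)
            mlog.to_frame().to_csv(out / f"qc_methylation_{tissue}.tsv", sep="\t", index=False)
            processed[tissue] = (Gq, Mq, C)
            report.append(
                f"qc[{tissue}]: snps {G.n_snps}->{Gq.n_snps} "
                f"(min_maf={config.min_maf}, hwe_alpha={config.hwe_alpha:g}, "
                f"max_snp_missing={config.max_snp_missing}); "
                f"cpgs {M.n_cpgs}->{Mq.n_cpgs} "
                f"(max_missing={config.max_cpg_missing}, detection_alpha={config.detection_alpha})"
            )

        stage = "scan"
        logger.info("stage %s", stage)
        tables: dict[str, MeqtlTable] = {}
        for tissue, (Gq, Mq, C) in processed.items():
            tab = scan.scan_tissue(
                Gq, Mq, C, window=config.window, p_threshold=config.p_threshold, tissue=tissue
            )
            tab.to_tsv(out / f"meqtl_{tissue}.tsv")
            tables[tissue] = tab
            report.append(
                f"scan[{tissue}]: {len(tab)} pairs at window={config.window} "
                f"pmax={config.p_threshold:g}"
            )

        stage = "compare"
        logger.info("stage %s", stage)
        first = next(iter(processed.values()))
        common_snps = first[0].snp_meta[["chrom", "pos"]]
        common_cpgs = first[1].cpg_meta[["chrom", "pos"]]
        for Gq, Mq, _ in processed.values():
            common_snps = common_snps.merge(Gq.snp_meta[["chrom", "pos"]], on=["chrom", "pos"])
            common_cpgs = common_cpgs.merge(Mq.cpg_meta[["chrom", "pos"]], on=["chrom", "pos"])
        summary = crosstissue.overlap_summary(tables, common_snps, common_cpgs)
        summary.to_frame().to_csv(out / "overlap_summary.tsv", sep="\t")
        (out / "overlap_report.txt").write_text(summary.report() + "\n")
        report.append("compare:\n" + summary.report())

        stage = "enrich"
        logger.info("stage %s", stage)
        ref_tissue = next(iter(processed))
        G_ref = processed[ref_tissue][0]
        priority = set(truth.risk_snps) & set(G_ref.snp_ids)
        pruned = enrich.supervised_ld_prune(
            G_ref, priority, r2_max=config.r2_max, window=config.prune_window
        )
        universe_maf = G_ref.snp_meta.loc[sorted(pruned), "maf"]
        meqtl_union = set()
        for tab in tables.values():
            meqtl_union |= set(tab.records["snp_id"])
        query = meqtl_union & pruned
        if query:
            result = enrich.snp_set_enrichment(
                query,
                set(truth.risk_snps),
                universe_maf,
                name="risk_loci",
                bin_width=config.bin_width,
                n_sets=config.n_sets,
                seed=config.seed + 1,
            )
            pd.DataFrame([result.to_dict()]).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report.append(
                f"enrich: observed={result.observed_proportion:.4f} "
                f"OR={result.odds_ratio:.3f} p_perm={result.p_perm:g} "
                f"p_fisher={result.p_fisher:g} (r2_max={config.r2_max}, "
                f"bin_width={config.bin_width}, n_sets={config.n_sets})"
            )
        else:
            pd.DataFrame().to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report.append("enrich: empty meQTL query after pruning; stage skipped")

        stage = "network"
        logger.info("stage %s", stage)
        targeted = set()
        for tab in tables.values():
            targeted |= set(tab.records["cpg_id"])
        # network runs on the cross-tissue targeted CpGs plus the planted module
        wanted = sorted(targeted | set(truth.module_cpgs))
        tissue_net = {}
        for tissue, (Gq, Mq, C) in processed.items():
            avail = [c for c in wanted if c in Mq.values.columns]
            tissue_net[tissue] = (Mq.subset_cpgs(avail), C)
        n_net_cpgs = min(len(m.values.columns) for m, _ in tissue_net.values())
        if n_net_cpgs >= max(2, config.min_module_size):
            modules, mod_stats, _ = conetwork.consensus_network(
                tissue_net,
                power=config.network_power,
                min_size=config.min_module_size,
                cut_height=config.cut_height,
                combine=config.combine,
            )
            assign = modules.rename("module").to_frame()
            for mod in mod_stats:
                assign.loc[list(mod.cpg_ids), "MM"] = mod.mm
                assign.loc[list(mod.cpg_ids), "MS"] = mod.ms
            assign.rename_axis("cpg_id").to_csv(out / "module_assignments.tsv", sep="\t")
            pd.DataFrame([m.summary_row() for m in mod_stats]).to_csv(
                out / "module_summary.tsv", sep="\t", index=False
            )
            report.append(
                f"network: {len(mod_stats)} modules (power={config.network_power}, "
                f"min_size={config.min_module_size}, cut_height={config.cut_height}, "
                f"combine={config.combine})"
            )
            for m in mod_stats:
                report.append(
                    f"  module {m.label}: size={m.size} combined_p={m.combined_p:g} "
                    f"mm_ms_r={m.mm_ms_r:.3f}"
                )
        else:
            pd.DataFrame().to_csv(out / "module_summary.tsv", sep="\t", index=False)
            report.append("network: too few targeted CpGs; stage skipped")
    except Exception:
        logger.exception("stage %s failed", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "report.txt").write_text("\n".join(report) + "\n")
    config.to_yaml(out / "run_config.yaml")
    return out
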