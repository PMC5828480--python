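"""Synthetic cohort generator: distributional, determinism, and truth checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import meqtlkit as mk
from meqtlkit.synth import (
    CohortSpec,
    SpecificationError,
    TruthTable,
    add_ld_partner,
    build_cohort,
    plant_annotation_set,
    simulate_covariates,
    simulate_genotypes,
    simulate_methylation,
)


class TestSimulateGenotypes:
    def test_dosages_and_positions(self, small_spec):
        G = simulate_genotypes(small_spec, n=40, seed=1)
        arr = G.dosages.to_numpy()
        assert set(np.unique(arr)) <= {0.0, 1.0, 2.0}
        pos = G.snp_meta["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()
        assert ((G.snp_meta["maf"] >= 0) & (G.snp_meta["maf"] <= 0.5)).all()

    def test_hwe_frequencies_at_half(self):
        spec = CohortSpec(n_snps=200, n_cpgs=5, module_size=2, maf_range=(0.5, 0.5), chrom_length=10**7)
        G = simulate_genotypes(spec, n=3000, seed=2)
        arr = G.dosages.to_numpy()
        freqs = np.array([(arr == k).mean() for k in (0, 1, 2)])
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_minimal_size(self):
        spec = CohortSpec(n_snps=1, n_cpgs=1, module_size=1)
        G = simulate_genotypes(spec, n=2, seed=0)
        assert G.dosages.shape == (2, 1)

    def test_deterministic(self, small_spec):
        G1 = simulate_genotypes(small_spec, n=20, seed=1)
        G2 = simulate_genotypes(small_spec, n=20, seed=1)
        pd.testing.assert_frame_equal(G1.dosages, G2.dosages)
        pd.testing.assert_frame_equal(G1.snp_meta, G2.snp_meta)

    def test_invalid_maf_range(self):
        with pytest.raises(SpecificationError):
            CohortSpec(maf_range=(0.0, 0.6)).validate()
        with pytest.raises(SpecificationError):
            simulate_genotypes(CohortSpec(maf_range=(-0.1, 0.2)), n=10, seed=0)


class TestSimulateMethylation:
    def _flat_inputs(self, spec, n=30, seed=0):
        from meqtlkit.synth import _simulate_cpg_universe, _simulate_snp_universe, _draw_dosages

        rng = np.random.default_rng(seed)
        snp_universe = _simulate_snp_universe(spec, rng)
        cpg_meta = _simulate_cpg_universe(spec, rng)
        G = _draw_dosages(snp_universe, n, rng)
        C = simulate_covariates(spec, n, seed + 1)
        return G, cpg_meta, C

    def test_zero_effect_zero_noise_constant(self):
        spec = CohortSpec(
            n_snps=10, n_cpgs=10, noise_sd=0.0, covariate_effect_sd=0.0,
            batch_shift_sd=0.0, module_effect=0.0, module_cor=0.0,
        )
        G, cpg_meta, C = self._flat_inputs(spec)
        truth = TruthTable(pd.DataFrame(columns=["snp_id", "cpg_id", "tissues", "effect"]), (), (), 1.0)
        M = simulate_methylation(G, cpg_meta, truth, C, spec, "brain", seed=5)
        assert np.allclose(M.values.std(axis=0), 0.0)
        expected = special.expit(cpg_meta["baseline_logit"].to_numpy())
        assert np.allclose(M.values.iloc[0].to_numpy(), expected)

    def test_single_pair_exact_logit_shift(self):
        spec = CohortSpec(
            n_snps=10, n_cpgs=10, noise_sd=0.0, covariate_effect_sd=0.0,
            batch_shift_sd=0.0, module_effect=0.0, module_cor=0.0, chrom_length=50_000,
        )
        G, cpg_meta, C = self._flat_inputs(spec, n=50)
        snp = G.snp_ids[0]
        pos_snp = int(G.snp_meta.loc[snp, "pos"])
        dist = (cpg_meta["pos"] - pos_snp).abs()
        cpg = dist.idxmin()
        assert dist[cpg] <= spec.cis_window
        effect = 0.4
        truth = TruthTable(
            pd.DataFrame([{"snp_id": snp, "cpg_id": cpg, "tissues": "brain", "effect": effect}]),
            (), (), 1.0,
        )
        M = simulate_methylation(G, cpg_meta, truth, C, spec, "brain", seed=5)
        logit = special.logit(M.values[cpg])
        g = G.dosages[snp]
        means = logit.groupby(g).mean()
        if 0.0 in means.index and 1.0 in means.index:
            assert means[1.0] - means[0.0] == pytest.approx(effect, abs=1e-10)

    def test_cis_window_violation_raises(self):
        spec = CohortSpec(n_snps=5, n_cpgs=5, chrom_length=10**7)
        G, cpg_meta, C = self._flat_inputs(spec)
        # pick the most distant SNP-CpG combination
        snp = G.snp_ids[0]
        cpg = cpg_meta.index[-1]
        assert abs(int(G.snp_meta.loc[snp, "pos"]) - int(cpg_meta.loc[cpg, "pos"])) > spec.cis_window
        truth = TruthTable(
            pd.DataFrame([{"snp_id": snp, "cpg_id": cpg, "tissues": "brain", "effect": 0.5}]),
            (), (), 1.0,
        )
        with pytest.raises(SpecificationError, match="cis window"):
            simulate_methylation(G, cpg_meta, truth, C, spec, "brain", seed=1)

    def test_beta_values_in_open_unit_interval(self, small_cohort):
        tissues, _ = small_cohort
        for _, M, _ in tissues.values():
            arr = M.values.to_numpy()
            assert (arr > 0).all() and (arr < 1).all()

    def test_noise_variance_matches_delta_method(self):
        # Var(beta) ~ (expit'(baseline) * noise_sd)^2 for small noise
        spec = CohortSpec(
            n_snps=5, n_cpgs=40, noise_sd=0.1, covariate_effect_sd=0.0,
            batch_shift_sd=0.0, module_effect=0.0, module_cor=0.0,
        )
        G, cpg_meta, C = self._flat_inputs(spec, n=4000)
        truth = TruthTable(pd.DataFrame(columns=["snp_id", "cpg_id", "tissues", "effect"]), (), (), 1.0)
        M = simulate_methylation(G, cpg_meta, truth, C, spec, "brain", seed=9)
        observed_sd = M.values.std(axis=0).to_numpy()
        b = cpg_meta["baseline_logit"].to_numpy()
        predicted_sd = special.expit(b) * (1 - special.expit(b)) * spec.noise_sd
        assert np.allclose(observed_sd, predicted_sd, rtol=0.1)

    def test_detection_p_channel_fraction(self):
        spec = CohortSpec(n_snps=5, n_cpgs=50, detect_fail_fraction=0.1)
        G, cpg_meta, C = self._flat_inputs(spec, n=100)
        truth = TruthTable(pd.DataFrame(columns=["snp_id", "cpg_id", "tissues", "effect"]), (), (), 1.0)
        M = simulate_methylation(G, cpg_meta, truth, C, spec, "brain", seed=3)
        frac = (M.detection_p.to_numpy() > 0.05).mean()
        assert frac == pytest.approx(0.1, abs=0.02)


class TestPlantAnnotationSet:
    @staticmethod
    def _sample_or(ann, truth, universe):
        a = len(ann & truth)
        b = len(ann - truth)
        c = len(truth - ann)
        d = len(universe) - a - b - c
        return (a * d) / (b * c)

    def test_or_one_is_independent(self):
        universe = [f"s{i}" for i in range(4000)]
        truth = set(universe[:400])
        ors = []
        for seed in range(60):
            ann = plant_annotation_set(universe, truth, 1.0, 400, seed)
            ors.append(self._sample_or(ann, truth, universe))
        assert np.mean(ors) == pytest.approx(1.0, abs=0.1)

    def test_or_two_recovered(self):
        universe = [f"s{i}" for i in range(4000)]
        truth = set(universe[:400])
        ors = [
            self._sample_or(plant_annotation_set(universe, truth, 2.0, 400, seed), truth, universe)
            for seed in range(200)
        ]
        assert np.mean(ors) == pytest.approx(2.0, abs=0.15)

    def test_infinite_or_full_overlap(self):
        universe = [f"s{i}" for i in range(100)]
        truth = set(universe[:50])
        ann = plant_annotation_set(universe, truth, np.inf, 30, seed=1)
        assert ann <= truth and len(ann) == 30

    def test_infeasible_raises(self):
        universe = [f"s{i}" for i in range(20)]
        with pytest.raises(SpecificationError):
            plant_annotation_set(universe, set(universe[:5]), np.inf, 10, seed=0)
        with pytest.raises(SpecificationError):
            plant_annotation_set(universe, set(universe[:5]), -1.0, 5, seed=0)
        with pytest.raises(SpecificationError):
            plant_annotation_set(universe, set(universe[:5]), 2.0, 30, seed=0)


class TestBuildCohort:
    def test_all_shared_when_frac_shared_one(self):
        spec = CohortSpec(
            n_subjects_per_tissue=(20, 20, 20), n_snps=60, n_cpgs=60,
            chrom_length=500_000, frac_shared=1.0, seed=4,
        )
        _, truth = build_cohort(spec)
        assert len(truth.planted_pairs) > 0
        assert (truth.planted_pairs["tissues"] == ",".join(spec.tissues)).all()

    def test_no_planted_pairs_yields_uniform_p(self):
        from meqtlkit import preprocess, scan

        spec = CohortSpec(
            n_subjects_per_tissue=(150, 150, 150), n_snps=60, n_cpgs=60,
            chrom_length=500_000, frac_cis_pairs=0.0, module_effect=0.0,
            module_cor=0.0, seed=8,
        )
        tissues, truth = build_cohort(spec)
        assert truth.planted_pairs.empty
        G, M, C = tissues["brain"]
        Mq, _ = preprocess.preprocess_methylation(M, C)
        Gq, _ = preprocess.genotype_qc(G)
        tab = mk.scan_tissue(Gq, Mq, C, p_threshold=1.0)
        pvals = tab.records["p"].to_numpy()
        assert len(pvals) > 50
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_byte_identical_reruns(self, small_spec, small_cohort, tmp_path):
        from meqtlkit.synth import write_cohort

        t1, truth1 = small_cohort
        t2, truth2 = build_cohort(small_spec)
        write_cohort(tmp_path / "a", t1, truth1, small_spec)
        write_cohort(tmp_path / "b", t2, truth2, small_spec)
        for rel in sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file()):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_planted_pairs_within_cis_window(self, small_cohort, small_spec):
        tissues, truth = small_cohort
        G, M, _ = tissues["brain"]
        for row in truth.planted_pairs.itertuples(index=False):
            d = abs(int(G.snp_meta.loc[row.snp_id, "pos"]) - int(M.cpg_meta.loc[row.cpg_id, "pos"]))
            assert d <= small_spec.cis_window


class TestLdPartner:
    @pytest.mark.parametrize("target_r2", [0.25, 0.81])
    def test_target_r2_reached_on_average(self, target_r2):
        from meqtlkit.enrich import genotype_r2

        spec = CohortSpec(n_snps=5, n_cpgs=5, module_size=2, maf_range=(0.3, 0.5))
        r2s = []
        for seed in range(40):
            G = simulate_genotypes(spec, n=800, seed=seed)
            G2 = add_ld_partner(G, G.snp_ids[0], target_r2, seed=seed + 1000)
            r2s.append(genotype_r2(G2.dosages.iloc[:, 0], G2.dosages.iloc[:, -1]))
        assert np.mean(r2s) == pytest.approx(target_r2, abs=0.06)
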