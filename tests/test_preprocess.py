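"""QC and normalization: thresholds, hand-computed oracles, and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meqtlkit import preprocess
from conftest import make_genotypes, make_methylation


class TestHweTest:
    def test_perfect_hwe_gives_p_one(self):
        assert preprocess.hwe_test((25, 50, 25)) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts",
        [(0, 100, 0), (50, 0, 50)],
        ids=["all_het", "no_het"],
    )
    def test_extreme_departures(self, counts):
        # chi-square statistic is 100 on 1 df in both cases
        p = preprocess.hwe_test(counts)
        assert p < 1e-6
        assert p == pytest.approx(stats.chi2.sf(100.0, 1), rel=1e-6)

    def test_monomorphic_is_consistent(self):
        assert preprocess.hwe_test((30, 0, 0)) == 1.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            preprocess.hwe_test((0, 0, 0))

    def test_simulated_hwe_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(300):
            g = rng.binomial(2, 0.3, size=500)
            pvals.append(preprocess.hwe_test(((g == 0).sum(), (g == 1).sum(), (g == 2).sum())))
        # continuity-corrected chi-square is conservative, not anti-conservative
        assert (np.array(pvals) < 0.01).mean() <= 0.02


class TestGenotypeQc:
    def test_low_maf_removed(self):
        rng = np.random.default_rng(1)
        dos = np.column_stack(
            [rng.binomial(2, 0.04, 500), rng.binomial(2, 0.3, 500)]
        ).astype(float)
        G = make_genotypes(dos)
        out, log = preprocess.genotype_qc(G, min_maf=0.05)
        assert list(out.snp_ids) == ["snp001"]
        assert log.counts["maf"] == 1

    def test_clean_snp_retained(self):
        g = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=float)
        G = make_genotypes(g[:, None])
        out, log = preprocess.genotype_qc(G)
        assert out.n_snps == 1 and log.total() == 0

    def test_hwe_rule_rarely_fires_under_hwe(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 1000), size=(300, 1000)).astype(float)
        G = make_genotypes(dos, positions=np.arange(1, 1001) * 100)
        _, log = preprocess.genotype_qc(G, hwe_alpha=1e-6)
        assert log.counts["hwe"] <= 2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, rng.uniform(0.02, 0.5, 50), size=(200, 50)).astype(float)
        G = make_genotypes(dos, positions=np.arange(1, 51) * 100)
        once, _ = preprocess.genotype_qc(G)
        twice, log2 = preprocess.genotype_qc(once)
        assert list(once.snp_ids) == list(twice.snp_ids)
        assert log2.total() == 0

    def test_missingness_rule(self):
        g = np.full((100, 1), 1.0)
        g[:60, 0] = [0, 2] * 30
        g[:5, 0] = np.nan
        G = make_genotypes(g)
        _, log = preprocess.genotype_qc(G, max_snp_missing=0.01)
        assert log.counts["missingness"] == 1


class TestMethylationQc:
    def test_blacklisted_removed(self):
        M = make_methylation(np.full((4, 2), 0.5))
        M.cpg_meta["blacklist_snp_coincident"] = [True, False]
        out, log = preprocess.methylation_qc(M)
        assert list(out.cpg_ids) == ["cg001"]
        assert log.counts["blacklist"] == 1

    def test_detection_p_masks_then_removes(self):
        det = np.zeros((100, 2)) + 0.001
        det[:2, 0] = 0.2  # 2% of entries fail detection for cg000
        M = make_methylation(np.full((100, 2), 0.5), detection_p=det)
        out, log = preprocess.methylation_qc(M, max_missing=0.01)
        assert list(out.cpg_ids) == ["cg001"]
        assert log.counts["missingness"] == 1

    def test_clean_cpg_retained(self):
        M = make_methylation(np.full((10, 3), 0.4))
        out, log = preprocess.methylation_qc(M)
        assert out.n_cpgs == 3 and log.total() == 0


class TestQuantileNormalize:
    def test_hand_example(self):
        M = make_methylation([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = preprocess.quantile_normalize(M)
        expected = np.array([[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])
        assert np.allclose(out.values.to_numpy(), expected)

    def test_identical_subjects_unchanged(self):
        row = np.array([0.1, 0.5, 0.9, 0.3])
        M = make_methylation(np.tile(row, (5, 1)))
        out = preprocess.quantile_normalize(M)
        assert np.allclose(out.values.to_numpy(), np.tile(row, (5, 1)))

    def test_rows_share_one_distribution(self):
        rng = np.random.default_rng(4)
        M = make_methylation(rng.random((8, 30)))
        out = preprocess.quantile_normalize(M).values.to_numpy()
        ref = np.sort(out[0])
        for i in range(1, 8):
            assert np.allclose(np.sort(out[i]), ref)

    def test_missing_entries_stay_missing(self):
        vals = np.random.default_rng(5).random((6, 20))
        vals[0, 3] = np.nan
        M = make_methylation(vals)
        out = preprocess.quantile_normalize(M)
        assert np.isnan(out.values.iloc[0, 3])
        assert out.values.isna().sum().sum() == 1

    def test_single_subject_identity(self):
        M = make_methylation([[0.2, 0.8, 0.5]])
        out = preprocess.quantile_normalize(M)
        assert np.allclose(out.values.to_numpy(), M.values.to_numpy())


class TestMeanImpute:
    def test_hand_example(self):
        M = make_methylation([[0.2], [np.nan], [0.4]])
        out = preprocess.mean_impute(M)
        assert np.allclose(out.values.iloc[:, 0], [0.2, 0.3, 0.4])

    def test_identity_without_missing(self):
        M = make_methylation([[0.2, 0.6], [0.4, 0.8]])
        out = preprocess.mean_impute(M)
        pd.testing.assert_frame_equal(out.values, M.values)

    def test_column_mean_preserved(self):
        rng = np.random.default_rng(6)
        vals = rng.random((20, 5))
        vals[rng.random((20, 5)) < 0.2] = np.nan
        M = make_methylation(vals)
        out = preprocess.mean_impute(M)
        assert np.allclose(out.values.mean(axis=0), M.values.mean(axis=0, skipna=True))

    def test_fully_missing_raises(self):
        M = make_methylation([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="fully-missing"):
            preprocess.mean_impute(M)


class TestRankNormalize:
    def test_monotone_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.random((15, 6))
        M1 = make_methylation(vals)
        M2 = make_methylation(np.exp(3 * vals))  # strictly monotone transform
        out1 = preprocess.rank_normalize(M1).values.to_numpy()
        out2 = preprocess.rank_normalize(M2).values.to_numpy()
        assert np.allclose(out1, out2)

    def test_blom_scores_n3(self):
        M = make_methylation(np.array([[5.0], [1.0], [9.0]]))
        out = preprocess.rank_normalize(M).values.iloc[:, 0].to_numpy()
        expected = stats.norm.ppf((np.array([2.0, 1.0, 3.0]) - 0.375) / 3.25)
        assert np.allclose(out, expected)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_moments_and_rank_preservation(self):
        rng = np.random.default_rng(8)
        M = make_methylation(rng.random((200, 4)))
        out = preprocess.rank_normalize(M)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-3)
        assert np.allclose(out.values.std(axis=0, ddof=1), 1.0, atol=0.05)
        for j in range(4):
            rho = stats.spearmanr(M.values.iloc[:, j], out.values.iloc[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_constant_cpg_raises(self):
        M = make_methylation(np.full((5, 1), 0.5))
        with pytest.raises(ValueError, match="constant"):
            preprocess.rank_normalize(M)


class TestBatchAdjust:
    def _shifted(self, shift=0.1, noise=1e-3, n=30, p=12, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.3, 0.7, p)
        vals = np.tile(base, (n, 1)) + rng.normal(0, noise, (n, p))
        vals[n // 2 :] += shift
        M = make_methylation(vals)
        batch = pd.Series(["b1"] * (n // 2) + ["b2"] * (n // 2), index=M.values.index)
        return M, batch

    def test_constant_shift_removed(self):
        M, batch = self._shifted()
        out = preprocess.batch_adjust(M, batch)
        m1 = out.values[batch == "b1"].mean()
        m2 = out.values[batch == "b2"].mean()
        assert np.abs(m1 - m2).max() < 1e-3

    def test_single_batch_identity_with_warning(self):
        M, batch = self._shifted()
        with pytest.warns(UserWarning, match="single batch"):
            out = preprocess.batch_adjust(M, pd.Series("b1", index=M.values.index))
        pd.testing.assert_frame_equal(out.values, M.values)

    def test_protected_diagnosis_effect_survives(self):
        rng = np.random.default_rng(9)
        n, p = 60, 10
        diagnosis = np.array([0, 1] * (n // 2), dtype=float)
        batch = pd.Series(["b1"] * (n // 2) + ["b2"] * (n // 2))
        effect = 0.2
        vals = (
            np.tile(rng.uniform(0.3, 0.5, p), (n, 1))
            + effect * diagnosis[:, None]
            + 0.15 * (batch == "b2").to_numpy(float)[:, None]
            + rng.normal(0, 1e-3, (n, p))
        )
        M = make_methylation(vals)
        batch.index = M.values.index
        protected = pd.DataFrame({"diagnosis": diagnosis}, index=M.values.index)
        out = preprocess.batch_adjust(M, batch, protected)
        recovered = (
            out.values[diagnosis == 1].mean() - out.values[diagnosis == 0].mean()
        ).mean()
        assert recovered == pytest.approx(effect, rel=0.1)

    def test_between_batch_variance_suppressed(self):
        # planted batch shifts of SD 0.5 leave <1% between-batch variance
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 40, 15
            shift = rng.normal(0, 0.5, p)
            vals = rng.normal(0.5, 0.1, (n, p))
            vals[n // 2 :] += shift
            M = make_methylation(vals)
            batch = pd.Series(["b1"] * (n // 2) + ["b2"] * (n // 2), index=M.values.index)
            out = preprocess.batch_adjust(M, batch).values.to_numpy()
            grand = out.mean(axis=0)
            between = 0.5 * (
                (out[: n // 2].mean(axis=0) - grand) ** 2
                + (out[n // 2 :].mean(axis=0) - grand) ** 2
            )
            total = out.var(axis=0)
            fractions.append((between / total).mean())
        assert np.mean(fractions) < 0.01


class TestFullPipeline:
    def test_order_and_output_shape(self, small_cohort):
        tissues, _ = small_cohort
        _, M, C = tissues["blood"]
        out, log = preprocess.preprocess_methylation(M, C)
        assert out.values.notna().all().all()
        assert out.n_cpgs <= M.n_cpgs
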