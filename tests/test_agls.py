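import numpy as np
import pytest
from scipy import stats

from aglscan.agls import (
    PhenotypeTable,
    ScanConfig,
    adjust_phenotypes,
    contrast_test,
    fit_snp,
    genome_scan,
)
from aglscan.quantgen import (
    UntestableSNPError,
    additive_contrast_coefficients,
    compute_snp_frequencies,
    dominance_contrast_coefficients,
)


def iid_table(rng, n, sd=1.0):
    return PhenotypeTable(np.arange(n), rng.normal(0, sd, n), np.zeros(n))


class TestAdjustPhenotypes:
    def test_zero_adjustment_is_identity(self):
        t = PhenotypeTable([1, 2], [-10.0, 5.0], [0.0, 0.0])
        assert adjust_phenotypes(t) == pytest.approx([-10.0, 5.0])

    def test_elementwise_subtraction(self):
        t = PhenotypeTable([1, 2], [-10.0, 5.0], [-2.0, 1.0])
        assert adjust_phenotypes(t) == pytest.approx([-8.0, 4.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            PhenotypeTable([1, 2], [0.0, 1.0], [0.0])


class TestFitSnp:
    def test_estimates_are_class_means(self):
        codes = np.repeat([0, 1, 2], 4).astype(float)
        y = np.repeat([1.0, 2.0, 3.0], 4)
        est = fit_snp(y, codes)
        assert est.g_hat.as_array() == pytest.approx([1.0, 2.0, 3.0])
        assert est.class_counts == (4, 4, 4)
        assert est.v2 == pytest.approx(0.0)
        assert est.k == 3

    def test_constant_phenotype_gives_zero_variance(self):
        est = fit_snp(np.full(9, 7.0), np.repeat([0, 1, 2], 3).astype(float))
        assert est.g_hat.as_array() == pytest.approx([7.0, 7.0, 7.0])
        assert est.v2 == 0.0

    def test_matches_generalized_inverse_least_squares(self, rng):
        # oracle: explicit pseudoinverse of the rank-deficient (mu, g) design
        n = 60
        codes = rng.integers(0, 3, n).astype(float)
        codes[rng.random(n) < 0.1] = np.nan
        y = rng.normal(0, 2, n)
        keep = ~np.isnan(codes)
        X = np.column_stack(
            [np.ones(keep.sum())]
            + [(codes[keep] == c).astype(float) for c in range(3)]
        )
        b = np.linalg.pinv(X) @ y[keep]
        resid = y[keep] - X @ b
        k = len({int(c) for c in codes[keep]})
        est = fit_snp(y, codes)
        assert est.v2 == pytest.approx(resid @ resid / (keep.sum() - k), rel=1e-9)
        for s in (
            additive_contrast_coefficients(compute_snp_frequencies(codes)),
            dominance_contrast_coefficients(),
        ):
            assert float(s @ est.g_hat.as_array()) == pytest.approx(
                float(s @ b[1:]), abs=1e-9
            )

    def test_single_class_raises(self):
        with pytest.raises(UntestableSNPError):
            fit_snp(np.ones(5), np.ones(5))

    def test_empty_heterozygote_flags_dominance_untestable(self):
        codes = np.repeat([0.0, 2.0], 5)
        est = fit_snp(np.arange(10, dtype=float), codes)
        assert not est.dominance_testable
        with pytest.raises(UntestableSNPError):
            contrast_test(est, dominance_contrast_coefficients())


class TestContrastTest:
    def test_null_contrast(self):
        est = fit_snp(np.repeat([1.0, 2.0, 1.0], 4), np.repeat([0, 1, 2], 4).astype(float))
        ct = contrast_test(est, [1.0, 0.0, -1.0])
        assert ct.t == 0.0
        assert ct.p == 1.0
        assert ct.neglog10p == 0.0

    def test_matches_classical_two_sample_t(self, rng):
        y0 = rng.normal(0, 1, 30)
        y2 = rng.normal(0.8, 1, 30)
        y = np.concatenate([y0, y2])
        codes = np.repeat([0.0, 2.0], 30)
        est = fit_snp(y, codes)
        ct = contrast_test(est, [1.0, 0.0, -1.0])
        t_ref, p_ref = stats.ttest_ind(y0, y2, equal_var=True)
        assert ct.t == pytest.approx(abs(t_ref), rel=1e-12)
        assert ct.p == pytest.approx(p_ref, rel=1e-9)

    def test_zero_variance_with_signal_is_flagged(self):
        est = fit_snp(np.repeat([0.0, 1.0, 0.0], 3), np.repeat([0, 1, 2], 3).astype(float))
        ct = contrast_test(est, dominance_contrast_coefficients())
        assert ct.zero_variance
        assert np.isinf(ct.neglog10p)

    def test_extreme_signal_avoids_underflow_in_neglog10p(self, rng):
        n = 2000
        codes = rng.integers(0, 3, n).astype(float)
        y = codes * 50.0 + rng.normal(0, 0.1, n)
        est = fit_snp(y, codes)
        ct = contrast_test(est, additive_contrast_coefficients(compute_snp_frequencies(codes)))
        assert ct.p == 0.0 and ct.underflow
        assert np.isfinite(ct.neglog10p) and ct.neglog10p > 300

    def test_normal_mode_close_to_t_at_large_n(self, rng):
        codes = rng.integers(0, 3, 5000).astype(float)
        y = rng.normal(0, 1, 5000)
        est = fit_snp(y, codes)
        s = additive_contrast_coefficients(compute_snp_frequencies(codes))
        assert contrast_test(est, s, df_mode="normal").p == pytest.approx(
            contrast_test(est, s, df_mode="t").p, rel=1e-2
        )


class TestGenomeScan:
    def test_matches_per_snp_path(self, rng):
        n, S = 400, 25
        G = rng.integers(0, 3, (n, S)).astype(float)
        G[rng.random((n, S)) < 0.08] = np.nan
        table = iid_table(rng, n)
        res = genome_scan(
            table, G, config=ScanConfig(min_dominance_class_count=1)
        )
        for _, row in res.iterrows():
            j = int(str(row["snp"]).removeprefix("snp"))
            est = fit_snp(adjust_phenotypes(table), G[:, j])
            freqs = compute_snp_frequencies(G[:, j])
            ct_a = contrast_test(est, additive_contrast_coefficients(freqs))
            assert row["t_additive"] == pytest.approx(ct_a.t, rel=1e-9, abs=1e-12)
            assert row["neglog10p_additive"] == pytest.approx(
                ct_a.neglog10p, rel=1e-9, abs=1e-12
            )
            if est.dominance_testable:
                ct_d = contrast_test(est, dominance_contrast_coefficients())
                assert row["t_dominance"] == pytest.approx(ct_d.t, rel=1e-9, abs=1e-12)

    def test_maf_filter_excludes_rare_snps(self, rng):
        n = 1000
        common = rng.binomial(2, 0.4, n)
        rare = rng.binomial(2, 0.03, n)  # MAF ~0.03 < 0.05
        G = np.column_stack([common, rare]).astype(float)
        res = genome_scan(iid_table(rng, n), G)
        assert list(res["snp"]) == ["snp0"]

    def test_no_passing_snps_warns_and_returns_empty(self, rng):
        G = rng.binomial(2, 0.1, (200, 5)).astype(float)
        with pytest.warns(UserWarning, match="MAF"):
            res = genome_scan(iid_table(rng, 200), G, config=ScanConfig(maf_min=0.4))
        assert res.empty

    def test_deterministic(self, rng):
        n, S = 300, 20
        G = rng.integers(0, 3, (n, S)).astype(float)
        table = iid_table(rng, n)
        r1 = genome_scan(table, G)
        r2 = genome_scan(table, G)
        assert r1.equals(r2)

    def test_injected_additive_effect_is_flagged_significant(self, rng):
        # alpha = 0.5 at residual SD 1 and n = 500: expected t ~ 8, far
        # beyond the genome-wide threshold of 8 on the log10(1/p) scale
        n = 500
        codes = rng.binomial(2, 0.5, n).astype(float)
        y = 0.25 * (codes - 1) * 2 + rng.normal(0, 1, n)
        table = PhenotypeTable(np.arange(n), y, np.zeros(n))
        res = genome_scan(table, codes[:, None])
        assert bool(res["significant_additive"].iloc[0])
        assert not bool(res["significant_dominance"].iloc[0])

    def test_cross_snp_allelic_effects_use_mean_of_means(self, rng):
        n, S = 300, 8
        G = rng.integers(0, 3, (n, S)).astype(float)
        res = genome_scan(iid_table(rng, n), G)
        mu_all = res["mu"].mean()
        assert np.allclose(res["ae1"], res["mu1"] - mu_all)

    def test_null_rejection_rate_near_nominal_iid(self, rng):
        # 2000 independent null SNPs, iid phenotypes: the additive test
        # should reject at ~5%; band = 3 binomial SE
        n, S = 400, 2000
        G = rng.integers(0, 3, (n, S)).astype(float)
        res = genome_scan(iid_table(rng, n), G)
        rate = float((res["p_additive"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(rate - 0.05) < 3 * se

    def test_expected_significance_grows_with_effect_size(self, rng):
        # averaged over replicates, larger |alpha| never lowers the
        # expected additive neglog10p
        n, reps = 300, 25
        mean_nl = []
        for alpha in (0.0, 0.35, 0.7):
            vals = []
            for _ in range(reps):
                codes = rng.binomial(2, 0.5, n).astype(float)
                y = (alpha / 2) * (codes - 1) * 2 + rng.normal(0, 1, n)
                res = genome_scan(
                    PhenotypeTable(np.arange(n), y, np.zeros(n)), codes[:, None]
                )
                vals.append(float(res["neglog10p_additive"].iloc[0]))
            mean_nl.append(np.mean(vals))
        assert mean_nl[0] < mean_nl[1] < mean_nl[2]
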