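import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aglscan.quantgen import (
    GenotypicValues,
    MonomorphicSNPError,
    SNPFrequencies,
    UntestableSNPError,
    additive_contrast_coefficients,
    additive_decomposition,
    allele_frequency_from_genotypes,
    compute_snp_frequencies,
    dominance_contrast_coefficients,
    dominance_decomposition,
    dominance_effect_from_values,
)


def hwe(p1):
    p2 = 1.0 - p1
    return SNPFrequencies.from_genotype_frequencies(p1 * p1, 2 * p1 * p2, p2 * p2)


# Strategy: genotype counts giving a polymorphic SNP.
polymorphic_counts = st.tuples(
    st.integers(0, 200), st.integers(1, 200), st.integers(0, 200)
)
genotypic = st.tuples(
    st.floats(-20, 20), st.floats(-20, 20), st.floats(-20, 20)
)


class TestFrequencies:
    @pytest.mark.parametrize(
        "counts, P, p1",
        [
            ((25, 50, 25), (0.25, 0.50, 0.25), 0.5),
            ((0, 30, 70), (0.0, 0.3, 0.7), 0.15),
        ],
    )
    def test_counts_to_frequencies(self, counts, P, p1):
        codes = [0] * counts[0] + [1] * counts[1] + [2] * counts[2]
        f = compute_snp_frequencies(codes)
        assert (f.P11, f.P12, f.P22) == pytest.approx(P)
        assert f.p1 == pytest.approx(p1)
        assert f.p1 + f.p2 == pytest.approx(1.0)

    def test_missing_entries_use_complete_cases(self):
        f = compute_snp_frequencies([0, 1, 2, np.nan, np.nan, 1])
        assert f.n == 4
        assert f.P12 == pytest.approx(0.5)

    def test_rare_recessive_allele_frequency_reconstruction(self):
        # genotype frequencies 0.005 (RR) and 0.152 (DR) imply f_R = 0.081
        assert allele_frequency_from_genotypes(0.005, 0.152) == pytest.approx(
            0.081, abs=5e-4
        )
        f = SNPFrequencies.from_genotype_frequencies(0.005, 0.152, 0.843)
        assert f.p1 == pytest.approx(0.081, abs=5e-4)

    def test_all_missing_raises(self):
        with pytest.raises(UntestableSNPError):
            compute_snp_frequencies([np.nan, np.nan])

    def test_invalid_code_raises(self):
        with pytest.raises(ValueError, match="invalid genotype code"):
            compute_snp_frequencies([0, 1, 3])


class TestAdditiveContrast:
    @pytest.mark.parametrize(
        "p1, expected",
        [(0.3, (0.3, 0.4, -0.7)), (0.5, (0.5, 0.0, -0.5))],
    )
    def test_hwe_simplification(self, p1, expected):
        assert additive_contrast_coefficients(hwe(p1)) == pytest.approx(expected)

    def test_hwd_coefficients(self):
        # P = (0.2, 0.2, 0.6): p1 = 0.3 and the HWD formula gives
        # (2/3, 4/21, -6/7), not the HWE simplification
        f = SNPFrequencies.from_genotype_frequencies(0.2, 0.2, 0.6)
        s = additive_contrast_coefficients(f)
        assert s == pytest.approx((2 / 3, 4 / 21, -6 / 7), abs=1e-12)

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicSNPError):
            additive_contrast_coefficients(
                SNPFrequencies.from_genotype_frequencies(1.0, 0.0, 0.0)
            )

    @given(p1=st.floats(0.01, 0.99))
    @settings(derandomize=True, max_examples=60)
    def test_hwe_reduction_and_zero_sum(self, p1):
        s = additive_contrast_coefficients(hwe(p1))
        assert s == pytest.approx((p1, 1 - 2 * p1, -(1 - p1)), abs=1e-12)
        assert abs(s.sum()) < 1e-12

    @given(counts=polymorphic_counts)
    @settings(derandomize=True, max_examples=60)
    def test_zero_sum_under_hwd(self, counts):
        f = SNPFrequencies.from_counts(*counts)
        if f.is_monomorphic:
            return
        assert abs(additive_contrast_coefficients(f).sum()) < 1e-10


class TestDominanceContrast:
    def test_fixed_coefficients(self):
        assert dominance_contrast_coefficients() == pytest.approx((-0.5, 1.0, -0.5))

    def test_orthogonal_to_additive_pattern(self):
        s = dominance_contrast_coefficients()
        assert s @ np.array([1.0, 0.0, -1.0]) == 0.0
        assert s @ np.array([0.0, 1.0, 0.0]) == 1.0


class TestAdditiveDecomposition:
    def test_symmetric_additive_snp(self):
        add = additive_decomposition(GenotypicValues(1, 0, -1), hwe(0.5))
        assert add.mu1 == pytest.approx(0.5)
        assert add.mu2 == pytest.approx(-0.5)
        assert add.alpha == pytest.approx(1.0)
        assert add.mu == pytest.approx(0.0)

    def test_constant_genotypic_values_have_no_effect(self):
        add = additive_decomposition(
            GenotypicValues(3.3, 3.3, 3.3),
            SNPFrequencies.from_genotype_frequencies(0.2, 0.2, 0.6),
        )
        assert add.alpha == pytest.approx(0.0, abs=1e-12)
        assert add.a1 == pytest.approx(0.0, abs=1e-12)
        assert add.a2 == pytest.approx(0.0, abs=1e-12)

    def test_alpha_equals_contrast_under_hwd(self):
        f = SNPFrequencies.from_genotype_frequencies(0.2, 0.2, 0.6)
        g = GenotypicValues(1, 0, -1)
        add = additive_decomposition(g, f)
        assert add.alpha == pytest.approx(1.52381, abs=1e-5)
        assert add.alpha == pytest.approx(
            float(additive_contrast_coefficients(f) @ g.as_array()), abs=1e-10
        )

    def test_cross_snp_allelic_effects_shift_with_mu_all(self):
        add = additive_decomposition(GenotypicValues(1, 0, -1), hwe(0.5), mu_all=2.0)
        assert add.ae1 == pytest.approx(add.mu1 - 2.0)
        assert add.ae2 == pytest.approx(add.mu2 - 2.0)

    @given(g=genotypic, counts=polymorphic_counts)
    @settings(derandomize=True, max_examples=100)
    def test_identities_on_random_inputs(self, g, counts):
        f = SNPFrequencies.from_counts(*counts)
        if f.is_monomorphic:
            return
        gv = GenotypicValues(*g)
        add = additive_decomposition(gv, f)
        # frequency-weighted allelic effects cancel
        assert abs(f.p1 * add.a1 + f.p2 * add.a2) < 1e-10
        # alpha is simultaneously mu1 - mu2, a1 - a2, and the contrast s_a'g
        assert add.alpha == pytest.approx(add.a1 - add.a2, abs=1e-10)
        sa = additive_contrast_coefficients(f)
        assert add.alpha == pytest.approx(float(sa @ gv.as_array()), abs=1e-10)


class TestDominanceDecomposition:
    def test_purely_additive_snp_has_zero_dominance(self):
        dom = dominance_decomposition(GenotypicValues(1, 0, -1), hwe(0.5))
        assert (dom.d11, dom.d12, dom.d22) == pytest.approx((0, 0, 0), abs=1e-12)
        assert dom.delta == pytest.approx(0.0, abs=1e-12)
        assert dom.classification == "none"
        assert dom.recessive_allele is None

    def test_symmetric_overdominance(self):
        dom = dominance_decomposition(GenotypicValues(0, 1, 0), hwe(0.5))
        assert (dom.d11, dom.d12, dom.d22) == pytest.approx((-0.5, 0.5, -0.5))
        assert dom.delta == pytest.approx(1.0)
        assert dom.classification == "positive_overdominance"
        assert dom.recessive_allele is None  # tied homozygotes: undefined

    def test_recessive_allele_identification(self):
        # asymmetric: allele-1 homozygote clearly more negative
        f = hwe(0.1)
        dom = dominance_decomposition(GenotypicValues(-8.0, 0.8, 0.0), f)
        assert dom.classification == "positive_overdominance"
        assert dom.recessive_allele == 1
        mirrored = dominance_decomposition(GenotypicValues(0.0, 0.8, -8.0), hwe(0.9))
        assert mirrored.recessive_allele == 2

    def test_negative_overdominance(self):
        dom = dominance_decomposition(GenotypicValues(0, -1, 0), hwe(0.4))
        assert dom.classification == "negative_overdominance"

    @pytest.mark.parametrize(
        "d, expected",
        [((-9.76, 0.62, -0.06), 5.53), ((-9.72, 0.62, -0.06), 5.51)],
    )
    def test_reported_dominance_effect_reconstruction(self, d, expected):
        assert dominance_effect_from_values(*d) == pytest.approx(expected, abs=5e-3)

    @given(g=genotypic, counts=polymorphic_counts)
    @settings(derandomize=True, max_examples=100)
    def test_delta_identities(self, g, counts):
        f = SNPFrequencies.from_counts(*counts)
        if f.is_monomorphic:
            return
        gv = GenotypicValues(*g)
        dom = dominance_decomposition(gv, f)
        # delta in d space equals delta in g space (allelic effects cancel)
        assert dom.delta == pytest.approx(
            gv.g12 - 0.5 * (gv.g11 + gv.g22), abs=1e-10
        )

    @given(g=genotypic, p1=st.floats(0.02, 0.98))
    @settings(derandomize=True, max_examples=100)
    def test_hwe_dominance_values_average_to_zero(self, g, p1):
        f = hwe(p1)
        dom = dominance_decomposition(GenotypicValues(*g), f)
        total = f.P11 * dom.d11 + f.P12 * dom.d12 + f.P22 * dom.d22
        assert abs(total) < 1e-10
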