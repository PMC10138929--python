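"""Single-SNP quantitative-genetics decompositions.

Genotype codes count copies of allele 2: code 0 is genotype A1A1, code 1 is
A1A2, code 2 is A2A2.  All quantities are computed from the *observed*
genotype frequencies, so Hardy-Weinberg disequilibrium (HWD) is permitted
throughout; under HWE the formulas reduce to the familiar textbook forms.

Given the three genotypic values ``g11, g12, g22`` (phenotype units) and the
genotype frequencies of one biallelic SNP, this module provides

* the allelic means ``mu_i`` (conditional mean genotypic value of a gamete
  carrying allele i), the SNP genotypic mean ``mu``, the allelic effects
  ``a_i = mu_i - mu``, and the average effect of gene substitution
  ``alpha = mu_1 - mu_2``;
* the dominance values ``d_ij = g_ij - mu - a_i - a_j`` and the dominance
  effect ``delta = d12 - (d11 + d22)/2``, which equals
  ``g12 - (g11 + g22)/2`` because the allelic effects cancel;
* the frequency-adjusted additive contrast coefficients
  ``s_a = (P11/p1, 0.5*P12*(p2 - p1)/(p1*p2), -P22/p2)`` and the fixed
  dominance contrast coefficients ``s_d = (-0.5, 1, -0.5)``;
* overdominance classification: the heterozygote dominance value more
  extreme than both homozygote dominance values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "MonomorphicSNPError",
    "UntestableSNPError",
    "SNPFrequencies",
    "GenotypicValues",
    "AdditiveDecomposition",
    "DominanceDecomposition",
    "compute_snp_frequencies",
    "additive_contrast_coefficients",
    "dominance_contrast_coefficients",
    "additive_decomposition",
    "dominance_decomposition",
    "dominance_effect_from_values",
    "substitution_effect_from_allelic_effects",
    "allele_frequency_from_genotypes",
]

_EPS = 1e-12


class MonomorphicSNPError(ValueError):
    """The SNP carries only one allele; contrasts are undefined."""


class UntestableSNPError(ValueError):
    """The SNP has too little genotype information to support a test."""


@dataclass(frozen=True)
class SNPFrequencies:
    """Genotype and allele frequencies of one biallelic SNP (HWD allowed).

    ``n11, n12, n22`` are genotype counts over the non-missing records;
    frequency-only construction (e.g. from a published table) leaves the
    counts at zero.
    """

    n11: int
    n12: int
    n22: int
    P11: float
    P12: float
    P22: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n22) < 0:
            raise ValueError("genotype counts must be non-negative")
        if abs(self.P11 + self.P12 + self.P22 - 1.0) > 1e-9:
            raise ValueError("genotype frequencies must sum to 1")
        for name in ("P11", "P12", "P22", "p1", "p2"):
            v = getattr(self, name)
            if not (-_EPS <= v <= 1.0 + _EPS):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p1 - (self.P11 + 0.5 * self.P12)) > 1e-9:
            raise ValueError("p1 must equal P11 + P12/2")
        if abs(self.p1 + self.p2 - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")

    @classmethod
    def from_counts(cls, n11: int, n12: int, n22: int) -> "SNPFrequencies":
        n = n11 + n12 + n22
        if n <= 0:
            raise UntestableSNPError("no non-missing genotypes")
        P11, P12, P22 = n11 / n, n12 / n, n22 / n
        p1 = P11 + 0.5 * P12
        return cls(n11, n12, n22, P11, P12, P22, p1, 1.0 - p1)

    @classmethod
    def from_genotype_frequencies(
        cls, P11: float, P12: float, P22: float
    ) -> "SNPFrequencies":
        p1 = P11 + 0.5 * P12
        return cls(0, 0, 0, P11, P12, P22, p1, 1.0 - p1)

    @property
    def n(self) -> int:
        return self.n11 + self.n12 + self.n22

    @property
    def maf(self) -> float:
        return min(self.p1, self.p2)

    @property
    def is_monomorphic(self) -> bool:
        return self.maf <= 0.0

    # Conditional genotype frequencies given one sampled allele.
    @property
    def P11_1(self) -> float:
        return self.P11 / self.p1

    @property
    def P12_1(self) -> float:
        return self.P12 / self.p1

    @property
    def P12_2(self) -> float:
        return self.P12 / self.p2

    @property
    def P22_2(self) -> float:
        return self.P22 / self.p2


@dataclass(frozen=True)
class GenotypicValues:
    """Genotypic values of the three SNP genotypes, phenotype units."""

    g11: float
    g12: float
    g22: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.g11, self.g12, self.g22)):
            raise ValueError("genotypic values must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.g11, self.g12, self.g22], dtype=float)


@dataclass(frozen=True)
class AdditiveDecomposition:
    """Allelic means/effects and the average effect of gene substitution.

    ``a_i`` are deviations from the SNP's own genotypic mean ``mu``;
    ``ae_i`` are deviations from the cross-SNP mean ``mu_all`` and are the
    allelic effects comparable across SNPs.
    """

    mu1: float
    mu2: float
    mu: float
    a1: float
    a2: float
    ae1: float
    ae2: float
    alpha: float
    f1: float
    f2: float


Classification = Literal["positive_overdominance", "negative_overdominance", "none"]


@dataclass(frozen=True)
class DominanceDecomposition:
    """Dominance values, the dominance effect, and overdominance status.

    ``recessive_allele`` is identified only for positive overdominance: the
    allele whose homozygote has the strictly more negative dominance value
    (``None`` on ties or when there is no positive overdominance).
    """

    d11: float
    d12: float
    d22: float
    delta: float
    classification: Classification
    recessive_allele: Optional[int]


def compute_snp_frequencies(codes: Sequence[float]) -> SNPFrequencies:
    """Count genotypes over the non-missing entries of a code vector.

    Missing genotypes are NaN (or None).  Raises
    :class:`UntestableSNPError` when every entry is missing and
    ``ValueError`` on codes outside {0, 1, 2, NaN}.
    """
    arr = np.asarray(codes, dtype=float)
    present = ~np.isnan(arr)
    vals = arr[present]
    bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
    if bad.size:
        raise ValueError(f"invalid genotype code {bad[0]!r}; expected 0, 1, 2 or NaN")
    if vals.size == 0:
        raise UntestableSNPError("all genotypes missing for this SNP")
    n11 = int(np.count_nonzero(vals == 0.0))
    n12 = int(np.count_nonzero(vals == 1.0))
    n22 = int(np.count_nonzero(vals == 2.0))
    return SNPFrequencies.from_counts(n11, n12, n22)


def allele_frequency_from_genotypes(f_hom: float, f_het: float) -> float:
    """Frequency of an allele from its homozygote and heterozygote frequencies."""
    return f_hom + 0.5 * f_het


def _require_polymorphic(freqs: SNPFrequencies) -> None:
    if freqs.p1 <= 0.0 or freqs.p2 <= 0.0:
        raise MonomorphicSNPError(
            f"monomorphic SNP (p1={freqs.p1}); contrasts undefined"
        )


def additive_contrast_coefficients(freqs: SNPFrequencies) -> np.ndarray:
    """Frequency-adjusted additive contrast, valid under HWD.

    Returns ``(P11/p1, 0.5*P12*(p2 - p1)/(p1*p2), -P22/p2)``; under HWE this
    reduces to ``(p1, p2 - p1, -p2)``.  The coefficients always sum to zero,
    so the contrast is an estimable function of the genotype-class means.
    """
    _require_polymorphic(freqs)
    p1, p2 = freqs.p1, freqs.p2
    return np.array(
        [
            freqs.P11 / p1,
            0.5 * freqs.P12 * (p2 - p1) / (p1 * p2),
            -freqs.P22 / p2,
        ]
    )


def dominance_contrast_coefficients() -> np.ndarray:
    """Dominance contrast ``(-0.5, 1, -0.5)``; frequency-independent."""
    return np.array([-0.5, 1.0, -0.5])


def additive_decomposition(
    g: GenotypicValues, freqs: SNPFrequencies, mu_all: float = 0.0
) -> AdditiveDecomposition:
    """Allelic means, allelic effects and alpha for one SNP.

    ``mu_all`` is the average genotypic mean over all analysed SNPs; it only
    shifts the cross-SNP allelic effects ``ae_i`` and defaults to 0.
    """
    _require_polymorphic(freqs)
    if not math.isfinite(mu_all):
        raise ValueError("mu_all must be finite")
    mu1 = freqs.P11_1 * g.g11 + 0.5 * freqs.P12_1 * g.g12
    mu2 = 0.5 * freqs.P12_2 * g.g12 + freqs.P22_2 * g.g22
    mu = freqs.p1 * mu1 + freqs.p2 * mu2
    return AdditiveDecomposition(
        mu1=mu1,
        mu2=mu2,
        mu=mu,
        a1=mu1 - mu,
        a2=mu2 - mu,
        ae1=mu1 - mu_all,
        ae2=mu2 - mu_all,
        alpha=mu1 - mu2,
        f1=freqs.p1,
        f2=freqs.p2,
    )


def dominance_decomposition(
    g: GenotypicValues, freqs: SNPFrequencies
) -> DominanceDecomposition:
    """Dominance values ``d_ij = g_ij - mu - a_i - a_j`` and their contrast."""
    add = additive_decomposition(g, freqs)
    d11 = g.g11 - add.mu - 2.0 * add.a1
    d12 = g.g12 - add.mu - add.a1 - add.a2
    d22 = g.g22 - add.mu - 2.0 * add.a2
    delta = d12 - 0.5 * (d11 + d22)

    classification: Classification = "none"
    recessive: Optional[int] = None
    if d12 > d11 and d12 > d22:
        classification = "positive_overdominance"
        if d11 < d22:
            recessive = 1
        elif d22 < d11:
            recessive = 2
    elif d12 < d11 and d12 < d22:
        classification = "negative_overdominance"
    return DominanceDecomposition(d11, d12, d22, delta, classification, recessive)


def dominance_effect_from_values(d11: float, d12: float, d22: float) -> float:
    """Dominance effect ``delta`` from reported dominance values."""
    return d12 - 0.5 * (d11 + d22)


def substitution_effect_from_allelic_effects(ae1: float, ae2: float) -> float:
    """alpha from the two (cross-SNP comparable) allelic effects: ae1 - ae2."""
    return ae1 - ae2
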