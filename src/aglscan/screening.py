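"""Post-scan screening: overdominance features, population-mean contributions,
and the recessive-genotype culling statistics.

The rare-recessive overdominance pattern has five recognizable features: a
recessive homozygote with a very negative dominance value, a heterozygote
dominance value that is positive but small, a dominant homozygote near
zero, a recessive allele frequency below ~0.10, and a recessive genotype
frequency below ~0.01.  SNPs with that pattern support a concrete herd
decision: heifers homozygous for the recessive allele calve substantially
later (and yield less), so they are culling candidates.  The *negative
impact* of a recessive genotype is the mean phenotype of its carriers minus
the average of the other two genotype-class means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .quantgen import DominanceDecomposition, SNPFrequencies

__all__ = [
    "OverdominanceThresholds",
    "OverdominanceFeatures",
    "CullingReport",
    "CullingSummary",
    "contribution_to_mean",
    "negative_impact",
    "negative_impact_from_phenotypes",
    "flag_cull_candidates",
    "overdominance_features",
]

GenotypeLabel = Union[str, int]  # "11" / "22" (or allele 1 / 2)


def _recessive_code(recessive: GenotypeLabel) -> int:
    """Genotype code of the recessive homozygote from a label or allele."""
    label = str(recessive)
    if label in ("11", "1"):
        return 0
    if label in ("22", "2"):
        return 2
    raise ValueError(f"recessive genotype must be 11 or 22, got {recessive!r}")


def contribution_to_mean(d: float, f: float) -> float:
    """Contribution ``d * f`` of one genotype class to the population mean
    of the SNP's dominance values."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"genotype frequency {f} outside [0, 1]")
    return d * f


def negative_impact(
    y_means: Sequence[float], recessive: GenotypeLabel
) -> float:
    """Mean phenotype of recessive homozygotes minus the average of the
    other two genotype-class means.

    ``y_means`` is ``(y11, y12, y22)``; for recessive genotype 11 this is
    ``y11 - (y12 + y22)/2``.  Negative values on the negative-days scale
    mean later calving for recessive-homozygous animals.  Invariant to
    adding a constant to all three means.
    """
    y11, y12, y22 = (float(v) for v in y_means)
    if not all(np.isfinite([y11, y12, y22])):
        raise ValueError("all three genotype-class means are required")
    if _recessive_code(recessive) == 0:
        return y11 - 0.5 * (y12 + y22)
    return y22 - 0.5 * (y11 + y12)


def negative_impact_from_phenotypes(
    y: Sequence[float], codes: Sequence[float], recessive: GenotypeLabel
) -> float:
    """Negative impact computed from raw records (complete-case per SNP)."""
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes, dtype=float)
    keep = ~np.isnan(codes)
    y, codes = y[keep], codes[keep]
    means = []
    for c in range(3):
        cls = y[codes == c]
        if cls.size == 0:
            raise ValueError(f"genotype class {c} is empty")
        means.append(cls.mean())
    return negative_impact(means, recessive)


@dataclass(frozen=True)
class CullingReport:
    """Carriers of one SNP's recessive homozygous genotype."""

    snp_id: str
    recessive_genotype: str
    carrier_animals: tuple
    negative_impact: Optional[float] = None

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_animals)

    def to_row(self) -> dict:
        return {
            "snp": self.snp_id,
            "recessive_genotype": self.recessive_genotype,
            "n_carriers": self.n_carriers,
            "negative_impact": self.negative_impact,
        }


@dataclass(frozen=True)
class CullingSummary:
    """Per-SNP culling reports plus the any-of-list carrier count."""

    reports: tuple[CullingReport, ...]
    any_carriers: tuple

    @property
    def n_any(self) -> int:
        return len(self.any_carriers)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.reports])


def flag_cull_candidates(
    genotypes: pd.DataFrame,
    snp_ids: Sequence[str],
    recessive_labels: Mapping[str, GenotypeLabel],
    phenotypes: Optional[pd.Series] = None,
) -> CullingSummary:
    """List animals homozygous for the recessive allele at each listed SNP.

    ``genotypes`` is animals x SNPs (index = animal ids).  When a phenotype
    series aligned to the same animals is supplied, each report also carries
    the realized negative impact.  Raises on SNP ids absent from the matrix.
    """
    missing = [s for s in snp_ids if s not in genotypes.columns]
    if missing:
        raise ValueError(f"unknown snp_id(s): {missing}")
    reports = []
    any_mask = np.zeros(len(genotypes), dtype=bool)
    for snp in snp_ids:
        code = _recessive_code(recessive_labels[snp])
        col = genotypes[snp].to_numpy(dtype=float)
        mask = col == code
        any_mask |= mask
        impact = None
        if phenotypes is not None:
            impact = negative_impact_from_phenotypes(
                phenotypes.to_numpy(dtype=float), col, recessive_labels[snp]
            )
        reports.append(
            CullingReport(
                snp_id=str(snp),
                recessive_genotype="11" if code == 0 else "22",
                carrier_animals=tuple(genotypes.index[mask]),
                negative_impact=impact,
            )
        )
    return CullingSummary(
        reports=tuple(reports), any_carriers=tuple(genotypes.index[any_mask])
    )


@dataclass(frozen=True)
class OverdominanceThresholds:
    """Cutoffs for the five rare-recessive overdominance features.

    Defaults follow the observed pattern at study scale: recessive
    homozygote dominance value below -5 days; heterozygote dominance value
    positive yet small *relative to the recessive homozygote's* (under a
    quarter of |d_RR| -- "small" is inherently relative here, the observed
    ratios being ~1/15); dominant homozygote within 0.5 days of zero;
    recessive allele frequency under 0.10; recessive genotype frequency
    under 0.01.
    """

    d_recessive_max: float = -5.0
    d_het_ratio_max: float = 0.25
    d_dominant_abs_max: float = 0.5
    recessive_allele_freq_max: float = 0.10
    recessive_genotype_freq_max: float = 0.01


@dataclass(frozen=True)
class OverdominanceFeatures:
    recessive_hom_very_negative: bool
    het_positive_small: bool
    dominant_hom_near_zero: bool
    recessive_allele_rare: bool
    recessive_genotype_rare: bool

    @property
    def n_true(self) -> int:
        return sum(
            (
                self.recessive_hom_very_negative,
                self.het_positive_small,
                self.dominant_hom_near_zero,
                self.recessive_allele_rare,
                self.recessive_genotype_rare,
            )
        )

    @property
    def all_features(self) -> bool:
        return self.n_true == 5


def overdominance_features(
    dom: DominanceDecomposition,
    freqs: SNPFrequencies,
    thresholds: OverdominanceThresholds = OverdominanceThresholds(),
) -> OverdominanceFeatures:
    """Check the five-feature rare-recessive overdominance pattern.

    Without an identified recessive allele (no positive overdominance, or a
    tied pair of homozygote dominance values) every flag is False.
    """
    if dom.recessive_allele == 1:
        d_rr, d_dd = dom.d11, dom.d22
        f_r, f_rr = freqs.p1, freqs.P11
    elif dom.recessive_allele == 2:
        d_rr, d_dd = dom.d22, dom.d11
        f_r, f_rr = freqs.p2, freqs.P22
    else:
        return OverdominanceFeatures(False, False, False, False, False)
    t = thresholds
    return OverdominanceFeatures(
        recessive_hom_very_negative=d_rr < t.d_recessive_max,
        het_positive_small=0.0 < dom.d12 < t.d_het_ratio_max * abs(d_rr),
        dominant_hom_near_zero=abs(d_dd) <= t.d_dominant_abs_max,
        recessive_allele_rare=f_r < t.recessive_allele_freq_max,
        recessive_genotype_rare=f_rr < t.recessive_genotype_freq_max,
    )
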