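"""Pedigreed-population simulator with retained ground truth.

Generates the statistical structure the association analysis assumes, at
desk scale: founder genotypes drawn at configured allele frequencies,
descendants by Mendelian gene dropping through a dairy-like mating design
(few sires per generation, so strong paternal half-sib families),
polygenic values with covariance sigma_a^2 * A sampled by the Mendelian
sampling recursion, Gaussian residuals, and polygenic predictions in four
modes: the exact BLUP of the polygenic term (oracle adjustment), a
routine-evaluation-style BLUP computed from the raw phenotypes (which
absorbs part of any causal additive signal, as real PTAs do), the latter
degraded by reliability-scaled noise, or zero for an unadjusted analysis.

SNPs are unlinked; there is no LD along chromosomes and no selection.
Phenotypes are generated directly on the residual scale (the fixed
non-genetic effects a routine evaluation removes are not modelled).

Default variance components are sigma_a^2 = 10 and sigma_e^2 = 90 days^2:
a phenotypic SD of 10 days on the age-at-first-calving residual scale and
a narrow-sense heritability of 0.10, in line with the low heritability of
calving-age traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .agls import PhenotypeTable
from .blup import MixedModelSpec, Pedigree, build_A, solve_mme
from .quantgen import (
    GenotypicValues,
    SNPFrequencies,
    additive_decomposition,
    compute_snp_frequencies,
    dominance_decomposition,
)

__all__ = [
    "CausalSNP",
    "SimulationConfig",
    "CausalTruth",
    "SyntheticTruth",
    "SimulatedPopulation",
    "simulate_population",
    "sample_polygenic",
    "make_overdominant_causal",
]

PtaMode = Literal["exact_blup", "evaluation_blup", "noisy", "zero"]
N_CHROMOSOMES = 29  # bovine autosomes, for the synthetic SNP map
SNP_SPACING_BP = 50_000


@dataclass(frozen=True)
class CausalSNP:
    """A causal SNP: index into the simulated panel, its genotypic values,
    and optionally a pinned founder frequency of allele 2."""

    index: int
    g: GenotypicValues
    freq2: Optional[float] = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated population.

    The population grows from ``n_founders`` unrelated animals through
    ``n_generations`` of random matings; each generation has
    ``generation_size`` offspring (default: same as the founder count)
    sired by ``n_sires`` males, in full-sib litters of
    ``offspring_per_mating``.  ``maf_range`` bounds the founder minor
    allele frequencies (the analysis filter is 0.05, so founders start at
    or above it).  ``sigma2_a = 0`` is allowed as the degenerate
    no-polygenics case.
    """

    n_founders: int = 200
    n_generations: int = 2
    generation_size: Optional[int] = None
    offspring_per_mating: int = 2
    n_sires: int = 10
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal: tuple[CausalSNP, ...] = ()
    sigma2_a: float = 10.0
    sigma2_e: float = 90.0
    pta_mode: PtaMode = "exact_blup"
    pta_reliability: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e <= 0:
            raise ValueError("need sigma2_a >= 0 and sigma2_e > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for c in self.causal:
            if not (0 <= c.index < self.n_snps):
                raise ValueError(f"causal index {c.index} outside the SNP panel")
            if c.freq2 is not None and not (0 < c.freq2 < 1):
                raise ValueError("pinned causal frequency must be in (0, 1)")
        if self.pta_mode not in ("exact_blup", "evaluation_blup", "noisy", "zero"):
            raise ValueError(f"unknown pta_mode {self.pta_mode!r}")
        if self.n_sires < 1 or self.offspring_per_mating < 1:
            raise ValueError("need at least one sire and one offspring per mating")
        if self.n_founders < 2 * self.n_sires:
            raise ValueError("founders must outnumber twice the sires (need dams)")

    @property
    def gen_size(self) -> int:
        return self.generation_size or self.n_founders

    @property
    def n_animals(self) -> int:
        return self.n_founders + self.n_generations * self.gen_size


@dataclass(frozen=True)
class CausalTruth:
    """One causal SNP with its realized-frequency effect decomposition."""

    index: int
    snp: str
    g: GenotypicValues
    freqs: SNPFrequencies
    alpha: float
    delta: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    breeding_values: np.ndarray
    causal: tuple[CausalTruth, ...]
    founder_freq2: np.ndarray  # founder sampling frequency of allele 2


@dataclass(frozen=True)
class SimulatedPopulation:
    pedigree: Pedigree
    genotypes: pd.DataFrame  # animals x SNPs, codes 0/1/2
    snp_map: pd.DataFrame  # snp, chr, pos
    phenotypes: PhenotypeTable
    truth: SyntheticTruth


def _mating_plan(cfg: SimulationConfig, rng: np.random.Generator):
    """Yield (sire_idx, dam_idx) per offspring, generation by generation."""
    plan = []
    prev = np.arange(cfg.n_founders)
    next_id = cfg.n_founders
    for _gen in range(cfg.n_generations):
        sires = rng.choice(prev, size=min(cfg.n_sires, len(prev) // 2), replace=False)
        dams_pool = np.setdiff1d(prev, sires)
        n_off = cfg.gen_size
        n_matings = math.ceil(n_off / cfg.offspring_per_mating)
        if n_matings > len(dams_pool):
            mating_dams = rng.choice(dams_pool, size=n_matings, replace=True)
        else:
            mating_dams = rng.choice(dams_pool, size=n_matings, replace=False)
        mating_sires = rng.choice(sires, size=n_matings, replace=True)
        born = []
        for m in range(n_matings):
            for _ in range(cfg.offspring_per_mating):
                if len(born) == n_off:
                    break
                plan.append((int(mating_sires[m]), int(mating_dams[m])))
                born.append(next_id)
                next_id += 1
        prev = np.array(born)
        if len(prev) == 0:
            raise ValueError("infeasible mating structure: empty generation")
    return plan


def _drop_genotypes(
    cfg: SimulationConfig,
    plan: list[tuple[int, int]],
    freq2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder draws plus per-locus Mendelian transmission (unlinked SNPs)."""
    n = cfg.n_animals
    G = np.empty((n, cfg.n_snps), dtype=np.int8)
    G[: cfg.n_founders] = rng.binomial(2, freq2, size=(cfg.n_founders, cfg.n_snps))
    for row, (s, d) in enumerate(plan, start=cfg.n_founders):
        t_s = rng.random(cfg.n_snps) < G[s] / 2.0
        t_d = rng.random(cfg.n_snps) < G[d] / 2.0
        G[row] = t_s.astype(np.int8) + t_d.astype(np.int8)
    return G


def sample_polygenic(
    ped: Pedigree,
    sigma2_a: float,
    rng: np.random.Generator,
    A: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw a ~ N(0, sigma2_a * A) by the Mendelian-sampling recursion.

    a_i = 0.5 (a_s + a_d) + m_i with Mendelian-sampling variance
    sigma2_a * (0.5 - 0.25 (F_s + F_d)) for two known parents,
    sigma2_a * (0.75 - 0.25 F_p) for one, and sigma2_a for founders.
    Exact for any (inbred) pedigree; A supplies the inbreeding
    coefficients and is computed if not given.
    """
    if sigma2_a == 0.0:
        return np.zeros(ped.n)
    if A is None:
        A = build_A(ped)
    F = np.diag(A) - 1.0
    a = np.empty(ped.n)
    z = rng.standard_normal(ped.n)
    for i in range(ped.n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        if s >= 0 and d >= 0:
            mean = 0.5 * (a[s] + a[d])
            var = sigma2_a * (0.5 - 0.25 * (F[s] + F[d]))
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mean = 0.5 * a[p]
            var = sigma2_a * (0.75 - 0.25 * F[p])
        else:
            mean, var = 0.0, sigma2_a
        a[i] = mean + math.sqrt(var) * z[i]
    return a


def _synthetic_map(n_snps: int) -> pd.DataFrame:
    snp = [f"snp{j + 1:06d}" for j in range(n_snps)]
    per_chrom = math.ceil(n_snps / N_CHROMOSOMES)
    chrom = [(j // per_chrom) + 1 for j in range(n_snps)]
    pos = [((j % per_chrom) + 1) * SNP_SPACING_BP for j in range(n_snps)]
    return pd.DataFrame({"snp": snp, "chr": chrom, "pos": pos})


def simulate_population(cfg: SimulationConfig) -> SimulatedPopulation:
    """Simulate a pedigreed, genotyped, phenotyped population.

    Fully reproducible from ``cfg.seed`` (one master seed; independent
    child streams for mating/genotypes, polygenics, residuals, and PTA
    noise).  Phenotypes are ``y = sum of causal genotypic values + a + e``.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_geno = np.random.default_rng(ss[0])
    rng_poly = np.random.default_rng(ss[1])
    rng_resid = np.random.default_rng(ss[2])
    rng_pta = np.random.default_rng(ss[3])

    # founder allele-2 frequencies: MAF in range, minor allele on a random side
    maf = rng_geno.uniform(*cfg.maf_range, size=cfg.n_snps)
    flip = rng_geno.random(cfg.n_snps) < 0.5
    freq2 = np.where(flip, 1.0 - maf, maf)
    for c in cfg.causal:
        if c.freq2 is not None:
            freq2[c.index] = c.freq2

    plan = _mating_plan(cfg, rng_geno)
    G = _drop_genotypes(cfg, plan, freq2, rng_geno)

    n = cfg.n_animals
    ids = tuple(range(1, n + 1))
    sire = np.full(n, -1, dtype=int)
    dam = np.full(n, -1, dtype=int)
    for row, (s, d) in enumerate(plan, start=cfg.n_founders):
        sire[row], dam[row] = s, d
    ped = Pedigree(ids=ids, sire=sire, dam=dam)

    A = build_A(ped)
    a = sample_polygenic(ped, cfg.sigma2_a, rng_poly, A=A)
    e = rng_resid.normal(0.0, math.sqrt(cfg.sigma2_e), size=n)

    y_causal = np.zeros(n)
    for c in cfg.causal:
        y_causal = y_causal + c.g.as_array()[G[:, c.index]]
    y = y_causal + a + e

    a_tilde = _polygenic_prediction(cfg, y, y_causal, A, rng_pta)

    snp_map = _synthetic_map(cfg.n_snps)
    genotypes = pd.DataFrame(G, index=list(ids), columns=snp_map["snp"].tolist())
    genotypes.index.name = "animal"
    phenotypes = PhenotypeTable(
        animal_id=np.array(ids), y=y, a_tilde=a_tilde
    )

    causal_truth = []
    for c in cfg.causal:
        freqs = compute_snp_frequencies(G[:, c.index])
        add = additive_decomposition(c.g, freqs)
        dom = dominance_decomposition(c.g, freqs)
        causal_truth.append(
            CausalTruth(
                index=c.index,
                snp=snp_map["snp"].iloc[c.index],
                g=c.g,
                freqs=freqs,
                alpha=add.alpha,
                delta=dom.delta,
            )
        )
    truth = SyntheticTruth(
        breeding_values=a, causal=tuple(causal_truth), founder_freq2=freq2
    )
    return SimulatedPopulation(ped, genotypes, snp_map, phenotypes, truth)


def _polygenic_prediction(
    cfg: SimulationConfig,
    y: np.ndarray,
    y_causal: np.ndarray,
    A: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Polygenic adjustment per pta_mode.

    ``exact_blup`` is the exact BLUP of the model's polygenic term: the MME
    are solved on the polygenic-plus-residual part of the phenotype, which
    the simulator knows.  ``evaluation_blup`` solves the same intercept-only
    MME on the raw phenotype, the way a routine pedigree evaluation would;
    because causal SNP effects are heritable, that prediction absorbs part
    of them and attenuates the downstream additive estimates (proximal
    contamination).  ``noisy`` degrades evaluation_blup with
    reliability-scaled noise; ``zero`` disables the adjustment.
    """
    if cfg.pta_mode == "zero" or cfg.sigma2_a == 0.0:
        return np.zeros(len(y))
    spec = MixedModelSpec(sigma2_a=cfg.sigma2_a, sigma2_e=cfg.sigma2_e, A=A)
    X = np.ones((len(y), 1))
    if cfg.pta_mode == "exact_blup":
        _, a_hat = solve_mme(y - y_causal, X, None, spec)
        return a_hat
    _, a_hat = solve_mme(y, X, None, spec)
    if cfg.pta_mode == "evaluation_blup":
        return a_hat
    noise_var = (1.0 - cfg.pta_reliability) * float(np.var(a_hat))
    return a_hat + rng.normal(0.0, math.sqrt(noise_var), size=len(y))


def make_overdominant_causal(
    f_R: float,
    d_RR: float,
    d_DR: Optional[float] = None,
    recessive_allele: int = 1,
) -> GenotypicValues:
    """Genotypic values of a rare-recessive overdominant SNP.

    Constructs ``g`` (zero mean, zero additive part at HWE(f_R)) such that
    the dominance decomposition at Hardy-Weinberg frequencies for recessive
    allele frequency ``f_R`` returns exactly ``d_RR`` for the recessive
    homozygote.  At HWE the three dominance values have a single degree of
    freedom -- d_hom(rec) = -2 q^2 delta, d_het = 2 r q delta,
    d_hom(dom) = -2 r^2 delta for r = f_R, q = 1 - f_R -- so the
    heterozygote value is implied, not free; an explicit ``d_DR`` is only
    checked for sign consistency with the implied value.
    """
    if not (0.0 < f_R < 0.5):
        raise ValueError("recessive allele frequency must be in (0, 0.5)")
    if recessive_allele not in (1, 2):
        raise ValueError("recessive_allele must be 1 or 2")
    r, q = f_R, 1.0 - f_R
    delta = -d_RR / (2.0 * q * q)
    d_het = 2.0 * r * q * delta
    if d_DR is not None and d_DR * d_het < 0.0:
        raise ValueError(
            f"requested heterozygote dominance value {d_DR} conflicts in sign "
            f"with the HWE-implied value {d_het:.4g}"
        )
    d_other = -2.0 * r * r * delta
    if recessive_allele == 1:
        return GenotypicValues(d_RR, d_het, d_other)
    return GenotypicValues(d_other, d_het, d_RR)
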