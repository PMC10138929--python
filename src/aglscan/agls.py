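"""Approximate generalized least squares (AGLS) single-SNP association tests.

The analysis model for a quantitative record is

    y = mu + g(SNP genotype) + a + e,

with polygenic values ``a ~ N(0, sigma_a^2 A)`` for pedigree relationship
matrix A.  Exact GLS (or the equivalent mixed-model equations) is infeasible
when A cannot be inverted, so AGLS pre-adjusts the phenotype with a polygenic
prediction that is already available -- twice the predicted transmitting
ability (2*PTA) from routine evaluation, or an exact BLUP at desk scale --
and then applies ordinary least squares per SNP:

    y* = y - a_tilde,     g_hat_ij = mean of y* in genotype class ij.

Because the fixed design (intercept + three genotype indicators) is
rank-deficient, only estimable functions are reported; both the additive and
dominance contrast coefficient vectors sum to zero, so the contrasts are
invariant to the choice of generalized inverse and equal the same contrasts
of the genotype-class means.  The t statistic for contrast L = s'g_hat is

    t = |L| / sqrt(v2 * sum_j s_j^2 / n_j),   v2 = RSS / (n - k),

with k the number of non-empty genotype classes.  Tail probabilities are
evaluated in log space so genome-wide significance (log10(1/p) of 30+ in
large samples) does not underflow.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special, stats

from .quantgen import GenotypicValues, UntestableSNPError

__all__ = [
    "PhenotypeTable",
    "GenotypicValueEstimates",
    "ContrastTest",
    "ScanConfig",
    "adjust_phenotypes",
    "fit_snp",
    "contrast_test",
    "genome_scan",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)
_LN2 = math.log(2.0)


@dataclass
class PhenotypeTable:
    """Aligned phenotypic residuals and polygenic predictions per animal.

    ``y`` is the phenotypic residual after removing fixed non-genetic
    effects (negative-days scale for age at first calving); ``a_tilde`` is
    the polygenic adjustment (2*PTA, an exact BLUP, or zeros for an
    unadjusted analysis).
    """

    animal_id: np.ndarray
    y: np.ndarray
    a_tilde: np.ndarray

    def __post_init__(self) -> None:
        self.animal_id = np.asarray(self.animal_id)
        self.y = np.asarray(self.y, dtype=float)
        self.a_tilde = np.asarray(self.a_tilde, dtype=float)
        if not (len(self.animal_id) == len(self.y) == len(self.a_tilde)):
            raise ValueError(
                "animal_id, y and a_tilde must have equal length "
                f"({len(self.animal_id)}, {len(self.y)}, {len(self.a_tilde)})"
            )
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotypes y must be finite")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhenotypeTable":
        a_tilde = (
            df["a_tilde"].to_numpy(float)
            if "a_tilde" in df.columns
            else np.zeros(len(df))
        )
        return cls(df["animal_id"].to_numpy(), df["y"].to_numpy(float), a_tilde)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal_id": self.animal_id, "y": self.y, "a_tilde": self.a_tilde}
        )


def adjust_phenotypes(table: PhenotypeTable) -> np.ndarray:
    """Polygenically adjusted phenotypes ``y* = y - a_tilde``."""
    return table.y - table.a_tilde


@dataclass(frozen=True)
class GenotypicValueEstimates:
    """Per-SNP AGLS estimates of the three genotypic values.

    Empty genotype classes carry NaN estimates; ``k`` is the number of
    non-empty classes (the rank of the cell-means design) and ``v2`` the
    pooled within-class residual variance with ``n - k`` degrees of freedom.
    """

    g_hat: GenotypicValues
    class_counts: tuple[int, int, int]
    v2: float
    n: int
    k: int
    dominance_testable: bool = True

    def __post_init__(self) -> None:
        if self.n != sum(self.class_counts):
            raise ValueError("n must equal the sum of class counts")
        if self.k > 3:
            raise ValueError("k cannot exceed 3")
        if math.isfinite(self.v2) and self.v2 < 0:
            raise ValueError("v2 must be non-negative")


@dataclass(frozen=True)
class ContrastTest:
    """One contrast of the estimated genotypic values with its t test.

    When the p-value underflows double precision it is stored as 0.0 and
    ``underflow`` is set; ``neglog10p`` remains exact (computed in log
    space).  ``zero_variance`` flags a nonzero contrast with an estimated
    standard error of zero.
    """

    L: float
    se: float
    t: float
    p: float
    neglog10p: float
    df: float
    underflow: bool = False
    zero_variance: bool = False


def fit_snp(
    y_star: Sequence[float],
    codes: Sequence[float],
    min_class_count: int = 1,
) -> GenotypicValueEstimates:
    """Estimate g11, g12, g22 as genotype-class means of adjusted phenotypes.

    Missing codes (NaN) drop the record for this SNP (per-SNP complete
    case).  Classes with fewer than ``min_class_count`` records are treated
    as empty for estimation.  Raises :class:`UntestableSNPError` when fewer
    than two classes remain; an empty heterozygote class leaves the SNP
    additive-testable but flags the dominance contrast untestable.
    """
    y_star = np.asarray(y_star, dtype=float)
    codes = np.asarray(codes, dtype=float)
    if y_star.shape != codes.shape:
        raise ValueError("y_star and codes must be aligned")
    keep = ~np.isnan(codes)
    y_star, codes = y_star[keep], codes[keep]

    means = np.full(3, np.nan)
    counts = np.zeros(3, dtype=int)
    rss = 0.0
    for c in range(3):
        in_class = codes == c
        n_c = int(in_class.sum())
        if n_c < max(min_class_count, 1):
            continue  # below the estimation floor: treat as empty
        counts[c] = n_c
        means[c] = y_star[in_class].mean()
        rss += float(np.sum((y_star[in_class] - means[c]) ** 2))
    k = int(np.count_nonzero(counts))
    n = int(counts.sum())
    if k < 2:
        raise UntestableSNPError(
            f"only {k} non-empty genotype class(es); SNP untestable"
        )
    v2 = rss / (n - k) if n > k else float("nan")
    return GenotypicValueEstimates(
        g_hat=_genotypic_values_allow_nan(means),
        class_counts=(int(counts[0]), int(counts[1]), int(counts[2])),
        v2=v2,
        n=n,
        k=k,
        dominance_testable=bool(np.all(counts > 0)),
    )


def _genotypic_values_allow_nan(means: np.ndarray) -> GenotypicValues:
    # GenotypicValues insists on finite entries; bypass for empty classes,
    # whose contrast coefficients are required to vanish before use.
    gv = object.__new__(GenotypicValues)
    object.__setattr__(gv, "g11", float(means[0]))
    object.__setattr__(gv, "g12", float(means[1]))
    object.__setattr__(gv, "g22", float(means[2]))
    return gv


def _t_logsf(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Student-t log survival function, stable for extreme statistics.

    Where scipy's logsf underflows to -inf at finite t, substitute the
    leading term of the regularized incomplete beta expansion:
    sf = 0.5 * I_x(df/2, 1/2) with x = df/(df + t^2), and
    I_x(a, b) ~ x^a / (a * B(a, b)) as x -> 0.
    """
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    with np.errstate(invalid="ignore"):
        out = stats.t.logsf(t, df)
    bad = np.isneginf(out) & np.isfinite(t)
    if np.any(bad):
        a = np.broadcast_to(df, out.shape)[bad] / 2.0
        tb = np.broadcast_to(t, out.shape)[bad]
        x = 2.0 * a / (2.0 * a + tb * tb)
        out = np.array(out, copy=True)
        out[bad] = (
            a * np.log(x) - np.log(a) - special.betaln(a, 0.5) - _LN2
        )
    return out


def _log_two_sided_p(t: float, df: float, df_mode: str) -> float:
    if df_mode == "normal":
        return _LN2 + stats.norm.logsf(t)
    return _LN2 + float(_t_logsf(np.asarray(t), np.asarray(df)))


def contrast_test(
    est: GenotypicValueEstimates,
    s: Sequence[float],
    df_mode: str = "t",
) -> ContrastTest:
    """t test of the contrast ``L = s' g_hat`` under the cell-means fit.

    Every class with a nonzero coefficient must be non-empty (for the
    frequency-adjusted additive contrast this holds by construction, since
    an empty class has zero observed frequency and hence a zero
    coefficient).  ``df_mode`` chooses Student-t (``"t"``, default) or the
    normal approximation (``"normal"``) for the tail probability.
    """
    if df_mode not in ("t", "normal"):
        raise ValueError(f"df_mode must be 't' or 'normal', got {df_mode!r}")
    s = np.asarray(s, dtype=float)
    counts = np.asarray(est.class_counts, dtype=float)
    g = est.g_hat.as_array()
    active = s != 0.0
    if np.any(active & (counts == 0)):
        raise UntestableSNPError(
            "contrast places weight on an empty genotype class"
        )
    df = est.n - est.k
    if df <= 0:
        raise UntestableSNPError("no residual degrees of freedom")
    L = float(np.sum(s[active] * g[active]))
    var_L = est.v2 * float(np.sum(s[active] ** 2 / counts[active]))
    se = math.sqrt(var_L)

    if se == 0.0:
        if L == 0.0:
            return ContrastTest(L, 0.0, 0.0, 1.0, 0.0, df)
        return ContrastTest(
            L, 0.0, math.inf, 0.0, math.inf, df, underflow=True, zero_variance=True
        )
    t = abs(L) / se
    logp = min(0.0, _log_two_sided_p(t, df, df_mode))
    p = math.exp(logp)
    return ContrastTest(
        L=L,
        se=se,
        t=t,
        p=p,
        neglog10p=-logp / _LN10,
        df=df,
        underflow=(p == 0.0),
    )


@dataclass(frozen=True)
class ScanConfig:
    """Settings of a genome scan.

    ``maf_min`` is the minor-allele-frequency filter; ``threshold`` the
    genome-wide significance level on the log10(1/p) scale (the Bonferroni
    constant used at study scale); ``min_dominance_class_count`` guards the
    dominance test against nearly empty homozygote classes, whose tiny
    counts would otherwise dominate var(L).
    """

    maf_min: float = 0.05
    threshold: float = 8.0
    df_mode: str = "t"
    min_class_count: int = 1
    min_dominance_class_count: int = 10
    chunk_size: int = 2048

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


RESULT_COLUMNS = [
    "snp", "chr", "pos", "n", "n11", "n12", "n22",
    "p1", "p2", "maf", "P11", "P12", "P22",
    "g11", "g12", "g22", "v2",
    "mu", "mu1", "mu2", "a1", "a2", "ae1", "ae2",
    "alpha", "se_additive", "t_additive", "p_additive",
    "neglog10p_additive", "significant_additive",
    "delta", "d11", "d12", "d22",
    "se_dominance", "t_dominance", "p_dominance",
    "neglog10p_dominance", "significant_dominance", "dominance_testable",
    "classification", "recessive_allele",
]


def _vector_neglog10p(
    t: np.ndarray, df: np.ndarray, df_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """(p, log10(1/p)) for |t| statistics, evaluated in log space."""
    with np.errstate(invalid="ignore"):
        if df_mode == "normal":
            logsf = stats.norm.logsf(t)
        else:
            logsf = _t_logsf(t, df)
    logp = np.minimum(0.0, _LN2 + logsf)
    logp = np.where(np.isinf(t), -np.inf, logp)
    logp = np.where(np.isnan(t), np.nan, logp)
    with np.errstate(over="ignore"):
        p = np.exp(logp)
    return p, -logp / _LN10


def genome_scan(
    phenotypes: PhenotypeTable,
    genotypes: Union[pd.DataFrame, np.ndarray],
    snp_map: Optional[pd.DataFrame] = None,
    config: Optional[ScanConfig] = None,
) -> pd.DataFrame:
    """Additive and dominance scan of every SNP passing the MAF filter.

    ``genotypes`` is an animals x SNPs matrix of codes {0, 1, 2, NaN}; a
    DataFrame is aligned to ``phenotypes.animal_id`` by its index.  The
    returned table carries, per SNP, the genotype/allele frequencies, the
    AGLS genotypic-value estimates, the full additive and dominance
    decompositions (allelic effects ``ae_i`` are reported against the
    unweighted mean ``mu_all`` of the genotypic means of all passing SNPs),
    both contrast tests, and significance flags at
    ``neglog10p > config.threshold``.  Deterministic given its inputs.
    """
    config = config or ScanConfig()

    if isinstance(genotypes, pd.DataFrame):
        missing = np.setdiff1d(phenotypes.animal_id, genotypes.index.to_numpy())
        if missing.size:
            raise ValueError(f"genotypes missing for animals {missing[:5]!r}")
        G = genotypes.loc[phenotypes.animal_id].to_numpy(dtype=float)
        snp_ids = np.asarray(genotypes.columns)
    else:
        G = np.asarray(genotypes, dtype=float)
        if snp_map is not None:
            snp_ids = snp_map["snp"].to_numpy()
        else:
            snp_ids = np.array([f"snp{j}" for j in range(G.shape[1])])
    if G.shape[0] != len(phenotypes):
        raise ValueError("genotype rows must match phenotype records")

    y = adjust_phenotypes(phenotypes)
    y2 = y * y
    n_snps = G.shape[1]

    frames = []
    n_failed_maf = 0
    for start in range(0, n_snps, config.chunk_size):
        stop = min(start + config.chunk_size, n_snps)
        chunk = _scan_chunk(y, y2, G[:, start:stop], snp_ids[start:stop], config)
        n_failed_maf += chunk.attrs["n_failed_maf"]
        frames.append(chunk)

    if frames:
        res = pd.concat(frames, ignore_index=True)
    else:
        res = pd.DataFrame(columns=RESULT_COLUMNS)
    if res.empty:
        warnings.warn("no SNPs pass the MAF filter; empty results", stacklevel=2)
        res = pd.DataFrame(columns=RESULT_COLUMNS)
        logger.info("scan: 0/%d SNPs pass MAF >= %s", n_snps, config.maf_min)
        return res

    mu_all = float(res["mu"].mean())
    res["ae1"] = res["mu1"] - mu_all
    res["ae2"] = res["mu2"] - mu_all

    if snp_map is not None:
        res = res.drop(columns=["chr", "pos"]).merge(
            snp_map[["snp", "chr", "pos"]], on="snp", how="left"
        )
    res = res[RESULT_COLUMNS]
    logger.info(
        "scan: %d SNPs read, %d failed MAF < %s, %d tested, mu_all=%.6g, "
        "%d significant additive, %d significant dominance (log10(1/p) > %s)",
        n_snps, n_failed_maf, config.maf_min, len(res), mu_all,
        int(res["significant_additive"].sum()),
        int(res["significant_dominance"].sum()),
        config.threshold,
    )
    return res


def _scan_chunk(
    y: np.ndarray,
    y2: np.ndarray,
    G: np.ndarray,
    snp_ids: np.ndarray,
    config: ScanConfig,
) -> pd.DataFrame:
    cnt = np.empty((3, G.shape[1]))
    s1 = np.empty_like(cnt)
    s2 = np.empty_like(cnt)
    for c in range(3):
        ind = (G == c).astype(float)
        cnt[c] = ind.sum(axis=0)
        s1[c] = y @ ind
        s2[c] = y2 @ ind
    # drop classes below the estimation threshold
    if config.min_class_count > 1:
        below = (cnt > 0) & (cnt < config.min_class_count)
        cnt[below] = 0.0
        s1[below] = 0.0
        s2[below] = 0.0

    n = cnt.sum(axis=0)
    k = (cnt > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p2f = (cnt[1] + 2.0 * cnt[2]) / (2.0 * n)
    p1f = 1.0 - p2f
    maf = np.minimum(p1f, p2f)
    testable = (maf >= config.maf_min) & (k >= 2) & (n - k > 0)
    n_failed_maf = int(np.count_nonzero(~(maf >= config.maf_min)))
    if not np.any(testable):
        out = pd.DataFrame(columns=RESULT_COLUMNS)
        out.attrs["n_failed_maf"] = n_failed_maf
        return out

    idx = np.flatnonzero(testable)
    cnt, s1, s2 = cnt[:, idx], s1[:, idx], s2[:, idx]
    n, k, p1f, p2f, maf = n[idx], k[idx], p1f[idx], p2f[idx], maf[idx]

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnt > 0, s1 / np.where(cnt > 0, cnt, 1.0), np.nan)
        rss = np.sum(
            np.where(cnt > 0, s2 - s1**2 / np.where(cnt > 0, cnt, 1.0), 0.0),
            axis=0,
        )
    rss = np.maximum(rss, 0.0)  # clip negative rounding residue
    df = n - k
    v2 = rss / df
    P = cnt / n
    m = np.nan_to_num(means)  # zeros in empty classes; coefficients vanish there

    # additive contrast (coefficients vanish exactly on empty classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = np.vstack(
            [
                P[0] / p1f,
                0.5 * P[1] * (p2f - p1f) / (p1f * p2f),
                -P[2] / p2f,
            ]
        )
    L_a = np.sum(sa * m, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_a = v2 * np.sum(
            np.where(cnt > 0, sa**2 / np.where(cnt > 0, cnt, 1.0), 0.0), axis=0
        )
    se_a = np.sqrt(var_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_a = np.where(se_a > 0, np.abs(L_a) / se_a, np.where(L_a == 0, 0.0, np.inf))
    p_a, nl_a = _vector_neglog10p(t_a, df, config.df_mode)

    # dominance contrast: all three classes must meet the count floor
    dom_ok = np.all(cnt >= config.min_dominance_class_count, axis=0)
    L_d = m[1] - 0.5 * (m[0] + m[2])
    with np.errstate(invalid="ignore", divide="ignore"):
        var_d = v2 * (0.25 / cnt[0] + 1.0 / cnt[1] + 0.25 / cnt[2])
    se_d = np.where(dom_ok, np.sqrt(var_d), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_d = np.where(
            se_d > 0, np.abs(L_d) / se_d, np.where(L_d == 0, 0.0, np.inf)
        )
    t_d = np.where(dom_ok, t_d, np.nan)
    p_d, nl_d = _vector_neglog10p(t_d, df, config.df_mode)

    # quantitative-genetics decomposition from class means and frequencies
    mu1 = (P[0] * m[0] + 0.5 * P[1] * m[1]) / p1f
    mu2 = (0.5 * P[1] * m[1] + P[2] * m[2]) / p2f
    mu = p1f * mu1 + p2f * mu2
    a1, a2 = mu1 - mu, mu2 - mu
    alpha = mu1 - mu2
    d11 = means[0] - mu - 2.0 * a1
    d12 = means[1] - mu - a1 - a2
    d22 = means[2] - mu - 2.0 * a2
    delta = d12 - 0.5 * (d11 + d22)

    with np.errstate(invalid="ignore"):
        pos_over = (d12 > d11) & (d12 > d22)
        neg_over = (d12 < d11) & (d12 < d22)
    classification = np.where(
        pos_over, "positive_overdominance",
        np.where(neg_over, "negative_overdominance", "none"),
    )
    with np.errstate(invalid="ignore"):
        recessive = np.where(
            pos_over & (d11 < d22), 1, np.where(pos_over & (d22 < d11), 2, 0)
        )

    out = pd.DataFrame(
        {
            "snp": snp_ids[idx],
            "chr": pd.array([pd.NA] * len(idx)),
            "pos": pd.array([pd.NA] * len(idx)),
            "n": n.astype(int),
            "n11": cnt[0].astype(int),
            "n12": cnt[1].astype(int),
            "n22": cnt[2].astype(int),
            "p1": p1f, "p2": p2f, "maf": maf,
            "P11": P[0], "P12": P[1], "P22": P[2],
            "g11": means[0], "g12": means[1], "g22": means[2], "v2": v2,
            "mu": mu, "mu1": mu1, "mu2": mu2,
            "a1": a1, "a2": a2,
            "ae1": np.nan, "ae2": np.nan,
            "alpha": alpha,
            "se_additive": se_a, "t_additive": t_a, "p_additive": p_a,
            "neglog10p_additive": nl_a,
            "significant_additive": nl_a > config.threshold,
            "delta": np.where(dom_ok, delta, np.nan),
            "d11": d11, "d12": d12, "d22": d22,
            "se_dominance": se_d, "t_dominance": t_d, "p_dominance": p_d,
            "neglog10p_dominance": nl_d,
            "significant_dominance": np.where(dom_ok, nl_d > config.threshold, False),
            "dominance_testable": dom_ok,
            "classification": classification,
            "recessive_allele": recessive,
        }
    )
    out.attrs["n_failed_maf"] = n_failed_maf
    return out
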