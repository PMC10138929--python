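# Methods

## The analysis problem

`aglscan` performs single-SNP association analysis of a quantitative trait
recorded on pedigreed animals — the motivating application is age at first
calving (AFC) in dairy cattle, recorded in *negative days* so that a larger
value means a younger (more desirable) first calving.  The record model is

    y = mu + g + a + e,

where `y` is the phenotypic residual after removal of fixed non-genetic
effects, `g` is the genotypic value of the tested SNP (cell means g11, g12,
g22 for genotypes A1A1, A1A2, A2A2), `a` is the additive polygenic value
with `var(a) = sigma_a^2 A` for the pedigree numerator relationship matrix
`A`, and `e ~ N(0, sigma_e^2 I)`.  Genotype codes count copies of allele 2
(0/1/2, NA allowed).

## AGLS estimation

Exact GLS, `b_hat = (X'V^-1 X)^- X'V^-1 y` with `V = sigma_a^2 ZAZ' +
sigma_e^2 I`, and the equivalent mixed-model-equation (MME) solution both
require inverting matrices whose order is the number of animals.  The
approximate-GLS shortcut pre-adjusts the phenotype with an available
polygenic prediction,

    y* = y - a_tilde,        b_hat = (X'X)^- X'y*,

where `a_tilde` is twice the predicted transmitting ability (2×PTA) from
routine evaluation, or an exact BLUP at desk scale.  When `a_tilde` is the
BLUP from the *same* mixed model, this reproduces the exact BLUE of every
estimable function (an identity the test suite verifies against both the
GLS and MME oracles to 1e-8); with an external `a_tilde` it is an
approximation — hence the name.

The fixed design (intercept + three genotype indicators) is rank-deficient,
so the package fits the cell-means parameterization: `g_hat_ij` is the mean
of `y*` in genotype class ij.  Every reported quantity is an estimable
function — both contrast vectors below sum to zero — and is therefore
invariant to the choice of generalized inverse.

## Contrast tests

For contrast `L = s'g_hat`,

    t = |L| / sqrt(v2 * sum_j s_j^2 / n_j),    v2 = RSS / (n - k),

with `n_j` the class counts and `k` the number of non-empty classes.  The
additive contrast uses frequency-adjusted coefficients valid under
Hardy–Weinberg disequilibrium,

    s_a = (P11/p1,  0.5 P12 (p2 - p1)/(p1 p2),  -P22/p2),

which reduce to `(p1, p2 - p1, -p2)` under HWE; the dominance contrast is
the fixed `s_d = (-0.5, 1, -0.5)`.  Two-sided p-values use Student-t with
`n - k` degrees of freedom (`df_mode="normal"` switches to the Gaussian
tail, indistinguishable at large n).  Tail probabilities are computed in
log space; where even `logsf` underflows, the leading term of the
regularized-incomplete-beta expansion of the t tail takes over, so
`log10(1/p)` is finite and accurate for arbitrarily extreme statistics
while `p` itself is stored as 0 with an underflow flag.

## Effect decomposition

With conditional genotype frequencies `P11.1 = P11/p1` etc., the allelic
means are `mu_1 = P11.1 g11 + 0.5 P12.1 g12` and `mu_2 = 0.5 P12.2 g12 +
P22.2 g22`; the SNP mean is `mu = p1 mu_1 + p2 mu_2`; allelic effects are
`a_i = mu_i - mu`; and the average effect of gene substitution is

    alpha = mu_1 - mu_2 = a_1 - a_2 = s_a' g,

the quantity the additive contrast tests.  For cross-SNP comparison the
allelic effects are also reported against `mu_all`, the unweighted mean of
the genotypic means of all SNPs passing the MAF filter (computed in a first
pass over the scan).  Dominance values are `d_ij = g_ij - mu - a_i - a_j`
and the dominance effect is

    delta = d12 - (d11 + d22)/2 = g12 - (g11 + g22)/2,

the allelic effects cancelling.  A SNP shows *positive overdominance* when
`d12 > d11` and `d12 > d22` (heterozygote advantage), negative when both
inequalities reverse.  For positive overdominance the *recessive allele* is
the one whose homozygote has the strictly more negative dominance value
(undefined on ties).

## Genome scan defaults

* `maf_min = 0.05`: SNPs below 5% minor allele frequency are excluded
  (computed per SNP on the non-missing records; missing genotypes are
  complete-cased per SNP).
* `threshold = 8` on the `log10(1/p)` scale: the Bonferroni-style
  genome-wide significance constant used at study scale.
* `min_dominance_class_count = 10`: the dominance contrast places weight
  1/n_j on each homozygote class, so a nearly empty class would let a
  single animal dominate `var(L)`; classes below 10 make the dominance test
  "untestable" for that SNP rather than unstable.  The additive contrast
  needs no such guard because its coefficients vanish exactly on an empty
  class.
* Per-SNP residual variance `v2` (not pooled across SNPs).

## Screening statistics

The rare-recessive overdominance pattern is summarized by five boolean
features of a SNP's dominance decomposition: (1) recessive homozygote
dominance value below −5 days; (2) heterozygote dominance value positive
but below a quarter of |d_RR| — "small" is defined relative to the
recessive effect because the observed het/recessive ratios are ~1/15 and
any absolute cutoff would be arbitrary; (3) dominant homozygote within 0.5
days of zero; (4) recessive allele frequency below 0.10; (5) recessive
genotype frequency below 0.01.  All cutoffs are configurable.

The contribution of a genotype class to the population mean of the SNP's
dominance values is `d_ij × f_ij`.  The *negative impact* of a recessive
genotype is `y_RR − (y_Het + y_DomHom)/2` on raw class means of any trait
column; it is translation-invariant and is the statistic behind the
heifer-culling recommendation (animals homozygous for a listed recessive
allele are reported per SNP and as an any-of-list count).

## BLUP oracle

`build_A` implements the tabular method (dense, O(n²)); `solve_mme` builds
Henderson's equations with `lambda = sigma_e^2/sigma_a^2` against a dense
`A^{-1}` (1e-8 ridge on numerically singular input); `gls_estimate` forms
`V` explicitly.  All three are desk-scale by design (a few thousand
animals) — they exist to validate the AGLS shortcut and to supply exact
BLUPs for simulation, not to scale.  Rank-deficient fixed designs are
solved in the minimum-norm least-squares sense; only estimable functions
are meaningful, and the tests only ever compare those.

## Synthetic populations

The generator emulates the data structure the analysis assumes:

* **Pedigree**: `n_founders` unrelated animals, then `n_generations` of
  random matings with `n_sires` sires per generation (default 5% of a
  generation) and full-sib litters of `offspring_per_mating` (default 2) —
  a dairy-like strong paternal half-sib structure.
* **Genotypes**: founder codes Binomial(2, p) at per-SNP frequencies with
  MAF uniform on [0.05, 0.5] (minor allele on a random side); descendants
  by per-locus Mendelian gene dropping, so genotype correlations between
  relatives are consistent with `A`.  Causal SNPs can pin their founder
  frequency.
* **Polygenics**: the Mendelian-sampling recursion `a_i = 0.5(a_s + a_d) +
  m_i`, with sampling variance corrected for parental inbreeding from the
  diagonal of `A` — exact draws from `N(0, sigma_a^2 A)` in O(n).
* **Phenotypes**: `y = sum of causal genotypic values + a + e`.  Defaults
  `sigma_a^2 = 10`, `sigma_e^2 = 90` days² (phenotypic SD 10 days,
  h² = 0.10, in line with the low heritability of calving-age traits).
* **Reproducibility**: one master seed; independent child streams for
  mating/genotypes, polygenics, residuals and PTA noise, so outputs are
  bit-identical across runs.

`make_overdominant_causal(f_R, d_RR)` constructs genotypic values whose
dominance decomposition at HWE(f_R) returns exactly the requested recessive
homozygote dominance value, with zero mean and zero additive part.  Under
exact HWE the three dominance values have a single degree of freedom
(`d_rec = -2q²δ`, `d_het = 2rqδ`, `d_dom = -2r²δ` with `r = f_R`,
`q = 1 - r`), so the heterozygote value is implied rather than free — at
`(f_R, d_RR) = (0.081, -9.76)` it is 0.86.  An explicit `d_DR` argument is
accepted for sign validation only; reported rare-recessive pairs that
differ from the implied value reflect Hardy–Weinberg disequilibrium in real
data, which a HWE construction cannot reproduce.

### Polygenic-prediction (PTA) modes

* `exact_blup` — the exact BLUP of the model's polygenic term `a`,
  computed by solving the MME on the polygenic-plus-residual part of the
  phenotype (known to the simulator).  This is the oracle adjustment that
  isolates the estimator's own properties.
* `evaluation_blup` — an intercept-only animal-model BLUP computed from
  the raw phenotypes, the way a routine pedigree evaluation would be.
  Because causal SNP effects are transmitted through the pedigree, this
  prediction absorbs part of them, and downstream additive estimates are
  attenuated ("proximal contamination"): at h² = 0.10 with half-sib
  families of ~40, a true alpha of 1.0 day is estimated around 0.6–0.75.
  Real 2×PTA adjustments share this property, so study-scale additive
  effect sizes should be read as conservative.
* `noisy` — `evaluation_blup` plus `N(0, (1 - r²)·var(a_hat))` noise for a
  configurable reliability r² (default 0.8), emulating imperfect routine
  PTAs.
* `zero` — no adjustment (unadjusted least-squares analysis).

Dominance estimates are essentially immune to all of this: dominance
deviations are nearly orthogonal to additive family structure, so `delta`
is recovered without systematic bias in every mode.

## Null behaviour of the tests

On simulated data the tests behave as follows (measured, and asserted by
the test suite at its stated Monte-Carlo resolutions):

* Unrelated animals: both tests reject at the nominal 5% rate.
* Pedigreed animals, no adjustment: the additive test is inflated
  (~8.5% at h² = 0.10) — the classic stratification the adjustment exists
  to fix; the dominance test stays nominal.
* Pedigreed animals with exact-BLUP adjustment: the additive test is
  mildly *conservative* (~3.5% at the default family structure), because
  BLUP shrinks family-mean contrasts more strongly than within-family
  contrasts while the LS variance estimate `v2·Σ s_j²/n_j` averages over
  both; the dominance test stays nominal.  The conservativeness grows with
  half-sib family size and h², and never becomes anti-conservative — at
  the genome-wide threshold of `log10(1/p) = 8`, zero false positives were
  observed in 10,000 null SNPs.

## What the simulations do not show

SNPs are unlinked (no LD, so no clumping of signals around a causal
variant), there is no selection across generations, founder frequencies
are the panel's equilibrium frequencies, phenotypes are generated directly
on the residual scale (herd–year–season removal is not modelled), and
every animal is genotyped and phenotyped.  Passing tests therefore
validate the estimators and the screening logic, not robustness to
imputation error, ascertainment, or fixed-effect misspecification.

## Problem sizes

The heavier checks use 10,000 null SNPs on 2,001 animals (null
calibration) and 300 SNPs on 5,001 animals with two causal SNPs
(parameter recovery); estimator-oracle agreement uses 20 random instances
of 100–500 animals.  These sizes put each Monte-Carlo standard error well
below the quantities being checked while keeping the full suite and the
acceptance script in the minutes range on one CPU.

## Known limitations

* Dense `A^{-1}` limits exact BLUP to a few thousand animals; there is no
  sparse-inverse or iterative path.
* The additive test's conservativeness under exact-BLUP adjustment (above)
  is a property of the approximation itself, not of this implementation.
* Biallelic SNPs only; no haplotype or epistasis tests; no G-matrix
  (genomic-relationship) models; no REML — variance components are inputs.
* Gene annotation is nearest-gene within a window (default 1 Mb, strand-
  aware upstream/downstream labelling), not transcript-aware.
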