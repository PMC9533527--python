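# Methods

## Model

`corrscan` works on the single-record animal model

    y = Xb + Za + e,    a ~ N(0, G σg²),    e ~ N(0, I σe²)

with one phenotypic record per genotyped individual, so Z is the identity.
X encodes an intercept, categorical fixed effects (contemporary groups,
coded as full-rank indicator contrasts with the first observed level as
reference) and numeric covariates (age, principal components). G is the
VanRaden Method-1 genomic relationship matrix

    G = Z_c Z_c' / s,    Z_c = M − 2p,    s = 2 Σ_j p_j (1 − p_j)

where M holds allele counts in {0,1,2} and p_j is the frequency of the
counted allele estimated from the observed genotypes of SNP j. Missing
genotypes are imputed to the column mean 2p_j before centering (standard
GBLUP practice), which makes them contribute exactly zero to `Z_c`.
Monomorphic SNPs stay in the map but add nothing to the scale sum; a
warning lists them.

Variance components are **inputs** — either explicit (σg², σe²) or a
heritability h², which is converted via σg² = h²·σ̂p², σe² = (1−h²)·σ̂p²
with σ̂p² the variance of the phenotype after an ordinary-least-squares
adjustment for the fixed effects. The shrinkage factor is α = σe²/σg² =
(1−h²)/h². REML estimation is deliberately out of scope; practitioners
obtain components from dedicated software and pass them in.

## Solving the mixed model equations without inverting G

The Henderson system (scaled by σe²) is

    [X'X  X'          ] [b]   [X'y]
    [X    I + α G⁻¹   ] [a] = [y]

A Method-1 GRM whose allele frequencies come from the data itself is
*structurally singular*: every column of Z_c sums to zero, so G annihilates
the ones vector. Ridging G to force invertibility would contaminate the
back-solve identity at the size of the ridge. We instead substitute
a = G s, giving the exactly equivalent system

    [X'X  X'G     ] [b]   [X'y]
    [X    G + α I ] [s] = [y]

whose random block is positive definite for any PSD G and α > 0. The solve
returns b, s and a = G s; for a full-rank G, s equals G⁻¹a and the two
formulations coincide (verified against a brute-force dense solve of the
untransformed system to 1e−8 in the tests). An explicit ridge on G remains
available (`solve_mme(..., ridge=...)`) and is auto-applied with a logged
warning only when α = 0 would make the block singular.

Rank-deficient fixed-effect designs are rejected with the offending columns
named, rather than silently pseudo-inverted.

## Back-solving SNP effects

Per-SNP effects come from the Strandén–Garrick identity

    û = Z_c' G⁻¹ â / s  =  Z_c' s / s_scale

consumed directly from the MME substitution vector, so no inverse is ever
formed and the reconstruction Z_c û = G s = â holds to machine precision
(asserted on every simulated fit). The centered gene content is used on
both sides — GRM and back-solve — so the identity is exact by construction;
using raw allele counts on one side only would break it.

## The scan

Windows are laid out per chromosome: length K = 500 SNPs, step 100, starts
0, 100, …, ≤ N−K. Only full-length windows are formed; a chromosome with
fewer than K SNPs yields none (logged), because the significance test fixes
the per-window sample size at K. Chromosome labels are opaque strings — X
is scanned like any autosome — and windows never span chromosome
boundaries. Each window's statistic is the plain Pearson correlation of the
two traits' effect slices; a zero-variance slice gives an undefined window
that is recorded but excluded from testing (counted separately from
neutral).

## Permutation null and test

Each iteration reshuffles the *genome-wide* effect vector of each trait
independently (scheme `permute_both`; `permute_one` shuffles only trait B)
and recomputes every window's correlation from that shared shuffle; the
per-window mean over iterations is the null center r_p. Genome-wide
shuffles make r_p ≈ 0 with Monte-Carlo error 1/√(n_perm·K), so results are
insensitive to the scheme choice; sharing one shuffle across windows costs
a factor `windows × K` less than per-window shuffles and leaves the
per-window null mean unchanged.

The test statistic is the standardized Fisher-Z difference

    z = |Z_r − Z_rp| / sqrt(1/(n+3) + 1/(n−3)),    Z_x = ½ ln((1+x)/(1−x))

with n the window size in SNPs, referred two-tailed to the standard normal
(p = 2(1 − Φ(z)) on the folded statistic). The denominator is kept in this
exact form; the classical two-sample Fisher SE sqrt(2/(n−3)) differs by
under 0.2% at n = 500. Correlations at ±1 are clamped to 1−1e−12 before
transforming, with a warning. Bonferroni multiplies raw p-values by the
number of windows with defined r for the trait pair (no cross-pair
correction), and significance is the strict inequality p_adj < 0.05.

Classification: significant windows whose r shares the sign of the global
genetic correlation are drivers, opposite-sign ones antagonizers,
non-significant windows neutral. The global sign is supplied by the user
(typically from a bivariate REML estimate); if absent, the sign of the
correlation between the two genome-wide effect vectors is used and logged —
a weak fallback, since estimation noise attenuates that correlation
severely. Significant windows are ranked within each class by |r|
descending, ties broken by genome order; rank_percent = 100·position/size,
so the top window gets the smallest value and the column can serve as a
pseudo-p in downstream enrichment tools.

Note a known behaviour inherited from the fixed n = K assumption: strong
local LD makes back-solved effects smooth within a window, reducing the
effective number of independent SNPs below K and making the test
anti-conservative for strongly autocorrelated effect vectors. Under
exchangeable (independent) effects the test is conservative (the z
statistic has null variance ≈ ½), which the type-I simulations confirm.

## LD pruning

"LD > 0.5" is interpreted as pairwise r² > 0.5 of allele counts, the
convention of standard pruning tools. Greedy left-to-right within each
500-SNP window (step 100): the later SNP of any offending pair is removed;
passes repeat until none removes a SNP, so the kept set provably contains
no within-window pair above threshold (re-checked by an independent scan in
the tests). Pruning is deterministic given the map order.
`scan_consistency_report` matches pruned windows to full-scan windows by
base-pair midpoint and reports the correlation and sign agreement of the
matched r estimates.

## Synthetic data

The generator emulates the study design at desk scale, with every default
chosen once:

- **Map**: 10 chromosomes × 1500 SNPs, 2 kb spacing → 110 windows at
  K = 500 / step 100. Mirrors the study's ~1000-individual populations
  while shrinking the marker panel from ~600k.
- **Genotypes**: per-SNP MAF ~ Uniform(0.05, 0.5); first-order Markov
  haplotypes with copy probability ld_rho = 0.9, giving adjacent-genotype
  correlation ≈ 0.9 — the strong neighbour redundancy of high-density
  chips. The copy chain smooths marginal allele frequencies towards their
  neighbours; ld_rho = 0 recovers exact per-SNP frequencies. No coalescent
  realism, no sex-chromosome dosage, no genotyping error.
- **Effects**: drawn at every SNP (infinitesimal-style) from a bivariate
  normal whose correlation is region-specific: a planted driver region
  (ρ = +0.9) on chromosome 1 and antagonizing region (ρ = −0.9) on
  chromosome 2, each 1000 SNPs with 8× effect variance — a QTL-dense
  major-effect neighbourhood, PLAG1-like — over a ρ = 0.1 background.
  ρ = ±1 produces exactly degenerate draws.
- **Phenotypes**: y = group offsets + Z_c β + e with h² = 0.50 and 0.35
  (moderately-to-highly heritable, in the range of early-in-life fertility
  traits such as age at first corpus luteum and IGF-1 concentration);
  5 contemporary groups with N(0, sd(g)) offsets.

What passing simulations do *not* show about real data: the Markov LD has
no long-range structure or population stratification, effects are
independent across SNPs given their region, and heritabilities are treated
as known. In particular the end-to-end attenuation of local correlations —
back-solved effects recover planted ρ = 0.9 as window r ≈ 0.4–0.6 at
n = 1000 — will differ on real panels with other LD and sample sizes.

## Problem sizes and numerical choices

Test and acceptance runs use 1000 permutations at the 110-window desk scale
(the package default remains 10,000); oracle-equivalence checks run at
n ≤ 50 against dense brute-force solves; the back-solve identity is checked
at 200 × 5000 over 20 replicates. Tolerances: 1e−8 for linear-algebra
identities, 1e−12 for the windowed-Pearson oracle, exact clamping at
1−1e−12 for Fisher transforms. All randomness flows through
`numpy.random.default_rng` seeds; identical inputs, parameters and seed
reproduce scan tables byte-for-byte.

## Limitations

Two traits per scan only; Bonferroni is the only multiplicity control; the
permutation scheme destroys LD structure genome-wide rather than locally;
variance components are trusted as given; no support for multiple records
per individual, dominance/epistatic relationship matrices, or base-pair-
width windows.
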