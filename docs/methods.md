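# Methods

This note documents the statistical models behind `delload`, the design
of the synthetic-data generator, the numerical choices that affect
results, and what the recovery experiments do and do not demonstrate.

## Data model and conventions

Genotypes are alternate-allele dosages in {0, 1, 2} with an explicit
missing code; positions are 1-based (VCF convention) and BED intervals
are converted from 0-based half-open coordinates at the I/O boundary, so
a SNP at 1-based position p falls in interval [start, end) iff
start < p ≤ end. Allele frequencies are computed by allele counting over
non-missing calls, a heterozygous call contributing one allele of each
kind; inbred panels carry ~1% residual heterozygosity and dropping those
calls instead changes frequencies by well under the sampling error, but
callers who want the alternative can mask heterozygotes to missing
before counting. Triallelic records are dropped at load with a logged
count. "Genic" means the annotation assigns a gene id; enrichment
universes use genic SNPs only.

## Polarization and frequency spectra

The derived allele at a SNP is the one not matching the outgroup allele;
SNPs whose outgroup state is missing or matches neither allele are
flagged unpolarizable and excluded rather than treated as errors.
Spectra use equal-width half-open bins on [0, 1] with the last bin
closed; bin indices are computed as `floor(f·n_bins + 1e-9)` so that
decimal bin edges behave exactly (0.6 with 10 bins belongs to
[0.6, 0.7)). Class contrasts use the two-sided Mann-Whitney U test:
exact when both samples hold ≤ 50 values and are tie-free; with ties,
exact by full enumeration of rank splits when there are at most 2×10⁵ of
them; otherwise the tie-corrected normal approximation. (A tie-aware
exact test at n = 50 is not enumerable; the asymptotic fallback is
accurate at the panel sizes where it engages.)

## Differentiation

Per-SNP F_ST is the Weir & Cockerham (1984) multi-population θ with the
observed heterozygosity term retained, lines contributing alleles by
count. Per SNP, groups with fewer than one genotyped line are excluded
and at least two eligible groups are required; SNPs monomorphic across
the included groups are undefined (NaN), as θ's denominator vanishes.
The estimator can be slightly negative in finite samples; values are
reported as-is. A pairwise-mean mode (`fst_pairwise_mean`) averages
two-group θ over group pairs for comparison with the default joint
estimate.

The frequency-matched tail comparison resamples control SNPs to match
the deleterious class's histogram over 20 equal-width MAF bins on
[0, 0.5] — without replacement where the bin allows, with replacement
otherwise; bins with deleterious SNPs but no controls are dropped with a
warning. The top-tail threshold is the empirical quantile of the union
of the two matched sets (a single shared tail, so a fold of 1 is the
exact null). Finite-sample θ runs slightly lower for rare SNPs, so a
class that is merely rarer shifts the unmatched θ distribution — the
matched comparison removes exactly this artifact, and the test suite
verifies the rejection rate returns to α after matching.

## Heterosis

Genetic values are estimated under a fixed-genotype-effect model with
identity residual covariance; with single replicates per environment the
estimate is the per-genotype mean, which is what is computed (an
environment-adjusted least-squares variant would differ only in
unbalanced designs; the generator's designs are balanced). For each
cross, MPH, BPH_max and BPH_min are emitted together with a selected-BPH
column: best-parent heterosis is measured against the *lower* parent for
traits where smaller values are favourable (flowering time, tassel
traits, leaf angles; the list is configurable). The algebraic ordering
BPH_max ≤ MPH ≤ BPH_min holds row by row and is asserted in tests.

## Association scans

**Inbred scan.** The mixed model `g = 1μ + Sβ + u + ε`,
`u ~ N(0, σ²_u K)`, `ε ~ N(0, σ²_e I)`, is REML-fitted once without a
marker: the kinship K (identity-by-state, eigenvalues clipped at
−10⁻¹⁰ → 0, more negative is an error) is spectrally decomposed, and the
ratio δ = σ²_e/σ²_u is profiled on a 100-point log grid over
[10⁻⁵, 10⁵] refined by bounded scalar minimization — deterministic, with
each likelihood evaluation O(n). Every marker is then tested by
generalized least squares with δ fixed (the EMMAX/P3D approximation;
full per-marker REML is deliberately not implemented — at panel sizes of
a few hundred lines P3D is the accepted standard and the approximation
error is far below the sampling noise). Markers with missing calls drop
the affected lines and are solved through the Cholesky factor of the
subset covariance, which is exact, not an imputation. P-values are
two-sided t with the exact residual degrees of freedom; with K = I the
scan reproduces ordinary least squares to 10⁻⁸, which the suite checks.

**Hybrid scan.** `PH = 1μ′ + Dβ + Hϑ + ε′` is ordinary least squares
per SNP, where H ∈ {0, 1} indicates the hybrid is heterozygous at the
locus (defined only when both parental calls are homozygous — a missing
or residually heterozygous parent makes H missing) and D is the parental
genetic distance (1 − IBS). All per-SNP normal equations are assembled
in one vectorized pass over masked cross-products, so missingness
patterns do not force a Python-level loop. The MAF filter is applied to
the heterozygote-class frequency (≥ 0.05 and ≤ 0.95); a constant D is
dropped with a warning. Significance: P ≤ 0.001, plus Benjamini-
Hochberg flags at FDR 20% computed over each trait's tested SNPs.

## Enrichment

Fold enrichment is the ratio of the deleterious proportion among
significant items to the deleterious proportion in the universe —
chosen because it is exactly 1 in expectation under the null and is a
monotone transform of the Fisher table. Fisher tests are two-sided;
direction is read from f. At gene level the universe is genes with ≥ 1
tested SNP, a gene is significant iff any tested SNP in it is
significant, and a gene is deleterious iff it contains ≥ 1 annotated
deleterious SNP *including untested ones*: most deleterious alleles sit
below the MAF filter, and the gene-level test exists precisely to reach
them. The cross-trait sign test is exact binomial, two-sided by doubling
the smaller tail (capped at 1), with folds exactly equal to 1 excluded.
Controls: per-SNP-count-bin enrichment (strata of the gene universe by
tested-SNP count; bins under 5 genes skipped) and a specificity control
replacing the deleterious label with "contains a synonymous SNP of
derived frequency < 0.05".

## The synthetic-data generator

The generator produces the statistical structure the analyses assume,
not a population-genetic history (no linkage, no recombination maps, no
coalescent — those are out of scope by design).

*Genotypes.* Each SNP draws an ancestral derived-allele frequency from a
class-specific Beta; each group's frequency comes from the
Balding-Nichols model (Beta with mean p and variance F·p(1−p)); each
line is a doubled-haploid Bernoulli draw, then heterozygous and missing
calls are injected at 1% each (missing wins). Ref/alt labels are
randomized against ancestral/derived so polarization is genuinely
exercised, and 2% of outgroup alleles are blanked.

*Defaults as study conditions.* 200 lines in four groups of 50; 10,000
coding SNPs in 2,000 genes on 10 chromosomes at uniform 10-kb spacing;
25% nonsynonymous of which 20% deleterious (500 deleterious SNPs,
clustered ~2.5 per carrier gene, matching the observed co-occurrence of
predicted deleterious SNPs within genes); deleterious ancestral
frequencies Beta(0.3, 1.2) — chosen so ~45% of deleterious SNPs fall
below 5% derived frequency, the headline rarity of the empirical
spectrum — and Beta(0.5, 0.9) for other classes; group divergence
F = 0.12 per group, which realizes a mean per-SNP Weir-Cockerham θ of
≈ 0.085 on the default panel (the Balding-Nichols parameter is not the
realized mean θ, so F is set above the target mean); three environments;
1% heterozygosity/missingness.

*Traits.* Effects follow a dense polygenic reading of the dominance
model: every deleterious SNP carries a fitness penalty s ~ Exp(mean
0.1), and every trait draws its own independent Exp penalties for the
same 500 SNPs. An inbred's value is `baseline − Σ s_j·I(hom. derived)`;
a hybrid pays `s_j` where homozygous derived and `h·s_j` where
heterozygous, with dominance h = 0.1 (near-recessive). A parental call
that is missing or heterozygous makes the hybrid call missing at that
SNP and contributes no penalty, mirroring the downstream treatment of
missing calls. An optional oligogenic mechanism (a few "major"
deleterious genes per trait with multiplied penalties) exists in the
config but is off by default: with the structured panel, the
significant set of the hybrid scan is dominated by SNPs tagging group
structure, and a handful of major genes cannot move the gene-level fold
stably, whereas the dense architecture produces exactly the diffuse,
modest (f ≈ 1.1–1.3), consistently positive per-trait enrichment that
motivates the cross-trait sign test.

*Noise calibration.* `env_sd_for_heritability` sets the per-trait
environmental SD so that single-plot broad-sense heritability of the
inbred phenotypes is a target (0.5 in the recovery study):
`sd = sqrt(Vg·(1−H²)/H²)` with Vg the variance of noiseless inbred
values across the panel.

*Crossing design.* Tester designs (every line × one common tester) are
supported and mirror the empirical testcross populations, but a
power-budget argument fixes the recovery study's design: with
H² = 0.5, three environments and h = 0.1, the heritable fraction of
mid-parent heterosis is about (½−h)²/((½−h)² + ½) ≈ 0.24, so with only
~200 testcross hybrids no trait architecture can push more than a
handful of loci past P ≤ 0.001 — too few to steer a gene-level fold
against its sampling noise. The recovery study therefore crosses the
same 200 lines in a partial-diallel factorial of 3000 random pairs
(`random_crosses`, with `cross_heterozygosity`/`cross_distance`
generalizing the tester-based operations), a standard mating design for
heterosis studies that raises the hybrid count without enlarging the
panel.

## The recovery experiment

`delload.recovery.dominance_recovery_replicate` simulates the default
panel, calibrates noise to H² = 0.5, runs the heterozygosity scan per
trait for both MPH and BPH_max, and computes per-trait gene-level fold
enrichments. A replicate passes when the mean best-parent fold exceeds
1 *and* the exact cross-trait sign test on the sixteen mid-parent folds
rejects at 1%. The sign test operates on the mid-parent column because
that is the column the published cross-trait test used; best-parent
heterosis carries an extra |g₁−g₂|/2 noise term (the best parent
switches identity across crosses), which attenuates its per-trait folds
— the attenuation is visible in the reported BPH means (~1.05–1.15
versus ~1.15–1.35 for MPH) and is itself a faithful property of the
statistic. The low-frequency-synonymous control runs per trait and is
expected silent.

What passing shows: under genotype-frequency structure, effect sizes
and noise levels matching the stated study conditions, the pipeline's
scans and enrichment statistics recover a true dominance-model signal
as diffuse, consistently positive gene-level enrichment, and the
control shows the signal is specific to the deleterious label, not to
rarity or gene SNP content. What it does not show: anything about
linkage-driven synthetic associations (the generator has no LD, so
enrichment here flows only through the deleterious SNPs themselves),
about real predictor error (SIFT/MAPP-style calls are simulated with a
fixed 80% per-predictor hit rate and a consensus-consistent union), or
about pedigree relatedness within groups (lines are exchangeable within
a group, so within-group sharing–IBS correlations are weak by
construction, unlike panels with family structure).

## Numerical details and edge cases

- Monomorphic or collinear markers are skipped with a diagnostic, never
  fabricated as p = 1.
- The REML profile keeps the grid optimum if local refinement fails to
  improve it, guaranteeing the returned likelihood dominates every grid
  point.
- IBS pairs with no jointly observed SNP are NaN (error in strict
  mode); per-line load keeps the full deleterious count in the
  denominator so heavily missing lines bias low rather than dropping
  out.
- Batched per-SNP OLS solves 2×2/3×3 normal equations after a
  determinant screen (`det > 1e-10·n^k`) that removes degenerate
  designs before inversion.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the CLI derives per-stage seeds by
  hashing the stage name with the global seed, so stage outputs are
  reproducible independently of execution order.

## Known limitations

Full per-marker REML is not offered; hybrids of residually heterozygous
parents are dropped per SNP rather than modelled; the generator's
missingness is uniform (no GBS-style coverage structure); phenotype
sharing across traits is purely through the shared deleterious genotype,
so trait-trait correlations are weaker than in real multi-trait panels;
and the window-level covariate correlations are descriptive (no
autocorrelation correction across windows).
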