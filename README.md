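# delload

Deleterious-variant load, heterosis, and enrichment analysis for
structured panels of inbred lines and their hybrids.

Crop inbred panels (the motivating case is maize) segregate thousands of
nonsynonymous SNPs predicted to damage protein function. Under the
**dominance model of heterosis**, inbred lines are homozygous for
different complements of recessive deleterious alleles, and a hybrid's
advantage comes from each parent masking the other's defects. `delload`
implements the genome-wide analysis that connects predicted deleterious
variants to this model in a structured panel:

- **Frequency spectra.** Derived allele frequencies polarized against an
  outgroup allele, binned per functional class (synonymous /
  nonsynonymous-tolerated / nonsynonymous-deleterious), contrasted with
  exact or tie-corrected Mann-Whitney tests.
- **Differentiation.** Per-SNP multi-group Weir-Cockerham (1984)
  F<sub>ST</sub>, frequency-matched top-tail comparisons between SNP
  classes, joint SFS between genetic groups, identity-by-state and
  deleterious-allele-sharing matrices, per-line load, and 1-Mb window
  summaries with covariate correlations.
- **Heterosis.** Genetic values from replicated phenotypes and, per
  cross and trait, mid-parent and best-parent heterosis
  `MPH = g_12 − (g_1+g_2)/2`, `BPH_max = g_12 − max(g_1, g_2)`,
  `BPH_min = g_12 − min(g_1, g_2)`.
- **Association scans.** An EMMA-style mixed linear model for inbred
  genetic values, `g = 1μ + Mϑ + Sβ + Zu + ε` with
  `u ~ N(0, σ²_u K)` and K approximated by identity-by-state (variance
  components REML-fitted once on the null model and reused per marker —
  the EMMAX/P3D approximation); and a per-locus heterozygosity scan for
  hybrids, `PH = 1μ′ + Dβ + Hϑ + ε′`, where H indicates hybrid
  heterozygosity at the tested locus and D is the parental genetic
  distance. Significance at P ≤ 0.001 and Benjamini-Hochberg FDR 20%.
- **Enrichment.** SNP- and gene-level fold enrichment
  `f = [a/(a+b)] / [(a+c)/N]` of deleterious variants among significant
  associations, two-sided Fisher tests, SNP-count-stratified and
  low-frequency-synonymous controls, and the exact cross-trait sign
  test.
- **Synthetic panels.** A generator producing structured inbred panels
  (Balding-Nichols group divergence, doubled-haploid genotypes, rare
  deleterious alleles, residual heterozygosity/missingness) and hybrid
  phenotypes under the dominance model, with full ground truth for
  recovery experiments.

## Worked example

Simulate a 100-line panel in four groups, then characterize its
deleterious variation through the CLI:

```sh
cat > config.yaml <<EOF
workdir: out
seed: 42
testers: [L000]
sim:
  n_groups: 4
  lines_per_group: [25, 25, 25, 25]
  n_snps: 4000
  n_genes: 800
  group_divergence_F: [0.12, 0.12, 0.12, 0.12]
  n_traits: 4
  seed: 0
EOF
delload simulate -c config.yaml
delload sfs -c config.yaml
delload fst -c config.yaml
```

which prints

```
simulated 100 lines x 4000 SNPs into out
polarized 3912 of 4000 SNPs
mean F_ST 0.0867; matched-tail Fisher p 0.623
```

`out/sfs_contrasts.tsv` holds the class contrasts; here the deleterious
class shows the expected marked excess of rare derived alleles
(Mann-Whitney p = 5.8e-18 against synonymous SNPs, 4.4e-14 against
tolerated nonsynonymous SNPs) while tolerated nonsynonymous and
synonymous SNPs are indistinguishable (p = 0.46). The mean
F<sub>ST</sub> of 0.087 reflects the configured group divergence, and
after matching deleterious and control SNPs on minor-allele frequency
the classes occupy the top 1% of F<sub>ST</sub> at indistinguishable
rates (Fisher p = 0.62) — rarity, not differential selection between
groups, drives the raw contrast.

The end-to-end recovery experiment — does gene-level deleterious
enrichment in heterosis scans reappear when the dominance model is true
by construction? — runs from Python:

```python
from delload.recovery import dominance_recovery_replicate
r = dominance_recovery_replicate(seed=1)
print(round(r.mean_mph_fold, 2), round(r.mean_bph_fold, 2),
      r.mph_sign_p, r.control_significant)
```

printing `1.16 1.06 3.0517578125e-05 0`: on a default panel (200 lines,
10,000 SNPs of which 500 deleterious, 16 traits, broad-sense H² = 0.5,
3000-pair factorial crossing), genes containing deleterious SNPs are
enriched among heterosis-associated genes for every one of the 16
traits (mean mid-parent fold 1.16, sign test p ≈ 3e-5), best-parent
heterosis shows the same signal attenuated (mean fold 1.06), and the
low-frequency-synonymous control finds no trait significantly enriched.

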