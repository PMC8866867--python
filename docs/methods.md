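# Methods

## The screening problem

A case-control study looking for gene-environment (GxE) interactions faces
a power squeeze: interaction estimates have large variance, and a
genome-wide multiplicity correction on the interaction test alone would be
prohibitive at a few hundred samples. `gxescreen` implements the standard
two-stage answer. Stage 1 screens every variant with a 2-degree-of-freedom
joint test of the genetic main effect and the interaction — sensitive both
to pure genetic effects and to effects confined to one exposure stratum.
Stage 2 tests the interaction coefficient alone, but only among stage-1
survivors, at a threshold calibrated so the *conditional* type-I error —
P(interaction test rejects | joint test passed) — equals the nominal level.

## Models

For additive minor-allele dosage G ∈ {0,1,2}, binary exposure E and
ancestry covariates PC₁..PC_k:

- full model:    logit P(case) = β₀ + Σⱼ cⱼ PCⱼ + β_E E + β_G G + β_GE G·E
- reduced model: logit P(case) = β₀ + Σⱼ cⱼ PCⱼ + β_E E

The joint statistic is the likelihood-ratio statistic between the two
fits, referred to χ²(2); a likelihood-ratio test was chosen over a Wald
version for numerical stability near boundary fits, and is pinned against
an independent numeric likelihood-maximization oracle in the tests. The
interaction test is the Wald statistic (β_GE/se)² against χ²(1), matching
the convention of the common GWAS toolchains; an LRT variant is available
(`interaction_test(..., method="lrt")`) and the two agree in rejection on
≥98% of null replicates at n=538. The reduced model keeps E: the 2df
contrast must isolate exactly (β_G, β_GE). Without covariates, β_GE equals
the difference of the stratum-specific genotype slopes — an identity the
test suite asserts to 1e-8.

Fitting is iteratively reweighted least squares (Newton scoring) with step
halving; convergence means the maximum absolute score falls below 1e-8.
Fitted log-odds beyond ±20 flag (quasi-)separation: the score vanishes
there while the MLE diverges, so such fits are reported `non_converged`
and never yield Wald statistics. The genome scan and the calibration use a
batched IRLS, vectorized across variants/tests, with per-observation 0/1
weights implementing per-variant complete-case genotype missingness; it is
cross-checked against the single-fit path to 1e-6 in the suite. When no
calls are missing the reduced fit is shared across a chunk rather than
refitted per variant.

## Threshold calibration

The joint and interaction statistics share the interaction component, so
among stage-1 survivors the interaction p-values are enriched near zero
and a naive stage-2 threshold would be anticonservative. The calibration
simulates N independent null single-variant tests (default design: 344
cases / 194 controls, MAF ~ U[0.1, 0.5] in Hardy-Weinberg proportions,
exposure Bernoulli(0.3), five standard-normal covariates, all G and GxE
effects zero), computes (p_joint, p_GE) per test, and returns the
empirical 0.05-quantile (linear interpolation between order statistics) of
p_GE among tests with p_joint < 0.05, together with the quantile's
asymptotic Monte-Carlo standard error (density estimated by a central
difference of the empirical quantile function).

Under the global null, case status is independent of genotype, exposure
and covariates, so the simulator draws predictors directly for a fixed
344/194 case-control split — exactly the distribution rejection sampling
would produce, at a fraction of the cost. `empirical_conditional_type1` is
the exact inverse operation (the conditional rejection rate at given
thresholds on a null sample) and validates a calibrated threshold
out of sample.

Two analytic anchors bound the answer. If the G and GxE chi-square
components were independent (`regime="independent"`), the 1df critical
value at α₁·0.05 = 0.0025 (9.14) would exceed the 2df critical value at
α₁ = 0.05 (5.99), nesting the stage-2 rejection region inside stage 1 and
forcing the threshold to exactly 0.0025; dependence in real designs can
only raise it, and the threshold is monotone in both α₁ and the
conditional level. At the default study design the calibrated threshold
lands near 0.0028 (bracketing the conventional 0.00275), and is mildly
sensitive to exposure prevalence and the MAF range —
`calibration_sweep` reports that sensitivity over a grid.

## Regions and selection

Suggestive variants (p_joint < α₁) are sorted by position and greedily
merged while consecutive variants on one chromosome lie within a window
(default 500 kb — a first-class, reported parameter, since locus
definitions vary between studies). The region count R is the Bonferroni
denominator: a variant is declared significant when p_joint < α₁ and
p_GE < t/R (e.g. 0.00275/572 = 4.8e-6), with a suggestive tier reported at
5e-4. Cluster leads are the smallest-p_joint members, ties broken by
position then id. With no LD model, clustering is exercised by placing
simulated variants on a synthetic map with configurable within-cluster
spacing and between-cluster gaps.

## Quality control

Filters run in the fixed order imputation quality → HWE → MAF with
first-failing-rule attribution, making report counts deterministic (the
order is a package convention; the thresholds themselves are standard:
quality < 0.5, HWE exact p < 1e-4 in controls, MAF < 0.10). Hard-calling
retains the most-likely genotype only when its probability strictly
exceeds 0.9; ties and flat triplets become missing. The HWE test is the
exact conditional test given allele counts (no mid-p correction), summing
the probabilities of all heterozygote configurations no more probable than
the observed one; it agrees with an exact-rational enumeration oracle to
1e-12 exhaustively up to 50 diploids. MAF and HWE use per-variant
complete cases; PCA mean-imputes missing calls. Ancestry PCs use the
genotype matrix normalized per variant by 2p̂ and sqrt(2p̂(1−p̂)), with
scores the top right-singular directions scaled by singular values; no LD
pruning is applied (configurable upstream by subsetting variants).
Monomorphic variants are a hard error there (zero scale).

## Synthetic cohorts

The generator emulates a small European-ancestry case-control GxE study:
exact 344/194 case/control quotas filled by rejection sampling from the
prospective logistic model — the simplest scheme exactly consistent with
prospective logistic analysis of case-control data — with baseline
log-odds β₀ = −2 so rejection is efficient at default effect sizes.
Exposure prevalence defaults to 0.3 (a typical periconceptional exposure
frequency; the study family this emulates does not publish theirs, so the
value is configurable and swept in calibration). Variants are independent
(no LD), exposures are independent of genotype, and covariates are null
N(0,1) unless a two-subpopulation allele-frequency divergence is switched
on (recorded in `truth` and in a `subpop` sample column). Imputation
artifacts replace calls by probability triplets whose argmax is the true
genotype with probability 1 − miscall_rate, with a configurable fraction
of triplets too flat to survive the 0.9 hard-call bar, plus per-variant
quality scores uniform on a configurable range.

What passing tests do **not** show about real data: no LD structure (so
region counts here are by construction, not by haplotype), no confounding
of exposure with ancestry, binary-only exposures, no genotyping batch
effects, and X-chromosome variants are treated as autosomal additive.

## Problem sizes and numerical choices

The calibration and its out-of-sample check use 1e5–1.5e5 null tests
(Monte-Carlo SE of the threshold ≈ 1.5e-4); distributional test fixtures use
2,000 replicates at n=538 and 100–200 replicates at n=2,000/2,000 for
power/recovery properties — sizes at which the asserted tolerances are
several Monte-Carlo standard errors wide. Probability triplets are
validated to sum to 1 within 1e-6; batched Newton uses a 1e-10 ridge
purely to guard singular information matrices in degenerate chunks; LRT
statistics are clipped at zero (they can go infinitesimally negative by
round-off when both fits converge).

## Known limitations

- Dosage (fractional) genotypes are not an association input; triplets are
  hard-called first.
- Sample-level QC (call rate, relatedness, heterozygosity) is out of
  scope; inputs are assumed to be unrelated individuals.
- The Wald interaction test is conservative under near-separation
  (Hauck-Donner); such fits are flagged rather than corrected.
- Calibration assumes exchangeable independent null variants; with strong
  LD the effective dependence between stages could differ.
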