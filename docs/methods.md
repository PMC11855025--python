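# Methods

## The conditional triad likelihood

The unit of analysis is a case family: an affected child with both parents
genotyped (triad) or one parent genotyped (case-mother / case-father dyad).
At a biallelic autosomal SNP with minor-allele frequency `q`, conditioning
on the child being affected gives a multinomial over the 16 origin-resolved
configurations `(m, f, a_m, a_f)` — mother and father minor-allele doses and
the maternally/paternally transmitted allele indicators:

```
P(m, f, a_m, a_f | affected) ∝ π(m; q) π(f; q) τ(a_m | m) τ(a_f | f)
                               × Rm^m × Rcm^(a_m) × Rcf^(a_f)
```

* `π(·; q)` — Hardy–Weinberg genotype frequencies `(1−q)², 2q(1−q), q²`.
  Random mating makes the parental genotypes independent.
* `τ` — Mendelian transmission: ½ for a heterozygous parent, 1 otherwise.
* `Rm` — maternal per-allele relative risk (multiplicative in the mother's
  dose), the maternal-effect estimand.
* `Rcm`, `Rcf` — relative risks of a maternally vs paternally inherited
  minor allele. The parent-of-origin (PoO) estimand is the relative-risk
  ratio `RRR = Rcm / Rcf`; the homozygous child carries `Rcm·Rcf`
  (multiplicative). A plain child-dose model constrains `Rcm = Rcf = Rc`.

The baseline disease risk cancels in the conditional form, so it is never a
parameter. The 16 categories collapse to 15 observable `(m, f, c)` triples;
only `(1, 1, 1)` is origin-ambiguous and its likelihood sums both origins.
Dyads marginalize the missing parent's dose exactly inside the likelihood.
Reference implementations of this model family typically phrase the missing
data as an EM iteration; direct marginalization has the same maximizer with
a simpler convergence contract, and is what this package does.

Model choice is a `ModelSpec` with effects drawn from `{child_dose,
maternal_dose, poo}` (`child_dose` and `poo` are mutually exclusive
parameterizations of the child term). The maternal scan model co-estimates
the child dose effect by default because maternal and child doses are
correlated and omitting a real child effect biases `Rm`; `maternal_only`
drops it.

### Two conditioning variants and their closed forms

* Default: the full HWE + random-mating likelihood above, nuisance `q`
  estimated on the logit scale per fit. For the multiplicative child model
  on complete triads this likelihood factorizes over the four parental
  alleles — untransmitted alleles are Bernoulli(`q`), transmitted alleles
  Bernoulli(`qRc/(1−q+qRc)`) — so the MLE of `Rc` has the closed form
  *odds ratio of minor-allele counts among transmitted vs untransmitted
  parental alleles*. The test suite verifies the optimizer against this
  form at 1e-6.
* `conditional_on_parents=True`: condition each complete triad on the
  parental genotype pair (mating type). `q` drops out, robustness to
  allele-frequency misspecification is gained, efficiency from the parental
  enrichment is lost, and the multiplicative child-model MLE becomes the
  classical TDT transmission ratio `T/NT` from heterozygous parents — the
  second closed-form oracle in the suite. These two closed forms differ in
  finite samples; they estimate the same quantity under the model.

### Estimation and numerics

Families sharing an observed `(m, f, c)` pattern contribute identical terms,
so each fit reduces to at most ~45 pattern weights against the 16-category
weight vector. Maximization is BFGS on the unconstrained scale (logit `q`,
log relative risks) with an analytic gradient, started at the null (`q` =
parental allele frequency clipped to [0.02, 0.98], log RRs = 0), gradient
tolerance 1e-8, at most 200 iterations. The covariance is the inverse of a
central-finite-difference Hessian of the negative log-likelihood (step
1e-5·(1+|x|)). Degenerate fits — no informative families, separation
(|log RR| > 12), a singular or non-positive Hessian — are flagged
`converged=False` with infinite standard errors, never raised mid-scan.
Mendelian-impossible complete patterns are excluded from the fit with a
logged count (upstream, `validate_mendelian` reports them and the default
policy masks the offending parental dose).

## Wald tests

Main effects: two-sided Wald z on the log scale; 95% CIs as
`exp(est ± 1.96·SE)`. Interaction: the exposure strata are disjoint
families fitted independently (each with its own nuisance `q`), so

```
W = (θ̂₁ − θ̂₀)² / (se₀² + se₁²),   p = P(χ²₁ ≥ W),
```

where θ is `log Rm` (maternal) or `log RRR` (PoO, with the delta-method
variance from the stratum covariance of `(log Rcm, log Rcf)`). Families
with a missing value of the tested exposure are excluded from that scan
only. `wald_from_cis` inverts printed stratified CIs back to SEs
(`(log hi − log lo)/3.92`) for consistency checks against published tables.

## Region pooling

Per-SNP interaction p-values are clipped to `[1e-15, 1−1e-15]` and combined
per region two ways:

* **Empirical Fisher.** `F = −2Σ log p_i` referred to a Monte-Carlo null:
  draw `B` multivariate normal z-vectors with the founder genotype
  correlation matrix `R` (Pearson on parental doses, pairwise-complete,
  monomorphic columns set to identity with a warning, shrunk by 1e-6 toward
  the identity), convert to two-sided p-values, and report
  `(1 + #{F_b ≥ F_obs})/(B + 1)`. Mapping dose correlation directly to
  z-score correlation is a first-order approximation to the dependence of
  the Wald statistics; it is exact under the null for large samples and is
  preferred here for being assumption-explicit and reproducible. Default
  `B = 10 000`; the seed is an explicit argument and region streams derive
  from it deterministically, so region p-values are bit-reproducible.
* **Cauchy combination.** `T = Σ w_i tan((0.5−p_i)π)`,
  `p = 0.5 − arctan(T)/π`, equal weights by default, with the standard
  `w_i/(p_i π)` guard below 1e-16. Valid under arbitrary dependence.

The reported region p-value is the **minimum** of the two, judged against
`alpha / n_regions` (Bonferroni). Taking the minimum without a correction
for having tried two combiners is anti-conservative; it is reproduced here
deliberately as the published reporting convention, and both components are
always written alongside it.

## The synthetic cohort generator

Because every analysis conditions on the affected child, the generator
samples each family **directly from the conditional multinomial** for its
exposure stratum — no baseline risk, no rejection step, exact for the
analysis model by construction. One goodness-of-fit test
(`test_generator_and_likelihood_share_one_conditional_model`) ties the
generator and the likelihood to the same distribution; everything else rests
on that.

Defaults are the study conditions the package emulates: 404 triads + 26
case-mother + 14 case-father dyads (dyads are sampled as triads and the
designated parent deleted), smoking prevalence 99/444, folate prevalence
218/444, 17/444 missing smoking status, CL/P fraction 317/442 with 2/444
missing subtype, 272/444 male children, minor-allele frequency 0.25.
Exposure is Bernoulli, drawn independently of the mating type; subtype and
sex are assigned independently of genotype (a `clp_only_effects` flag
restricts the risk parameters to CL/P families for stress tests). The
`paper_like_scenario()` preset used for calibration and power tables keeps
the family composition and `q = 0.25` but balances the exposure
(prevalence 0.5), the canonical condition for a between-strata test.

LD within a block of SNPs comes from a latent Gaussian copula on
haplotypes: exchangeable latent correlation calibrated (bivariate normal
CDF + Brent root-finding) so the founder *dose* correlation hits the target
`r`; children inherit whole haplotypes, so LD propagates without
recombination. Non-causal SNPs in the causal SNP's block are drawn
conditional on each haplotype's causal allele, which is exact because the
disease depends on the causal SNP only. Blocks are independent;
`r ∈ [0, 1)` per block.

What the generator deliberately does **not** emulate: population
stratification and allele-frequency heterogeneity between recruitment
sites, assortative mating, genotyping error, imputation uncertainty, real
(non-exchangeable) LD, recombination, X-linked loci. Passing tests
therefore certify the statistics under the design's own assumptions, not
robustness to their violation — the known fragility of HWE-based triad
models to between-population frequency differences is inherited, not
solved.

## Power analysis

`estimate_power` simulates replicate cohorts, runs the stratified fits and
the interaction Wald test at the causal SNP, and reports the rejection
fraction with a Wilson 95% interval. Replicate streams derive from the
master seed by a counter scheme (`SeedSequence(seed, spawn_key=(i,))`), so
the estimate is independent of scheduling and reproducible from the seed
ledger. Non-converged replicates are counted and reported, never treated as
rejections. `power_curve` sweeps the exposed-stratum effect size with the
unexposed stratum at the null; for PoO the ratio `g` is split symmetrically
(`Rcm = √g`, `Rcf = 1/√g`).

The study-composition preset power table (alpha = 0.05/12, the Bonferroni
level for a 12-region panel) is *documented output, not a reproduction*:
the original power analysis's full scenario (its MAF, exposure prevalence
and exact alpha) is not specified in the main text it derives from, so this
package states its own preset and reports what that preset yields. Problem
sizes throughout the test suite and acceptance script (500-triad closed-form
checks, 1000-replicate calibration, 200-replicate recovery at 2000 triads,
150–300-replicate power points) were chosen as the smallest runs whose
Monte-Carlo error is well inside the margins being asserted.

## Data handling choices

* The minor allele is defined cohort-wide from **parental** genotypes
  (cases are ascertained; parents approximate the source population); a tie
  at 0.5 is broken toward the lexicographically smaller allele string.
  Orientation is idempotent.
* VCF positions are 1-based; region files are BED-like 0-based half-open.
  SNP identity is `(chrom, pos, alleles)` with the rsID as metadata.
* Families with missing exposure stay in the cohort and in summaries
  (full-count denominators, missing counts reported separately) and drop
  out only of the affected exposure's interaction scan. Summary percentages
  use the full family count as denominator even when a variable has missing
  values, matching the reporting convention of the tables the summary
  emulates.
* Mendelian-inconsistent (family, SNP) pairs default to masking the
  offending parental dose (the parent impossible against the child alone;
  both parents when only the pair is jointly impossible); `--exclude-family`
  removes the family instead.

## Open choices made here

* Whether the maternal analysis should co-estimate the child effect is not
  externally fixed; joint estimation is the default (safer under a real
  child effect), `maternal_only` provided.
* Each stratum estimates its own allele-frequency nuisance; sharing `q`
  across strata is statistically legitimate but couples the fits, and the
  Wald difference of independent fits is the cleaner match to the
  between-strata test being reproduced.
* Monte-Carlo defaults for the empirical Fisher null (`B = 10 000`, seeded)
  are declared package conventions, not inferred from any reference run.
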