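# Methods

`exoburden` implements a rare-variant gene burden association pipeline of
the kind large sequencing consortia run in a decentralised fashion: each
cohort applies a shared quality-control and analysis protocol locally and
only summary statistics are pooled. This note documents the statistical
model, the defaults and the design choices where the design was genuinely
open.

## Phenotypes

Three nested case definitions are analysed against all remaining samples
(including population controls of unknown status): severe disease (A2),
hospitalisation (B2) and susceptibility/infection (C2), with A2 ⊆ B2 ⊆ C2
as case sets. Every stage of the package enforces this nesting.

## Quality control

QC proceeds genotype → sample → variant, with call rates always computed
after genotype-level masking:

| stage | rule | boundary |
|---|---|---|
| genotype | GQ < 20, DP < 10, or allele balance: hom-ref AB > 0.1, hom-alt AB < 0.9, het AB outside [0.25, 0.75] | strict |
| sample | call rate < 97% or mean depth < 20 | strict |
| variant | mean GQ < 11, mean DP < 6, call rate ≤ 0.8, HWE p ≤ 5e-8 (burden) / ≤ 1e-16 (single variant) | call rate and HWE inclusive |

Allele balance is the alternate-read fraction AD_alt/(AD_ref+AD_alt); the
underlying protocols name the quantity without a formula and this is the
conventional definition. Hardy-Weinberg equilibrium uses the
Levene-Haldane exact conditional test (the probability-mass tail summed
over heterozygote configurations no likelier than the observed one),
because the chi-square approximation is badly anti-conservative exactly
where this pipeline lives — rare variants. On chromosome X the HWE test
uses female genotypes only.

Hemizygous male X calls are stored as dosage 0 or 2. This single
convention makes a male carrying one deleterious X allele land in the
homozygous stratum of the burden score and contribute one allele to
allele-frequency computations, which is how consortium summary tables
count male carriers.

## Masks and frequency policy

Variants qualify through three nested deleteriousness masks on the
canonical transcript:

* **M1** — the eight Ensembl high-impact (pLoF) terms: transcript
  ablation, splice acceptor, splice donor, stop gained, frameshift, stop
  lost, start lost, transcript amplification;
* **M3** — M1 + moderate-impact indels + missense deleterious in all five
  predictors (SIFT, LRT, MutationTaster, PolyPhen2-HDIV, PolyPhen2-HVAR);
* **M4** — M3 + missense deleterious in ≥ 1 predictor.

Open choices resolved here: "moderate-consequence indels" is interpreted
as `is_indel AND impact == MODERATE` with no predictor requirement;
missing predictor verdicts count as *not* deleterious (conservative for
M3); variants absent from the reference panel are treated as rare (a
novel variant cannot exceed a panel frequency threshold); panel MAF is
global, not ancestry-matched.

Each analysis runs at a MAF threshold of 1% or 0.1%. A variant qualifies
only if its reference-panel MAF is at or below the threshold *and* it is
not on the consortium exclusion list — the union over cohorts of variants
with in-cohort MAC ≥ 6 and MAF above the threshold. The MAC ≥ 6 guard
keeps tiny cohorts from blacklisting variants on sampling noise.

## Burden score and regression

Per gene, mask and threshold each individual scores 0 (no qualifying
variant), 1 (≥ 1 heterozygous qualifying variant) or 2 (≥ 1 homozygous or
hemizygous qualifying variant). Compound heterozygotes are deliberately
*not* promoted to 2 — the score tracks the worst single genotype, which
keeps cross-cohort meta-analysis of the score interpretable. Samples with
every qualifying call missing score 0, matching the complete-case
handling of the regressor.

The score is the exposure in a Firth-penalized logistic regression with
covariates age, age², sex, age·sex, age²·sex, 10 principal components
from common variants (MAF > 1%) and 20 principal components from rare
variants (MAF < 1%; burden tests only — single-variant tests use the
common-PC set and additionally require MAF > 0.1% and MAC ≥ 6, reading
the "allele count of 6 or more" phrasing as MAC ≥ 6). Firth's Jeffreys
penalty ½·log det I(β) removes first-order small-sample bias and yields
finite estimates under complete separation, the regime produced by zero
control carriers.

Implementation: Newton iterations on the modified score with
step-halving; convergence at gradient max-norm ≤ 1e-6, max 100
iterations; per-gene fits warm-started from a covariates-only base fit.
P-values are two-sided Wald from the penalized β/SE (consistent with how
consortium tables print beta, SE and p); a penalized likelihood-ratio
p-value per coefficient is available as `firth_lrt_p`. This is a
documented deviation from pipelines that use an approximate Firth LRT.
There is no whole-genome ridge/LOCO polygenic predictor stage: the
package fits Firth regressions directly, with structure control left to
the PCs. Relatedness control is out of scope.

Rare-variant PCs are computed leave-one-chromosome-out: at desk-scale
variant panels the tested gene's own variants would otherwise dominate a
component and become exactly collinear with (or absorb) its burden score.
Exome-scale analyses are insensitive to this; small panels are not. PCs
come from the standardized dosage matrix (missing calls mean-imputed,
variants scaled by √(2p(1−p))), computed exactly via the Gram-matrix
spectrum with a deterministic sign convention, with PC counts capped at a
quarter of the available variants — at the panel size itself the PC span
contains every variant and one-variant gene scores become collinear by
construction.

## Meta-analysis

Stage 1 pools cohorts within each of six genetic ancestries (AFR, AMR,
EAS, EUR, MID, SAS) by fixed-effect inverse-variance weighting; stage 2
pools ancestry-level estimates with the DerSimonian-Laird moment
estimator (τ² floored at zero, no iterative refinement — the named
estimator, not Paule-Mandel/REML). The reported heterogeneity p-value is
Cochran's Q at the across-ancestry stage; within-ancestry heterogeneity
is computed but not reported. When Q ≤ k−1 the random-effects result
equals the fixed-effect result exactly. Genes present in one ancestry
pass through stage 2 unchanged.

P-values across masks (per gene and phenotype; mask × threshold jointly
is supported, masks-only is the default) combine with the aggregated
Cauchy association test, T = Σ wᵢ·tan((0.5−pᵢ)π)/Σwᵢ with equal weights,
combined p = 0.5 − arctan(T)/π. ACAT tolerates the strong positive
dependence between nested masks; p below 1e-15 uses the asymptotic
1/(pπ) tangent replacement. Calibration is monitored with the genomic
inflation factor λ = median(χ²₁-quantile of 1−p)/0.456, and multiplicity
with Bonferroni thresholds α/n_genes (0.05/20,000 = 2.5e-6 exome-wide).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not sequencing physics. Per variant, genotypes are binomial in an
ancestry-specific frequency drawn Balding-Nichols style (a beta draw
around the global MAF with an FST-like parameter, default 0.002 — beta
draws at rare frequencies degenerate to monomorphism well below the
common-variant F ≈ 0.01, so the default is deliberately mild; pass a
larger value to manufacture cross-ancestry heterogeneity). Male X
genotypes are haploid. Rare MAFs are log-uniform on (2e-5, 1e-3) by
default; a block of common variants supports PC computation. Annotations
assign consequence classes and predictor verdicts consistent with each
variant's mask tier.

Planted effects enter the severe-disease liability as (log-OR) × (burden
score of the causal gene at its mask tier), computed before QC-noise
injection; each causal gene is guaranteed ≥ 5 tier-qualifying variants
whose MAFs are set equal so the gene's carrier fraction hits a
configurable target (default 0.5%) with every variant safely inside the
0.1% policy, and those variants are exempt from the ancestry
perturbation so the realized carrier fraction tracks the target. The
severe phenotype is drawn directly from a logistic model (so the planted
log-OR is exactly the regression estimand); hospitalisation and
infection add further sequential-inclusion draws, preserving nesting by
construction but making the broader phenotypes only approximately
logistic. Age is uniform 30–90 and sex Bernoulli(0.5), matching the
marginal moments typical of these cohorts (mean age ≈ 55, about half
female) without claiming the real shape; age/sex enter each stage's
liability (0.25 per decade, 0.35 male excess by default). QC noise
injects low-GQ, low-DP, aberrant-allele-balance calls and per-sample
missingness at configurable rates (default zero; with all rates zero the
QC stage removes nothing).

What the generator does not emulate — linkage disequilibrium, relatedness,
sequencing-platform batch effects, imputation error, ancestry
misassignment — bounds what passing tests show: they validate the
statistics of the pipeline, not its robustness to real-data artifacts.

## Validation experiments and problem sizes

* **Parameter recovery** (`validation.coverage_experiment`): 50 seeded
  cohorts of n = 20,000 with one X-linked causal gene (log-OR 1.66, mask
  M3, ~0.5% carriers), full pipeline on the severe phenotype; the pooled
  95% CI must cover the generating value in ≥ 90% of replicates.
* **Null calibration** (`validation.null_calibration`): one cohort of
  n = 8,000 with 1,000 null genes at per-variant MAF 0.1–0.5% under the
  1% policy; type-I error at 0.05 must lie in [0.03, 0.07] and λ in
  [0.9, 1.1]. The gene size and frequency range are chosen so genes carry
  tens of carriers: with only a handful of carriers the Wald p-value is
  essentially discrete and no continuous calibration diagnostic is
  meaningful (an exact 2×2 hypergeometric computation of the null
  distribution of the Firth-Wald p shows calibration holding at these
  carrier counts and degrading below ~10 carriers).

## Known limitations

* Wald inference from penalized fits is slightly conservative at very
  small carrier counts; the LRT option mitigates but does not remove this.
* The burden score ignores compound heterozygosity and variant weighting
  by design; variance-component tests (SKAT family) are out of scope.
* The exclusion list uses exact in-cohort MAC/MAF; no allowance is made
  for cohorts reporting frequencies on different reference builds.
* Single-variant and burden analyses share the QC framework but the
  package does not implement the cross-biobank "reference panel"
  restriction some consortia apply to off-target exome calls.
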