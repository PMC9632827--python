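# exoburden

Rare-variant gene burden association testing for case-control sequencing
studies, built for the decentralised consortium setting: every cohort runs
the same quality-control and analysis protocol locally, and only summary
statistics are pooled across cohorts and genetic ancestries.

The package is aimed at statistical geneticists who need a transparent,
fully tested reference implementation of the exome-wide burden-testing
stack — sequencing QC, deleteriousness masks, gene collapsing, penalized
association, meta-analysis — together with a synthetic multi-cohort
generator that makes every stage testable without access to individual-
level data (which, for real consortia, never leaves the cohort).

## The statistics

**Burden score.** Qualifying variants in a gene collapse per individual to
a score s ∈ {0, 1, 2}: 0 with no qualifying variant, 1 with ≥ 1
heterozygous qualifying variant, 2 with ≥ 1 homozygous (or male-X
hemizygous) qualifying variant. Variants qualify through nested masks —
M1 (predicted loss of function), M3 (M1 + moderate-impact indels +
missense deleterious by all 5 in-silico predictors), M4 (M3 + missense
deleterious by ≥ 1 predictor) — at a reference-panel MAF threshold of 1%
or 0.1%, minus a consortium exclusion list (any cohort: MAC ≥ 6 and MAF
above threshold).

**Association.** Firth-penalized logistic regression,
maximising ℓ(β) + ½·log det I(β): the Jeffreys penalty removes
small-sample bias and keeps β finite under complete separation (zero
carrier controls), the defining regime of rare-variant case-control
analysis. Covariates: age, age², sex, age·sex, age²·sex, 10 common-variant
PCs, and 20 rare-variant PCs for burden tests.

**Meta-analysis.** Fixed-effect inverse-variance pooling of cohorts
within ancestry, DerSimonian-Laird random effects across ancestries
(τ² by method of moments, Cochran's Q heterogeneity p), and the
aggregated Cauchy association test (ACAT) to combine p-values across
masks, which is valid under the strong dependence nested masks induce.
Calibration is tracked by the genomic inflation factor λ and
significance by Bonferroni thresholds (0.05/20,000 = 2.5×10⁻⁶
exome-wide).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

`examples/04_end_to_end_meta.py` simulates a two-cohort, two-ancestry
consortium with one planted gene effect (log-OR 1.2 at mask M3), builds
the shared exclusion list, runs the per-cohort pipeline and pools the
summary statistics:

```
exclusion list (MAF>0.1%, MAC>=6 in any cohort): 71 variants

meta-analysis, planted gene (true log-OR 1.2):
  beta 1.029  se 0.475  OR 2.80 (95% CI 1.10-7.10)
  p 3.03e-02  heterogeneity p 0.729  ancestries 2
  cases 0|1|2: 345|4|0   controls 0|1|2: 7609|42|0

ACAT across masks: p = 4.29e-02
```

The planted log-odds ratio 1.2 sits inside the pooled 95% CI; the
"0|1|2" strings are the burden-score carrier counts for cases and
controls in the convention consortium tables print; the heterogeneity
p-value is Cochran's Q across the two ancestries. Other examples cover
cohort simulation (`01`), QC and masks on noisy data (`02`), Firth under
complete separation (`03`) and sex-stratified X-linked analysis (`05`).

A thin CLI mirrors the decentralised protocol
(`exoburden simulate | qc | mask | collapse | assoc | build-exclusion-list
| meta | acat`), exchanging VCF and TSV files.

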