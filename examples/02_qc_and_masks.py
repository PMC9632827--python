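"""Sequencing QC and deleteriousness-mask classification on noisy data.

Injects genotype-level artifacts (low GQ, low depth, aberrant allele
balance, per-sample missingness) into a simulated cohort, runs the QC
framework, and classifies the surviving variants into the nested M1/M3/M4
masks.  The printed removal counts show each filter acting at its
threshold: calls masked at GQ<20 / DP<10 / bad allele balance, samples
dropped below 97% call rate or mean depth 20, variants dropped at mean
GQ<11, mean depth<6, call rate <= 0.8 or HWE p <= 5e-8.
"""

from exoburden import QCNoise, SimulationConfig, classify_masks, run_qc, simulate_cohort
from exoburden.containers import MISSING

cfg = SimulationConfig(
    n_samples=1500,
    n_genes=12,
    qc_noise=QCNoise(low_gq=0.003, low_dp=0.003, bad_ab=0.005, sample_missingness=0.02),
    seed=8,
)
cohort = simulate_cohort(cfg)
g = cohort.genotypes

res = run_qc(g)
n_masked = (res.genotypes.dosage == MISSING).sum() - (g.dosage == MISSING).sum()
print(f"variants in: {g.n_variants}, samples in: {g.n_samples}")
print(f"samples removed: {res.removed_samples['sample'].nunique()} "
      f"({', '.join(res.removed_samples['reason'].unique())})")
print(f"variants removed: {res.removed_variants['variant'].nunique()}")
print("removal reasons:")
print(res.removed_variants["reason"].value_counts().to_string())

member = classify_masks(cohort.annotations)
print("\nmask sizes (nested by construction):")
for m in ("M1", "M3", "M4"):
    print(f"  {m}: {member[m].sum()} variants")
# M1 counts only predicted loss-of-function; M3 adds moderate-impact
# indels and 5/5-predictor missense; M4 adds >=1-predictor missense.
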