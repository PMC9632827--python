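"""Sex-stratified burden testing of an X-linked gene.

On chromosome X, male carriers are hemizygous and collapse to burden
score 2 (homozygous stratum), while female heterozygotes score 1.  A
sex-stratified fit checks whether the severe-disease effect is present in
both sexes — the pattern that distinguishes a dominant/co-dominant
X-linked risk factor from a purely male phenomenon.
"""

import numpy as np

from exoburden import (
    CausalGene,
    CovariateSet,
    SimulationConfig,
    collapse_genes,
    sex_stratified_burden,
    simulate_cohort,
)
from exoburden.masks import ExclusionList, FrequencyPolicy, qualifying_variants

cfg = SimulationConfig(
    n_samples=12_000,
    n_genes=8,
    causal_genes=(CausalGene("GENE0005", 1.66, "M3"),),
    causal_carrier_freq=0.01,
    x_linked_genes=("GENE0005",),
    seed=99,
)
cohort = simulate_cohort(cfg)

policy = FrequencyPolicy(maf_threshold=0.01,
                         exclusion_list=ExclusionList(threshold=0.01))
qual = qualifying_variants(cohort.annotations, "M3", policy)
scores = collapse_genes(cohort.genotypes, {"GENE0005": qual["GENE0005"]}, "M3", 0.01)

cov = CovariateSet(
    age=cohort.phenotypes["age"].to_numpy(),
    sex=cohort.phenotypes["sex"].to_numpy(),
)
for stratum in ("male", "female"):
    res = sex_stratified_burden(scores, cohort.phenotypes, cov, stratum)[0]
    lo, hi = res.ci()
    print(
        f"{stratum:6s}: OR {res.odds_ratio:5.2f} (95% CI {lo:.2f}-{hi:.2f})  "
        f"cases 0|1|2 {res.case_counts}  controls 0|1|2 {res.control_counts}"
    )
# Male carriers appear in the score-2 column; female carriers in score 1.
# Both strata should show an elevated odds ratio under the planted
# co-dominant effect (log-OR 1.66 per score unit).
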