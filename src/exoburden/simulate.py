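"""Synthetic multi-ancestry case-control exome cohorts.

Generates datasets with the statistical structure the pipeline assumes:
rare deleterious variants binomially sampled at ancestry-perturbed MAFs,
hemizygous male X genotypes, annotation tables whose consequence terms and
predictor verdicts place each variant in a known mask tier, nested
case-control phenotypes (severe ⊆ hospitalised ⊆ infected) drawn from a
logistic model with age/sex effects and planted per-gene burden effects,
and optional QC artifacts (low-GQ, low-DP, aberrant allele-balance calls,
per-sample missingness).

The severe phenotype is generated directly from a logistic model so that
the planted log-odds ratio is exactly the estimand of the severe-outcome
burden regression; the broader phenotypes add further case draws on top
(sequential inclusion), which preserves nesting by construction.  Ancestry
allele-frequency perturbation uses a Balding-Nichols beta draw around each
variant's global MAF with a configurable FST-like parameter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .collapse import collapse_genes
from .containers import GenotypeMatrix, check_phenotypes
from .masks import LOF_CONSEQUENCES, MASKS, PREDICTOR_COLUMNS

# proportions of annotation classes within a gene's variants
_CLASS_PROBS = {
    "lof": 0.15,
    "missense_strict": 0.15,  # deleterious by all five predictors
    "missense_partial": 0.20,  # deleterious by 1-4 predictors
    "moderate_indel": 0.05,
    "missense_benign": 0.20,
    "synonymous": 0.25,
}


@dataclass(frozen=True)
class CausalGene:
    gene: str
    log_or: float
    tier: str = "M3"  # mask at which the gene's qualifying variants act

    def __post_init__(self):
        if self.tier not in MASKS:
            raise ValueError(f"causal tier must be one of {MASKS}, got {self.tier!r}")


@dataclass(frozen=True)
class PhenotypeModel:
    """Logistic intercepts and covariate effects for the three outcomes.

    ``a2_intercept`` sets the severe-disease baseline prevalence directly;
    ``b2_extra`` and ``c2_extra`` are the log-odds of the *additional*
    draws that promote non-severe samples into the hospitalised and
    infected case sets.  Age enters per decade from age 55, matching a
    cohort mix centred in late middle age.
    """

    a2_intercept: float = -3.6
    b2_extra: float = -3.0
    c2_extra: float = -2.0
    age_beta: float = 0.25  # per decade above 55, severe outcome
    sex_beta: float = 0.35  # male excess risk


@dataclass(frozen=True)
class QCNoise:
    """Rates of injected sequencing artifacts (all zero = clean data)."""

    low_gq: float = 0.0
    low_dp: float = 0.0
    bad_ab: float = 0.0
    sample_missingness: float = 0.0

    def any(self) -> bool:
        return any((self.low_gq, self.low_dp, self.bad_ab, self.sample_missingness))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort."""

    n_samples: int = 20_000
    ancestries: tuple = (("EUR", 1.0),)  # (label, proportion) pairs
    n_genes: int = 50
    variants_per_gene: int = 10
    n_common_variants: int = 60  # MAF in (0.05, 0.5), for common-variant PCs
    maf_range: tuple = (2e-5, 1e-3)  # log-uniform rare-variant MAF support
    causal_genes: tuple = ()
    causal_carrier_freq: float = 0.005  # target carrier fraction per causal gene
    x_linked_genes: tuple = ()
    phenotype_model: PhenotypeModel = PhenotypeModel()
    qc_noise: QCNoise = QCNoise()
    fst: float = 0.002  # beta-draw differentiation; rare MAFs degenerate fast above this
    male_fraction: float = 0.5
    cohort: str = "cohort1"
    seed: int = 2024

    def __post_init__(self):
        labels = [a for a, _ in self.ancestries]
        valid = {"AFR", "AMR", "EAS", "EUR", "MID", "SAS"}
        if not set(labels) <= valid:
            raise ValueError(f"ancestry labels must be a subset of {sorted(valid)}")
        props = np.array([p for _, p in self.ancestries], dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("ancestry proportions must sum to 1")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        for cg in self.causal_genes:
            if cg.gene not in self.gene_names():
                raise ValueError(f"causal gene {cg.gene!r} not among simulated genes")
        for g in self.x_linked_genes:
            if g not in self.gene_names():
                raise ValueError(f"x-linked gene {g!r} not among simulated genes")

    def gene_names(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    annotations: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict
    config: SimulationConfig


def _draw_annotations(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant table: positions, genes, consequence classes, predictor
    verdicts consistent with each variant's mask tier, panel MAFs."""
    genes = cfg.gene_names()
    x_genes = set(cfg.x_linked_genes)
    classes = list(_CLASS_PROBS)
    probs = np.array([_CLASS_PROBS[c] for c in classes])
    rows = []
    for gi, gene in enumerate(genes):
        chrom = "X" if gene in x_genes else str(1 + gi % 22)
        base = 1_000_000 * (gi + 1)
        var_classes = rng.choice(classes, size=cfg.variants_per_gene, p=probs)
        for vi, cls in enumerate(var_classes):
            pos = base + vi * 100 + int(rng.integers(1, 100))
            is_indel = cls == "moderate_indel"
            if cls == "lof":
                consequence = rng.choice(sorted(LOF_CONSEQUENCES))
                impact = "HIGH"
                n_del = int(rng.integers(0, 6))
            elif cls == "moderate_indel":
                consequence = rng.choice(["inframe_insertion", "inframe_deletion"])
                impact = "MODERATE"
                n_del = int(rng.integers(0, 6))
            elif cls == "missense_strict":
                consequence, impact, n_del = "missense_variant", "MODERATE", 5
            elif cls == "missense_partial":
                consequence, impact, n_del = "missense_variant", "MODERATE", int(rng.integers(1, 5))
            elif cls == "missense_benign":
                consequence, impact, n_del = "missense_variant", "MODERATE", 0
            else:
                consequence, impact, n_del = "synonymous_variant", "LOW", 0
            verdicts = ["deleterious"] * n_del + ["tolerated"] * (5 - n_del)
            rng.shuffle(verdicts)
            ref, alt = ("A", "AT") if (is_indel and consequence == "inframe_insertion") else (
                ("AT", "A") if is_indel else ("A", "G")
            )
            row = {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": consequence,
                "impact": impact,
                "is_indel": is_indel,
                "class": cls,
            }
            row.update(dict(zip(PREDICTOR_COLUMNS, verdicts)))
            rows.append(row)
    ann = pd.DataFrame(rows)
    # rare-variant global MAFs, log-uniform over the configured support
    lo, hi = cfg.maf_range
    ann["maf"] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ann)))
    # causal genes: guarantee tier-qualifying variants and scale their MAFs
    # so the gene's carrier fraction lands near the configured target
    tier_classes = {
        "M1": ("lof",),
        "M3": ("lof", "moderate_indel", "missense_strict"),
        "M4": ("lof", "moderate_indel", "missense_strict", "missense_partial"),
    }
    ann["causal_qualifying"] = False
    for cg in cfg.causal_genes:
        in_gene = ann.index[ann["gene"] == cg.gene]
        qual = in_gene[ann.loc[in_gene, "class"].isin(tier_classes[cg.tier])]
        want = min(5, len(in_gene))
        if len(qual) < want:
            promote = in_gene.difference(qual)[: want - len(qual)]
            lead = tier_classes[cg.tier][-1]
            cons = {
                "lof": ("stop_gained", "HIGH", 5),
                "moderate_indel": ("inframe_deletion", "MODERATE", 0),
                "missense_strict": ("missense_variant", "MODERATE", 5),
                "missense_partial": ("missense_variant", "MODERATE", 2),
            }[lead]
            ann.loc[promote, "consequence"] = cons[0]
            ann.loc[promote, "class"] = lead
            ann.loc[promote, "impact"] = cons[1]
            ann.loc[promote, "is_indel"] = lead == "moderate_indel"
            for col, verdict in zip(
                PREDICTOR_COLUMNS, ["deleterious"] * cons[2] + ["tolerated"] * (5 - cons[2])
            ):
                ann.loc[promote, col] = verdict
            qual = in_gene[ann.loc[in_gene, "class"].isin(tier_classes[cg.tier])]
        # equal per-variant MAFs keep each qualifying variant safely below
        # the 0.1% policy threshold while hitting the carrier target
        ann.loc[qual, "maf"] = cfg.causal_carrier_freq / 2.0 / len(qual)
        ann.loc[qual, "causal_qualifying"] = True
    # common background variants (autosomal, gene-less) for PC computation
    common = pd.DataFrame(
        {
            "chrom": "22",
            "pos": 50_000_000 + np.arange(cfg.n_common_variants) * 1000,
            "ref": "C",
            "alt": "T",
            "gene": "",
            "consequence": "intron_variant",
            "impact": "LOW",
            "is_indel": False,
            "class": "common_background",
            "maf": rng.uniform(0.05, 0.5, size=cfg.n_common_variants),
        }
    )
    for col in PREDICTOR_COLUMNS:
        common[col] = ""
    common["causal_qualifying"] = False
    ann = pd.concat([ann, common], ignore_index=True)
    ann["causal_qualifying"] = ann["causal_qualifying"].astype(bool)
    # reference-panel MAF: the generating global MAF (the panel is assumed
    # large enough to estimate it without error)
    ann["panel_maf"] = ann["maf"]
    return ann


def _ancestry_mafs(maf, fst, rng):
    """Balding-Nichols perturbation of global MAFs for one ancestry."""
    if fst <= 0:
        return maf.copy()
    a = maf * (1.0 - fst) / fst
    b = (1.0 - maf) * (1.0 - fst) / fst
    drawn = rng.beta(a, b)
    return np.clip(drawn, 1e-7, 0.5)


def _draw_metadata(cfg, rng, dosage):
    """GQ/DP/allele-balance consistent with the drawn genotypes, then
    QC-noise injection."""
    shape = dosage.shape
    gq = rng.integers(30, 100, size=shape).astype(np.int16)
    dp = np.maximum(rng.poisson(35, size=shape), 12).astype(np.int16)
    ab = np.empty(shape, dtype=np.float32)
    ab[dosage == 0] = rng.uniform(0.0, 0.02, size=int((dosage == 0).sum()))
    ab[dosage == 2] = rng.uniform(0.98, 1.0, size=int((dosage == 2).sum()))
    het = dosage == 1
    ab[het] = np.clip(rng.normal(0.5, 0.05, size=int(het.sum())), 0.30, 0.70)
    noise = cfg.qc_noise
    if noise.low_gq > 0:
        hit = rng.random(shape) < noise.low_gq
        gq[hit] = rng.integers(0, 20, size=int(hit.sum()))
    if noise.low_dp > 0:
        hit = rng.random(shape) < noise.low_dp
        dp[hit] = rng.integers(0, 10, size=int(hit.sum()))
    if noise.bad_ab > 0:
        hit = (rng.random(shape) < noise.bad_ab) & het
        n_hit = int(hit.sum())
        low = rng.uniform(0.02, 0.20, size=n_hit)
        high = rng.uniform(0.80, 0.98, size=n_hit)
        ab[hit] = np.where(rng.random(n_hit) < 0.5, low, high)
    if noise.sample_missingness > 0:
        miss_rate = rng.uniform(0, noise.sample_missingness, size=shape[0])
        hit = rng.random(shape) < miss_rate[:, None]
        dosage[hit] = -1
    return gq, dp, ab


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw one complete synthetic cohort.

    Raises if any of the three phenotypes ends up with zero cases or zero
    controls, naming the phenotype.
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _draw_annotations(cfg, rng)
    n, m = cfg.n_samples, len(ann)

    labels = [a for a, _ in cfg.ancestries]
    props = [p for _, p in cfg.ancestries]
    ancestry = rng.choice(labels, size=n, p=props)
    is_male = rng.random(n) < cfg.male_fraction
    age = rng.uniform(30, 90, size=n)

    global_maf = ann["maf"].to_numpy()
    x_col = ann["chrom"].to_numpy() == "X"
    dosage = np.zeros((n, m), dtype=np.int8)
    for lab in labels:
        sel = ancestry == lab
        anc_rng = np.random.default_rng((cfg.seed, zlib.crc32(lab.encode())))
        p_anc = _ancestry_mafs(global_maf, cfg.fst, anc_rng)
        # planted variants stay at their configured frequency in every
        # ancestry so the realized carrier fraction tracks the target
        causal_q = ann["causal_qualifying"].to_numpy()
        p_anc[causal_q] = global_maf[causal_q]
        n_sel = int(sel.sum())
        block = rng.binomial(2, p_anc, size=(n_sel, m)).astype(np.int8)
        if x_col.any():
            male_sel = is_male[sel]
            hemi = rng.binomial(1, p_anc[x_col], size=(int(male_sel.sum()), int(x_col.sum())))
            tmp = block[male_sel]
            tmp[:, x_col] = (hemi * 2).astype(np.int8)
            block[male_sel] = tmp
        dosage[sel] = block

    samples = np.array([f"S{i:06d}" for i in range(n)])
    variants = ann[["chrom", "pos", "ref", "alt"]].copy()

    # planted effects: burden score of each causal gene at its mask tier,
    # computed on the clean genotypes (truth precedes QC-noise injection)
    from .containers import variant_keys as vkeys

    keys = vkeys(ann)
    eta = np.zeros(n)
    truth_genes = []
    clean = GenotypeMatrix(
        dosage=dosage.copy(), gq=None, dp=None, ab=None,
        samples=samples, is_male=is_male, variants=variants,
    )
    from .masks import classify_masks

    membership = classify_masks(ann)
    for cg in cfg.causal_genes:
        in_gene = (ann["gene"] == cg.gene).to_numpy() & membership[cg.tier].to_numpy()
        qual = {cg.gene: keys[in_gene].tolist()}
        scores = collapse_genes(clean, qual, mask=cg.tier, maf_threshold=np.nan)
        s = (
            scores.scores.loc[cg.gene].to_numpy(dtype=float)
            if cg.gene in scores.scores.index
            else np.zeros(n)
        )
        eta += cg.log_or * s
        truth_genes.append(
            {
                "gene": cg.gene,
                "log_or": cg.log_or,
                "tier": cg.tier,
                "carriers": samples[s > 0].tolist(),
                "scores": s.astype(int),
            }
        )

    pm = cfg.phenotype_model
    covar_eta = pm.age_beta * (age - 55.0) / 10.0 + pm.sex_beta * is_male
    a2 = rng.random(n) < expit(pm.a2_intercept + covar_eta + eta)
    b2 = a2 | (rng.random(n) < expit(pm.b2_extra + covar_eta + eta))
    c2 = b2 | (rng.random(n) < expit(pm.c2_extra + covar_eta + eta))
    for name, flags in (("A2", a2), ("B2", b2), ("C2", c2)):
        if flags.sum() == 0:
            raise ValueError(f"simulation produced zero cases for phenotype {name}")
        if flags.sum() == n:
            raise ValueError(f"simulation produced zero controls for phenotype {name}")

    gq, dp, ab = _draw_metadata(cfg, rng, dosage)
    genotypes = GenotypeMatrix(
        dosage=dosage, gq=gq, dp=dp, ab=ab,
        samples=samples, is_male=is_male, variants=variants,
    )
    phenotypes = pd.DataFrame(
        {
            "sample": samples,
            "a2": a2.astype(int),
            "b2": b2.astype(int),
            "c2": c2.astype(int),
            "age": age,
            "sex": is_male.astype(int),
            "ancestry": ancestry,
            "cohort": cfg.cohort,
        }
    )
    check_phenotypes(phenotypes)
    annotations = ann.drop(columns=["class", "maf", "causal_qualifying"])
    truth = {
        "causal_genes": truth_genes,
        "generating_maf": global_maf,
        "variant_class": ann["class"].to_numpy(),
    }
    return SyntheticCohort(
        genotypes=genotypes,
        annotations=annotations,
        phenotypes=phenotypes,
        truth=truth,
        config=cfg,
    )


def plant_separation(
    cfg: SimulationConfig, gene: str, n_case_carriers: int = 9
) -> SyntheticCohort:
    """Simulate a cohort, then force complete separation on one gene.

    After the draw, every severe-outcome control carrier of the gene's
    mask-qualifying variants has those genotypes set to reference, and
    carriers are planted among severe cases until ``n_case_carriers`` is
    reached — the zero-control-carrier regime in which the unpenalized
    logistic MLE diverges while the Firth estimate stays finite.
    """
    if gene not in cfg.gene_names():
        raise ValueError(f"gene {gene!r} not among simulated genes")
    cohort = simulate_cohort(cfg)
    rng = np.random.default_rng((cfg.seed, 7))
    tier = next((cg.tier for cg in cfg.causal_genes if cg.gene == gene), "M3")
    from .containers import variant_keys as vkeys
    from .masks import classify_masks

    ann = cohort.annotations
    membership = classify_masks(ann)
    in_gene = (ann["gene"] == gene).to_numpy() & membership[tier].to_numpy()
    cols = np.flatnonzero(in_gene)
    if cols.size == 0:
        raise ValueError(f"gene {gene!r} has no {tier}-qualifying variants to plant")
    g = cohort.genotypes
    a2 = cohort.phenotypes["a2"].to_numpy(dtype=bool)
    carrier = (g.dosage[:, cols] > 0).any(axis=1)
    # wipe control carriers
    for i in np.flatnonzero(carrier & ~a2):
        g.dosage[i, cols] = 0
        g.ab[i, cols] = 0.01
    # top up case carriers (het; hemizygous-coded for males on X)
    current = int((carrier & a2).sum())
    need = n_case_carriers - current
    x_gene = ann["chrom"].iloc[cols[0]] == "X"
    if need > 0:
        candidates = np.flatnonzero(a2 & ~carrier)
        chosen = rng.choice(candidates, size=min(need, candidates.size), replace=False)
        for i in chosen:
            j = cols[int(rng.integers(0, cols.size))]
            dose = 2 if (x_gene and g.is_male[i]) else 1
            g.dosage[i, j] = dose
            g.ab[i, j] = 0.99 if dose == 2 else 0.5
    elif need < 0:
        drop = rng.choice(np.flatnonzero(carrier & a2), size=-need, replace=False)
        for i in drop:
            g.dosage[i, cols] = 0
            g.ab[i, cols] = 0.01
    keys = vkeys(ann)
    carriers_now = (g.dosage[:, cols] > 0).any(axis=1)
    cohort.truth["separated_gene"] = {
        "gene": gene,
        "tier": tier,
        "variant_keys": keys[in_gene].tolist(),
        "case_carriers": g.samples[carriers_now & a2].tolist(),
        "control_carriers": g.samples[carriers_now & ~a2].tolist(),
    }
    return cohort


def simulate_consortium(
    base: SimulationConfig, cohorts: list[tuple[str, tuple]]
) -> list[SyntheticCohort]:
    """Simulate several cohorts from one base config.

    ``cohorts`` lists (cohort name, ancestries) pairs; each cohort gets a
    distinct child seed derived from the base seed.
    """
    out = []
    for i, (name, ancestries) in enumerate(cohorts):
        cfg = replace(base, cohort=name, ancestries=ancestries, seed=base.seed + 1000 * (i + 1))
        out.append(simulate_cohort(cfg))
    return out
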