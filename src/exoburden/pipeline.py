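"""End-to-end orchestration: per-cohort analysis and cross-cohort meta.

``run_cohort`` embodies the decentralised per-cohort run: QC, mask
classification, frequency filtering, 0/1/2 collapsing and Firth burden
tests, executed separately within each genetic ancestry, emitting only
summary statistics (no individual-level data crosses the cohort
boundary).  ``run_meta`` consumes summary tables from many cohorts and
applies the two-stage meta-analysis, ACAT mask combination and inflation
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .association import CovariateSet, burden_test, compute_pcs, results_frame
from .collapse import BurdenScoreMatrix, collapse_genes
from .containers import GenotypeMatrix, check_phenotypes
from .masks import (
    ExclusionList,
    FrequencyPolicy,
    build_exclusion_list,
    qualifying_variants,
)
from .meta import combine_masks_acat, genomic_lambda, two_stage_meta

DEFAULT_MASKS = ("M1", "M3", "M4")
DEFAULT_THRESHOLDS = (0.01, 0.001)
DEFAULT_PHENOTYPES = ("A2", "B2", "C2")


def cohort_allele_stats(g: GenotypeMatrix, cohort: str) -> pd.DataFrame:
    """Per-variant (MAC, MAF) rows for exclusion-list building."""
    stats = g.allele_counts()
    return pd.DataFrame(
        {"cohort": cohort, "key": g.keys, "mac": stats["mac"], "maf": stats["maf"]}
    )


@dataclass
class CohortRun:
    summary: pd.DataFrame
    manifest: dict
    allele_stats: pd.DataFrame
    qc: "qc_mod.QCResult" = field(repr=False, default=None)


def run_cohort(
    genotypes: GenotypeMatrix,
    annotations: pd.DataFrame,
    phenotypes: pd.DataFrame,
    *,
    masks: tuple = DEFAULT_MASKS,
    thresholds: tuple = DEFAULT_THRESHOLDS,
    outcome_phenotypes: tuple = DEFAULT_PHENOTYPES,
    exclusion_lists: dict | None = None,
    n_common_pcs: int = 10,
    n_rare_pcs: int = 20,
    skip_qc: bool = False,
) -> CohortRun:
    """Run the full per-cohort burden pipeline.

    ``exclusion_lists`` maps MAF threshold -> ExclusionList (consortium
    lists built elsewhere); empty lists are used when omitted.  PC counts
    fall back to the available variant count when the cohort is smaller
    than the requested dimensionality (recorded in the manifest).
    Returns the summary-statistics table (one row per gene x mask x
    threshold x phenotype x ancestry), the run manifest, and the cohort's
    allele statistics for consortium exclusion-list building.
    """
    check_phenotypes(phenotypes)
    if not set(masks) <= set(DEFAULT_MASKS):
        raise ValueError(f"masks must be a subset of {DEFAULT_MASKS}")
    cohort = str(phenotypes["cohort"].iloc[0])
    manifest: dict = {
        "cohort": cohort,
        "n_samples_in": genotypes.n_samples,
        "n_variants_in": genotypes.n_variants,
        "masks": list(masks),
        "maf_thresholds": list(thresholds),
    }

    if skip_qc:
        clean = genotypes
        manifest["qc"] = "skipped"
    else:
        qc_res = qc_mod.run_qc(genotypes, mode="burden")
        clean = qc_res.genotypes
        manifest["n_samples_removed"] = int(qc_res.removed_samples["sample"].nunique())
        manifest["n_variants_removed"] = int(qc_res.removed_variants["variant"].nunique())
    manifest["n_samples_analyzed"] = clean.n_samples
    manifest["n_variants_analyzed"] = clean.n_variants

    # align phenotype rows with surviving samples
    pheno = phenotypes.set_index("sample").loc[clean.samples].reset_index()
    stats = cohort_allele_stats(clean, cohort)
    maf_by_key = pd.Series(stats["maf"].to_numpy(), index=stats["key"].to_numpy())
    ann_keys = (
        annotations["chrom"].astype(str)
        + ":" + annotations["pos"].astype(str)
        + ":" + annotations["ref"].astype(str)
        + ":" + annotations["alt"].astype(str)
    )
    cohort_maf_aligned = ann_keys.map(maf_by_key)

    all_rows = []
    for ancestry, anc_pheno in pheno.groupby("ancestry", sort=True):
        idx = anc_pheno.index.to_numpy()
        g_anc = clean.take_samples(idx)
        anc_pheno = anc_pheno.reset_index(drop=True)
        anc_stats = g_anc.allele_counts()

        # keep the PC count well under the variant count: with k equal to
        # the number of variants the PCs span every single dosage vector
        # and any one-variant gene score becomes exactly collinear
        n_common_avail = int((anc_stats["maf"] > 0.01).sum())
        n_rare_avail = int(((anc_stats["maf"] < 0.01) & (anc_stats["maf"] > 0)).sum())
        anc_maf = anc_stats["maf"].to_numpy()
        k_common = min(n_common_pcs, n_common_avail // 4)
        common_pcs = (
            compute_pcs(g_anc, "common", k_common, max_variants=2000, maf=anc_maf)
            if k_common
            else None
        )
        manifest.setdefault("pcs", {})[ancestry] = {"common": k_common}

        # rare PCs are leave-one-chromosome-out: a tested gene's own rare
        # variants must not appear among its covariates, where they could
        # absorb (or mimic) the burden signal
        gene_chrom = annotations.groupby("gene")["chrom"].first().astype(str)
        chrom_col = g_anc.variants["chrom"].astype(str).to_numpy()
        rare_pcs_by_chrom: dict[str, np.ndarray | None] = {}

        def rare_pcs_for(ch: str):
            if ch not in rare_pcs_by_chrom:
                avail = int(
                    (
                        (anc_stats["maf"] < 0.01)
                        & (anc_stats["maf"] > 0)
                        & (chrom_col != ch)
                    ).sum()
                )
                k = min(n_rare_pcs, avail // 4)
                rare_pcs_by_chrom[ch] = (
                    compute_pcs(
                        g_anc, "rare", k, exclude_chrom=ch, max_variants=1500,
                        maf=anc_maf,
                    )
                    if k
                    else None
                )
                manifest["pcs"][ancestry][f"rare_loco_{ch}"] = k
            return rare_pcs_by_chrom[ch]

        for threshold in thresholds:
            excl = (exclusion_lists or {}).get(threshold) or ExclusionList(threshold=threshold)
            policy = FrequencyPolicy(maf_threshold=threshold, exclusion_list=excl)
            for mask in masks:
                qual = qualifying_variants(
                    annotations, mask, policy, cohort_mafs=cohort_maf_aligned
                )
                scores = collapse_genes(g_anc, qual, mask=mask, maf_threshold=threshold)
                if not len(scores.genes):
                    continue
                chrom_of_genes = gene_chrom.reindex(scores.genes)
                for outcome in outcome_phenotypes:
                    y = anc_pheno[{"A2": "a2", "B2": "b2", "C2": "c2"}[outcome]]
                    if y.sum() == 0 or y.sum() == len(y):
                        manifest.setdefault("skipped", []).append(
                            f"{ancestry}/{outcome}: no cases or no controls"
                        )
                        continue
                    for ch, genes in chrom_of_genes.groupby(chrom_of_genes):
                        sub = BurdenScoreMatrix(
                            scores=scores.scores.loc[genes.index],
                            mask=mask,
                            maf_threshold=threshold,
                            skipped_genes=[],
                        )
                        covariates = CovariateSet(
                            age=anc_pheno["age"].to_numpy(),
                            sex=anc_pheno["sex"].to_numpy(),
                            common_pcs=common_pcs,
                            rare_pcs=rare_pcs_for(str(ch)),
                        )
                        res = burden_test(
                            sub,
                            anc_pheno,
                            covariates,
                            phenotype=outcome,
                            ancestry=str(ancestry),
                            cohort=cohort,
                        )
                        all_rows.append(results_frame(res))

    summary = (
        pd.concat(all_rows, ignore_index=True)
        if all_rows
        else results_frame([])
    )
    manifest["n_summary_rows"] = len(summary)
    return CohortRun(summary=summary, manifest=manifest, allele_stats=stats,
                     qc=None if skip_qc else qc_res)


@dataclass
class MetaRun:
    meta: pd.DataFrame
    acat: pd.DataFrame
    lambdas: pd.DataFrame


def run_meta(summaries: list[pd.DataFrame]) -> MetaRun:
    """Two-stage meta-analysis + ACAT + inflation factors over cohort
    summary tables.

    Each input must carry the per-cohort summary column set (``unit, mask,
    maf_threshold, phenotype, ancestry, cohort, beta, se, ...``).  Lambda
    is reported per mask x threshold x phenotype over the meta-analyzed
    gene p-values.
    """
    if not summaries:
        raise ValueError("run_meta requires at least one summary table")
    required = {"unit", "mask", "maf_threshold", "phenotype", "ancestry", "beta", "se"}
    frames = []
    for i, s in enumerate(summaries):
        missing = required - set(s.columns)
        if missing:
            raise ValueError(f"summary table {i} missing columns: {sorted(missing)}")
        frames.append(s)
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        raise ValueError("all summary tables are empty; nothing to meta-analyze")
    meta = two_stage_meta(pooled)
    acat_tbl = combine_masks_acat(meta)
    lam_rows = []
    for (mask, thr, phen), grp in meta.groupby(
        ["mask", "maf_threshold", "phenotype"], sort=True
    ):
        lam_rows.append(
            {
                "mask": mask,
                "maf_threshold": thr,
                "phenotype": phen,
                "n_genes": len(grp),
                "lambda": genomic_lambda(grp["p"].to_numpy()),
            }
        )
    return MetaRun(meta=meta, acat=acat_tbl, lambdas=pd.DataFrame(lam_rows))
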