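"""Deleteriousness masks, frequency policies and the cross-cohort exclusion list.

Variants qualify for gene collapsing through three nested masks:

* **M1** — predicted loss of function: the eight high-impact consequence
  terms (transcript ablation, splice acceptor/donor, stop gained,
  frameshift, stop lost, start lost, transcript amplification);
* **M3** — M1 plus moderate-impact indels plus missense variants called
  deleterious by all five in-silico predictors (SIFT, LRT, MutationTaster,
  PolyPhen2-HDIV, PolyPhen2-HVAR);
* **M4** — M3 plus missense variants called deleterious by at least one
  predictor.

Rare-variant eligibility combines a reference-panel MAF threshold (1% or
0.1%) with a consortium-wide exclusion list: any variant observed in any
cohort with MAC >= 6 and MAF above the threshold is excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MASKS = ("M1", "M3", "M4")

LOF_CONSEQUENCES = frozenset(
    {
        "transcript_ablation",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
        "transcript_amplification",
    }
)

#: non-LoF terms the classifier accepts (Ensembl controlled vocabulary subset)
OTHER_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
        "splice_region_variant",
        "synonymous_variant",
        "stop_retained_variant",
        "start_retained_variant",
        "intron_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
    }
)

KNOWN_CONSEQUENCES = LOF_CONSEQUENCES | OTHER_CONSEQUENCES

PREDICTOR_COLUMNS = ("sift", "lrt", "mutation_taster", "polyphen2_hdiv", "polyphen2_hvar")

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "impact",
    "is_indel",
    *PREDICTOR_COLUMNS,
    "panel_maf",
)


def _deleterious_counts(annotations: pd.DataFrame) -> np.ndarray:
    """Number of predictors (0..5) calling each variant deleterious.

    Missing verdicts count as not deleterious, which is conservative for
    the all-five M3 rule.
    """
    counts = np.zeros(len(annotations), dtype=int)
    for col in PREDICTOR_COLUMNS:
        counts += (annotations[col].fillna("").astype(str).str.lower() == "deleterious").to_numpy()
    return counts


def classify_masks(annotations: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask-membership columns M1/M3/M4 for an annotation table.

    Raises on consequence terms outside the recognised vocabulary so that
    typos cannot silently drop variants from every mask.
    """
    cons = annotations["consequence"].astype(str)
    unknown = sorted(set(cons) - KNOWN_CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequence term(s): {unknown}")
    m1 = cons.isin(LOF_CONSEQUENCES).to_numpy()
    missense = (cons == "missense_variant").to_numpy()
    n_del = _deleterious_counts(annotations)
    moderate_indel = (
        annotations["is_indel"].to_numpy(dtype=bool)
        & (annotations["impact"].astype(str).str.upper() == "MODERATE").to_numpy()
    )
    m3 = m1 | moderate_indel | (missense & (n_del == len(PREDICTOR_COLUMNS)))
    m4 = m3 | (missense & (n_del >= 1))
    return pd.DataFrame({"M1": m1, "M3": m3, "M4": m4}, index=annotations.index)


@dataclass(frozen=True)
class ExclusionList:
    """Consortium-wide common-variant exclusion list at one MAF threshold."""

    threshold: float
    variant_keys: frozenset = field(default_factory=frozenset)

    def __contains__(self, key: str) -> bool:
        return key in self.variant_keys

    def __len__(self) -> int:
        return len(self.variant_keys)


def build_exclusion_list(cohort_allele_stats: pd.DataFrame, threshold: float) -> ExclusionList:
    """Union over cohorts of variants with MAC >= 6 and MAF > threshold.

    ``cohort_allele_stats`` has one row per (cohort, variant) with columns
    ``key``, ``mac``, ``maf``.  The MAC >= 6 requirement damps sampling
    fluctuations in small cohorts.
    """
    if len(cohort_allele_stats) == 0:
        return ExclusionList(threshold=threshold)
    hits = cohort_allele_stats[
        (cohort_allele_stats["mac"] >= 6) & (cohort_allele_stats["maf"] > threshold)
    ]
    return ExclusionList(threshold=threshold, variant_keys=frozenset(hits["key"]))


@dataclass(frozen=True)
class FrequencyPolicy:
    """A MAF threshold paired with its matching exclusion list."""

    maf_threshold: float
    exclusion_list: ExclusionList

    def __post_init__(self):
        if self.exclusion_list.threshold != self.maf_threshold:
            raise ValueError(
                f"exclusion list threshold {self.exclusion_list.threshold} does not "
                f"match policy threshold {self.maf_threshold}"
            )


def apply_frequency_policy(
    annotations: pd.DataFrame,
    policy: FrequencyPolicy,
    cohort_mafs: pd.Series | None = None,
) -> np.ndarray:
    """Boolean per-variant retention under a frequency policy.

    A variant is retained iff its reference-panel MAF is at or below the
    threshold AND its key is not on the exclusion list.  Variants absent
    from the panel (NaN ``panel_maf``) are treated as rare and retained:
    a novel variant cannot exceed a panel frequency threshold.  If the
    cohort's own MAFs are supplied they are screened at the same threshold;
    normally in-cohort common variants reach the analysis only through the
    shared exclusion list.
    """
    from .containers import variant_keys

    panel = annotations["panel_maf"].to_numpy(dtype=float)
    keep = np.isnan(panel) | (panel <= policy.maf_threshold)
    keys = variant_keys(annotations)
    keep &= ~keys.isin(policy.exclusion_list.variant_keys).to_numpy()
    if cohort_mafs is not None:
        keep &= np.asarray(cohort_mafs, dtype=float) <= policy.maf_threshold
    return keep


def qualifying_variants(
    annotations: pd.DataFrame,
    mask: str,
    policy: FrequencyPolicy,
    cohort_mafs: pd.Series | None = None,
) -> dict[str, list[str]]:
    """Per-gene lists of qualifying variant keys for one (mask, threshold).

    Genes whose qualifying set is empty are omitted.
    """
    from .containers import variant_keys

    if mask not in MASKS:
        raise ValueError(f"unknown mask {mask!r}; expected one of {MASKS}")
    member = classify_masks(annotations)[mask].to_numpy()
    retained = apply_frequency_policy(annotations, policy, cohort_mafs=cohort_mafs)
    sel = member & retained
    keys = variant_keys(annotations)
    out: dict[str, list[str]] = {}
    for gene, group in annotations[sel].groupby("gene", sort=True):
        out[str(gene)] = keys.loc[group.index].tolist()
    return out
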