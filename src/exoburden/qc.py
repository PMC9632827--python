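"""Genotype-, sample- and variant-level sequencing quality control.

The framework mirrors a decentralised case-control exome QC protocol:

1. genotype-level masking — a call is set to missing if GQ < 20, DP < 10,
   or its allele balance is inconsistent with the called genotype
   (hom-ref with AB > 0.1, hom-alt with AB < 0.9, het outside [0.25, 0.75]);
2. sample filtering — samples with call rate < 97% or mean depth < 20
   are removed;
3. variant filtering — variants with mean GQ < 11, mean DP < 6, call rate
   <= 0.8, or a Hardy-Weinberg exact p-value <= 5e-8 (burden analyses;
   1e-16 for single-variant analyses) are removed.

Boundary semantics are deliberate: sample/genotype thresholds are strict
"less than", the variant call-rate and HWE thresholds are "less than or
equal".  Call rates are computed after genotype-level masking.  HWE uses
the Levene-Haldane exact conditional test, with chromosome-X genotypes
restricted to females.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix

GQ_MIN = 20
DP_MIN = 10
AB_HOM_REF_MAX = 0.1
AB_HOM_ALT_MIN = 0.9
AB_HET_LO = 0.25
AB_HET_HI = 0.75
SAMPLE_CALL_RATE_MIN = 0.97
SAMPLE_MEAN_DEPTH_MIN = 20
VARIANT_MEAN_GQ_MIN = 11
VARIANT_MEAN_DP_MIN = 6
VARIANT_CALL_RATE_MAX_FAIL = 0.8  # fail if call rate <= this
HWE_P_BURDEN = 5e-8
HWE_P_SINGLE_VARIANT = 1e-16


def mask_genotypes(g: GenotypeMatrix) -> GenotypeMatrix:
    """Set individual calls to missing on GQ/DP/allele-balance failures.

    Idempotent: already-missing calls stay missing and carry no metadata
    requirements.
    """
    for name in ("gq", "dp", "ab"):
        if getattr(g, name) is None:
            raise ValueError(f"genotype-level masking requires per-call '{name}' metadata")
    called = g.dosage != MISSING
    bad = (g.gq < GQ_MIN) | (g.dp < DP_MIN)
    ab = g.ab
    with np.errstate(invalid="ignore"):
        bad |= (g.dosage == 0) & (ab > AB_HOM_REF_MAX)
        bad |= (g.dosage == 2) & (ab < AB_HOM_ALT_MIN)
        bad |= (g.dosage == 1) & ((ab < AB_HET_LO) | (ab > AB_HET_HI))
    out = g.copy()
    out.dosage[called & bad] = MISSING
    return out


def sample_metrics(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample call rate (post-masking) and mean depth over called sites."""
    called = g.dosage != MISSING
    call_rate = called.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_depth = np.where(
            called.any(axis=1),
            np.where(called, g.dp, 0).sum(axis=1) / np.maximum(called.sum(axis=1), 1),
            0.0,
        )
    return pd.DataFrame(
        {"sample": g.samples, "call_rate": call_rate, "mean_depth": mean_depth}
    )


def filter_samples(g: GenotypeMatrix):
    """Remove samples with call rate < 97% or mean depth < 20.

    Returns the filtered matrix and a removal log (sample, reason, value).
    """
    m = sample_metrics(g)
    low_cr = m["call_rate"].to_numpy() < SAMPLE_CALL_RATE_MIN
    low_dp = m["mean_depth"].to_numpy() < SAMPLE_MEAN_DEPTH_MIN
    removed = low_cr | low_dp
    log = []
    for i in np.flatnonzero(removed):
        if low_cr[i]:
            log.append((g.samples[i], "call_rate", m["call_rate"].iloc[i]))
        if low_dp[i]:
            log.append((g.samples[i], "mean_depth", m["mean_depth"].iloc[i]))
    log = pd.DataFrame(log, columns=["sample", "reason", "value"])
    return g.take_samples(np.flatnonzero(~removed)), log


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Levene-Haldane exact Hardy-Weinberg test p-value.

    Conditions on the minor-allele count and sums the probabilities of all
    heterozygote configurations no more likely than the observed one.
    Monomorphic sites return 1.0 exactly.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype counts: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes observed")
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log pmf of the Levene-Haldane distribution, up to a shared constant:
    # P(het = h | n, rare) ∝ 2^h * n! / (h! * n_AA! * n_aa!)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    p_obs = pmf[hets == n_het][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))


def variant_metrics(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant mean GQ/DP, call rate (post-masking) and exact HWE p.

    HWE on chromosome X is computed from female genotypes only; means and
    call rates use all samples.
    """
    called = g.dosage != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_gq = np.where(called, g.gq, 0).sum(axis=0) / np.maximum(n_called, 1)
        mean_dp = np.where(called, g.dp, 0).sum(axis=0) / np.maximum(n_called, 1)
    call_rate = n_called / g.n_samples if g.n_samples else np.zeros(g.n_variants)
    xv = g.x_mask()
    female = ~g.is_male
    hwe = np.ones(g.n_variants)
    for j in range(g.n_variants):
        rows = female if xv[j] else slice(None)
        dos = g.dosage[rows, j]
        dos = dos[dos != MISSING]
        if dos.size == 0:
            continue
        hwe[j] = hwe_exact_p(
            int((dos == 0).sum()), int((dos == 1).sum()), int((dos == 2).sum())
        )
    return pd.DataFrame(
        {
            "key": g.keys,
            "mean_gq": mean_gq,
            "mean_dp": mean_dp,
            "call_rate": call_rate,
            "hwe_p": hwe,
        }
    )


def filter_variants(g: GenotypeMatrix, mode: str = "burden"):
    """Remove variants failing site-level QC.

    ``mode`` selects the HWE threshold: 5e-8 for burden analyses, 1e-16 for
    single-variant analyses.  Returns the filtered matrix and a removal log.
    """
    if mode not in ("burden", "single_variant"):
        raise ValueError(f"unknown QC mode {mode!r}")
    hwe_thresh = HWE_P_BURDEN if mode == "burden" else HWE_P_SINGLE_VARIANT
    m = variant_metrics(g)
    fails = {
        "mean_gq": m["mean_gq"].to_numpy() < VARIANT_MEAN_GQ_MIN,
        "mean_dp": m["mean_dp"].to_numpy() < VARIANT_MEAN_DP_MIN,
        "call_rate": m["call_rate"].to_numpy() <= VARIANT_CALL_RATE_MAX_FAIL,
        "hwe_p": m["hwe_p"].to_numpy() <= hwe_thresh,
    }
    removed = np.zeros(g.n_variants, dtype=bool)
    log = []
    for reason, f in fails.items():
        removed |= f
        for j in np.flatnonzero(f):
            log.append((m["key"].iloc[j], reason, m[reason].iloc[j]))
    log = pd.DataFrame(log, columns=["variant", "reason", "value"])
    return g.take_variants(np.flatnonzero(~removed)), log


@dataclass
class QCResult:
    genotypes: GenotypeMatrix
    removed_samples: pd.DataFrame
    removed_variants: pd.DataFrame


def run_qc(g: GenotypeMatrix, mode: str = "burden") -> QCResult:
    """Full QC pass: genotype masking, then sample, then variant filtering."""
    masked = mask_genotypes(g)
    kept, sample_log = filter_samples(masked)
    kept, variant_log = filter_variants(kept, mode=mode)
    return QCResult(kept, sample_log, variant_log)
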