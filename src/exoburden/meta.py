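"""Meta-analysis of per-cohort summary statistics.

Two-stage scheme: inverse-variance-weighted fixed-effect pooling of
cohorts within each genetic ancestry, then a DerSimonian-Laird
random-effects model across ancestries (between-ancestry variance tau^2
from the method of moments, floored at zero, with Cochran's Q
heterogeneity p-value).  P-values across masks are combined with the
aggregated Cauchy association test (ACAT), which tolerates the strong
dependence between nested masks.  A genomic inflation factor over the
gene-level p-values serves as the calibration diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import cauchy, chi2, norm

CHI2_1_MEDIAN = chi2.ppf(0.5, df=1)  # ~0.4549


@dataclass
class MetaResult:
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    tau2: float
    q_stat: float
    het_p: float
    k: int
    betas: np.ndarray = field(default_factory=lambda: np.array([]))
    ses: np.ndarray = field(default_factory=lambda: np.array([]))
    model: str = "fixed"

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.pooled_beta))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        return (
            float(np.exp(self.pooled_beta - z * self.pooled_se)),
            float(np.exp(self.pooled_beta + z * self.pooled_se)),
        )


@dataclass
class ACATResult:
    combined_p: float
    component_ps: np.ndarray
    weights: np.ndarray


def _validate(betas, ses):
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("meta-analysis requires at least one input")
    if betas.shape != ses.shape:
        raise ValueError("betas and ses are not aligned")
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    return betas, ses


def ivw_fixed(betas, ses) -> MetaResult:
    """Fixed-effect inverse-variance-weighted pooling."""
    betas, ses = _validate(betas, ses)
    w = 1.0 / ses**2
    pooled = float((w * betas).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    k = betas.size
    q = float((w * (betas - pooled) ** 2).sum())
    het_p = float(chi2.sf(q, df=k - 1)) if k > 1 else 1.0
    return MetaResult(
        pooled_beta=pooled,
        pooled_se=pooled_se,
        pooled_p=float(2.0 * norm.sf(abs(pooled / pooled_se))),
        tau2=0.0,
        q_stat=q,
        het_p=het_p,
        k=k,
        betas=betas,
        ses=ses,
        model="fixed",
    )


def dersimonian_laird(betas, ses) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with Q from
    the fixed-effect fit; when Q <= k-1 the estimate floors at zero and
    the result coincides with the fixed-effect model.  A single input
    passes through unchanged (tau^2 = 0, het p = 1).
    """
    betas, ses = _validate(betas, ses)
    k = betas.size
    fixed = ivw_fixed(betas, ses)
    if k == 1:
        fixed.model = "random"
        return fixed
    w = 1.0 / ses**2
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (fixed.q_stat - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    pooled = float((w_star * betas).sum() / w_star.sum())
    pooled_se = float(1.0 / np.sqrt(w_star.sum()))
    return MetaResult(
        pooled_beta=pooled,
        pooled_se=pooled_se,
        pooled_p=float(2.0 * norm.sf(abs(pooled / pooled_se))),
        tau2=float(tau2),
        q_stat=fixed.q_stat,
        het_p=fixed.het_p,
        k=k,
        betas=betas,
        ses=ses,
        model="random",
    )


TINY_P = 1e-15


def acat(pvals, weights=None) -> ACATResult:
    """Aggregated Cauchy association test.

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i;  combined p =
    0.5 - arctan(T)/pi.  For p below 1e-15 the tangent is replaced by its
    asymptotic equivalent 1/(p pi) for numerical stability.  Invariant to
    rescaling the weights; equal weights by default.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("acat requires at least one p-value")
    if ((pvals <= 0) | (pvals >= 1)).any():
        raise ValueError("p-values must lie strictly inside (0, 1)")
    if weights is None:
        weights = np.ones_like(pvals)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    t_terms = np.where(
        pvals < TINY_P, 1.0 / (pvals * np.pi), np.tan((0.5 - pvals) * np.pi)
    )
    t = float((weights * t_terms).sum() / weights.sum())
    combined = float(cauchy.sf(t))  # = 0.5 - arctan(t)/pi
    return ACATResult(combined_p=combined, component_ps=pvals, weights=weights)


def two_stage_meta(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-unit two-stage meta-analysis over a summary-statistics table.

    ``summary`` holds per cohort x ancestry rows with columns at least
    ``unit, mask, maf_threshold, phenotype, ancestry, cohort, beta, se``
    (carrier-count columns pass through by summation when present).
    Stage 1 pools cohorts within ancestry by fixed effect; stage 2 pools
    ancestries by DerSimonian-Laird.  Units seen in a single ancestry pass
    through stage 2 unchanged.  The reported heterogeneity p is Cochran's
    Q at the across-ancestry stage.
    """
    required = {"unit", "mask", "maf_threshold", "phenotype", "ancestry", "beta", "se"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    group_cols = ["unit", "mask", "maf_threshold", "phenotype"]
    count_cols = [c for c in ("n_cases", "n_controls") if c in summary.columns]
    rows = []
    for key, grp in summary.groupby(group_cols, sort=True):
        stage1 = (
            grp.groupby("ancestry", sort=True)
            .apply(
                lambda a: ivw_fixed(a["beta"].to_numpy(), a["se"].to_numpy()),
                include_groups=False,
            )
        )
        res = dersimonian_laird(
            np.array([m.pooled_beta for m in stage1]),
            np.array([m.pooled_se for m in stage1]),
        )
        lo, hi = res.ci()
        row = dict(zip(group_cols, key))
        row.update(
            beta=res.pooled_beta,
            se=res.pooled_se,
            odds_ratio=res.odds_ratio,
            ci_lower=lo,
            ci_upper=hi,
            p=res.pooled_p,
            het_p=res.het_p,
            tau2=res.tau2,
            k_ancestries=res.k,
        )
        for c in count_cols:
            row[c] = int(grp[c].sum())
        for c in ("case_counts", "control_counts"):
            if c in grp.columns:
                row[c] = _sum_counts(grp[c])
        rows.append(row)
    return pd.DataFrame(rows)


def _sum_counts(strings: pd.Series) -> str:
    """Sum pipe-delimited "n0|n1|n2" strings elementwise."""
    totals = np.zeros(3, dtype=np.int64)
    for s in strings:
        totals += np.array([int(x) for x in str(s).split("|")])
    return "|".join(str(int(x)) for x in totals)


def combine_masks_acat(meta: pd.DataFrame, by=("unit", "phenotype")) -> pd.DataFrame:
    """Equal-weight ACAT over the available mask x threshold p-values of
    each gene/phenotype."""
    if "p" not in meta.columns:
        raise ValueError("meta table must have a 'p' column")
    rows = []
    for key, grp in meta.groupby(list(by), sort=True):
        res = acat(grp["p"].to_numpy())
        row = dict(zip(by, key))
        row.update(acat_p=res.combined_p, n_components=len(grp))
        rows.append(row)
    return pd.DataFrame(rows)


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor: median association chi-square over the
    null chi-square(1) median (~0.456)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("genomic_lambda requires at least one p-value")
    chisq = chi2.isf(pvals, df=1)
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def qq_data(meta: pd.DataFrame, p_col: str = "p") -> pd.DataFrame:
    """Per-gene −log10 p with expected null quantiles, for QQ/Manhattan plots."""
    if p_col not in meta.columns:
        raise ValueError(f"meta table has no column {p_col!r}")
    out = meta[["unit", p_col]].copy().sort_values(p_col).reset_index(drop=True)
    n = len(out)
    out["neg_log10_p"] = -np.log10(out[p_col])
    out["expected_neg_log10_p"] = -np.log10((np.arange(n) + 0.5) / n)
    return out


def significance_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    return alpha / n_genes
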