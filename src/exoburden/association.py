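"""Association testing: burden and single-variant Firth regressions.

Covariates follow the case-control GWAS convention for infectious-disease
outcomes: age, age^2, sex, age*sex, age^2*sex, 10 principal components from
common variants (MAF > 1%) and — for burden tests only — 20 additional
principal components from rare variants (MAF < 1%), since population
structure confounds rare-variant burdens differently than common alleles.
All fits are complete-case and per ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collapse import BurdenScoreMatrix, format_carrier_counts
from .containers import GenotypeMatrix
from .firth import fit_firth

PHENOTYPES = {"A2": "a2", "B2": "b2", "C2": "c2"}

SINGLE_VARIANT_MAF_MIN = 0.001  # strictly greater than
SINGLE_VARIANT_MAC_MIN = 6  # at least


@dataclass
class CovariateSet:
    """Design-matrix block shared by every gene/variant fit.

    ``common_pcs`` holds principal components from common variants,
    ``rare_pcs`` from rare variants (used by burden tests only).
    """

    age: np.ndarray
    sex: np.ndarray  # 1 = male
    common_pcs: np.ndarray | None = None
    rare_pcs: np.ndarray | None = None

    def matrix(self, include_rare_pcs: bool, include_sex_terms: bool = True) -> np.ndarray:
        age = np.asarray(self.age, dtype=float)
        # centring age keeps age^2 terms from swamping the conditioning
        a = age - age.mean()
        cols = [a, a**2]
        if include_sex_terms:
            sex = np.asarray(self.sex, dtype=float)
            cols += [sex, a * sex, (a**2) * sex]
        block = np.column_stack(cols)
        if self.common_pcs is not None and self.common_pcs.size:
            block = np.hstack([block, self.common_pcs])
        if include_rare_pcs and self.rare_pcs is not None and self.rare_pcs.size:
            block = np.hstack([block, self.rare_pcs])
        # constant columns (e.g. age terms in a single-age stratum) carry no
        # information and break full rank alongside the intercept
        keep = block.std(axis=0) > 0
        return block[:, keep]


def compute_pcs(
    genotypes: GenotypeMatrix,
    maf_window: str = "common",
    k: int = 10,
    exclude_chrom: str | None = None,
    max_variants: int | None = None,
    maf: np.ndarray | None = None,
) -> np.ndarray:
    """Top-k principal components of the standardized dosage matrix.

    ``maf_window`` selects variants with MAF > 1% ("common") or MAF < 1%
    ("rare").  Missing dosages are mean-imputed; each variant is centred
    and scaled by sqrt(2 p (1-p)).  Returns orthonormal sample scores with
    a deterministic sign convention (the largest-magnitude loading of each
    component is positive).

    ``exclude_chrom`` drops one chromosome from the input (leave-one-
    chromosome-out, so that a tested gene's own variants cannot leak into
    its covariates); ``max_variants`` caps the input by deterministic
    even-spaced thinning for large panels.
    """
    if maf_window not in ("common", "rare"):
        raise ValueError(f"maf_window must be 'common' or 'rare', got {maf_window!r}")
    if maf is None:
        maf = genotypes.allele_counts()["maf"].to_numpy()
    maf = np.asarray(maf, dtype=float)
    sel = (maf > 0.01) if maf_window == "common" else ((maf < 0.01) & (maf > 0))
    if exclude_chrom is not None:
        sel &= genotypes.variants["chrom"].astype(str).to_numpy() != str(exclude_chrom)
    idx = np.flatnonzero(sel)
    if max_variants is not None and len(idx) > max_variants:
        idx = idx[np.linspace(0, len(idx) - 1, max_variants).round().astype(int)]
    if len(idx) < k:
        raise ValueError(
            f"requested {k} components but only {len(idx)} {maf_window} variants available"
        )
    dos = genotypes.dosage[:, idx].astype(float)
    dos[dos < 0] = np.nan
    mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), mean, dos)
    p = mean / 2.0
    scale = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12))
    z = (dos - mean) / scale
    n, m = z.shape
    if m <= n:
        # exact top-k via the m x m Gram spectrum: cheaper than a full SVD
        # of the tall matrix and fully deterministic
        gram = z.T @ z
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        s = np.sqrt(np.maximum(evals[order], 0.0))
        v = evecs[:, order]
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(s > 0, (z @ v) / s, 0.0)
        vt = v.T
    else:
        u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > max(s[0], 1e-300) * 1e-9).sum()) if s.size else 0
    if rank < k:
        raise ValueError(f"genotype matrix rank {rank} below requested {k} components")
    u = u[:, :k]
    vt = vt[:k]
    # sign convention: largest-magnitude variant loading positive
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            u[:, j] = -u[:, j]
    return u


@dataclass
class AssociationResult:
    """One fitted score/variant term with its context."""

    unit: str  # gene or variant key
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    case_counts: str = ""
    control_counts: str = ""
    mask: str = ""
    maf_threshold: float = np.nan
    phenotype: str = ""
    ancestry: str = ""
    cohort: str = ""
    converged: bool = True

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return (np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se))


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.ci()
        rows.append(
            {
                "unit": r.unit,
                "mask": r.mask,
                "maf_threshold": r.maf_threshold,
                "phenotype": r.phenotype,
                "ancestry": r.ancestry,
                "cohort": r.cohort,
                "beta": r.beta,
                "se": r.se,
                "odds_ratio": r.odds_ratio,
                "ci_lower": lo,
                "ci_upper": hi,
                "p": r.p,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "case_counts": r.case_counts,
                "control_counts": r.control_counts,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)


def _base_beta(y, covar_block):
    """Covariates-only Firth fit, used to warm-start the per-term fits
    (the term coefficient starts at zero)."""
    X0 = np.column_stack([np.ones(len(y)), covar_block])
    return fit_firth(y, X0).beta


def _fit_term(y, predictor, covar_block, base_beta=None):
    """Firth fit of y on [intercept, predictor, covariates]; returns the
    predictor's (beta, se, p, converged)."""
    X = np.column_stack([np.ones(len(y)), predictor, covar_block])
    beta0 = None
    if base_beta is not None:
        beta0 = np.insert(base_beta, 1, 0.0)
    fit = fit_firth(y, X, beta0=beta0)
    return float(fit.beta[1]), float(fit.se[1]), float(fit.wald_p()[1]), fit.converged


def burden_test(
    scores: BurdenScoreMatrix,
    phenotypes: pd.DataFrame,
    covariates: CovariateSet,
    phenotype: str = "A2",
    ancestry: str = "",
    cohort: str = "",
) -> list[AssociationResult]:
    """Firth regression of a phenotype on each gene's 0/1/2 burden score.

    Genes whose score vector is all zero among analyzed samples are
    omitted (their effect is not identified).  Carrier-count strings in
    the "n0|n1|n2" convention are attached to every result.
    """
    col = PHENOTYPES[phenotype]
    y = phenotypes[col].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"phenotype {phenotype} has no cases or no controls")
    covar = covariates.matrix(include_rare_pcs=True)
    counts = scores.carrier_counts(y.astype(bool))
    base = _base_beta(y, covar)
    out = []
    for gene in scores.genes:
        s = scores.scores.loc[gene].to_numpy(dtype=float)
        if not s.any():
            continue
        beta, se, p, conv = _fit_term(y, s, covar, base_beta=base)
        row = counts.loc[gene]
        out.append(
            AssociationResult(
                unit=str(gene),
                beta=beta,
                se=se,
                p=p,
                n_cases=int(y.sum()),
                n_controls=int(len(y) - y.sum()),
                case_counts=format_carrier_counts(
                    (row["case_n0"], row["case_n1"], row["case_n2"])
                ),
                control_counts=format_carrier_counts(
                    (row["control_n0"], row["control_n1"], row["control_n2"])
                ),
                mask=scores.mask,
                maf_threshold=scores.maf_threshold,
                phenotype=phenotype,
                ancestry=ancestry,
                cohort=cohort,
                converged=conv,
            )
        )
    return out


def single_variant_test(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: CovariateSet,
    phenotype: str = "A2",
    ancestry: str = "",
    cohort: str = "",
) -> list[AssociationResult]:
    """Additive per-allele Firth fit for each variant with MAF > 0.1% and
    MAC >= 6; rare-variant PCs are not used (single-variant covariate set).
    """
    col = PHENOTYPES[phenotype]
    y = phenotypes[col].to_numpy(dtype=float)
    covar = covariates.matrix(include_rare_pcs=False)
    stats = genotypes.allele_counts()
    ok = (stats["maf"].to_numpy() > SINGLE_VARIANT_MAF_MIN) & (
        stats["mac"].to_numpy() >= SINGLE_VARIANT_MAC_MIN
    )
    keys = genotypes.keys
    out = []
    for j in np.flatnonzero(ok):
        dos = genotypes.dosage[:, j].astype(float)
        keep = dos >= 0  # complete-case on the genotype
        beta, se, p, conv = _fit_term(y[keep], dos[keep], covar[keep])
        out.append(
            AssociationResult(
                unit=str(keys.iloc[j]),
                beta=beta,
                se=se,
                p=p,
                n_cases=int(y[keep].sum()),
                n_controls=int(keep.sum() - y[keep].sum()),
                phenotype=phenotype,
                ancestry=ancestry,
                cohort=cohort,
                converged=conv,
            )
        )
    return out


def sex_stratified_burden(
    scores: BurdenScoreMatrix,
    phenotypes: pd.DataFrame,
    covariates: CovariateSet,
    stratum: str,
    phenotype: str = "A2",
    ancestry: str = "",
    cohort: str = "",
) -> list[AssociationResult]:
    """Burden test restricted to one sex; sex and interaction terms dropped."""
    if stratum not in ("male", "female"):
        raise ValueError(f"stratum must be 'male' or 'female', got {stratum!r}")
    sex = np.asarray(covariates.sex, dtype=int)
    sel = sex == (1 if stratum == "male" else 0)
    if not sel.any():
        raise ValueError(f"empty {stratum} stratum")
    col = PHENOTYPES[phenotype]
    y = phenotypes[col].to_numpy(dtype=float)[sel]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"{stratum} stratum lacks cases or controls for {phenotype}")
    sub_cov = CovariateSet(
        age=np.asarray(covariates.age)[sel],
        sex=sex[sel],
        common_pcs=None if covariates.common_pcs is None else covariates.common_pcs[sel],
        rare_pcs=None if covariates.rare_pcs is None else covariates.rare_pcs[sel],
    )
    covar = sub_cov.matrix(include_rare_pcs=True, include_sex_terms=False)
    counts_scores = BurdenScoreMatrix(
        scores=scores.scores.loc[:, sel],
        mask=scores.mask,
        maf_threshold=scores.maf_threshold,
        skipped_genes=scores.skipped_genes,
    )
    counts = counts_scores.carrier_counts(y.astype(bool))
    base = _base_beta(y, covar)
    out = []
    for gene in scores.genes:
        s = counts_scores.scores.loc[gene].to_numpy(dtype=float)
        if not s.any():
            continue
        beta, se, p, conv = _fit_term(y, s, covar, base_beta=base)
        row = counts.loc[gene]
        out.append(
            AssociationResult(
                unit=str(gene),
                beta=beta,
                se=se,
                p=p,
                n_cases=int(y.sum()),
                n_controls=int(len(y) - y.sum()),
                case_counts=format_carrier_counts(
                    (row["case_n0"], row["case_n1"], row["case_n2"])
                ),
                control_counts=format_carrier_counts(
                    (row["control_n0"], row["control_n1"], row["control_n2"])
                ),
                mask=scores.mask,
                maf_threshold=scores.maf_threshold,
                phenotype=f"{phenotype}:{stratum}",
                ancestry=ancestry,
                cohort=cohort,
                converged=conv,
            )
        )
    return out
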