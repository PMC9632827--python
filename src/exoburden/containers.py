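"""Core in-memory containers shared across the pipeline stages.

The central object is :class:`GenotypeMatrix`, a dense samples x variants
dosage matrix with the per-call metadata (GQ, DP, allele balance) that the
quality-control stage consumes.  Dosages are coded 0/1/2 with ``-1`` for
missing; hemizygous male chromosome-X calls are stored as 0 (reference) or 2
(alternate) so that a single hemizygous deleterious allele lands in the
homozygous stratum of the burden score, matching how male X carriers are
counted in case/control "0|1|2" summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: chromosome labels treated as the X chromosome
X_CHROMS = frozenset({"X", "chrX", "x", "23"})


def is_x(chrom) -> np.ndarray:
    """Vectorised test for X-chromosome labels."""
    return np.isin(np.asarray(chrom, dtype=object), list(X_CHROMS))


def variant_keys(variants: pd.DataFrame) -> pd.Series:
    """Canonical ``chrom:pos:ref:alt`` key strings for a variant table."""
    return (
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ":"
        + variants["alt"].astype(str)
    )


@dataclass
class GenotypeMatrix:
    """Dense genotype dosages plus per-call quality metadata.

    Parameters
    ----------
    dosage
        ``(n_samples, n_variants)`` int8 array in {0, 1, 2, -1(missing)}.
    gq, dp
        Per-call genotype quality and read depth, same shape as ``dosage``.
    ab
        Per-call alternate-allele balance AD_alt / (AD_ref + AD_alt) in
        [0, 1]; NaN where depth is zero.
    samples
        Sample identifiers, length ``n_samples``.
    is_male
        Boolean per-sample sex indicator (True = male), used for hemizygous
        chromosome-X handling.
    variants
        Variant table with at least ``chrom, pos, ref, alt`` columns;
        positions are 1-based as in VCF.
    """

    dosage: np.ndarray
    gq: np.ndarray
    dp: np.ndarray
    ab: np.ndarray
    samples: np.ndarray
    is_male: np.ndarray
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.is_male = np.asarray(self.is_male, dtype=bool)
        n_s, n_v = self.dosage.shape
        for name in ("gq", "dp", "ab"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n_s, n_v):
                raise ValueError(f"{name} shape {arr.shape} != dosage shape {(n_s, n_v)}")
        if len(self.samples) != n_s:
            raise ValueError("samples length mismatch")
        if len(self.is_male) != n_s:
            raise ValueError("is_male length mismatch")
        if len(self.variants) != n_v:
            raise ValueError("variant table length mismatch")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def keys(self) -> pd.Series:
        return variant_keys(self.variants)

    def x_mask(self) -> np.ndarray:
        """Boolean per-variant mask for X-chromosome variants."""
        return is_x(self.variants["chrom"].to_numpy())

    # -- subsetting -----------------------------------------------------
    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosage=self.dosage[idx],
            gq=self.gq[idx] if self.gq is not None else None,
            dp=self.dp[idx] if self.dp is not None else None,
            ab=self.ab[idx] if self.ab is not None else None,
            samples=np.asarray(self.samples)[idx],
            is_male=self.is_male[idx],
            variants=self.variants,
        )

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosage=self.dosage[:, idx],
            gq=self.gq[:, idx] if self.gq is not None else None,
            dp=self.dp[:, idx] if self.dp is not None else None,
            ab=self.ab[:, idx] if self.ab is not None else None,
            samples=self.samples,
            is_male=self.is_male,
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosage=self.dosage.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            dp=None if self.dp is None else self.dp.copy(),
            ab=None if self.ab is None else self.ab.copy(),
            samples=np.asarray(self.samples).copy(),
            is_male=self.is_male.copy(),
            variants=self.variants.copy(),
        )

    # -- allele statistics ----------------------------------------------
    def allele_counts(self) -> pd.DataFrame:
        """Per-variant alternate/total allele counts and minor-allele stats.

        Male X calls contribute a single allele; missing calls contribute
        nothing.  Returns columns ``aac`` (alternate allele count), ``an``
        (allele number), ``maf`` and ``mac`` (minor allele).
        """
        dos = self.dosage
        obs = dos != MISSING
        xv = self.x_mask()
        ploidy = np.full(dos.shape, 2, dtype=np.int8)
        if xv.any():
            ploidy[np.ix_(self.is_male, xv)] = 1
        # keep temporaries in int8: these matrices are large
        alt = np.where(obs, dos, np.int8(0))
        # hemizygous alt stored as dosage 2 but carries one allele
        if xv.any():
            male_x = np.zeros(dos.shape, dtype=bool)
            male_x[np.ix_(self.is_male, xv)] = True
            alt = np.where(male_x, alt // np.int8(2), alt)
        aac = alt.sum(axis=0, dtype=np.int64)
        an = (ploidy * obs).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(an > 0, aac / an, 0.0)
        maf = np.minimum(af, 1.0 - af)
        mac = np.minimum(aac, an - aac)
        return pd.DataFrame({"aac": aac, "an": an, "af": af, "maf": maf, "mac": mac})


def check_phenotypes(phenotypes: pd.DataFrame) -> None:
    """Validate a phenotype table: required columns and A2 ⊆ B2 ⊆ C2 nesting."""
    required = {"sample", "a2", "b2", "c2", "age", "sex", "ancestry", "cohort"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    a2 = phenotypes["a2"].to_numpy(dtype=bool)
    b2 = phenotypes["b2"].to_numpy(dtype=bool)
    c2 = phenotypes["c2"].to_numpy(dtype=bool)
    if (a2 & ~b2).any() or (b2 & ~c2).any():
        raise ValueError("phenotype nesting violated: every severe case must be "
                         "hospitalised and every hospitalised case infected")
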