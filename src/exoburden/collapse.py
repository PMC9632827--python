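"""Gene-level 0/1/2 burden collapsing.

For each gene and individual, qualifying variants collapse to a single
score: 2 if the individual carries at least one homozygous (or male-X
hemizygous) qualifying variant, else 1 if they carry at least one
heterozygous qualifying variant, else 0.  Compound heterozygosity is
deliberately not promoted to 2, and missing calls contribute nothing;
an individual whose every qualifying call is missing scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@dataclass
class BurdenScoreMatrix:
    """Gene x sample burden scores for one (mask, MAF-threshold) pair."""

    scores: pd.DataFrame  # index = gene, columns = samples, values in {0,1,2}
    mask: str
    maf_threshold: float
    skipped_genes: list

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns

    def carrier_counts(self, case_flags: np.ndarray) -> pd.DataFrame:
        """Per-gene (n0, n1, n2) counts for cases and controls.

        ``case_flags`` is a boolean vector aligned with the score columns.
        """
        case_flags = np.asarray(case_flags, dtype=bool)
        s = self.scores.to_numpy()
        rows = {}
        for label, sel in (("case", case_flags), ("control", ~case_flags)):
            sub = s[:, sel]
            for k in (0, 1, 2):
                rows[f"{label}_n{k}"] = (sub == k).sum(axis=1)
        return pd.DataFrame(rows, index=self.scores.index)


def collapse_genes(
    genotypes: GenotypeMatrix,
    qualifying: dict[str, list[str]],
    mask: str,
    maf_threshold: float,
) -> BurdenScoreMatrix:
    """Collapse qualifying variants to per-gene 0/1/2 burden scores.

    ``qualifying`` maps gene -> qualifying variant keys (QC and frequency
    policy already applied).  Genes with no qualifying variant present in
    the genotype matrix are omitted and logged in ``skipped_genes``.
    """
    key_to_col = {k: j for j, k in enumerate(genotypes.keys)}
    dos = genotypes.dosage
    gene_rows = []
    gene_names = []
    skipped = []
    for gene in sorted(qualifying):
        cols = [key_to_col[k] for k in qualifying[gene] if k in key_to_col]
        if not cols:
            skipped.append(gene)
            continue
        sub = dos[:, cols]
        has_hom = (sub == 2).any(axis=1)
        has_het = (sub == 1).any(axis=1)
        gene_rows.append(np.where(has_hom, 2, np.where(has_het, 1, 0)).astype(np.int8))
        gene_names.append(gene)
    scores = pd.DataFrame(
        np.vstack(gene_rows) if gene_rows else np.empty((0, genotypes.n_samples), dtype=np.int8),
        index=pd.Index(gene_names, name="gene"),
        columns=pd.Index(genotypes.samples, name="sample"),
    )
    return BurdenScoreMatrix(scores=scores, mask=mask, maf_threshold=maf_threshold,
                             skipped_genes=skipped)


def format_carrier_counts(counts_row) -> str:
    """Render an (n0, n1, n2) triple as the pipe-delimited "n0|n1|n2" string."""
    n0, n1, n2 = (int(x) for x in counts_row)
    return f"{n0}|{n1}|{n2}"
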