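"""Readers and writers for the pipeline's exchange formats.

VCF 4.2 with GT:GQ:DP:AD per-call fields carries genotypes between stages
(reading via pysam; writing as plain text, with male chromosome-X calls
emitted haploid).  Annotations, phenotypes, summary and meta statistics,
removal logs and exclusion lists travel as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import MISSING, GenotypeMatrix, is_x
from .masks import ANNOTATION_COLUMNS, ExclusionList

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=exoburden
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as uncompressed VCF with GT:GQ:DP:AD."""
    path = Path(path)
    xv = is_x(g.variants["chrom"].to_numpy())
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.samples)
            + "\n"
        )
        gt_diploid = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        gt_haploid = {0: "0", 2: "1", MISSING: "."}
        for j in range(g.n_variants):
            v = g.variants.iloc[j]
            fields = [str(v["chrom"]), str(v["pos"]), ".", str(v["ref"]), str(v["alt"]),
                      ".", "PASS", ".", "GT:GQ:DP:AD"]
            hemi_row = xv[j]
            calls = []
            for i in range(g.n_samples):
                d = int(g.dosage[i, j])
                hemi = hemi_row and g.is_male[i]
                gt = gt_haploid[d] if hemi else gt_diploid[d]
                dp = int(g.dp[i, j])
                ab = float(g.ab[i, j]) if dp > 0 else 0.0
                ad_alt = int(round(dp * ab))
                ad_ref = dp - ad_alt
                calls.append(f"{gt}:{int(g.gq[i, j])}:{dp}:{ad_ref},{ad_alt}")
            fh.write("\t".join(fields + calls) + "\n")


def read_vcf(path, is_male=None) -> GenotypeMatrix:
    """Read an uncompressed VCF with GT:GQ:DP:AD into a GenotypeMatrix.

    Haploid (male chromosome-X) alternate calls are coded as dosage 2.
    ``is_male`` (per-sample booleans aligned with the VCF sample order)
    defaults to all-female when omitted; pass it when X variants matter.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    n = len(samples)
    dosage_rows, gq_rows, dp_rows, ab_rows, var_rows = [], [], [], [], []
    for rec in vf:
        var_rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
        dos = np.full(n, MISSING, dtype=np.int8)
        gq = np.zeros(n, dtype=np.int16)
        dp = np.zeros(n, dtype=np.int16)
        ab = np.zeros(n, dtype=np.float32)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            alleles = [a for a in call["GT"] if a is not None]
            if alleles:
                d = sum(alleles)
                if len(alleles) == 1:  # haploid call
                    d *= 2
                dos[i] = d
            gq[i] = call.get("GQ") or 0
            dp[i] = call.get("DP") or 0
            ad = call.get("AD")
            if ad and dp[i] > 0 and ad[0] is not None:
                ab[i] = ad[1] / max(ad[0] + ad[1], 1)
        dosage_rows.append(dos)
        gq_rows.append(gq)
        dp_rows.append(dp)
        ab_rows.append(ab)
    vf.close()
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt"])
    if is_male is None:
        is_male = np.zeros(n, dtype=bool)
    return GenotypeMatrix(
        dosage=np.array(dosage_rows, dtype=np.int8).T,
        gq=np.array(gq_rows, dtype=np.int16).T,
        dp=np.array(dp_rows, dtype=np.int16).T,
        ab=np.array(ab_rows, dtype=np.float32).T,
        samples=np.array(samples),
        is_male=np.asarray(is_male, dtype=bool),
        variants=variants,
    )


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False,
                      na_values=[""])
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {sorted(missing)}")
    ann["is_indel"] = ann["is_indel"].astype(bool)
    for col in ("sift", "lrt", "mutation_taster", "polyphen2_hdiv", "polyphen2_hvar"):
        ann[col] = ann[col].fillna("")
    return ann


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "ancestry": str, "cohort": str})


def write_exclusion_list(excl: ExclusionList, path) -> None:
    """Sorted one-key-per-line TSV, shareable across cohort runs."""
    with open(path, "w") as fh:
        fh.write(f"# maf_threshold={excl.threshold}\n")
        for key in sorted(excl.variant_keys):
            fh.write(key + "\n")


def read_exclusion_list(path) -> ExclusionList:
    threshold = None
    keys = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "maf_threshold=" in line:
                    threshold = float(line.split("maf_threshold=")[1])
            elif line:
                keys.append(line)
    if threshold is None:
        raise ValueError(f"exclusion list {path} lacks a maf_threshold header")
    return ExclusionList(threshold=threshold, variant_keys=frozenset(keys))


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
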