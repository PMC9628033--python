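"""Readers and writers for the pipeline's plain-text formats.

Beta matrices, annotation, dosages and truth tables travel as TSV (first
column the feature id, remaining columns samples); sample sheets as CSV.
Missing values are encoded "NA". Positions are 1-based in every file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BetaMatrix, GenotypeMatrix, ProbeAnnotation


def write_beta_tsv(matrix: BetaMatrix, path: str) -> None:
    matrix.values.to_csv(
        path, sep="\t", index_label="cpg_id", na_rep="NA", float_format="%.10g"
    )


def read_beta_tsv(
    path: str,
    annotation: ProbeAnnotation | None = None,
    sheet: pd.DataFrame | None = None,
    adjusted: bool = False,
) -> BetaMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for col in header:  # pandas silently mangles duplicate headers
        if col in seen:
            raise ValueError(f"duplicate sample id {col!r} in {path}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in {path}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        line = df.index.get_loc(bad.index[0]) + 2 if len(bad) else "?"
        raise ValueError(f"non-numeric cell in column {col!r} near line {line} of {path}")
    return BetaMatrix(df, annotation=annotation, sheet=sheet, adjusted=adjusted)


def write_annotation_tsv(annotation: ProbeAnnotation, path: str) -> None:
    out = annotation.table.copy()
    for flag in ("flag_xy", "flag_snp", "flag_multimap"):
        out[flag] = out[flag].astype(int)
    out.to_csv(path, sep="\t", index_label="cpg_id")


def read_annotation_tsv(path: str) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for flag in ("flag_xy", "flag_snp", "flag_multimap"):
        df[flag] = df[flag].astype(bool)
    return ProbeAnnotation(df)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    out = pd.concat([genotypes.snps[["chrom", "pos"]], genotypes.dosages], axis=1)
    out.to_csv(path, sep="\t", index_label="snp_id", na_rep="NA", float_format="%g")


def read_genotypes(path: str, fmt: str = "dosage_tsv") -> GenotypeMatrix:
    """Read genotypes from a dosage TSV or a VCF (GT field -> 0/1/2)."""
    if fmt == "dosage_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        snps = df[["chrom", "pos"]].copy()
        dosages = df.drop(columns=["chrom", "pos"]).astype(float)
        maf = np.minimum(dosages.mean(axis=1) / 2.0, 1 - dosages.mean(axis=1) / 2.0)
        snps["maf"] = maf
        return GenotypeMatrix(snps, dosages)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    import logging

    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dose = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        rows.append({"snp_id": snp_id, "chrom": var.CHROM, "pos": var.POS})
        dosage_rows.append(dose)
    if n_multi:
        logging.getLogger(__name__).warning("skipped %d multi-allelic records", n_multi)
    snps = pd.DataFrame(rows).set_index("snp_id")
    dosages = pd.DataFrame(dosage_rows, index=snps.index, columns=samples)
    mean = dosages.mean(axis=1) / 2.0
    snps["maf"] = np.minimum(mean, 1 - mean)
    return GenotypeMatrix(snps, dosages)


def write_sheet_csv(sheet: pd.DataFrame, path: str) -> None:
    sheet.to_csv(path, index_label="sample_id")


def read_sheet_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_cpg_list(path: str) -> set[str]:
    """One CpG id per line, blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
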