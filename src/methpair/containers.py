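"""Core in-memory containers for the paired-tissue methylation pipeline.

All containers are thin, validated wrappers around pandas/numpy objects so
that every pipeline stage exchanges ordinary DataFrames underneath.
Positions are 1-based everywhere a container is read or written; 0-based
arithmetic happens only inside binning code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: The eight gene-region annotation categories used throughout.
REGION_CATEGORIES = (
    "TSS1500",
    "TSS200",
    "5UTR",
    "1stExon",
    "ExonBnd",
    "Body",
    "3UTR",
    "IGR",
)


class ProbeAnnotation:
    """Per-CpG genomic annotation: chromosome, 1-based position, gene-region
    category and blacklist flags (X/Y chromosome, SNP-overlapping,
    multi-mapping).

    Parameters
    ----------
    table : DataFrame indexed by CpG id with columns
        ``chrom, pos, region, flag_xy, flag_snp, flag_multimap``.
    """

    REQUIRED = ("chrom", "pos", "region", "flag_xy", "flag_snp", "flag_multimap")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate CpG ids in annotation: {dups}")
        dup_pos = table.duplicated(subset=["chrom", "pos"])
        if dup_pos.any():
            bad = table.loc[dup_pos, ["chrom", "pos"]].iloc[0]
            raise ValueError(
                f"duplicate (chrom, position) in annotation: {bad.chrom}:{bad.pos}"
            )
        bad_region = set(table["region"]) - set(REGION_CATEGORIES)
        if bad_region:
            raise ValueError(f"unknown region categories: {sorted(bad_region)}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, cpg_ids: Iterable[str]) -> "ProbeAnnotation":
        return ProbeAnnotation(self.table.loc[list(cpg_ids)])


class BetaMatrix:
    """CpGs x samples matrix of methylation beta values.

    Raw betas live in [0, 1]; covariate-adjusted matrices may leave that
    range (adjustment is linear and deliberately not clipped), which is
    signalled with ``adjusted=True``. Missing values (NaN) are allowed and
    handled pairwise-complete downstream.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        annotation: Optional[ProbeAnnotation] = None,
        sheet: Optional[pd.DataFrame] = None,
        adjusted: bool = False,
    ):
        if values.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        arr = values.to_numpy(dtype=float)
        if not adjusted:
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("beta values outside [0, 1] in unadjusted matrix")
        self.values = values
        self.annotation = annotation
        self.sheet = sheet
        self.adjusted = adjusted

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, cpg_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(
            self.values.loc[list(cpg_ids)],
            annotation=self.annotation,
            sheet=self.sheet,
            adjusted=self.adjusted,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        sheet = self.sheet
        ids = list(sample_ids)
        if sheet is not None:
            sheet = sheet.loc[sheet.index.intersection(ids)]
        return BetaMatrix(
            self.values[ids], annotation=self.annotation, sheet=sheet, adjusted=self.adjusted
        )


class GenotypeMatrix:
    """SNP dosage matrix (SNPs x samples, additive coding 0/1/2; NaN = missing)
    with per-SNP chromosome, 1-based position and minor-allele frequency."""

    def __init__(self, snps: pd.DataFrame, dosages: pd.DataFrame):
        if not snps.index.equals(dosages.index):
            raise ValueError("snp table and dosage matrix indices differ")
        for col in ("chrom", "pos"):
            if col not in snps.columns:
                raise ValueError(f"snp table missing column {col!r}")
        arr = dosages.to_numpy(dtype=float)
        observed = arr[np.isfinite(arr)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        self.snps = snps
        self.dosages = dosages

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class CellReference:
    """Per-tissue reference methylation signatures: for each tissue a
    DataFrame of reference beta values, CpGs x cell types."""

    signatures: dict[str, pd.DataFrame]

    def __post_init__(self):
        for tissue, sig in self.signatures.items():
            arr = sig.to_numpy(dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"reference betas outside [0,1] for tissue {tissue!r}")

    def for_tissue(self, tissue: str) -> pd.DataFrame:
        return self.signatures[tissue]


@dataclass
class QCReport:
    """Bookkeeping for one filtering step: what was excluded and why."""

    stage: str
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )
    n_before: int = 0
    n_after: int = 0

    def __post_init__(self):
        n_excluded = self.excluded["id"].nunique() if len(self.excluded) else 0
        if self.n_before - n_excluded != self.n_after:
            raise ValueError(
                f"{self.stage}: inconsistent QC counts "
                f"({self.n_before} - {n_excluded} != {self.n_after})"
            )

    def to_frame(self) -> pd.DataFrame:
        out = self.excluded.copy()
        out.insert(0, "stage", self.stage)
        return out
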