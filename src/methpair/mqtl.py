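"""cis-mQTL mapping: additive linear models within +-1 Mb of each CpG.

Per SNP-CpG pair, the methylation value is regressed on the dosage plus a
fixed covariate set (sex, genetic PCs, methylation PCs, genotyping batch);
the dosage t-statistic yields a two-sided p. Benjamini-Hochberg q-values
are computed over ALL tested pairs even though only pairs below the
reporting threshold are stored. Computation uses the
Frisch-Waugh-Lovell decomposition: betas and dosages are residualized on
the covariates once, after which each pair is a simple regression with
df = n - rank(covariates) - 1, numerically identical to the full OLS fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, GenotypeMatrix, ProbeAnnotation
from .correlation import bh_fdr
from .covariates import _encode_design


def enumerate_cis_pairs(
    annotation: ProbeAnnotation,
    genotypes: GenotypeMatrix,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """All same-chromosome (snp, cpg) pairs with |pos_snp - pos_cpg| <= window
    (closed interval). Distance is signed as snp_pos - cpg_pos."""
    rows = []
    snps = genotypes.snps.reset_index().sort_values(["chrom", "pos"])
    cpgs = annotation.table.reset_index().sort_values(["chrom", "pos"])
    for chrom, cgrp in cpgs.groupby("chrom", sort=True):
        sgrp = snps[snps["chrom"] == chrom]
        if sgrp.empty:
            continue
        spos = sgrp["pos"].to_numpy()
        sid = sgrp["snp_id"].to_numpy()
        for cpg, cpos in zip(cgrp["cpg_id"], cgrp["pos"]):
            lo = np.searchsorted(spos, cpos - window, side="left")
            hi = np.searchsorted(spos, cpos + window, side="right")
            for k in range(lo, hi):
                rows.append((sid[k], cpg, int(spos[k] - cpos)))
    return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "distance"])


@dataclass
class MQTLFit:
    """Stored records plus the metadata needed for a valid FDR."""

    records: pd.DataFrame
    n_tests: int
    n_skipped_monomorphic: int = 0
    tissue: str = ""


def fit_mqtls(
    betas: BetaMatrix,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    report_p: float = 0.05,
    min_minor_count: int = 3,
    tissue: str = "",
) -> MQTLFit:
    """Fit the additive model for every candidate pair.

    ``covariates`` columns are encoded as in the adjustment module (numeric
    centred, categoricals sum-to-zero). SNPs with minor allele count below
    ``min_minor_count`` among analysed samples are skipped and counted.
    Samples are matched by the individual: genotype columns must be
    individual ids and the beta matrix sheet must map samples to
    individuals (or the beta columns already equal individual ids).
    """
    sheet = betas.sheet
    if sheet is not None and "individual" in sheet.columns:
        individuals = sheet.loc[betas.sample_ids, "individual"].tolist()
    else:
        individuals = list(betas.sample_ids)
    missing = set(individuals) - set(genotypes.sample_ids)
    if missing:
        raise ValueError(f"no genotypes for individuals: {sorted(missing)[:5]}")

    n = len(individuals)
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[betas.sample_ids]
        Z, names = _encode_design(cov)
        X = np.column_stack([np.ones(n), Z])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient covariate design")
    else:
        X = np.ones((n, 1))
    rank_cov = X.shape[1]
    Q, _ = np.linalg.qr(X)

    def resid(M: np.ndarray) -> np.ndarray:
        return M - Q @ (Q.T @ M)

    used_cpgs = pairs["cpg_id"].unique()
    used_snps = pairs["snp_id"].unique()
    Y = betas.values.loc[used_cpgs].to_numpy(dtype=float).T  # n x cpgs
    G = genotypes.dosages.loc[used_snps, individuals].to_numpy(dtype=float).T
    cpg_pos = {c: i for i, c in enumerate(used_cpgs)}
    snp_pos = {s: i for i, s in enumerate(used_snps)}

    complete = np.isfinite(Y).all(axis=0)
    Yr = resid(np.nan_to_num(Y))
    Gr = resid(np.nan_to_num(G))
    g_finite = np.isfinite(G).all(axis=0)

    df = n - rank_cov - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate set")

    out_rows = []
    pvals = np.empty(len(pairs))
    n_tests = 0
    n_skip = 0
    for i, (snp, cpg, dist) in enumerate(
        pairs[["snp_id", "cpg_id", "distance"]].itertuples(index=False)
    ):
        gi, yi = snp_pos[snp], cpg_pos[cpg]
        g_raw = G[:, gi]
        y_raw = Y[:, yi]
        ok = np.isfinite(g_raw) & np.isfinite(y_raw)
        minor = min(np.nansum(g_raw[ok]), 2 * ok.sum() - np.nansum(g_raw[ok]))
        if minor < min_minor_count:
            pvals[i] = np.nan
            n_skip += 1
            continue
        if ok.all() and complete[yi] and g_finite[gi]:
            g, y, dfi = Gr[:, gi], Yr[:, yi], df
        else:
            # pairwise-complete fallback: refit the projection on the kept rows
            Xo = X[ok]
            Qo, _ = np.linalg.qr(Xo)
            g = g_raw[ok] - Qo @ (Qo.T @ g_raw[ok])
            y = y_raw[ok] - Qo @ (Qo.T @ y_raw[ok])
            dfi = ok.sum() - np.linalg.matrix_rank(Xo) - 1
            if dfi <= 0:
                pvals[i] = np.nan
                n_skip += 1
                continue
        gg = g @ g
        if gg <= 0:
            pvals[i] = np.nan
            n_skip += 1
            continue
        beta_hat = (g @ y) / gg
        rss = y @ y - beta_hat * (g @ y)
        sigma2 = rss / dfi
        if sigma2 <= 0:
            t = np.inf * np.sign(beta_hat)
            p = 0.0
        else:
            t = beta_hat / np.sqrt(sigma2 / gg)
            p = 2.0 * stats.t.sf(abs(t), df=dfi)
        pvals[i] = p
        n_tests += 1
        out_rows.append((snp, cpg, dist, beta_hat, t, p, i))

    ok_p = np.isfinite(pvals)
    q = np.full(len(pairs), np.nan)
    if ok_p.any():
        q[ok_p] = bh_fdr(pvals[ok_p])
    records = pd.DataFrame(
        out_rows, columns=["snp_id", "cpg_id", "distance", "beta", "t", "p", "_i"]
    )
    records["q"] = q[records["_i"].to_numpy(dtype=int)] if len(records) else []
    records = records.drop(columns="_i")
    records["tissue"] = tissue
    stored = records[records["p"] < report_p].reset_index(drop=True)
    return MQTLFit(
        records=stored, n_tests=n_tests, n_skipped_monomorphic=n_skip, tissue=tissue
    )


def is_mqtl(fit: MQTLFit | pd.DataFrame, q_thresh: float = 0.05) -> set[str]:
    """CpGs with at least one genome-wide significant cis association."""
    records = fit.records if isinstance(fit, MQTLFit) else fit
    if len(records) == 0:
        return set()
    return set(records.loc[records["q"] < q_thresh, "cpg_id"])


class CisMQTLModel:
    """Model object for cis-mQTL discovery in one tissue.

    Parameters
    ----------
    betas : cell-composition-adjusted beta matrix for the tissue.
    genotypes : dosage matrix over the same individuals.
    annotation : probe positions used for cis-pair enumeration.
    covariates : per-sample covariate frame (sex, genetic PCs, methylation
        PCs, genotyping batch).
    window : cis window in bp (default +-1 Mb).
    """

    def __init__(
        self,
        betas: BetaMatrix,
        genotypes: GenotypeMatrix,
        annotation: ProbeAnnotation | None = None,
        covariates: pd.DataFrame | None = None,
        window: int = 1_000_000,
        tissue: str = "",
    ):
        self.betas = betas
        self.genotypes = genotypes
        self.annotation = annotation or betas.annotation
        if self.annotation is None:
            raise ValueError("probe annotation required for cis-pair enumeration")
        self.covariates = covariates
        self.window = window
        self.tissue = tissue

    def fit(self, report_p: float = 0.05, min_minor_count: int = 3) -> "MQTLResults":
        ann = self.annotation.subset(
            [c for c in self.annotation.cpg_ids if c in set(self.betas.cpg_ids)]
        )
        pairs = enumerate_cis_pairs(ann, self.genotypes, self.window)
        fit = fit_mqtls(
            self.betas,
            self.genotypes,
            pairs,
            covariates=self.covariates,
            report_p=report_p,
            min_minor_count=min_minor_count,
            tissue=self.tissue,
        )
        return MQTLResults(self, fit)


class MQTLResults:
    """Fitted cis-mQTL scan: stored records, total test count, CpG calls."""

    def __init__(self, model: CisMQTLModel, fit: MQTLFit):
        self.model = model
        self._fit = fit
        self.records = fit.records
        self.n_tests = fit.n_tests
        self.n_skipped_monomorphic = fit.n_skipped_monomorphic

    def significant_cpgs(self, q_thresh: float = 0.05) -> set[str]:
        return is_mqtl(self._fit, q_thresh)

    def summary(self) -> str:
        n_sig = int((self.records["q"] < 0.05).sum()) if len(self.records) else 0
        return "\n".join(
            [
                f"cis-mQTL scan ({self.model.tissue or 'tissue'})",
                "=" * 40,
                f"pairs tested            {self.n_tests:>10,}",
                f"skipped (monomorphic)   {self.n_skipped_monomorphic:>10,}",
                f"stored (p < 0.05)       {len(self.records):>10,}",
                f"significant (q < 0.05)  {n_sig:>10,}",
                f"mQTL CpGs (q < 0.05)    {len(self.significant_cpgs()):>10,}",
            ]
        )

    def to_tsv(self, path: str) -> None:
        self.records.to_csv(path, sep="\t", index=False, na_rep="NA")
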