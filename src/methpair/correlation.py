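"""Genome-wide cross-tissue Spearman correlation map.

For each CpG the beta values of the two tissues are rank-correlated across
paired individuals (average ranks for ties; two-sided p from the
t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df, the behaviour of
R's cor.test in the presence of ties), adjusted by Benjamini-Hochberg and
called significant at q < 0.05. The |rho| > 0.5 variant and per-batch
replication cross-checks are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal rounding with ties away from zero, as used in printed tables."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def _t_approx_p(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho) | (n < 4), np.nan, p)


def spearman_map(
    brain: BetaMatrix,
    buccal: BetaMatrix,
    pairing: pd.DataFrame | None = None,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG Spearman correlation between two paired tissue matrices.

    ``pairing`` maps individuals to sample ids (columns ``brain`` and
    ``buccal`` indexed by individual). When omitted, the two matrices must
    have column orders that correspond pairwise. Missing entries are
    dropped pairwise per CpG; CpGs with fewer than 4 complete pairs get a
    missing p and are excluded from the FDR.
    """
    if list(brain.cpg_ids) != list(buccal.cpg_ids):
        raise ValueError("matrices must share an identical probe set")
    if pairing is not None:
        missing_b = set(pairing["brain"]) - set(brain.sample_ids)
        missing_u = set(pairing["buccal"]) - set(buccal.sample_ids)
        if missing_b or missing_u:
            raise ValueError(
                f"unpaired samples: {sorted(missing_b | missing_u)[:5]}"
            )
        X = brain.values[pairing["brain"].tolist()].to_numpy(dtype=float)
        Y = buccal.values[pairing["buccal"].tolist()].to_numpy(dtype=float)
    else:
        if brain.shape[1] != buccal.shape[1]:
            raise ValueError("matrices have different sample counts and no pairing given")
        X = brain.values.to_numpy(dtype=float)
        Y = buccal.values.to_numpy(dtype=float)

    m, n = X.shape
    rho = np.full(m, np.nan)
    ncomp = np.full(m, n)
    complete = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    if complete.any():
        rx = _rank_rows(X[complete])
        ry = _rank_rows(Y[complete])
        rho[complete] = _rowwise_pearson(rx, ry)
    for j in np.flatnonzero(~complete):
        ok = np.isfinite(X[j]) & np.isfinite(Y[j])
        ncomp[j] = int(ok.sum())
        if ncomp[j] >= 4:
            rx = stats.rankdata(X[j, ok])
            ry = stats.rankdata(Y[j, ok])
            rho[j] = _rowwise_pearson(rx[None, :], ry[None, :])[0]
    p = _t_approx_p(rho, ncomp.astype(float))

    records = pd.DataFrame(index=brain.cpg_ids)
    ann = brain.annotation
    if ann is not None:
        sub = ann.table.reindex(records.index)
        records["chrom"] = sub["chrom"]
        records["pos"] = sub["pos"]
        if "region" in sub:
            records["region"] = sub["region"]
    records["n"] = ncomp
    records["rho"] = rho
    records["p"] = p
    q = np.full(m, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    records["q"] = q
    records["significant"] = (records["q"] < q_thresh).fillna(False)
    return records


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CorrelationSummary:
    """Headline counts of a correlation map."""

    n_tested: int
    n_significant: int
    n_positive: int
    n_negative: int
    pct_positive: float | None
    pct_negative: float | None
    pct_positive_rounded: float | None
    pct_negative_rounded: float | None
    pct_significant: float
    pct_significant_rounded: float
    n_abs_rho_above_threshold: int
    q_thresh: float
    rho_thresh: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(
    records: pd.DataFrame, q_thresh: float = 0.05, rho_thresh: float = 0.5
) -> CorrelationSummary:
    """Counts and printed-precision percentages for a correlation map."""
    if len(records) == 0:
        raise ValueError("no records to summarize")
    tested = records[np.isfinite(records["p"])]
    sig = tested[tested["q"] < q_thresh]
    n_sig = len(sig)
    n_pos = int((sig["rho"] > 0).sum())
    n_neg = int((sig["rho"] < 0).sum())
    if n_sig > 0:
        pct_pos = 100.0 * n_pos / n_sig
        pct_neg = 100.0 * n_neg / n_sig
        pct_pos_r = round_half_up(pct_pos)
        pct_neg_r = round_half_up(pct_neg)
    else:
        pct_pos = pct_neg = pct_pos_r = pct_neg_r = None
    pct_sig = 100.0 * n_sig / len(tested) if len(tested) else 0.0
    return CorrelationSummary(
        n_tested=len(tested),
        n_significant=n_sig,
        n_positive=n_pos,
        n_negative=n_neg,
        pct_positive=pct_pos,
        pct_negative=pct_neg,
        pct_positive_rounded=pct_pos_r,
        pct_negative_rounded=pct_neg_r,
        pct_significant=pct_sig,
        pct_significant_rounded=round_half_up(pct_sig),
        n_abs_rho_above_threshold=int((sig["rho"].abs() > rho_thresh).sum()),
        q_thresh=q_thresh,
        rho_thresh=rho_thresh,
    )


def per_batch_crosscheck(
    records_all: pd.DataFrame,
    records_batch1: pd.DataFrame,
    records_batch2: pd.DataFrame,
    p_thresh: float = 0.05,
    q_thresh: float = 0.05,
) -> dict:
    """Replication of combined-analysis hits in each batch separately.

    Among CpGs significant in the combined analysis, counts and fractions
    with nominal p < ``p_thresh`` in batch 1, batch 2, and both.
    """
    sig = records_all.index[records_all["q"] < q_thresh]
    n_sig = len(sig)
    in1 = records_batch1.reindex(sig)["p"] < p_thresh
    in2 = records_batch2.reindex(sig)["p"] < p_thresh
    out = {
        "n_significant_combined": n_sig,
        "n_replicated_batch1": int(in1.sum()),
        "n_replicated_batch2": int(in2.sum()),
        "n_replicated_both": int((in1 & in2).sum()),
    }
    for key in ("batch1", "batch2", "both"):
        cnt = out[f"n_replicated_{key}"]
        out[f"frac_{key}"] = cnt / n_sig if n_sig else None
    return out


class CrossTissueSpearman:
    """Model object for the paired-tissue correlation map.

    Built from two beta matrices (one per tissue) whose samples are paired
    through a shared individual; ``fit`` produces a
    :class:`CorrelationResults`.
    """

    def __init__(
        self,
        brain: BetaMatrix,
        buccal: BetaMatrix,
        pairing: pd.DataFrame | None = None,
    ):
        self.brain = brain
        self.buccal = buccal
        if pairing is None and brain.sheet is not None and buccal.sheet is not None:
            b = pd.Series(brain.sheet.index, index=brain.sheet["individual"])
            u = pd.Series(buccal.sheet.index, index=buccal.sheet["individual"])
            if b.index.has_duplicates or u.index.has_duplicates:
                raise ValueError("an individual has more than one sample per tissue")
            common = b.index.intersection(u.index)
            pairing = pd.DataFrame({"brain": b.loc[common], "buccal": u.loc[common]})
        self.pairing = pairing

    @classmethod
    def from_dataframes(
        cls, brain: pd.DataFrame, buccal: pd.DataFrame
    ) -> "CrossTissueSpearman":
        return cls(BetaMatrix(brain, adjusted=True), BetaMatrix(buccal, adjusted=True))

    def fit(self, q_thresh: float = 0.05, rho_thresh: float = 0.5) -> "CorrelationResults":
        records = spearman_map(self.brain, self.buccal, self.pairing, q_thresh=q_thresh)
        return CorrelationResults(self, records, q_thresh=q_thresh, rho_thresh=rho_thresh)


class CorrelationResults:
    """Fitted correlation map: per-CpG records, summary counts, replication
    checks, and TSV export."""

    def __init__(
        self,
        model: CrossTissueSpearman,
        records: pd.DataFrame,
        q_thresh: float = 0.05,
        rho_thresh: float = 0.5,
    ):
        self.model = model
        self.records = records
        self.q_thresh = q_thresh
        self.rho_thresh = rho_thresh

    @property
    def significant_cpgs(self) -> list[str]:
        return self.records.index[self.records["significant"]].tolist()

    def summarize(self) -> CorrelationSummary:
        return summarize(self.records, self.q_thresh, self.rho_thresh)

    def crosscheck(
        self, batch1: "CorrelationResults", batch2: "CorrelationResults", p_thresh: float = 0.05
    ) -> dict:
        return per_batch_crosscheck(
            self.records, batch1.records, batch2.records, p_thresh, self.q_thresh
        )

    def summary(self) -> str:
        s = self.summarize()
        lines = [
            "Cross-tissue Spearman correlation map",
            "=" * 46,
            f"CpGs tested                {s.n_tested:>12,}",
            f"significant (q < {s.q_thresh:g})    {s.n_significant:>12,}"
            f"   ({s.pct_significant:.2f}%, prints as {s.pct_significant_rounded:.0f}%)",
        ]
        if s.n_significant:
            lines += [
                f"  positive rho             {s.n_positive:>12,}"
                f"   ({s.pct_positive:.2f}%, prints as {s.pct_positive_rounded:.0f}%)",
                f"  negative rho             {s.n_negative:>12,}"
                f"   ({s.pct_negative:.2f}%, prints as {s.pct_negative_rounded:.0f}%)",
                f"  |rho| > {s.rho_thresh:g}              {s.n_abs_rho_above_threshold:>12,}",
            ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        out = self.records.copy()
        if "chrom" in out.columns:
            out = out.sort_values(["chrom", "pos"])
        out.to_csv(path, sep="\t", index_label="cpg_id", na_rep="NA")
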