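"""Enrichment and set-overlap reporting.

Chi-squared tests of independence with optional Yates continuity
correction for 2x2 tables (matching R's chisq.test defaults), Pearson
residuals (always computed without the correction, so their squared sum
equals the uncorrected statistic), mQTL enrichment on a bin-matched
spatially decorrelated background, gene-region enrichment over the eight
annotation categories, and Venn-style overlap reports with
printed-precision percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import REGION_CATEGORIES, ProbeAnnotation
from .correlation import round_half_up
from .covariates import bin_subsample


@dataclass
class EnrichmentResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    pearson_residuals: pd.DataFrame
    continuity_correction: bool
    meta: dict | None = None


def chi2_test(table: pd.DataFrame | np.ndarray, yates: bool = True) -> EnrichmentResult:
    """Chi-squared test of independence on a two-way contingency table.

    The Yates continuity correction (|O-E| reduced by 0.5) applies only to
    2x2 tables and only when ``yates`` is set. Pearson residuals
    (O-E)/sqrt(E) are reported without the correction.
    """
    obs = pd.DataFrame(table).astype(float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table needs at least 2 rows and 2 columns")
    if (obs.to_numpy() < 0).any():
        raise ValueError("negative counts")
    rows = obs.sum(axis=1).to_numpy()
    cols = obs.sum(axis=0).to_numpy()
    total = rows.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    exp = np.outer(rows, cols) / total
    apply_yates = yates and obs.shape == (2, 2)
    diff = np.abs(obs.to_numpy() - exp)
    if apply_yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    resid = (obs.to_numpy() - exp) / np.sqrt(exp)
    return EnrichmentResult(
        observed=obs,
        expected=pd.DataFrame(exp, index=obs.index, columns=obs.columns),
        chi2=chi2,
        df=df,
        p=p,
        pearson_residuals=pd.DataFrame(resid, index=obs.index, columns=obs.columns),
        continuity_correction=apply_yates,
    )


def mqtl_enrichment(
    correlated: set[str],
    mqtl: set[str],
    universe: set[str],
    annotation: ProbeAnnotation,
    bin_size: int = 100_000,
    seed: int = 0,
    yates: bool = True,
) -> EnrichmentResult:
    """Enrichment of mQTLs among correlated CpGs on a bin-matched background.

    The universe is reduced to one random CpG per 100 kb bin (spatial
    decorrelation) before building the 2x2 (correlated x mQTL) table.
    """
    if not correlated <= universe or not mqtl <= universe:
        raise ValueError("correlated and mqtl sets must be subsets of the universe")
    ann_univ = annotation.subset([c for c in annotation.cpg_ids if c in universe])
    subset = bin_subsample(ann_univ, bin_size=bin_size, seed=seed)
    sub = set(subset)
    a = len(sub & correlated & mqtl)
    b = len((sub & correlated) - mqtl)
    c = len((sub & mqtl) - correlated)
    d = len(sub - correlated - mqtl)
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=pd.Index(["correlated", "not_correlated"]),
        columns=pd.Index(["mqtl", "not_mqtl"]),
    )
    rows = table.sum(axis=1).to_numpy()
    cols = table.sum(axis=0).to_numpy()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in enrichment table")
    exp = np.outer(rows, cols) / rows.sum()
    if (exp < 1).any():
        raise ValueError(
            "expected count below 1 in the bin-subsampled table; use a larger universe"
        )
    res = chi2_test(table, yates=yates)
    res.meta = {"subset_size": len(subset), "bin_size": bin_size, "seed": seed}
    return res


def region_enrichment(
    correlated: set[str], universe: set[str], annotation: ProbeAnnotation
) -> EnrichmentResult:
    """2 x 8 gene-region enrichment of a CpG set against its universe.

    Categories absent from the universe are dropped with a warning and the
    degrees of freedom adjust accordingly. Residual sign per region:
    positive = enrichment among correlated CpGs, negative = depletion.
    """
    import warnings

    regions = annotation.table["region"]
    univ = [c for c in annotation.cpg_ids if c in universe]
    reg = regions.loc[univ]
    in_corr = reg.index.isin(correlated)
    counts = pd.DataFrame(
        {
            "correlated": reg[in_corr].value_counts(),
            "not_correlated": reg[~in_corr].value_counts(),
        }
    ).reindex(list(REGION_CATEGORIES)).fillna(0.0)
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"region categories absent from universe dropped: {list(counts.index[empty])}"
        )
        counts = counts[~empty]
    return chi2_test(counts.T, yates=False)


@dataclass
class OverlapReport:
    counts: dict[str, int]
    percentages: dict[str, float | None]
    denominator: str
    denominator_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subset": k,
                "count": v,
                f"pct_of_{self.denominator}": self.percentages.get(k),
            }
            for k, v in self.counts.items()
        ]
        return pd.DataFrame(rows)


def overlap_report(
    sets: dict[str, set[str]],
    denominator: str,
    precision: int = 0,
) -> OverlapReport:
    """Pairwise/three-way intersections, unions and complements of named CpG
    sets, with percentages against a declared denominator set, rounded
    half-up to the requested printed precision."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if denominator not in sets:
        raise ValueError(f"unknown denominator set {denominator!r}")
    names = list(sets)
    counts: dict[str, int] = {name: len(s) for name, s in sets.items()}
    for a, b in combinations(names, 2):
        counts[f"{a}&{b}"] = len(sets[a] & sets[b])
        counts[f"{a}|{b}"] = len(sets[a] | sets[b])
    for combo in combinations(names, 3):
        inter = set.intersection(*(sets[c] for c in combo))
        counts["&".join(combo)] = len(inter)
    denom_set = sets[denominator]
    others = [n for n in names if n != denominator]
    if others:
        union_others = set.union(*(sets[n] for n in others))
        counts[f"{denominator}&any_other"] = len(denom_set & union_others)
        counts[f"{denominator}_only"] = len(denom_set - union_others)
    denom = len(denom_set)
    percentages: dict[str, float | None] = {}
    for k, v in counts.items():
        percentages[k] = round_half_up(100.0 * v / denom, precision) if denom else None
    return OverlapReport(
        counts=counts,
        percentages=percentages,
        denominator=denominator,
        denominator_size=denom,
    )


def lookup_cpgs(
    records: pd.DataFrame,
    query: list[str],
    mqtl_sets: dict[str, set[str]] | None = None,
    q_thresh: float = 0.05,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Annotated look-up of query CpGs in a correlation map.

    Returns rho/p/q, significance at q < ``q_thresh`` and nominal
    p < ``p_thresh``, and membership in each supplied mQTL set; unknown ids
    are flagged as not tested."""
    mqtl_sets = mqtl_sets or {}
    rows = []
    for cpg in query:
        if cpg in records.index:
            rec = records.loc[cpg]
            row = {
                "cpg_id": cpg,
                "tested": True,
                "rho": rec["rho"],
                "p": rec["p"],
                "q": rec["q"],
                "significant_q": bool(rec["q"] < q_thresh) if np.isfinite(rec["q"]) else False,
                "nominal_p": bool(rec["p"] < p_thresh) if np.isfinite(rec["p"]) else False,
            }
        else:
            row = {
                "cpg_id": cpg,
                "tested": False,
                "rho": np.nan,
                "p": np.nan,
                "q": np.nan,
                "significant_q": False,
                "nominal_p": False,
            }
        for name, s in mqtl_sets.items():
            row[f"in_{name}"] = cpg in s
        rows.append(row)
    return pd.DataFrame(rows).set_index("cpg_id")
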