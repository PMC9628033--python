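"""Sample- and probe-level quality control.

Rules implemented: exclusion of samples with bisulfite conversion
efficiency below 80% (>= 80 kept); removal of X/Y, SNP-overlapping and
multi-mapping probes; detection-p masking with a beadcount rule; a
deterministic PCA/IQR outlier screen standing in for array-level outlier
detection; probe intersection across datasets; and reference-based
cell-type deconvolution by non-negative least squares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import BetaMatrix, ProbeAnnotation, QCReport


def filter_samples_by_conversion(
    sheet: pd.DataFrame, threshold: float = 80.0
) -> tuple[list[str], QCReport]:
    """Keep samples with conversion efficiency >= ``threshold`` percent.

    The partner sample of an excluded individual is flagged in the report
    (reason ``partner_excluded``) but remains in the kept list; paired
    analyses drop it downstream when aligning pairs.
    """
    if "conversion" not in sheet.columns:
        raise ValueError("sample sheet has no 'conversion' column")
    missing = sheet.index[sheet["conversion"].isna()]
    if len(missing):
        raise ValueError(f"missing conversion efficiency for sample {missing[0]!r}")
    keep_mask = sheet["conversion"] >= threshold
    kept = sheet.index[keep_mask].tolist()
    rows = [
        {"id": s, "reason": f"conversion {sheet.loc[s, 'conversion']} < {threshold}"}
        for s in sheet.index[~keep_mask]
    ]
    if "individual" in sheet.columns:
        dropped_ind = set(sheet.loc[~keep_mask, "individual"])
        for s in kept:
            if sheet.loc[s, "individual"] in dropped_ind:
                rows.append({"id": s, "reason": "partner_excluded (flag only)"})
    excluded = pd.DataFrame(rows, columns=["id", "reason"])
    really_excluded = excluded[~excluded["reason"].str.contains("flag only")]
    report = QCReport(
        stage="conversion_filter",
        excluded=really_excluded,
        n_before=len(sheet),
        n_after=len(kept),
    )
    report.flagged_partners = excluded[excluded["reason"].str.contains("flag only")]
    return kept, report


def detect_outlier_samples(
    betas: BetaMatrix,
    threshold: float = 0.15,
    bin_size: int = 100_000,
    seed: int = 0,
) -> tuple[list[str], QCReport]:
    """Flag outlying samples by their leading principal-component coordinates.

    PCA is run on a 100 kb bin-subsampled probe set; each sample is scored
    on each of the first two PCs by its distance beyond the far-out Tukey
    fences [Q1 - 3 IQR, Q3 + 3 IQR], normalised by the IQR, and the maximum
    over the scored PCs is compared against ``threshold``. PCs whose
    variance share is indistinguishable from noise (<= 2/(n_samples-1))
    carry no outlier information and are skipped.
    """
    from .covariates import bin_subsample, pca  # local import, avoids cycle

    if betas.shape[1] < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    if betas.annotation is not None:
        subset = bin_subsample(betas.annotation, bin_size=bin_size, seed=seed)
        subset = [c for c in subset if c in betas.cpg_ids]
    else:
        subset = list(betas.cpg_ids)
    vals = betas.values.loc[subset]
    if float(np.nanstd(vals.to_numpy())) == 0.0:
        scores = np.zeros(betas.shape[1])
    else:
        res = pca(betas, subset)
        k = min(2, res.scores.shape[1])
        coords = res.scores.to_numpy()[:, :k]
        scores = np.zeros(coords.shape[0])
        # a PC carrying only noise has variance share ~1/(n-1); fences on such
        # axes are meaningless, so only PCs with clear structure are scored
        noise_share = 2.0 / max(betas.shape[1] - 1, 1)
        for c in range(k):
            if res.variance_explained[c] <= noise_share:
                continue
            x = coords[:, c]
            q1, q3 = np.percentile(x, [25, 75])
            iqr = q3 - q1
            if iqr == 0:
                continue
            lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
            out = np.maximum(lo - x, x - hi) / iqr
            scores = np.maximum(scores, out)
    mask = scores > threshold
    outliers = [s for s, flag in zip(betas.sample_ids, mask) if flag]
    excluded = pd.DataFrame(
        {"id": outliers, "reason": [f"outlyingness {s:.3f} > {threshold}" for s in scores[mask]]}
    )
    report = QCReport(
        stage="outlier_detection",
        excluded=excluded if len(excluded) else pd.DataFrame(columns=["id", "reason"]),
        n_before=betas.shape[1],
        n_after=betas.shape[1] - len(outliers),
    )
    return outliers, report


def filter_probes(annotation: ProbeAnnotation) -> tuple[list[str], QCReport]:
    """Remove probes flagged X/Y, SNP-overlapping or multi-mapping."""
    tab = annotation.table
    flags = tab[["flag_xy", "flag_snp", "flag_multimap"]].astype(bool)
    bad = flags.any(axis=1)
    rows = []
    for cpg in tab.index[bad]:
        reasons = [f for f in flags.columns if flags.loc[cpg, f]]
        rows.append({"id": cpg, "reason": "+".join(reasons)})
    kept = tab.index[~bad].tolist()
    report = QCReport(
        stage="probe_blacklist",
        excluded=pd.DataFrame(rows, columns=["id", "reason"]),
        n_before=len(tab),
        n_after=len(kept),
    )
    return kept, report


def mask_by_detection(
    betas: BetaMatrix,
    detp: pd.DataFrame,
    beadcount: pd.DataFrame,
    p_thresh: float = 0.01,
    min_beads: int = 3,
    max_fail_frac: float = 0.05,
) -> tuple[BetaMatrix, QCReport]:
    """Mask unreliable entries and drop low-beadcount probes.

    Entries with detection p > ``p_thresh`` become missing; a probe is
    removed entirely when beadcount < ``min_beads`` in strictly more than
    ``max_fail_frac`` of samples.
    """
    vals = betas.values
    for name, mat in (("detection-p", detp), ("beadcount", beadcount)):
        if not (mat.index.equals(vals.index) and mat.columns.equals(vals.columns)):
            raise ValueError(f"{name} matrix is not aligned with the beta matrix")
    masked = vals.where(detp.to_numpy() <= p_thresh)
    fail_frac = (beadcount.to_numpy() < min_beads).mean(axis=1)
    drop = fail_frac > max_fail_frac
    kept = vals.index[~drop]
    excluded = pd.DataFrame(
        {
            "id": vals.index[drop],
            "reason": [
                f"beadcount<{min_beads} in {100 * f:.1f}% of samples"
                for f in fail_frac[drop]
            ],
        }
    )
    report = QCReport(
        stage="detection_mask",
        excluded=excluded if len(excluded) else pd.DataFrame(columns=["id", "reason"]),
        n_before=len(vals.index),
        n_after=len(kept),
    )
    out = BetaMatrix(
        masked.loc[kept], annotation=betas.annotation, sheet=betas.sheet, adjusted=betas.adjusted
    )
    return out, report


def estimate_cell_composition(
    betas: BetaMatrix, reference: pd.DataFrame
) -> pd.DataFrame:
    """Reference-based deconvolution: per sample, non-negative least squares
    of the sample's betas on the reference signature matrix, renormalised to
    sum to one. Returns fractions plus the residual norm per sample."""
    ref_cpgs = reference.index
    missing = ref_cpgs.difference(betas.cpg_ids)
    if len(missing):
        raise ValueError(f"reference CpGs absent from beta matrix: {list(missing[:5])}")
    R = reference.to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("reference signature matrix is rank-deficient")
    M = betas.values.loc[ref_cpgs].to_numpy(dtype=float)
    out = np.zeros((betas.shape[1], R.shape[1]))
    resid = np.zeros(betas.shape[1])
    for i in range(betas.shape[1]):
        y = M[:, i]
        ok = np.isfinite(y)
        w, rnorm = nnls(R[ok], y[ok])
        total = w.sum()
        out[i] = w / total if total > 0 else np.full(R.shape[1], 1.0 / R.shape[1])
        resid[i] = rnorm
    frac = pd.DataFrame(out, index=betas.sample_ids, columns=reference.columns)
    frac["residual_norm"] = resid
    return frac


def intersect_probes(matrices: list[BetaMatrix]) -> list[str]:
    """Probe ids present in every matrix, ordered as in the first."""
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].cpg_ids)
    for m in matrices[1:]:
        common &= set(m.cpg_ids)
    if not common:
        raise ValueError("empty probe intersection: nothing to analyse")
    return [c for c in matrices[0].cpg_ids if c in common]
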