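"""Covariate detection and removal.

The procedure: PCA on a spatially decorrelated probe subset (one random
CpG per 100 kb genomic bin), selection of leading components, screening of
candidate covariates against those components (Pearson for numeric,
one-way ANOVA for categorical, flag at p < 0.01 on any retained PC), and
linear removal of flagged covariates / the batch factor from every probe
by per-CpG ordinary least squares with sum-to-zero coding, mirroring
limma's removeBatchEffect. A direct adjustment for the first k principal
components is provided as a robustness variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, ProbeAnnotation


def bin_subsample(
    annotation: ProbeAnnotation, bin_size: int = 100_000, seed: int = 0
) -> list[str]:
    """One uniformly chosen CpG per non-empty ``bin_size`` genomic bin.

    Bins are half-open [k*bin_size, (k+1)*bin_size) on 0-based coordinates;
    stored 1-based positions are converted by pos - 1. Output is sorted by
    (chromosome, position), chromosomes lexicographically.
    """
    tab = annotation.table
    if len(tab) == 0:
        return []
    rng = np.random.default_rng(seed)
    binned = tab.assign(_bin=(tab["pos"] - 1) // bin_size)
    picks = []
    for key, idx in sorted(binned.groupby(["chrom", "_bin"]).groups.items()):
        idx = list(idx)
        picks.append(idx[rng.integers(len(idx))] if len(idx) > 1 else idx[0])
    chosen = tab.loc[picks].sort_values(["chrom", "pos"])
    return chosen.index.tolist()


@dataclass
class PCAResult:
    """Principal components of samples over a probe subset (probes centred,
    not scaled; singular value decomposition as in R's prcomp)."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # probes x components
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    subset_cpgs: list[str]
    n_selected: int | None = None


def pca(betas: BetaMatrix, subset: list[str] | None = None) -> PCAResult:
    """PCA with samples as observations and subset CpGs as variables."""
    subset = list(subset) if subset is not None else list(betas.cpg_ids)
    X = betas.values.loc[subset].to_numpy(dtype=float).T  # samples x probes
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = (Xc**2).sum() / (n - 1)
    if total_var == 0:
        raise ValueError("constant matrix: PCA undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = S**2 / (n - 1)
    comp_names = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=betas.values.columns, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=subset, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eig,
        variance_explained=eig / total_var,
        subset_cpgs=subset,
    )


def select_pcs(pca_result: PCAResult, method: str = "cumvar", **params) -> int:
    """Number of leading components to retain for covariate screening.

    method 'fixed' -> params['k']; method 'cumvar' -> smallest k whose
    cumulative variance explained reaches params['frac'] (default 0.8).
    """
    ve = pca_result.variance_explained
    if len(ve) == 0:
        raise ValueError("empty PCA result")
    if method == "fixed":
        k = int(params["k"])
    elif method == "cumvar":
        frac = float(params.get("frac", 0.8))
        cum = np.cumsum(ve)
        reach = np.flatnonzero(cum >= frac - 1e-12)
        k = int(reach[0]) + 1 if len(reach) else len(ve)
    else:
        raise ValueError(f"unknown PC selection method {method!r}")
    k = max(1, min(k, len(ve)))
    pca_result.n_selected = k
    return k


@dataclass
class CovariateScreenResult:
    """Per (covariate, PC) association tests and the flagged covariate set."""

    tests: pd.DataFrame  # covariate, pc, test, statistic, p
    flagged: list[str] = field(default_factory=list)
    alpha: float = 0.01


def screen_covariates(
    pca_result: PCAResult,
    sheet: pd.DataFrame,
    numeric: list[str],
    categorical: list[str],
    alpha: float = 0.01,
) -> CovariateScreenResult:
    """Screen candidate covariates against the retained PCs.

    Numeric covariates: Pearson correlation with each retained PC score
    vector, two-sided t-test with n-2 df. Categorical: one-way ANOVA of PC
    scores grouped by level. A covariate is flagged when its minimum p over
    the retained PCs is below ``alpha``. Degenerate covariates (constant
    numeric, single-level categorical) are skipped with a warning.
    """
    if pca_result.n_selected is None:
        raise ValueError("call select_pcs before screening")
    k = pca_result.n_selected
    scores = pca_result.scores
    cov_data = sheet.loc[scores.index]
    rows = []
    flagged = []
    n = len(scores)
    for cov in numeric:
        x = cov_data[cov].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"numeric covariate {cov!r} has zero variance; skipped")
            continue
        xc = x - x.mean()
        best_p = np.inf
        for pc in scores.columns[:k]:
            y = scores[pc].to_numpy()
            yc = y - y.mean()
            r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
            r = float(np.clip(r, -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
                t = np.inf * np.sign(r)
            else:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p = 2 * stats.t.sf(abs(t), df=n - 2)
            rows.append(
                {"covariate": cov, "pc": pc, "test": "pearson", "statistic": r, "p": p}
            )
            best_p = min(best_p, p)
        if best_p < alpha:
            flagged.append(cov)
    for cov in categorical:
        levels = cov_data[cov].astype(str)
        groups = levels.unique()
        if len(groups) < 2:
            warnings.warn(f"categorical covariate {cov!r} has a single level; skipped")
            continue
        best_p = np.inf
        for pc in scores.columns[:k]:
            grouped = [scores.loc[levels == g, pc].to_numpy() for g in groups]
            F, p = stats.f_oneway(*grouped)
            rows.append(
                {"covariate": cov, "pc": pc, "test": "anova", "statistic": float(F), "p": float(p)}
            )
            best_p = min(best_p, p)
        if best_p < alpha:
            flagged.append(cov)
    tests = pd.DataFrame(rows, columns=["covariate", "pc", "test", "statistic", "p"])
    return CovariateScreenResult(tests=tests, flagged=flagged, alpha=alpha)


def _encode_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (effect) coding for categoricals, centring for numerics."""
    cols = []
    names = []
    for cov in covariates.columns:
        series = covariates[cov]
        if pd.api.types.is_numeric_dtype(series):
            x = series.to_numpy(dtype=float)
            cols.append(x - x.mean())
            names.append(cov)
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                continue
            last = levels[-1]
            for lev in levels[:-1]:
                col = np.where(series.astype(str) == lev, 1.0, 0.0)
                col[series.astype(str) == last] = -1.0
                cols.append(col)
                names.append(f"{cov}[{lev}]")
    if not cols:
        return np.empty((len(covariates), 0)), []
    return np.column_stack(cols), names


def residualize(betas: BetaMatrix, nuisance: pd.DataFrame | None) -> BetaMatrix:
    """Remove the fitted nuisance contribution from every probe.

    Per CpG, OLS of the beta values on [intercept | encoded nuisance terms];
    the intercept (grand mean) is retained and only the nuisance fit is
    subtracted. Adjusted values may leave [0, 1] and are not clipped.
    """
    if nuisance is None or nuisance.shape[1] == 0:
        return betas
    nuisance = nuisance.loc[betas.sample_ids]
    Z, names = _encode_design(nuisance)
    if Z.shape[1] == 0:
        return betas
    X = np.column_stack([np.ones(Z.shape[0]), Z])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by rank-revealing QR on successive prefixes
        aliased = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                aliased.append(names[j - 1])
        raise ValueError(f"rank-deficient nuisance design; aliased terms: {aliased}")
    Y = betas.values.to_numpy(dtype=float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    adjusted = Y - Z @ coef[1:]
    out = pd.DataFrame(adjusted.T, index=betas.cpg_ids, columns=betas.sample_ids)
    return BetaMatrix(out, annotation=betas.annotation, sheet=betas.sheet, adjusted=True)


def combine_and_debatch(batch1: BetaMatrix, batch2: BetaMatrix) -> BetaMatrix:
    """Column-concatenate two batches sharing a probe set and residualize on
    the batch factor."""
    if batch1.shape[1] == 0 or batch2.shape[1] == 0:
        raise ValueError("cannot combine an empty batch")
    if list(batch1.cpg_ids) != list(batch2.cpg_ids):
        raise ValueError("probe sets differ between batches; intersect first")
    if set(batch1.sample_ids) & set(batch2.sample_ids):
        raise ValueError("batches share sample ids")
    vals = pd.concat([batch1.values, batch2.values], axis=1)
    sheets = [s for s in (batch1.sheet, batch2.sheet) if s is not None]
    sheet = pd.concat(sheets) if len(sheets) == 2 else None
    combined = BetaMatrix(
        vals,
        annotation=batch1.annotation,
        sheet=sheet,
        adjusted=batch1.adjusted or batch2.adjusted,
    )
    batch_factor = pd.DataFrame(
        {
            "batch": ["b1"] * batch1.shape[1] + ["b2"] * batch2.shape[1],
        },
        index=vals.columns,
    )
    return residualize(combined, batch_factor)


def direct_pc_adjust(
    betas: BetaMatrix,
    k: int = 3,
    annotation: ProbeAnnotation | None = None,
    bin_size: int = 100_000,
    seed: int = 0,
) -> BetaMatrix:
    """Robustness variant: residualize every probe on the first ``k``
    principal-component score vectors (computed on the bin-subsampled
    probe set)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > betas.shape[1] - 1:
        raise ValueError("k must be at most n_samples - 1")
    annotation = annotation or betas.annotation
    subset = None
    if annotation is not None:
        subset = [c for c in bin_subsample(annotation, bin_size=bin_size, seed=seed)
                  if c in betas.cpg_ids]
        if not subset:
            subset = None
    res = pca(betas, subset)
    pcs = res.scores.iloc[:, :k]
    return residualize(betas, pcs)
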