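"""End-to-end synthetic pipeline: simulate -> QC -> covariate adjustment ->
correlation map -> cis-mQTLs -> enrichment -> report.

Every stage logs its input/output dimensions; a resolved configuration
snapshot is written next to the outputs so any run can be reproduced from
the snapshot alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import PipelineConfig
from .containers import BetaMatrix
from .correlation import CrossTissueSpearman
from .covariates import bin_subsample, pca, residualize, screen_covariates, select_pcs, combine_and_debatch
from .enrichment import mqtl_enrichment, overlap_report, region_enrichment
from .mqtl import CisMQTLModel
from .qc import (
    detect_outlier_samples,
    estimate_cell_composition,
    filter_probes,
    filter_samples_by_conversion,
    intersect_probes,
)
from .simulate import generate_paired_dataset

log = logging.getLogger("methpair")

NUMERIC_SCREEN = ["conversion"]
CATEGORICAL_SCREEN = ["diagnosis", "array_id", "array_position", "extraction_date"]


def _genetic_pcs(genotypes, individuals, k=5) -> pd.DataFrame:
    G = genotypes.dosages[individuals].to_numpy(dtype=float).T  # ind x snp
    G = np.nan_to_num(G - np.nanmean(G, axis=0, keepdims=True))
    sd = G.std(axis=0)
    G = G[:, sd > 0] / sd[sd > 0]
    U, S, _ = np.linalg.svd(G, full_matrices=False)
    k = min(k, len(S))
    return pd.DataFrame(
        U[:, :k] * S[:k], index=individuals, columns=[f"gPC{i+1}" for i in range(k)]
    )


def adjust_dataset(
    betas: BetaMatrix,
    fractions: pd.DataFrame,
    config: PipelineConfig,
    label: str = "",
) -> tuple[BetaMatrix, object]:
    """One dataset's screen-and-residualize step.

    Candidate covariates: conversion efficiency and the estimated cell
    fractions (numeric); diagnosis, array id, array position and
    extraction date (categorical). Covariates flagged at p < alpha on any
    retained PC are removed by per-CpG OLS.
    """
    subset = bin_subsample(betas.annotation, config.bin_size, seed=config.seed)
    subset = [c for c in subset if c in set(betas.cpg_ids)]
    res = pca(betas, subset)
    k = select_pcs(res, config.pc_method, k=int(config.pc_param), frac=config.pc_param)
    frac_cols = [c for c in fractions.columns if c != "residual_norm"]
    sheet_ext = betas.sheet.join(fractions[frac_cols], how="left")
    screen = screen_covariates(
        res,
        sheet_ext,
        numeric=NUMERIC_SCREEN + frac_cols,
        categorical=CATEGORICAL_SCREEN,
        alpha=config.alpha,
    )
    flagged = list(screen.flagged)
    # all cell fractions sum to one; keep the design full rank
    if set(frac_cols) <= set(flagged):
        flagged.remove(frac_cols[-1])
    log.info("%s: %d PCs retained, flagged covariates: %s", label, k, flagged)
    if not flagged:
        return betas, screen
    nuisance = sheet_ext[flagged]
    return residualize(betas, nuisance), screen


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the result bundle and writes
    artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)

    log.info("simulate: n_pairs=%d n_cpgs=%d", sim_cfg.n_pairs, sim_cfg.n_cpgs)
    ds = generate_paired_dataset(sim_cfg)
    tissues = sim_cfg.tissues
    batches = sim_cfg.batches

    # ---- QC ----------------------------------------------------------------
    qc_reports = []
    kept_samples: dict[tuple[str, str], list[str]] = {}
    for key, mat in ds.betas.items():
        kept, rep = filter_samples_by_conversion(mat.sheet, config.conversion_threshold)
        qc_reports.append(rep)
        sub = mat.subset_samples(kept)
        if sub.shape[1] >= 4:
            outliers, rep2 = detect_outlier_samples(
                sub, config.outlier_threshold, config.bin_size, seed=config.seed
            )
            qc_reports.append(rep2)
            kept = [s for s in kept if s not in set(outliers)]
        kept_samples[key] = kept
    kept_probes, rep = filter_probes(ds.annotation)
    qc_reports.append(rep)
    filtered = {
        key: mat.subset_samples(kept_samples[key]).subset_probes(kept_probes)
        for key, mat in ds.betas.items()
    }
    common = intersect_probes(list(filtered.values()))
    filtered = {key: mat.subset_probes(common) for key, mat in filtered.items()}
    log.info("qc: %d probes in all four datasets", len(common))

    # drop individuals that lost a sample in any dataset (pairing must survive)
    kept_inds = set(ds.sheet["individual"])
    for key, mat in filtered.items():
        t, b = key
        inds_now = set(mat.sheet.loc[list(mat.sample_ids), "individual"])
        inds_orig = set(
            ds.sheet[(ds.sheet["tissue"] == t) & (ds.sheet["batch"] == b)]["individual"]
        )
        kept_inds -= inds_orig - inds_now
    filtered = {
        key: mat.subset_samples(
            [s for s in mat.sample_ids if mat.sheet.loc[s, "individual"] in kept_inds]
        )
        for key, mat in filtered.items()
    }

    # ---- cell composition ---------------------------------------------------
    fractions: dict[str, pd.DataFrame] = {}
    for t in tissues:
        ref = ds.reference.for_tissue(t)
        ref = ref.loc[ref.index.intersection(common)]
        mats = [filtered[(t, b)] for b in batches]
        both = pd.concat([m.values for m in mats], axis=1)
        sheet = pd.concat([m.sheet.loc[list(m.sample_ids)] for m in mats])
        combined = BetaMatrix(both, annotation=ds.annotation, sheet=sheet)
        fractions[t] = estimate_cell_composition(combined, ref)

    # ---- covariate screen + adjustment per dataset -------------------------
    adjusted: dict[tuple[str, str], BetaMatrix] = {}
    screens = {}
    for key, mat in filtered.items():
        adj, screen = adjust_dataset(
            mat, fractions[key[0]].loc[list(mat.sample_ids)], config, label=str(key)
        )
        adjusted[key] = adj
        screens[key] = screen

    # ---- combine batches, remove the batch factor --------------------------
    combined_adj: dict[str, BetaMatrix] = {}
    for t in tissues:
        combined_adj[t] = combine_and_debatch(adjusted[(t, batches[0])], adjusted[(t, batches[1])])

    # ---- correlation map ----------------------------------------------------
    t_brain, t_buccal = tissues[0], tissues[-1]
    model = CrossTissueSpearman(combined_adj[t_brain], combined_adj[t_buccal])
    results = model.fit(q_thresh=config.q_thresh, rho_thresh=config.rho_thresh)
    summary = results.summarize()
    log.info("correlation: %d/%d significant", summary.n_significant, summary.n_tested)

    batch_results = {}
    for b in batches:
        bmodel = CrossTissueSpearman(adjusted[(t_brain, b)], adjusted[(t_buccal, b)])
        batch_results[b] = bmodel.fit(q_thresh=config.q_thresh)
    crosscheck = results.crosscheck(
        batch_results[batches[0]], batch_results[batches[1]], config.batch_p_thresh
    )

    # ---- cis-mQTLs ----------------------------------------------------------
    mqtl_results = {}
    mqtl_sets: dict[str, set[str]] = {}
    if config.run_mqtl and len(ds.genotypes):
        for t in tissues:
            mats = [filtered[(t, b)] for b in batches]
            vals = pd.concat([m.values for m in mats], axis=1)
            sheet = pd.concat([m.sheet.loc[list(m.sample_ids)] for m in mats])
            raw = BetaMatrix(vals, annotation=ds.annotation, sheet=sheet)
            frac_cols = [c for c in fractions[t].columns if c != "residual_norm"]
            cell_adj = residualize(raw, fractions[t].loc[list(raw.sample_ids), frac_cols[:-1]])
            individuals = sheet.loc[list(raw.sample_ids), "individual"].tolist()
            gpcs = _genetic_pcs(ds.genotypes, individuals, k=5)
            gpcs.index = raw.sample_ids
            subset = [
                c for c in bin_subsample(ds.annotation, config.bin_size, seed=config.seed)
                if c in set(raw.cpg_ids)
            ]
            mres = pca(raw, subset)
            dnam_pcs = mres.scores.iloc[:, : config.n_dnam_pcs_mqtl]
            cov = pd.concat(
                [sheet.loc[list(raw.sample_ids), ["sex", "genotyping_batch"]], gpcs, dnam_pcs],
                axis=1,
            )
            mq_model = CisMQTLModel(
                cell_adj,
                ds.genotypes,
                annotation=ds.annotation,
                covariates=cov,
                window=config.cis_window,
                tissue=t,
            )
            mfit = mq_model.fit(report_p=config.mqtl_report_p)
            mqtl_results[t] = mfit
            mqtl_sets[t] = mfit.significant_cpgs(config.q_thresh)
            log.info("mqtl %s: %s", t, mfit.summary().splitlines()[-1])

    # ---- enrichment & overlap ----------------------------------------------
    universe = set(results.records.index[np.isfinite(results.records["p"])])
    correlated = set(results.significant_cpgs)
    enrich = {}
    if mqtl_sets:
        union_mqtl = set.union(*mqtl_sets.values()) & universe
        if correlated and union_mqtl:
            try:
                e = mqtl_enrichment(
                    correlated,
                    union_mqtl,
                    universe,
                    ds.annotation.subset(sorted(universe)),
                    bin_size=config.bin_size,
                    seed=config.seed,
                    yates=config.yates,
                )
                enrich["mqtl"] = {
                    "chi2": e.chi2,
                    "df": e.df,
                    "p": e.p,
                    "observed": e.observed.to_dict(),
                    "residuals": e.pearson_residuals.to_dict(),
                }
            except ValueError as err:
                log.warning("mqtl enrichment skipped: %s", err)
    if correlated:
        e = region_enrichment(correlated, universe, ds.annotation.subset(sorted(universe)))
        enrich["region"] = {
            "chi2": e.chi2,
            "df": e.df,
            "p": e.p,
            "residuals": e.pearson_residuals.to_dict(),
        }
    overlap = None
    if mqtl_sets and correlated:
        named = {"correlated": correlated}
        named.update({f"{t}_mqtl": s for t, s in mqtl_sets.items()})
        overlap = overlap_report(named, denominator="correlated", precision=2)

    # ---- artifacts ----------------------------------------------------------
    results.to_tsv(out / "correlation_map.tsv")
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index_label="cpg_id")
    mio.write_sheet_csv(ds.sheet, out / "sample_sheet.csv")
    pd.concat([r.to_frame() for r in qc_reports]).to_csv(
        out / "qc_report.tsv", sep="\t", index=False
    )
    for key, screen in screens.items():
        screen.tests.to_csv(
            out / f"screen_{key[0]}_{key[1]}.tsv", sep="\t", index=False
        )
    for t, mfit in mqtl_results.items():
        mfit.to_tsv(out / f"mqtl_{t}.tsv")
    bundle = {
        "summary": summary.as_dict(),
        "crosscheck": crosscheck,
        "enrichment": enrich,
        "overlap": dataclasses.asdict(overlap) if overlap else None,
        "n_probes_after_qc": len(common),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    config.to_yaml(str(out / "resolved_config.yaml"))

    return {
        "results": results,
        "batch_results": batch_results,
        "summary": summary,
        "crosscheck": crosscheck,
        "mqtl": mqtl_results,
        "mqtl_sets": mqtl_sets,
        "enrichment": enrich,
        "overlap": overlap,
        "dataset": ds,
        "adjusted": combined_adj,
    }
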