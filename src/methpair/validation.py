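"""Built-in simulation studies validating the pipeline's operating
characteristics on synthetic data with known ground truth.

Each study simulates data under the package's study design (120 paired
individuals in two batches unless stated otherwise), runs the relevant
pipeline stage, and returns the measured operating characteristic:
false-discovery behaviour under the null, sensitivity for planted
correlations, confounder detection and removal, cis-mQTL recovery, and
enrichment-test calibration. The same studies back the automated
acceptance checks and can be run standalone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig, SimulationConfig
from .containers import BetaMatrix
from .correlation import CrossTissueSpearman
from .covariates import combine_and_debatch
from .enrichment import mqtl_enrichment
from .mqtl import CisMQTLModel
from .pipeline import adjust_dataset
from .qc import estimate_cell_composition
from .simulate import (
    generate_genotypes,
    generate_paired_dataset,
    generate_probe_annotation,
    plant_truth,
)

_ZERO_EFFECTS = {
    "batch": 0.0, "diagnosis": 0.0, "array_id": 0.0,
    "array_position": 0.0, "conversion": 0.0, "celltype": 0.0,
}


def _combined(ds, tissue: str) -> BetaMatrix:
    vals = pd.concat(
        [ds.betas[(tissue, "batch1")].values, ds.betas[(tissue, "batch2")].values],
        axis=1,
    )
    return BetaMatrix(vals, annotation=ds.annotation, sheet=ds.sheet.loc[vals.columns])


def null_fdr_study(
    n_datasets: int = 200,
    n_pairs: int = 120,
    n_cpgs: int = 5000,
    q_thresh: float = 0.05,
    seed: int = 0,
) -> dict:
    """Realised false-discovery proportion of the correlation map under the
    global null (no planted correlation, no genetics, no shared covariate
    effects). Under the global null the FDP is 1 whenever anything is
    rejected, so its mean estimates the family-wise error BH yields there
    (~ q). Returns the mean FDP and its Monte-Carlo standard error."""
    fdps = []
    for i in range(n_datasets):
        cfg = SimulationConfig(
            n_pairs=n_pairs, n_cpgs=n_cpgs, n_snps=0,
            batch_sizes=(n_pairs // 3, n_pairs - n_pairs // 3),
            frac_correlated=0.0, frac_mqtl=0.0,
            shared_covariate_effects=False,
            seed=seed * 100_003 + i,
        )
        ds = generate_paired_dataset(cfg)
        res = CrossTissueSpearman(_combined(ds, "brain"), _combined(ds, "buccal")).fit(
            q_thresh=q_thresh
        )
        n_rej = int(res.records["significant"].sum())
        fdps.append(1.0 if n_rej > 0 else 0.0)  # all rejections are false
    fdps = np.asarray(fdps)
    return {
        "mean_fdp": float(fdps.mean()),
        "se": float(fdps.std(ddof=1) / np.sqrt(len(fdps))),
        "n_datasets": n_datasets,
        "n_cpgs": n_cpgs,
    }


def power_study(
    n_planted: int = 100,
    rho: float = 0.5,
    n_cpgs: int = 5000,
    n_pairs: int = 120,
    q_thresh: float = 0.05,
    seed: int = 0,
) -> dict:
    """Sensitivity of the correlation map for exactly ``n_planted`` CpGs with
    target Spearman ``rho`` among ``n_cpgs``."""
    cfg = SimulationConfig(
        n_pairs=n_pairs, n_cpgs=n_cpgs, n_snps=0,
        batch_sizes=(44 * n_pairs // 120, n_pairs - 44 * n_pairs // 120),
        frac_correlated=0.0, frac_mqtl=0.0, seed=seed,
    )
    ann = generate_probe_annotation(cfg)
    rng = np.random.default_rng(seed + 1)
    truth = pd.DataFrame(index=ann.cpg_ids)
    truth["region"] = ann.table["region"]
    planted_idx = rng.choice(n_cpgs, n_planted, replace=False)
    is_corr = np.zeros(n_cpgs, dtype=bool)
    is_corr[planted_idx] = True
    truth["is_correlated"] = is_corr
    truth["rho_target"] = np.where(is_corr, rho, 0.0)
    truth["mqtl_snp"] = ""
    truth["mqtl_beta"] = 0.0
    ds = generate_paired_dataset(cfg, annotation=ann, truth=truth)
    res = CrossTissueSpearman(_combined(ds, "brain"), _combined(ds, "buccal")).fit(
        q_thresh=q_thresh
    )
    rec = res.records
    sens = float(rec.loc[truth.index[is_corr], "significant"].mean())
    n_false = int(rec.loc[truth.index[~is_corr], "significant"].sum())
    n_sig = int(rec["significant"].sum())
    return {
        "sensitivity": sens,
        "n_false_positive": n_false,
        "fdp": n_false / n_sig if n_sig else 0.0,
        "n_planted": n_planted,
        "n_cpgs": n_cpgs,
    }


def _confounded_config(n_cpgs: int, n_pairs: int, seed: int) -> SimulationConfig:
    """Study conditions with a planted batch shift (~ +0.05 on the beta scale
    near beta = 0.5, i.e. 0.2 logit units) shared between tissues, plus
    cell-composition and conversion-efficiency effects."""
    return SimulationConfig(
        n_pairs=n_pairs, n_cpgs=n_cpgs, n_snps=0,
        batch_sizes=(44 * n_pairs // 120, n_pairs - 44 * n_pairs // 120),
        frac_correlated=0.0, frac_mqtl=0.0,
        batch_effect_mean=0.2,
        shared_covariate_effects=True,
        # diagnosis is left at zero here: a weak *shared* effect would sit
        # below the screen's detection threshold yet still shift the null
        # p-value distribution, confounding the calibration question this
        # study asks (can the screen find, and the adjustment remove, the
        # planted detectable confounders?)
        covariate_effect_sds={
            "batch": 0.05, "diagnosis": 0.0, "array_id": 0.05,
            "array_position": 0.03, "conversion": 0.05, "celltype": 1.0,
        },
        seed=seed,
    )


def confounder_study(
    n_reps: int = 100,
    n_cpgs_screen: int = 2000,
    n_cpgs_ks: int = 5000,
    n_pairs: int = 120,
    seed: int = 0,
) -> dict:
    """Confounder detection and removal.

    (1) Screen power: across ``n_reps`` replicate datasets, how often the
    covariate screen flags the planted conversion-efficiency and dominant
    cell-fraction covariates in every tissue/batch dataset.
    (2) Removal: on one larger dataset, after screen -> residualize ->
    combine-and-debatch, null-CpG cross-tissue p-values are tested for
    uniformity (Kolmogorov-Smirnov), and compared with the unadjusted run.
    """
    config = PipelineConfig(seed=seed)
    flag_hits = 0
    for i in range(n_reps):
        cfg = _confounded_config(n_cpgs_screen, n_pairs, seed * 99_991 + i + 1)
        ds = generate_paired_dataset(cfg)
        all_flagged = True
        for key, mat in ds.betas.items():
            tissue = key[0]
            ref = ds.reference.for_tissue(tissue)
            frac = estimate_cell_composition(mat, ref)
            frac_cols = [c for c in frac.columns if c != "residual_norm"]
            dominant = frac[frac_cols].mean().idxmax()
            _, screen = adjust_dataset(mat, frac, config, label=str(key))
            flagged = set(screen.flagged)
            if "conversion" not in flagged or dominant not in flagged:
                all_flagged = False
                break
        flag_hits += all_flagged

    cfg = _confounded_config(n_cpgs_ks, n_pairs, seed)
    ds = generate_paired_dataset(cfg)
    adjusted = {}
    for key, mat in ds.betas.items():
        frac = estimate_cell_composition(mat, ds.reference.for_tissue(key[0]))
        adjusted[key], _ = adjust_dataset(mat, frac, config, label=str(key))
    combined = {
        t: combine_and_debatch(adjusted[(t, "batch1")], adjusted[(t, "batch2")])
        for t in ("brain", "buccal")
    }
    res = CrossTissueSpearman(combined["brain"], combined["buccal"]).fit()
    ks_adj = stats.kstest(res.records["p"].dropna(), "uniform")
    raw = CrossTissueSpearman(_combined(ds, "brain"), _combined(ds, "buccal")).fit()
    ks_raw = stats.kstest(raw.records["p"].dropna(), "uniform")
    return {
        "screen_flag_rate": flag_hits / n_reps,
        "n_reps": n_reps,
        "ks_p_adjusted": float(ks_adj.pvalue),
        "ks_p_unadjusted": float(ks_raw.pvalue),
        "n_significant_unadjusted": int(raw.records["significant"].sum()),
        "n_significant_adjusted": int(res.records["significant"].sum()),
    }


def mqtl_recovery_study(
    n_runs: int = 20,
    n_individuals: int = 500,
    n_cpgs: int = 5000,
    n_snps: int = 2750,
    frac_mqtl: float = 0.01,
    effect: float = 1.0,
    seed: int = 0,
) -> dict:
    """Recovery of planted cis-mQTLs (large logit-scale effect, MAF 0.3).

    Each run simulates ~``n_cpgs * frac_mqtl`` planted mQTL CpGs on a sparse
    genome (~1-2 candidate SNPs per cis window, ~5000 tested pairs), fits
    the cis model in brain, and records sensitivity and the number of
    non-planted CpGs called at q < 0.05."""
    sens_runs, false_runs, tests = [], [], []
    for i in range(n_runs):
        cfg = SimulationConfig(
            n_pairs=n_individuals, n_cpgs=n_cpgs, n_snps=n_snps,
            batch_sizes=(n_individuals // 2, n_individuals - n_individuals // 2),
            chrom_lengths={f"chr{c}": 250_000_000 for c in range(1, 23)},
            frac_correlated=0.0, frac_mqtl=frac_mqtl,
            mqtl_effect_size=effect, maf_range=(0.3, 0.3),
            seed=seed * 90_007 + i,
        )
        ds = generate_paired_dataset(cfg)
        betas = _combined(ds, "brain")
        res = CisMQTLModel(betas, ds.genotypes, tissue="brain").fit()
        planted = set(ds.truth.index[ds.truth["mqtl_snp"] != ""])
        found = res.significant_cpgs(0.05)
        sens_runs.append(len(found & planted) / len(planted) if planted else np.nan)
        false_runs.append(len(found - planted))
        tests.append(res.n_tests)
    false_runs = np.asarray(false_runs)
    return {
        "mean_sensitivity": float(np.nanmean(sens_runs)),
        "mean_false_cpgs": float(false_runs.mean()),
        "frac_runs_zero_false": float((false_runs == 0).mean()),
        "mean_tests": float(np.mean(tests)),
        "n_runs": n_runs,
    }


def enrichment_study(
    n_null_seeds: int = 200,
    n_cpgs: int = 10_000,
    multiplier: float = 4.0,
    seed: int = 0,
) -> dict:
    """Calibration and power of the bin-matched mQTL enrichment test.

    Power: one universe with the planted odds multiplier; the test must give
    a vanishing p with a positive residual in the (correlated, mQTL) cell.
    Calibration: with multiplier 1.0, enrichment p-values across independent
    universes are tested for uniformity (continuity correction off; with it
    the p-values are conservative by construction)."""
    cfg = SimulationConfig(
        n_pairs=4, n_cpgs=n_cpgs, n_snps=2000, batch_sizes=(2, 2),
        frac_correlated=0.2, frac_negative=0.0, frac_mqtl=0.1,
        mqtl_enrichment=multiplier, seed=seed,
    )
    ann = generate_probe_annotation(cfg)
    gen = generate_genotypes(cfg)
    truth = plant_truth(cfg, ann, gen)
    correlated = set(truth.index[truth["is_correlated"]])
    mqtl = set(truth.index[truth["mqtl_snp"] != ""])
    planted = mqtl_enrichment(correlated, mqtl, set(ann.cpg_ids), ann, seed=seed)

    null_ps = []
    for i in range(n_null_seeds):
        cfg_i = dataclasses.replace(cfg, mqtl_enrichment=1.0, seed=seed * 70_001 + i + 1)
        ann_i = generate_probe_annotation(cfg_i)
        gen_i = generate_genotypes(cfg_i)
        truth_i = plant_truth(cfg_i, ann_i, gen_i)
        corr_i = set(truth_i.index[truth_i["is_correlated"]])
        mqtl_i = set(truth_i.index[truth_i["mqtl_snp"] != ""])
        res = mqtl_enrichment(
            corr_i, mqtl_i, set(ann_i.cpg_ids), ann_i, seed=i, yates=False
        )
        null_ps.append(res.p)
    ks = stats.kstest(null_ps, "uniform")
    return {
        "planted_p": float(planted.p),
        "planted_residual_corr_mqtl": float(
            planted.pearson_residuals.loc["correlated", "mqtl"]
        ),
        "null_ks_p": float(ks.pvalue),
        "n_null_seeds": n_null_seeds,
    }
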