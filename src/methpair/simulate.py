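"""Synthetic paired-tissue methylation data with planted, recoverable structure.

The generative model works on the logit (M-value) scale. For individual i,
CpG j, tissue t:

    M_ijt = mu_jt + s_jt * u_ij + gamma_j' c_it + (covariate effects)
            + g_j * dose_i + eps_ijt,        beta = logistic(M)

where ``u_ij`` is a standard-normal per-(individual, CpG) factor shared
between the two tissues at planted-correlated CpGs (independent across
CpGs), ``c_it`` are Dirichlet cell-type fractions mixing reference
signatures, and ``g_j`` is a cis genetic effect.
Because the logistic transform is strictly monotone, the cross-tissue
Spearman correlation of the betas equals that of the latent Gaussians, so
target Spearman magnitudes can be planted exactly through the classical
identity rho_S = (6/pi) * asin(r/2) for a bivariate Gaussian with Pearson
correlation r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import SimulationConfig
from .containers import (
    REGION_CATEGORIES,
    BetaMatrix,
    CellReference,
    GenotypeMatrix,
    ProbeAnnotation,
)

_STREAMS = {"annotation": 1, "genotypes": 2, "truth": 3, "data": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stage]])


def spearman_to_pearson(rho_s):
    """Pearson correlation of a bivariate Gaussian with Spearman ``rho_s``."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s) / 6.0)


def pearson_to_spearman(r):
    """Population Spearman correlation of a bivariate Gaussian with Pearson ``r``."""
    return (6.0 / np.pi) * np.arcsin(np.asarray(r) / 2.0)


def _sample_distinct_positions(
    rng: np.random.Generator, length: int, n: int
) -> np.ndarray:
    """Uniformly sample ``n`` distinct 1-based positions on [1, length]."""
    if n > length:
        raise ValueError(f"cannot place {n} probes on a chromosome of length {length}")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(1, length + 1, size=n - len(chosen))
        chosen.update(int(x) for x in draw)
    return np.sort(np.fromiter(chosen, dtype=np.int64))


def generate_probe_annotation(
    config: SimulationConfig,
    region_probs: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ProbeAnnotation:
    """Draw CpG positions uniformly per chromosome (proportional allocation by
    length), assign each of the eight gene-region categories from a
    categorical distribution, and plant blacklist flags."""
    rng = rng if rng is not None else _rng(config.seed, "annotation")
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    if config.n_cpgs > lengths.sum():
        raise ValueError("n_cpgs exceeds the total number of assignable positions")
    if config.n_cpgs == 0:
        empty = pd.DataFrame(
            columns=["chrom", "pos", "region", "flag_xy", "flag_snp", "flag_multimap"]
        )
        return ProbeAnnotation(empty)
    counts = rng.multinomial(config.n_cpgs, lengths / lengths.sum())
    # proportional allocation can overfill a short chromosome; redistribute
    for _ in range(100):
        over = counts - lengths.astype(int)
        if (over <= 0).all():
            break
        excess = int(over[over > 0].sum())
        counts = np.minimum(counts, lengths.astype(int))
        room = lengths.astype(int) - counts
        add = rng.multinomial(excess, room / room.sum())
        counts = counts + add

    if region_probs is None:
        probs = np.array([0.14, 0.07, 0.09, 0.07, 0.01, 0.32, 0.03, 0.27])
    else:
        probs = np.array([region_probs[c] for c in REGION_CATEGORIES], dtype=float)
        probs = probs / probs.sum()

    rows = []
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        pos = _sample_distinct_positions(rng, config.chrom_lengths[chrom], int(n_c))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    table = pd.concat(rows, ignore_index=True)
    table["region"] = rng.choice(REGION_CATEGORIES, size=len(table), p=probs)
    for flag, frac in config.frac_flagged.items():
        table[flag] = rng.random(len(table)) < frac
    table.index = pd.Index(
        [f"cg{i:08d}" for i in range(len(table))], name="cpg_id"
    )
    return ProbeAnnotation(table)


def generate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages: per SNP an allele frequency drawn uniformly from
    ``maf_range`` and per-individual dosage ~ Binomial(2, p)."""
    rng = rng if rng is not None else _rng(config.seed, "genotypes")
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n = config.n_snps
    individuals = [f"ind{i:04d}" for i in range(config.n_pairs)]
    if n == 0:
        snps = pd.DataFrame(columns=["chrom", "pos", "maf"])
        snps.index.name = "snp_id"
        return GenotypeMatrix(snps, pd.DataFrame(index=snps.index, columns=individuals))
    counts = rng.multinomial(n, lengths / lengths.sum())
    rows = []
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        pos = _sample_distinct_positions(rng, config.chrom_lengths[chrom], int(n_c))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    snps = pd.concat(rows, ignore_index=True)
    snps["maf"] = rng.uniform(*config.maf_range, size=len(snps))
    snps.index = pd.Index([f"rs{i:07d}" for i in range(len(snps))], name="snp_id")
    dos = rng.binomial(2, snps["maf"].to_numpy()[:, None], size=(len(snps), config.n_pairs))
    dosages = pd.DataFrame(dos.astype(float), index=snps.index, columns=individuals)
    return GenotypeMatrix(snps, dosages)


def plant_truth(
    config: SimulationConfig,
    annotation: ProbeAnnotation,
    genotypes: GenotypeMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign planted cross-tissue correlation targets and cis-mQTL status.

    mQTL status is sampled with odds multiplied by ``mqtl_enrichment`` for
    correlated CpGs; each mQTL CpG is tied to its nearest SNP within the
    +-1 Mb cis window (CpGs with no cis SNP lose mQTL status). Negative-
    target CpGs are never assigned an mQTL so the shared genetic component
    cannot fight the planted anti-correlation.
    """
    rng = rng if rng is not None else _rng(config.seed, "truth")
    ann = annotation.table
    n = len(ann)
    truth = pd.DataFrame(index=ann.index)
    truth["region"] = ann["region"]

    is_corr = rng.random(n) < config.frac_correlated
    rho = np.zeros(n)
    lo, hi = config.rho_target_range
    rho[is_corr] = rng.uniform(lo, hi, size=int(is_corr.sum()))
    neg = is_corr & (rng.random(n) < config.frac_negative)
    rho[neg] *= -1.0
    truth["is_correlated"] = is_corr
    truth["rho_target"] = rho

    # mQTL status: base odds, multiplied for (positively) correlated CpGs
    p0 = config.frac_mqtl
    odds0 = p0 / (1.0 - p0) if p0 < 1 else np.inf
    odds1 = odds0 * config.mqtl_enrichment
    p1 = odds1 / (1.0 + odds1)
    p_mqtl = np.where(is_corr, p1, p0)
    p_mqtl[neg] = 0.0
    has_mqtl = rng.random(n) < p_mqtl

    mqtl_snp = np.full(n, "", dtype=object)
    mqtl_beta = np.zeros(n)
    if genotypes is not None and len(genotypes) and has_mqtl.any():
        snp_by_chrom = {
            chrom: grp.sort_values("pos")
            for chrom, grp in genotypes.snps.groupby("chrom")
        }
        signs = rng.choice([-1.0, 1.0], size=n)
        idx_mqtl = np.flatnonzero(has_mqtl)
        for ji in idx_mqtl:
            chrom = ann["chrom"].iloc[ji]
            pos = ann["pos"].iloc[ji]
            grp = snp_by_chrom.get(chrom)
            if grp is None:
                continue
            dist = (grp["pos"] - pos).abs()
            best = dist.idxmin()
            if dist.loc[best] <= 1_000_000:
                mqtl_snp[ji] = best
                mqtl_beta[ji] = signs[ji] * config.mqtl_effect_size
    truth["mqtl_snp"] = mqtl_snp
    truth["mqtl_beta"] = mqtl_beta
    return truth


def _dirichlet_cov(alpha: np.ndarray) -> np.ndarray:
    a0 = alpha.sum()
    denom = a0 * a0 * (a0 + 1.0)
    cov = -np.outer(alpha, alpha) / denom
    np.fill_diagonal(cov, alpha * (a0 - alpha) / denom)
    return cov


def _solve_loading(r_abs: float, w_b: float, w_u: float, h: float) -> float:
    """Scale ``a`` of the shared-factor loadings s_t = a*sqrt(w_t) such that
    the latent Pearson correlation (including shared genetic variance h)
    equals ``r_abs``. Monotone in a; solved by Brent's method."""

    def corr(a: float) -> float:
        num = a * a * np.sqrt(w_b * w_u) + h
        den = np.sqrt(((a * a + 1) * w_b + h) * ((a * a + 1) * w_u + h))
        return num / den

    if corr(0.0) >= r_abs:
        return 0.0
    hi = 1.0
    while corr(hi) < r_abs and hi < 1e6:
        hi *= 2.0
    if corr(hi) < r_abs:
        raise ValueError(f"cannot reach latent correlation {r_abs}")
    return brentq(lambda a: corr(a) - r_abs, 0.0, hi, xtol=1e-12)


@dataclass
class SimulatedDataset:
    """Everything one synthetic study produces."""

    betas: dict[tuple[str, str], BetaMatrix]  # (tissue, batch) -> matrix
    sheet: pd.DataFrame
    truth: pd.DataFrame
    annotation: ProbeAnnotation
    genotypes: GenotypeMatrix
    reference: CellReference
    cell_fractions: dict[str, pd.DataFrame]  # tissue -> individuals x cell types


def _make_sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    individuals = [f"ind{i:04d}" for i in range(config.n_pairs)]
    batch = np.repeat(list(config.batches), config.batch_sizes)
    diagnosis = rng.choice(["control", "AD", "other_neuro"], size=config.n_pairs,
                           p=[0.3, 0.4, 0.3])
    sex = rng.choice(["F", "M"], size=config.n_pairs)
    geno_batch = rng.choice(["g1", "g2"], size=config.n_pairs)
    rows = []
    for tissue in config.tissues:
        for b_i, b in enumerate(config.batches):
            # each tissue is processed in its own order on its own arrays, so
            # array/position groupings are not shared between the two tissues
            idx = rng.permutation(np.flatnonzero(batch == b))
            for slot, i in enumerate(idx):
                rows.append(
                    {
                        "sample_id": f"{individuals[i]}:{tissue}",
                        "individual": individuals[i],
                        "tissue": tissue,
                        "batch": b,
                        "diagnosis": diagnosis[i],
                        "conversion": float(np.round(rng.uniform(85.0, 99.5), 2)),
                        "array_id": f"{tissue[:2]}_{b}_A{slot // 8}",
                        "array_position": f"R{slot % 8 + 1:02d}C01",
                        "extraction_date": f"2018-0{b_i + 1}-{(int(rng.integers(4))) * 7 + 1:02d}",
                        "sex": sex[i],
                        "genotyping_batch": geno_batch[i],
                    }
                )
    sheet = pd.DataFrame(rows).set_index("sample_id")
    return sheet


def generate_paired_dataset(
    config: SimulationConfig,
    annotation: ProbeAnnotation | None = None,
    genotypes: GenotypeMatrix | None = None,
    truth: pd.DataFrame | None = None,
) -> SimulatedDataset:
    """Generate the four beta matrices (2 tissues x 2 batches), sample sheet,
    ground-truth table and cell-type reference for one synthetic study."""
    if annotation is None:
        annotation = generate_probe_annotation(config)
    if genotypes is None:
        genotypes = generate_genotypes(config)
    if truth is None:
        truth = plant_truth(config, annotation, genotypes)
    rng = _rng(config.seed, "data")

    n, m = config.n_pairs, len(annotation)
    individuals = [f"ind{i:04d}" for i in range(n)]
    sheet = _make_sample_sheet(config, rng)
    tissues = config.tissues
    sds = config.covariate_effect_sds

    # baseline methylation: bimodal on the logit scale, small tissue offsets
    comp = rng.choice([-2.5, 2.5, 0.0], size=m, p=[0.45, 0.45, 0.10])
    mu0 = comp + rng.normal(0.0, 0.8, size=m)
    mu = {t: mu0 + rng.normal(0.0, 0.3, size=m) for t in tissues}

    # cell-type structure: informative CpGs carry centred per-cell-type offsets
    informative = rng.random(m) < config.frac_cell_informative
    gamma: dict[str, np.ndarray] = {}
    fractions: dict[str, pd.DataFrame] = {}
    signatures: dict[str, pd.DataFrame] = {}
    cell_var: dict[str, np.ndarray] = {}
    for t in tissues:
        k = config.n_celltypes[t]
        g = np.zeros((m, k))
        g[informative] = rng.normal(0.0, sds.get("celltype", 0.0), size=(informative.sum(), k))
        g -= g.mean(axis=1, keepdims=True)
        gamma[t] = g
        alpha = np.asarray(config.dirichlet_alpha[t], dtype=float)
        w = rng.dirichlet(alpha, size=n)
        fractions[t] = pd.DataFrame(
            w, index=individuals, columns=[f"{t}_ct{j + 1}" for j in range(k)]
        )
        sig = expit(mu[t][informative, None] + g[informative])
        signatures[t] = pd.DataFrame(
            sig,
            index=annotation.cpg_ids[informative],
            columns=[f"{t}_ct{j + 1}" for j in range(k)],
        )
        cov = _dirichlet_cov(alpha)
        cell_var[t] = np.einsum("jk,kl,jl->j", g, cov, g)

    # covariate effects (per CpG, per tissue unless shared)
    batch_ind = np.repeat([0.0, 1.0], config.batch_sizes)
    p_b = config.batch_sizes[1] / n
    diag_levels = ["control", "AD", "other_neuro"]
    diag_of_ind = sheet.loc[[f"{i}:{tissues[0]}" for i in individuals], "diagnosis"].to_numpy()
    diag_probs = np.array([0.3, 0.4, 0.3])

    def draw_effects(sd: float, shape) -> np.ndarray:
        return rng.normal(0.0, sd, size=shape) if sd > 0 else np.zeros(shape)

    b_eff: dict[str, np.ndarray] = {}
    d_eff: dict[str, np.ndarray] = {}
    shared_b = config.batch_effect_mean + draw_effects(sds.get("batch", 0.0), m)
    shared_d = draw_effects(sds.get("diagnosis", 0.0), (m, 3))
    shared_d -= (shared_d * diag_probs).sum(axis=1, keepdims=True)
    for t in tissues:
        if config.shared_covariate_effects:
            b_eff[t] = shared_b
            d_eff[t] = shared_d
        else:
            b_eff[t] = config.batch_effect_mean + draw_effects(sds.get("batch", 0.0), m)
            de = draw_effects(sds.get("diagnosis", 0.0), (m, 3))
            de -= (de * diag_probs).sum(axis=1, keepdims=True)
            d_eff[t] = de

    # genetic effects (shared between tissues: same individual dosage)
    g_j = truth["mqtl_beta"].to_numpy()
    dose_of_cpg = np.zeros((m, n))
    gen_var = np.zeros(m)
    has_g = truth["mqtl_snp"].to_numpy() != ""
    if has_g.any():
        snp_ids = truth.loc[has_g, "mqtl_snp"]
        dose_of_cpg[has_g] = genotypes.dosages.loc[snp_ids, individuals].to_numpy()
        maf = genotypes.snps.loc[snp_ids, "maf"].to_numpy()
        gen_var[has_g] = g_j[has_g] ** 2 * 2.0 * maf * (1.0 - maf)

    # per-CpG independent variance (per tissue) for the loading calibration
    var_diag = {
        t: (d_eff[t] ** 2 * diag_probs).sum(axis=1)
        - ((d_eff[t] * diag_probs).sum(axis=1)) ** 2
        for t in tissues
    }
    conv_sd = sds.get("conversion", 0.0)
    conv_var = {}
    conv_eff = {}
    conv_vals = {}
    for t in tissues:
        conv = sheet.loc[[f"{i}:{t}" for i in individuals], "conversion"].to_numpy()
        conv_vals[t] = conv - conv.mean()
        conv_eff[t] = draw_effects(conv_sd, m)
        conv_var[t] = conv_eff[t] ** 2 * conv_vals[t].var()
    arr_eff = {}
    arr_val = {}
    arr_var = {}
    pos_eff = {}
    pos_val = {}
    pos_var = {}
    for t in tissues:
        samples_t = [f"{i}:{t}" for i in individuals]
        arrays = sheet.loc[samples_t, "array_id"]
        arr_levels = sorted(arrays.unique())
        ae = draw_effects(sds.get("array_id", 0.0), (m, len(arr_levels)))
        ae -= ae.mean(axis=1, keepdims=True)
        codes = arrays.map({a: i for i, a in enumerate(arr_levels)}).to_numpy()
        arr_eff[t], arr_val[t] = ae, codes
        arr_var[t] = ae[:, codes].var(axis=1)
        positions = sheet.loc[samples_t, "array_position"]
        pos_levels = sorted(positions.unique())
        pe = draw_effects(sds.get("array_position", 0.0), (m, len(pos_levels)))
        pe -= pe.mean(axis=1, keepdims=True)
        pcodes = positions.map({a: i for i, a in enumerate(pos_levels)}).to_numpy()
        pos_eff[t], pos_val[t] = pe, pcodes
        pos_var[t] = pe[:, pcodes].var(axis=1)

    w_indep = {}
    for t in tissues:
        w = (
            config.noise_sd**2
            + cell_var[t]
            + var_diag[t]
            + conv_var[t]
            + arr_var[t]
            + pos_var[t]
        )
        if not config.shared_covariate_effects:
            w = w + b_eff[t] ** 2 * p_b * (1.0 - p_b)
        w_indep[t] = w

    shared_extra = gen_var.copy()
    if config.shared_covariate_effects:
        shared_extra = shared_extra + shared_b**2 * p_b * (1.0 - p_b) + (
            (shared_d**2 * diag_probs).sum(axis=1)
            - ((shared_d * diag_probs).sum(axis=1)) ** 2
        )

    # shared-factor loadings from the Spearman targets; the factor u is a
    # per-(individual, CpG) standard normal shared between the two tissues,
    # independent across CpGs
    rho_t = truth["rho_target"].to_numpy()
    s = {t: np.zeros(m) for t in tissues}
    t_b, t_u = tissues[0], tissues[-1]
    planted_rows = np.flatnonzero(rho_t != 0.0)
    for ji in planted_rows:
        r_abs = abs(float(spearman_to_pearson(rho_t[ji])))
        a = _solve_loading(r_abs, w_indep[t_b][ji], w_indep[t_u][ji], shared_extra[ji])
        s[t_b][ji] = a * np.sqrt(w_indep[t_b][ji])
        s[t_u][ji] = np.sign(rho_t[ji]) * a * np.sqrt(w_indep[t_u][ji])

    u = np.zeros((m, n))
    if len(planted_rows):
        u[planted_rows] = rng.normal(0.0, 1.0, size=(len(planted_rows), n))
    diag_code = np.array([diag_levels.index(d) for d in diag_of_ind])

    betas: dict[tuple[str, str], BetaMatrix] = {}
    for t in tissues:
        M = (
            mu[t][:, None]
            + s[t][:, None] * u
            + gamma[t] @ fractions[t].to_numpy().T
            + b_eff[t][:, None] * batch_ind[None, :]
            + d_eff[t][:, diag_code]
            + conv_eff[t][:, None] * conv_vals[t][None, :]
            + arr_eff[t][:, arr_val[t]]
            + pos_eff[t][:, pos_val[t]]
            + g_j[:, None] * dose_of_cpg
            + rng.normal(0.0, config.noise_sd, size=(m, n))
        )
        if not np.isfinite(M).all():
            raise ValueError("non-finite latent logit values generated")
        vals = pd.DataFrame(
            expit(M), index=annotation.cpg_ids, columns=[f"{i}:{t}" for i in individuals]
        )
        for b in config.batches:
            cols = [c for c in vals.columns if sheet.loc[c, "batch"] == b]
            betas[(t, b)] = BetaMatrix(
                vals[cols], annotation=annotation, sheet=sheet.loc[cols]
            )

    reference = CellReference(signatures)
    return SimulatedDataset(
        betas=betas,
        sheet=sheet,
        truth=truth,
        annotation=annotation,
        genotypes=genotypes,
        reference=reference,
        cell_fractions=fractions,
    )
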