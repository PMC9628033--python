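# Methods

`methpair` implements a paired-tissue DNA-methylation correlation analysis
as a tested, reusable pipeline, together with a synthetic-data generator
that reproduces the statistical structure such an analysis assumes. This
note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic validation does and does not
demonstrate about real data.

## The analysis

The pipeline takes beta-value matrices (CpGs × samples) for two tissues —
called *brain* and *buccal* throughout — collected from the same
individuals in two laboratory batches, and produces:

1. **QC.** Samples with bisulfite conversion efficiency below 80% are
   excluded (≥ 80 kept); probes on the X/Y chromosomes, overlapping SNPs,
   or mapping to multiple genomic locations are removed; a deterministic
   PCA-based outlier screen flags aberrant samples; analysis is restricted
   to probes present in all four tissue × batch datasets. Detection-p
   masking (entries with detection p > 0.01 set missing; probes with
   beadcount < 3 in strictly more than 5% of samples removed) is available
   for array exports that provide those matrices.
2. **Covariate detection and removal.** Per dataset, PCA (probes centred,
   not scaled, singular value decomposition — the behaviour of R's
   `prcomp`) on a spatially decorrelated probe subset built by taking one
   random CpG per 100 kb genomic bin. Candidate covariates are screened
   against the retained components: Pearson correlation with a two-sided
   t-test for numeric covariates (conversion efficiency, estimated cell
   fractions), one-way ANOVA for categorical ones (diagnosis, array id,
   array position, extraction date). Covariates with p < 0.01 on any
   retained PC are removed from every probe by per-CpG OLS with
   sum-to-zero coding, which preserves the grand mean — the behaviour of
   limma's `removeBatchEffect`. The two batches are then concatenated per
   tissue and the batch factor removed the same way. A robustness variant
   residualizes all probes directly on the first k = 3 PCs.
3. **Correlation map.** Per CpG, Spearman rank correlation between the two
   tissues across paired individuals: average ranks for ties, two-sided p
   from the t approximation t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 df (what R's
   `cor.test` does in the presence of ties), pairwise-complete handling of
   missing entries, records with fewer than 4 complete pairs excluded from
   the FDR. Benjamini–Hochberg adjustment over exactly the tested probes;
   q < 0.05 is genome-wide significant; a |ρ| > 0.5 variant and per-batch
   replication checks (nominal p < 0.05 in each batch separately) are
   reported alongside.
4. **cis-mQTLs.** For every SNP–CpG pair on the same chromosome within
   ±1 Mb (closed interval; distance signed SNP − CpG), an additive linear
   model of the cell-composition-adjusted methylation value on dosage plus
   sex, genetic PCs 1–5, methylation PCs 1–10 and genotyping batch.
   Computation uses the Frisch–Waugh–Lovell decomposition (covariates
   projected out of both variables once), which is numerically identical
   to the full OLS fit. q-values are computed over *all* tested pairs even
   though only pairs with p < 0.05 are stored — the convention of
   matrix-eQTL-style software; a CpG is an mQTL CpG if any of its pairs
   reaches q < 0.05. SNPs with minor allele count < 3 in the analysed
   samples are skipped (such fits are degenerate; the threshold is this
   package's choice).
5. **Enrichment and overlap.** Chi-squared tests of independence with
   Yates continuity correction for 2×2 tables by default (the R
   `chisq.test` default) and without it for larger tables; Pearson
   residuals (O−E)/√E always computed without the correction so that their
   squared sum equals the uncorrected statistic. mQTL enrichment among
   correlated CpGs is tested on a bin-matched background (the same one-
   CpG-per-100-kb subsample used for PCA, with its own seed). Gene-region
   enrichment uses a 2×8 table over the categories TSS1500, TSS200, 5'UTR,
   1st exon, exon boundary, gene body, 3'UTR, IGR. Overlap reports compute
   Venn-style intersections with percentages rounded half-up to the
   printed precision.

Pearson correlation is deliberately not offered for the map: beta values
are bounded and typically bimodal, so rank correlation is the appropriate
choice; it is also invariant under the logistic link the simulation uses.

## The generative model

Simulation happens on the logit (M-value) scale, where additive effects
are well defined and the logistic transform keeps betas strictly inside
(0, 1). For individual i, CpG j, tissue t:

    M_ijt = mu_jt + s_jt·u_ij + Σ_k γ_jk·c_ik(t) + b_jt·batch_i
            + (diagnosis, array, position, conversion effects)
            + g_j·dose_i + ε_ijt,            beta = logistic(M)

* `mu_jt`: bimodal baseline (mixture of logit ±2.5 and 0) with small
  tissue offsets, mimicking the U-shaped beta distribution of methylation
  arrays.
* `u_ij`: standard-normal factor shared between the two tissues of the
  same individual at planted-correlated CpGs, independent across CpGs.
  Sharing it across CpGs instead would couple the sampling errors of all
  planted correlations within a dataset (a single lucky or unlucky draw
  of the factor shifts every planted correlation together), which is why
  the factor is per-CpG.
* `c_ik(t)`: Dirichlet cell-type fractions (defaults: 2 brain cell types,
  α = (8, 4); 3 buccal types, α = (6, 2, 2) — a dominant type plus
  minority types, as reference-based deconvolution of these tissues
  typically shows). A fraction of CpGs (default 10%) carries centred
  per-cell-type offsets γ with sd 1.0 logit units; the cell-type
  *reference* returned to the deconvolution step is the logistic of
  mu + γ at those CpGs, so generator and deconvolution share one model.
* Covariate effects: per-CpG coefficients drawn independently per tissue
  by default, so they add variance without adding cross-tissue
  correlation. With `shared_covariate_effects=True` the batch and
  diagnosis coefficients (individual-level variables) are shared between
  tissues — this is the *confounded* regime, since a shared coefficient
  times a shared covariate induces spurious cross-tissue correlation that
  the screening/adjustment stage must remove. `batch_effect_mean` plants
  a systematic batch shift; 0.2 logit units ≈ +0.05 beta near beta 0.5.
* `g_j`: cis genetic effect (default magnitude 1.0 logit per dosage unit,
  random sign), identical in both tissues — genetic control of
  methylation is the systemic, tissue-shared mechanism the enrichment
  analysis looks for. mQTL status is sampled with odds multiplied by
  `mqtl_enrichment` (default 4) for correlated CpGs, and each mQTL CpG is
  tied to its nearest SNP within ±1 Mb. CpGs with planted *negative*
  correlation never receive an mQTL: the shared genetic component is
  always positively correlated across tissues and would fight the
  anti-correlated factor.
* `ε`: independent Gaussian noise, default sd 0.5 logit units.

### Calibration of planted correlations

Because the logistic link is strictly monotone, the Spearman correlation
of the betas equals that of the latent variables. For a bivariate
Gaussian with Pearson correlation r the population Spearman is
ρ_S = (6/π)·asin(r/2), so a target ρ_S is converted exactly to a latent
Pearson target r = 2·sin(π·ρ_S/6). The shared-factor loadings are then
s_t = a·σ_t with σ_t² the CpG's independent variance in tissue t
(noise + cell-mixture + covariate terms, computed analytically — the
Dirichlet covariance is closed-form) and `a` solved by Brent's method
from

    ( a²·σ_b σ_u + h ) / sqrt( ((a²+1)σ_b² + h)((a²+1)σ_u² + h) ) = r,

where h is the variance already shared through a planted genetic effect
(2·maf·(1−maf)·g²). The left side is monotone in `a`; if the genetic
share alone exceeds the target, a = 0. Monte-Carlo checks in the test
suite confirm the empirical Spearman at planted CpGs is within ±0.05 of
the target. The cell-mixture term makes the latent variable slightly
non-Gaussian, so the identity is approximate at cell-informative CpGs —
in practice well inside that tolerance.

Defaults mirror the emulated study design: 120 individuals, batches of
44 and 76, a minority (5%) of CpGs with planted correlation drawn from
(0.3, 0.9) in magnitude, 1.4% of those negative, and mQTL base rate 15%
with enrichment odds 4 — chosen so that simulated maps reproduce the
qualitative picture of real paired-tissue maps (a few percent of CpGs
significant, overwhelmingly positive, strongly mQTL-enriched).

## Design choices where the design was open

* **Outlier stand-in.** Array-level outlier detection is reimplemented as
  a documented, deterministic procedure: PCA on the bin-subsampled
  probes, each sample scored on the leading (at most two) PCs by its
  distance beyond the far-out Tukey fences [Q1 − 3·IQR, Q3 + 3·IQR]
  in IQR units, flagged when the maximum score exceeds 0.15. Two
  refinements proved necessary: inner fences (1.5·IQR) co-flag clean
  samples under ordinary Gaussian variation, and PCs whose variance share
  is indistinguishable from noise (≤ 2/(n−1)) carry no outlier
  information, so only structured PCs are scored.
* **Deconvolution** is non-negative least squares per sample followed by
  renormalisation to sum to one. The downstream pipeline only consumes
  the fractions as screening covariates, so the simplest estimator
  satisfying the constraints is used; its recovery error on noisy
  synthetic mixtures (sd 0.02) is ≤ 0.05 mean absolute error.
* **PC selection** defaults to the smallest k reaching 80% cumulative
  variance ("cumvar 0.8"), because scree-plot selection is visual and not
  reproducible; a fixed-k mode exists (k = 3 for the robustness variant).
  The count used is always recorded.
* **Cell-fraction collinearity.** Estimated fractions sum to one; when
  every fraction of a tissue is flagged, the last one is dropped from the
  nuisance design to keep it full rank.
* **Yates correction** is on by default for 2×2 tables (matching the R
  default the analysis relied on) and exposed as a flag. Calibration
  checks of the enrichment test's null distribution are run with the
  correction off, because the corrected p-values are conservative by
  construction and cannot be uniform.
* **Positions** are 1-based everywhere in files and containers; 0-based
  half-open arithmetic exists only inside the binning routine
  (pos − 1) // bin_size.
* **Rounding** of reported percentages is decimal half-up (not banker's),
  matching how the printed values were produced.

## Validation studies and their problem sizes

`methpair.validation` packages five simulation studies; the acceptance
test suite runs them at these sizes (the standalone script uses the same
studies, some at reduced replicate counts, all sizes recorded in its
output):

* **Null FDR**: 200 datasets, 120 pairs × 5000 CpGs, no planted
  correlation, genetics or shared effects; mean realised false-discovery
  proportion at q < 0.05 (≈ the BH nominal level, since under the global
  null FDP is 1 exactly when anything is rejected).
* **Power**: 100 CpGs planted at ρ = 0.5 among 5000, 120 pairs;
  sensitivity at q < 0.05.
* **Confounder removal**: batch shift +0.05 beta with shared
  coefficients plus cell-composition and conversion effects; screen flag
  rate over 100 replicate studies, and KS uniformity of null-CpG p-values
  after the full screen → residualize → combine pipeline on a 5000-CpG
  dataset.
* **mQTL recovery**: 20 runs of ~50 planted large-effect cis-mQTLs
  (1.0 logit/dosage, MAF 0.3, n = 500) among ~5000 tested pairs on a
  sparse genome; sensitivity and false CpG counts at q < 0.05.
* **Enrichment**: one universe of 10,000 CpGs with planted odds
  multiplier 4 (power) and 200 universes with multiplier 1 (calibration).

## Known limitations

* A zero-false-discovery requirement is incompatible with BH at q < 0.05:
  with ~50 strong discoveries among ~5000 tests the BH rejection
  threshold sits near 5×10⁻⁴, so ~2.5 null pairs are expected beyond it
  in every run and most runs contain at least one false CpG. BH controls
  the expected false-discovery *proportion* (here ~5% of ~52
  discoveries), which the recovery study confirms; anyone needing zero
  expected false positives should use a family-wise procedure instead.
* The generator omits probe-chemistry effects (type I/II), age drift,
  linkage disequilibrium between SNPs, and region-dependent correlation
  structure; passing tests therefore demonstrate correctness of the
  *procedures* under the generative model, not performance on any real
  array dataset.
* The empirical Spearman of a planted CpG has sampling sd ≈ 0.07 at
  n = 120; planted targets are population values, recovered on average,
  not per CpG.
* Bisulfite conversion efficiency is consumed as a sample-sheet column;
  how it is derived from control probes is out of scope.
* Residualization removes degrees of freedom that the Spearman t
  approximation (df = n−2) does not know about. When the nuisance
  directions removed from the two tissues are *distinct* (tissue-specific
  arrays, positions, dates, cell fractions — the situation the generator
  emulates, since each tissue is processed in its own order on its own
  arrays), this has no measurable effect on calibration; the KS study
  verifies it. Removing the *shared* batch factor costs one common
  direction, inflating null |ρ| by ~1/(2n) — negligible at n = 120. A
  design where many nuisance directions are shared between the tissues
  (e.g. paired samples deliberately placed at identical array positions)
  would make the map anticonservative after adjustment; such designs need
  an explicit df correction that this package, like the workflow it
  reproduces, does not apply.
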