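"""Covariate detection and removal: binning, PCA, screening, residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpair.containers import BetaMatrix
from methpair.covariates import (
    bin_subsample,
    combine_and_debatch,
    direct_pc_adjust,
    pca,
    residualize,
    screen_covariates,
    select_pcs,
)

from conftest import make_annotation


def _matrix(values, annotation=None, sheet=None, adjusted=True):
    df = pd.DataFrame(
        values,
        index=[f"cg{i:05d}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return BetaMatrix(df, annotation=annotation, sheet=sheet, adjusted=adjusted)


class TestBinSubsample:
    def test_bin_arithmetic_one_based(self):
        """1-based positions 10, 50,020 share bin 0; 100,001 is 0-based
        100,000, the first position of bin 1."""
        ann = make_annotation([10, 50_020, 100_001])
        subset = bin_subsample(ann, bin_size=100_000, seed=0)
        assert len(subset) == 2
        assert "cg00002" in subset  # sole occupant of bin 1
        assert subset[0] in ("cg00000", "cg00001")

    def test_singleton_bins_identity(self):
        ann = make_annotation([50, 100_050, 200_050])
        for seed in (0, 1, 2):
            assert bin_subsample(ann, seed=seed) == list(ann.cpg_ids)

    def test_deterministic(self, small_annotation):
        assert bin_subsample(small_annotation, seed=7) == bin_subsample(
            small_annotation, seed=7
        )

    def test_output_sorted(self, small_annotation):
        subset = bin_subsample(small_annotation, seed=3)
        tab = small_annotation.table.loc[subset]
        assert list(tab.index) == list(
            tab.sort_values(["chrom", "pos"]).index
        )


class TestPCA:
    def test_two_samples_single_component(self):
        rng = np.random.default_rng(0)
        res = pca(_matrix(rng.normal(size=(30, 2))))
        assert (res.eigenvalues[1:] < 1e-20).all()

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(1)
        res = pca(_matrix(rng.normal(size=(10, 6))))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_scores_centered(self):
        rng = np.random.default_rng(2)
        res = pca(_matrix(rng.normal(size=(15, 8))))
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-10)

    def test_eigenvalues_match_svd_oracle(self):
        """5 variables x 4 samples of seeded Gaussians vs an independent SVD."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))  # probes x samples
        res = pca(_matrix(X))
        Xc = X.T - X.T.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert np.allclose(res.eigenvalues, s**2 / 3, atol=1e-8)

    def test_constant_matrix_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pca(_matrix(np.full((10, 5), 0.4)))


class TestSelectPCs:
    def _fake(self, ve):
        from methpair.covariates import PCAResult

        return PCAResult(
            scores=pd.DataFrame(), loadings=pd.DataFrame(),
            eigenvalues=np.asarray(ve), variance_explained=np.asarray(ve),
            subset_cpgs=[],
        )

    def test_cumvar(self):
        assert select_pcs(self._fake([0.5, 0.3, 0.1, 0.1]), "cumvar", frac=0.8) == 2

    def test_fixed_three(self):
        assert select_pcs(self._fake([0.5, 0.3, 0.1, 0.1]), "fixed", k=3) == 3

    def test_cumvar_full(self):
        assert select_pcs(self._fake([0.5, 0.3, 0.1, 0.1]), "cumvar", frac=1.0) == 4

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            select_pcs(self._fake([1.0]), "elbow")


class TestScreen:
    def _pca_with_scores(self, scores):
        from methpair.covariates import PCAResult

        res = PCAResult(
            scores=scores, loadings=pd.DataFrame(),
            eigenvalues=np.ones(scores.shape[1]),
            variance_explained=np.ones(scores.shape[1]) / scores.shape[1],
            subset_cpgs=[], n_selected=scores.shape[1],
        )
        return res

    def test_covariate_equal_to_pc_flagged(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame({"PC1": rng.normal(size=30)},
                              index=[f"s{i}" for i in range(30)])
        sheet = pd.DataFrame({"x": scores["PC1"]}, index=scores.index)
        res = screen_covariates(self._pca_with_scores(scores), sheet, ["x"], [])
        assert res.flagged == ["x"]
        assert res.tests["statistic"].iloc[0] == pytest.approx(1.0)

    def test_anova_matches_closed_form(self):
        """Groups (1,2,3) and (2,3,4): one-way ANOVA F = 1.5 on (1,4) df."""
        scores = pd.DataFrame({"PC1": [1.0, 2, 3, 2, 3, 4]},
                              index=[f"s{i}" for i in range(6)])
        sheet = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=scores.index)
        res = screen_covariates(self._pca_with_scores(scores), sheet, [], ["g"])
        row = res.tests.iloc[0]
        assert row["statistic"] == pytest.approx(1.5, abs=1e-12)
        assert row["p"] == pytest.approx(stats.f.sf(1.5, 1, 4), abs=1e-12)

    def test_null_flag_rate(self):
        """Independent covariate, k retained PCs: flag probability across
        1000 replicates close to 1-(1-alpha)^k."""
        rng = np.random.default_rng(5)
        n, k, alpha = 200, 3, 0.01
        flags = 0
        reps = 1000
        scores = pd.DataFrame(
            rng.normal(size=(n, k)), columns=[f"PC{i+1}" for i in range(k)],
            index=[f"s{i}" for i in range(n)],
        )
        res = self._pca_with_scores(scores)
        for _ in range(reps):
            sheet = pd.DataFrame({"x": rng.normal(size=n)}, index=scores.index)
            out = screen_covariates(res, sheet, ["x"], [], alpha=alpha)
            flags += bool(out.flagged)
        expected = 1 - (1 - alpha) ** k
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(flags / reps - expected) < 4 * se + 0.005

    def test_single_level_categorical_skipped(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame({"PC1": rng.normal(size=10)},
                              index=[f"s{i}" for i in range(10)])
        sheet = pd.DataFrame({"g": ["a"] * 10}, index=scores.index)
        with pytest.warns(UserWarning, match="single level"):
            res = screen_covariates(self._pca_with_scores(scores), sheet, [], ["g"])
        assert res.flagged == []


class TestResidualize:
    def test_empty_design_identity(self):
        rng = np.random.default_rng(0)
        mat = _matrix(rng.uniform(0.2, 0.8, size=(20, 10)), adjusted=False)
        out = residualize(mat, None)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_batch_shift_removed_to_grand_mean(self):
        """beta = 0.5 + 0.1*batch2, equal batches: adjusted values all 0.55."""
        vals = np.concatenate([np.full((3, 4), 0.5), np.full((3, 4), 0.6)], axis=1)
        mat = _matrix(vals, adjusted=False)
        design = pd.DataFrame({"batch": ["b1"] * 4 + ["b2"] * 4},
                              index=mat.sample_ids)
        out = residualize(mat, design)
        assert np.allclose(out.values.to_numpy(), 0.55, atol=1e-12)

    def test_numeric_covariate_orthogonal_after(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        vals = 0.5 + 0.05 * x[None, :] + rng.normal(0, 0.01, size=(30, 40))
        mat = _matrix(vals)
        design = pd.DataFrame({"x": x}, index=mat.sample_ids)
        out = residualize(mat, design)
        resid = out.values.to_numpy()
        corr = (resid - resid.mean(axis=1, keepdims=True)) @ (x - x.mean())
        assert np.allclose(corr, 0, atol=1e-10)

    def test_projection_idempotent(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.1, 0.9, size=(25, 30))
        mat = _matrix(vals)
        design = pd.DataFrame(
            {"x": rng.normal(size=30), "g": rng.choice(["a", "b", "c"], 30)},
            index=mat.sample_ids,
        )
        once = residualize(mat, design)
        twice = residualize(once, design)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_rank_deficient_lists_aliased(self):
        rng = np.random.default_rng(3)
        mat = _matrix(rng.uniform(size=(10, 8)))
        g = ["a"] * 4 + ["b"] * 4
        design = pd.DataFrame({"g1": g, "g2": g}, index=mat.sample_ids)
        with pytest.raises(ValueError, match="aliased"):
            residualize(mat, design)


class TestCombineDebatch:
    def test_batch_mean_difference_removed(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.3, 0.7, size=(50, 20))
        b1 = _matrix(base[:, :10], adjusted=False)
        b2_vals = np.clip(base[:, 10:] + 0.05, 0, 1)
        b2 = pd.DataFrame(b2_vals, index=b1.cpg_ids, columns=[f"t{j}" for j in range(10)])
        out = combine_and_debatch(b1, BetaMatrix(b2))
        arr = out.values.to_numpy()
        diff = arr[:, :10].mean(axis=1) - arr[:, 10:].mean(axis=1)
        assert np.allclose(diff, 0, atol=1e-10)
        assert out.shape[1] == 20

    def test_probe_mismatch_errors(self):
        a = _matrix(np.full((5, 3), 0.5))
        b = BetaMatrix(pd.DataFrame(0.5, index=[f"x{i}" for i in range(5)],
                                    columns=["t0", "t1"]))
        with pytest.raises(ValueError, match="probe"):
            combine_and_debatch(a, b)

    def test_empty_batch_errors(self):
        a = _matrix(np.full((5, 3), 0.5))
        empty = BetaMatrix(pd.DataFrame(index=a.cpg_ids, columns=[], dtype=float))
        with pytest.raises(ValueError, match="empty"):
            combine_and_debatch(a, empty)


class TestDirectPCAdjust:
    def test_orthogonal_to_removed_pcs(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.2, 0.8, size=(100, 30))
        mat = _matrix(vals)
        res = pca(mat)
        out = direct_pc_adjust(mat, k=3)
        arr = out.values.to_numpy()
        for pc in range(3):
            v = res.scores.iloc[:, pc].to_numpy()
            proj = (arr - arr.mean(axis=1, keepdims=True)) @ (v - v.mean())
            assert np.allclose(proj, 0, atol=1e-8)

    def test_k_nonpositive_errors(self):
        mat = _matrix(np.random.default_rng(0).uniform(size=(10, 6)))
        with pytest.raises(ValueError, match="positive"):
            direct_pc_adjust(mat, k=0)

    def test_shared_confounder_suppressed(self):
        """A shared per-individual factor inflates cross-tissue correlation at
        null CpGs; removing the leading PCs deflates the excess."""
        from methpair.correlation import spearman_map

        rng = np.random.default_rng(6)
        n, m = 80, 400
        conf = rng.normal(size=n)
        load = rng.normal(0, 0.8, size=m)
        def tissue():
            return 1 / (1 + np.exp(-(load[:, None] * conf[None, :]
                                     + rng.normal(0, 0.5, size=(m, n)))))
        A = _matrix(tissue(), adjusted=False)
        B = _matrix(tissue(), adjusted=False)
        raw = spearman_map(A, B)
        adjA = direct_pc_adjust(A, k=3)
        adjB = direct_pc_adjust(B, k=3)
        adj = spearman_map(adjA, adjB)
        fp_raw = (raw["q"] < 0.05).sum()
        fp_adj = (adj["q"] < 0.05).sum()
        assert fp_adj < fp_raw
        assert fp_adj <= m * 0.02
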