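"""Spearman map, BH adjustment and summary arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpair.containers import BetaMatrix
from methpair.correlation import (
    CrossTissueSpearman,
    bh_fdr,
    per_batch_crosscheck,
    round_half_up,
    spearman_map,
    summarize,
)


def _mat(values, ids=None):
    values = np.asarray(values, dtype=float)
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=ids or [f"cg{i:05d}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        adjusted=True,
    )


class TestSpearmanMap:
    def test_perfect_monotone(self):
        rec = spearman_map(_mat([[1, 2, 3, 4, 5]]), _mat([[2, 4, 6, 8, 10]]))
        assert rec["rho"].iloc[0] == pytest.approx(1.0)
        assert rec["p"].iloc[0] == 0.0

    def test_perfect_antimonotone(self):
        rec = spearman_map(_mat([[1, 2, 3, 4]]), _mat([[4, 3, 2, 1]]))
        assert rec["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_scipy_rowwise(self):
        """20 x 10 seeded matrix vs per-row scipy.spearmanr (rho to 1e-12; p
        identical because scipy uses the same t approximation)."""
        rng = np.random.default_rng(0)
        X, Y = rng.random((20, 10)), rng.random((20, 10))
        rec = spearman_map(_mat(X), _mat(Y))
        for j in range(20):
            rho, p = stats.spearmanr(X[j], Y[j])
            assert rec["rho"].iloc[j] == pytest.approx(rho, abs=1e-12)
            assert rec["p"].iloc[j] == pytest.approx(p, abs=1e-12)

    def test_matches_naive_rank_oracle(self):
        """Double-loop oracle: average ranks by hand, Pearson on ranks."""
        rng = np.random.default_rng(1)
        X = rng.integers(0, 5, size=(20, 10)).astype(float)  # plenty of ties
        Y = rng.integers(0, 5, size=(20, 10)).astype(float)
        rec = spearman_map(_mat(X / 4), _mat(Y / 4))
        for j in range(20):
            rx = stats.rankdata(X[j])
            ry = stats.rankdata(Y[j])
            if np.std(rx) == 0 or np.std(ry) == 0:
                assert np.isnan(rec["rho"].iloc[j])
                continue
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rec["rho"].iloc[j] == pytest.approx(oracle, abs=1e-12)

    def test_permutation_oracle_with_ties(self):
        """n = 7 with one tie: rho exact vs the full 5040-permutation null;
        the t-approximation p within 0.05 of the exact permutation p."""
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        y = np.array([0.15, 0.15, 0.35, 0.30, 0.55, 0.50, 0.70])
        rec = spearman_map(_mat(x[None, :]), _mat(y[None, :]))
        rho_obs = rec["rho"].iloc[0]
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert rho_obs == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        null = []
        for perm in itertools.permutations(range(7)):
            null.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
        null = np.abs(np.array(null))
        p_exact = (null >= abs(rho_obs) - 1e-12).mean()
        assert rec["p"].iloc[0] == pytest.approx(p_exact, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        X, Y = rng.random((15, 12)), rng.random((15, 12))
        base = spearman_map(_mat(X), _mat(Y))
        warped = spearman_map(_mat(np.exp(X) / 3), _mat(Y**3))
        assert np.allclose(base["rho"], warped["rho"], atol=1e-12)

    def test_missing_entries_pairwise(self):
        rng = np.random.default_rng(3)
        X, Y = rng.random((5, 10)), rng.random((5, 10))
        Xm = X.copy()
        Xm[0, :3] = np.nan
        rec = spearman_map(_mat(Xm), _mat(Y))
        assert rec["n"].iloc[0] == 7
        rho_direct, _ = stats.spearmanr(X[0, 3:], Y[0, 3:])
        assert rec["rho"].iloc[0] == pytest.approx(rho_direct, abs=1e-12)

    def test_too_few_pairs_excluded_from_fdr(self):
        X = np.full((2, 6), np.nan)
        X[0] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        X[1, :3] = [0.1, 0.2, 0.3]
        Y = np.random.default_rng(4).random((2, 6))
        rec = spearman_map(_mat(np.clip(X, 0, 1)), _mat(Y))
        assert np.isnan(rec["p"].iloc[1])
        assert np.isnan(rec["q"].iloc[1])
        assert np.isfinite(rec["q"].iloc[0])

    def test_probe_mismatch_errors(self):
        with pytest.raises(ValueError, match="probe"):
            spearman_map(_mat(np.zeros((2, 5))), _mat(np.zeros((2, 5)), ids=["a", "b"]))


class TestBHFDR:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        """p = (0.01..0.05): every q equals 0.05 by the step-up minimum."""
        q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.random(100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _records(n, n_sig, n_pos, rho_high=0):
    """Synthetic record frame with the requested significance structure."""
    rho = np.full(n, 0.01)
    q = np.full(n, 0.5)
    q[:n_sig] = 0.01
    rho[:n_pos] = 0.4
    rho[n_pos:n_sig] = -0.4
    rho[:rho_high] = 0.6
    p = q / 10
    return pd.DataFrame(
        {"rho": rho, "p": p, "q": q, "n": 120,
         "significant": q < 0.05},
        index=[f"cg{i:07d}" for i in range(n)],
    )


class TestSummarize:
    def test_published_positive_share(self):
        """24,636 positive of 24,980 significant = 98.62%, printing as 99%."""
        rec = _records(730_157, 24_980, 24_636)
        s = summarize(rec)
        assert s.n_significant == 24_980
        assert s.pct_positive == pytest.approx(98.62, abs=0.005)
        assert s.pct_positive_rounded == 99
        assert s.pct_negative_rounded == 1
        assert s.pct_significant_rounded == 3

    def test_all_negative(self):
        s = summarize(_records(100, 10, 0))
        assert s.pct_positive == 0.0 and s.n_negative == 10

    def test_abs_rho_threshold(self):
        rec = pd.DataFrame(
            {"rho": [0.6, -0.6, 0.3], "p": [1e-4] * 3, "q": [1e-3] * 3,
             "n": 120, "significant": [True] * 3},
            index=["a", "b", "c"],
        )
        assert summarize(rec).n_abs_rho_above_threshold == 2

    def test_zero_significant_undefined(self):
        rec = _records(50, 0, 0)
        s = summarize(rec)
        assert s.pct_positive is None and s.pct_negative is None


class TestRounding:
    @pytest.mark.parametrize(
        "x,digits,expected",
        [(98.62, 0, 99), (10.455, 2, 10.46), (0.5, 0, 1), (2.5, 0, 3),
         (23.69, 0, 24), (83.72, 0, 84), (89.54, 0, 90)],
    )
    def test_half_up(self, x, digits, expected):
        assert round_half_up(x, digits) == expected


class TestCrosscheck:
    def test_identical_batches_full_replication(self):
        rec = _records(100, 20, 20)
        out = per_batch_crosscheck(rec, rec, rec)
        assert out["frac_both"] == 1.0

    def test_disjoint(self):
        rec = _records(100, 20, 20)
        null = rec.copy()
        null["p"] = 0.9
        out = per_batch_crosscheck(rec, null, null)
        assert out["frac_both"] == 0.0

    def test_split_batches_replicate_planted_signal(self):
        """Planted rho = 0.6, two batches of 50: both-batch replication of
        combined hits at p < 0.05 should be high (Fisher-z power ~0.99)."""
        rng = np.random.default_rng(7)
        n, m = 100, 300
        m_sig = 100
        u = rng.normal(size=(m_sig, n))
        r = 0.612  # latent Pearson for Spearman ~0.6
        lam = np.sqrt(r / (1 - r))
        X = np.vstack([lam * u + rng.normal(size=(m_sig, n)),
                       rng.normal(size=(m - m_sig, n))])
        Y = np.vstack([lam * u + rng.normal(size=(m_sig, n)),
                       rng.normal(size=(m - m_sig, n))])
        Xb, Yb = 1 / (1 + np.exp(-X)), 1 / (1 + np.exp(-Y))
        rec_all = spearman_map(_mat(Xb), _mat(Yb))
        rec_b1 = spearman_map(_mat(Xb[:, :50]), _mat(Yb[:, :50]))
        rec_b2 = spearman_map(_mat(Xb[:, 50:]), _mat(Yb[:, 50:]))
        out = per_batch_crosscheck(rec_all, rec_b1, rec_b2)
        assert out["n_significant_combined"] >= 90
        assert out["frac_both"] >= 0.8


class TestModelObject:
    def test_fit_returns_results_with_summary(self, small_dataset):
        from conftest import combined_tissue_matrices

        mats = combined_tissue_matrices(small_dataset)
        res = CrossTissueSpearman(mats["brain"], mats["buccal"]).fit()
        text = res.summary()
        assert "significant" in text
        assert len(res.records) == len(mats["brain"].cpg_ids)

    def test_pairing_respected_not_column_order(self, small_dataset):
        from conftest import combined_tissue_matrices

        mats = combined_tissue_matrices(small_dataset)
        shuffled = mats["buccal"].values.sample(frac=1, axis=1, random_state=0)
        bu = BetaMatrix(shuffled, annotation=mats["buccal"].annotation,
                        sheet=small_dataset.sheet.loc[shuffled.columns])
        res_shuf = CrossTissueSpearman(mats["brain"], bu).fit()
        res_base = CrossTissueSpearman(mats["brain"], mats["buccal"]).fit()
        assert np.allclose(res_shuf.records["rho"], res_base.records["rho"],
                           atol=1e-12, equal_nan=True)
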