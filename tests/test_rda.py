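"""RDA machinery: brute-force and vegan oracles, selection, partitioning,
Mahalanobis flagging."""

from __future__ import annotations

import subprocess

import numpy as np
import pandas as pd
import pytest

from haplopop import (
    GenotypeMatrix,
    MicrohapLocus,
    code_alleles,
    env_pca,
    forward_select,
    mahalanobis_flags,
    rda_fit,
    spatial_design,
    varpart,
    varpart_fractions,
)
from haplopop.model import EnvTable


class TestCoding:
    def _geno(self):
        loci = [MicrohapLocus("L0", "c", 2, ("AA", "AT", "TT"))]
        calls = np.array([[[0, 0], [0, 1], [2, 2], [-1, -1]]])
        return GenotypeMatrix(["a", "b", "c", "d"], loci, calls)

    def test_homozygote_dosage(self):
        Y = code_alleles(self._geno())
        raw = Y.matrix + Y.column_means
        assert raw[0].tolist() == pytest.approx([2, 0, 0])  # hom for allele 0
        assert raw[1].tolist() == pytest.approx([1, 1, 0])

    def test_columns_centered_and_imputed(self):
        Y = code_alleles(self._geno())
        assert np.allclose(Y.matrix.mean(axis=0), 0, atol=1e-12)
        raw = Y.matrix + Y.column_means
        # missing individual receives the observed column means
        assert raw[3] == pytest.approx(raw[:3].mean(axis=0))

    def test_observed_rows_sum_to_two(self):
        Y = code_alleles(self._geno())
        raw = Y.matrix + Y.column_means
        assert np.allclose(raw[:3].sum(axis=1), 2.0)


class TestEnvPca:
    def test_rank_bound_two_estuaries(self):
        env = EnvTable(pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)),
                                    index=["e1", "e2"]))
        res = env_pca(env)
        assert res.scores.shape[1] == 1

    def test_zero_variance_dropped(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 3)),
                          index=list("abcde"), columns=["v1", "v2", "v3"])
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = env_pca(EnvTable(df))
        assert "flat" in res.dropped_variables

    def test_percent_variance_sums_to_100(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(6, 8)))
        df.index = [f"e{i}" for i in range(6)]
        res = env_pca(EnvTable(df))
        assert res.percent_variance.sum() == pytest.approx(100.0)


class TestSpatialDesign:
    def test_degree_one_single_centered_column(self):
        x = [0.0, 0.0, 100.0, 100.0]
        cols = spatial_design(x, degree=1, jitter_sd_km=0.0)
        assert cols.shape == (4, 1)
        assert cols.mean() == pytest.approx(0.0, abs=1e-12)

    def test_columns_orthogonal(self):
        rng = np.random.default_rng(3)
        x = np.repeat([0, 100, 250, 400, 600], 8)
        cols = spatial_design(x, degree=3, jitter_sd_km=2.0, rng=rng)
        gram = cols.T @ cols
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            spatial_design([5.0, 5.0, 5.0], degree=2, jitter_sd_km=0.0)

    def test_jitter_barely_moves_r2(self):
        rng = np.random.default_rng(4)
        est = np.repeat(np.arange(5) * 100.0, 12)
        Y = rng.normal(size=(60, 30)) + np.repeat(rng.normal(size=(5, 30)),
                                                  12, axis=0) * 0.5
        r2 = []
        for sd in (0.0, 1.0):
            X = spatial_design(est, degree=3, jitter_sd_km=sd,
                               rng=np.random.default_rng(5))
            r2.append(rda_fit(Y, X, n_perm=0).R2)
        assert abs(r2[1] - r2[0]) / r2[0] < 0.01


class TestFit:
    def test_brute_force_oracle(self):
        # 5 individuals x 4 response columns x 1 constraint
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(5, 4))
        X = rng.normal(size=(5, 1))
        m = rda_fit(Y, X, n_perm=0)
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        Yhat = Xc @ B
        eig = np.linalg.eigvalsh(Yhat.T @ Yhat / 4)[::-1]
        eig = eig[eig > 1e-12]
        assert m.eigenvalues == pytest.approx(eig, abs=1e-10)
        assert m.R2 == pytest.approx((Yhat**2).sum() / (Yc**2).sum(), abs=1e-12)
        # site scores: fitted values projected on the canonical axis
        u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
        assert np.abs(m.site_scores[:, 0]) == pytest.approx(
            np.abs(u[:, 0] * s[0]), abs=1e-10)

    def test_saturated_model_r2_one(self):
        rng = np.random.default_rng(7)
        n = 8
        Y = rng.normal(size=(n, 5))
        X = np.eye(n)[:, : n - 1]  # n-1 indicator contrasts
        m = rda_fit(Y, X, n_perm=0)
        assert m.R2 == pytest.approx(1.0, abs=1e-10)

    def test_noise_constraint_mean_r2(self):
        # E[R2] = m/(n-1) for a random independent constraint
        rng = np.random.default_rng(8)
        n, m_cols = 20, 2
        vals = []
        for _ in range(300):
            Y = rng.normal(size=(n, 6))
            X = rng.normal(size=(n, m_cols))
            vals.append(rda_fit(Y, X, n_perm=0).R2)
        assert np.mean(vals) == pytest.approx(m_cols / (n - 1), abs=0.01)

    def test_adjusted_r2_formula_random_shapes(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(10, 30))
            q = int(rng.integers(2, 6))
            m_cols = int(rng.integers(1, 4))
            Y = rng.normal(size=(n, q))
            X = rng.normal(size=(n, m_cols))
            fit = rda_fit(Y, X, n_perm=0)
            expected = 1 - (1 - fit.R2) * (n - 1) / (n - m_cols - 1)
            assert fit.adjR2 == pytest.approx(expected, abs=1e-12)

    def test_unconstrained_limit_reproduces_pca(self):
        rng = np.random.default_rng(10)
        n = 9
        Y = rng.normal(size=(n, 5))
        X = np.eye(n)[:, : n - 1]
        m = rda_fit(Y, X, n_perm=0)
        Yc = Y - Y.mean(axis=0)
        pca_eig = np.linalg.eigvalsh(Yc.T @ Yc / (n - 1))[::-1]
        assert m.eigenvalues == pytest.approx(pca_eig[: len(m.eigenvalues)],
                                              abs=1e-10)

    def test_matches_vegan(self, tmp_path):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(12, 6))
        X = rng.normal(size=(12, 3))
        m = rda_fit(Y, X, n_perm=0)
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = (
            f'library(vegan);'
            f'Y<-as.matrix(read.csv("{tmp_path}/Y.csv",header=FALSE));'
            f'X<-as.data.frame(read.csv("{tmp_path}/X.csv",header=FALSE));'
            f'm<-rda(Y~.,data=X);'
            f'cat(RsquareAdj(m)$r.squared,RsquareAdj(m)$adj.r.squared,m$CCA$eig,sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        assert m.R2 == pytest.approx(vals[0], abs=1e-7)
        assert m.adjR2 == pytest.approx(vals[1], abs=1e-7)
        assert m.eigenvalues == pytest.approx(vals[2:], abs=1e-7)


class TestForwardSelect:
    def test_strong_single_candidate_selected(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        Y = np.outer(x, rng.normal(size=5)) + 0.1 * rng.normal(size=(40, 5))
        sel, trace = forward_select(Y, pd.DataFrame({"x": x}), n_perm=99,
                                    rng=rng)
        assert sel == ["x"]

    def test_noise_candidates_mostly_rejected(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(30, 8))
        cands = pd.DataFrame(rng.normal(size=(30, 5)),
                             columns=[f"c{i}" for i in range(5)])
        sel, _ = forward_select(Y, cands, alpha=0.05, n_perm=199, rng=rng)
        assert len(sel) <= 1

    def test_signal_axis_found_among_distractors(self, gulf_scenario):
        ds, truth = gulf_scenario
        rng = np.random.default_rng(14)
        Y = code_alleles(ds.genotypes)
        pca = env_pca(ds.env)
        scores = pca.scores.loc[ds.estuary_of()].reset_index(drop=True)
        sel, _ = forward_select(Y, scores.iloc[:, :6], n_perm=99, rng=rng)
        assert len(sel) >= 1  # environmental signal is detected


class TestVarpart:
    def test_published_marginals_reproduce_shared_fraction(self):
        # printed marginal adjusted R2 values are internally consistent
        fr = varpart_fractions(ab=0.00026, bc=0.00014, abc=0.00024)
        assert fr["shared"] == pytest.approx(0.00016, abs=1e-12)
        assert fr["env_unique"] == pytest.approx(0.00010, abs=1e-12)
        assert fr["xy_unique"] == pytest.approx(-0.00002, abs=1e-12)
        assert fr["residual"] == pytest.approx(0.99976, abs=1e-12)

    def test_identities_hold_on_random_data(self):
        rng = np.random.default_rng(15)
        Y = rng.normal(size=(25, 6))
        A = rng.normal(size=(25, 2))
        B = rng.normal(size=(25, 2))
        res = varpart(Y, A, B, n_perm=0, rng=rng)
        assert res.env_unique == pytest.approx(res.adjR2_full - res.adjR2_xy_total,
                                               abs=1e-12)
        assert res.xy_unique == pytest.approx(res.adjR2_full - res.adjR2_env_total,
                                              abs=1e-12)
        assert res.shared == pytest.approx(
            res.adjR2_env_total + res.adjR2_xy_total - res.adjR2_full, abs=1e-12)
        assert res.residual == pytest.approx(1 - res.adjR2_full, abs=1e-12)

    def test_duplicated_predictors_share_everything(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(20, 2))
        Y = X @ rng.normal(size=(2, 5)) + 0.5 * rng.normal(size=(20, 5))
        res = varpart(Y, X, X.copy(), n_perm=0, rng=rng)
        assert abs(res.env_unique) < 1e-10
        assert abs(res.xy_unique) < 1e-10
        assert res.shared == pytest.approx(res.adjR2_full, abs=1e-10)

    def test_orthogonal_predictors_share_nothing(self):
        rng = np.random.default_rng(17)
        n = 40
        A = np.zeros((n, 1)); A[: n // 2] = 1.0
        B = np.tile([1.0, -1.0], n // 2)[:, None]
        Y = A @ rng.normal(size=(1, 6)) + B @ rng.normal(size=(1, 6)) \
            + 0.3 * rng.normal(size=(n, 6))
        res = varpart(Y, A, B, n_perm=0, rng=rng)
        assert abs(res.shared) < 0.04


class TestMahalanobis:
    def _model_with_loadings(self, pts):
        from haplopop.rda import RdaModel
        return RdaModel(n=10, m=2, p_cond=0, eigenvalues=np.ones(2),
                        R2=0.1, adjR2=0.1,
                        axis_percent_constrained=np.array([50.0, 50.0]),
                        site_scores=np.zeros((10, 2)), allele_loadings=pts,
                        pseudo_F=1.0, p_perm=1.0,
                        columns=[(f"L{i}", 0) for i in range(len(pts))])

    def test_gaussian_cloud_flag_rate_matches_chi2_tail(self):
        # P(chi2_2 > 25) = exp(-12.5) ~ 3.7e-6: expect ~0 flags in 1e5 points
        rng = np.random.default_rng(18)
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.5], [0.5, 1.0]], size=100_000)
        res = mahalanobis_flags(self._model_with_loadings(pts), threshold=25)
        assert res.table["flagged"].sum() <= 3
        # at a chi2 threshold with sizeable tail the empirical rate matches
        import scipy.stats as ss
        thr = ss.chi2.ppf(0.99, df=2)
        rate = (res.table["mahalanobis_D2"] > thr).mean()
        assert rate == pytest.approx(0.01, abs=0.002)

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(19)
        pts = rng.normal(size=(500, 2))
        pts[0] = [10.0, 10.0]
        res = mahalanobis_flags(self._model_with_loadings(pts), threshold=25)
        assert "L0" in res.flagged_loci

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_flags(self._model_with_loadings(np.zeros((2, 2))))
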