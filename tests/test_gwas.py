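import numpy as np
import pandas as pd
import pytest

from ssblup.gwas import (
    GwasResult,
    VarianceComponents,
    _reml_neg_loglik,
    compute_lr,
    compute_pp,
    emmax_scan,
    estimate_vc_reml,
    smooth_lr,
)
from conftest import make_genotypes


def _polygenic_K(n, m, seed):
    M, _ = make_genotypes(n, m, seed=seed)
    Z = M - M.mean(axis=0)
    K = Z @ Z.T / m
    return K / np.mean(np.diag(K))


class TestReml:
    def test_optimum_beats_h2_grid(self, rng):
        n = 150
        K = _polygenic_K(n, 300, seed=0)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = L @ rng.normal(size=n) * np.sqrt(0.4) + rng.normal(size=n) * np.sqrt(0.6)
        X = np.ones((n, 1))
        vc = estimate_vc_reml(y, X, K)
        S, U = np.linalg.eigh(K)
        S = np.clip(S, 0, None)
        yt, Xt = U.T @ y, U.T @ X
        opt = _reml_neg_loglik(np.log(vc.ratio), S, Xt, yt, n, 1)
        for h2 in np.arange(0.01, 1.0, 0.07):
            assert opt <= _reml_neg_loglik(np.log(h2 / (1 - h2)), S, Xt, yt, n, 1) + 1e-6

    def test_total_variance_recovered_with_identity_K(self):
        """With K = I the split is unidentifiable but sigma_u2 + sigma_e2
        must recover the total variance."""
        rng = np.random.default_rng(3)
        n = 500
        y = rng.normal(0, np.sqrt(2.0), size=n)
        vc = estimate_vc_reml(y, np.ones((n, 1)), np.eye(n))
        assert vc.sigma_u2 + vc.sigma_e2 == pytest.approx(2.0, rel=0.15)

    def test_null_heritability_small(self):
        """Pure-noise phenotypes on a block-diagonal kinship: h2 near 0."""
        hits = 0
        n = 300
        K = np.kron(np.eye(30), np.full((10, 10), 0.5) + 0.5 * np.eye(10))
        for r in range(10):
            y = np.random.default_rng(100 + r).normal(size=n)
            vc = estimate_vc_reml(y, np.ones((n, 1)), K)
            hits += vc.h2 < 0.05
        assert hits >= 9

    def test_non_psd_K_rejected(self, rng):
        K = -np.eye(20)
        with pytest.raises(ValueError, match="PSD"):
            estimate_vc_reml(rng.normal(size=20), np.ones((20, 1)), K)


class TestEmmaxScan:
    def test_matches_dense_gls_oracle(self, rng):
        n, m = 200, 500
        M, _ = make_genotypes(n, m, seed=2)
        K = _polygenic_K(n, 400, seed=3)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        vc = VarianceComponents(0.35, 0.65)
        res = emmax_scan(y, X, M, vc, K)
        V = vc.sigma_u2 * K + vc.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        idx = np.arange(0, m, 25)  # spot-check a grid of markers densely
        for j in idx:
            A = np.column_stack([X, M[:, j]])
            C = np.linalg.inv(A.T @ Vi @ A)
            th = C @ A.T @ Vi @ y
            assert res.table["beta"][j] == pytest.approx(th[-1], abs=1e-8)
            assert res.table["se"][j] == pytest.approx(np.sqrt(C[-1, -1]), abs=1e-8)

    def test_sigma_u_zero_reduces_to_ols(self, rng):
        n, m = 80, 40
        M, _ = make_genotypes(n, m, seed=4)
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        vc = VarianceComponents(1e-12, 1.0)
        res = emmax_scan(y, X, M, vc, np.eye(n))
        Mc = M - M.mean(axis=0)
        yc = y - y.mean()
        beta_ols = (Mc.T @ yc) / np.einsum("ij,ij->j", Mc, Mc)
        assert np.allclose(res.table["beta"], beta_ols, atol=1e-6)

    def test_collinear_marker_flagged(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        M = np.column_stack([X[:, 1], rng.integers(0, 3, n).astype(float)])
        res = emmax_scan(rng.normal(size=n), X, M, VarianceComponents(0.5, 0.5), np.eye(n))
        assert not res.table["tested"][0]
        assert res.table["pvalue"][0] == 1.0
        assert res.table["tested"][1]

    def test_type_I_error_calibrated(self):
        """Null markers on a polygenic background: empirical alpha at 0.05
        within [0.03, 0.07] over >= 2000 tests."""
        rng = np.random.default_rng(5)
        n, m = 300, 2500
        M, _ = make_genotypes(n, m, seed=6)
        K = _polygenic_K(n, 2000, seed=7)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = L @ rng.normal(size=n) * np.sqrt(0.3) + rng.normal(size=n) * np.sqrt(0.7)
        vc = estimate_vc_reml(y, np.ones((n, 1)), K)
        res = emmax_scan(y, np.ones((n, 1)), M, vc, K)
        alpha = (res.table["pvalue"][res.table["tested"]] < 0.05).mean()
        assert 0.03 <= alpha <= 0.07


class TestLrSmoothPp:
    def _result(self, lr, chrom=None):
        m = len(lr)
        tab = pd.DataFrame(
            {
                "marker": [f"m{j}" for j in range(m)],
                "chrom": chrom if chrom is not None else np.ones(m, int),
                "pos": np.tile(np.arange(m, dtype=float), 1),
                "tested": True,
                "t": np.sqrt(2 * np.asarray(lr, float)),
            }
        )
        if chrom is not None:  # positions restart per chromosome
            pos = np.concatenate([np.arange((np.asarray(chrom) == c).sum(), dtype=float)
                                  for c in pd.unique(pd.Series(chrom))])
            tab["pos"] = pos
        res = GwasResult(tab, VarianceComponents(0.5, 0.5))
        return compute_lr(res)

    @pytest.mark.parametrize("t,expect", [(0.0, 0.0), (2.0, 2.0), (3.1, 4.805)])
    def test_lr_from_t(self, t, expect):
        tab = pd.DataFrame(
            {"marker": ["m0"], "chrom": [1], "pos": [0.0], "tested": [True], "t": [t]}
        )
        res = compute_lr(GwasResult(tab, VarianceComponents(0.5, 0.5)))
        assert res.table["lr"][0] == pytest.approx(expect)

    def test_smooth_constant_unchanged(self):
        res = smooth_lr(self._result(np.full(50, 3.0)))
        assert np.allclose(res.table["lr_smooth"], 3.0)

    def test_smooth_interior_spike(self):
        lr = np.zeros(41)
        lr[20] = 21.0
        res = smooth_lr(self._result(lr))
        assert res.table["lr_smooth"][20] == pytest.approx(1.0)

    def test_smooth_truncated_at_chromosome_start(self):
        lr = np.zeros(30)
        lr[0] = 11.0
        res = smooth_lr(self._result(lr))
        assert res.table["lr_smooth"][0] == pytest.approx(1.0)  # 11 values in window

    def test_smooth_does_not_cross_chromosomes(self):
        lr = np.concatenate([np.zeros(15), [21.0], np.zeros(16)])
        chrom = np.repeat([1, 2], 16)  # spike is the last marker of chrom 1
        res = smooth_lr(self._result(lr, chrom=chrom))
        assert (res.table["lr_smooth"][chrom == 2] == 0).all()

    def test_smooth_requires_sorted_map(self):
        res = self._result(np.zeros(5))
        res.table.loc[0, "pos"] = 99.0
        with pytest.raises(ValueError, match="sorted"):
            smooth_lr(res)

    @pytest.mark.parametrize(
        "lr,expect", [(0.0, 0.001), (np.log(999), 0.5)]
    )
    def test_pp_closed_forms(self, lr, expect):
        res = smooth_lr(self._result([lr]))
        res = compute_pp(res, prior=0.001)
        assert res.table["pp"][0] == pytest.approx(expect, abs=1e-9)

    def test_pp_monotone_and_bounded(self):
        lr = np.linspace(0, 25, 200)
        res = smooth_lr(self._result(lr))
        # bypass smoothing effect for monotonicity: use lr directly
        res.table["lr_smooth"] = lr
        pp = compute_pp(res, prior=0.001).table["pp"].to_numpy()
        assert np.all(np.diff(pp) > 0)
        assert pp[0] == pytest.approx(0.001) and pp[-1] <= 1.0

    def test_pp_invalid_prior(self):
        res = smooth_lr(self._result([1.0]))
        with pytest.raises(ValueError):
            compute_pp(res, prior=0.0)
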