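import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ssblup.mme import ModelSpec
from ssblup.pqtn import forward_cv_select, full_covariates, impute_pqtn, ld_r2, prune_candidates


def _gwas_table(pvals, chrom=None, pos=None):
    m = len(pvals)
    return pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, int),
            "pos": pos if pos is not None else np.arange(m, dtype=float),
            "pvalue": pvals,
            "tested": True,
        }
    )


class TestPrune:
    def test_perfect_ld_collapses_to_one(self, rng):
        base = rng.binomial(2, 0.5, 50).astype(float)
        codes = np.tile(base[:, None], (1, 20))
        tab = _gwas_table(rng.uniform(size=20))
        kept = prune_candidates(tab, codes, r2_max=0.3, n_candidates=15)
        assert kept == [int(np.argmin(tab["pvalue"]))]

    def test_independent_markers_exhaust_list(self, rng):
        codes = rng.binomial(2, 0.5, size=(500, 10)).astype(float)
        tab = _gwas_table(rng.uniform(size=10))
        kept = prune_candidates(tab, codes, n_candidates=15)
        assert len(kept) == 10

    def test_matches_bruteforce_greedy(self, rng):
        n, m = 80, 40
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        pvals = rng.uniform(size=m)
        tab = _gwas_table(pvals)
        kept = prune_candidates(tab, codes, r2_max=0.2, n_candidates=8)
        # oracle: explicit greedy on the r2 matrix
        order = np.argsort(pvals, kind="stable")
        oracle = []
        for j in order:
            if all(ld_r2(codes[:, j], codes[:, k]) < 0.2 for k in oracle):
                oracle.append(int(j))
                if len(oracle) == 8:
                    break
        assert kept == oracle

    def test_order_invariance_under_shuffle(self, rng):
        n, m = 60, 25
        codes = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        pvals = rng.uniform(size=m)
        tab = _gwas_table(pvals)
        kept = prune_candidates(tab, codes, n_candidates=6)
        perm = rng.permutation(m)
        tab2 = tab.iloc[perm].reset_index(drop=True)
        kept2 = prune_candidates(tab2, codes[:, perm], n_candidates=6)
        assert [tab["marker"][j] for j in kept] == [tab2["marker"][j] for j in kept2]


class TestImpute:
    def test_unrelated_animal_gets_zero(self):
        Pg = np.array([[0.0], [2.0]])
        Ang = np.zeros((1, 2))
        assert np.allclose(impute_pqtn(Pg, Ang, np.eye(2)), 0.0)

    def test_offspring_of_two_genotyped_parents_is_average(self):
        """Ang=[0.5, 0.5], Agg=I: the imputed row is the parental mean."""
        Pg = np.array([[0.0, 2.0], [2.0, 1.0]])
        Ang = np.array([[0.5, 0.5]])
        out = impute_pqtn(Pg, Ang, np.eye(2))
        assert np.allclose(out, [[1.0, 1.5]])

    def test_constant_column_linear_algebra_oracle(self, rng):
        ng, g = 6, 5
        Agg = np.eye(g) + 0.2
        Ang = rng.uniform(0, 0.5, size=(ng, g))
        c = 1.7
        out = impute_pqtn(np.full((g, 1), c), Ang, Agg)
        oracle = c * (Ang @ np.linalg.solve(Agg, np.ones(g)))
        assert np.allclose(out.ravel(), oracle)

    def test_singular_Agg_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            impute_pqtn(np.ones((2, 1)), np.ones((1, 2)), np.zeros((2, 2)))

    def test_full_covariates_layout(self, rng):
        g_index = np.array([1, 3])
        ng_index = np.array([0, 2])
        codes = rng.integers(0, 3, (2, 1)).astype(float)
        P = full_covariates(codes, np.zeros((2, 2)), np.eye(2), g_index, ng_index)
        assert P.shape == (4, 1)
        assert np.allclose(P[g_index], codes)
        assert np.allclose(P[ng_index], 0.0)


def _selection_problem(seed, n=200, n_cand=6, causal_var=0.3, causal_first=True):
    """All-genotyped toy population: candidate 0 optionally explains
    ``causal_var`` of the phenotypic variance, the rest are noise."""
    rng = np.random.default_rng(seed)
    cols = rng.binomial(2, 0.5, size=(n, n_cand)).astype(float)
    cols -= cols.mean(axis=0)
    y = rng.normal(size=n)
    if causal_first:
        c = cols[:, 0]
        y = c * np.sqrt(causal_var / c.var()) + rng.normal(size=n) * np.sqrt(1 - causal_var)
    spec = ModelSpec(
        X=np.ones((n, 1)), record_animal=np.arange(n), n_animals=n,
        hinv=sp.eye(n, format="csr"), sigma_u2=0.2, sigma_e2=0.8,
    )
    return spec, y, cols


class TestForwardCv:
    def test_zero_candidates_returns_empty(self):
        spec, y, cols = _selection_problem(0)
        out = forward_cv_select([], spec, y, cols, seed=0)
        assert out.k == 0
        assert out.full_P().shape == (spec.n_animals, 0)

    def test_large_effect_candidate_accepted_reliably(self):
        """A candidate explaining ~30% of variance must be accepted in
        nearly every replicate."""
        hits = 0
        for r in range(10):
            spec, y, cols = _selection_problem(100 + r)
            out = forward_cv_select(list(range(cols.shape[1])), spec, y, cols, seed=r)
            hits += 0 in out.marker_idx.tolist()
        assert hits >= 9

    def test_noise_candidates_rarely_accepted_on_polygenic_trait(self):
        """15 pure-noise candidates against a genuinely polygenic base
        model: the acceptance threshold keeps the median accepted count low
        (noise covariates dilute an already-predictive model)."""
        counts = []
        n_fam, fam = 80, 8
        n = n_fam * fam
        K = np.kron(np.eye(n_fam), np.full((fam, fam), 0.5) + 0.5 * np.eye(fam))
        hinv = sp.csr_matrix(np.linalg.inv(K))
        for r in range(10):
            rng = np.random.default_rng(300 + r)
            u = np.linalg.cholesky(K) @ rng.normal(size=n) * np.sqrt(0.5)
            y = u + rng.normal(size=n) * np.sqrt(0.5)
            cols = rng.binomial(2, 0.5, size=(n, 15)).astype(float)
            cols -= cols.mean(axis=0)
            spec = ModelSpec(
                X=np.ones((n, 1)), record_animal=np.arange(n), n_animals=n,
                hinv=hinv, sigma_u2=0.5, sigma_e2=0.5,
            )
            out = forward_cv_select(list(range(15)), spec, y, cols, seed=r)
            counts.append(out.k)
        assert np.median(counts) <= 2

    def test_deterministic_given_seed(self):
        spec, y, cols = _selection_problem(7)
        a = forward_cv_select(list(range(6)), spec, y, cols, seed=3)
        b = forward_cv_select(list(range(6)), spec, y, cols, seed=3)
        assert a.marker_idx.tolist() == b.marker_idx.tolist()
        assert [e["accuracy"] for e in a.log] == [e["accuracy"] for e in b.log]

    def test_accepted_accuracy_trace_nondecreasing(self):
        spec, y, cols = _selection_problem(8)
        out = forward_cv_select(list(range(6)), spec, y, cols, seed=1)
        accepted_acc = [e["accuracy"] for e in out.log[1:] if e["accepted"]]
        assert all(np.diff(accepted_acc) >= 0) if len(accepted_acc) > 1 else True

    def test_all_candidates_evaluated_despite_rejections(self):
        spec, y, cols = _selection_problem(9, n_cand=8, causal_first=False)
        out = forward_cv_select(list(range(8)), spec, y, cols, seed=2)
        assert len([e for e in out.log if e["step"] != "base"]) == 8

    def test_too_few_records_errors(self):
        spec, y, cols = _selection_problem(10, n=8)
        with pytest.raises(ValueError, match="too few"):
            forward_cv_select([0], spec, y, cols, folds=5)
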