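"""Henderson's mixed model equations for the single-step animal model.

Model per phenotype record:

    y = X b + P q + W u + e,   u ~ N(0, H sigma_u^2),   e ~ N(0, I sigma_e^2)

b are ordinary fixed effects, q the (fixed) effects of pseudo-QTN marker
covariates, and W maps each record to one animal equation; animals without
records still receive a breeding-value solution through H^-1.  The
3x3-block coefficient matrix is (after cancelling the common 1/sigma_e^2)

    [[X'X, X'P, X'W ],
     [P'X, P'P, P'W ],
     [W'X, W'P, W'W + lambda H^-1]],   lambda = sigma_e^2 / sigma_u^2,

with right-hand side [X'y, P'y, W'y].  Genomic breeding values are
g_i = P_i q + u_i, using imputed P rows for non-genotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hmatrix import HInverse

#: above this many equations the solver switches from a direct sparse
#: factorization to preconditioned conjugate gradients
DIRECT_SOLVE_LIMIT = 20_000


@dataclass
class ModelSpec:
    """Design matrices and variance components for one MME fit.

    ``record_animal`` gives, per phenotype record, the index of the animal
    in the global (pedigree) ordering; ``hinv`` may be an :class:`HInverse`
    block form, a sparse matrix, or a dense array (A^-1 for pedigree BLUP).
    """

    X: np.ndarray  # records x p
    record_animal: np.ndarray  # records,
    n_animals: int
    hinv: object
    sigma_u2: float
    sigma_e2: float
    P: np.ndarray | None = None  # records x q, optional pQTN covariates

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.record_animal = np.asarray(self.record_animal, dtype=int)
        if self.X.shape[0] != self.record_animal.size:
            raise ValueError("X rows must match record count")
        if self.P is not None:
            self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
            if self.P.shape[0] != self.record_animal.size:
                raise ValueError("P rows must match record count")
        if self.sigma_e2 <= 0 or self.sigma_u2 <= 0:
            raise ValueError("variance components must be positive")

    @property
    def n_fixed(self) -> int:
        q = 0 if self.P is None else self.P.shape[1]
        return self.X.shape[1] + q


@dataclass
class MmeSolution:
    b: np.ndarray
    q: np.ndarray
    u: np.ndarray
    gebv: np.ndarray | None = None
    solver: str = "direct"
    residual_norm: float = 0.0
    iterations: int = 0


def _hinv_sparse(hinv, n: int) -> sp.csr_matrix:
    if isinstance(hinv, HInverse):
        H = hinv.to_sparse()
    elif sp.issparse(hinv):
        H = hinv.tocsr()
    else:
        H = sp.csr_matrix(np.asarray(hinv, dtype=float))
    if H.shape != (n, n):
        raise ValueError("H^-1 dimension does not match animal count")
    return H


def _checked_design(spec: ModelSpec, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Validate y and build the full-rank fixed design F = [X P]."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size != spec.record_animal.size:
        raise ValueError("y length must match record count")
    F = spec.X if spec.P is None else np.hstack([spec.X, spec.P])
    nf = F.shape[1]
    if np.linalg.matrix_rank(F) < nf:
        # name offending columns by projecting each on the preceding ones
        bad = []
        for j in range(1, nf):
            r = np.linalg.lstsq(F[:, :j], F[:, j], rcond=None)[1]
            if r.size == 0 or r[0] < 1e-10 * max(1.0, float(F[:, j] @ F[:, j])):
                bad.append(j)
        raise ValueError(f"fixed block [X P] is rank deficient; confounded columns {bad}")
    return y, F


class BlockSolver:
    """Layered exact solver for the single-step MME coefficient matrix

        C = [[F'F, F'W], [W'F, W'W + lam*(A^-1 + E Lambda E')]].

    Factorizing C as one sparse matrix is ruinous: the fixed-effect rows are
    dense and the genomic correction Lambda = G_omega^-1 - Agg^-1 is a dense
    g x g block, so SuperLU fill explodes.  Instead the animal block
    S = W'W + lam*A^-1 (sparse, SPD) is factorized once; the correction is
    applied through the Woodbury identity with one dense factorization of
    the g x g capacity matrix; and the p fixed-effect equations are solved
    by a dense Schur complement over the animal block.
    """

    def __init__(self, F, rec, n_animals, hpart_lam, corr_lam=None, g_index=None,
                 corr_inv_lam=None):
        F = np.atleast_2d(np.asarray(F, dtype=float))
        self.p = F.shape[1]
        self.n = n_animals
        S = (sp.diags(np.bincount(rec, minlength=n_animals).astype(float))
             + hpart_lam).tocsc()
        self.lu = spla.splu(S, permc_spec="MMD_AT_PLUS_A")
        if (corr_lam is not None or corr_inv_lam is not None) and len(g_index):
            self.g = np.asarray(g_index, dtype=int)
            gN = self.g.size
            B = np.zeros((n_animals, gN))
            B[self.g, np.arange(gN)] = 1.0
            Ygg = self.lu.solve(B)[self.g]
            if corr_inv_lam is None:
                corr_inv_lam = sla.lu_solve(
                    sla.lu_factor(corr_lam, check_finite=False), np.eye(gN),
                    check_finite=False)
            self.M = sla.lu_factor(corr_inv_lam + Ygg, check_finite=False)
        else:
            self.g = None
            self.M = None
        # fixed-effect Schur complement over the animal block
        U = np.zeros((n_animals, self.p))
        for j in range(self.p):
            U[:, j] = np.bincount(rec, weights=F[:, j], minlength=n_animals)
        self.U = U
        self.V = self._inner(U)
        self.Sp = sla.lu_factor(F.T @ F - U.T @ self.V, check_finite=False)

    def _inner(self, b):
        """(S + lam E Lambda E')^-1 b on the animal block (vector or matrix)."""
        z = self.lu.solve(b)
        if self.M is None:
            return z
        w = sla.lu_solve(self.M, z[self.g], check_finite=False)
        return z - self._Y(w)

    def _Y(self, w):
        # S^-1 E w via one extra sparse solve (E scatters w to genotyped rows)
        full = np.zeros((self.n,) + w.shape[1:])
        full[self.g] = w
        return self.lu.solve(full)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve C [b; u] = rhs with rhs stacked as [fixed, animal]."""
        rf, ru = rhs[: self.p], rhs[self.p :]
        t = self._inner(ru)
        b = sla.lu_solve(self.Sp, rf - self.U.T @ t, check_finite=False)
        u = t - self.V @ b
        return np.concatenate([b, u])


def assemble_mme(spec: ModelSpec, y: np.ndarray) -> tuple[sp.csc_matrix, np.ndarray]:
    """Assemble the symmetric MME coefficient matrix and right-hand side.

    The fixed block [X P] is checked for rank; a deficient block raises an
    error listing the confounded columns (a pQTN column collinear with X is
    the usual culprit).
    """
    y, F = _checked_design(spec, y)
    lam = spec.sigma_e2 / spec.sigma_u2
    Hs = _hinv_sparse(spec.hinv, spec.n_animals)
    C = _data_blocks(F, spec.record_animal, spec.n_animals, lam * Hs)
    rhs = np.concatenate(
        [F.T @ y, np.bincount(spec.record_animal, weights=y, minlength=spec.n_animals)]
    )
    return C, rhs


def _data_blocks(F: np.ndarray, rec: np.ndarray, n: int, Hpart: sp.spmatrix) -> sp.csc_matrix:
    """[[F'F, F'W], [W'F, W'W + Hpart]] as one sparse matrix."""
    nf = F.shape[1]
    FtW = np.zeros((nf, n))
    for j in range(nf):
        FtW[j] = np.bincount(rec, weights=F[:, j], minlength=n)
    WtW = sp.diags(np.bincount(rec, minlength=n).astype(float))
    return sp.bmat(
        [
            [sp.csr_matrix(F.T @ F), sp.csr_matrix(FtW)],
            [sp.csr_matrix(FtW.T), WtW + Hpart],
        ],
        format="csc",
    )


def solve_mme(
    spec: ModelSpec,
    y: np.ndarray,
    tol_direct: float = 1e-10,
    tol_iter: float = 1e-8,
    P_full: np.ndarray | None = None,
) -> MmeSolution:
    """Solve the assembled MME.

    With a block-form H^-1 (the usual single-step case) the dense genomic
    correction is handled by the Woodbury identity (:class:`BlockSolver`);
    otherwise a direct sparse factorization is used below 20k equations and
    preconditioned conjugate gradients above.  When ``P_full`` (animals x q
    covariates, imputed where needed) is given, per-animal breeding values
    g = P_full q + u are filled in.
    """
    sol = None
    neq_est = spec.n_fixed + spec.n_animals
    if neq_est <= DIRECT_SOLVE_LIMIT:
        yv, F = _checked_design(spec, y)
        lam = spec.sigma_e2 / spec.sigma_u2
        if isinstance(spec.hinv, HInverse):
            hpart = lam * sp.csr_matrix(spec.hinv.ainv)
            corr = lam * spec.hinv.correction
            corr_inv = spec.hinv.correction_inverse() / lam
            g_index = spec.hinv.g_index
        else:
            hpart = lam * _hinv_sparse(spec.hinv, spec.n_animals)
            corr, corr_inv, g_index = None, None, None
        rhs = np.concatenate(
            [F.T @ yv,
             np.bincount(spec.record_animal, weights=yv, minlength=spec.n_animals)]
        )
        try:
            solver_obj = BlockSolver(F, spec.record_animal, spec.n_animals,
                                     hpart, corr, g_index, corr_inv_lam=corr_inv)
            sol = solver_obj.solve(rhs)
            Cx = _data_blocks(F, spec.record_animal, spec.n_animals, hpart) @ sol
            if corr is not None:
                g_eqs = F.shape[1] + g_index
                Cx[g_eqs] += corr @ sol[g_eqs]
            res = float(np.linalg.norm(Cx - rhs) / max(np.linalg.norm(rhs), 1e-30))
            solver, it = "block", 1
        except np.linalg.LinAlgError:
            sol = None  # singular capacity matrix: fall through to direct
    if sol is None:
        C, rhs = assemble_mme(spec, y)
        neq = C.shape[0]
        if neq <= DIRECT_SOLVE_LIMIT:
            lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
            sol = lu.solve(rhs)
            solver, it = "direct", 1
        else:
            ilu = spla.spilu(C.tocsc(), drop_tol=1e-5, fill_factor=10)
            prec = spla.LinearOperator(C.shape, ilu.solve)
            sol, info = spla.cg(C, rhs, rtol=tol_iter, maxiter=5000, M=prec)
            if info != 0:
                raise RuntimeError(f"iterative MME solve did not converge (info={info})")
            solver, it = "pcg", info if info > 0 else 0
        res = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30))
    tol = tol_direct if solver != "pcg" else tol_iter
    if res > max(tol * 1e4, 1e-6):
        raise RuntimeError(f"MME solution residual too large: {res:.3g}")
    p = spec.X.shape[1]
    nq = 0 if spec.P is None else spec.P.shape[1]
    b = sol[:p]
    qhat = sol[p : p + nq]
    u = sol[p + nq :]
    gebv = None
    if P_full is not None and nq:
        gebv = np.asarray(P_full, dtype=float) @ qhat + u
    elif nq == 0:
        gebv = u.copy()
    return MmeSolution(b, qhat, u, gebv, solver, res, it)


def predict_gebv(solution: MmeSolution, P_full: np.ndarray | None = None) -> np.ndarray:
    """g_i = P_i q + u_i for every animal (P rows imputed where needed)."""
    if P_full is None or solution.q.size == 0:
        return solution.u.copy()
    return np.asarray(P_full, dtype=float) @ solution.q + solution.u
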