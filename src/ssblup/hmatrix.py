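"""Single-step combined relationship machinery.

The single-step model replaces the pedigree kinship A by a matrix H that
agrees with the (blended) genomic matrix G_omega on genotyped animals and
propagates genomic information to their relatives.  Estimation only ever
needs the inverse,

    H^-1 = A^-1 + [[0, 0], [0, G_omega^-1 - Agg^-1]],

which is kept in block form: the sparse pedigree A^-1 over all animals plus
a dense correction on the genotyped rows/columns.  The dense four-block H
itself is provided as a small-scale oracle for equivalence tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .pedigree import RelationshipMatrix


class SingularKinshipError(np.linalg.LinAlgError):
    pass


def _pd_inverse(mat: np.ndarray, name: str) -> np.ndarray:
    """Inverse via symmetric positive-definite (Cholesky) factorization."""
    try:
        c, low = sla.cho_factor(mat, check_finite=False)
    except np.linalg.LinAlgError:
        raise SingularKinshipError(
            f"{name} is not positive definite; blend G with the pedigree block "
            "(G_omega = 0.95 G + 0.05 Agg) before building H"
        ) from None
    return sla.cho_solve((c, low), np.eye(mat.shape[0]), check_finite=False)


@dataclass
class HInverse:
    """H^-1 in block form: sparse A^-1 + dense correction on genotyped ids."""

    ainv: sp.spmatrix
    correction: np.ndarray  # G_omega^-1 - Agg^-1, genotyped x genotyped
    g_index: np.ndarray  # genotyped positions in the global animal order

    def __post_init__(self):
        if self.correction.shape != (len(self.g_index), len(self.g_index)):
            raise ValueError("correction block / genotyped index mismatch")
        if np.max(np.abs(self.correction - self.correction.T)) > 1e-8 * (
            1 + np.max(np.abs(self.correction))
        ):
            raise ValueError("correction block not symmetric")

    @property
    def n(self) -> int:
        return self.ainv.shape[0]

    def correction_inverse(self) -> np.ndarray:
        """Inverse of the correction block, cached (reused across solves)."""
        if getattr(self, "_corr_inv", None) is None:
            g = self.correction.shape[0]
            self._corr_inv = sla.lu_solve(
                sla.lu_factor(self.correction, check_finite=False), np.eye(g),
                check_finite=False,
            )
        return self._corr_inv

    def to_sparse(self) -> sp.csr_matrix:
        """Materialize H^-1 as one sparse matrix."""
        corr = sp.coo_matrix(
            (
                self.correction.ravel(),
                (
                    np.repeat(self.g_index, len(self.g_index)),
                    np.tile(self.g_index, len(self.g_index)),
                ),
            ),
            shape=(self.n, self.n),
        )
        return (self.ainv + corr).tocsr()


def build_H_inverse(
    ainv: sp.spmatrix,
    Gomega: RelationshipMatrix,
    Agg: np.ndarray,
    g_index: np.ndarray,
) -> HInverse:
    """H^-1 = A^-1 + [[0,0],[0, G_omega^-1 - Agg^-1]] on genotyped rows/cols."""
    g_index = np.asarray(g_index, dtype=int)
    if g_index.size == 0:
        raise ValueError("no genotyped animals: single-step H is undefined")
    if Gomega.n != g_index.size or Agg.shape != (g_index.size, g_index.size):
        raise ValueError("G_omega / Agg dimension does not match genotyped index")
    Ginv = _pd_inverse(Gomega.values, "G_omega")
    Agg_inv = _pd_inverse(Agg, "Agg")
    corr = Ginv - Agg_inv
    corr = 0.5 * (corr + corr.T)
    return HInverse(sp.csr_matrix(ainv), corr, g_index)


def build_H(
    A: RelationshipMatrix, Gomega: RelationshipMatrix, g_index: np.ndarray
) -> RelationshipMatrix:
    """Dense H by the four-block formula (small problems / test oracle).

    With n = non-genotyped, g = genotyped and P = Ang Agg^-1:

        H_nn = Ann + P (G_omega - Agg) P',  H_ng = P G_omega,  H_gg = G_omega.
    """
    g_index = np.asarray(g_index, dtype=int)
    n = A.n
    ng_index = np.setdiff1d(np.arange(n), g_index)
    Av = A.values
    Agg = Av[np.ix_(g_index, g_index)]
    Ang = Av[np.ix_(ng_index, g_index)]
    Agg_inv = _pd_inverse(Agg, "Agg")
    P = Ang @ Agg_inv
    Gw = Gomega.values
    H = np.empty_like(Av)
    H[np.ix_(g_index, g_index)] = Gw
    H[np.ix_(ng_index, g_index)] = P @ Gw
    H[np.ix_(g_index, ng_index)] = (P @ Gw).T
    H[np.ix_(ng_index, ng_index)] = Av[np.ix_(ng_index, ng_index)] + P @ (Gw - Agg) @ P.T
    return RelationshipMatrix(H, A.ids, "H")
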