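"""EMMAX-style single-marker mixed-model association scan.

Variance components of y ~ N(Xb, K sigma_u^2 + I sigma_e^2) are estimated
once by REML using a single eigendecomposition of the kinship K and a 1-D
optimization over the variance ratio; each marker is then tested by
generalized least squares with the components held fixed (the EMMAX
approximation), implemented on the rotated (whitened) data so the scan is
O(markers x n).

From the per-marker Wald statistic t = beta/se the scan derives a
log-likelihood ratio LR = t^2 / 2, smooths it by a chromosome-truncated
moving average over each marker and its 20 surrounding neighbours, and
converts the smoothed LR into a posterior probability of association

    PP_j = pi e^{LR_j} / (pi e^{LR_j} + 1 - pi),    pi = 0.001 by default,

which downstream serves as the marker weight d_j in the weighted genomic
relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    loglik: float = np.nan

    def __post_init__(self):
        if self.sigma_u2 < 0 or self.sigma_e2 < 0 or self.sigma_u2 + self.sigma_e2 <= 0:
            raise ValueError("variance components must be non-negative, not both zero")

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)

    @property
    def ratio(self) -> float:
        """delta = sigma_u^2 / sigma_e^2."""
        return self.sigma_u2 / self.sigma_e2


@dataclass
class GwasResult:
    """Per-marker scan results; ``table`` columns:
    marker chrom pos beta se t pvalue lr lr_smooth pp, plus ``tested``."""

    table: pd.DataFrame
    vc: VarianceComponents

    def to_tsv(self, path) -> None:
        cols = ["marker", "chrom", "pos", "beta", "se", "t", "pvalue", "lr", "lr_smooth", "pp"]
        out = self.table[[c for c in cols if c in self.table.columns]]
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _reml_neg_loglik(log_delta, S, Xt, yt, n, p):
    """Negative restricted log-likelihood profiled over beta and sigma_e^2."""
    delta = np.exp(log_delta)
    D = delta * S + 1.0
    w = 1.0 / D
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    if rss <= 0:
        return np.inf
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    _, logdet_XtX = np.linalg.slogdet(Xt.T @ Xt)
    nm = n - p
    ll = -0.5 * (
        nm * np.log(2 * np.pi * rss / nm)
        + nm
        + np.sum(np.log(D))
        + logdet_XtWX
        - logdet_XtX
    )
    return -ll


def estimate_vc_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    h2_bounds: tuple[float, float] = (1e-5, 1 - 1e-5),
    tol: float = 1e-8,
) -> VarianceComponents:
    """REML variance components via one eigendecomposition of K.

    K must be symmetric PSD and n > rank(X) + 1.  The restricted likelihood
    is maximized over log(delta) with delta = sigma_u^2/sigma_e^2, by a
    coarse grid followed by bounded scalar refinement.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    p = np.linalg.matrix_rank(X)
    if n <= p + 1:
        raise ValueError("too few observations for REML")
    K = np.asarray(K, dtype=float)
    S, U = np.linalg.eigh(0.5 * (K + K.T))
    if S.min() < -1e-6 * max(1.0, S.max()):
        raise ValueError(f"kinship not PSD (min eigenvalue {S.min():.3g})")
    S = np.clip(S, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    lo = np.log(h2_bounds[0] / (1 - h2_bounds[0]))
    hi = np.log(h2_bounds[1] / (1 - h2_bounds[1]))
    grid = np.linspace(lo, hi, 40)
    vals = [_reml_neg_loglik(g, S, Xt, yt, n, p) for g in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(a, b),
        args=(S, Xt, yt, n, p),
        method="bounded",
        options={"xatol": tol},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("REML optimization failed to bracket a finite optimum")
    delta = float(np.exp(res.x))
    # profile sigma_e^2 at the optimum
    D = delta * S + 1.0
    w = 1.0 / D
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ XtW, XtW.T @ yt)
    r = yt - Xt @ beta
    sigma_e2 = float(r @ (w * r)) / (n - p)
    return VarianceComponents(delta * sigma_e2, sigma_e2, loglik=-res.fun)


def emmax_scan(
    y: np.ndarray,
    X: np.ndarray,
    M: np.ndarray,
    vc: VarianceComponents,
    K: np.ndarray,
    markers: pd.DataFrame | None = None,
) -> GwasResult:
    """GLS per marker with V = K sigma_u^2 + I sigma_e^2 held fixed.

    Data are rotated by the eigenvectors of K (whitening), X is projected
    out under the V^-1 inner product, and every marker is tested at once:
    beta_j and se_j = (m_j'^perp V^-1 m_j^perp)^(-1/2) on the X-adjusted
    marker, with a standard-normal p-value on t = beta/se.  Markers whose
    adjusted variance vanishes (monomorphic or collinear with X) are
    flagged untested and carry LR = 0 into the smoothing step.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = np.asarray(M, dtype=float)
    n, m = M.shape
    S, U = np.linalg.eigh(0.5 * (np.asarray(K) + np.asarray(K).T))
    S = np.clip(S, 0.0, None)
    w = 1.0 / (vc.ratio * S + 1.0)  # V^-1 = U diag(w) U' / sigma_e^2
    yt = U.T @ y
    Xt = U.T @ X
    Mt = U.T @ M
    XtW = Xt * w[:, None]
    XtWX_inv = np.linalg.inv(Xt.T @ XtW)
    # project X out of y and every marker under the weighted inner product
    y_adj = yt - Xt @ (XtWX_inv @ (XtW.T @ yt))
    M_adj = Mt - Xt @ (XtWX_inv @ (XtW.T @ Mt))
    denom = np.einsum("ij,ij->j", M_adj, w[:, None] * M_adj)
    scale = np.einsum("ij,ij->j", Mt, Mt)
    tested = denom > 1e-10 * np.maximum(scale, 1.0)
    num = M_adj.T @ (w * y_adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(tested, num / denom, np.nan)
        se = np.where(tested, np.sqrt(vc.sigma_e2 / denom), np.nan)
        t = beta / se
    pval = np.where(tested, 2.0 * stats.norm.sf(np.abs(t)), 1.0)
    if markers is None:
        markers = pd.DataFrame(
            {"marker": [f"m{j}" for j in range(m)], "chrom": 1, "pos": np.arange(m)}
        )
    tab = markers[["marker", "chrom", "pos"]].reset_index(drop=True).copy()
    tab["beta"] = beta
    tab["se"] = se
    tab["t"] = t
    tab["pvalue"] = pval
    tab["tested"] = tested
    return GwasResult(tab, vc)


def compute_lr(result: GwasResult) -> GwasResult:
    """Log-likelihood ratio per marker: LR_j = (beta_j / se_j)^2 / 2."""
    tab = result.table
    t = tab["t"].to_numpy()
    lr = np.where(tab["tested"].to_numpy(), 0.5 * t * t, 0.0)
    tab["lr"] = np.nan_to_num(lr)
    return result

def smooth_lr(result: GwasResult, n_neighbors: int = 20) -> GwasResult:
    """Moving average of LR over each marker and its surrounding neighbours.

    The window covers the marker plus ``n_neighbors // 2`` markers on each
    side and never crosses a chromosome boundary: edge windows simply
    average over the values available.
    """
    tab = result.table
    key = tab[["chrom", "pos"]]
    if not key.sort_values(["chrom", "pos"], kind="stable").index.equals(key.index):
        raise ValueError("marker map must be sorted by (chrom, pos) before smoothing")
    half = n_neighbors // 2
    sm = (
        tab.groupby("chrom", sort=False)["lr"]
        .transform(lambda s: s.rolling(2 * half + 1, center=True, min_periods=1).mean())
    )
    tab["lr_smooth"] = sm.to_numpy()
    return result


def compute_pp(result: GwasResult, prior: float = 0.001) -> GwasResult:
    """Posterior probability of association from the smoothed LR.

    PP_j = pi e^{LR_j} / (pi e^{LR_j} + 1 - pi); computed in a form that is
    stable for large LR.  These values are the marker weights of the
    weighted genomic relationship matrix.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError("prior probability must lie in (0, 1)")
    lr = result.table["lr_smooth"].to_numpy()
    pp = 1.0 / (1.0 + np.exp(np.log((1.0 - prior) / prior) - lr))
    result.table["pp"] = pp
    return result


def run_scan(
    y, X, M, K, markers=None, n_neighbors: int = 20, prior: float = 0.001,
    vc: VarianceComponents | None = None,
) -> GwasResult:
    """Convenience pipeline: REML -> EMMAX scan -> LR -> smoothing -> PP."""
    if vc is None:
        vc = estimate_vc_reml(y, X, K)
    res = emmax_scan(y, X, M, vc, K, markers=markers)
    res = compute_lr(res)
    res = smooth_lr(res, n_neighbors=n_neighbors)
    res = compute_pp(res, prior=prior)
    return res
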