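"""Genotype I/O, marker quality control and genomic relationship matrices.

Genotypes are additively coded 0/1/2 copies of the counted allele, with
``NaN`` for missing calls.  After QC (minor-allele frequency, call rate and
a 1-df Hardy-Weinberg chi-square), missing entries are mean-imputed so that
they contribute zero to the centered matrix ``Z``.

The genomic relationship matrix follows VanRaden:

    G = Z diag(d) Z' / sum_j 2 p_j (1 - p_j),   Z_ij = M_ij - 2 p_j,

where ``d_j`` are per-marker weights (all ones gives the unweighted ``Gu``).
By default a supplied weight vector is rescaled to mean 1 so that weighted
and unweighted G share a scale.  For numerical stability among genotyped
animals, G is blended with the pedigree block: ``G_omega = 0.95 G + 0.05 Agg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import RelationshipMatrix


@dataclass
class GenotypeData:
    """0/1/2 genotype matrix plus marker map and (post-QC) allele frequencies."""

    matrix: np.ndarray  # animals x markers, float, NaN = missing
    markers: pd.DataFrame  # columns: marker, chrom, pos
    ids: np.ndarray  # animal ids, ordered
    allele_freq: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.markers)):
            raise ValueError("genotype matrix shape does not match ids x markers")
        if self.markers["marker"].duplicated().any():
            raise ValueError("duplicate marker ids")

    @property
    def n_animals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]

    def subset_animals(self, index: np.ndarray) -> "GenotypeData":
        return GenotypeData(self.matrix[index], self.markers, self.ids[index], self.allele_freq)


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_cr: int
    n_removed_hwe: int
    n_retained: int


def observed_allele_freq(matrix: np.ndarray) -> np.ndarray:
    """Frequency of the counted allele per marker, ignoring missing calls."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix, axis=0) / 2.0


def hwe_pvalues(matrix: np.ndarray) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg test per marker (no continuity correction).

    Observed genotype counts among non-missing calls are compared with the
    expectation at the observed allele frequency; monomorphic markers get
    p = 1 (they are removed by the MAF filter anyway).
    """
    obs0 = np.nansum(matrix == 0, axis=0).astype(float)
    obs1 = np.nansum(matrix == 1, axis=0).astype(float)
    obs2 = np.nansum(matrix == 2, axis=0).astype(float)
    n = obs0 + obs1 + obs2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * obs2 + obs1) / (2 * n)
        q = 1 - p
        exp = np.stack([n * q * q, 2 * n * p * q, n * p * p])
        chi2 = np.nansum((np.stack([obs0, obs1, obs2]) - exp) ** 2 / exp, axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0) | (p >= 1) | (n == 0)
    pval[mono] = 1.0
    return pval


def qc_filter(
    geno: GenotypeData,
    maf_min: float = 0.05,
    cr_min: float = 0.95,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeData, QCReport]:
    """Remove markers failing MAF/call-rate/HWE filters; impute the rest.

    Returns the filtered data (missing entries set to the column mean
    ``2 p_j``, allele frequencies attached) and a per-filter removal report.
    """
    M = geno.matrix
    freq = observed_allele_freq(M)
    maf = np.minimum(freq, 1 - freq)
    cr = np.mean(~np.isnan(M), axis=0)
    hwe_p = hwe_pvalues(M)
    fail_maf = ~(maf >= maf_min)
    fail_cr = cr < cr_min
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_maf | fail_cr | fail_hwe)
    if not np.any(keep):
        raise ValueError("all markers removed by QC")
    Mk = M[:, keep].copy()
    pk = observed_allele_freq(Mk)
    # mean imputation: missing -> 2p, so the entry centers to 0 in Z
    miss = np.isnan(Mk)
    if miss.any():
        Mk[miss] = np.broadcast_to(2 * pk, Mk.shape)[miss]
    out = GenotypeData(
        Mk, geno.markers.loc[keep].reset_index(drop=True), geno.ids, allele_freq=pk
    )
    report = QCReport(
        n_input=geno.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_cr=int((fail_cr & ~fail_maf).sum()),
        n_removed_hwe=int((fail_hwe & ~fail_maf & ~fail_cr).sum()),
        n_retained=int(keep.sum()),
    )
    return out, report


def center_matrix(geno: GenotypeData, freq: np.ndarray | None = None) -> np.ndarray:
    """Centered genotype matrix Z with Z_ij = M_ij - 2 p_j."""
    p = geno.allele_freq if freq is None else freq
    if p is None:
        p = observed_allele_freq(geno.matrix)
    return geno.matrix - 2.0 * p


def normalize_weights(weights: np.ndarray) -> np.ndarray:
    """Rescale non-negative marker weights to mean 1."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    m = w.mean()
    if m <= 0:
        raise ValueError("weights must have positive mean")
    return w / m


def build_G(
    geno: GenotypeData,
    weights: np.ndarray | None = None,
    freq: np.ndarray | None = None,
    normalize: bool = True,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix, optionally marker-weighted.

    With ``weights=None`` (or all ones) this is the unweighted ``Gu``.  The
    denominator ``sum_j 2 p_j (1-p_j)`` excludes the weights; by default the
    weight vector is rescaled to mean 1 (``normalize=False`` uses it raw).
    """
    p = freq if freq is not None else geno.allele_freq
    if p is None:
        p = observed_allele_freq(geno.matrix)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    Z = geno.matrix - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    kind = "Gu"
    if weights is None:
        G = Z @ Z.T / denom
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (geno.n_markers,):
            raise ValueError("weights length does not match marker count")
        if normalize:
            w = normalize_weights(w)
        G = (Z * w) @ Z.T / denom
        kind = "G"
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, geno.ids, kind)


def blend_G(
    G: RelationshipMatrix, Agg: RelationshipMatrix, g_weight: float = 0.95
) -> RelationshipMatrix:
    """G_omega = g_weight * G + (1 - g_weight) * Agg (default 0.95/0.05)."""
    if G.n != Agg.n or not np.array_equal(G.ids, Agg.ids):
        raise ValueError("G and Agg id order mismatch")
    return RelationshipMatrix(g_weight * G.values + (1 - g_weight) * Agg.values, G.ids, "Gomega")


# ---------------------------------------------------------------------------
# I/O: PLINK .raw-style TSV (id + one 0/1/2 column per marker) + marker map
# ---------------------------------------------------------------------------

def read_genotypes(geno_path, map_path) -> GenotypeData:
    gm = pd.read_csv(map_path, sep=None, engine="python")
    gm.columns = [c.strip().lower() for c in gm.columns]
    for c in ("marker", "chrom", "pos"):
        if c not in gm.columns:
            raise ValueError(f"marker map lacks required column {c!r}")
    df = pd.read_csv(geno_path, sep=None, engine="python", na_values=["NA"])
    id_col = df.columns[0]
    ids = df[id_col].astype(str).to_numpy(dtype=object)
    markers = [c for c in df.columns if c != id_col]
    if list(markers) != list(gm["marker"].astype(str)):
        raise ValueError("genotype columns do not match marker map order")
    M = df[markers].to_numpy(dtype=float)
    return GenotypeData(M, gm[["marker", "chrom", "pos"]], ids)


def write_genotypes(geno: GenotypeData, geno_path, map_path) -> None:
    df = pd.DataFrame(geno.matrix, columns=geno.markers["marker"].astype(str))
    df.insert(0, "id", [str(a) for a in geno.ids])
    df.to_csv(geno_path, sep="\t", index=False, na_rep="NA")
    geno.markers[["marker", "chrom", "pos"]].to_csv(map_path, sep="\t", index=False)
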